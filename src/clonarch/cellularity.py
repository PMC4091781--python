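"""Maximum-likelihood classification of sample cellularity.

A sorted well may contain one cell or two. In a single cell every somatic
variant it carries sits at true VAF 0.5 (diploid heterozygous); in a two-cell
mixture, variants heterozygous in exactly one of the two cells dilute to
0.25. Variant read counts at cluster loci are modeled per locus as
Bin(n, p) with p = f(1-e) + (1-f)e, where f is the source VAF implied by a
candidate pair of clones (0, 0.25, or 0.5 per cluster) and e is a per-cluster
cumulative error rate estimated from cells of other subjects, which are
reference at these positions and therefore act as mutual controls.

All unordered pairs over {clones, non-tumor} are scored. Pairs of two
identical sources form the clonally-pure null (one cell, or two cells of the
same clone — the model cannot distinguish these); pairs of distinct sources
are the mixed alternative. A likelihood-ratio statistic 2(l_mixed - l_pure),
floored at zero, is referred to a one-sided chi-square with one degree of
freedom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import NON_TUMOR, ClonalArchitecture, LocusCatalog, ReadCountTable

__all__ = [
    "ErrorProfile",
    "MixtureHypothesis",
    "CellularityResult",
    "estimate_error_profile",
    "site_success_prob",
    "hypothesis_loglik",
    "classify_sample",
    "classify_all",
]

_E_FLOOR = 1e-6
_E_CEIL = 0.5 - 1e-9


@dataclass(frozen=True)
class ErrorProfile:
    """Per-cluster cumulative error rate (WGA + library + sequencing)."""

    rates: Mapping[str, float]

    def __post_init__(self) -> None:
        for c, e in self.rates.items():
            if not 0.0 <= e < 0.5:
                raise ValueError(f"error rate for {c!r} outside [0, 0.5): {e}")

    def __getitem__(self, cluster: str) -> float:
        return self.rates[cluster]


@dataclass(frozen=True)
class MixtureHypothesis:
    """An unordered pair of source clones for a (putative) two-cell sample.

    ``source_a == source_b`` represents the clonally-pure case. The implied
    per-cluster source VAF is the carried-allele fraction over the four
    pooled alleles: 0.5 if both sources carry the cluster, 0.25 if exactly
    one does, 0 otherwise.
    """

    source_a: str
    source_b: str

    @property
    def is_pure(self) -> bool:
        return self.source_a == self.source_b

    def cluster_vaf(self, arch: ClonalArchitecture, cluster: str) -> float:
        n_carriers = sum(
            cluster in arch.lineage_clusters(src) for src in (self.source_a, self.source_b)
        )
        return n_carriers / 4.0

    def __str__(self) -> str:
        return f"{self.source_a}+{self.source_b}"


@dataclass(frozen=True)
class CellularityResult:
    sample_id: str
    best_pure: MixtureHypothesis
    best_pure_loglik: float
    best_mixed: MixtureHypothesis
    best_mixed_loglik: float
    lrt: float
    p_value: float
    classification: str  # "pure" | "mixed" | "indeterminate"
    n_loci: int


def estimate_error_profile(
    control_counts: ReadCountTable,
    catalog: LocusCatalog,
    subject: str,
) -> ErrorProfile:
    """Estimate per-cluster error rates from other subjects' cells.

    Pools reads across all control samples at ``subject``'s somatic cluster
    loci (where controls are expected reference) and takes the pooled VAF per
    cluster, clipped to [1e-6, 0.5).
    """
    cluster_map = catalog.cluster_map(subject, include_outliers=False)
    df = control_counts.entries.merge(
        cluster_map.rename("cluster"), left_on="locus_id", right_index=True
    )
    df = df[(df["ref_reads"] + df["var_reads"]) > 0]
    if df.empty:
        raise ValueError(f"no covered control loci for subject {subject!r}")
    pooled = df.groupby("cluster")[["ref_reads", "var_reads"]].sum()
    rates = {}
    for cluster in cluster_map.unique():
        if cluster in pooled.index:
            row = pooled.loc[cluster]
            e = row["var_reads"] / (row["ref_reads"] + row["var_reads"])
        else:
            e = 0.0
        rates[cluster] = float(np.clip(e, _E_FLOOR, _E_CEIL))
    return ErrorProfile(rates=rates)


def site_success_prob(f: float, e: float) -> float:
    """Variant-read probability p = f(1-e) + (1-f)e.

    Symmetric in the error: at f=0.5 the error cancels and p=0.5 exactly.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f outside [0, 1]: {f}")
    if not 0.0 <= e <= 1.0:
        raise ValueError(f"e outside [0, 1]: {e}")
    return f * (1.0 - e) + (1.0 - f) * e


def hypothesis_loglik(
    sample_counts: pd.DataFrame,
    hyp: MixtureHypothesis,
    arch: ClonalArchitecture,
    err: ErrorProfile,
    cluster_map: pd.Series,
) -> float:
    """Summed log binomial likelihood of one sample's cluster-locus counts.

    ``sample_counts`` is one sample's slice of a read-count table;
    ``cluster_map`` maps locus_id -> cluster. Loci with zero depth (or
    absent from the map) contribute nothing; an empty selection gives 0.
    """
    df = sample_counts.merge(cluster_map.rename("cluster"), left_on="locus_id", right_index=True)
    depth = (df["ref_reads"] + df["var_reads"]).to_numpy()
    keep = depth > 0
    if not keep.any():
        return 0.0
    df = df[keep]
    depth = depth[keep]
    k = df["var_reads"].to_numpy()
    p_by_cluster = {
        c: site_success_prob(hyp.cluster_vaf(arch, c), err[c])
        for c in df["cluster"].unique()
    }
    p = df["cluster"].map(p_by_cluster).to_numpy(dtype=float)
    return float(np.sum(stats.binom.logpmf(k, depth, p)))


def _enumerate_hypotheses(arch: ClonalArchitecture) -> list[MixtureHypothesis]:
    sources = [c.id for c in arch.clones] + [NON_TUMOR]
    return [
        MixtureHypothesis(a, b)
        for a, b in itertools.combinations_with_replacement(sources, 2)
    ]


def classify_sample(
    sample_counts: pd.DataFrame,
    arch: ClonalArchitecture,
    err: ErrorProfile,
    catalog: LocusCatalog,
    alpha: float = 0.05,
    sample_id: str | None = None,
) -> CellularityResult:
    """Classify one sample as clonally pure or a two-clone mixture.

    Scores every unordered pair over {clones, non-tumor}; the best same-
    source pair is the pure null, the best distinct-source pair the mixed
    alternative. LRT = max(0, 2(l_mixed - l_pure)) with a one-sided
    chi-square(1) tail; classification is "mixed" iff p < alpha.
    Germline heterozygous loci carry no signal (f = 0.5 under every
    hypothesis) and are excluded by restricting to somatic cluster loci.
    """
    sid = sample_id or str(sample_counts["sample_id"].iloc[0])
    cluster_map = catalog.cluster_map(arch.subject, include_outliers=False)
    df = sample_counts[sample_counts["locus_id"].isin(cluster_map.index)]
    n_loci = int(((df["ref_reads"] + df["var_reads"]) > 0).sum())

    hyps = _enumerate_hypotheses(arch)
    logliks = {
        h: hypothesis_loglik(sample_counts, h, arch, err, cluster_map) for h in hyps
    }
    pure = {h: ll for h, ll in logliks.items() if h.is_pure}
    mixed = {h: ll for h, ll in logliks.items() if not h.is_pure}
    # deterministic tie-break: higher loglik, then lexicographic hypothesis
    best_pure = max(pure, key=lambda h: (pure[h], str(h)))
    best_mixed = max(mixed, key=lambda h: (mixed[h], str(h)))

    if n_loci == 0:
        return CellularityResult(
            sample_id=sid,
            best_pure=best_pure,
            best_pure_loglik=0.0,
            best_mixed=best_mixed,
            best_mixed_loglik=0.0,
            lrt=0.0,
            p_value=1.0,
            classification="indeterminate",
            n_loci=0,
        )

    lrt = max(0.0, 2.0 * (mixed[best_mixed] - pure[best_pure]))
    p = float(stats.chi2.sf(lrt, df=1))
    return CellularityResult(
        sample_id=sid,
        best_pure=best_pure,
        best_pure_loglik=pure[best_pure],
        best_mixed=best_mixed,
        best_mixed_loglik=mixed[best_mixed],
        lrt=lrt,
        p_value=p,
        classification="mixed" if p < alpha else "pure",
        n_loci=n_loci,
    )


def classify_all(
    counts: ReadCountTable,
    arch: ClonalArchitecture,
    err: ErrorProfile,
    catalog: LocusCatalog,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify every sample in a read-count table; returns a tidy table
    mirroring the per-sample cellularity summary (sample, best pure, best
    mixed, LRT, p, classification)."""
    rows = []
    for sid in counts.sample_ids:
        res = classify_sample(
            counts.for_sample(sid), arch, err, catalog, alpha=alpha, sample_id=sid
        )
        rows.append(
            {
                "sample_id": res.sample_id,
                "best_pure": str(res.best_pure),
                "best_pure_loglik": res.best_pure_loglik,
                "best_mixed": str(res.best_mixed),
                "best_mixed_loglik": res.best_mixed_loglik,
                "lrt": res.lrt,
                "p_value": res.p_value,
                "classification": res.classification,
                "n_loci": res.n_loci,
            }
        )
    return pd.DataFrame(rows)
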