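"""Genotype calling from read counts and benchmarking against known truth.

Calls are made per site by maximum binomial likelihood over three diploid
hypotheses — homozygous reference (variant-read probability e), heterozygous
(0.5), homozygous variant (1 - e) — gated on a minimum depth (25x by
default, the reference dataset's callable-site rule) and a minimum
variant-read floor that protects the false-positive budget at high depth.

Benchmarking follows allele-level confusion accounting at sites with known
truth: a call is "positive" when at least one non-reference allele is
called. Sensitivity is undefined at homozygous-reference truth (no true
positives exist there) and specificity undefined at truth carrying a
variant allele, so rates are stratified by truth zygosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import HOMREF, HET, HOMVAR, ReadCountTable

__all__ = [
    "NOCALL",
    "CallerParams",
    "GenotypeMatrix",
    "BenchmarkReport",
    "call_site",
    "call_matrix",
    "benchmark",
    "ado_symmetry_test",
    "locus_dropout_concordance",
]

NOCALL = -1

GENOTYPE_TSV_CODES = {NOCALL: ".", HOMREF: "0", HET: "1", HOMVAR: "2"}


@dataclass(frozen=True)
class CallerParams:
    """Binomial genotyper settings.

    min_depth : callable-site gate; sites below it are NOCALL.
    seq_error : per-read miscall rate shared across all cells (the joint-
        calling analog: one error model estimated over the cohort).
    min_var_reads : variant-read floor for any non-HOMREF call.
    """

    min_depth: int = 25
    seq_error: float = 0.01
    min_var_reads: int = 3

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.0 < self.seq_error < 0.5:
            raise ValueError("seq_error must be in (0, 0.5)")
        if self.min_var_reads < 0:
            raise ValueError("min_var_reads must be >= 0")


@dataclass
class GenotypeMatrix:
    """Cells x loci genotype calls in {NOCALL, HOMREF, HET, HOMVAR}."""

    calls: pd.DataFrame
    callable_threshold: int = 25

    def __post_init__(self) -> None:
        self.calls = self.calls.astype(np.int8)
        valid = {NOCALL, HOMREF, HET, HOMVAR}
        bad = set(np.unique(self.calls.to_numpy())) - valid
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")

    @property
    def cells(self) -> pd.Index:
        return self.calls.index

    @property
    def loci(self) -> pd.Index:
        return self.calls.columns

    def callable_fraction(self) -> pd.Series:
        """Fraction of loci with a call (depth >= threshold), per cell."""
        return (self.calls != NOCALL).mean(axis=1).rename("callable_fraction")

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.loc[:, list(locus_ids)], self.callable_threshold)


def _loglik_table(depth: np.ndarray, var: np.ndarray, e: float) -> np.ndarray:
    """Log-likelihoods of (HOMREF, HET, HOMVAR), stacked on axis 0."""
    out = np.stack(
        [
            stats.binom.logpmf(var, depth, e),
            stats.binom.logpmf(var, depth, 0.5),
            stats.binom.logpmf(var, depth, 1.0 - e),
        ]
    )
    return out


def call_site(ref_reads: int, var_reads: int, params: CallerParams = CallerParams()) -> int:
    """Call one site. Returns a genotype code (NOCALL/HOMREF/HET/HOMVAR)."""
    if ref_reads < 0 or var_reads < 0:
        raise ValueError("read counts must be >= 0")
    depth = ref_reads + var_reads
    if depth < params.min_depth:
        return NOCALL
    ll = _loglik_table(np.array([depth]), np.array([var_reads]), params.seq_error)[:, 0]
    # argmax order HOMREF, HET, HOMVAR: exact ties resolve toward HOMREF
    g = int(np.argmax(ll))
    if g != HOMREF and var_reads < params.min_var_reads:
        return HOMREF
    return g


def call_matrix(counts: ReadCountTable, params: CallerParams = CallerParams()) -> GenotypeMatrix:
    """Apply the binomial genotyper elementwise over a read-count table."""
    if len(counts) == 0:
        raise ValueError("empty read-count table")
    depth, var = counts.pivot()
    d = depth.to_numpy(dtype=np.int64)
    v = var.to_numpy(dtype=np.int64)
    ll = _loglik_table(d, v, params.seq_error)
    g = np.argmax(ll, axis=0).astype(np.int8)
    g[(g != HOMREF) & (v < params.min_var_reads)] = HOMREF
    g[d < params.min_depth] = NOCALL
    calls = pd.DataFrame(g, index=depth.index.rename("cell_id"), columns=depth.columns)
    return GenotypeMatrix(calls=calls, callable_threshold=params.min_depth)


@dataclass
class BenchmarkReport:
    """Allele-level confusion accounting at callable sites with known truth.

    Counts follow the convention: positive call = at least one non-reference
    allele called. Rates are reported overall and stratified by truth
    zygosity; a rate whose denominator is empty is NaN (undefined).
    """

    tp: int
    tn: int
    fp: int
    fn: int
    by_truth: pd.DataFrame = field(repr=False)

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else float("nan")

    @property
    def fnr(self) -> float:
        t = self.tpr
        return float("nan") if np.isnan(t) else 1.0 - t


def benchmark(calls: GenotypeMatrix, truth: pd.DataFrame) -> BenchmarkReport:
    """Score calls against a truth matrix (codes {0,1,2}) over callable sites.

    ``truth`` must cover every locus (and cell) present in ``calls``.
    """
    missing_loci = set(calls.loci) - set(truth.columns)
    if missing_loci:
        raise KeyError(f"loci absent from truth: {sorted(missing_loci)[:5]} ...")
    missing_cells = set(calls.cells) - set(truth.index)
    if missing_cells:
        raise KeyError(f"cells absent from truth: {sorted(missing_cells)[:5]} ...")
    t = truth.loc[calls.cells, calls.loci].to_numpy()
    c = calls.calls.to_numpy()
    called = c != NOCALL
    call_pos = called & (c != HOMREF)
    call_neg = called & (c == HOMREF)
    truth_pos = t != HOMREF
    rows = {}
    for label, mask in (
        ("homozygous_ref", t == HOMREF),
        ("heterozygous", t == HET),
        ("homozygous_var", t == HOMVAR),
    ):
        tp = int(np.sum(call_pos & truth_pos & mask))
        tn = int(np.sum(call_neg & ~truth_pos & mask))
        fp = int(np.sum(call_pos & ~truth_pos & mask))
        fn = int(np.sum(call_neg & truth_pos & mask))
        rows[label] = {
            "TP": tp,
            "TN": tn,
            "FP": fp,
            "FN": fn,
            "TPR": tp / (tp + fn) if (tp + fn) else np.nan,
            "FPR": fp / (fp + tn) if (fp + tn) else np.nan,
            "FNR": fn / (tp + fn) if (tp + fn) else np.nan,
        }
    by_truth = pd.DataFrame(rows).T
    return BenchmarkReport(
        tp=int(np.sum(call_pos & truth_pos)),
        tn=int(np.sum(call_neg & ~truth_pos)),
        fp=int(np.sum(call_pos & ~truth_pos)),
        fn=int(np.sum(call_neg & truth_pos)),
        by_truth=by_truth,
    )


@dataclass(frozen=True)
class AdoSymmetryResult:
    homref_errors: int
    homvar_errors: int
    p_value: float
    degenerate: bool


def ado_symmetry_test(calls: GenotypeMatrix, truth_het_loci: Sequence[str]) -> AdoSymmetryResult:
    """Test whether reference and variant alleles drop at equal rates.

    At known heterozygous loci, erroneous homozygous calls are counted per
    direction and compared with a two-sided exact binomial test against 0.5.
    With zero errors the result is degenerate (p = 1, flagged).
    """
    sub = calls.subset_loci(truth_het_loci).calls.to_numpy()
    n_ref = int(np.sum(sub == HOMREF))
    n_var = int(np.sum(sub == HOMVAR))
    total = n_ref + n_var
    if total == 0:
        return AdoSymmetryResult(0, 0, 1.0, degenerate=True)
    p = stats.binomtest(n_ref, total, 0.5, alternative="two-sided").pvalue
    return AdoSymmetryResult(n_ref, n_var, float(p), degenerate=False)


def locus_dropout_concordance(fnr_by_locus: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Pairwise squared Pearson correlation of per-locus dropout rates.

    ``fnr_by_locus`` maps a group label (e.g. a subject) to a Series of
    per-locus false-negative (dropout) rates over shared heterozygous loci.
    Returns a tidy DataFrame (group_a, group_b, n_loci, r_squared).
    """
    groups = list(fnr_by_locus)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            joined = pd.concat([fnr_by_locus[a], fnr_by_locus[b]], axis=1, join="inner").dropna()
            if len(joined) < 3:
                raise ValueError(f"fewer than 3 shared loci between {a!r} and {b!r}")
            x, y = joined.iloc[:, 0], joined.iloc[:, 1]
            if x.std() == 0 or y.std() == 0:
                r2 = np.nan
            else:
                r2 = float(stats.pearsonr(x, y).statistic ** 2)
            rows.append({"group_a": a, "group_b": b, "n_loci": len(joined), "r_squared": r2})
    return pd.DataFrame(rows)
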