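"""Simulation of tumor clonal architectures and single-cell targeted sequencing.

A tumor is modeled as a hierarchy of clones: the founding clone acquires a
cluster of somatic SNVs, and each subclone descends from a parent clone by
acquiring one additional mutation cluster. A sample is a mixture of these
clones plus a non-tumor fraction. Every somatic variant is heterozygous at a
diploid locus in the cells that carry it, so its expected bulk variant allele
fraction (VAF) is half the cumulative prevalence of the clones carrying it.

Single-cell libraries are produced by whole-genome amplification (WGA), which
introduces two dominant artifacts emulated here:

* **allelic dropout (ADO)** — with probability ``ado_prob`` one of the two
  alleles at a heterozygous site is lost before amplification, rendering the
  site homozygous-appearing; the lost allele is chosen uniformly, so
  reference and variant alleles drop at equal rates;
* **non-uniform coverage** — per-locus depth follows an overdispersed
  (negative binomial) distribution with a zero point mass for loci that fail
  to amplify at all, so only ~55% of targeted sites reach the 25x callable
  threshold at the reference dataset's mean single-cell coverage of ~113x.

Sequencing miscalls are applied on top at a per-read rate ``seq_error``.

Two-cell ("doublet") samples pool the four alleles of two cells with equal
amplification by default: a site heterozygous in exactly one of the two cells
dilutes to an expected VAF of 0.25, while shared heterozygous sites stay at
0.5 — the signature used downstream to classify sample cellularity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HOMREF",
    "HET",
    "HOMVAR",
    "NON_TUMOR",
    "ArchitectureError",
    "Clone",
    "ClonalArchitecture",
    "LocusCatalog",
    "WgaNoiseModel",
    "ReadCountTable",
    "SingleCellSim",
    "build_architecture",
    "expected_bulk_vaf",
    "study_architectures",
    "build_locus_catalog",
    "study_catalog",
    "simulate_bulk_counts",
    "simulate_cells",
    "simulate_multiplet",
]

# Genotype codes shared across the package (the genotype module adds NOCALL).
HOMREF = 0
HET = 1
HOMVAR = 2

#: Label used for cells that belong to no tumor clone.
NON_TUMOR = "non_tumor"

_FREQ_TOL = 1e-9


class ArchitectureError(ValueError):
    """Raised when a clonal-architecture description violates its invariants."""


@dataclass(frozen=True)
class Clone:
    """One clonal population.

    Parameters
    ----------
    id : str
        Clone label, unique within a subject.
    parent : str or None
        Parent clone label; ``None`` marks the founding clone.
    frequency : float
        Fraction of all cells (tumor + non-tumor) belonging to this clone.
    new_cluster : str
        Label of the mutation cluster this clone introduces. A clone carries
        its own cluster plus every cluster of its ancestors.
    """

    id: str
    parent: str | None
    frequency: float
    new_cluster: str


@dataclass(frozen=True)
class ClonalArchitecture:
    """A validated clone hierarchy with population frequencies."""

    subject: str
    clones: tuple[Clone, ...]
    non_tumor_fraction: float

    def __post_init__(self) -> None:
        if not self.clones:
            raise ArchitectureError("architecture needs at least one clone")
        if not 0.0 <= self.non_tumor_fraction <= 1.0:
            raise ArchitectureError("non_tumor_fraction outside [0, 1]")
        ids = [c.id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ArchitectureError("duplicate clone ids")
        clusters = [c.new_cluster for c in self.clones]
        if len(set(clusters)) != len(clusters):
            raise ArchitectureError("each clone must introduce a distinct cluster")
        roots = [c for c in self.clones if c.parent is None]
        if len(roots) != 1:
            raise ArchitectureError(
                f"exactly one founding clone required, found {len(roots)}"
            )
        by_id = {c.id: c for c in self.clones}
        for c in self.clones:
            if c.parent is not None and c.parent not in by_id:
                raise ArchitectureError(f"clone {c.id!r} has unknown parent {c.parent!r}")
            if c.frequency <= 0.0:
                raise ArchitectureError(f"clone {c.id!r} frequency must be > 0")
        # cycle check: walking up from every clone must terminate at the root
        for c in self.clones:
            seen = set()
            node: Clone | None = c
            while node is not None:
                if node.id in seen:
                    raise ArchitectureError("cyclic parentage")
                seen.add(node.id)
                node = by_id[node.parent] if node.parent is not None else None
        total = sum(c.frequency for c in self.clones) + self.non_tumor_fraction
        if abs(total - 1.0) > _FREQ_TOL:
            raise ArchitectureError(
                f"clone frequencies + non_tumor_fraction sum to {total}, expected 1"
            )

    # -- hierarchy queries ---------------------------------------------------

    def clone(self, clone_id: str) -> Clone:
        for c in self.clones:
            if c.id == clone_id:
                return c
        raise KeyError(f"unknown clone {clone_id!r}")

    @property
    def root(self) -> Clone:
        return next(c for c in self.clones if c.parent is None)

    def children(self, clone_id: str) -> list[Clone]:
        return [c for c in self.clones if c.parent == clone_id]

    def descendants(self, clone_id: str) -> list[Clone]:
        out: list[Clone] = []
        stack = [clone_id]
        while stack:
            cur = stack.pop()
            for child in self.children(cur):
                out.append(child)
                stack.append(child.id)
        return out

    def lineage_clusters(self, clone_id: str) -> tuple[str, ...]:
        """Clusters carried by cells of ``clone_id`` (root-first order).

        The ``non_tumor`` pseudo-clone carries no clusters.
        """
        if clone_id == NON_TUMOR:
            return ()
        by_id = {c.id: c for c in self.clones}
        path: list[str] = []
        node: Clone | None = self.clone(clone_id)
        while node is not None:
            path.append(node.new_cluster)
            node = by_id[node.parent] if node.parent is not None else None
        return tuple(reversed(path))

    def clusters(self) -> list[str]:
        """All cluster labels, ordered by their introducing clone's depth."""
        depth = {c.id: len(self.lineage_clusters(c.id)) for c in self.clones}
        ordered = sorted(self.clones, key=lambda c: (depth[c.id], c.id))
        return [c.new_cluster for c in ordered]

    def clone_for_cluster(self, cluster: str) -> Clone:
        for c in self.clones:
            if c.new_cluster == cluster:
                return c
        raise KeyError(f"unknown cluster {cluster!r} in subject {self.subject!r}")

    def cluster_parent(self, cluster: str) -> str | None:
        """Parent cluster in the hierarchy, or None for the founding cluster."""
        clone = self.clone_for_cluster(cluster)
        if clone.parent is None:
            return None
        return self.clone(clone.parent).new_cluster

    def cumulative_prevalence(self, cluster: str) -> float:
        """Fraction of all cells carrying ``cluster``: the introducing clone
        plus every descendant clone."""
        clone = self.clone_for_cluster(cluster)
        return clone.frequency + sum(d.frequency for d in self.descendants(clone.id))

    def expected_bulk_vaf(self, cluster: str) -> float:
        """Expected bulk VAF of a cluster: half its cumulative prevalence
        (every carrier is heterozygous diploid)."""
        return self.cumulative_prevalence(cluster) / 2.0

    def clone_frequencies(self, include_non_tumor: bool = True) -> dict[str, float]:
        out = {c.id: c.frequency for c in self.clones}
        if include_non_tumor:
            out[NON_TUMOR] = self.non_tumor_fraction
        return out

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "non_tumor_fraction": self.non_tumor_fraction,
            "clones": [
                {
                    "id": c.id,
                    "parent": c.parent,
                    "frequency": c.frequency,
                    "cluster": c.new_cluster,
                }
                for c in self.clones
            ],
        }


def build_architecture(spec: Mapping) -> ClonalArchitecture:
    """Build and validate a :class:`ClonalArchitecture` from a plain mapping.

    Expected keys: ``subject``, ``non_tumor_fraction``, ``clones`` (a list of
    mappings with ``id``, ``parent``, ``frequency``, ``cluster``).
    """
    try:
        clones = tuple(
            Clone(
                id=str(c["id"]),
                parent=None if c.get("parent") in (None, "") else str(c["parent"]),
                frequency=float(c["frequency"]),
                new_cluster=str(c["cluster"]),
            )
            for c in spec["clones"]
        )
        return ClonalArchitecture(
            subject=str(spec["subject"]),
            clones=clones,
            non_tumor_fraction=float(spec.get("non_tumor_fraction", 0.0)),
        )
    except KeyError as exc:
        raise ArchitectureError(f"missing architecture key: {exc}") from exc


def expected_bulk_vaf(arch: ClonalArchitecture, cluster: str) -> float:
    """Module-level convenience for :meth:`ClonalArchitecture.expected_bulk_vaf`."""
    return arch.expected_bulk_vaf(cluster)


def study_architectures() -> dict[str, ClonalArchitecture]:
    """The three sAML clone models used throughout this package.

    UPN461282: 10% non-tumor plus five nested subclones (6/4/33/33/14%); the
    rare clone 5 descends from clone 4 (resolved by single-cell data).
    UPN182896: 35% non-tumor plus two nested subclones (13/52%).
    UPN288033: 7% non-tumor plus two nested subclones (62/31%).
    """

    def _linear(subject: str, ntf: float, freqs: Sequence[float]) -> ClonalArchitecture:
        clones = []
        for i, f in enumerate(freqs, start=1):
            clones.append(
                Clone(
                    id=f"clone{i}",
                    parent=None if i == 1 else f"clone{i - 1}",
                    frequency=f,
                    new_cluster=f"cluster{i}",
                )
            )
        return ClonalArchitecture(subject=subject, clones=tuple(clones), non_tumor_fraction=ntf)

    return {
        "UPN461282": _linear("UPN461282", 0.10, [0.06, 0.04, 0.33, 0.33, 0.14]),
        "UPN182896": _linear("UPN182896", 0.35, [0.13, 0.52]),
        "UPN288033": _linear("UPN288033", 0.07, [0.62, 0.31]),
    }


# ---------------------------------------------------------------------------
# Locus catalog
# ---------------------------------------------------------------------------

_LOCUS_KINDS = ("somatic_cluster", "germline_het", "germline_homref", "germline_homvar")


@dataclass(frozen=True)
class LocusCatalog:
    """Targeted loci: somatic cluster SNVs plus germline SNP controls.

    ``loci`` columns:

    locus_id : unique string id
    subject : subject whose tumor carries the somatic SNV (germline loci are
        assigned to a subject too; every library is sequenced over the full
        capture target regardless of subject)
    kind : one of ``somatic_cluster``, ``germline_het``, ``germline_homref``,
        ``germline_homvar``
    cluster : true mutation cluster (somatic loci only, always set)
    bulk_cluster : cluster label visible from bulk sequencing; missing for
        outlier SNVs that bulk analysis could not confidently cluster
    """

    loci: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"locus_id", "subject", "kind", "cluster", "bulk_cluster"}
        missing = required - set(self.loci.columns)
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")
        if self.loci["locus_id"].duplicated().any():
            raise ValueError("duplicate locus_ids in catalog")
        bad = set(self.loci["kind"]) - set(_LOCUS_KINDS)
        if bad:
            raise ValueError(f"unknown locus kinds: {sorted(bad)}")
        somatic = self.loci["kind"] == "somatic_cluster"
        if self.loci.loc[somatic, "cluster"].isna().any():
            raise ValueError("somatic loci must carry a cluster label")
        if self.loci.loc[~somatic, "cluster"].notna().any():
            raise ValueError("germline loci must not carry a cluster label")

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> pd.Index:
        return pd.Index(self.loci["locus_id"])

    def somatic(self, subject: str | None = None) -> pd.DataFrame:
        df = self.loci[self.loci["kind"] == "somatic_cluster"]
        if subject is not None:
            df = df[df["subject"] == subject]
        return df

    def germline(self, kind: str | None = None) -> pd.DataFrame:
        df = self.loci[self.loci["kind"] != "somatic_cluster"]
        if kind is not None:
            df = df[df["kind"] == kind]
        return df

    def outliers(self, subject: str | None = None) -> pd.DataFrame:
        """Somatic loci whose cluster could not be assigned from bulk."""
        df = self.somatic(subject)
        return df[df["bulk_cluster"].isna()]

    def cluster_map(self, subject: str, include_outliers: bool = False) -> pd.Series:
        """locus_id -> cluster label for one subject's somatic SNVs.

        By default uses the bulk-visible labels (outliers excluded), which is
        what downstream consumers are allowed to know.
        """
        df = self.somatic(subject)
        col = "cluster" if include_outliers else "bulk_cluster"
        s = df.set_index("locus_id")[col].dropna()
        s.name = "cluster"
        return s


#: Targeted somatic SNV counts per subject in the reference sAML cohort.
STUDY_SNV_COUNTS = {"UPN461282": 872, "UPN182896": 777, "UPN288033": 304}

#: Cluster sizes per subject. Only the rare UPN461282 cluster 5 size (60) is
#: reported; the remainder is split evenly across the other clusters.
STUDY_CLUSTER_SIZES = {
    "UPN461282": {"cluster1": 203, "cluster2": 203, "cluster3": 203, "cluster4": 203, "cluster5": 60},
    "UPN182896": {"cluster1": 389, "cluster2": 388},
    "UPN288033": {"cluster1": 152, "cluster2": 152},
}


def build_locus_catalog(
    cluster_sizes: Mapping[str, Mapping[str, int]],
    germline_het: int = 200,
    germline_homref: int = 100,
    germline_homvar: int = 50,
    outlier_fraction: float = 0.0,
    seed: int | None = None,
) -> LocusCatalog:
    """Build a catalog from per-subject cluster sizes plus germline SNP panels.

    ``outlier_fraction`` of somatic SNVs (chosen uniformly per subject) have
    their bulk cluster label masked, emulating variants that bulk VAF
    clustering could not place.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for subject, sizes in cluster_sizes.items():
        for cluster, n in sizes.items():
            for i in range(n):
                rows.append(
                    {
                        "locus_id": f"{subject}_{cluster}_snv{i:04d}",
                        "subject": subject,
                        "kind": "somatic_cluster",
                        "cluster": cluster,
                        "bulk_cluster": cluster,
                    }
                )
        for kind, count in (
            ("germline_het", germline_het),
            ("germline_homref", germline_homref),
            ("germline_homvar", germline_homvar),
        ):
            for i in range(count):
                rows.append(
                    {
                        "locus_id": f"{subject}_{kind}_{i:04d}",
                        "subject": subject,
                        "kind": kind,
                        "cluster": None,
                        "bulk_cluster": None,
                    }
                )
    df = pd.DataFrame(rows)
    if outlier_fraction > 0:
        somatic_idx = df.index[df["kind"] == "somatic_cluster"]
        n_out = int(round(outlier_fraction * len(somatic_idx)))
        masked = rng.choice(somatic_idx, size=n_out, replace=False)
        df.loc[masked, "bulk_cluster"] = None
    return LocusCatalog(loci=df)


def study_catalog(outlier_fraction: float = 0.09, seed: int | None = 0) -> LocusCatalog:
    """The study-shaped catalog: 872 + 777 + 304 = 1,953 somatic SNVs across
    three subjects, plus germline SNP panels, with ~9% bulk-unclusterable
    outliers."""
    return build_locus_catalog(
        STUDY_CLUSTER_SIZES, outlier_fraction=outlier_fraction, seed=seed
    )


# ---------------------------------------------------------------------------
# Noise model and read-count container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WgaNoiseModel:
    """WGA + sequencing noise parameters for sorted-cell libraries.

    Defaults reproduce the reference cohort's single-cell regime: mean on-target
    coverage 113x with strong overdispersion and a locus-dropout mass sized
    so ~55% of sites reach the 25x callable gate; per-allele ADO probability
    0.24 (twice the observed het-site FNR of 0.12); per-read miscall rate
    0.01 within the observed FPR ~ 0.02 budget.
    """

    ado_prob: float = 0.24
    seq_error: float = 0.01
    depth_mean: float = 113.0
    depth_dispersion: float = 0.8
    locus_dropout_prob: float = 0.27
    #: optional per-locus multiplier on ado_prob (locus_id -> multiplier);
    #: models a site-specific dropout component, off by default
    locus_ado_multiplier: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for name in ("ado_prob", "seq_error", "locus_dropout_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be > 0")

    def effective_ado(self, locus_ids: Sequence[str]) -> np.ndarray:
        d = np.full(len(locus_ids), self.ado_prob, dtype=float)
        if self.locus_ado_multiplier is not None:
            mult = np.array(
                [self.locus_ado_multiplier.get(l, 1.0) for l in locus_ids], dtype=float
            )
            d = np.clip(d * mult, 0.0, 1.0)
        return d

    def sample_depths(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Zero-inflated negative-binomial depths."""
        r = self.depth_dispersion
        p = r / (r + self.depth_mean)
        depth = rng.negative_binomial(r, p, size=n)
        dropped = rng.random(n) < self.locus_dropout_prob
        depth[dropped] = 0
        return depth


@dataclass
class ReadCountTable:
    """Per sample x locus reference/variant read counts.

    Backed by a DataFrame with columns ``sample_id``, ``locus_id``,
    ``ref_reads``, ``var_reads``.
    """

    entries: pd.DataFrame

    COLUMNS = ("sample_id", "locus_id", "ref_reads", "var_reads")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.entries.columns)
        if missing:
            raise ValueError(f"read-count table missing columns: {sorted(missing)}")
        self.entries = self.entries.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        for col in ("ref_reads", "var_reads"):
            vals = self.entries[col]
            if (vals < 0).any():
                raise ValueError(f"negative counts in {col}")
            self.entries[col] = vals.astype(np.int64)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.entries["sample_id"]))

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        df = self.entries[self.entries["sample_id"] == sample_id]
        if df.empty:
            raise KeyError(f"no counts for sample {sample_id!r}")
        return df

    def with_depth_vaf(self) -> pd.DataFrame:
        df = self.entries.copy()
        df["depth"] = df["ref_reads"] + df["var_reads"]
        with np.errstate(invalid="ignore"):
            df["vaf"] = np.where(df["depth"] > 0, df["var_reads"] / df["depth"], np.nan)
        return df

    def pivot(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(depth, var_reads) matrices, samples x loci; absent entries are 0."""
        ref = self.entries.pivot_table(
            index="sample_id", columns="locus_id", values="ref_reads", fill_value=0, aggfunc="sum"
        )
        var = self.entries.pivot_table(
            index="sample_id", columns="locus_id", values="var_reads", fill_value=0, aggfunc="sum"
        )
        return ref + var, var

    @staticmethod
    def concat(tables: Iterable["ReadCountTable"]) -> "ReadCountTable":
        frames = [t.entries for t in tables]
        return ReadCountTable(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _truth_f(code: int) -> float:
    return {HOMREF: 0.0, HET: 0.5, HOMVAR: 1.0}[code]


def truth_genotype_vector(
    arch: ClonalArchitecture, catalog: LocusCatalog, clone_id: str
) -> pd.Series:
    """True genotype codes over all catalog loci for a cell of ``clone_id``.

    Somatic SNVs of other subjects are homozygous reference (subjects'
    somatic variants are mutually exclusive); germline loci follow their kind.
    """
    carried = set(arch.lineage_clusters(clone_id))
    loci = catalog.loci
    codes = np.zeros(len(loci), dtype=np.int8)
    som = (loci["kind"] == "somatic_cluster") & (loci["subject"] == arch.subject)
    codes[som.to_numpy() & loci["cluster"].isin(carried).to_numpy()] = HET
    codes[(loci["kind"] == "germline_het").to_numpy()] = HET
    codes[(loci["kind"] == "germline_homvar").to_numpy()] = HOMVAR
    return pd.Series(codes, index=catalog.locus_ids, name=clone_id)


@dataclass
class SingleCellSim:
    """Bundle returned by :func:`simulate_cells`.

    truth : cells x loci matrix of true (pre-ADO) genotype codes {0,1,2}
    cell_clones : cell_id -> clone label (``non_tumor`` included)
    effective_vaf : cells x loci post-ADO allele fraction in {0, 0.5, 1}
    counts : the simulated read counts
    """

    truth: pd.DataFrame
    cell_clones: pd.Series
    effective_vaf: pd.DataFrame
    counts: ReadCountTable


def simulate_cells(
    arch: ClonalArchitecture,
    catalog: LocusCatalog,
    noise: WgaNoiseModel,
    n_cells: int,
    seed: int | np.random.SeedSequence,
    sample_prefix: str | None = None,
) -> SingleCellSim:
    """Simulate ``n_cells`` sorted single cells from ``arch`` over ``catalog``.

    Each cell's clone is drawn from the clone/non-tumor frequencies. At every
    heterozygous locus, one allele drops with probability ``noise.ado_prob``
    (direction uniform); depth follows the zero-inflated negative-binomial
    model; variant reads are binomial with the sequencing-error-adjusted
    success probability f(1-e) + (1-f)e.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    prefix = sample_prefix or f"{arch.subject}_cell"

    freqs = arch.clone_frequencies()
    labels = list(freqs)
    probs = np.array([freqs[l] for l in labels], dtype=float)
    probs = probs / probs.sum()

    locus_ids = catalog.locus_ids
    n_loci = len(locus_ids)
    clone_truth = {l: truth_genotype_vector(arch, catalog, l).to_numpy() for l in labels}
    d_locus = noise.effective_ado(list(locus_ids))
    e = noise.seq_error

    cell_ids = [f"{prefix}{i + 1:02d}" for i in range(n_cells)]
    chosen = rng.choice(len(labels), size=n_cells, p=probs)

    truth = np.empty((n_cells, n_loci), dtype=np.int8)
    for i, ci in enumerate(chosen):
        truth[i] = clone_truth[labels[ci]]

    f = truth.astype(float) / 2.0
    het = truth == HET
    ado = het & (rng.random((n_cells, n_loci)) < d_locus[None, :])
    drop_var = rng.random((n_cells, n_loci)) < 0.5
    f = np.where(ado & drop_var, 0.0, f)
    f = np.where(ado & ~drop_var, 1.0, f)

    depth = noise.sample_depths(rng, n_cells * n_loci).reshape(n_cells, n_loci)
    p = f * (1.0 - e) + (1.0 - f) * e
    var = rng.binomial(depth, p)
    ref = depth - var

    entries = pd.DataFrame(
        {
            "sample_id": np.repeat(cell_ids, n_loci),
            "locus_id": np.tile(locus_ids.to_numpy(), n_cells),
            "ref_reads": ref.ravel(),
            "var_reads": var.ravel(),
        }
    )
    return SingleCellSim(
        truth=pd.DataFrame(truth, index=pd.Index(cell_ids, name="cell_id"), columns=locus_ids),
        cell_clones=pd.Series(
            [labels[ci] for ci in chosen], index=pd.Index(cell_ids, name="cell_id"), name="clone"
        ),
        effective_vaf=pd.DataFrame(f, index=pd.Index(cell_ids, name="cell_id"), columns=locus_ids),
        counts=ReadCountTable(entries),
    )


def simulate_multiplet(
    cell_a_truth: pd.Series,
    cell_b_truth: pd.Series,
    noise: WgaNoiseModel,
    seed: int | np.random.SeedSequence,
    sample_id: str = "doublet",
    weight_a: float = 0.5,
) -> ReadCountTable:
    """Simulate a two-cell library pooling the alleles of two cells.

    ``cell_a_truth``/``cell_b_truth`` are genotype-code Series over the same
    loci. With equal amplification (``weight_a=0.5``) a locus heterozygous in
    exactly one cell has expected VAF 0.25; in both, 0.5. ADO applies to each
    cell's heterozygous sites independently before pooling.
    """
    if not cell_a_truth.index.equals(cell_b_truth.index):
        raise ValueError("the two truth vectors must cover the same loci")
    if not 0.0 <= weight_a <= 1.0:
        raise ValueError("weight_a outside [0, 1]")
    rng = np.random.default_rng(seed)
    locus_ids = cell_a_truth.index
    n_loci = len(locus_ids)
    d_locus = noise.effective_ado(list(locus_ids))
    e = noise.seq_error

    fs = []
    for truth in (cell_a_truth, cell_b_truth):
        codes = truth.to_numpy()
        f = codes.astype(float) / 2.0
        het = codes == HET
        ado = het & (rng.random(n_loci) < d_locus)
        drop_var = rng.random(n_loci) < 0.5
        f = np.where(ado & drop_var, 0.0, f)
        f = np.where(ado & ~drop_var, 1.0, f)
        fs.append(f)
    f_pool = weight_a * fs[0] + (1.0 - weight_a) * fs[1]

    depth = noise.sample_depths(rng, n_loci)
    p = f_pool * (1.0 - e) + (1.0 - f_pool) * e
    var = rng.binomial(depth, p)
    entries = pd.DataFrame(
        {
            "sample_id": sample_id,
            "locus_id": locus_ids.to_numpy(),
            "ref_reads": depth - var,
            "var_reads": var,
        }
    )
    return ReadCountTable(entries)


def simulate_bulk_counts(
    arch: ClonalArchitecture,
    catalog: LocusCatalog,
    depth: int,
    seed: int | np.random.SeedSequence,
    seq_error: float = 0.0,
    sample_id: str | None = None,
) -> ReadCountTable:
    """Simulate bulk (unfractionated) read counts at every catalog locus.

    Variant reads are binomial around the expected bulk VAF of each somatic
    cluster (germline het 0.5, hom-var 1, everything else 0), adjusted for
    ``seq_error``.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    sample = sample_id or f"{arch.subject}_bulk"
    loci = catalog.loci
    f = np.zeros(len(loci), dtype=float)
    vaf_by_cluster = {c: arch.expected_bulk_vaf(c) for c in arch.clusters()}
    som = (loci["kind"] == "somatic_cluster") & (loci["subject"] == arch.subject)
    f[som.to_numpy()] = loci.loc[som, "cluster"].map(vaf_by_cluster).to_numpy()
    f[(loci["kind"] == "germline_het").to_numpy()] = 0.5
    f[(loci["kind"] == "germline_homvar").to_numpy()] = 1.0
    p = f * (1.0 - seq_error) + (1.0 - f) * seq_error
    var = rng.binomial(depth, p)
    entries = pd.DataFrame(
        {
            "sample_id": sample,
            "locus_id": catalog.locus_ids.to_numpy(),
            "ref_reads": depth - var,
            "var_reads": var,
        }
    )
    return ReadCountTable(entries)
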