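"""Mapping single-cell genotype profiles onto bulk-predicted clone models.

Each cell is assigned to the clone whose mutation-cluster profile it
exhibits: a cluster counts as "observed" in a cell when the majority of its
callable SNVs are called variant, and the cell's clone is the deepest
observed cluster whose ancestors are all observed too. Because allelic
dropout (ADO) turns true variants into reference calls at a known rate,
three further analyses separate dropout from genuine substructure:

* an excess-reference test per cell and per cluster-block against the
  germline-estimated false-negative rate (scattered reference calls are
  ADO; aggregated blocks are candidate subclones);
* mutual-exclusivity branch detection — sets of SNVs never co-occurring in
  any cell, each supported by multiple cells, with the probability of the
  pattern under independent ADO as the null;
* rescue of outlier SNVs (unclusterable from bulk VAFs) by matching their
  cell-level presence/absence pattern to a cluster's, tolerating only
  variant-to-reference mismatches at the ADO rate.

Finally, clone frequencies observed among single cells are compared with
the bulk prediction (cluster mean VAF) by squared Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import NOCALL, GenotypeMatrix
from .simulate import HET, HOMREF, HOMVAR, NON_TUMOR, ClonalArchitecture

__all__ = [
    "CloneAssignment",
    "BranchReport",
    "OutlierAssignment",
    "assign_cells",
    "assignments_frame",
    "reference_call_excess",
    "detect_branches",
    "rescue_outliers",
    "clone_frequency_concordance",
]


@dataclass(frozen=True)
class CloneAssignment:
    """A cell's inferred clone with per-cluster detection evidence.

    ``detection`` maps cluster -> fraction of callable cluster SNVs called
    variant (NaN when fewer than the minimum callable sites were available).
    ``inconsistent`` marks cells observing a descendant cluster without one
    of its ancestors.
    """

    cell_id: str
    clone: str
    detection: Mapping[str, float] = field(hash=False)
    n_callable: Mapping[str, int] = field(hash=False)
    inconsistent: bool = False


def _is_variant(calls: np.ndarray) -> np.ndarray:
    return (calls == HET) | (calls == HOMVAR)


def assign_cells(
    matrix: GenotypeMatrix,
    cluster_map: pd.Series,
    arch: ClonalArchitecture,
    tau_detect: float = 0.5,
    min_callable: int = 3,
) -> list[CloneAssignment]:
    """Assign each cell to a clone by its observed mutation clusters.

    A cluster is observed in a cell iff >= ``min_callable`` of its SNVs are
    callable and the variant-call fraction among them is >= ``tau_detect``.
    The clone is the deepest clone whose full cluster lineage is observed;
    cells observing nothing are ``non_tumor``; cells observing a cluster
    outside that lineage are flagged inconsistent.
    """
    if matrix.calls.empty:
        raise ValueError("empty genotype matrix")
    clusters = arch.clusters()
    out: list[CloneAssignment] = []
    for cell_id, row in matrix.calls.iterrows():
        detection: dict[str, float] = {}
        n_call: dict[str, int] = {}
        observed: set[str] = set()
        for cluster in clusters:
            loci = cluster_map.index[cluster_map == cluster]
            loci = loci.intersection(row.index)
            calls = row.loc[loci].to_numpy()
            callable_mask = calls != NOCALL
            n = int(callable_mask.sum())
            n_call[cluster] = n
            if n == 0:
                detection[cluster] = float("nan")
                continue
            frac = float(_is_variant(calls[callable_mask]).mean())
            detection[cluster] = frac
            if n >= min_callable and frac >= tau_detect:
                observed.add(cluster)
        # deepest clone whose whole lineage is observed
        best_clone = NON_TUMOR
        best_depth = 0
        for clone in arch.clones:
            lineage = arch.lineage_clusters(clone.id)
            if set(lineage) <= observed and len(lineage) > best_depth:
                best_clone = clone.id
                best_depth = len(lineage)
        covered = set(arch.lineage_clusters(best_clone)) if best_clone != NON_TUMOR else set()
        inconsistent = bool(observed - covered)
        out.append(
            CloneAssignment(
                cell_id=str(cell_id),
                clone=best_clone,
                detection=detection,
                n_callable=n_call,
                inconsistent=inconsistent,
            )
        )
    return out


def assignments_frame(assignments: Sequence[CloneAssignment]) -> pd.DataFrame:
    """Tidy table of assignments (one row per cell, detection fractions as
    ``det_<cluster>`` columns)."""
    rows = []
    for a in assignments:
        row = {"cell_id": a.cell_id, "clone": a.clone, "inconsistent": a.inconsistent}
        for c, frac in a.detection.items():
            row[f"det_{c}"] = frac
            row[f"n_callable_{c}"] = a.n_callable[c]
        rows.append(row)
    return pd.DataFrame(rows).set_index("cell_id")


def _carrier_cells(
    assignments: Sequence[CloneAssignment], arch: ClonalArchitecture, cluster: str
) -> set[str]:
    return {
        a.cell_id
        for a in assignments
        if a.clone != NON_TUMOR and cluster in arch.lineage_clusters(a.clone)
    }


def reference_call_excess(
    matrix: GenotypeMatrix,
    assignments: Sequence[CloneAssignment],
    cluster_map: pd.Series,
    arch: ClonalArchitecture,
    fnr_est: float,
    alpha: float = 0.05,
    min_block_snvs: int = 2,
    min_block_cells: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test reference calls at expected-variant sites against the ADO rate.

    Per cell: exact binomial tail of the observed reference-call count among
    callable SNVs of clusters the assigned clone carries, at rate
    ``fnr_est`` (one-sided, excess direction).

    Per cluster: SNVs are grouped by the exact set of carrier cells in which
    they are called reference; a group of >= ``min_block_snvs`` SNVs
    reference in the same >= ``min_block_cells`` cells is a candidate
    substructure block (its probability under independent dropout,
    ``fnr^(snvs*cells)``, is reported) — scattered singleton reference calls
    are consistent with ADO.
    """
    if not 0.0 < fnr_est < 1.0:
        raise ValueError("fnr_est must be in (0, 1)")
    by_cell = {a.cell_id: a for a in assignments}
    cell_rows = []
    for cell_id, row in matrix.calls.iterrows():
        a = by_cell[str(cell_id)]
        carried = set(arch.lineage_clusters(a.clone))
        loci = cluster_map.index[cluster_map.isin(carried)].intersection(row.index)
        calls = row.loc[loci].to_numpy()
        callable_mask = calls != NOCALL
        n = int(callable_mask.sum())
        n_ref = int(np.sum(calls[callable_mask] == HOMREF))
        p = (
            float(stats.binomtest(n_ref, n, fnr_est, alternative="greater").pvalue)
            if n > 0
            else float("nan")
        )
        cell_rows.append(
            {
                "cell_id": cell_id,
                "clone": a.clone,
                "n_expected_variant": n,
                "n_reference_calls": n_ref,
                "reference_rate": n_ref / n if n else float("nan"),
                "p_value": p,
                "excess_flag": bool(n > 0 and p < alpha),
            }
        )
    per_cell = pd.DataFrame(cell_rows).set_index("cell_id")

    block_rows = []
    for cluster in arch.clusters():
        carriers = _carrier_cells(assignments, arch, cluster)
        loci = cluster_map.index[cluster_map == cluster].intersection(matrix.loci)
        if not carriers or loci.empty:
            continue
        sub = matrix.calls.loc[sorted(carriers), loci]
        ref_sets: dict[frozenset[str], list[str]] = {}
        for locus in loci:
            col = sub[locus]
            ref_cells = frozenset(col.index[col == HOMREF].astype(str))
            if len(ref_cells) >= min_block_cells:
                ref_sets.setdefault(ref_cells, []).append(locus)
        # multiplicity: a minimal (2 SNVs x 2 cells) block can arise by
        # scanning ~C(m,2)*C(n,2) candidate positions, so the null
        # probability is Bonferroni-scaled by that search space
        n_snv = len(loci)
        n_cell = len(carriers)
        n_candidates = max(1, (n_snv * (n_snv - 1) // 2) * (n_cell * (n_cell - 1) // 2))
        for cells, snvs in ref_sets.items():
            if len(snvs) < min_block_snvs:
                continue
            p_null = fnr_est ** (len(snvs) * len(cells))
            p_adj = min(1.0, p_null * n_candidates)
            block_rows.append(
                {
                    "cluster": cluster,
                    "n_snvs": len(snvs),
                    "n_cells": len(cells),
                    "snvs": ",".join(sorted(snvs)),
                    "cells": ",".join(sorted(cells)),
                    "p_null_ado": p_null,
                    "p_adj": p_adj,
                    "substructure_flag": bool(p_adj < alpha),
                }
            )
    per_cluster = pd.DataFrame(
        block_rows,
        columns=[
            "cluster",
            "n_snvs",
            "n_cells",
            "snvs",
            "cells",
            "p_null_ado",
            "p_adj",
            "substructure_flag",
        ],
    )
    return per_cell, per_cluster


@dataclass(frozen=True)
class BranchReport:
    """Mutually exclusive SNV sets suggesting an evolutionary branch point."""

    branches: pd.DataFrame  # cluster, snvs_a, snvs_b, cells_a, cells_b, p_null, p_adj, reported
    n_pairs_tested: int


def detect_branches(
    matrix: GenotypeMatrix,
    assignments: Sequence[CloneAssignment],
    cluster_map: pd.Series,
    arch: ClonalArchitecture,
    fnr_est: float,
    min_cells: int = 2,
    alpha: float = 0.05,
) -> BranchReport:
    """Find SNV sets within a cluster that never co-occur in any cell.

    Within each cluster, SNVs are joined into co-occurrence components (edge
    = variant together in >= 1 cell). Two components whose supporting cell
    sets are disjoint — each with >= ``min_cells`` supporting cells — form a
    candidate branch. Under the ADO null (all SNVs present in all carrier
    cells) the exclusivity pattern requires every off-side reference call to
    be a dropout, so its null probability is ``fnr^m`` with m the number of
    such calls; Bonferroni correction is applied over tested pairs.
    """
    tumor_cells = [a.cell_id for a in assignments if a.clone != NON_TUMOR]
    if len(tumor_cells) < 2:
        raise ValueError("need >= 2 tumor cells")
    if not 0.0 <= fnr_est < 1.0:
        raise ValueError("fnr_est must be in [0, 1)")
    rows = []
    n_tested = 0
    for cluster in arch.clusters():
        loci = cluster_map.index[cluster_map == cluster].intersection(matrix.loci)
        if loci.empty:
            continue
        sub = matrix.calls.loc[matrix.calls.index.intersection(tumor_cells), loci]
        variant_cells = {
            locus: frozenset(sub.index[_is_variant(sub[locus].to_numpy())].astype(str))
            for locus in loci
        }
        informative = [l for l in loci if variant_cells[l]]
        # union-find over co-occurrence
        parent = {l: l for l in informative}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        by_cell: dict[str, list[str]] = {}
        for l in informative:
            for c in variant_cells[l]:
                by_cell.setdefault(c, []).append(l)
        for snvs in by_cell.values():
            for other in snvs[1:]:
                ra, rb = find(snvs[0]), find(other)
                if ra != rb:
                    parent[rb] = ra
        components: dict[str, list[str]] = {}
        for l in informative:
            components.setdefault(find(l), []).append(l)
        comps = sorted(components.values(), key=lambda ls: sorted(ls)[0])
        for i, comp_a in enumerate(comps):
            cells_a = frozenset().union(*(variant_cells[l] for l in comp_a))
            for comp_b in comps[i + 1 :]:
                cells_b = frozenset().union(*(variant_cells[l] for l in comp_b))
                if len(cells_a) < min_cells or len(cells_b) < min_cells:
                    continue
                n_tested += 1
                m = 0
                for cells, snvs in ((cells_b, comp_a), (cells_a, comp_b)):
                    block = matrix.calls.loc[sorted(cells), snvs].to_numpy()
                    m += int(np.sum(block == HOMREF))
                p_null = fnr_est**m if m > 0 else 1.0
                rows.append(
                    {
                        "cluster": cluster,
                        "snvs_a": ",".join(sorted(comp_a)),
                        "snvs_b": ",".join(sorted(comp_b)),
                        "n_cells_a": len(cells_a),
                        "n_cells_b": len(cells_b),
                        "n_off_side_reference_calls": m,
                        "p_null_ado": p_null,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "snvs_a",
            "snvs_b",
            "n_cells_a",
            "n_cells_b",
            "n_off_side_reference_calls",
            "p_null_ado",
        ],
    )
    if len(df):
        df["p_adj"] = np.minimum(df["p_null_ado"] * max(n_tested, 1), 1.0)
        df["reported"] = df["p_adj"] < alpha
        df = df[df["reported"]].reset_index(drop=True)
    else:
        df["p_adj"] = pd.Series(dtype=float)
        df["reported"] = pd.Series(dtype=bool)
    return BranchReport(branches=df, n_pairs_tested=n_tested)


@dataclass(frozen=True)
class OutlierAssignment:
    snv_id: str
    assigned_cluster: str | None
    status: str  # "assigned" | "unassigned" | "ambiguous" | "uninformative"
    score: float
    n_informative_cells: int


def rescue_outliers(
    matrix: GenotypeMatrix,
    assignments: Sequence[CloneAssignment],
    outlier_snvs: Sequence[str],
    arch: ClonalArchitecture,
    fnr_est: float,
    min_informative_cells: int = 4,
) -> list[OutlierAssignment]:
    """Assign bulk-unclusterable SNVs to clusters by cell-pattern matching.

    An outlier matches a cluster when (hard constraint) no cell lacking the
    cluster carries the variant, and reference calls among carrier cells —
    the only ADO-explainable mismatch direction — number at most
    ``ceil(fnr_est * carrier_callable_cells)``. A unique match is assigned;
    none -> unassigned; several (no informative cell separates them) ->
    ambiguous.
    """
    by_cell = {a.cell_id: a for a in assignments}
    clusters = arch.clusters()
    out: list[OutlierAssignment] = []
    for snv in outlier_snvs:
        if snv not in matrix.loci:
            out.append(OutlierAssignment(snv, None, "uninformative", float("nan"), 0))
            continue
        col = matrix.calls[snv]
        callable_cells = [str(c) for c in col.index[col.to_numpy() != NOCALL]]
        clones_spanned = {by_cell[c].clone for c in callable_cells if c in by_cell}
        if len(callable_cells) < min_informative_cells or len(clones_spanned) < 2:
            out.append(
                OutlierAssignment(snv, None, "uninformative", float("nan"), len(callable_cells))
            )
            continue
        matches: list[tuple[str, float]] = []
        for cluster in clusters:
            expected = {
                c: cluster in arch.lineage_clusters(by_cell[c].clone)
                for c in callable_cells
                if c in by_cell
            }
            variant = {c: bool(_is_variant(np.array([col.loc[c]]))[0]) for c in expected}
            # hard constraint: a variant call in a non-carrier cell can never
            # be explained by dropout
            if any(variant[c] and not expected[c] for c in expected):
                continue
            carriers = [c for c in expected if expected[c]]
            mismatches = sum(1 for c in carriers if not variant[c])
            if not carriers:
                continue
            if mismatches <= math.ceil(fnr_est * len(carriers)):
                score = (len(expected) - mismatches) / len(expected)
                matches.append((cluster, score))
        if len(matches) == 1:
            cluster, score = matches[0]
            out.append(
                OutlierAssignment(snv, cluster, "assigned", score, len(callable_cells))
            )
        elif not matches:
            out.append(OutlierAssignment(snv, None, "unassigned", float("nan"), len(callable_cells)))
        else:
            out.append(OutlierAssignment(snv, None, "ambiguous", float("nan"), len(callable_cells)))
    return out


@dataclass(frozen=True)
class ConcordanceResult:
    r_squared: float
    pairs: pd.DataFrame  # subject, clone, single_cell_freq, bulk_vaf


def clone_frequency_concordance(
    assignments_by_subject: Mapping[str, Sequence[CloneAssignment]],
    bulk_vaf_by_subject: Mapping[str, Mapping[str, float]],
    archs: Mapping[str, ClonalArchitecture] | None = None,
) -> ConcordanceResult:
    """Correlate single-cell clone frequencies with bulk cluster mean VAFs.

    The bulk predictor for a clone is the mean VAF of its defining cluster,
    which reflects the *cumulative* prevalence of the clone and all its
    descendants (every carrier cell contributes reads). The matching
    single-cell quantity — used when ``archs`` is supplied — is therefore
    the fraction of cells *carrying* the defining cluster (assigned to the
    clone or any descendant). Without ``archs`` the plain assigned-cell
    fraction is used. Returns the squared Pearson correlation over all
    (subject, clone) pairs.
    """
    rows = []
    for subject, assignments in assignments_by_subject.items():
        total = len(assignments)
        if total == 0:
            continue
        for clone, vaf in bulk_vaf_by_subject[subject].items():
            if archs is not None:
                arch = archs[subject]
                cluster = arch.clone(clone).new_cluster
                n = sum(
                    1
                    for a in assignments
                    if a.clone != NON_TUMOR and cluster in arch.lineage_clusters(a.clone)
                )
            else:
                n = sum(1 for a in assignments if a.clone == clone)
            rows.append(
                {
                    "subject": subject,
                    "clone": clone,
                    "single_cell_freq": n / total,
                    "bulk_vaf": float(vaf),
                }
            )
    pairs = pd.DataFrame(rows)
    if len(pairs) < 3:
        raise ValueError("need >= 3 (subject, clone) pairs")
    x = pairs["bulk_vaf"]
    y = pairs["single_cell_freq"]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the frequency vectors")
    r2 = float(stats.pearsonr(x, y).statistic ** 2)
    return ConcordanceResult(r_squared=r2, pairs=pairs)
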