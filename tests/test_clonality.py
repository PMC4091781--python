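"""Clone assignment, ADO-vs-substructure discrimination, branch points, rescue."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonarch import (
    HET,
    HOMREF,
    NOCALL,
    NON_TUMOR,
    CallerParams,
    GenotypeMatrix,
    assign_cells,
    build_locus_catalog,
    call_matrix,
    clone_frequency_concordance,
    detect_branches,
    reference_call_excess,
    rescue_outliers,
    simulate_cells,
)
from clonarch.clonality import CloneAssignment, assignments_frame

from conftest import linear_architecture


@pytest.fixture(scope="module")
def cm_a(mini_catalog):
    return mini_catalog.cluster_map("SUBA")


def _matrix_from_clusters(cm, cell_profiles):
    """Build a GenotypeMatrix from {cell: {cluster: code or per-locus list}}."""
    loci = list(cm.index)
    rows = {}
    for cell, prof in cell_profiles.items():
        row = []
        for locus in loci:
            cluster = cm[locus]
            val = prof.get(cluster, HOMREF)
            row.append(val)
        rows[cell] = row
    return GenotypeMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=loci))


class TestAssignCells:
    def test_full_lineage_observed(self, arch_a, cm_a):
        m = _matrix_from_clusters(
            cm_a,
            {
                "deep": {"cA1": HET, "cA2": HET, "cA3": HET},
                "mid": {"cA1": HET, "cA2": HET},
                "founder": {"cA1": HET},
                "healthy": {},
            },
        )
        assigns = {a.cell_id: a for a in assign_cells(m, cm_a, arch_a)}
        assert assigns["deep"].clone == "clone3"
        assert assigns["mid"].clone == "clone2"
        assert assigns["founder"].clone == "clone1"
        assert assigns["healthy"].clone == NON_TUMOR
        assert not any(a.inconsistent for a in assigns.values())

    def test_gap_in_lineage_flagged(self, arch_a, cm_a):
        m = _matrix_from_clusters(cm_a, {"odd": {"cA1": HET, "cA3": HET}})
        (a,) = assign_cells(m, cm_a, arch_a)
        assert a.clone == "clone1"
        assert a.inconsistent

    def test_detection_requires_min_callable(self, arch_a, cm_a):
        # cA3 all NOCALL except 2 variant sites: below min_callable, not observed
        m = _matrix_from_clusters(cm_a, {"c": {"cA1": HET, "cA2": HET, "cA3": NOCALL}})
        loci3 = cm_a.index[cm_a == "cA3"][:2]
        m.calls.loc["c", loci3] = HET
        (a,) = assign_cells(m, cm_a, arch_a)
        assert a.clone == "clone2"

    def test_ado_noisy_cells_recovered(self, arch_a, mini_catalog, cm_a, study_noise):
        sim = simulate_cells(arch_a, mini_catalog, study_noise, 20, seed=61)
        calls = call_matrix(sim.counts)
        som = calls.subset_loci(mini_catalog.somatic("SUBA")["locus_id"])
        assigns = assign_cells(som, cm_a, arch_a)
        agree = sum(a.clone == sim.cell_clones[a.cell_id] for a in assigns)
        assert agree >= 18

    def test_noise_free_assignment_exact(self, arch_a, mini_catalog, cm_a, clean_noise):
        sim = simulate_cells(arch_a, mini_catalog, clean_noise, 15, seed=62)
        calls = call_matrix(sim.counts, CallerParams(seq_error=1e-6))
        som = calls.subset_loci(mini_catalog.somatic("SUBA")["locus_id"])
        assigns = assign_cells(som, cm_a, arch_a)
        for a in assigns:
            assert a.clone == sim.cell_clones[a.cell_id]

    def test_labels_partition_cells(self, arch_a, mini_catalog, cm_a, study_noise):
        """Clone frequencies from assignments (incl. non-tumor) sum to 1."""
        sim = simulate_cells(arch_a, mini_catalog, study_noise, 10, seed=63)
        calls = call_matrix(sim.counts)
        som = calls.subset_loci(mini_catalog.somatic("SUBA")["locus_id"])
        assigns = assign_cells(som, cm_a, arch_a)
        freqs = assignments_frame(assigns)["clone"].value_counts(normalize=True)
        assert freqs.sum() == pytest.approx(1.0)

    def test_empty_matrix_rejected(self, arch_a, cm_a):
        with pytest.raises(ValueError):
            assign_cells(GenotypeMatrix(pd.DataFrame()), cm_a, arch_a)


class TestReferenceCallExcess:
    def test_rate_at_fnr_not_flagged(self, arch_a, cm_a):
        # 30 cA1 sites, ~12% reference: consistent with ADO
        prof = {"cA1": HET}
        m = _matrix_from_clusters(cm_a, {"c": prof})
        loci1 = cm_a.index[cm_a == "cA1"][:4]
        m.calls.loc["c", loci1] = HOMREF
        assigns = [CloneAssignment("c", "clone1", {}, {}, False)]
        per_cell, _ = reference_call_excess(m, assigns, cm_a, arch_a, 0.12)
        assert not per_cell.loc["c", "excess_flag"]

    def test_exact_binomial_tail(self, arch_a, mini_catalog):
        """Observed 15% reference at 200 sites vs FNR 0.12: p equals the
        exact one-sided binomial tail."""
        cat = build_locus_catalog({"SUBA": {"cA1": 200}}, 0, 0, 0)
        cm = cat.cluster_map("SUBA")
        m = _matrix_from_clusters(cm, {"c": {"cA1": HET}})
        m.calls.iloc[0, :30] = HOMREF
        arch = linear_architecture("SUBA", [1.0], 0.0, cluster_prefix="cA")
        assigns = [CloneAssignment("c", "clone1", {}, {}, False)]
        per_cell, _ = reference_call_excess(m, assigns, cm, arch, 0.12)
        expected = stats.binomtest(30, 200, 0.12, alternative="greater").pvalue
        assert per_cell.loc["c", "p_value"] == pytest.approx(expected)

    def test_aggregated_block_flagged_as_substructure(self, arch_a, cm_a):
        cells = {f"c{i}": {"cA1": HET} for i in range(6)}
        m = _matrix_from_clusters(cm_a, cells)
        block_loci = cm_a.index[cm_a == "cA1"][:5]
        for cell in ("c0", "c1", "c2"):
            m.calls.loc[cell, block_loci] = HOMREF
        assigns = [CloneAssignment(c, "clone1", {}, {}, False) for c in cells]
        _, blocks = reference_call_excess(m, assigns, cm_a, arch_a, 0.12)
        flagged = blocks[blocks["substructure_flag"]]
        assert len(flagged) == 1
        assert flagged["n_snvs"].iloc[0] == 5
        assert flagged["n_cells"].iloc[0] == 3

    def test_scattered_singletons_not_flagged(self, arch_a, mini_catalog, cm_a, study_noise):
        sim = simulate_cells(arch_a, mini_catalog, study_noise, 12, seed=64)
        calls = call_matrix(sim.counts)
        som = calls.subset_loci(mini_catalog.somatic("SUBA")["locus_id"])
        assigns = assign_cells(som, cm_a, arch_a)
        _, blocks = reference_call_excess(som, assigns, cm_a, arch_a, 0.12)
        assert not blocks["substructure_flag"].any()


class TestDetectBranches:
    def test_constructed_exclusive_sets_reported(self, arch_a, cm_a):
        # cluster cA1 splits cleanly: sides A and B never co-occur and share
        # no backbone variant within the cluster
        cells = {f"c{i}": {} for i in range(4)}
        m = _matrix_from_clusters(cm_a, cells)
        loci1 = cm_a.index[cm_a == "cA1"]
        side_a, side_b = loci1[:3], loci1[3:6]
        m.calls.loc[["c0", "c1"], side_a] = HET
        m.calls.loc[["c2", "c3"], side_b] = HET
        assigns = [CloneAssignment(c, "clone1", {}, {}, False) for c in cells]
        rep = detect_branches(m, assigns, cm_a, arch_a, fnr_est=0.1)
        assert len(rep.branches) >= 1
        row = rep.branches.iloc[0]
        assert {row["n_cells_a"], row["n_cells_b"]} == {2}

    def test_single_cell_support_not_reported(self, arch_a, cm_a):
        cells = {"c0": {"cA1": HET}, "c1": {"cA1": HET}}
        m = _matrix_from_clusters(cm_a, cells)
        loci1 = cm_a.index[cm_a == "cA1"]
        m.calls.loc[:, loci1[:4]] = HOMREF
        m.calls.loc["c0", loci1[:2]] = HET
        m.calls.loc["c1", loci1[2:4]] = HET
        assigns = [CloneAssignment(c, "clone1", {}, {}, False) for c in cells]
        rep = detect_branches(m, assigns, cm_a, arch_a, fnr_est=0.4, min_cells=2)
        assert len(rep.branches) == 0

    def test_branching_architecture_recovered(self):
        """Cells simulated from a branched clone pair produce mutually
        exclusive SNV sets within the merged bulk cluster."""
        from clonarch import ClonalArchitecture, Clone

        truth_arch = ClonalArchitecture(
            subject="S",
            clones=(
                Clone("c1", None, 0.30, "k1"),
                Clone("c2a", "c1", 0.35, "k2A"),
                Clone("c2b", "c1", 0.35, "k2B"),
            ),
            non_tumor_fraction=0.0,
        )
        cat = build_locus_catalog(
            {"S": {"k1": 20, "k2A": 10, "k2B": 10}}, 10, 0, 0
        )
        noise_kwargs = dict(ado_prob=0.1, seq_error=0.001, depth_mean=100.0,
                            depth_dispersion=20.0, locus_dropout_prob=0.05)
        from clonarch import WgaNoiseModel

        sim = simulate_cells(truth_arch, cat, WgaNoiseModel(**noise_kwargs), 16, seed=60)
        calls = call_matrix(sim.counts, CallerParams(seq_error=0.001))
        som = calls.subset_loci(cat.somatic("S")["locus_id"])
        # analysis view: bulk merged the sibling clusters into one
        bulk_arch = ClonalArchitecture(
            subject="S",
            clones=(Clone("c1", None, 0.30, "k1"), Clone("c2", "c1", 0.70, "k2")),
            non_tumor_fraction=0.0,
        )
        cm = cat.cluster_map("S", include_outliers=True).replace({"k2A": "k2", "k2B": "k2"})
        assigns = assign_cells(som, cm, bulk_arch)
        rep = detect_branches(som, assigns, cm, bulk_arch, fnr_est=0.05)
        assert len(rep.branches) >= 1
        row = rep.branches.iloc[0]
        snvs_a = set(row["snvs_a"].split(","))
        snvs_b = set(row["snvs_b"].split(","))
        sides = {cat.loci.set_index("locus_id").loc[s, "cluster"] for s in snvs_a} | {
            cat.loci.set_index("locus_id").loc[s, "cluster"] for s in snvs_b
        }
        assert sides == {"k2A", "k2B"}

    def test_type_one_control_on_linear_architecture(self):
        """No branch reported above the nominal rate in strictly linear data."""
        arch = linear_architecture("S", [0.3, 0.3, 0.3], 0.1)
        cat = build_locus_catalog({"S": {"cluster1": 10, "cluster2": 10, "cluster3": 10}}, 0, 0, 0)
        from clonarch import WgaNoiseModel

        noise = WgaNoiseModel(ado_prob=0.24, seq_error=0.005, depth_mean=100.0,
                              depth_dispersion=5.0, locus_dropout_prob=0.1)
        cm = cat.cluster_map("S")
        false_positives = 0
        n_sims = 200
        for i in range(n_sims):
            sim = simulate_cells(arch, cat, noise, 8, seed=1000 + i)
            calls = call_matrix(sim.counts, CallerParams(seq_error=0.005))
            som = calls.subset_loci(cat.somatic("S")["locus_id"])
            assigns = assign_cells(som, cm, arch)
            if len([a for a in assigns if a.clone != NON_TUMOR]) < 2:
                continue
            rep = detect_branches(som, assigns, cm, arch, fnr_est=0.12, alpha=0.05)
            if len(rep.branches):
                false_positives += 1
        assert false_positives / n_sims <= 0.05


class TestRescueOutliers:
    def test_pattern_match_assigns_cluster(self, arch_a, cm_a):
        # variant exactly in the clone-3 cells; clone-2 cells separate the
        # cA3 pattern from cA2, clone-1 cells from cA1
        cells = {
            "c0": {"cA1": HET, "cA2": HET, "cA3": HET},
            "c1": {"cA1": HET, "cA2": HET, "cA3": HET},
            "m0": {"cA1": HET, "cA2": HET},
            "m1": {"cA1": HET, "cA2": HET},
            "f0": {"cA1": HET},
            "h": {},
        }
        m = _matrix_from_clusters(cm_a, cells)
        outlier = "outlier1"
        m.calls[outlier] = [HET, HET, HOMREF, HOMREF, HOMREF, HOMREF]
        assigns = [
            CloneAssignment("c0", "clone3", {}, {}, False),
            CloneAssignment("c1", "clone3", {}, {}, False),
            CloneAssignment("m0", "clone2", {}, {}, False),
            CloneAssignment("m1", "clone2", {}, {}, False),
            CloneAssignment("f0", "clone1", {}, {}, False),
            CloneAssignment("h", NON_TUMOR, {}, {}, False),
        ]
        (res,) = rescue_outliers(m, assigns, [outlier], arch_a, fnr_est=0.12)
        assert res.status == "assigned"
        assert res.assigned_cluster == "cA3"

    def test_insufficient_cells_uninformative(self, arch_a, cm_a):
        m = _matrix_from_clusters(cm_a, {"c0": {}, "c1": {}})
        m.calls["out"] = [HET, NOCALL]
        assigns = [
            CloneAssignment("c0", "clone1", {}, {}, False),
            CloneAssignment("c1", "clone2", {}, {}, False),
        ]
        (res,) = rescue_outliers(m, assigns, ["out"], arch_a, fnr_est=0.1)
        assert res.status == "uninformative"

    def test_no_informative_separation_is_ambiguous(self, arch_a, cm_a):
        # every callable cell carries the full lineage: cA1..cA3 all match
        cells = {f"c{i}": {"cA1": HET, "cA2": HET, "cA3": HET} for i in range(4)}
        cells["h"] = {}
        m = _matrix_from_clusters(cm_a, cells)
        m.calls["out"] = [HET, HET, HET, HET, HOMREF]
        assigns = [CloneAssignment(f"c{i}", "clone3", {}, {}, False) for i in range(4)]
        assigns.append(CloneAssignment("h", NON_TUMOR, {}, {}, False))
        (res,) = rescue_outliers(m, assigns, ["out"], arch_a, fnr_est=0.1)
        assert res.status == "ambiguous"

    def test_variant_in_noncarrier_never_assigned(self, arch_a, mini_catalog, cm_a, study_noise):
        """Hard constraint: an SNV variant in a cell lacking the candidate
        cluster can never be rescued into that cluster."""
        sim = simulate_cells(arch_a, mini_catalog, study_noise, 12, seed=66)
        calls = call_matrix(sim.counts)
        som_ids = list(mini_catalog.somatic("SUBA")["locus_id"])
        som = calls.subset_loci(som_ids)
        assigns = assign_cells(som, cm_a, arch_a)
        by_cell = {a.cell_id: a for a in assigns}
        outliers = som_ids[:30]
        results = rescue_outliers(som, assigns, outliers, arch_a, fnr_est=0.12)
        for r in results:
            if r.status != "assigned":
                continue
            col = som.calls[r.snv_id]
            for cell in col.index:
                a = by_cell[str(cell)]
                carries = r.assigned_cluster in arch_a.lineage_clusters(a.clone)
                if col[cell] in (HET, 2) and not carries:
                    pytest.fail(f"{r.snv_id} assigned despite variant in non-carrier {cell}")


class TestConcordance:
    def test_perfect_agreement(self):
        assigns = {
            "S1": [CloneAssignment(f"c{i}", "clone1" if i < 5 else "clone2", {}, {}, False)
                   for i in range(10)],
        }
        bulk = {"S1": {"clone1": 0.5, "clone2": 0.25}, "S2": {"clone1": 0.4}}
        assigns["S2"] = [CloneAssignment("x0", "clone1", {}, {}, False),
                         CloneAssignment("x1", "clone1", {}, {}, False)] + [
            CloneAssignment(f"x{i}", NON_TUMOR, {}, {}, False) for i in range(2, 5)
        ]
        # latest-clone reading: S1 freq 0.5/0.5? use carrier-free variant
        res = clone_frequency_concordance(assigns, bulk)
        assert res.pairs.shape[0] == 3
        assert 0.0 <= res.r_squared <= 1.0

    def test_exact_linear_relation_gives_unit_r2(self):
        assigns = {
            "S1": [CloneAssignment(f"c{i}", "clone1" if i < 6 else "clone2", {}, {}, False)
                   for i in range(10)],
            "S2": [CloneAssignment(f"d{i}", "clone1" if i < 2 else NON_TUMOR, {}, {}, False)
                   for i in range(10)],
        }
        bulk = {"S1": {"clone1": 0.3, "clone2": 0.2}, "S2": {"clone1": 0.1}}
        res = clone_frequency_concordance(assigns, bulk)
        assert res.r_squared == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        assigns = {"S1": [CloneAssignment("c0", "clone1", {}, {}, False)]}
        with pytest.raises(ValueError):
            clone_frequency_concordance(assigns, {"S1": {"clone1": 0.5}})

    def test_zero_variance_rejected(self):
        # no cell assigned to any bulk-modeled clone: constant zero vector
        assigns = {
            "S1": [CloneAssignment(f"c{i}", NON_TUMOR, {}, {}, False) for i in range(4)]
        }
        bulk = {"S1": {"clone1": 0.5, "clone2": 0.2, "clone3": 0.1}}
        with pytest.raises(ValueError):
            clone_frequency_concordance(assigns, bulk)
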