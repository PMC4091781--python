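"""File formats, run configuration, and the end-to-end pipeline driver.

Everything is plain text: read counts and genotype matrices as TSV,
architectures and configuration as JSON, trees as Newick. The pipeline
(`run_pipeline`) chains simulate -> call -> cellularity -> clonality ->
phylo per subject and writes a manifest recording the seed and a hash of
the configuration, so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cellularity import classify_all, estimate_error_profile
from .clonality import (
    assign_cells,
    assignments_frame,
    clone_frequency_concordance,
    detect_branches,
    reference_call_excess,
    rescue_outliers,
)
from .genotype import (
    GENOTYPE_TSV_CODES,
    CallerParams,
    GenotypeMatrix,
    benchmark,
    call_matrix,
)
from .phylo import bootstrap_support
from .simulate import (
    ClonalArchitecture,
    ReadCountTable,
    WgaNoiseModel,
    build_architecture,
    simulate_bulk_counts,
    simulate_cells,
    simulate_multiplet,
    study_architectures,
    study_catalog,
    truth_genotype_vector,
)

__all__ = [
    "RunConfig",
    "PipelineError",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_architecture_json",
    "write_architecture_json",
    "run_pipeline",
]

logger = logging.getLogger("clonarch")

_COUNTS_HEADER = ["sample_id", "locus_id", "ref_reads", "var_reads"]
_CODE_TO_TSV = GENOTYPE_TSV_CODES
_TSV_TO_CODE = {v: k for k, v in GENOTYPE_TSV_CODES.items()}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# TSV / JSON formats
# ---------------------------------------------------------------------------


def read_counts_tsv(path: str | Path) -> ReadCountTable:
    """Read a read-count TSV (header: sample_id, locus_id, ref_reads,
    var_reads). Malformed rows raise with their line number."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _COUNTS_HEADER:
            raise ValueError(
                f"{path}: bad header {header!r}, expected {_COUNTS_HEADER!r}"
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            sample_id, locus_id, ref_s, var_s = parts
            try:
                ref, var = int(ref_s), int(var_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer count") from exc
            if ref < 0 or var < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            rows.append((sample_id, locus_id, ref, var))
    return ReadCountTable(pd.DataFrame(rows, columns=_COUNTS_HEADER))


def write_counts_tsv(counts: ReadCountTable, path: str | Path) -> None:
    counts.entries.to_csv(path, sep="\t", index=False)


def write_genotype_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write cells x loci calls with codes {., 0, 1, 2}."""
    df = matrix.calls.map(lambda g: _CODE_TO_TSV[int(g)])
    df.index.name = "cell_id"
    df.to_csv(path, sep="\t")


def read_genotype_tsv(path: str | Path, callable_threshold: int = 25) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        calls = df.map(lambda s: _TSV_TO_CODE[s])
    except KeyError as exc:
        raise ValueError(f"{path}: invalid genotype code {exc}") from exc
    return GenotypeMatrix(calls=calls, callable_threshold=callable_threshold)


def read_architecture_json(path: str | Path) -> ClonalArchitecture:
    with Path(path).open() as fh:
        return build_architecture(json.load(fh))


def write_architecture_json(arch: ClonalArchitecture, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(arch.to_dict(), fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; serializes losslessly to/from JSON.

    The defaults reproduce the reference secondary-AML dataset's shape: three subjects, 12 single
    cells plus 2 two-cell samples each, single-cell noise at the WGA
    defaults, bulk depth ~500x, the 25x callable gate, and 1000 bootstrap
    iterations.
    """

    seed: int = 0
    subjects: tuple[str, ...] = ("UPN461282", "UPN182896", "UPN288033")
    n_cells: int = 12
    n_doublets: int = 2
    bulk_depth: int = 500
    outlier_fraction: float = 0.09
    noise: WgaNoiseModel = field(default_factory=WgaNoiseModel)
    caller: CallerParams = field(default_factory=CallerParams)
    tau_detect: float = 0.5
    alpha_cellularity: float = 0.05
    alpha_branch: float = 0.05
    bootstrap_iters: int = 1000

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_doublets < 0:
            raise ValueError("n_doublets must be >= 0")
        if self.bulk_depth < 1:
            raise ValueError("bulk_depth must be >= 1")
        if not self.subjects:
            raise ValueError("at least one subject required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["subjects"] = list(self.subjects)
        if d["noise"].get("locus_ado_multiplier") is None:
            d["noise"].pop("locus_ado_multiplier", None)
        else:
            d["noise"]["locus_ado_multiplier"] = dict(d["noise"]["locus_ado_multiplier"])
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "noise" in data:
            data["noise"] = WgaNoiseModel(**data["noise"])
        if "caller" in data:
            data["caller"] = CallerParams(**data["caller"])
        if "subjects" in data:
            data["subjects"] = tuple(data["subjects"])
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class SubjectResult:
    subject: str
    counts: ReadCountTable
    calls: GenotypeMatrix
    benchmark_table: pd.DataFrame
    fnr_het: float
    cellularity: pd.DataFrame
    assignments: pd.DataFrame
    branches: pd.DataFrame
    outliers: pd.DataFrame
    tree_newick: str


@dataclass
class PipelineResult:
    subjects: dict[str, SubjectResult]
    concordance: pd.DataFrame
    concordance_r2: float
    manifest: dict


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full simulate -> call -> cellularity -> clonality -> phylo
    pipeline for every configured subject.

    If ``out_dir`` is given, all result tables, trees, and a manifest
    naming the seed and config hash are written there. Any stage failure
    aborts with the stage name and removes partially written outputs.
    """
    master = np.random.SeedSequence(config.seed)
    # fixed spawn order keeps child streams stable as long as the roster is
    streams = master.spawn(2 + 3 * len(config.subjects))
    catalog = study_catalog(
        outlier_fraction=config.outlier_fraction,
        seed=int(streams[0].generate_state(1)[0] % (2**31)),
    )
    archs = {s: a for s, a in study_architectures().items() if s in config.subjects}
    missing = set(config.subjects) - set(archs)
    if missing:
        raise PipelineError(f"stage 'setup' failed: unknown subjects {sorted(missing)}")

    sims: dict[str, object] = {}
    doublet_counts: dict[str, ReadCountTable] = {}

    @_stage("simulate")
    def _simulate() -> None:
        for i, subject in enumerate(config.subjects):
            ss = streams[2 + 3 * i]
            sim = simulate_cells(
                archs[subject], catalog, config.noise, config.n_cells, ss
            )
            sims[subject] = sim
            rng = np.random.default_rng(streams[2 + 3 * i + 1])
            tables = []
            clones = list(archs[subject].clone_frequencies())
            probs = np.array(list(archs[subject].clone_frequencies().values()))
            probs /= probs.sum()
            for j in range(config.n_doublets):
                pair = rng.choice(len(clones), size=2, p=probs)
                ta = truth_genotype_vector(archs[subject], catalog, clones[pair[0]])
                tb = truth_genotype_vector(archs[subject], catalog, clones[pair[1]])
                tables.append(
                    simulate_multiplet(
                        ta,
                        tb,
                        config.noise,
                        rng.integers(2**31),
                        sample_id=f"{subject}_twocell{j + 1:02d}",
                    )
                )
            if tables:
                doublet_counts[subject] = ReadCountTable.concat(tables)

    _simulate()

    results: dict[str, SubjectResult] = {}
    assignments_by_subject = {}
    bulk_vaf_by_subject = {}

    @_stage("analyze")
    def _analyze() -> None:
        for i, subject in enumerate(config.subjects):
            arch = archs[subject]
            sim = sims[subject]
            all_counts = [sim.counts]
            if subject in doublet_counts:
                all_counts.append(doublet_counts[subject])
            counts = ReadCountTable.concat(all_counts)

            calls_all = call_matrix(counts, config.caller)
            single_cells = list(sim.truth.index)
            calls = GenotypeMatrix(
                calls_all.calls.loc[single_cells], calls_all.callable_threshold
            )

            # benchmark at germline SNPs (the sites with array-like truth)
            germ_loci = catalog.germline()["locus_id"]
            bench = benchmark(
                calls.subset_loci(germ_loci), sim.truth.loc[:, germ_loci]
            )
            fnr_het = float(bench.by_truth.loc["heterozygous", "FNR"])

            # mutual-control error model: other subjects' single cells
            controls = [
                sims[s].counts for s in config.subjects if s != subject and s in sims
            ]
            err = estimate_error_profile(
                ReadCountTable.concat(controls), catalog, subject
            )
            cellularity_table = classify_all(
                counts, arch, err, catalog, alpha=config.alpha_cellularity
            )

            cluster_map = catalog.cluster_map(subject)
            som_calls = GenotypeMatrix(
                calls.calls.loc[:, calls.calls.columns.intersection(
                    catalog.somatic(subject)["locus_id"]
                )],
                calls.callable_threshold,
            )
            assigns = assign_cells(
                som_calls, cluster_map, arch, tau_detect=config.tau_detect
            )
            assignments_by_subject[subject] = assigns
            _, blocks = reference_call_excess(
                som_calls, assigns, cluster_map, arch, max(fnr_het, 1e-6)
            )
            branch_rep = detect_branches(
                som_calls,
                assigns,
                cluster_map,
                arch,
                max(fnr_het, 0.0),
                alpha=config.alpha_branch,
            )
            outlier_ids = list(catalog.outliers(subject)["locus_id"])
            rescued = rescue_outliers(
                som_calls, assigns, outlier_ids, arch, max(fnr_het, 1e-6)
            )
            outlier_df = pd.DataFrame(
                [dataclasses.asdict(o) for o in rescued],
                columns=[
                    "snv_id",
                    "assigned_cluster",
                    "status",
                    "score",
                    "n_informative_cells",
                ],
            )

            # bulk prediction: cluster mean VAF from simulated bulk counts
            bulk = simulate_bulk_counts(
                arch,
                catalog,
                config.bulk_depth,
                streams[2 + 3 * i + 2],
            )
            bdf = bulk.with_depth_vaf().merge(
                cluster_map.rename("cluster"), left_on="locus_id", right_index=True
            )
            mean_vaf = bdf.groupby("cluster")["vaf"].mean()
            bulk_vaf_by_subject[subject] = {
                c.id: float(mean_vaf.get(c.new_cluster, np.nan)) for c in arch.clones
            }

            tree = bootstrap_support(
                som_calls,
                n_iter=config.bootstrap_iters,
                seed=np.random.SeedSequence(
                    entropy=config.seed, spawn_key=(1000 + i,)
                ),
            ) if len(calls.cells) >= 4 else None

            results[subject] = SubjectResult(
                subject=subject,
                counts=counts,
                calls=calls_all,
                benchmark_table=bench.by_truth.reset_index(names="truth_zygosity"),
                fnr_het=fnr_het,
                cellularity=cellularity_table,
                assignments=assignments_frame(assigns),
                branches=branch_rep.branches,
                outliers=outlier_df,
                tree_newick=tree.to_newick(with_support=True) if tree else "",
            )

    _analyze()

    @_stage("concordance")
    def _concordance():
        return clone_frequency_concordance(
            assignments_by_subject, bulk_vaf_by_subject, archs=archs
        )

    conc = _concordance()

    manifest = {
        "tool": "clonarch",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "subjects": list(config.subjects),
        "concordance_r2": conc.r_squared,
    }
    result = PipelineResult(
        subjects=results,
        concordance=conc.pairs,
        concordance_r2=conc.r_squared,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        for subject, res in result.subjects.items():
            def _w(name: str) -> Path:
                p = out_dir / name
                written.append(p)
                return p

            write_counts_tsv(res.counts, _w(f"counts_{subject}.tsv"))
            write_genotype_tsv(res.calls, _w(f"calls_{subject}.tsv"))
            res.benchmark_table.to_csv(_w(f"benchmark_{subject}.tsv"), sep="\t", index=False)
            res.cellularity.to_csv(_w(f"cellularity_{subject}.tsv"), sep="\t", index=False)
            res.assignments.to_csv(_w(f"assignments_{subject}.tsv"), sep="\t")
            res.branches.to_csv(_w(f"branches_{subject}.tsv"), sep="\t", index=False)
            res.outliers.to_csv(_w(f"outliers_{subject}.tsv"), sep="\t", index=False)
            if res.tree_newick:
                _w(f"tree_{subject}.nwk").write_text(res.tree_newick + "\n")
        p = out_dir / "concordance.tsv"
        written.append(p)
        result.concordance.to_csv(p, sep="\t", index=False)
        p = out_dir / "manifest.json"
        written.append(p)
        with p.open("w") as fh:
            json.dump(result.manifest, fh, indent=2, default=str)
            fh.write("\n")
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
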