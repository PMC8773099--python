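"""End-to-end orchestration: simulate -> qc -> assoc -> rank -> evaluate -> network.

One master seed is fanned out to per-stage seeds through a SeedSequence, so
a run is reproducible end to end; each stage writes its outputs before the
next starts and a JSON manifest records the configuration, seeds, library
versions and per-stage record counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, association, evaluation, network, qc, ranking, synthetic
from . import io as gio

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "assoc", "rank", "evaluate", "network")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Every stage parameter of a full run, with study defaults.

    Defaults follow the printed analysis rules: 10% missingness cutoff,
    PRU > 234 resistance, alpha 0.05 with odds ratio > 10 at the filter,
    100 ranking iterations with an 80/20 split.
    """

    # inputs: either simulate (genotypes_path None) or load from files
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    edges_path: str | None = None
    annotation_path: str | None = None
    cohort: synthetic.CohortSpec = field(default_factory=synthetic.CohortSpec)
    # stage parameters
    missing_threshold: float = 0.10
    pru_threshold: float = 234.0
    alpha: float = 0.05
    or_threshold: float = 10.0
    contrast: str = "case-control"
    n_iterations: int = 100
    train_fraction: float = 0.8
    top_k: int = 20
    methods: tuple[str, ...] = ranking.METHODS
    eval_models: tuple[str, ...] = evaluation.EVAL_MODELS
    max_features: int = 10
    eval_splits: int = 20
    tolerance: float = 0.005
    max_path_length: int = 2
    use_annotation_filter: bool = False
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        raw = tomllib.loads(Path(path).read_text())
        cohort = synthetic.CohortSpec(**raw.pop("cohort", {}))
        for key in ("methods", "eval_models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(cohort=cohort, **raw)


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31 - 1))
        for stage, child in zip(STAGES, children)
    }


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages into ``outdir``; returns the manifest dict.

    Re-running with an identical config reproduces byte-identical analytic
    outputs (ranking TSV, curve TSV/JSON, network TSVs).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "config": _config_dict(config),
        "stage_seeds": seeds,
        "versions": _versions(),
        "stages": {},
    }
    try:
        _run_stages(config, out, seeds, manifest)
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest


def _run_stages(config: RunConfig, out: Path, seeds: dict, manifest: dict) -> None:
    def record(stage: str, t0: float, **counts) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **counts}
        logger.info("stage %s done: %s", stage, counts)

    # ---- simulate / load -------------------------------------------------
    t0 = time.time()
    stage = "simulate"
    try:
        if config.genotypes_path is None:
            spec = dataclasses.replace(config.cohort, seed=seeds["simulate"])
            matrix, pheno, causal = synthetic.generate_cohort(spec)
            gio.write_genotypes(matrix, out / "genotypes.tsv")
            gio.write_phenotypes(pheno, out / "phenotypes.tsv")
            synthetic.write_annotation(matrix, out / "annotation.tsv")
            manifest["truth"] = causal
        else:
            if config.phenotypes_path is None:
                raise ValueError("phenotypes_path required with genotypes_path")
            matrix = gio.read_genotypes(config.genotypes_path)
            pheno = gio.read_phenotypes(config.phenotypes_path)
        record(stage, t0, n_subjects=matrix.n_subjects, n_snps=matrix.n_snps)

        # ---- qc ----------------------------------------------------------
        stage, t0 = "qc", time.time()
        matrix, report = qc.filter_snps(matrix, config.missing_threshold)
        pheno = pheno.aligned_to(matrix)
        report.to_tsv(out / "qc_per_snp.tsv")
        report.to_json(out / "qc_summary.json")
        record(stage, t0, n_input=report.n_input,
               n_removed_maf0=report.n_removed_maf0,
               n_removed_missing=report.n_removed_missing,
               n_retained=report.n_retained)

        # ---- association -------------------------------------------------
        stage, t0 = "assoc", time.time()
        records = association.associate(matrix, pheno, contrast=config.contrast)
        retained = association.filter_associations(
            records, alpha=config.alpha, or_threshold=config.or_threshold
        )
        association.write_association_tsv(records, out / "association.tsv")
        association.write_association_tsv(retained, out / "association_retained.tsv")
        record(stage, t0, n_tested=int((~records["untestable"]).sum()),
               n_retained=len(retained))
        if len(retained) == 0:
            raise ValueError(
                "no SNP passes the association filter; relax alpha/or_threshold"
            )
        matrix_f = matrix.subset_snps(list(retained.index))

        # ---- rank --------------------------------------------------------
        stage, t0 = "rank", time.time()
        labels = _pipeline_labels(pheno, config.contrast)
        rcfg = ranking.RankingConfig(
            n_iterations=config.n_iterations,
            train_fraction=config.train_fraction,
            top_k=min(config.top_k, matrix_f.n_snps),
            methods=config.methods,
            seed=seeds["rank"],
        )
        consensus = ranking.consensus_rank(matrix_f, labels, rcfg)
        consensus.to_tsv(out / "ranking.tsv")
        consensus.log_to_json(out / "ranking_log.json")
        record(stage, t0, n_ranked=len(consensus.counts),
               count_total=int(consensus.counts.sum()))

        # ---- evaluate ----------------------------------------------------
        stage, t0 = "evaluate", time.time()
        eval_cfg = ranking.RankingConfig(
            n_iterations=config.eval_splits,
            train_fraction=config.train_fraction,
            top_k=rcfg.top_k,
            seed=seeds["evaluate"],
        )
        splits = ranking.bootstrap_splits(labels, eval_cfg)
        annotation = None
        if config.use_annotation_filter:
            annotation = matrix_f.snp_meta
        curve = evaluation.evaluate_curve(
            matrix_f,
            labels,
            consensus,
            splits,
            models=config.eval_models,
            max_features=min(config.max_features, matrix_f.n_snps),
            seed=seeds["evaluate"],
            annotation=annotation,
            tolerance=config.tolerance,
        )
        curve.to_tsv(out / "curve.tsv")
        curve.to_json(out / "curve.json")
        evaluation.plot_curve(curve, out / "curve.png")
        freq = evaluation.genotype_frequency_table(
            matrix_f, labels.astype(bool), curve.selected_snps
        )
        freq.to_csv(out / "genotype_frequencies.tsv", sep="\t", na_rep="NA")
        record(stage, t0, selected_model=curve.selected_model,
               selected_feature_count=curve.selected_feature_count,
               selected_snps=curve.selected_snps)

        # ---- network -----------------------------------------------------
        stage, t0 = "network", time.time()
        if config.edges_path is not None:
            edges = gio.read_edge_list(config.edges_path)
        else:
            edges = network.load_example_edges()
        genes = sorted(
            {
                g
                for g in matrix_f.snp_meta.loc[curve.selected_snps, "gene"]
                if isinstance(g, str) and g
            }
        )
        if not genes:
            record(stage, t0, n_signature_genes=0, skipped=True)
        else:
            graph = network.build_subnetwork(
                edges, genes, max_path_length=config.max_path_length
            )
            graph.to_edge_tsv(out / "network_edges.tsv")
            network.component_summary(graph).to_csv(
                out / "network_components.tsv", sep="\t", index=False
            )
            record(stage, t0, n_signature_genes=len(genes),
                   n_nodes=graph.graph.number_of_nodes(),
                   n_bridges=len(graph.bridges))
    except Exception as exc:  # annotate with the failing stage
        raise StageError(f"stage {stage!r} failed: {exc}") from exc


def _pipeline_labels(pheno: gio.PhenotypeTable, contrast: str) -> np.ndarray:
    if contrast == "case-control":
        return pheno.df["case"].to_numpy(dtype=int)
    res = pheno.df["resistance"]
    if res.isna().any():
        raise ValueError(
            "resistance contrast requires a resistance label for every subject"
        )
    return res.astype(bool).to_numpy(dtype=int)


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cohort"]["causal_genes"] = list(d["cohort"]["causal_genes"])
    d["cohort"]["maf_range"] = list(d["cohort"]["maf_range"])
    d["methods"] = list(d["methods"])
    d["eval_models"] = list(d["eval_models"])
    return d


def _versions() -> dict:
    import sklearn

    return {
        "clopisig": __version__,
        "numpy": np.__version__,
        "sklearn": sklearn.__version__,
    }
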