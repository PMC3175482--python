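"""End-to-end orchestration: features -> imputation -> per-phenotype models.

A run consumes a raw best-hit score table (or a prebuilt genotype matrix),
a reference self-score table, a phenotype table and optional annotations,
and produces a self-describing run directory: the genotype matrix, the
imputed phenotypes, one JSON summary per phenotype (chosen components and
shrinkage, CVRMSE, cross-validated d-index, selected genes), optional
permutation-null draws, the pleiotropy table and enrichment tables.
Everything random flows from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association_stats, genotype_features, model_selection, phenotype_prep

logger = logging.getLogger("stpls")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (defaults are the study's)."""

    scores: str | None = None  # best-hit score TSV (genome_id, gene_id, score)
    blast: str | None = None  # or raw 12-column tabular alignment rows
    refs: str | None = None  # reference FASTA or self-score TSV
    genotype_matrix: str | None = None  # or a prebuilt X TSV
    phenotypes: str | None = None
    annotations: str | None = None  # per-gene boolean flag TSV
    go: str | None = None  # long-format gene_id -> term TSV
    rates: str | None = None  # per-gene evolutionary-rate TSV
    out_dir: str = "stpls_run"
    components: tuple = tuple(model_selection.K_GRID)
    deltas: tuple = tuple(model_selection.DELTA_GRID)
    segment_size: int = 3
    slack_se: float = 2.0
    min_genes: int = 25
    knn_k: int = 5
    filter_threshold: float = 0.5
    paralog_e_max: float = 1e-10
    paralog_min_cov: float = 0.5
    pleiotropy_fraction: float = 0.25
    n_perm: int = 0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not (0.0 < self.filter_threshold <= 1.0):
            raise ValueError("filter_threshold must be in (0, 1]")
        if self.min_genes < 0 or self.knn_k < 1 or self.segment_size < 1:
            raise ValueError("invalid counts in configuration")
        if self.slack_se < 0 or self.n_perm < 0:
            raise ValueError("slack_se and n_perm must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage '{stage}' failed: {exc}")
        self.stage = stage


def _load_refs(path: str) -> pd.DataFrame:
    if path.endswith((".fa", ".fasta", ".faa", ".fna")):
        return genotype_features.self_scores(path)
    return genotype_features.read_self_scores(path)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full mining pipeline; returns the run directory.

    Any stage error aborts with a message naming the stage; outputs written
    before the failure are retained for inspection.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: build-matrix -------------------------------------------
    try:
        if cfg.genotype_matrix:
            gm = genotype_features.read_genotype_matrix(cfg.genotype_matrix)
        else:
            if cfg.refs is None or (cfg.scores is None and cfg.blast is None):
                raise ValueError(
                    "need either genotype_matrix, or refs plus scores/blast"
                )
            refs = _load_refs(cfg.refs)
            if cfg.scores:
                scores = pd.read_csv(cfg.scores, sep="\t")
            else:
                scores = genotype_features.parse_blast_tabular(
                    cfg.blast, known_genes=refs.index, on_unknown_gene="drop"
                )
            gm = genotype_features.build_genotype_matrix(
                scores, refs, threshold=cfg.filter_threshold
            )
        gm.to_tsv(out / "genotype_matrix.tsv")
        genotype_features.write_discarded(gm.discarded, out / "discarded_genes.txt")
    except Exception as exc:
        raise StageError("build-matrix", exc) from exc

    # --- stage: impute --------------------------------------------------
    try:
        if cfg.phenotypes is None:
            raise ValueError("no phenotype table configured")
        pheno = phenotype_prep.read_phenotypes(cfg.phenotypes)
        pheno = pheno.loc[gm.strains]
        pheno = phenotype_prep.knn_impute(pheno, k=cfg.knn_k)
        phenotype_prep.write_phenotypes(pheno, out / "phenotypes_imputed.tsv")
    except Exception as exc:
        raise StageError("impute", exc) from exc

    # --- stage: per-phenotype model fitting -----------------------------
    root_ss = np.random.SeedSequence(cfg.seed)
    cv_streams = root_ss.spawn(len(pheno.columns))
    selections: dict[str, set] = {}
    summaries = {}
    for v, name in enumerate(pheno.columns):
        try:
            choice = model_selection.run_selection(
                gm.frame,
                pheno[name],
                k_grid=cfg.components,
                delta_grid=cfg.deltas,
                segment_size=cfg.segment_size,
                slack_se=cfg.slack_se,
                min_genes=cfg.min_genes,
                rng=np.random.default_rng(cv_streams[v]),
            )
        except Exception as exc:
            raise StageError(f"fit[{name}]", exc) from exc
        selections[name] = choice.model.selected
        summary = {
            "phenotype": name,
            "k": choice.k,
            "delta": choice.delta,
            "cvrmse": choice.cvrmse,
            "cvrmse_min": choice.cvrmse_min,
            "slack_bound": choice.slack_bound,
            "d_index": choice.cv_d_index,
            "min_genes_relaxed": choice.min_genes_relaxed,
            "n_selected": choice.model.n_selected,
            "selected": sorted(choice.model.selected),
        }
        summaries[name] = summary
        (out / f"model_{name}.json").write_text(json.dumps(summary, indent=1))
        logger.info(
            "%s: k=%d delta=%.2f d=%.3f genes=%d",
            name,
            choice.k,
            choice.delta,
            choice.cv_d_index,
            choice.model.n_selected,
        )

    # --- stage: permutation null ---------------------------------------
    if cfg.n_perm > 0:
        try:
            null_seed = int(root_ss.generate_state(1)[0] % (2**31))
            null = model_selection.permutation_null(
                gm.frame,
                pheno[pheno.columns[0]],
                n_perm=cfg.n_perm,
                seed=null_seed,
                k_grid=cfg.components,
                delta_grid=cfg.deltas,
                segment_size=cfg.segment_size,
                slack_se=cfg.slack_se,
                min_genes=cfg.min_genes,
            )
            null.to_csv(out / "permutation_null.tsv", sep="\t", index=False)
        except Exception as exc:
            raise StageError("null", exc) from exc

    # --- stage: pleiotropy + enrichment --------------------------------
    try:
        pleio = association_stats.pleiotropy_set(
            selections, fraction=cfg.pleiotropy_fraction
        )
        pleio.counts.to_frame("n_phenotypes").to_csv(
            out / "pleiotropy.tsv", sep="\t", index_label="gene"
        )
        (out / "pleiotropy_set.txt").write_text(
            "".join(f"{g}\n" for g in pleio.genes)
        )
        if cfg.annotations:
            flags = pd.read_csv(cfg.annotations, sep="\t", index_col=0)
            universe = set(gm.genes)
            categories = {
                col: set(flags.index[flags[col].astype(bool)]) & universe
                for col in flags.columns
            }
            if cfg.go:
                go = pd.read_csv(cfg.go, sep="\t")
                for term, grp in go.groupby("term"):
                    categories[str(term)] = set(grp["gene_id"]) & universe
            for name, sel in selections.items():
                table = association_stats.enrichment_table(
                    sel & universe, categories, universe
                )
                table.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
        if cfg.rates:
            rates = pd.read_csv(cfg.rates, sep="\t", index_col=0).iloc[:, 0]
            overall = set().union(*selections.values()) if selections else set()
            if len(overall) >= 2:
                rc = association_stats.compare_rates(rates, overall)
                (out / "rate_comparison.json").write_text(
                    json.dumps(dataclasses.asdict(rc), indent=1)
                )
    except Exception as exc:
        raise StageError("enrich", exc) from exc

    meta = {
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "phenotypes": list(pheno.columns),
        "n_strains": len(gm.strains),
        "n_genes": len(gm.genes),
        "n_discarded": len(gm.discarded),
    }
    (out / "run_meta.json").write_text(json.dumps(meta, indent=1, default=str))
    return out
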