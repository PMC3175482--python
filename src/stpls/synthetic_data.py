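"""Seeded synthetic fixtures emulating the study's data shapes.

The generators produce (i) strain x gene evolutionary-distance matrices
with block-correlated genes (genes in the same functional neighbourhood
diverge together), (ii) phenotypes from a sparse linear model y = X beta +
noise with known support, (iii) raw best-hit score tables whose pipeline
output is known by construction, and (iv) gene annotations with planted
category enrichment and an elevated evolutionary rate among true support
genes.  Defaults mirror the study's shape at desk scale: n = 36 strains,
p around 1000 genes, around 1% of genes truly influential, and rate means
matching the reported influential/non-influential contrast (0.100 vs
0.078).  Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .genotype_features import (
    GenotypeMatrix,
    JC_EPS,
    SCORE_FLOOR,
    jc_distance,
    jc_dmax,
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    n, p
        Strains and genes (36 x ~1000 mirrors the real 36 x 5791 shape at
        desk scale).
    block_size, rho
        Genes are grouped into equicorrelated blocks of ``block_size`` with
        latent correlation ``rho`` (0.3: moderately correlated functional
        neighbourhoods).
    support_size, effect_size, noise_sd
        The phenotype depends linearly on ``support_size`` genes with
        coefficients of magnitude ``effect_size`` and random sign, plus
        N(0, noise_sd^2) noise on standardized genotype columns.
    n_filtered
        Score-table fixtures plant this many columns with every normalized
        score below 0.5, which the similarity filter must drop.
    category_size, enrichment_odds
        Annotation fixtures draw a category of about ``category_size``
        genes whose odds of membership are boosted ``enrichment_odds``-fold
        inside the true support.
    rate_mean_support, rate_mean_other
        Mean evolutionary-rate (dN/dS-style) draws for support and
        non-support genes.
    """

    n: int = 36
    p: int = 1000
    block_size: int = 20
    rho: float = 0.3
    support_size: int = 10
    effect_size: float = 1.0
    noise_sd: float = 0.5
    n_phenotypes: int = 1
    n_filtered: int = 3
    category_size: int = 100
    enrichment_odds: float = 10.0
    rate_mean_support: float = 0.100
    rate_mean_other: float = 0.078
    seed: int = 0

    def __post_init__(self):
        if self.support_size > self.p:
            raise ValueError("support_size must not exceed p")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.n, self.p, self.block_size, self.n_phenotypes) < 1:
            raise ValueError("counts must be positive")
        if self.block_size > self.p:
            raise ValueError("block_size must not exceed p")
        if self.enrichment_odds < 1.0:
            raise ValueError("enrichment_odds must be >= 1")


@dataclass
class SimulatedTruth:
    """Ground truth recorded alongside a simulated phenotype."""

    support: list
    beta: dict
    config: SimulationConfig
    y_name: str = "pheno_01"


def _strain_labels(n: int) -> list[str]:
    return [f"strain_{i + 1:03d}" for i in range(n)]


def _gene_labels(p: int) -> list[str]:
    return [f"gene_{j + 1:04d}" for j in range(p)]


def gene_blocks(p: int, block_size: int) -> np.ndarray:
    """Block index of each gene (contiguous blocks; last may be short)."""
    return np.arange(p) // block_size


def simulate_genotype_matrix(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Block-correlated strain x gene distance matrix.

    Latent z_ij = sqrt(rho) u_{i,b(j)} + sqrt(1-rho) e_ij with standard
    normal block factors u and noise e gives within-block equicorrelation
    rho; z is squashed monotonically to a normalized score in (1/20, 1) and
    mapped through the Jukes-Cantor transform, so every value is a valid
    distance in (0, D_max).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    blocks = gene_blocks(cfg.p, cfg.block_size)
    n_blocks = int(blocks.max()) + 1
    u = rng.standard_normal((cfg.n, n_blocks))
    e = rng.standard_normal((cfg.n, cfg.p))
    z = np.sqrt(cfg.rho) * u[:, blocks] + np.sqrt(1.0 - cfg.rho) * e
    s = SCORE_FLOOR + (1.0 - SCORE_FLOOR) * expit(z)  # monotone, in (0.05, 1)
    dist = jc_distance(s)
    frame = pd.DataFrame(
        dist, index=_strain_labels(cfg.n), columns=_gene_labels(cfg.p)
    )
    return GenotypeMatrix(frame=frame, d_max=jc_dmax(JC_EPS))


def choose_support(
    cfg: SimulationConfig, rng: np.random.Generator, p: int | None = None
) -> np.ndarray:
    """True-support column indices, spread over distinct blocks when possible
    so the planted signals carry distinct information."""
    blocks = gene_blocks(cfg.p if p is None else p, cfg.block_size)
    p = cfg.p if p is None else p
    n_blocks = int(blocks.max()) + 1
    if cfg.support_size <= n_blocks:
        chosen_blocks = rng.choice(n_blocks, size=cfg.support_size, replace=False)
        idx = [rng.choice(np.flatnonzero(blocks == b)) for b in chosen_blocks]
        return np.sort(np.array(idx))
    return np.sort(rng.choice(p, size=cfg.support_size, replace=False))


def simulate_phenotypes(
    X: GenotypeMatrix | pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    *,
    name: str = "pheno_01",
) -> tuple[pd.Series, SimulatedTruth]:
    """Phenotype from a sparse linear model with known support.

    y = Z_support beta + eps where Z holds the genotype columns
    standardized to sd 1 (so ``effect_size`` and ``noise_sd`` are on a
    common scale and the signal variance is about support_size *
    effect_size^2 when support genes sit in distinct blocks) and
    eps ~ N(0, noise_sd^2).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    frame = X.frame if isinstance(X, GenotypeMatrix) else X
    support_idx = choose_support(cfg, rng, p=frame.shape[1])
    signs = rng.choice([-1.0, 1.0], size=cfg.support_size)
    beta = signs * cfg.effect_size
    Z = frame.iloc[:, support_idx].to_numpy(dtype=float)
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
    y = Z @ beta + rng.normal(0.0, cfg.noise_sd, size=frame.shape[0])
    support = [frame.columns[j] for j in support_idx]
    truth = SimulatedTruth(
        support=support,
        beta={g: float(b) for g, b in zip(support, beta)},
        config=cfg,
        y_name=name,
    )
    return pd.Series(y, index=frame.index, name=name), truth


def simulate_score_table(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GenotypeMatrix]:
    """Raw score-table fixture whose feature-pipeline output is known.

    Normalized scores are planted directly: most columns get at least one
    value >= 0.5, while ``cfg.n_filtered`` columns are kept entirely below
    0.5 so the similarity filter must drop them; a sprinkling of pairs is
    planted at the 1/20 floor and emitted as *absent* rows (no hit).  Raw
    scores are the planted scores times integer self-scores, so running
    ``build_genotype_matrix`` on the fixture reproduces the expected matrix
    to floating-point accuracy.

    Returns (score table, reference set, expected genotype matrix).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    n, p = cfg.n, cfg.p
    strains, genes = _strain_labels(n), _gene_labels(p)
    s = rng.uniform(SCORE_FLOOR, 1.0, size=(n, p))
    # plant absent pairs (no alignment row: the pipeline floors them)
    absent = rng.random((n, p)) < 0.05
    # columns the 0.5 filter must drop: every planted score below 0.5
    filtered_cols = rng.choice(p, size=min(cfg.n_filtered, p), replace=False)
    s[:, filtered_cols] = rng.uniform(SCORE_FLOOR, 0.499, size=(n, len(filtered_cols)))
    # every other column gets at least one surviving (non-absent, >= 0.5) hit
    keep_row = rng.integers(0, n, size=p)
    forced = rng.uniform(0.5, 1.0, size=p)
    kept_mask = np.ones(p, dtype=bool)
    kept_mask[filtered_cols] = False
    present_max = np.where(absent, 0.0, s).max(axis=0)
    for j in np.flatnonzero(kept_mask & (present_max < 0.5)):
        s[keep_row[j], j] = forced[j]
        absent[keep_row[j], j] = False

    self_scores = rng.integers(100, 1000, size=p)
    refs = pd.DataFrame(
        {"self_score": self_scores}, index=pd.Index(genes, name="gene_id")
    )
    raw = s * self_scores  # raw best-hit scores on the self-score scale
    ii, jj = np.nonzero(~absent)
    scores = pd.DataFrame(
        {
            "genome_id": [strains[i] for i in ii],
            "gene_id": [genes[j] for j in jj],
            "score": raw[ii, jj],
        }
    )

    # the planted normalized score is raw/self, the very division the
    # pipeline performs, so the expected matrix matches it exactly
    recovered = np.where(
        absent, SCORE_FLOOR, np.clip(raw / self_scores, SCORE_FLOOR, 1.0)
    )
    keep = recovered.max(axis=0) >= 0.5
    expected = pd.DataFrame(
        jc_distance(recovered[:, keep]),
        index=strains,
        columns=[g for g, k in zip(genes, keep) if k],
    )
    return scores, refs, GenotypeMatrix(
        frame=expected,
        d_max=jc_dmax(JC_EPS),
        discarded=[g for g, k in zip(genes, keep) if not k],
    )


@dataclass
class SimulatedAnnotation:
    """Gene annotations with planted structure."""

    flags: pd.DataFrame  # boolean columns: essential, paralog, ...
    go: pd.DataFrame  # long format: gene_id, term
    rates: pd.Series  # per-gene evolutionary rate
    coords: pd.DataFrame  # chromosome, strand, start, end
    category: set = field(default_factory=set)  # the planted enriched category


def simulate_annotations(
    genes,
    support,
    *,
    category_size: int = 100,
    enrichment_odds: float = 10.0,
    rate_mean_support: float = 0.100,
    rate_mean_other: float = 0.078,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> SimulatedAnnotation:
    """Annotations with a category enriched in the true support.

    Baseline membership probability is ``category_size / p``; inside the
    support the *odds* of membership are multiplied by ``enrichment_odds``
    (odds = 1 makes the category independent of the support).  Rates are
    Gamma draws (shape 10) with the given group means, emulating the faster
    evolution of influential genes.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    genes = list(genes)
    p = len(genes)
    support = set(support)
    q0 = category_size / p
    odds0 = q0 / (1.0 - q0)
    q1 = (enrichment_odds * odds0) / (1.0 + enrichment_odds * odds0)
    in_support = np.array([g in support for g in genes])
    probs = np.where(in_support, q1, q0)
    member = rng.random(p) < probs
    category = {g for g, m in zip(genes, member) if m}

    flag_probs = {
        "essential": 0.18,
        "paralog": 0.12,
        "frameshift": 0.05,
        "stop_codon": 0.05,
        "copy_number": 0.04,
    }
    flags = pd.DataFrame(
        {name: rng.random(p) < prob for name, prob in flag_probs.items()},
        index=pd.Index(genes, name="gene_id"),
    )
    flags["planted_category"] = member

    means = np.where(in_support, rate_mean_support, rate_mean_other)
    shape = 10.0
    rates = pd.Series(
        rng.gamma(shape, means / shape), index=flags.index, name="rate"
    )

    n_terms = 12
    term_labels = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    go_rows = []
    for g in genes:
        k = rng.integers(0, 4)
        for t in rng.choice(n_terms, size=k, replace=False):
            go_rows.append((g, term_labels[t]))
    go = pd.DataFrame(go_rows, columns=["gene_id", "term"])

    chroms = [f"chr{r}" for r in (
        "I II III IV V VI VII VIII IX X XI XII XIII XIV XV XVI".split()
    )]
    chrom = rng.choice(len(chroms), size=p)
    start = rng.integers(1, 1_500_000, size=p)
    length = rng.integers(300, 4000, size=p)
    coords = pd.DataFrame(
        {
            "chromosome": [chroms[c] for c in chrom],
            "strand": rng.choice(["+", "-"], size=p),
            "start": start,
            "end": start + length,
        },
        index=flags.index,
    )
    return SimulatedAnnotation(
        flags=flags, go=go, rates=rates, coords=coords, category=category
    )


def write_fixture_dir(cfg: SimulationConfig, out_dir: str | Path) -> Path:
    """Write a complete text fixture: scores, refs, phenotypes, annotations,
    and a truth JSON, all derived from ``cfg.seed``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scores, refs, expected = simulate_score_table(cfg)
    scores.to_csv(out / "scores.tsv", sep="\t", index=False)
    refs.to_csv(out / "refs.tsv", sep="\t")

    rng = np.random.default_rng(cfg.seed + 1)
    phenos = {}
    truths = {}
    for v in range(cfg.n_phenotypes):
        name = f"pheno_{v + 1:02d}"
        y, truth = simulate_phenotypes(expected, cfg, rng, name=name)
        phenos[name] = y
        truths[name] = {"support": truth.support, "beta": truth.beta}
    pheno_df = pd.DataFrame(phenos)
    pheno_df.to_csv(out / "phenotypes.tsv", sep="\t", index_label="strain")

    ann = simulate_annotations(
        expected.genes,
        truths[f"pheno_01"]["support"],
        category_size=cfg.category_size,
        enrichment_odds=cfg.enrichment_odds,
        rate_mean_support=cfg.rate_mean_support,
        rate_mean_other=cfg.rate_mean_other,
        seed=cfg.seed + 3,
    )
    ann.flags.to_csv(out / "annotations.tsv", sep="\t")
    ann.go.to_csv(out / "go.tsv", sep="\t", index=False)
    ann.rates.to_frame().to_csv(out / "rates.tsv", sep="\t", index_label="gene_id")
    ann.coords.to_csv(out / "coords.tsv", sep="\t", index_label="gene_id")

    truth_payload = {
        "config": asdict(cfg),
        "phenotypes": truths,
        "planted_category": sorted(ann.category),
        "filtered_genes": expected.discarded,
    }
    (out / "truth.json").write_text(json.dumps(truth_payload, indent=1))
    return out
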