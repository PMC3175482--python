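"""Evolutionary-distance genotype features from pairwise-alignment scores.

Each strain genome is summarised against a reference gene set by the best
(maximum) alignment bit-score per reference gene.  Scores are normalized by
the reference's self-alignment score under unit match scoring (which equals
its length in residues), clamped to [1/20, 1], and mapped through a 20-state
Jukes-Cantor transform to an approximate evolutionary distance.  Reference
genes with no normalized score >= 0.5 in any genome are discarded as
uninformative.  The result is the n x p genotype matrix X used for
regression: X[i, j] = 0 means gene j is found at 100% identity in genome i,
larger values mean greater divergence, and the saturation cap D_max marks
genes with no detectable homology.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("stpls")

#: Lower bound on the normalized score: the 20-state Jukes-Cantor saturation
#: point, below which the distance is undefined.
SCORE_FLOOR = 1.0 / 20.0

#: Floor on the Jukes-Cantor log argument at score saturation.
JC_EPS = 1e-8

#: Columns of the 12-column tabular alignment dialect (BLAST outfmt 6).
BLAST_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


class BlastParseError(ValueError):
    """A malformed row in tabular alignment input (carries the line number)."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def jc_dmax(eps: float = JC_EPS) -> float:
    """Distance cap implied by flooring the log argument at ``eps``."""
    return -(19.0 / 20.0) * math.log(eps)


@dataclass
class GenotypeMatrix:
    """n x p evolutionary-distance matrix with strain rows and gene columns."""

    frame: pd.DataFrame
    d_max: float
    discarded: list[str] = field(default_factory=list)

    @property
    def strains(self) -> list[str]:
        return list(self.frame.index)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="genome_id")


def read_blast_tabular(source) -> pd.DataFrame:
    """Read 12-column tabular alignment rows into a typed DataFrame.

    ``source`` is a path or an open text stream.  Raises
    :class:`BlastParseError` naming the 1-based line number on a wrong column
    count or a non-numeric numeric field.  Comment lines starting with ``#``
    and blank lines are skipped.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt") as fh:
            return read_blast_tabular(fh)
    rows = []
    reader = csv.reader(source, delimiter="\t")
    for lineno, parts in enumerate(reader, start=1):
        if not parts or (parts[0].startswith("#") and len(parts) == 1):
            continue
        if parts and parts[0].startswith("#"):
            continue
        if len(parts) != 12:
            raise BlastParseError(
                f"expected 12 tab-separated columns, found {len(parts)}", lineno
            )
        try:
            rows.append(
                (
                    parts[0],
                    parts[1],
                    float(parts[2]),
                    int(parts[3]),
                    int(parts[4]),
                    int(parts[5]),
                    int(parts[6]),
                    int(parts[7]),
                    int(parts[8]),
                    int(parts[9]),
                    float(parts[10]),
                    float(parts[11]),
                )
            )
        except ValueError as exc:
            raise BlastParseError(f"non-numeric field ({exc})", lineno) from None
    return pd.DataFrame(rows, columns=BLAST_COLUMNS)


def parse_blast_tabular(
    source,
    genome_of_query: Callable[[str], str] | Mapping[str, str] | None = None,
    *,
    known_genes: Iterable[str] | None = None,
    on_unknown_gene: str = "error",
) -> pd.DataFrame:
    """Collapse alignment rows to per-(genome, gene) maximum bit-scores.

    Parameters
    ----------
    source
        Path or text stream of 12-column tabular alignment rows; subject ids
        are reference gene ids.
    genome_of_query
        Rule labelling each query id with its genome: a callable, a mapping,
        or None (the query id *is* the genome id).
    known_genes
        If given, rows whose subject id is not in this set follow
        ``on_unknown_gene``: ``"error"`` raises, ``"drop"`` discards with a
        warning.

    Returns
    -------
    DataFrame with columns ``genome_id``, ``gene_id``, ``score`` and at most
    one row per (genome, gene) pair; pairs with no alignment rows are absent
    (implicitly score 0).
    """
    raw = read_blast_tabular(source)
    if raw.empty:
        return pd.DataFrame(columns=["genome_id", "gene_id", "score"])
    if genome_of_query is None:
        genomes = raw["qseqid"]
    elif callable(genome_of_query):
        genomes = raw["qseqid"].map(genome_of_query)
    else:
        genomes = raw["qseqid"].map(dict(genome_of_query))
        if genomes.isna().any():
            bad = raw.loc[genomes.isna(), "qseqid"].unique()
            raise ValueError(f"queries with no genome label: {sorted(bad)[:5]}")
    table = pd.DataFrame(
        {"genome_id": genomes, "gene_id": raw["sseqid"], "score": raw["bitscore"]}
    )
    if known_genes is not None:
        known = set(known_genes)
        unknown = ~table["gene_id"].isin(known)
        if unknown.any():
            names = sorted(table.loc[unknown, "gene_id"].unique())
            if on_unknown_gene == "drop":
                logger.warning(
                    "dropping %d hits to %d unknown reference genes (e.g. %s)",
                    int(unknown.sum()),
                    len(names),
                    names[:3],
                )
                table = table[~unknown]
            else:
                raise ValueError(f"hits to unknown reference genes: {names[:5]}")
    if table.empty:
        return pd.DataFrame(columns=["genome_id", "gene_id", "score"])
    if (table["score"] < 0).any():
        raise ValueError("negative bit-scores in alignment input")
    out = (
        table.groupby(["genome_id", "gene_id"], sort=False, as_index=False)["score"]
        .max()
    )
    return out


def self_scores(sequences) -> pd.DataFrame:
    """Self-alignment scores of reference sequences under unit match scoring.

    Aligning a sequence against itself with score 1 per match yields its
    length in residues, so ``self_score(gene) = len(sequence)``.

    ``sequences`` may be a FASTA path, an iterable of Bio.SeqRecord, or an
    iterable of (id, sequence) pairs.  Returns a DataFrame indexed by
    ``gene_id`` with a ``self_score`` column.
    """
    if isinstance(sequences, (str, Path)):
        from Bio import SeqIO

        records = ((r.id, str(r.seq)) for r in SeqIO.parse(str(sequences), "fasta"))
        return self_scores(records)
    ids: list[str] = []
    lengths: list[int] = []
    seen: set[str] = set()
    for rec in sequences:
        if hasattr(rec, "id") and hasattr(rec, "seq"):
            gene_id, seq = rec.id, str(rec.seq)
        else:
            gene_id, seq = rec
        if gene_id in seen:
            raise ValueError(f"duplicate reference id: {gene_id!r}")
        if len(seq) == 0:
            raise ValueError(f"zero-length reference sequence: {gene_id!r}")
        seen.add(gene_id)
        ids.append(gene_id)
        lengths.append(len(seq))
    if not ids:
        raise ValueError("no reference sequences provided")
    return pd.DataFrame({"self_score": lengths}, index=pd.Index(ids, name="gene_id"))


def read_self_scores(path: str | Path) -> pd.DataFrame:
    """Read a precomputed (gene_id, self_score) TSV as a ReferenceSet table."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "self_score" not in df.columns:
        raise ValueError("self-score TSV needs 'gene_id' and 'self_score' columns")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in self-score table")
    out = df.set_index("gene_id")
    if (out["self_score"] <= 0).any():
        raise ValueError("self scores must be positive")
    return out


def normalize_scores(
    scores: pd.DataFrame,
    refs: pd.DataFrame,
    *,
    floor: float = SCORE_FLOOR,
    genome_order: str = "input",
) -> pd.DataFrame:
    """Normalize best-hit scores by reference self-scores, clamped to [1/20, 1].

    value(i, j) = clamp(S(g_i; r_j) / S(r_j; r_j), floor, 1.0).  Pairs absent
    from ``scores`` count as raw score 0 and therefore normalize to the floor
    (absence of detectable homology is treated as maximal divergence).  Raw
    bit-scores exceeding the unit-match self-score clamp to 1.0.
    """
    if not set(scores["gene_id"]).issubset(set(refs.index)):
        extra = sorted(set(scores["gene_id"]) - set(refs.index))
        raise ValueError(f"scored genes missing from reference set: {extra[:5]}")
    if (refs["self_score"] <= 0).any():
        raise ValueError("self scores must be positive")
    genomes = list(dict.fromkeys(scores["genome_id"]))
    if genome_order == "sorted":
        genomes = sorted(genomes)
    elif genome_order != "input":
        raise ValueError("genome_order must be 'input' or 'sorted'")
    wide = (
        scores.pivot(index="genome_id", columns="gene_id", values="score")
        .reindex(index=genomes, columns=refs.index)
        .fillna(0.0)
    )
    norm = wide.div(refs["self_score"], axis=1).clip(lower=floor, upper=1.0)
    norm.columns.name = None
    norm.index.name = None
    return norm


def filter_references(
    m: pd.DataFrame, threshold: float = 0.5
) -> tuple[pd.DataFrame, list[str]]:
    """Discard gene columns whose normalized score is below ``threshold``
    in every genome; such genes show no clear similarity anywhere and add
    noise rather than information.  Returns (kept matrix, discarded genes),
    preserving the survivors' column order.
    """
    if m.empty:
        raise ValueError("empty normalized-score matrix")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    keep = m.max(axis=0) >= threshold
    discarded = [g for g, k in keep.items() if not k]
    if discarded:
        logger.info("discarded %d reference genes below %.2f", len(discarded), threshold)
    return m.loc[:, keep], discarded


def jc_distance(s, *, eps: float = JC_EPS):
    """20-state Jukes-Cantor distance for a normalized score in [1/20, 1].

    d = -(19/20) * ln(max((20 s - 1) / 19, eps)).  d = 0 iff s = 1; the
    transform diverges at the saturation score s = 1/20, so the log argument
    is floored at ``eps``, capping the distance at D_max = -(19/20) ln(eps).
    Scalar in, scalar out; array in, array out.
    """
    arr = np.asarray(s, dtype=float)
    if np.any(arr < SCORE_FLOOR - 1e-12) or np.any(arr > 1.0 + 1e-12):
        raise ValueError("normalized score outside [1/20, 1]; clamp first")
    d = -(19.0 / 20.0) * np.log(np.maximum((20.0 * arr - 1.0) / 19.0, eps))
    d = np.maximum(d, 0.0)  # guard -0.0 / roundoff at s == 1
    if np.isscalar(s):
        return float(d)
    return d


def jc_inverse(d, *, eps: float = JC_EPS):
    """Inverse of :func:`jc_distance` on (0.05, 1]: s = (1 + 19 e^{-d/0.95})/20."""
    arr = np.asarray(d, dtype=float)
    s = (1.0 + 19.0 * np.exp(-arr / 0.95)) / 20.0
    if np.isscalar(d):
        return float(s)
    return s


def build_genotype_matrix(
    scores: pd.DataFrame,
    refs: pd.DataFrame,
    *,
    threshold: float = 0.5,
    eps: float = JC_EPS,
    genome_order: str = "input",
) -> GenotypeMatrix:
    """Full feature pipeline: normalize -> filter -> Jukes-Cantor transform.

    Requires at least 2 genomes and 1 surviving gene.  Row order is the input
    genome order (or sorted, per ``genome_order``); discarded genes are
    recorded on the result.
    """
    norm = normalize_scores(scores, refs, genome_order=genome_order)
    if norm.shape[0] < 2:
        raise ValueError("need at least 2 genomes to build a genotype matrix")
    kept, discarded = filter_references(norm, threshold)
    if kept.shape[1] == 0:
        raise ValueError("no reference genes survive the similarity filter")
    dist = pd.DataFrame(
        jc_distance(kept.to_numpy(), eps=eps), index=kept.index, columns=kept.columns
    )
    return GenotypeMatrix(frame=dist, d_max=jc_dmax(eps), discarded=discarded)


def write_discarded(discarded: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in discarded))


def read_genotype_matrix(path: str | Path, *, eps: float = JC_EPS) -> GenotypeMatrix:
    """Read a genotype-matrix TSV written by :meth:`GenotypeMatrix.to_tsv`."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index.name = None
    return GenotypeMatrix(frame=frame, d_max=jc_dmax(eps))
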