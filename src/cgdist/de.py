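"""Differential-expression selection and GO-term summaries.

Works from an already-corrected DE gene table (columns: gene symbol, gene
ID, fold change as the after/before expression ratio, adjusted p value).
Selection uses the classical |2|-fold rule: a gene is *up* when fold
change >= T and p < P, *down* when fold change <= 1/T and p < P (T = 2,
P = 0.05 by default; fold bounds inclusive, p strict), else *unchanged*.

Each GO term is summarized by the net-direction Z-score

    z = (n_up - n_down) / sqrt(count)

over the term's genes present in the DE table, and a binary gene-by-term
occurrence matrix records multi-term membership, rows sorted by |log2
fold change| descending.

The packaged GO membership file is synthetic/illustrative — real
assignments depend on the annotation release — so any quantitative use
should supply its own membership CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("gene", "gene_id", "fold_change", "p_value")


@dataclass(frozen=True)
class DEGene:
    """One DE-table row with the derived direction call."""

    symbol: str
    gene_id: str
    fold_change: float  # after/before expression ratio, > 0
    p_value: float
    log_fc: float  # log2(fold_change)
    direction: str = "unchanged"  # {up, down, unchanged}


@dataclass(frozen=True)
class GoTermSet:
    """A GO BP term and its member gene symbols."""

    term: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"term {self.term!r} has no members")


@dataclass(frozen=True)
class GoZScore:
    """Net direction of change of one term: (up - down) / sqrt(count)."""

    term: str
    count: int
    n_up: int
    n_down: int
    z: float


def packaged_table2_path() -> Path:
    """The packaged 39-gene DE table (verbatim transcription)."""
    return Path(str(resources.files("cgdist").joinpath("data/table2.csv")))


def packaged_go_membership_path() -> Path:
    """The packaged synthetic/illustrative five-term GO membership CSV."""
    return Path(str(resources.files("cgdist").joinpath("data/go_membership_synthetic.csv")))


def read_de_table(path: str | Path) -> list[DEGene]:
    """Read a DE table CSV into :class:`DEGene` records.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        For non-positive fold changes (naming the row), bad p values, or
        duplicate gene symbols.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"DE table is missing columns {missing}")
    dupes = df["gene"][df["gene"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate gene symbols: {sorted(set(dupes))}")
    genes = []
    for i, row in df.iterrows():
        fc = float(row["fold_change"])
        if not fc > 0:
            raise ValidationError(
                f"row {i} ({row['gene']}): fold_change must be > 0, got {fc}"
            )
        p = float(row["p_value"])
        if not 0.0 < p <= 1.0:
            raise ValidationError(f"row {i} ({row['gene']}): p_value must be in (0,1], got {p}")
        genes.append(
            DEGene(
                symbol=str(row["gene"]),
                gene_id=str(row["gene_id"]),
                fold_change=fc,
                p_value=p,
                log_fc=float(np.log2(fc)),
            )
        )
    return genes


def classify_de(
    genes: list[DEGene],
    fold_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> tuple[dict[str, int], list[DEGene]]:
    """Call each gene up/down/unchanged and tally the counts.

    Fold bounds are inclusive (>= T up, <= 1/T down), the p cut strict
    (< P).  Returns ``({'up': ..., 'down': ..., 'unchanged': ...},
    classified_genes)``.
    """
    if not fold_threshold > 1.0:
        raise ValidationError(f"fold_threshold must be > 1, got {fold_threshold}")
    if not 0.0 < p_threshold <= 1.0:
        raise ValidationError(f"p_threshold must be in (0,1], got {p_threshold}")
    classified = []
    counts = {"up": 0, "down": 0, "unchanged": 0}
    for g in genes:
        if g.p_value < p_threshold and g.fold_change >= fold_threshold:
            direction = "up"
        elif g.p_value < p_threshold and g.fold_change <= 1.0 / fold_threshold:
            direction = "down"
        else:
            direction = "unchanged"
        counts[direction] += 1
        classified.append(
            DEGene(
                symbol=g.symbol,
                gene_id=g.gene_id,
                fold_change=g.fold_change,
                p_value=g.p_value,
                log_fc=g.log_fc,
                direction=direction,
            )
        )
    return counts, classified


def read_go_membership(path: str | Path) -> list[GoTermSet]:
    """Read a (term, gene) membership CSV into :class:`GoTermSet` records."""
    df = pd.read_csv(path)
    for col in ("term", "gene"):
        if col not in df.columns:
            raise SchemaError(f"GO membership table is missing column {col!r}")
    return [
        GoTermSet(term=term, members=frozenset(sub["gene"]))
        for term, sub in df.groupby("term", sort=True)
    ]


def go_zscore(term: GoTermSet, classified: list[DEGene]) -> GoZScore:
    """Summarize one term's net direction over the classified DE genes.

    Term members absent from the DE table are dropped (and logged).

    Raises
    ------
    ValidationError
        If no term member is present in the DE table.
    """
    by_symbol = {g.symbol: g for g in classified}
    present = sorted(term.members & by_symbol.keys())
    absent = sorted(term.members - by_symbol.keys())
    if absent:
        log.info("term %r: %d members absent from DE table: %s", term.term, len(absent), absent)
    if not present:
        raise ValidationError(f"term {term.term!r} shares no genes with the DE table")
    n_up = sum(1 for s in present if by_symbol[s].direction == "up")
    n_down = sum(1 for s in present if by_symbol[s].direction == "down")
    count = len(present)
    return GoZScore(
        term=term.term,
        count=count,
        n_up=n_up,
        n_down=n_down,
        z=(n_up - n_down) / np.sqrt(count),
    )


def occurrence_matrix(terms: list[GoTermSet], classified: list[DEGene]) -> pd.DataFrame:
    """Binary gene-by-term incidence over DE-table genes.

    Rows (genes) sorted by |log2 fold change| descending; a trailing
    ``term_count`` column gives each gene's multi-term membership.  Terms
    with no DE-table gene are excluded with a warning.
    """
    if not terms:
        raise ValidationError("at least one term is required")
    symbols = {g.symbol for g in classified}
    kept = []
    for t in terms:
        if t.members & symbols:
            kept.append(t)
        else:
            log.warning("term %r references no DE gene; excluded", t.term)
    order = sorted(
        (g for g in classified if any(g.symbol in t.members for t in kept)),
        key=lambda g: -abs(g.log_fc),
    )
    mat = pd.DataFrame(
        {t.term: [int(g.symbol in t.members) for g in order] for t in kept},
        index=[g.symbol for g in order],
    )
    mat["term_count"] = mat.sum(axis=1)
    mat.index.name = "gene"
    return mat


def summarize_de(
    de_csv: str | Path,
    go_csv: str | Path | None = None,
    fold_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> dict:
    """One-call DE summary: counts, per-term Z-scores, occurrence matrix."""
    genes = read_de_table(de_csv)
    counts, classified = classify_de(genes, fold_threshold, p_threshold)
    out: dict = {"counts": counts, "n_genes": len(genes), "classified": classified}
    if go_csv is not None:
        terms = read_go_membership(go_csv)
        out["zscores"] = [go_zscore(t, classified) for t in terms]
        out["occurrence"] = occurrence_matrix(terms, classified)
    return out
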