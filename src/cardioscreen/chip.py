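"""Histone-mark ChIP signal quantification, one scheme per mark.

* H2Bub1: median-of-ratios library normalization, counts divided by gene
  length (first TSS to last TSE), replicates averaged, identically
  processed input subtracted; a gene is "occupied" when its signal is > 0.
* H3K4me3: RPKM-scale maximum per-base signal in a +/- 1 kb window around
  each TSS, replicates averaged, input subtracted, best TSS kept per gene;
  genes are retained above a 500-RPKM floor.
* H3K36me3: gene-body RPKM normalized to gene length, replicates averaged;
  the top quintile by score is retained.

All functions accept feature-count tables (the simulator's native output);
negative post-subtraction signals are kept as-is so stage deltas remain
linear, with the occupancy call handling the sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .screenstats import size_factors


class ChipError(ValueError):
    pass


@dataclass(frozen=True)
class StageDesign:
    """Columns of one stage/genotype: ChIP replicate columns and the input."""

    chip: tuple[str, ...]
    input: str


def _rpkm(counts: pd.Series, library_size: float, length_bp: pd.Series | float) -> pd.Series:
    if library_size <= 0:
        raise ChipError("zero or negative library size")
    return counts * 1e9 / (library_size * length_bp)


def h2bub_gene_signal(
    counts: pd.DataFrame,
    stages: Mapping[str, StageDesign],
    gene_lengths: pd.Series,
    stage_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Gene-body H2Bub1 signal per stage, occupancy calls and stage delta.

    ``counts``: genes x samples raw gene-body read counts for every ChIP
    replicate and input listed in ``stages``.  Size factors are computed
    jointly across all columns so stages are comparable.  When two stages
    are given, ``delta`` is second minus first in ``stage_order`` (default:
    mapping order) — adult minus neonatal in the maturation design.
    """
    for st, d in stages.items():
        if len(d.chip) < 1:
            raise ChipError(f"stage {st}: need >= 1 ChIP replicate")
    genes = counts.index.intersection(gene_lengths.dropna().index)
    dropped = counts.index.difference(genes)
    if len(dropped):
        import warnings

        warnings.warn(f"{len(dropped)} genes absent from annotation; skipped")
    counts = counts.loc[genes]
    lengths = gene_lengths.loc[genes].astype(float)

    sf = size_factors(counts)
    per_kb = counts.div(sf, axis=1).div(lengths / 1e3, axis=0)

    out = pd.DataFrame(index=genes)
    order = list(stage_order) if stage_order is not None else list(stages)
    for st in order:
        d = stages[st]
        chip_avg = per_kb[list(d.chip)].mean(axis=1)
        signal = chip_avg - per_kb[d.input]
        out[f"signal_{st}"] = signal
        out[f"occupied_{st}"] = signal > 0
    if len(order) == 2:
        out["delta"] = out[f"signal_{order[1]}"] - out[f"signal_{order[0]}"]
    return out


def h3k4me3_tss_signal(
    tss_table: pd.DataFrame,
    design: StageDesign,
    library_sizes: Mapping[str, float],
    floor: float = 500.0,
) -> pd.DataFrame:
    """Best-TSS H3K4me3 promoter score per gene.

    ``tss_table``: one row per TSS with a ``gene_id`` column plus, per
    sample, the maximum per-base read coverage in the TSS +/- 1 kb window.
    Coverage is converted to the RPKM scale (per-base coverage x 1e9 /
    library size), replicates averaged and input subtracted; the
    highest-scoring TSS represents the gene; ``retained`` iff score > floor.
    """
    if "gene_id" not in tss_table.columns:
        raise ChipError("tss_table must carry a gene_id column")
    score = pd.Series(0.0, index=tss_table.index)
    for col in design.chip:
        score = score + _rpkm(tss_table[col], float(library_sizes[col]), 1.0)
    score = score / len(design.chip)
    score = score - _rpkm(
        tss_table[design.input], float(library_sizes[design.input]), 1.0
    )
    scored = tss_table[["gene_id"]].assign(score=score)
    scored = scored.sort_values(["gene_id", "score"], ascending=[True, False])
    best = scored.groupby("gene_id", sort=True).head(1)
    out = pd.DataFrame(
        dict(best_tss=best.index, score=best["score"].to_numpy()),
        index=pd.Index(best["gene_id"], name="gene_id"),
    )
    out["retained"] = out["score"] > floor
    return out


def h3k36me3_gene_signal(
    counts: pd.DataFrame,
    design: StageDesign | Sequence[str],
    library_sizes: Mapping[str, float],
    gene_lengths: pd.Series,
    quintile: float = 0.2,
) -> pd.DataFrame:
    """Gene-body H3K36me3 RPKM with the retained top-quintile set.

    Input subtraction is applied only when ``design`` carries an input
    column.  Ties at the quintile boundary break deterministically by gene
    id.  ``retained`` marks the top ``quintile`` fraction by score.
    """
    if isinstance(design, StageDesign):
        chip_cols, input_col = list(design.chip), design.input
    else:
        chip_cols, input_col = list(design), None
    lengths = gene_lengths.loc[counts.index].astype(float)
    score = pd.Series(0.0, index=counts.index)
    for col in chip_cols:
        score = score + _rpkm(counts[col], float(library_sizes[col]), lengths)
    score = score / len(chip_cols)
    if input_col is not None:
        score = score - _rpkm(counts[input_col], float(library_sizes[input_col]), lengths)
    out = pd.DataFrame(dict(score=score))
    n_keep = int(round(len(out) * quintile))
    ranked = out.assign(gene=out.index).sort_values(
        ["score", "gene"], ascending=[False, True]
    )
    keep = set(ranked.index[:n_keep])
    out["retained"] = [g in keep for g in out.index]
    return out


def shared_occupancy_fraction(signal: pd.DataFrame, stages: Sequence[str]) -> float:
    """Fraction of ever-occupied genes occupied at every stage."""
    occ = signal[[f"occupied_{s}" for s in stages]]
    any_occ = occ.any(axis=1)
    if not any_occ.any():
        return float("nan")
    return float(occ.all(axis=1)[any_occ].mean())
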