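"""Epigenome-transcriptome integration of cardiomyocyte maturation.

Links maturational gene-expression change (adult P28 vs neonatal P1),
maturational H2Bub1 change, and the transcriptional response to RNF20/40
knockout: maturational fold changes by the NB-Wald core, custom
adult/neonatal stage gene sets, preranked GSEA, binned delta summaries,
quadrant classification of knockout-responsive genes, and Fisher exact
contingency tests on the quadrant tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .screenstats import nb_two_group_test


class IntegrationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Maturational differential expression and stage gene sets


def maturational_fc(
    counts_p1: pd.DataFrame, counts_p28: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene log2 fold change (P28 vs P1) with Wald and BH-adjusted p."""
    if counts_p1.shape[1] < 2 or counts_p28.shape[1] < 2:
        raise IntegrationError("need >= 2 replicates per stage")
    combined = pd.concat([counts_p1, counts_p28], axis=1)
    cond = [False] * counts_p1.shape[1] + [True] * counts_p28.shape[1]
    return nb_two_group_test(combined, cond)


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise IntegrationError(f"gene set {self.name}: duplicate members")

    def __len__(self) -> int:
        return len(self.members)


def make_stage_gene_sets(
    fc_table: pd.DataFrame, k: int = 100
) -> tuple[GeneSet, GeneSet]:
    """Top-k and bottom-k genes by maturational fold change.

    The highest ``k`` genes form the adult-specific set, the lowest ``k``
    the neonatal-specific set; ties break deterministically by gene id.
    """
    fc = fc_table["log2fc"].dropna()
    if len(fc) < 2 * k:
        raise IntegrationError(f"need >= {2 * k} ranked genes, have {len(fc)}")
    ranked = fc.reset_index()
    ranked.columns = ["gene", "log2fc"]
    ranked = ranked.sort_values(["log2fc", "gene"], ascending=[False, True])
    adult = GeneSet("adult_specific", tuple(ranked["gene"].head(k)))
    neonatal = GeneSet("neonatal_specific", tuple(ranked["gene"].tail(k)))
    return adult, neonatal


# ---------------------------------------------------------------------------
# Preranked GSEA


@dataclass(frozen=True)
class GseaResult:
    name: str
    es: float
    nes: float
    nominal_p: float
    size: int
    n_perm: int


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n_total: int
) -> np.ndarray:
    """Signed running-sum extremum for one or more hit-position sets.

    ``positions``: (n_sets, h) ascending hit indices in the ranking;
    ``weights``: matching |score|^w weights.  The running sum increments by
    weight/total at hits and decrements 1/(N-h) at misses; its extremum is
    attained adjacent to a hit, so only those points are evaluated.
    """
    n_sets, h = positions.shape
    n_miss = n_total - h
    w_tot = weights.sum(axis=1, keepdims=True)
    w_tot = np.where(w_tot == 0, 1.0, w_tot)
    cw = np.cumsum(weights, axis=1) / w_tot
    i = np.arange(1, h + 1)
    miss_after = (positions + 1 - i) / n_miss
    miss_before = (positions - (i - 1)) / n_miss
    dev_hi = cw - miss_after
    dev_lo = np.concatenate(
        [np.zeros((n_sets, 1)), cw[:, :-1]], axis=1
    ) - miss_before
    # interleave (before-hit, after-hit) in walk order so that equal-magnitude
    # extrema resolve to the first one encountered along the ranking
    alldev = np.empty((n_sets, 2 * h))
    alldev[:, 0::2] = dev_lo
    alldev[:, 1::2] = dev_hi
    idx = np.argmax(np.abs(alldev), axis=1)
    return alldev[np.arange(n_sets), idx]


def gsea_preranked(
    scores: pd.Series,
    gene_set: GeneSet,
    n_perm: int = 10_000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 30,
) -> GseaResult:
    """Weighted Kolmogorov-Smirnov preranked gene-set enrichment.

    ``scores`` ranks the universe (higher = more positively associated);
    the enrichment score is the signed extremum of the running sum with
    weight exponent ``weight``.  The null permutes gene labels (random
    same-size sets); nominal p is the fraction of same-sign null ES at
    least as extreme, and NES normalizes ES by the mean magnitude of the
    same-sign null.
    """
    members = set(gene_set.members)
    missing = members - set(scores.index)
    if missing:
        raise IntegrationError(
            f"gene set {gene_set.name}: {len(missing)} members outside the ranking"
        )
    if len(members) < min_size:
        raise IntegrationError(
            f"gene set {gene_set.name}: size {len(members)} below floor {min_size}"
        )
    ranked = scores.reset_index()
    ranked.columns = ["gene", "score"]
    ranked = ranked.sort_values(["score", "gene"], ascending=[False, True])
    genes = ranked["gene"].to_numpy()
    vals = ranked["score"].to_numpy(dtype=float)
    n = len(genes)
    w_all = np.abs(vals) ** weight
    hit_mask = np.isin(genes, list(members))
    pos_obs = np.where(hit_mask)[0][None, :]
    es = float(_es_from_positions(pos_obs, w_all[pos_obs], n)[0])

    h = int(hit_mask.sum())
    rng = np.random.default_rng(seed)
    null_pos = np.sort(
        np.stack([rng.choice(n, size=h, replace=False) for _ in range(n_perm)]),
        axis=1,
    )
    null_es = _es_from_positions(null_pos, w_all[null_pos], n)

    same_sign = null_es >= 0 if es >= 0 else null_es <= 0
    pool = np.abs(null_es[same_sign])
    if pool.size == 0:
        pool = np.abs(null_es)
    nominal_p = (1.0 + (pool >= abs(es)).sum()) / (pool.size + 1.0)
    nes = es / pool.mean() if pool.mean() > 0 else float("nan")
    return GseaResult(gene_set.name, es, float(nes), float(nominal_p), h, n_perm)


# ---------------------------------------------------------------------------
# Binning, quadrants, Fisher


def bin_delta_summary(
    table: pd.DataFrame,
    edges: Sequence[float],
    value_cols: Sequence[str] = ("h2bub_p1", "h2bub_delta"),
    fc_col: str = "rna_log2fc_maturation",
) -> pd.DataFrame:
    """Box-plot summaries of ChIP values across maturational-RNA bins.

    Bins are left-open right-closed, matching "(-1, 0]" style notation.
    Whisker bounds are quartile -/+ 1.5 x IQR.
    """
    df = table.dropna(subset=[fc_col])
    bins = pd.cut(df[fc_col], bins=list(edges), right=True)
    rows = []
    for col in value_cols:
        for interval, grp in df.groupby(bins, observed=False):
            v = grp[col].dropna()
            if len(v):
                q1, med, q3 = np.percentile(v, [25, 50, 75])
                iqr = q3 - q1
                lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            else:
                q1 = med = q3 = lo = hi = np.nan
            rows.append(
                dict(
                    variable=col,
                    bin=str(interval),
                    n=len(v),
                    median=med,
                    q1=q1,
                    q3=q3,
                    whisker_lo=lo,
                    whisker_hi=hi,
                )
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p_two_sided: float
    p_greater: float
    p_less: float

    def as_dict(self) -> dict:
        return dict(
            odds_ratio=self.odds_ratio,
            p_two_sided=self.p_two_sided,
            p_greater=self.p_greater,
            p_less=self.p_less,
        )


def fisher_quadrant(table: Sequence[Sequence[int]]) -> FisherResult:
    """Exact hypergeometric test of a 2x2 table.

    Reports the standard two-sided p (sum of table probabilities <= the
    observed one) and both one-sided tails; the odds ratio uses the Haldane
    0.5 correction when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise IntegrationError("need a 2x2 table of nonnegative integers")
    a, b = t[0]
    c, d = t[1]
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    _, p_two = stats.fisher_exact(t, alternative="two-sided")
    _, p_greater = stats.fisher_exact(t, alternative="greater")
    _, p_less = stats.fisher_exact(t, alternative="less")
    return FisherResult(float(orr), float(p_two), float(p_greater), float(p_less))


_QUADRANTS = ("UR", "UL", "LR", "LL")


def quadrant_classify(
    table: pd.DataFrame,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Quadrant labels for knockout-responsive genes plus 2x2 summaries.

    A gene is classified when |ko_log2fc| > ``lfc_threshold`` ("more than
    2-fold" on the log2 scale), ko_adj_p < ``alpha``, and both
    maturational deltas are defined.  Quadrants follow the signs of
    (rna_log2fc_maturation, h2bub_delta): UR = both positive, LL = both
    negative.  For each quadrant the summary holds the 2x2 tables of
    KO-down (and KO-up) inside versus outside the quadrant, with Fisher
    exact results.
    """
    df = table.copy()
    up = (df["ko_log2fc"] > lfc_threshold) & (df["ko_adj_p"] < alpha)
    down = (df["ko_log2fc"] < -lfc_threshold) & (df["ko_adj_p"] < alpha)
    df["ko_call"] = np.where(up, "up", np.where(down, "down", "ns"))
    defined = df["rna_log2fc_maturation"].notna() & df["h2bub_delta"].notna()
    x = df["rna_log2fc_maturation"]
    y = df["h2bub_delta"]
    quad = np.select(
        [
            (x > 0) & (y > 0),
            (x < 0) & (y > 0),
            (x > 0) & (y < 0),
            (x < 0) & (y < 0),
        ],
        ["UR", "UL", "LR", "LL"],
        default="none",
    )
    classified = defined & (df["ko_call"] != "ns")
    df["quadrant"] = np.where(classified, quad, "none")

    summaries: dict = {}
    cls = df[df["quadrant"].isin(_QUADRANTS)]
    for q in _QUADRANTS:
        in_q = cls["quadrant"] == q
        out_q = ~in_q
        summary = {"n": int(in_q.sum())}
        for call in ("down", "up"):
            a = int((in_q & (cls["ko_call"] == call)).sum())
            bb = int((in_q & (cls["ko_call"] != call)).sum())
            cc = int((out_q & (cls["ko_call"] == call)).sum())
            dd = int((out_q & (cls["ko_call"] != call)).sum())
            t = [[a, bb], [cc, dd]]
            fisher = (
                fisher_quadrant(t).as_dict()
                if (a + bb) and (cc + dd)
                else None
            )
            summary[f"ko_{call}"] = dict(table=t, fisher=fisher)
        summaries[q] = summary
    return df, summaries
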