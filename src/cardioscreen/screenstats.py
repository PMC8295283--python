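"""Guide- and gene-level screen enrichment statistics.

Two-level readout of a pooled screen: per-guide differential representation
(sorted vs input) by a negative-binomial Wald test with median-of-ratios
library normalization and Benjamini-Hochberg correction, then gene-level
consolidation of the (typically six) guides per gene with an
alpha-restricted robust-rank-aggregation score and a permutation p-value.

The NB core deliberately implements only the Wald test machinery: per-guide
method-of-moments dispersion shrunk 50/50 (in log space) toward a log-linear
mean-dispersion trend, exact group-mean MLEs at fixed dispersion via Fisher
scoring, and a normal-null Wald statistic on log2 fold change.  No Cook's
distance filtering, LFC shrinkage, or independent filtering.  Guides that
cannot support the model (all-zero in a group) are flagged rather than
pseudo-counted, and are excluded from the BH denominator.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

_LN2 = np.log(2.0)
_DISP_FLOOR = 1e-8
_DISP_CEIL = 20.0


class StatsError(ValueError):
    pass


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one per sample/column).

    Per sample, the median over features of count / geometric-mean-across-
    samples, computed over features with all-nonzero rows.  If no row is
    all-nonzero, falls back (with a warning) to rows nonzero in >= 90% of
    samples, with geometric means and ratios taken over the nonzero entries.
    """
    X = counts.to_numpy(dtype=float)
    if X.size == 0:
        raise StatsError("empty count table")
    all_nonzero = (X > 0).all(axis=1)
    if all_nonzero.any():
        sub = X[all_nonzero]
        geo = np.exp(np.log(sub).mean(axis=1))
        sf = np.median(sub / geo[:, None], axis=0)
    else:
        frac = (X > 0).mean(axis=1)
        rows = frac >= 0.9
        if not rows.any():
            raise StatsError("no feature detected in >= 90% of samples")
        warnings.warn(
            "no all-nonzero feature row; using rows nonzero in >= 90% of samples"
        )
        sub = X[rows]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(sub), np.nan)
        geo = np.exp(np.nanmean(logs, axis=1))
        ratios = np.where(sub > 0, sub / geo[:, None], np.nan)
        sf = np.nanmedian(ratios, axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment; NaN entries pass through."""
    out = pd.Series(np.nan, index=p.index)
    ok = p.notna()
    if ok.any():
        out[ok] = multipletests(p[ok].to_numpy(), method="fdr_bh")[1]
    return out


def _mom_dispersion(norm: np.ndarray, groups: Sequence[np.ndarray], inv_sf_mean: float):
    """Pooled within-group method-of-moments dispersion per feature."""
    num = np.zeros(norm.shape[0])
    den = 0.0
    mean_all = np.zeros(norm.shape[0])
    for idx in groups:
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(idx) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m * inv_sf_mean) / np.square(m)
        a = np.where(np.isfinite(a), a, 0.0)
        num += w * a
        den += w
        mean_all += m / len(groups)
    return np.clip(num / den, 0.0, None), mean_all


def _fit_group_mean(y: np.ndarray, sf: np.ndarray, alpha: np.ndarray):
    """MLE of the group mean of an NB log-link model with sample offsets.

    Solves sum_j (y_j - mu_j) / (1 + alpha*mu_j) = 0 with mu_j = sf_j * m
    by Fisher scoring on eta = log m, vectorized across features.  Returns
    (eta, fisher_information); features with zero group total get -inf eta.
    """
    tot = y.sum(axis=1)
    m0 = np.maximum((y / sf).mean(axis=1), 1e-8)
    eta = np.log(m0)
    a = alpha[:, None]
    for _ in range(50):
        mu = sf * np.exp(eta)[:, None]
        denom = 1.0 + a * mu
        U = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = U / np.maximum(info, 1e-12)
        step = np.clip(step, -3.0, 3.0)
        eta = eta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = sf * np.exp(eta)[:, None]
    info = (mu / (1.0 + a * mu)).sum(axis=1)
    eta = np.where(tot > 0, eta, -np.inf)
    return eta, info


def nb_two_group_test(
    counts: pd.DataFrame,
    condition: Sequence[bool],
    sf: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """NB Wald test of the ``condition=True`` group versus the reference group.

    Returns a frame indexed like ``counts`` with columns base_mean, log2fc,
    wald_se, wald_stat, wald_p, bh_adj_p and status ('ok', 'all_zero', or
    'group_zero' for guides unusable without a pseudo-count).
    """
    cond = np.asarray(condition, dtype=bool)
    if cond.sum() < 2 or (~cond).sum() < 2:
        raise StatsError("need >= 2 samples per group")
    if sf is None:
        sf = size_factors(counts)
    sfv = sf.to_numpy(dtype=float)
    Y = counts.to_numpy(dtype=float)
    norm = Y / sfv
    inv_sf_mean = float(np.mean(1.0 / sfv))
    groups = [np.where(~cond)[0], np.where(cond)[0]]
    alpha_raw, _ = _mom_dispersion(norm, groups, inv_sf_mean)
    base_mean = norm.mean(axis=1)

    # log-linear mean-dispersion trend, 50/50 shrinkage in log space
    ok = (alpha_raw > 1e-6) & (base_mean > 0)
    la = np.log(np.clip(alpha_raw, _DISP_FLOOR, _DISP_CEIL))
    if ok.sum() >= 10:
        b, a0 = np.polyfit(np.log(base_mean[ok]), la[ok], 1)
        trend = a0 + b * np.log(np.maximum(base_mean, 1e-8))
    else:
        trend = np.full_like(la, np.median(la[ok]) if ok.any() else np.log(0.01))
    alpha = np.exp(0.5 * (la + trend))
    alpha = np.clip(alpha, _DISP_FLOOR, _DISP_CEIL)

    eta_ref, info_ref = _fit_group_mean(Y[:, groups[0]], sfv[groups[0]], alpha)
    eta_alt, info_alt = _fit_group_mean(Y[:, groups[1]], sfv[groups[1]], alpha)

    all_zero = Y.sum(axis=1) == 0
    group_zero = (~all_zero) & (
        (Y[:, groups[0]].sum(axis=1) == 0) | (Y[:, groups[1]].sum(axis=1) == 0)
    )
    usable = ~(all_zero | group_zero)

    with np.errstate(invalid="ignore"):
        lfc = (eta_alt - eta_ref) / _LN2
        se = np.sqrt(1.0 / np.maximum(info_ref, 1e-12) + 1.0 / np.maximum(info_alt, 1e-12)) / _LN2
        z = lfc / se
    lfc[~usable] = np.nan
    se[~usable] = np.nan
    z[~usable] = np.nan
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[~usable] = np.nan

    out = pd.DataFrame(
        dict(
            base_mean=base_mean,
            log2fc=lfc,
            wald_se=se,
            wald_stat=z,
            wald_p=p,
            dispersion=alpha,
        ),
        index=counts.index,
    )
    out["bh_adj_p"] = bh_adjust(out["wald_p"])
    status = np.where(all_zero, "all_zero", np.where(group_zero, "group_zero", "ok"))
    out["status"] = status
    return out


def guide_test(
    counts: pd.DataFrame,
    roles: Mapping[str, str],
    qc_pass: Optional[Mapping[str, bool]] = None,
) -> pd.DataFrame:
    """Per-guide sorted-vs-input NB Wald test on QC-passing samples."""
    samples = [s for s in counts.columns if qc_pass is None or qc_pass.get(s, True)]
    if not samples:
        raise StatsError("no QC-passing samples")
    cond = [roles[s] == "sorted" for s in samples]
    return nb_two_group_test(counts[samples], cond)


# ---------------------------------------------------------------------------
# alpha-RRA gene aggregation


def _rho_matrix(u_sorted: np.ndarray, n_sig: np.ndarray) -> np.ndarray:
    """min over k <= n_sig of Beta(k, m-k+1) CDF of the k-th smallest u.

    ``u_sorted``: (n_sets, m) ascending normalized ranks; rho = 1 when a set
    has no alpha-significant guide.
    """
    n_sets, m = u_sorted.shape
    k = np.arange(1, m + 1)
    beta_cdf = special.betainc(k, m - k + 1, u_sorted)
    mask = k[None, :] > n_sig[:, None]
    beta_cdf = np.where(mask, np.inf, beta_cdf)
    rho = beta_cdf.min(axis=1)
    return np.where(np.isfinite(rho), rho, 1.0)


def gene_rra(
    stats_table: pd.DataFrame,
    gene_map: pd.Series,
    direction: str = "enrich",
    alpha_p: float = 0.001,
    n_perm: int = 10_000,
    seed: int = 0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Robust rank aggregation of guide statistics into gene scores.

    Guides are ranked by their one-sided p in the requested direction
    (derived from the signed Wald statistic); only guides with one-sided
    p < ``alpha_p`` contribute order statistics to a gene's rho.  The gene
    p-value comes from permuting the guide-to-gene assignment (preserving
    guides-per-gene counts): random same-size guide sets when
    ``exhaustive=False``, all combinations otherwise.  Non-targeting guides
    (gene NA) stay in the ranking but receive no gene score.
    """
    if direction not in ("enrich", "deplete"):
        raise StatsError(f"unknown direction {direction!r}")
    z = stats_table["wald_stat"]
    testable = z.notna()
    z = z[testable]
    p1 = pd.Series(
        stats.norm.sf(z.to_numpy()) if direction == "enrich" else stats.norm.cdf(z.to_numpy()),
        index=z.index,
    )
    order = sorted(p1.index, key=lambda g: (p1[g], g))
    n = len(order)
    u = pd.Series((np.arange(n) + 1) / n, index=order)
    sig = p1 < alpha_p

    gm = gene_map.reindex(p1.index)
    genes = sorted(gm.dropna().unique())
    u_by_guide = u
    sig_by_guide = sig

    rng = np.random.default_rng(seed)
    all_u = u_by_guide.loc[order].to_numpy()
    all_sig = sig_by_guide.loc[order].to_numpy()

    # observed rho per gene
    rows = []
    sizes: dict[int, list[int]] = {}
    for gi, gene in enumerate(genes):
        gids = gm.index[gm == gene]
        gu = np.sort(u_by_guide.loc[gids].to_numpy())
        gsig = int(sig_by_guide.loc[gids].sum())
        rho = float(_rho_matrix(gu[None, :], np.array([gsig]))[0])
        rows.append(dict(gene=gene, n_guides=len(gids), n_sig=gsig, rho=rho))
        sizes.setdefault(len(gids), []).append(gi)

    # permutation null per gene size, shared across genes of that size
    null_by_size: dict[int, np.ndarray] = {}
    for m in sizes:
        if exhaustive:
            combos = np.array(list(combinations(range(n), m)), dtype=int)
            idx = combos
        else:
            idx = np.stack(
                [rng.choice(n, size=m, replace=False) for _ in range(n_perm)]
            )
        U = np.sort(all_u[idx], axis=1)
        S = all_sig[idx].sum(axis=1)
        null_by_size[m] = np.sort(_rho_matrix(U, S))

    out = pd.DataFrame(rows).set_index("gene")
    pvals = np.empty(len(out))
    for i, (gene, row) in enumerate(out.iterrows()):
        null = null_by_size[int(row["n_guides"])]
        n_le = int(np.searchsorted(null, row["rho"] + 1e-12, side="right"))
        pvals[i] = (1.0 + n_le) / (len(null) + 1.0)
    out["p"] = pvals
    order_idx = np.lexsort(
        (out.index.to_numpy(), out["rho"].to_numpy(), out["p"].to_numpy())
    )
    ranks = np.empty(len(out), dtype=int)
    ranks[order_idx] = np.arange(1, len(out) + 1)
    out["rank"] = ranks
    return out


def score_genes(
    stats_table: pd.DataFrame,
    gene_map: pd.Series,
    alpha_p: float = 0.001,
    n_perm: int = 10_000,
    seed: int = 0,
    sig_adj_alpha: float = 0.001,
) -> pd.DataFrame:
    """Both-direction gene score table (enrich_* and deplete_* columns)."""
    enr = gene_rra(stats_table, gene_map, "enrich", alpha_p, n_perm, seed)
    dep = gene_rra(stats_table, gene_map, "deplete", alpha_p, n_perm, seed + 1)
    out = pd.DataFrame(index=enr.index)
    out["n_guides"] = enr["n_guides"]
    # guides called at the screen's per-guide significance level
    adj = stats_table["bh_adj_p"]
    gm = gene_map.reindex(stats_table.index)
    nsig = (
        pd.DataFrame({"gene": gm, "sig": adj < sig_adj_alpha})
        .dropna(subset=["gene"])
        .groupby("gene")["sig"]
        .sum()
    )
    out["n_sig_guides"] = nsig.reindex(out.index).fillna(0).astype(int)
    out["enrich_rho"] = enr["rho"]
    out["enrich_p"] = enr["p"]
    out["enrich_rank"] = enr["rank"]
    out["deplete_rho"] = dep["rho"]
    out["deplete_p"] = dep["p"]
    out["deplete_rank"] = dep["rank"]
    return out
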