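"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by direct enumeration, deliberately
sharing no code with the implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import hypergeom

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_force_offtargets(spacer: str, genome: dict[str, str], max_mm: int = 2):
    """Scan every genomic position on both strands for NGG protospacers."""
    counts = [0] * (max_mm + 1)
    for seq in genome.values():
        seq = seq.upper()
        n = len(seq)
        for strand_seq in (seq, rc(seq)):
            for p in range(n - 22):
                if strand_seq[p + 21 : p + 23] != "GG":
                    continue
                proto = strand_seq[p : p + 20]
                mm = sum(1 for a, b in zip(spacer, proto) if a != b or b == "N")
                if mm <= max_mm:
                    counts[mm] += 1
    return tuple(counts)


def brute_force_oof(window: str, cut: int) -> float:
    """Exhaustive microhomology enumeration out-of-frame score."""
    window = window.upper()
    L = len(window)
    pats = []
    for k in range(cut - 1, 1, -1):
        for j in range(cut, L - k + 1):
            for i in range(0, cut - k + 1):
                if window[i : i + k] == window[j : j + k]:
                    pats.append((i, i + k, j, j + k))
    tot = oof = 0.0
    kept = []
    for idx, (i1, i2, j1, j2) in enumerate(pats):
        contained = any(
            i1 >= a and i2 <= b and j1 >= c and j2 <= d
            and (i1 - a) == (j1 - c) and (i2 - b) == (j2 - d)
            for a, b, c, d in pats[:idx]
        )
        if not contained:
            kept.append((i1, i2, j1, j2))
    for i1, i2, j1, j2 in kept:
        mh = window[i1:i2]
        gc = sum(1 for x in mh if x in "GC")
        at = len(mh) - gc
        dlen = j1 - i1
        score = 100.0 / math.exp(dlen / 20.0) * (at + 2 * gc)
        tot += score
        if dlen % 3 != 0:
            oof += score
    return 0.0 if tot == 0 else 100.0 * oof / tot


def bh_stepup(pvals):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adj[i] = running
    return adj


def rra_rho(u_sorted, n_sig):
    """min over k <= n_sig of the Beta(k, m-k+1) CDF of the k-th order stat."""
    m = len(u_sorted)
    if n_sig == 0:
        return 1.0
    return min(
        beta_dist.cdf(u_sorted[k - 1], k, m - k + 1) for k in range(1, n_sig + 1)
    )


def exhaustive_rra(u_all, sig_all, gene_indices, alpha_sorted=True):
    """rho and exhaustive-permutation p for one gene's guide set.

    ``u_all``/``sig_all``: per-guide normalized ranks and significance
    flags for the whole library; ``gene_indices``: the gene's guides.
    The null enumerates every same-size subset of the library.
    """
    m = len(gene_indices)
    gu = sorted(u_all[i] for i in gene_indices)
    gsig = sum(bool(sig_all[i]) for i in gene_indices)
    rho_obs = rra_rho(gu, gsig)
    null = []
    for combo in combinations(range(len(u_all)), m):
        cu = sorted(u_all[i] for i in combo)
        cs = sum(bool(sig_all[i]) for i in combo)
        null.append(rra_rho(cu, cs))
    n_le = sum(1 for r in null if r <= rho_obs + 1e-12)
    return rho_obs, (1.0 + n_le) / (len(null) + 1.0)


def fisher_two_sided(table) -> float:
    """Two-sided Fisher p by full enumeration over tables with fixed margins."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, col1 - (c + d)), min(row1, col1) + 1):
        px = rv.pmf(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return float(min(total, 1.0))


def gsea_es_bruteforce(scores, hit_genes, weight=1.0) -> float:
    """Enrichment score by literally walking the full running sum."""
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    hits = [g in hit_genes for g, _ in items]
    w = [abs(v) ** weight for _, v in items]
    wsum = sum(wi for wi, h in zip(w, hits) if h)
    n_miss = len(items) - sum(hits)
    running = 0.0
    best = 0.0
    for wi, h in zip(w, hits):
        if h:
            running += wi / wsum
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best
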