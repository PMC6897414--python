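"""Brute-force reference implementations used as independent oracles.

Deliberately written with plain Python loops and the statistics module
(no shared code with the package) so that agreement is meaningful.
"""

from __future__ import annotations

import math
import statistics


def sd(xs: list[float]) -> float:
    """Sample SD, n-1 denominator."""
    return statistics.stdev(xs)


def pairwise_sd_matrix(cq: dict[str, list[float]]) -> dict[tuple[str, str], float]:
    """SD across samples of Cq_j - Cq_k for every unordered gene pair."""
    genes = list(cq)
    out = {}
    for a in genes:
        for b in genes:
            if a == b:
                out[(a, b)] = 0.0
            else:
                diffs = [x - y for x, y in zip(cq[a], cq[b])]
                out[(a, b)] = sd(diffs)
    return out


def deltacq_stability(cq: dict[str, list[float]]) -> dict[str, float]:
    mat = pairwise_sd_matrix(cq)
    genes = list(cq)
    return {
        g: sum(mat[(g, k)] for k in genes if k != g) / (len(genes) - 1)
        for g in genes
    }


def quantities(cq: dict[str, list[float]], eff: dict[str, float]) -> dict[str, list[float]]:
    out = {}
    for g, row in cq.items():
        lo = min(row)
        out[g] = [eff[g] ** (lo - x) for x in row]
    return out


def genorm_m(q: dict[str, list[float]]) -> dict[str, float]:
    """Mean over partners of SD of log2 expression ratios."""
    genes = list(q)
    m = {}
    for a in genes:
        vals = []
        for b in genes:
            if b == a:
                continue
            ratios = [math.log2(x / y) for x, y in zip(q[a], q[b])]
            vals.append(sd(ratios))
        m[a] = sum(vals) / len(vals)
    return m


def nf_series(q: dict[str, list[float]], ranking: list[str]) -> dict[int, list[float]]:
    """NF_n per sample: geometric mean of the n most stable genes' Q."""
    n_samples = len(next(iter(q.values())))
    out = {}
    for n in range(2, len(ranking) + 1):
        chosen = ranking[:n]
        nf = []
        for j in range(n_samples):
            prod = 1.0
            for g in chosen:
                prod *= q[g][j]
            nf.append(prod ** (1.0 / n))
        out[n] = nf
    return out


def v_series(q: dict[str, list[float]], ranking: list[str]) -> dict[int, float]:
    """V[n/n+1] = SD over samples of log2(NF_n / NF_{n+1})."""
    nf = nf_series(q, ranking)
    out = {}
    for n in range(2, len(ranking)):
        ratios = [math.log2(a / b) for a, b in zip(nf[n], nf[n + 1])]
        out[n] = sd(ratios)
    return out


def bestkeeper_index(cq: dict[str, list[float]]) -> list[float]:
    genes = list(cq)
    n_samples = len(cq[genes[0]])
    idx = []
    for j in range(n_samples):
        prod = 1.0
        for g in genes:
            prod *= cq[g][j]
        idx.append(prod ** (1.0 / len(genes)))
    return idx


def bestkeeper_mad(xs: list[float]) -> float:
    mean = sum(xs) / len(xs)
    return sum(abs(x - mean) for x in xs) / len(xs)


def pearson(xs: list[float], ys: list[float]) -> float:
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys))
    return num / den


def normfinder_single_group(q: dict[str, list[float]]) -> dict[str, float]:
    """Literal evaluation of the single-group estimator:
    sample-centered log quantities, naive per-gene variance,
    centering bias correction, clipped, square root."""
    genes = list(q)
    n_genes = len(genes)
    n_samples = len(q[genes[0]])
    y = {g: [math.log2(v) for v in q[g]] for g in genes}
    col_means = [
        sum(y[g][j] for g in genes) / n_genes for j in range(n_samples)
    ]
    z = {g: [y[g][j] - col_means[j] for j in range(n_samples)] for g in genes}
    s2 = {g: statistics.variance(z[g]) for g in genes}
    u_bar = sum(s2.values()) / n_genes
    out = {}
    for g in genes:
        sigma2 = (n_genes / (n_genes - 2)) * (s2[g] - u_bar / (n_genes - 1))
        out[g] = math.sqrt(max(0.0, sigma2))
    return out
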