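"""Independent brute-force oracles for the statistical battery.

Everything here is written as plain textbook arithmetic (explicit loops,
closed-form rank formulas, full enumeration) so it shares no code path with
the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def average_ranks(values) -> list[float]:
    """Average ranks computed by sorting and walking tie groups."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson_loops(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def spearman_oracle(x, y) -> tuple[float, float]:
    """rho = Pearson on average ranks; two-sided p via t with n-2 df."""
    from scipy.stats import t as tdist

    rx = average_ranks(list(x))
    ry = average_ranks(list(y))
    rho = pearson_loops(rx, ry)
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = 2 * tdist.sf(abs(t), n - 2)
    return rho, p


def spearman_d2_formula(x, y) -> float:
    """1 - 6 sum d^2 / (n (n^2 - 1)); valid only without ties."""
    rx = average_ranks(list(x))
    ry = average_ranks(list(y))
    n = len(x)
    d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
    return 1 - 6 * d2 / (n * (n**2 - 1))


def icc_oracle(a, b) -> float:
    """ICC(2,1) from explicitly looped two-way ANOVA sums of squares."""
    n = len(a)
    k = 2
    data = [[float(a[i]), float(b[i])] for i in range(n)]
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_total = sum((data[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def bland_altman_oracle(a, b) -> tuple[float, float, float, float]:
    n = len(a)
    d = [float(x) - float(y) for x, y in zip(a, b)]
    bias = sum(d) / n
    var = sum((x - bias) ** 2 for x in d) / (n - 1)
    sd = math.sqrt(var)
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def wilcoxon_oracle(a, b) -> tuple[float, float]:
    """Signed-rank statistic min(W+, W-) and exact two-sided p by full
    enumeration of all 2^n sign assignments of the nonzero differences."""
    d = [float(x) - float(y) for x, y in zip(a, b) if float(x) != float(y)]
    n = len(d)
    if n == 0:
        raise ValueError("degenerate: all differences zero")
    ranks = np.asarray(average_ranks([abs(v) for v in d]))
    signs = np.asarray(d) > 0
    w_plus = float(ranks[signs].sum())
    w_minus = float(ranks[~signs].sum())

    # distribution of W+ over all sign patterns, one bit per difference
    n_pat = 2**n
    w_all = np.zeros(n_pat)
    codes = np.arange(n_pat)
    for j in range(n):
        w_all += ((codes >> j) & 1) * ranks[j]
    p_le = float(np.count_nonzero(w_all <= w_plus + 1e-9)) / n_pat
    p_ge = float(np.count_nonzero(w_all >= w_plus - 1e-9)) / n_pat
    return min(w_plus, w_minus), min(1.0, 2.0 * min(p_le, p_ge))
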