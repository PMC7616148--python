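"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (python loops, explicit model
comparisons, direct numerical integration) and shares no code with the
implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate
from scipy.stats import f as f_dist
from scipy.stats import norm


def naive_median3x3(grid: np.ndarray) -> np.ndarray:
    """Per-pixel 3x3 median with edge replication, via python loops."""
    h, w = grid.shape
    out = np.empty_like(grid, dtype=float)
    for i in range(h):
        for j in range(w):
            vals = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii = min(max(i + di, 0), h - 1)
                    jj = min(max(j + dj, 0), w - 1)
                    vals.append(float(grid[ii, jj]))
            vals.sort()
            out[i, j] = vals[4]
    return out


def naive_ratio(red: np.ndarray, green: np.ndarray, eps: float) -> np.ndarray:
    out = np.empty(red.shape, dtype=float)
    for i in range(red.shape[0]):
        for j in range(red.shape[1]):
            out[i, j] = float(red[i, j]) / (float(green[i, j]) + eps)
    return out


def _fill_holes_bruteforce(mask: np.ndarray) -> np.ndarray:
    """Fill enclosed holes: background pixels not 4-connected to the border."""
    h, w = mask.shape
    outside = np.zeros((h, w), dtype=bool)
    stack = [
        (i, j)
        for i in range(h)
        for j in range(w)
        if (i in (0, h - 1) or j in (0, w - 1)) and not mask[i, j]
    ]
    for i, j in stack:
        outside[i, j] = True
    while stack:
        i, j = stack.pop()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ii, jj = i + di, j + dj
            if 0 <= ii < h and 0 <= jj < w and not mask[ii, jj] and not outside[ii, jj]:
                outside[ii, jj] = True
                stack.append((ii, jj))
    return mask | (~mask & ~outside)


def brute_force_detect(
    green: np.ndarray,
    red: np.ndarray,
    tissue_threshold: float,
    ratio_epsilon: float,
    ratio_threshold: float,
    red_threshold: float,
    min_area: int,
    connectivity: int,
) -> list[set[tuple[int, int]]]:
    """Exhaustive per-pixel double-threshold rule plus flood-fill labeling.

    Mirrors the detection contract with no filtering: tissue mask from a
    fixed green threshold with hole filling, candidate pixels pass the
    ratio AND red thresholds inside tissue, components at the requested
    connectivity, small components discarded. Returns pixel sets sorted by
    component centroid.
    """
    h, w = green.shape
    tissue = _fill_holes_bruteforce(green > tissue_threshold)
    cand = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            if not tissue[i, j]:
                continue
            ratio = float(red[i, j]) / (float(green[i, j]) + ratio_epsilon)
            if ratio > ratio_threshold and float(red[i, j]) > red_threshold:
                cand[i, j] = True
    if connectivity == 8:
        neigh = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    else:
        neigh = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    seen = np.zeros((h, w), dtype=bool)
    comps = []
    for i in range(h):
        for j in range(w):
            if not cand[i, j] or seen[i, j]:
                continue
            comp = set()
            stack = [(i, j)]
            seen[i, j] = True
            while stack:
                y, x = stack.pop()
                comp.add((y, x))
                for dy, dx in neigh:
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and cand[yy, xx] and not seen[yy, xx]:
                        seen[yy, xx] = True
                        stack.append((yy, xx))
            if len(comp) >= min_area:
                comps.append(comp)

    def centroid(comp):
        ys = sum(p[0] for p in comp) / len(comp)
        xs = sum(p[1] for p in comp) / len(comp)
        return (ys, xs)

    comps.sort(key=centroid)
    return comps


def _sum_coding_columns(levels: list, observed) -> np.ndarray:
    """Sum-to-zero (deviation) coding: k-1 columns, last level = -1."""
    k = len(levels)
    cols = np.zeros((len(observed), k - 1))
    for r, val in enumerate(observed):
        idx = levels.index(val)
        if idx < k - 1:
            cols[r, idx] = 1.0
        else:
            cols[r, :] = -1.0
    return cols


def ls_anova_type3(df, factors: tuple[str, ...], value: str = "value") -> dict:
    """Type III factorial ANOVA by explicit least-squares model comparison.

    Builds sum-coded design matrices for all main effects and interactions,
    computes each term's sum of squares as SSE(model without the term) -
    SSE(full model), and F/p against the full-model residual.
    """
    y = df[value].to_numpy(dtype=float)
    n = len(y)
    level_map = {f: sorted(df[f].unique()) for f in factors}
    main = {f: _sum_coding_columns(level_map[f], df[f].tolist()) for f in factors}

    term_cols: dict[str, np.ndarray] = {}
    term_names = []
    for order in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, order):
            name = ":".join(combo)
            cols = main[combo[0]]
            for f in combo[1:]:
                cols = np.concatenate(
                    [cols[:, [i]] * main[f] for i in range(cols.shape[1])], axis=1
                )
            term_cols[name] = cols
            term_names.append(name)

    def sse(names) -> float:
        X = np.concatenate(
            [np.ones((n, 1))] + [term_cols[t] for t in names], axis=1
        )
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(resid @ resid)

    sse_full = sse(term_names)
    df_resid = n - 1 - sum(term_cols[t].shape[1] for t in term_names)
    ms_resid = sse_full / df_resid
    out = {}
    for t in term_names:
        reduced = [u for u in term_names if u != t]
        ss = sse(reduced) - sse_full
        df_t = term_cols[t].shape[1]
        F = (ss / df_t) / ms_resid
        out[t] = {
            "df": df_t,
            "sum_sq": ss,
            "F": F,
            "p": float(f_dist.sf(F, df_t, df_resid)),
        }
    out["Residual"] = {"df": df_resid, "sum_sq": sse_full, "F": np.nan, "p": np.nan}
    return out


def studentized_range_sf_numint(q: float, k: int, df: int) -> float:
    """P(Q > q) for the studentized range, by direct numerical integration.

    Integrates the classical double integral: the range CDF of k standard
    normals, mixed over the distribution of the scale estimate
    S = sqrt(chi2_df / df).
    """

    def range_cdf(x: float) -> float:
        if x <= 0:
            return 0.0
        val, _ = integrate.quad(
            lambda z: norm.pdf(z) * (norm.cdf(z) - norm.cdf(z - x)) ** (k - 1),
            -np.inf,
            np.inf,
            limit=200,
        )
        return k * val

    log_const = (df / 2.0) * math.log(df / 2.0) - math.lgamma(df / 2.0) + math.log(2.0)

    def s_pdf(s: float) -> float:
        return math.exp(log_const + (df - 1) * math.log(s) - df * s * s / 2.0)

    cdf, _ = integrate.quad(lambda s: range_cdf(q * s) * s_pdf(s), 0, np.inf, limit=200)
    return 1.0 - cdf


def naive_quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Sort-based quantile normalization with mean-of-reference tie handling."""
    n_rows, n_cols = X.shape
    ref = np.zeros(n_rows)
    for j in range(n_cols):
        ref += np.array(sorted(X[:, j]))
    ref /= n_cols
    out = np.zeros_like(X, dtype=float)
    for j in range(n_cols):
        col = list(X[:, j])
        order = sorted(range(n_rows), key=lambda i: col[i])
        for v in set(col):
            positions = [rank for rank, i in enumerate(order) if col[i] == v]
            mean_ref = sum(ref[p] for p in positions) / len(positions)
            for i in range(n_rows):
                if col[i] == v:
                    out[i, j] = mean_ref
    return out
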