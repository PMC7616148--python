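"""Factorial ANOVA and Tukey post-hoc tests on per-animal measurements.

Two- and three-way fixed-effects ANOVA with Type III sums of squares under
sum-to-zero factor coding — the convention GraphPad Prism applies, and the
one whose main-effect tests remain marginal means tests on unbalanced data
(relevant here: one genotype group can have n=4 while the rest have n=5).
Post-hoc comparisons are all pairwise cell-mean contrasts using the
studentized-range distribution with the factorial residual mean square,
with the Tukey-Kramer correction for unequal group sizes.

The statistical unit is the animal: image-level metrics are averaged per
animal before entering these tests.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import studentized_range

__all__ = [
    "two_way_anova",
    "three_way_anova",
    "tukey_hsd",
    "type1_error_simulation",
]


def _check_table(table: pd.DataFrame, factors: tuple[str, ...], value: str) -> None:
    for col in (*factors, value):
        if col not in table.columns:
            raise ValueError(f"measurement table missing column {col!r}")
    if not np.isfinite(table[value].to_numpy(dtype=float)).all():
        raise ValueError(f"non-finite values in column {value!r}")
    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 observed levels")
    levels = [sorted(table[f].unique()) for f in factors]
    counts = table.groupby(list(factors)).size()
    for cell in itertools.product(*levels):
        key = cell if len(cell) > 1 else cell[0]
        if key not in counts.index:
            raise ValueError(f"empty design cell: {dict(zip(factors, cell))}")
    n_cells = int(np.prod([len(lv) for lv in levels]))
    if len(table) - n_cells < 1:
        raise ValueError("no residual degrees of freedom (need n > number of cells)")


def _term_name(raw: str, factors: tuple[str, ...]) -> str:
    """Map an internal patsy term like C(__f0, Sum):C(__f1, Sum) back to A:B."""
    parts = raw.split(":")
    out = []
    for p in parts:
        for i, f in enumerate(factors):
            if f"__f{i}" in p:
                out.append(f)
                break
        else:
            return raw
    return ":".join(out)


def _factorial_anova(
    table: pd.DataFrame, factors: tuple[str, ...], value: str
) -> pd.DataFrame:
    _check_table(table, factors, value)
    # internal column names keep user factor names (e.g. "C", "Q") from
    # shadowing patsy's builtins inside the formula namespace
    safe = pd.DataFrame(
        {f"__f{i}": table[f].to_numpy() for i, f in enumerate(factors)}
        | {"__y": table[value].to_numpy(dtype=float)}
    )
    rhs = " * ".join(f"C(__f{i}, Sum)" for i in range(len(factors)))
    model = smf.ols(f"__y ~ {rhs}", data=safe).fit()
    with warnings.catch_warnings():
        # anova_lm emits spurious runtime warnings for near-zero SS terms
        warnings.simplefilter("ignore", RuntimeWarning)
        raw = sm.stats.anova_lm(model, typ=3)
    raw = raw.drop(index="Intercept")
    terms = [_term_name(t, factors) if t != "Residual" else "Residual" for t in raw.index]
    out = pd.DataFrame(
        {
            "df": raw["df"].to_numpy(),
            "sum_sq": raw["sum_sq"].to_numpy(),
        },
        index=pd.Index(terms, name="term"),
    )
    out["mean_sq"] = out["sum_sq"] / out["df"]
    out["F"] = raw["F"].to_numpy()
    out["p"] = raw["PR(>F)"].to_numpy()
    return out


def two_way_anova(
    table: pd.DataFrame,
    factors: tuple[str, str] = ("PINK1", "POLG"),
    value: str = "value",
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA (Type III, sum-to-zero coding).

    Returns a table indexed by term (``A``, ``B``, ``A:B``, ``Residual``)
    with columns df, sum_sq, mean_sq, F, p.
    """
    if len(factors) != 2:
        raise ValueError("two_way_anova needs exactly two factors")
    return _factorial_anova(table, tuple(factors), value)


def three_way_anova(
    table: pd.DataFrame,
    factors: tuple[str, str, str] = ("PINK1", "POLG", "muscle"),
    value: str = "value",
) -> pd.DataFrame:
    """Three-way fixed-effects ANOVA with all interaction terms (Type III).

    A factor with a single observed level carries no information: it is
    dropped with a warning and the ANOVA collapses to the lower-order model
    on the remaining factors.
    """
    if len(factors) != 3:
        raise ValueError("three_way_anova needs exactly three factors")
    active = tuple(f for f in factors if table[f].nunique() >= 2)
    if len(active) < len(factors):
        dropped = [f for f in factors if f not in active]
        warnings.warn(
            f"factors with a single observed level dropped: {dropped}", stacklevel=2
        )
    if len(active) < 2:
        raise ValueError("need at least two non-degenerate factors")
    return _factorial_anova(table, active, value)


def tukey_hsd(
    table: pd.DataFrame,
    factors: tuple[str, ...] = ("PINK1", "POLG"),
    value: str = "value",
) -> pd.DataFrame:
    """All pairwise Tukey(-Kramer) comparisons of the crossed-factor cell means.

    The error term is the residual mean square of the full factorial model
    (identical to the within-cell pooled variance, since the full factorial
    is the cell-means model). For unequal n the Tukey-Kramer standard error
    ``sqrt(MSw/2 * (1/n_i + 1/n_j))`` is used; adjusted p-values come from
    the studentized-range distribution with k = number of cells and the
    residual degrees of freedom. With k = 2 this reduces exactly to the
    pooled two-sample t-test.
    """
    _check_table(table, tuple(factors), value)
    cells = table.groupby(list(factors))[value]
    means = cells.mean()
    ns = cells.size()
    k = len(means)
    if k < 2:
        raise ValueError("Tukey test needs at least 2 groups")
    if (ns == 0).any():
        raise ValueError("every group must have n >= 1")
    n_total = int(ns.sum())
    sse = float(((table[value] - cells.transform("mean")) ** 2).sum())
    df_resid = n_total - k
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom for the Tukey error term")
    msw = sse / df_resid

    def _label(key) -> str:
        return ":".join(map(str, key)) if isinstance(key, tuple) else str(key)

    rows = []
    keys = list(means.index)
    for i, j in itertools.combinations(range(k), 2):
        gi, gj = keys[i], keys[j]
        diff = float(means.iloc[i] - means.iloc[j])
        se = float(np.sqrt(msw / 2.0 * (1.0 / ns.iloc[i] + 1.0 / ns.iloc[j])))
        q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else np.inf)
        p = float(studentized_range.sf(q, k, df_resid)) if np.isfinite(q) else 0.0
        rows.append(
            {
                "group1": _label(gi),
                "group2": _label(gj),
                "mean_diff": diff,
                "se": se,
                "q": q,
                "p_adj": min(max(p, 0.0), 1.0),
                "n1": int(ns.iloc[i]),
                "n2": int(ns.iloc[j]),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["ms_residual"] = msw
    out.attrs["df_residual"] = df_resid
    out.attrs["k"] = k
    return out


def type1_error_simulation(
    n_per_group: int = 5,
    n_reps: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of the two-way ANOVA under a 2x2 null design.

    Simulates ``n_reps`` replicates of i.i.d. standard-normal data in a
    balanced 2x2 design with ``n_per_group`` observations per cell, runs
    :func:`two_way_anova` on each, and reports the per-term rejection rate
    at level ``alpha`` plus the rate at which any main effect rejects.
    """
    if n_reps < 100:
        warnings.warn(
            f"n_reps={n_reps} gives an unstable type-I error estimate", stacklevel=2
        )
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    rng = np.random.default_rng(seed)
    levels_a = np.repeat(["a1", "a2"], 2 * n_per_group)
    levels_b = np.tile(np.repeat(["b1", "b2"], n_per_group), 2)
    hits = {"A": 0, "B": 0, "A:B": 0, "any_main_effect": 0}
    for _ in range(n_reps):
        df = pd.DataFrame(
            {"A": levels_a, "B": levels_b, "value": rng.standard_normal(4 * n_per_group)}
        )
        tab = two_way_anova(df, factors=("A", "B"))
        pa, pb, pab = tab.loc["A", "p"], tab.loc["B", "p"], tab.loc["A:B", "p"]
        hits["A"] += pa < alpha
        hits["B"] += pb < alpha
        hits["A:B"] += pab < alpha
        hits["any_main_effect"] += (pa < alpha) or (pb < alpha)
    return {k: v / n_reps for k, v in hits.items()}


def anova_report(anova: pd.DataFrame, tukey: pd.DataFrame | None = None) -> str:
    """Plain-text report in figure-legend style (main effects, interaction, post-tests)."""

    def _stars(p: float) -> str:
        for thr, s in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
            if p < thr:
                return s
        return "ns"

    lines = ["ANOVA (Type III, sum-to-zero coding)"]
    for term, row in anova.iterrows():
        if term == "Residual":
            lines.append(f"  Residual: df={row['df']:.0f}, MS={row['mean_sq']:.4g}")
        else:
            lines.append(
                f"  {term}: F({row['df']:.0f}, {anova.loc['Residual', 'df']:.0f}) = "
                f"{row['F']:.3f}, p = {row['p']:.4g} {_stars(row['p'])}"
            )
    if tukey is not None:
        lines.append("Tukey multiple comparisons")
        for _, r in tukey.iterrows():
            lines.append(
                f"  {r['group1']} vs {r['group2']}: diff = {r['mean_diff']:.4g}, "
                f"p = {r['p_adj']:.4g} {_stars(r['p_adj'])}"
            )
    return "\n".join(lines)
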