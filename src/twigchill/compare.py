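"""Heteroscedastic treatment comparison across cutting dates.

An ANOVA-style cell-means model of forcing on cutting date (as a factor) x
treatment, with a separate residual variance per cutting date — a
generalized-least-squares structure in which, because the design is
saturated, the cell means are simply per-cell averages and the per-level
variances are pooled within-cell residual variances.  Post-hoc contrasts
(S vs C at each cutting date; pairwise between cutting dates within a
treatment) use those variances with Welch-Satterthwaite degrees of freedom
and Holm multiplicity adjustment, summarised as a significance map and a
compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparisonResult",
    "fit_heteroscedastic_cellmeans",
    "posthoc_sc",
    "posthoc_levels",
    "compact_letters",
]


@dataclass
class GroupComparisonResult:
    """Cell means and per-chilling-level variances of the fitted model."""

    endpoint: str
    definition: str
    cell_means: dict[tuple[int, str], float]
    cell_sizes: dict[tuple[int, str], int]
    level_variances: dict[int, float]  # pooled across treatments per level
    level_dofs: dict[int, int]
    sc_contrasts: Optional[pd.DataFrame] = None
    level_contrasts: dict[str, pd.DataFrame] = field(default_factory=dict)

    def levels(self) -> list[int]:
        return sorted({i for i, _ in self.cell_means})

    def cell_se(self, level: int, treatment: str) -> float:
        return float(np.sqrt(self.level_variances[level] / self.cell_sizes[(level, treatment)]))


def fit_heteroscedastic_cellmeans(
    table: pd.DataFrame,
    endpoint: str = "bbch7",
    definition: str = "calendar",
    exclude_outliers: bool = True,
) -> GroupComparisonResult:
    """Fit the saturated cell-means model with one variance per cutting date.

    The forcing scale defaults to calendar days inside.  Cells with fewer
    than two rows contribute a mean but no variance information; a level
    whose cells are all singletons gets no variance estimate.
    """
    sel = table["endpoint"] == endpoint
    if exclude_outliers:
        sel &= ~table["excluded"]
    sub = table.loc[sel]
    col = f"force_{definition}"
    if sub.empty:
        raise ValueError(f"no rows at endpoint {endpoint!r}")

    cell_means: dict[tuple[int, str], float] = {}
    cell_sizes: dict[tuple[int, str], int] = {}
    level_variances: dict[int, float] = {}
    level_dofs: dict[int, int] = {}
    for level, lev_df in sub.groupby("cutting_index"):
        ss, dof = 0.0, 0
        for tr, cell in lev_df.groupby("treatment"):
            y = cell[col].to_numpy(dtype=float)
            cell_means[(level, tr)] = float(y.mean())
            cell_sizes[(level, tr)] = len(y)
            if len(y) >= 2:
                ss += float(((y - y.mean()) ** 2).sum())
                dof += len(y) - 1
        if dof > 0:
            level_variances[int(level)] = ss / dof
            level_dofs[int(level)] = dof

    levels_both = {
        i for i in {k[0] for k in cell_means}
        if (i, "S") in cell_means and (i, "C") in cell_means
    }
    if len(levels_both) < 2 and len(level_variances) == 0:
        raise ValueError("all cells are singletons; cannot estimate variances")
    return GroupComparisonResult(endpoint, definition, cell_means, cell_sizes,
                                 level_variances, level_dofs)


def posthoc_sc(result: GroupComparisonResult, alpha: float = 0.05) -> pd.DataFrame:
    """S-vs-C contrast at each cutting date, Holm-adjusted across dates.

    Returns a DataFrame indexed by cutting index with estimate (S - C),
    standard error, raw and adjusted p, and a significance flag.  Levels
    missing a treatment or a variance estimate are skipped.
    """
    rows = []
    for level in result.levels():
        if (level, "S") not in result.cell_means or (level, "C") not in result.cell_means:
            continue
        if level not in result.level_variances:
            continue
        var = result.level_variances[level]
        n_s = result.cell_sizes[(level, "S")]
        n_c = result.cell_sizes[(level, "C")]
        est = result.cell_means[(level, "S")] - result.cell_means[(level, "C")]
        se = np.sqrt(var * (1.0 / n_s + 1.0 / n_c))
        df = result.level_dofs[level]
        if se == 0:
            p = 0.0 if est != 0 else 1.0
            tstat = np.inf if est != 0 else 0.0
        else:
            tstat = est / se
            p = 2.0 * scipy.stats.t.sf(abs(tstat), df)
        rows.append({"cutting_index": level, "estimate": est, "se": se,
                     "df": df, "t": tstat, "p_raw": p})
    out = pd.DataFrame(rows).set_index("cutting_index")
    if out.empty:
        return out
    _, p_adj, _, _ = multipletests(out["p_raw"], alpha=alpha, method="holm")
    out["p_adj"] = p_adj
    out["significant"] = out["p_adj"] < alpha
    return out


def _welch(result: GroupComparisonResult, i: int, j: int, treatment: str):
    """Welch t contrast between two cutting dates within one treatment."""
    mi, mj = result.cell_means[(i, treatment)], result.cell_means[(j, treatment)]
    vi, vj = result.level_variances[i], result.level_variances[j]
    ni, nj = result.cell_sizes[(i, treatment)], result.cell_sizes[(j, treatment)]
    dfi, dfj = result.level_dofs[i], result.level_dofs[j]
    se2 = vi / ni + vj / nj
    est = mi - mj
    if se2 == 0:
        return est, 0.0, np.inf, (0.0 if est != 0 else 1.0)
    df = se2**2 / ((vi / ni) ** 2 / dfi + (vj / nj) ** 2 / dfj)
    t = est / np.sqrt(se2)
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return est, float(np.sqrt(se2)), df, p


def posthoc_levels(
    result: GroupComparisonResult, treatment: str, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[int, str]]:
    """All pairwise cutting-date contrasts within one treatment, plus letters.

    Returns the Holm-adjusted pairwise table and a compact letter display:
    cutting dates sharing a letter are not significantly different.
    """
    levels = [
        i for i in result.levels()
        if (i, treatment) in result.cell_means and i in result.level_variances
    ]
    if len(levels) < 2:
        raise ValueError("need >= 2 usable levels for pairwise comparison")
    rows = []
    for i, j in combinations(levels, 2):
        est, se, df, p = _welch(result, i, j, treatment)
        rows.append({"level_i": i, "level_j": j, "estimate": est, "se": se,
                     "df": df, "p_raw": p})
    out = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(out["p_raw"], alpha=alpha, method="holm")
    out["p_adj"] = p_adj
    out["significant"] = out["p_adj"] < alpha
    sig_pairs = {
        (int(r.level_i), int(r.level_j)) for r in out.itertuples() if r.significant
    }
    letters = compact_letters(levels, sig_pairs)
    return out, letters


def compact_letters(
    levels: list[int], significant_pairs: set[tuple[int, int]]
) -> dict[int, str]:
    """Compact letter display by insert-and-absorb.

    Starts from one group holding all levels; every significant pair splits
    each group containing both members; groups contained in another are
    absorbed.  Two levels share a letter iff their pair is not significant.
    """
    sig = {frozenset(p) for p in significant_pairs}
    groups: list[set[int]] = [set(levels)]
    for pair in sig:
        i, j = tuple(pair)
        new_groups: list[set[int]] = []
        for g in groups:
            if i in g and j in g:
                new_groups.append(g - {i})
                new_groups.append(g - {j})
            else:
                new_groups.append(g)
        # absorb: drop groups that are subsets of another
        groups = [
            g for k, g in enumerate(new_groups)
            if g and not any(k != m and g < h or (g == h and k > m)
                             for m, h in enumerate(new_groups))
        ]
    # stable letter order: by smallest member
    groups.sort(key=lambda g: min(g))
    import string

    alphabet = string.ascii_lowercase + string.ascii_uppercase + string.digits
    if len(groups) > len(alphabet):
        raise ValueError(
            f"{len(groups)} letter groups exceed the symbol alphabet; "
            "the significance pattern is too fragmented for a letter display"
        )
    out: dict[int, str] = {lv: "" for lv in levels}
    for k, g in enumerate(groups):
        for lv in sorted(g):
            out[lv] += alphabet[k]
    return out


def significance_map(
    sc: pd.DataFrame, letters_s: dict[int, str], letters_c: dict[int, str]
) -> str:
    """Text rendering of the significance structure: one line per cutting
    date with the S/C difference marker and per-treatment letters."""
    lines = ["cutting  S-vs-C  letters(S)  letters(C)"]
    levels = sorted(set(letters_s) | set(letters_c) | set(sc.index))
    for lv in levels:
        marker = "§" if lv in sc.index and bool(sc.loc[lv, "significant"]) else " "
        lines.append(
            f"{lv:>7}  {marker:^6}  {letters_s.get(lv, '-'):<10}  {letters_c.get(lv, '-'):<10}"
        )
    return "\n".join(lines)
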