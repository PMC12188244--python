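"""Longitudinal acclimation check and between-group inference.

One-way ANOVA with a post hoc Tukey HSD test (studentized-range adjusted
p-values plus a compact letter display), and a trailing-window coefficient
of variation stopping rule for acclimation.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class StatsError(ValueError):
    pass


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass
class PairResult:
    group_i: str
    group_j: str
    mean_diff: float  # mean_j - mean_i
    q: float
    p_adj: float


@dataclass
class TukeyResult:
    pairs: list
    letters: dict  # group label -> letter string
    alpha: float

    def p_adj(self, a: str, b: str) -> float:
        for pr in self.pairs:
            if {pr.group_i, pr.group_j} == {a, b}:
                return pr.p_adj
        raise KeyError((a, b))

    def significant(self, a: str, b: str) -> bool:
        return self.p_adj(a, b) < self.alpha


def acclimation_check(
    durations: Sequence[float],
    days: Optional[Sequence] = None,
    window: int = 5,
    cv_max: float = 0.05,
) -> tuple[bool, Optional[object]]:
    """First day ending a trailing window whose CV (sample sd / mean) is
    below ``cv_max``; ``(False, None)`` if the series never settles."""
    x = np.asarray(durations, dtype=float)
    if x.size < window:
        raise StatsError(f"need at least {window} observations")
    if days is None:
        days = list(range(1, x.size + 1))
    if len(days) != x.size:
        raise StatsError("days and durations must have equal length")
    for end in range(window, x.size + 1):
        win = x[end - window : end]
        m = win.mean()
        if m <= 0:
            raise StatsError("nonpositive mean within a window")
        cv = win.std(ddof=1) / m
        if cv < cv_max:
            return True, days[end - 1]
    return False, None


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise StatsError("need at least 2 groups")
    for g in gs:
        if g.size < 2:
            raise StatsError("each group needs at least 2 observations")
    return gs


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical between/within sum-of-squares F test.

    Zero within-group variance with equal means yields F = 0, p = 1 rather
    than a division error.
    """
    gs = _check_groups(groups)
    k = len(gs)
    n = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    dfb, dfw = k - 1, n - k
    if ssw == 0:
        if ssb == 0:
            return AnovaResult(0.0, dfb, dfw, 1.0)
        return AnovaResult(np.inf, dfb, dfw, 0.0)
    F = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(F, dfb, dfw))
    return AnovaResult(float(F), dfb, dfw, p)


def _compact_letters(
    labels: Sequence[str], means: dict, sig: dict, alphabet: str = "abcdefghijklmnopqrstuvwxyz"
) -> dict:
    """Insert-and-absorb compact letter display.

    ``sig[(a, b)]`` is True when groups a and b differ significantly.
    Groups sharing no letter differ; groups sharing a letter do not.
    """
    order = sorted(labels, key=lambda l: -means[l])
    columns: list[frozenset] = [frozenset(order)]
    for a, b in combinations(order, 2):
        if not sig[frozenset((a, b))]:
            continue
        new_cols = []
        for col in columns:
            if a in col and b in col:
                new_cols.extend([col - {a}, col - {b}])
            else:
                new_cols.append(col)
        # absorb: drop empties, duplicates, and columns inside another
        new_cols = [c for c in dict.fromkeys(new_cols) if c]
        columns = [
            c for c in new_cols if not any(c < other for other in new_cols)
        ]
    # assign letters in the order groups appear
    columns = sorted(columns, key=lambda col: min(order.index(l) for l in col))
    letters = {l: "" for l in labels}
    for letter, col in zip(alphabet, columns):
        for l in order:
            if l in col:
                letters[l] += letter
    return letters


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> TukeyResult:
    """All-pairs Tukey HSD with studentized-range adjusted p-values."""
    gs = _check_groups(groups)
    k = len(gs)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    labels = list(labels)
    n = sum(g.size for g in gs)
    dfw = n - k
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    mse = ssw / dfw
    means = {l: g.mean() for l, g in zip(labels, gs)}
    sizes = {l: g.size for l, g in zip(labels, gs)}

    pairs = []
    sig = {}
    for (la, ga), (lb, gb) in combinations(zip(labels, gs), 2):
        diff = gb.mean() - ga.mean()
        if mse == 0:
            q = 0.0 if diff == 0 else np.inf
            p_adj = 1.0 if diff == 0 else 0.0
        else:
            se = np.sqrt(mse / 2 * (1 / sizes[la] + 1 / sizes[lb]))
            q = abs(diff) / se
            p_adj = float(np.clip(stats.studentized_range.sf(q, k, dfw), 0, 1))
        pairs.append(PairResult(la, lb, float(diff), float(q), p_adj))
        sig[frozenset((la, lb))] = p_adj < alpha

    letters = _compact_letters(labels, means, sig)
    return TukeyResult(pairs=pairs, letters=letters, alpha=alpha)


def feature_group_table(
    features: pd.DataFrame,
    feature_cols: Sequence[str],
    group_col: str = "treatment",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Summary table: per feature and group, mean +/- sd plus Tukey letters.

    ANOVA is run per feature; the Tukey letters are computed whenever the
    ANOVA is significant at ``alpha``, otherwise all groups share 'a'.
    """
    rows = []
    group_labels = list(dict.fromkeys(features[group_col]))
    for feat in feature_cols:
        groups = [features.loc[features[group_col] == g, feat].to_numpy() for g in group_labels]
        an = one_way_anova(groups)
        if an.p < alpha:
            letters = tukey_hsd(groups, labels=group_labels, alpha=alpha).letters
        else:
            letters = {g: "a" for g in group_labels}
        for g, vals in zip(group_labels, groups):
            rows.append(
                {
                    "feature": feat,
                    "group": g,
                    "n": len(vals),
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)),
                    "summary": f"{np.mean(vals):.2f}±{np.std(vals, ddof=1):.2f}"
                    + letters[g],
                    "letters": letters[g],
                    "anova_F": an.F,
                    "anova_p": an.p,
                }
            )
    return pd.DataFrame(rows)
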