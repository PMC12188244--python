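"""Multi-contrast rank-based gene-set enrichment.

Directional per-gene scores from each contrast are converted to ranks; a
gene set's per-contrast enrichment score s = 2*(mean member rank -
(N+1)/2)/N lies in (-1, 1), and the multi-contrast score S is the
Euclidean norm of the s vector.  Significance comes from a two-group
MANOVA (Pillai trace) of scaled ranks, members versus non-members.
"""
from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dge import bh_fdr


class EnrichError(ValueError):
    pass


class GeneSetLibrary(Mapping):
    """Named gene sets with optional per-set descriptions (GMT semantics).

    Duplicate members within a set are removed, preserving order.
    """

    def __init__(
        self,
        sets: Mapping[str, Sequence[str]],
        descriptions: Optional[Mapping[str, str]] = None,
        name: str = "",
    ):
        self._sets = {}
        for set_name, members in sets.items():
            members = list(dict.fromkeys(members))
            if not members:
                raise EnrichError(f"gene set {set_name!r} has no members")
            self._sets[set_name] = members
        self.descriptions = dict(descriptions or {})
        self.name = name

    def __getitem__(self, key):
        return self._sets[key]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self):
        return len(self._sets)

    @classmethod
    def read_gmt(cls, path) -> "GeneSetLibrary":
        sets: dict = {}
        descriptions: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise EnrichError(
                        f"{path}: malformed GMT line {lineno} "
                        f"(expected name, description and >=1 member)"
                    )
                name, desc, *members = fields
                members = [m for m in members if m]
                if not members:
                    raise EnrichError(f"{path}: no members on GMT line {lineno}")
                if name in sets:
                    raise EnrichError(f"{path}: duplicate set name on line {lineno}")
                sets[name] = members
                descriptions[name] = desc
        return cls(sets, descriptions, name=str(path))

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self._sets.items():
                desc = self.descriptions.get(name, "na")
                fh.write("\t".join([name, desc, *members]) + "\n")


def load_gmt(path) -> GeneSetLibrary:
    return GeneSetLibrary.read_gmt(path)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass
class RankedProfiles:
    """Per-gene directional scores and their (scaled) ranks per contrast."""

    d: pd.DataFrame  # directional scores, genes x contrasts
    ranks: pd.DataFrame  # average ranks 1..N
    scaled: pd.DataFrame  # ranks / N, in (0, 1]

    @property
    def genes(self) -> pd.Index:
        return self.d.index

    def __len__(self) -> int:
        return len(self.d)


def directional_score(table: pd.DataFrame, floor: float = 1e-300) -> pd.Series:
    """d = sign(log2fc) * (-log10 p); the ranking statistic per contrast."""
    p = table["pvalue"].clip(lower=floor)
    return np.sign(table["log2fc"]) * (-np.log10(p))


def build_profiles(tables: Mapping[str, pd.DataFrame]) -> RankedProfiles:
    """Inner-join contrast tables on gene and rank the directional scores.

    Ties receive average (mid) ranks; scaled ranks are rank/N in (0, 1].
    """
    if len(tables) < 2:
        raise EnrichError("need at least two contrasts")
    d = pd.DataFrame({name: directional_score(t) for name, t in tables.items()})
    d = d.dropna()
    if d.empty:
        raise EnrichError("contrast tables share no genes")
    ranks = d.apply(lambda col: stats.rankdata(col, method="average"))
    ranks = pd.DataFrame(ranks, index=d.index, columns=d.columns)
    return RankedProfiles(d=d, ranks=ranks, scaled=ranks / len(d))


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _pillai_p(scaled: np.ndarray, member: np.ndarray) -> float:
    """Two-group MANOVA p-value via the Pillai trace on scaled ranks.

    Falls back to per-contrast one-way rank ANOVA with a Bonferroni
    minimum-p combination when the scatter matrix is singular.
    """
    n, pdim = scaled.shape
    n1 = int(member.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0 or n - pdim - 1 <= 0:
        return 1.0
    grand = scaled.mean(axis=0)
    h = np.zeros((pdim, pdim))
    e = np.zeros((pdim, pdim))
    for mask, ng in ((member, n1), (~member, n2)):
        grp = scaled[mask]
        mg = grp.mean(axis=0)
        dmean = (mg - grand)[:, None]
        h += ng * dmean @ dmean.T
        resid = grp - mg
        e += resid.T @ resid
    try:
        v = float(np.trace(h @ np.linalg.inv(h + e)))
        if not 0 <= v < 1:
            raise np.linalg.LinAlgError
        f_stat = (v / (1 - v)) * (n - pdim - 1) / pdim
        return float(stats.f.sf(f_stat, pdim, n - pdim - 1))
    except np.linalg.LinAlgError:
        ps = []
        for j in range(pdim):
            a, b = scaled[member, j], scaled[~member, j]
            ps.append(stats.f_oneway(a, b).pvalue)
        return float(min(1.0, pdim * np.nanmin(ps)))


def score_gene_sets(
    profiles: RankedProfiles,
    library: GeneSetLibrary,
    minsetsize: int = 20,
) -> pd.DataFrame:
    """Per-contrast s scores, multi-contrast S, p and FDR for every set
    with at least ``minsetsize`` members inside the profile universe."""
    genes = profiles.genes
    pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    ranks = profiles.ranks.to_numpy()
    scaled = profiles.scaled.to_numpy()
    contrasts = list(profiles.d.columns)

    rows = []
    for name, members in library.items():
        idx = np.array([pos[g] for g in members if g in pos], dtype=int)
        m = idx.size
        if m < minsetsize:
            continue
        mean_rank = ranks[idx].mean(axis=0)
        s = 2.0 * (mean_rank - (n + 1) / 2.0) / n
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        p = _pillai_p(scaled, mask)
        row = {"set": name, "m": m}
        row.update({f"s_{c}": float(sv) for c, sv in zip(contrasts, s)})
        row["S"] = float(np.linalg.norm(s))
        row["p"] = p
        rows.append(row)

    if not rows:
        warnings.warn("no gene set passes the size filter")
        cols = ["set", "m", *(f"s_{c}" for c in contrasts), "S", "p", "fdr"]
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out.set_index("set", drop=False)


def filter_enriched(
    rows: pd.DataFrame, max_fdr: float = 0.01, min_s: float = 0.1
) -> pd.DataFrame:
    """Keep sets with fdr < max_fdr and multi-contrast score S > min_s."""
    return rows[(rows["fdr"] < max_fdr) & (rows["S"] > min_s)]


def select_gene_sets(
    rows: pd.DataFrame,
    delta: float = 0.1,
    early_col: str = "s_early",
    late_col: str = "s_late",
    require_sign_change: bool = False,
) -> pd.DataFrame:
    """Sets whose enrichment changes substantially between the early and
    late contrasts: |s_early - s_late| >= delta, optionally also requiring
    a sign change."""
    keep = (rows[early_col] - rows[late_col]).abs() >= delta
    if require_sign_change:
        keep &= np.sign(rows[early_col]) != np.sign(rows[late_col])
    return rows[keep]
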