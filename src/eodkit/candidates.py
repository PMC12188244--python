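"""Candidate-gene derivation.

Candidates are the union of (genes of any select gene set that are
significant in at least one contrast) and manually nominated significant
genes, minus two exclusions: genes significant only in the early
(control vs T1day) contrast, and an explicit gene blacklist.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dge import CONTRASTS, fc_from_log2fc
from .enrich import GeneSetLibrary

EARLY_CONTRAST = "control_vs_T1day"


class CandidateError(ValueError):
    pass


@dataclass(frozen=True)
class ExclusionPolicy:
    drop_early_only: bool = True
    blacklist: tuple = ("srd5a2",)


def derive_candidates(
    select_sets: Sequence[str],
    library: GeneSetLibrary,
    calls: Mapping[str, pd.Series],
    tables: Optional[Mapping[str, pd.DataFrame]] = None,
    manual_adds: Sequence[str] = (),
    policy: ExclusionPolicy = ExclusionPolicy(),
    themes: Optional[Mapping[str, str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidate table plus the excluded-gene table.

    Parameters
    ----------
    select_sets : names of the select gene sets (must exist in ``library``)
    calls : per-contrast up/down/ns series sharing a gene universe
    tables : optional per-contrast DE tables used to attach fold changes
    manual_adds : manually nominated genes; kept only if significant in at
        least one contrast (a warning names the ones dropped)
    themes : optional gene -> free-text theme map

    Returns ``(candidates, excluded)``; excluded rows carry a reason and
    never appear in the candidate table.
    """
    themes = dict(themes or {})
    contrast_names = list(calls.keys())
    call_df = pd.DataFrame(calls)
    significant = call_df.index[(call_df != "ns").any(axis=1)]
    sig_set = set(significant)

    missing_sets = [s for s in select_sets if s not in library]
    if missing_sets:
        raise CandidateError(f"select sets not in library: {missing_sets}")

    membership: dict[str, list[str]] = {}
    for set_name in select_sets:
        for g in library[set_name]:
            if g in sig_set:
                membership.setdefault(g, []).append(set_name)

    sources: dict[str, str] = {g: "set_intersection" for g in membership}
    for g in manual_adds:
        if g not in sig_set:
            warnings.warn(f"manual add {g!r} is not significant in any contrast")
            continue
        sources.setdefault(g, "manual_annotation")

    rows = []
    excluded = []
    for g in sorted(sources):
        gene_calls = call_df.loc[g]
        sig_in = [c for c in contrast_names if gene_calls[c] != "ns"]
        reason = None
        if g in policy.blacklist:
            reason = "blacklist"
        elif policy.drop_early_only and sig_in == [EARLY_CONTRAST]:
            reason = "early-only"
        record = {
            "gene": g,
            "source": sources[g],
            "gene_sets": ";".join(membership.get(g, [])),
            "theme": themes.get(g, ""),
        }
        for c in contrast_names:
            record[f"call_{c}"] = gene_calls[c]
            if tables is not None and g in tables[c].index:
                record[f"fc_{c}"] = (
                    fc_from_log2fc(float(tables[c].loc[g, "log2fc"]))
                    if gene_calls[c] != "ns"
                    else np.nan
                )
        if reason is None:
            rows.append(record)
        else:
            record["reason"] = reason
            excluded.append(record)

    cand_cols = ["gene", "source", "gene_sets", "theme"] + [
        col
        for c in contrast_names
        for col in (f"call_{c}", f"fc_{c}")
        if tables is not None or not col.startswith("fc_")
    ]
    candidates = pd.DataFrame(rows, columns=cand_cols if not rows else None)
    excluded_df = pd.DataFrame(
        excluded, columns=(cand_cols + ["reason"]) if not excluded else None
    )
    if rows:
        candidates = candidates.sort_values("gene").reset_index(drop=True)
    if excluded:
        excluded_df = excluded_df.sort_values("gene").reset_index(drop=True)
    return candidates, excluded_df
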