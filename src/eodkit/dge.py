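"""Count normalization, a stand-in DE test, significance filtering,
three-contrast pattern classification and contrast summaries.

The DE test here (Welch's t on TMM-normalized log2 CPM) is a documented
stand-in, not a negative-binomial GLM; externally produced per-contrast
tables (gene, log2fc, pvalue, fdr, mean_expr) are accepted as first-class
input everywhere downstream.
"""
from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class DGEError(ValueError):
    pass


#: contrast name -> (group A, group B); B is the longer 17aMT exposure, and
#: log2fc is oriented mean(B) - mean(A) so positive = up with longer exposure
CONTRASTS = {
    "control_vs_T8day": ("control", "T8day"),
    "control_vs_T1day": ("control", "T1day"),
    "T1day_vs_T8day": ("T1day", "T8day"),
}

#: contrast name -> its role in the pattern framework
CONTRAST_ROLES = {
    "control_vs_T8day": "broad",
    "control_vs_T1day": "early",
    "T1day_vs_T8day": "late",
}

CALLS = ("up", "down", "ns")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: Optional[str] = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors (Robinson & Oshlack).

    The reference sample is the one whose upper quartile (of counts scaled
    by library size) is closest to the mean upper quartile.  Per sample,
    the factor is 2 to the precision-weighted mean of M-values after
    trimming ``trim_m`` of M (each tail) and ``trim_a`` of A.  Factors are
    normalized to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise DGEError("need at least 2 samples")
    libs = counts.sum(axis=0).astype(float)
    if (libs <= 0).any():
        raise DGEError("every sample must have a positive total count")
    props = counts.divide(libs, axis=1)

    if ref_sample is None:
        uq = props.apply(lambda c: np.quantile(c[c > 0], 0.75) if (c > 0).any() else 0.0)
        ref_sample = (uq - uq.mean()).abs().idxmin()

    ref = counts[ref_sample].to_numpy(dtype=float)
    n_ref = libs[ref_sample]
    factors = {}
    for s in counts.columns:
        if s == ref_sample:
            factors[s] = 1.0
            continue
        y = counts[s].to_numpy(dtype=float)
        keep = (y > 0) & (ref > 0)
        if not keep.any():
            warnings.warn(f"sample {s!r} shares no expressed genes with the reference")
            factors[s] = 1.0
            continue
        ys, yr = y[keep], ref[keep]
        n_s = libs[s]
        m = np.log2((ys / n_s) / (yr / n_ref))
        a = 0.5 * np.log2((ys / n_s) * (yr / n_ref))
        w = (n_s - ys) / (n_s * ys) + (n_ref - yr) / (n_ref * yr)

        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        sel = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a) & (w > 0)
        if not sel.any():
            warnings.warn(f"sample {s!r}: nothing survives trimming; factor set to 1")
            factors[s] = 1.0
            continue
        factors[s] = float(2.0 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])))

    f = pd.Series(factors).reindex(counts.columns)
    return f / np.exp(np.log(f).mean())


def log_cpm(
    counts: pd.DataFrame, factors: Optional[pd.Series] = None, prior: float = 0.5
) -> pd.DataFrame:
    """log2 counts-per-million on TMM-effective library sizes."""
    if factors is None:
        factors = tmm_factors(counts)
    eff = counts.sum(axis=0).astype(float) * factors
    return np.log2((counts + prior).divide(eff, axis=1) * 1e6)


def tmm_normalize(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Scaling factors plus TMM-normalized log2 CPM expression."""
    factors = tmm_factors(counts)
    return factors, log_cpm(counts, factors)


# ---------------------------------------------------------------------------
# Testing and filtering
# ---------------------------------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values with monotonicity."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise DGEError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DGEError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def expressed_genes(
    counts: pd.DataFrame, samples: Sequence[str], min_prop: float = 0.5
) -> pd.Index:
    """Genes with a positive count in at least ``min_prop`` of the samples."""
    sub = counts[list(samples)]
    return counts.index[(sub > 0).mean(axis=1) >= min_prop]


def simple_de(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_prop_expressed: float = 0.5,
) -> pd.DataFrame:
    """Stand-in differential expression test for one contrast.

    log2fc is the difference of group means of TMM-normalized log2 CPM,
    oriented mean(B) - mean(A); p comes from Welch's t on the same values;
    fdr from Benjamini-Hochberg.  Returns columns gene, log2fc, pvalue,
    fdr, mean_expr, indexed by gene, restricted to expressed genes.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise DGEError("both groups need at least 2 samples")
    sub = counts[group_a + group_b]
    keep = expressed_genes(counts, group_a + group_b, min_prop_expressed)
    sub = sub.loc[keep]
    _, expr = tmm_normalize(sub)
    xa = expr[group_a].to_numpy()
    xb = expr[group_b].to_numpy()

    log2fc = xb.mean(axis=1) - xa.mean(axis=1)
    with np.errstate(invalid="ignore"):
        t, p = stats.ttest_ind(xb, xa, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance genes -> ns
    table = pd.DataFrame(
        {
            "gene": sub.index,
            "log2fc": log2fc,
            "pvalue": p,
            "fdr": bh_fdr(p),
            "mean_expr": expr.mean(axis=1).to_numpy(),
        }
    ).set_index("gene", drop=False)
    return table


def run_contrasts(
    counts: pd.DataFrame,
    treatments: pd.Series,
    min_prop_expressed: float = 0.5,
) -> dict[str, pd.DataFrame]:
    """All three canonical contrasts on a labeled count matrix."""
    tables = {}
    for name, (a, b) in CONTRASTS.items():
        sa = treatments.index[treatments == a]
        sb = treatments.index[treatments == b]
        tables[name] = simple_de(counts, sa, sb, min_prop_expressed)
    return tables


def fc_from_log2fc(log2fc: float) -> float:
    """Signed linear fold change: FC = sign(log2fc) * 2**|log2fc|."""
    return float(np.sign(log2fc) * 2.0 ** abs(log2fc)) if log2fc != 0 else 1.0


def filter_degs(
    table: pd.DataFrame, min_fc: float = 4.0, max_fdr: float = 0.001
) -> pd.Series:
    """Per-gene call: 'up' iff log2fc >= log2(min_fc) and fdr < max_fdr,
    'down' symmetric, else 'ns'.  The FC bound is inclusive, the FDR bound
    strict."""
    lfc_min = np.log2(min_fc)
    up = (table["log2fc"] >= lfc_min) & (table["fdr"] < max_fdr)
    down = (table["log2fc"] <= -lfc_min) & (table["fdr"] < max_fdr)
    calls = pd.Series("ns", index=table.index, name="call")
    calls[up] = "up"
    calls[down] = "down"
    return calls


def classify_patterns(calls: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Deterministic pattern label from the (broad, early, late) call triple.

    Returns a frame indexed by gene with columns broad, early, late,
    pattern and conflict.  ``conflict`` is True when the broad call is up
    (down) while both granular calls are down (up).
    """
    missing = [c for c in CONTRASTS if c not in calls]
    if missing:
        raise DGEError(f"missing contrasts: {missing}")
    df = pd.DataFrame(
        {CONTRAST_ROLES[c]: calls[c] for c in CONTRASTS}
    )
    if df.isna().any().any():
        raise DGEError("contrasts do not share a gene universe")

    def label(row) -> str:
        parts = [
            f"{role}_{row[role]}"
            for role in ("broad", "early", "late")
            if row[role] != "ns"
        ]
        return "+".join(parts) if parts else "ns"

    df["pattern"] = df.apply(label, axis=1)
    df["conflict"] = ((df["broad"] == "up") & (df["early"] == "down") & (df["late"] == "down")) | (
        (df["broad"] == "down") & (df["early"] == "up") & (df["late"] == "up")
    )
    return df


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def pct_half_up(n_deg: int, n_expressed: int, decimals: int = 2) -> float:
    """100*n_deg/n_expressed rounded half-up, computed exactly."""
    q = Decimal(100 * n_deg) / Decimal(n_expressed)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def summarize_contrasts(
    calls: Optional[Mapping[str, pd.Series]] = None,
    n_expressed: Optional[Mapping[str, int]] = None,
    side_counts: Optional[Mapping[str, tuple[int, int]]] = None,
) -> pd.DataFrame:
    """Per-contrast DEG summary (totals, per-side up counts, percentage).

    Either ``calls`` (per-contrast up/down/ns series) or explicit
    ``side_counts`` (contrast -> (n up in A, n up in B)) must be given.  A
    gene called 'up' is upregulated in B (longer exposure); 'down' means
    upregulated in A.  ``pct_deg`` = 100*n_deg/n_expressed rounded half-up
    to 2 decimals, when ``n_expressed`` is known.
    """
    if calls is None and side_counts is None:
        raise DGEError("give either calls or side_counts")
    rows = []
    contrasts = list((calls or side_counts).keys())
    for c in contrasts:
        a_label, b_label = CONTRASTS.get(c, ("A", "B"))
        if calls is not None:
            series = calls[c]
            n_up_b = int((series == "up").sum())
            n_up_a = int((series == "down").sum())
        else:
            n_up_a, n_up_b = (int(x) for x in side_counts[c])
        n_deg = n_up_a + n_up_b
        row = {
            "contrast": c,
            "n_deg": n_deg,
            "n_up_a": n_up_a,
            "n_up_b": n_up_b,
            "up_a_label": a_label,
            "up_b_label": b_label,
        }
        if n_expressed is not None and c in n_expressed:
            ne = int(n_expressed[c])
            if n_deg > ne:
                raise DGEError(f"{c}: n_deg ({n_deg}) exceeds n_expressed ({ne})")
            row["n_expressed"] = ne
            row["pct_deg"] = pct_half_up(n_deg, ne)
        rows.append(row)
    return pd.DataFrame(rows).set_index("contrast", drop=False)


def sample_correlation(
    counts: pd.DataFrame, min_count: int = 10
) -> pd.DataFrame:
    """Samples x samples Pearson correlation of log2 CPM, restricted to
    genes exceeding ``min_count`` in at least one sample."""
    if counts.shape[1] < 2:
        raise DGEError("need at least 2 samples")
    keep = (counts > min_count).any(axis=1)
    if not keep.any():
        raise DGEError("no genes pass the count filter")
    expr = log_cpm(counts.loc[keep])
    r = np.corrcoef(expr.to_numpy().T)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=counts.columns, columns=counts.columns)
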