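"""Synthetic data generators with known ground truth.

Four generators cover every pipeline input: biphasic pulse snippets
(Gaussian bumps plus an exact exponential recovery tail, so every waveform
feature has an analytically tractable truth), longitudinal three-group
cohorts of such snippets, negative-binomial count matrices with planted
differentially expressed genes, and gene-set libraries with planted
enrichment signs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .waveform import DetectionConfig, Recording

TREATMENTS = ("control", "T1day", "T8day")


class SynthError(ValueError):
    """Raised for invalid generator parameters."""


# ---------------------------------------------------------------------------
# Pulse snippets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EODPulseParams:
    """Parameters of the synthetic biphasic pulse model.

    The continuous model is, in raw (pre-normalization) units,

        v(t) = a1*exp(-(t-t1)^2 / (2*w1^2)) - a2*exp(-(t-t2)^2 / (2*w2^2))

    for t <= t2, and an exact exponential recovery

        v(t) = v(t2) * exp(-tau*(t - t2))

    for t > t2, continuous at the junction.  The global minimum is exactly
    at t2.  Times are milliseconds; tau is per millisecond.
    """

    a1: float = 0.41
    a2: float = 0.60
    t1: float = 3.8
    t2: float = 4.13
    w1: float = 0.06
    w2: float = 0.055
    tau: float = 31.06  # Gaussian-amplitude defaults echo an untreated pulse
    offset: float = 0.0
    noise_sd: float = 0.005
    sample_rate: float = 250_000.0
    npts: int = 2048

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "w1", "w2", "tau"):
            if getattr(self, name) <= 0:
                raise SynthError(f"{name} must be positive")
        if not self.t1 < self.t2:
            raise SynthError("t1 must precede t2")
        if self.sample_rate <= 0:
            raise SynthError("sample_rate must be positive")
        if self.npts < 4:
            raise SynthError("npts too small")
        if self.noise_sd < 0:
            raise SynthError("noise_sd must be non-negative")

    @property
    def dt_ms(self) -> float:
        return 1e3 / self.sample_rate

    def time_scaled(self, s: float) -> "EODPulseParams":
        """Dilate the pulse time axis by ``s`` about t1 (widths, the
        P1->P2 gap and the decay time constant all scale by ``s``)."""
        if s <= 0:
            raise SynthError("scale must be positive")
        return replace(
            self,
            w1=self.w1 * s,
            w2=self.w2 * s,
            t2=self.t1 + (self.t2 - self.t1) * s,
            tau=self.tau / s,
        )


class PulseModel:
    """Continuous noise-free pulse model (callable on time in ms)."""

    def __init__(self, p: EODPulseParams):
        self.p = p
        self.v_min = p.a1 * math.exp(-((p.t2 - p.t1) ** 2) / (2 * p.w1**2)) - p.a2
        if self.v_min >= 0:
            raise SynthError("parameters do not produce a biphasic pulse")

    def __call__(self, t):
        p = self.p
        t = np.asarray(t, dtype=float)
        g1 = p.a1 * np.exp(-((t - p.t1) ** 2) / (2 * p.w1**2))
        g2 = p.a2 * np.exp(-((t - p.t2) ** 2) / (2 * p.w2**2))
        tail = self.v_min * np.exp(-p.tau * (t - p.t2))
        return np.where(t <= p.t2, g1 - g2, tail)

    def deriv(self, t):
        p = self.p
        t = np.asarray(t, dtype=float)
        g1 = p.a1 * np.exp(-((t - p.t1) ** 2) / (2 * p.w1**2))
        g2 = p.a2 * np.exp(-((t - p.t2) ** 2) / (2 * p.w2**2))
        head = -g1 * (t - p.t1) / p.w1**2 + g2 * (t - p.t2) / p.w2**2
        tail = -p.tau * self.v_min * np.exp(-p.tau * (t - p.t2))
        return np.where(t <= p.t2, head, tail)


@dataclass(frozen=True)
class PulseTruth:
    """Model-derived landmark times (ms, snippet time axis) and features.

    ``t_end`` is defined consistently with the trailing-window end rule:
    it is the time at which the mean of the trailing ``end_window`` samples
    of the continuous model crosses the negative threshold, so discrete
    detection matches it to within a sample interval.
    """

    t_start: float
    t_end: float
    t_vp1: float
    t_vp2: float
    t_zerocross: float
    v_vp1: float
    v_vp2: float
    eod_duration: float
    p1_duration: float
    p2_duration: float
    p1p2_delay: float
    vp2_vp1_ratio: float
    tau: float
    sp1: float


def compute_truth(
    params: EODPulseParams, cfg: DetectionConfig = DetectionConfig()
) -> PulseTruth:
    """Landmarks and features of the noise-free continuous model."""
    p = params
    model = PulseModel(p)
    dt = p.dt_ms

    res = minimize_scalar(
        lambda t: -model(t),
        bounds=(p.t1 - 4 * p.w1, p.t2),
        method="bounded",
        options={"xatol": 1e-12},
    )
    t_vp1 = float(res.x)
    v_max = float(model(t_vp1))
    pkpk = v_max - model.v_min
    thr = cfg.threshold_frac * pkpk

    t_zero = float(brentq(lambda t: model(t), t_vp1, p.t2, xtol=1e-12))

    # first |v| threshold crossing: vectorized coarse scan, then refine
    ts = np.arange(0.0, p.t2, dt / 8)
    idx = np.nonzero(np.abs(model(ts)) > thr)[0]
    if idx.size == 0 or idx[0] == 0:
        raise SynthError("pulse not contained in snippet (no onset crossing)")
    a, b = ts[idx[0] - 1], ts[idx[0]]
    t_start = float(brentq(lambda t: abs(model(t)) - thr, a, b, xtol=1e-12))

    # end per the trailing-mean rule; on the exponential tail the trailing
    # mean is the pointwise value times a closed-form factor
    win = cfg.end_window
    mbar = float(np.mean(np.exp(p.tau * dt * np.arange(win))))
    t_end = p.t2 + math.log(-model.v_min * mbar / thr) / p.tau
    if t_end - (win - 1) * dt < p.t2:  # pragma: no cover - very short tails
        g = lambda t: np.mean(model(t - dt * np.arange(win))) + thr
        t_end = float(brentq(g, p.t2 + (win - 1) * dt, p.t2 + 50 / p.tau, xtol=1e-12))

    horizon = (p.npts - 1) * dt
    if t_start < 0 or t_end > horizon:
        raise SynthError("pulse not contained in snippet")

    res = minimize_scalar(
        lambda t: -model.deriv(t),
        bounds=(t_start, t_vp1),
        method="bounded",
        options={"xatol": 1e-12},
    )
    sp1 = float(model.deriv(res.x)) / pkpk

    return PulseTruth(
        t_start=t_start,
        t_end=t_end,
        t_vp1=t_vp1,
        t_vp2=p.t2,
        t_zerocross=t_zero,
        v_vp1=v_max / pkpk,
        v_vp2=model.v_min / pkpk,
        eod_duration=t_end - t_start,
        p1_duration=t_zero - t_start,
        p2_duration=t_end - t_zero,
        p1p2_delay=p.t2 - t_vp1,
        vp2_vp1_ratio=model.v_min / v_max,
        tau=p.tau,
        sp1=sp1,
    )


def simulate_eod_snippet(
    params: EODPulseParams,
    seed: int,
    cfg: DetectionConfig = DetectionConfig(),
    meta: Optional[dict] = None,
) -> tuple[Recording, PulseTruth]:
    """One sampled snippet plus the continuous-model ground truth."""
    truth = compute_truth(params, cfg)
    rng = np.random.default_rng(seed)
    t = np.arange(params.npts) * params.dt_ms
    v = PulseModel(params)(t) + params.offset
    if params.noise_sd > 0:
        v = v + rng.normal(0.0, params.noise_sd, params.npts)
    rec = Recording(samples=v, dt=1.0 / params.sample_rate, meta=dict(meta or {}))
    return rec, truth


def scale_for_duration(
    params: EODPulseParams,
    target_duration: float,
    cfg: DetectionConfig = DetectionConfig(),
    iters: int = 4,
) -> tuple[EODPulseParams, PulseTruth]:
    """Time-dilate ``params`` so the model truth duration hits the target.

    The end-rule lag makes duration slightly non-linear in the dilation
    factor, so a few fixed-point refinements are used.
    """
    if target_duration <= 0:
        raise SynthError("target duration must be positive")
    s = target_duration / compute_truth(params, cfg).eod_duration
    scaled = params.time_scaled(s)
    truth = compute_truth(scaled, cfg)
    for _ in range(iters - 1):
        s *= target_duration / truth.eod_duration
        scaled = params.time_scaled(s)
        truth = compute_truth(scaled, cfg)
    return scaled, truth


# ---------------------------------------------------------------------------
# Longitudinal cohort
# ---------------------------------------------------------------------------

def _default_days() -> dict:
    return {"control": tuple(range(9)), "T1day": (0, 1), "T8day": tuple(range(9))}


def _default_trajectory() -> tuple:
    # linear ramp in duration multiplier, 1.0 at day 0 to 1.96 at day 8
    return tuple(1.0 + 0.96 * d / 8 for d in range(9))


@dataclass(frozen=True)
class CohortDesign:
    """Three-treatment longitudinal recording design."""

    groups: tuple = (("control", 6), ("T1day", 7), ("T8day", 7))
    days: Mapping[str, tuple] = field(default_factory=_default_days)
    snippets_per_session: int = 10
    elongation_trajectory: tuple = field(default_factory=_default_trajectory)
    base_duration_mean: float = 0.685
    base_duration_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for label, n in self.groups:
            if label not in TREATMENTS:
                raise SynthError(f"unknown treatment label: {label!r}")
            if n < 1:
                raise SynthError("group sizes must be >= 1")
        if self.snippets_per_session < 1:
            raise SynthError("snippets_per_session must be >= 1")
        traj = self.elongation_trajectory
        if abs(traj[0] - 1.0) > 1e-12:
            raise SynthError("elongation multiplier must be 1 at day 0")
        if any(b < a - 1e-12 for a, b in zip(traj, traj[1:])):
            raise SynthError("elongation trajectory must be non-decreasing")

    def multiplier(self, treatment: str, day: int) -> float:
        if treatment not in TREATMENTS:
            raise SynthError(f"unknown treatment label: {treatment!r}")
        if treatment != "T8day" or day <= 0:
            return 1.0
        traj = self.elongation_trajectory
        return traj[min(day, len(traj) - 1)]


@dataclass
class Cohort:
    """Simulated recordings plus per-fish per-day ground truth."""

    recordings: dict  # (fish, day) -> list[Recording]
    truth: pd.DataFrame  # fish, treatment, day, multiplier, target/realized truth


def simulate_cohort(
    design: CohortDesign,
    base_params: EODPulseParams = EODPulseParams(),
    cfg: DetectionConfig = DetectionConfig(),
) -> Cohort:
    """Per fish per day, ``snippets_per_session`` noisy snippets.

    Control and T1day fish keep a duration multiplier of 1; T8day fish have
    their time-axis parameters dilated by the elongation trajectory after
    day 0.  The truth table carries the intended (= realized model truth)
    duration for every session.
    """
    rows = []
    recordings: dict = {}
    fish_idx = 0
    for label, n in design.groups:
        for _ in range(n):
            fish = f"{label}_{fish_idx:02d}"
            fish_ss = np.random.SeedSequence(
                entropy=design.seed, spawn_key=(fish_idx,)
            )
            rng = np.random.default_rng(fish_ss)
            base_dur = max(
                0.45,
                rng.normal(design.base_duration_mean, design.base_duration_sd),
            )
            a1 = float(np.clip(rng.normal(base_params.a1, 0.015), 0.3, 0.5))
            fish_params = replace(base_params, a1=a1)
            # cache duration solutions per multiplier (shared across days)
            cache: dict = {}
            for day in design.days[label]:
                m = design.multiplier(label, day)
                if m not in cache:
                    cache[m] = scale_for_duration(fish_params, base_dur * m, cfg)
                day_params, day_truth = cache[m]
                seeds = rng.integers(0, 2**63 - 1, size=design.snippets_per_session)
                recs = []
                for s in seeds:
                    rec, _ = simulate_eod_snippet(
                        day_params,
                        int(s),
                        cfg,
                        meta={"fish": fish, "treatment": label, "day": int(day)},
                    )
                    recs.append(rec)
                recordings[(fish, int(day))] = recs
                rows.append(
                    {
                        "fish": fish,
                        "treatment": label,
                        "day": int(day),
                        "multiplier": m,
                        "duration": day_truth.eod_duration,
                        "p1_duration": day_truth.p1_duration,
                        "p2_duration": day_truth.p2_duration,
                        "p1p2_delay": day_truth.p1p2_delay,
                        "vp2_vp1_ratio": day_truth.vp2_vp1_ratio,
                        "tau": day_truth.tau,
                        "sp1": day_truth.sp1,
                    }
                )
            fish_idx += 1
    truth = pd.DataFrame(rows)
    return Cohort(recordings=recordings, truth=truth)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

PATTERNS = ("broad", "early", "late")
DIRECTIONS = ("up", "down")


@dataclass(frozen=True)
class PlantedDEG:
    pattern: str  # broad | early | late
    direction: str  # up | down
    effect: float  # log2 units, positive

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise SynthError(f"unknown pattern: {self.pattern!r}")
        if self.direction not in DIRECTIONS:
            raise SynthError(f"unknown direction: {self.direction!r}")
        if not math.isfinite(self.effect) or self.effect <= 0:
            raise SynthError("effect must be positive and finite")


@dataclass(frozen=True)
class ExprSimParams:
    """Negative-binomial count simulation parameters.

    Planted genes with an ``early`` pattern get their mean shifted in both
    T1day and T8day samples; ``late`` only in T8day; ``broad`` gets the
    full shift in T8day and, by default, half the log2 effect in T1day.
    """

    n_genes: int = 2000
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"control": 6, "T1day": 7, "T8day": 7}
    )
    mean_log2_loc: float = 4.0
    mean_log2_scale: float = 2.0
    dispersion: float = 0.04  # common NB dispersion (BCV 0.2)
    library_sizes: object = 1_000_000.0  # scalar or per-sample sequence
    planted_degs: Mapping[str, PlantedDEG] = field(default_factory=dict)
    broad_t1day_fraction: float = 0.5
    planted_min_log2: float = 4.0  # floor on planted genes' base abundance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise SynthError("n_genes must be >= 1")
        for g in self.group_sizes:
            if g not in TREATMENTS:
                raise SynthError(f"unknown treatment label: {g!r}")
        if np.any(np.asarray(self.dispersion) < 0):
            raise SynthError("dispersion must be >= 0")

    def sample_names(self) -> list[str]:
        return [
            f"{grp}_{i + 1}" for grp in self.group_sizes for i in range(self.group_sizes[grp])
        ]


def gene_names(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


@dataclass
class CountSim:
    counts: pd.DataFrame  # genes x samples
    treatments: pd.Series  # sample -> treatment
    truth: pd.DataFrame  # gene, pattern, direction, effect


def simulate_counts(params: ExprSimParams) -> CountSim:
    """Gene x sample NB counts with planted fold changes and truth table."""
    rng = np.random.default_rng(params.seed)
    genes = gene_names(params.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    samples = params.sample_names()
    n_samples = len(samples)

    libs = np.asarray(params.library_sizes, dtype=float)
    if libs.ndim == 0:
        libs = np.full(n_samples, float(libs))
    elif libs.size != n_samples:
        raise SynthError(
            f"library_sizes length {libs.size} inconsistent with "
            f"{n_samples} samples"
        )

    base = 2.0 ** rng.normal(params.mean_log2_loc, params.mean_log2_scale, params.n_genes)

    mult = {t: np.ones(params.n_genes) for t in params.group_sizes}
    for gene, deg in params.planted_degs.items():
        if gene not in gene_pos:
            raise SynthError(f"planted gene {gene!r} not in gene universe")
        i = gene_pos[gene]
        # planted signal must be detectable: floor the base abundance
        base[i] = max(base[i], 2.0**params.planted_min_log2)
        sign = 1.0 if deg.direction == "up" else -1.0
        full = 2.0 ** (sign * deg.effect)
        if deg.pattern == "early":
            if "T1day" in mult:
                mult["T1day"][i] *= full
            if "T8day" in mult:
                mult["T8day"][i] *= full
        elif deg.pattern == "late":
            if "T8day" in mult:
                mult["T8day"][i] *= full
        else:  # broad
            if "T8day" in mult:
                mult["T8day"][i] *= full
            if "T1day" in mult:
                mult["T1day"][i] *= 2.0 ** (
                    sign * deg.effect * params.broad_t1day_fraction
                )

    treatments = pd.Series(
        {s: s.rsplit("_", 1)[0] for s in samples}, name="treatment"
    )
    counts = np.empty((params.n_genes, n_samples), dtype=np.int64)
    disp = np.broadcast_to(np.asarray(params.dispersion, dtype=float), (params.n_genes,))
    for j, s in enumerate(samples):
        rel = base * mult[treatments[s]]
        mu = libs[j] * rel / rel.sum()
        zero = disp == 0
        col = np.empty(params.n_genes, dtype=np.int64)
        if zero.any():
            col[zero] = rng.poisson(mu[zero])
        if (~zero).any():
            r = 1.0 / disp[~zero]
            p = r / (r + mu[~zero])
            col[~zero] = rng.negative_binomial(r, p)
        counts[:, j] = col

    truth = pd.DataFrame(
        [
            {
                "gene": g,
                "pattern": d.pattern,
                "direction": d.direction,
                "effect": d.effect,
            }
            for g, d in params.planted_degs.items()
        ],
        columns=["gene", "pattern", "direction", "effect"],
    )
    return CountSim(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        treatments=treatments,
        truth=truth,
    )


def random_planted_degs(
    n_genes: int,
    n_per_class: int,
    effect: float,
    seed: int = 0,
) -> dict[str, PlantedDEG]:
    """Convenience: plant ``n_per_class`` genes for every pattern/direction."""
    rng = np.random.default_rng(seed)
    genes = gene_names(n_genes)
    need = n_per_class * len(PATTERNS) * len(DIRECTIONS)
    if need > n_genes:
        raise SynthError("more planted genes requested than the universe holds")
    chosen = rng.choice(n_genes, size=need, replace=False)
    out = {}
    k = 0
    for pattern in PATTERNS:
        for direction in DIRECTIONS:
            for _ in range(n_per_class):
                out[genes[chosen[k]]] = PlantedDEG(pattern, direction, effect)
                k += 1
    return out


# ---------------------------------------------------------------------------
# Gene-set libraries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichedSetSpec:
    pattern: str
    direction: str
    size: int = 40
    planted_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS or self.direction not in DIRECTIONS:
            raise SynthError("invalid enriched-set spec")
        if self.size < 1:
            raise SynthError("set sizes must be >= 1")
        if not 0 <= self.planted_fraction <= 1:
            raise SynthError("planted_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GeneSetSimParams:
    n_sets: int = 100
    size_range: tuple = (20, 120)
    enriched_sets: Mapping[str, EnrichedSetSpec] = field(default_factory=dict)
    allow_overlap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sets < 0:
            raise SynthError("n_sets must be >= 0")
        lo, hi = self.size_range
        if lo < 1 or hi < lo:
            raise SynthError("invalid size_range")


_SIGNS = {
    # pattern, direction -> expected enrichment sign per (broad, early, late)
    ("early", "up"): (1, 1, 0),
    ("early", "down"): (-1, -1, 0),
    ("late", "up"): (1, 0, 1),
    ("late", "down"): (-1, 0, -1),
    ("broad", "up"): (1, 1, 1),
    ("broad", "down"): (-1, -1, -1),
}


def simulate_geneset_library(
    params: GeneSetSimParams,
    expr_truth: pd.DataFrame,
    universe: Sequence[str],
):
    """GMT-writable library plus an enrichment truth table.

    Enriched sets preferentially sample planted genes of the designated
    pattern and direction; the rest of each set, and all background sets,
    are uniform draws from the gene universe.
    """
    from .enrich import GeneSetLibrary

    rng = np.random.default_rng(params.seed)
    universe = list(universe)
    n_univ = len(universe)
    sets: dict[str, list[str]] = {}
    rows = []

    for name, spec in params.enriched_sets.items():
        if spec.size > n_univ:
            raise SynthError(f"set {name!r} larger than the gene universe")
        pool = expr_truth.loc[
            (expr_truth["pattern"] == spec.pattern)
            & (expr_truth["direction"] == spec.direction),
            "gene",
        ].tolist()
        k = min(int(round(spec.planted_fraction * spec.size)), len(pool), spec.size)
        members = list(rng.choice(pool, size=k, replace=False)) if k else []
        rest = [g for g in universe if g not in set(members)]
        members += list(rng.choice(rest, size=spec.size - k, replace=False))
        sets[name] = members
        sb, se, sl = _SIGNS[(spec.pattern, spec.direction)]
        rows.append(
            {
                "set": name,
                "pattern": spec.pattern,
                "direction": spec.direction,
                "n_planted": k,
                "sign_broad": sb,
                "sign_early": se,
                "sign_late": sl,
            }
        )

    lo, hi = params.size_range
    for i in range(params.n_sets):
        name = f"SET_{i:04d}"
        if name in sets:  # pragma: no cover - name collision guard
            name = f"SET_bg_{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        if size > n_univ:
            raise SynthError("requested set size exceeds the gene universe")
        sets[name] = list(rng.choice(universe, size=size, replace=False))
        rows.append(
            {
                "set": name,
                "pattern": "none",
                "direction": "none",
                "n_planted": 0,
                "sign_broad": 0,
                "sign_early": 0,
                "sign_late": 0,
            }
        )

    truth = pd.DataFrame(
        rows,
        columns=[
            "set",
            "pattern",
            "direction",
            "n_planted",
            "sign_broad",
            "sign_early",
            "sign_late",
        ],
    )
    return GeneSetLibrary(sets, name="synthetic"), truth
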