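"""Kinetic traces, double-logistic fitting and curve descriptors.

The population-level Ca²⁺ signal is the per-time-bin median of the Fluo-4
channel of a gated population, divided by the resting (pre-activation)
fluorescence so that every curve starts at 1.  Most activation curves follow
a double-logistic course

    f(t) = S + H1 / (1 + exp(-k1 (t - m1))) - H2 / (1 + exp(-k2 (t - m2)))

a rising logistic (store release + entry) minus a falling one (clearance
toward the SOCE plateau).  ``S`` is the limit at -inf (the standardized
starting value), ``S + H1 - H2`` the limit at +inf (the Ending value), the
``k``'s are rates (1/s) and the ``m``'s midpoints (s).  Nine descriptors are
derived from the fitted function: Start, Max, Ending, T to Max, T to 1st
50%, T from 50% to Max, Slope at 1st 50% (positive), T from Max to 2nd 50%,
Slope at 2nd 50% (negative), and the AUC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .fcs_io import KineticRecording, TIME_CHANNEL

__all__ = [
    "PopulationTrace",
    "KineticFit",
    "KineticDescriptors",
    "double_logistic",
    "double_logistic_deriv",
    "double_logistic_auc",
    "bin_median_trace",
    "normalize_trace",
    "fit_kinetic",
    "derive_descriptors",
    "descriptor_table",
    "DESCRIPTOR_NAMES",
]

logger = logging.getLogger(__name__)

FLUO4_CHANNEL = "Fluo4"

DESCRIPTOR_NAMES = (
    "start", "max", "ending", "t_to_max", "t_to_50", "t_50_to_max",
    "slope_at_50", "t_max_to_2nd50", "slope_at_2nd50", "auc",
)

ModelKind = Literal["constant", "logistic", "dlogist"]


# ---------------------------------------------------------------------------
# Model family


def double_logistic(t, S, H1, k1, m1, H2=0.0, k2=1.0, m2=0.0):
    """Evaluate f(t) = S + H1·σ(k1(t−m1)) − H2·σ(k2(t−m2))."""
    t = np.asarray(t, dtype=float)
    out = S + H1 * expit(k1 * (t - m1))
    if H2 != 0.0:
        out = out - H2 * expit(k2 * (t - m2))
    return out


def double_logistic_deriv(t, S, H1, k1, m1, H2=0.0, k2=1.0, m2=0.0):
    """First derivative of the double-logistic function."""
    t = np.asarray(t, dtype=float)
    g1 = expit(k1 * (t - m1))
    out = H1 * k1 * g1 * (1.0 - g1)
    if H2 != 0.0:
        g2 = expit(k2 * (t - m2))
        out = out - H2 * k2 * g2 * (1.0 - g2)
    return out


def _softplus(x):
    # log(1 + e^x), overflow-safe
    return np.logaddexp(0.0, x)


def double_logistic_auc(a, b, S, H1, k1, m1, H2=0.0, k2=1.0, m2=0.0,
                        baseline: Literal["start", "zero"] = "start"):
    """Closed-form ∫ₐᵇ (f(t) − S) dt via the logistic antiderivative.

    ∫ H σ(k(t−m)) dt = (H/k)·log(1 + e^{k(t−m)}).  With ``baseline='zero'``
    the integral of f itself is returned (adds S·(b−a))."""
    def F(t):
        val = (H1 / k1) * _softplus(k1 * (t - m1))
        if H2 != 0.0:
            val = val - (H2 / k2) * _softplus(k2 * (t - m2))
        return val

    area = F(b) - F(a)
    if baseline == "zero":
        area = area + S * (b - a)
    return float(area)


# ---------------------------------------------------------------------------
# Containers


@dataclass
class PopulationTrace:
    """Binned median-fluorescence time course for one gated population."""

    population: str
    bin_centers: np.ndarray
    medians_raw: np.ndarray
    bin_counts: np.ndarray
    t_act: float
    t_end: float
    medians_norm: np.ndarray | None = None
    baseline_stat: float | None = None

    @property
    def is_normalized(self) -> bool:
        return self.medians_norm is not None

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)

    def to_frame(self) -> pd.DataFrame:
        d = {
            "time_s": self.bin_centers,
            "median_raw": self.medians_raw,
            "n_events": self.bin_counts,
        }
        if self.is_normalized:
            d["median_norm"] = self.medians_norm
        return pd.DataFrame(d)


@dataclass
class KineticFit:
    """Fitted kinetic model for one normalized population trace.

    ``S`` is the resting level (limit at −∞), ``H1``/``k1``/``m1`` the rise
    amplitude, rate and midpoint, ``H2``/``k2``/``m2`` the decay.  For
    ``model='logistic'`` H2 = 0, for ``model='constant'`` H1 = H2 = 0.
    """

    model: ModelKind
    S: float
    H1: float = 0.0
    k1: float = 1.0
    m1: float = 0.0
    H2: float = 0.0
    k2: float = 1.0
    m2: float = 0.0
    rss: float = math.nan
    r2: float = math.nan
    n_bins: int = 0
    converged: bool = True

    @property
    def params(self) -> tuple[float, ...]:
        return (self.S, self.H1, self.k1, self.m1, self.H2, self.k2, self.m2)

    def __call__(self, t):
        return double_logistic(t, *self.params)

    def deriv(self, t):
        return double_logistic_deriv(t, *self.params)

    def auc(self, a: float, b: float, baseline: str = "start") -> float:
        return double_logistic_auc(a, b, *self.params, baseline=baseline)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class KineticDescriptors:
    """The nine curve descriptors; times are seconds from activation.

    Any field may be NaN when undefined for the fitted model (e.g. the
    descending-limb descriptors of a curve with no decay phase).
    """

    start: float
    max: float
    ending: float
    t_to_max: float
    t_to_50: float
    t_50_to_max: float
    slope_at_50: float
    t_max_to_2nd50: float
    slope_at_2nd50: float
    auc: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


# ---------------------------------------------------------------------------
# Trace construction


def bin_median_trace(
    recording: KineticRecording,
    population: np.ndarray | None = None,
    bin_width: float = 5.0,
    fluo_channel: str = FLUO4_CHANNEL,
    min_per_bin: int = 5,
    name: str = "all",
) -> PopulationTrace:
    """Per-bin median Fluo-4 over fixed-width bins spanning [0, t_end].

    ``population`` is an event index (or boolean mask) selecting the gated
    subset; bins holding fewer than ``min_per_bin`` events are dropped.
    """
    if population is None:
        events = recording.events
    else:
        sel = np.asarray(population)
        if sel.dtype == bool:
            sel = np.nonzero(sel)[0]
        events = recording.events.iloc[sel]
    t = events[TIME_CHANNEL].to_numpy(float)
    y = events[fluo_channel].to_numpy(float)

    edges = np.arange(0.0, recording.t_end + bin_width, bin_width)
    edges = edges[edges <= recording.t_end + 1e-9]
    if edges[-1] < recording.t_end:
        edges = np.append(edges, recording.t_end)
    idx = np.digitize(t, edges) - 1
    idx[t >= edges[-1]] = len(edges) - 2

    centers, medians, counts = [], [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n < min_per_bin:
            if n:
                logger.debug("dropping bin %d (%d events < %d)", b, n, min_per_bin)
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        medians.append(float(np.median(y[sel])))
        counts.append(n)
    if not centers:
        raise ValueError(f"trace unfittable: no bins with >= {min_per_bin} events")

    return PopulationTrace(
        population=name,
        bin_centers=np.asarray(centers),
        medians_raw=np.asarray(medians),
        bin_counts=np.asarray(counts),
        t_act=recording.t_act,
        t_end=recording.t_end,
    )


def normalize_trace(
    trace: PopulationTrace,
    stat: Literal["median", "mean"] = "median",
    min_baseline_bins: int = 3,
) -> PopulationTrace:
    """Standardize the trace by its resting fluorescence.

    The divisor is the median (default; mean selectable) of the bin medians
    whose centers precede activation-agent contact minus any gap, i.e. lie
    in the baseline acquisition.  After division the median of the
    normalized baseline bins equals 1 exactly.
    """
    baseline_end = trace.t_act  # bins before t_act are pre-activation
    base = trace.bin_centers < baseline_end
    if base.sum() < min_baseline_bins:
        raise ValueError(
            f"need >= {min_baseline_bins} baseline bins before t_act="
            f"{trace.t_act:.1f}s, found {int(base.sum())}"
        )
    vals = trace.medians_raw[base]
    divisor = float(np.median(vals) if stat == "median" else np.mean(vals))
    if divisor <= 0:
        raise ValueError(f"non-positive resting fluorescence ({divisor})")
    return PopulationTrace(
        population=trace.population,
        bin_centers=trace.bin_centers,
        medians_raw=trace.medians_raw,
        bin_counts=trace.bin_counts,
        t_act=trace.t_act,
        t_end=trace.t_end,
        medians_norm=trace.medians_raw / divisor,
        baseline_stat=divisor,
    )


# ---------------------------------------------------------------------------
# Fitting

_MIN_BINS = {"constant": 2, "logistic": 4, "dlogist": 8}


def _initial_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Deterministic start values for the double logistic (normalized y)."""
    S0 = 1.0
    ymax = float(y.max())
    imax = int(np.argmax(y))
    H1_0 = max(ymax - S0, 1e-3)
    half1 = S0 + H1_0 / 2.0
    above = np.nonzero(y[: imax + 1] >= half1)[0]
    m1_0 = float(t[above[0]]) if len(above) else float(t[imax]) * 0.5
    rise_span = max(float(t[imax]) - m1_0, 1.0) * 2.0
    k1_0 = min(max(4.0 / rise_span, 1e-3), 5.0)

    ylast = float(y[-1])
    H2_0 = max(ymax - ylast, 1e-3)
    half2 = ylast + (ymax - ylast) / 2.0
    below = np.nonzero(y[imax:] <= half2)[0]
    m2_0 = float(t[imax + below[0]]) if len(below) else float(t[imax] + (t[-1] - t[imax]) / 2)
    fall_span = max(2.0 * (m2_0 - float(t[imax])), 10.0)
    k2_0 = min(max(4.0 / fall_span, 1e-3), 5.0)
    return np.array([S0, H1_0, k1_0, m1_0, H2_0, k2_0, m2_0])


def _wls(t, y, w, model: ModelKind, x0, bounds, max_nfev=2000):
    sw = np.sqrt(w)

    if model == "constant":
        S = float(np.sum(w * y) / np.sum(w))
        rss = float(np.sum(w * (y - S) ** 2))
        return np.array([S]), rss, True
    if model == "logistic":
        pick = [0, 1, 2, 3]
    else:
        pick = [0, 1, 2, 3, 4, 5, 6]

    def unpack(p):
        full = np.array([p[0], 0.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        full[pick] = p
        return full

    def resid(p):
        return sw * (double_logistic(t, *unpack(p)) - y)

    res = optimize.least_squares(
        resid, x0[pick],
        bounds=(bounds[0][pick], bounds[1][pick]),
        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=max_nfev,
    )
    return unpack(res.x), float(2 * res.cost), bool(res.success)


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    denom = n - k - 1
    return aic + (2 * k * (k + 1) / denom if denom > 0 else math.inf)


def fit_kinetic(
    trace: PopulationTrace,
    model: ModelKind | Literal["auto"] = "auto",
    weighted: bool = True,
    n_restarts: int = 5,
    restart_seed: int = 1234,
) -> KineticFit:
    """Weighted nonlinear least-squares fit of the kinetic model family.

    Weights are proportional to per-bin event counts so sparse late bins do
    not dominate.  ``model='auto'`` fits constant, logistic and double
    logistic and selects by small-sample-corrected AIC.  Initialization is
    deterministic (see ``_initial_guess``) with ``n_restarts`` seeded
    perturbed restarts; identical inputs always give identical fits.
    """
    if not trace.is_normalized:
        raise ValueError("fit_kinetic requires a normalized trace")
    t = np.asarray(trace.bin_centers, float)
    y = np.asarray(trace.medians_norm, float)
    n = len(t)
    w = trace.bin_counts / trace.bin_counts.mean() if weighted else np.ones(n)

    candidates = ["constant", "logistic", "dlogist"] if model == "auto" else [model]
    candidates = [m for m in candidates if n >= _MIN_BINS[m]]
    if not candidates:
        raise ValueError(f"only {n} bins: too few for model {model!r}")

    x0 = _initial_guess(t, y)
    Hcap = 10.0 * x0[1] + 1.0
    lo = np.array([0.0, 0.0, 1e-4, 0.0, 0.0, 1e-4, 0.0])
    hi = np.array([10.0, Hcap, 10.0, trace.t_end, Hcap, 10.0, trace.t_end])
    x0 = np.clip(x0, lo, hi)

    rng = np.random.default_rng(restart_seed)
    starts = [x0]
    for _ in range(n_restarts):
        pert = x0 * rng.lognormal(0.0, 0.3, size=7)
        starts.append(np.clip(pert, lo, hi))

    best: dict[str, tuple] = {}
    for mk in candidates:
        if mk == "constant":
            p, rss, ok = _wls(t, y, w, mk, x0, (lo, hi))
            best[mk] = (np.array([p[0], 0, 1, 0, 0, 1, 0]), rss, ok)
            continue
        mbest = None
        for s in starts:
            p, rss, ok = _wls(t, y, w, mk, s, (lo, hi))
            if mbest is None or rss < mbest[1] - 1e-15:
                mbest = (p, rss, ok)
        best[mk] = mbest

    kparams = {"constant": 1, "logistic": 4, "dlogist": 7}
    chosen = min(candidates, key=lambda mk: _aicc(best[mk][1], n, kparams[mk]))
    p, rss, ok = best[chosen]
    tss = float(np.sum(w * (y - np.sum(w * y) / np.sum(w)) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-12 else 0.0)
    if not ok:
        logger.warning("fit of %s did not converge cleanly", trace.population)
    return KineticFit(
        model=chosen, S=p[0], H1=p[1], k1=p[2], m1=p[3], H2=p[4], k2=p[5],
        m2=p[6], rss=rss, r2=r2, n_bins=n, converged=ok,
    )


# ---------------------------------------------------------------------------
# Descriptors


def _locate_window_max(fit: KineticFit, t_act: float, t_end: float) -> tuple[float, float]:
    """Maximum of f on [t_act, t_end]: coarse grid + bounded refinement."""
    grid = np.linspace(t_act, t_end, 4001)
    vals = fit(grid)
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if lo == hi:
        return float(grid[i]), float(vals[i])
    res = optimize.minimize_scalar(
        lambda t: -fit(t), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    t_star, f_star = float(res.x), float(-res.fun)
    if f_star < vals[i]:
        return float(grid[i]), float(vals[i])
    return t_star, f_star


def _crossing(fit: KineticFit, level: float, lo: float, hi: float) -> float | None:
    """Earliest root of f(t) − level on [lo, hi] (sign change required)."""
    grid = np.linspace(lo, hi, 2001)
    d = fit(grid) - level
    sign = np.sign(d)
    changes = np.nonzero(np.diff(sign) != 0)[0]
    if len(changes) == 0:
        return None
    j = changes[0]
    return float(optimize.brentq(lambda t: fit(t) - level, grid[j], grid[j + 1],
                                 xtol=1e-8))


def derive_descriptors(
    fit: KineticFit,
    t_act: float,
    t_end: float = 780.0,
    auc_baseline: Literal["start", "zero"] = "start",
    tol: float = 1e-6,
) -> KineticDescriptors:
    """Derive the nine curve descriptors from a fitted kinetic model.

    Start is the limit at −∞ (= S, 1 on a standardized trace); Ending the
    limit at +∞ (= S + H1 − H2); Max the maximum over the observation
    window [t_act, t_end].  The 1st 50% level is halfway between Start and
    Max (ascending crossing), the 2nd 50% level halfway between Max and
    Ending (descending crossing, which may fall beyond t_end).  All times
    are measured from t_act; AUC integrates f − S over [t_act, t_end] in
    closed form (or f itself with ``auc_baseline='zero'``).  Descriptors
    that do not exist for the fitted shape are NaN.
    """
    if t_act >= t_end:
        raise ValueError(f"t_act={t_act} must precede t_end={t_end}")
    NA = math.nan
    start = fit.S
    ending = fit.S + fit.H1 - fit.H2
    auc = fit.auc(t_act, t_end, baseline=auc_baseline)

    if fit.model == "constant" or (fit.H1 < tol and fit.H2 < tol):
        return KineticDescriptors(start, start, ending, NA, NA, NA, NA, NA, NA, auc)

    t_max_abs, fmax = _locate_window_max(fit, t_act, t_end)
    t_to_max = t_max_abs - t_act

    t_to_50 = t_50_to_max = slope_50 = NA
    if fmax - start > tol:
        L1 = start + (fmax - start) / 2.0
        tc = _crossing(fit, L1, t_act, t_max_abs)
        if tc is not None:
            t_to_50 = tc - t_act
            t_50_to_max = t_to_max - t_to_50
            slope_50 = float(fit.deriv(tc))

    t_max_to_2nd50 = slope_2nd50 = NA
    if fmax - ending > tol and fit.H2 > tol:
        L2 = ending + (fmax - ending) / 2.0
        hi = max(t_end, fit.m2 + 40.0 / fit.k2)
        tc2 = _crossing(fit, L2, t_max_abs, hi)
        if tc2 is not None:
            t_max_to_2nd50 = tc2 - t_max_abs
            slope_2nd50 = float(fit.deriv(tc2))

    return KineticDescriptors(
        start=start, max=fmax, ending=ending, t_to_max=t_to_max,
        t_to_50=t_to_50, t_50_to_max=t_50_to_max, slope_at_50=slope_50,
        t_max_to_2nd50=t_max_to_2nd50, slope_at_2nd50=slope_2nd50, auc=auc,
    )


# ---------------------------------------------------------------------------
# Plotting


def plot_trace(trace: PopulationTrace, fit: KineticFit | None = None, path=None):
    """Plot a standardized trace (and optionally its fit) to SVG/PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = trace.medians_norm if trace.is_normalized else trace.medians_raw
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(trace.bin_centers, y, ".", ms=3, color="0.4", label="bin medians")
    if fit is not None:
        tt = np.linspace(0, trace.t_end, 600)
        ax.plot(tt, fit(tt), "-", color="crimson", label=f"fit ({fit.model})")
    ax.axvline(trace.t_act, ls="--", color="0.7", label="activation")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("standardized Fluo-4 MFI" if trace.is_normalized else "Fluo-4 MFI")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# Tables


def descriptor_table(
    fits: Mapping[tuple[str, str, str], KineticDescriptors],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format descriptor table plus a median-per-cell pivot.

    ``fits`` maps (sample, population, agent) to descriptors.  Returns
    ``(long, pivot)`` where the pivot holds the median over samples for
    each (agent, descriptor) × population cell, NaN cells propagated.
    """
    rows = []
    for (sample, population, agent), d in fits.items():
        for name, value in d.to_dict().items():
            rows.append(
                {"sample": sample, "population": population, "agent": agent,
                 "descriptor": name, "value": value}
            )
    long = pd.DataFrame(rows)
    if long.empty:
        return long, pd.DataFrame()
    pivot = long.pivot_table(
        index=["agent", "descriptor"], columns="population", values="value",
        aggfunc="median", dropna=False,
    )
    return long, pivot
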