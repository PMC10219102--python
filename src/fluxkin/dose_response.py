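"""Agonist titration: stimulation-vs-[agonist] dose-response fitting.

The hyperbolic stimulation model (Hill slope 1)

    Y = Bottom + X (Top - Bottom) / (EC50 + X)

is fit to per-sample descriptor values (Max or Ending) measured across a
concentration series; EC50 is the agonist concentration giving the
half-maximal response.  A variable-slope (4PL) variant is available but is
not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize

__all__ = ["DoseResponseFit", "fit_stimulation_response", "stimulation_model"]


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    ec50: float
    r2: float
    n: int
    converged: bool
    hill: float = 1.0

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.hill == 1.0:
            return self.bottom + x * (self.top - self.bottom) / (self.ec50 + x)
        xh = np.power(x, self.hill, where=x > 0, out=np.zeros_like(x))
        return self.bottom + xh * (self.top - self.bottom) / (self.ec50 ** self.hill + xh)

    def to_dict(self) -> dict:
        return asdict(self)


def stimulation_model(x, bottom, top, ec50):
    x = np.asarray(x, dtype=float)
    return bottom + x * (top - bottom) / (ec50 + x)


def fit_stimulation_response(
    concentrations,
    responses,
    variable_slope: bool = False,
) -> DoseResponseFit:
    """Least-squares fit of the stimulation dose-response model.

    Requires >= 4 distinct concentrations spanning low and high doses.
    Initialization is deterministic: Bottom0 = min Y, Top0 = max Y, EC500 =
    the concentration whose response lies nearest mid-range.  R² is
    1 − RSS/TSS over the fitted points.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and responses must be equal-length 1-D")
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct concentrations for a dose-response fit")
    if np.ptp(y) < 1e-12 or np.std(y) < 1e-9 * max(1.0, abs(float(np.mean(y)))):
        raise ValueError("flat dose-response: EC50 is unidentifiable")

    b0, t0 = float(y.min()), float(y.max())
    mid = (b0 + t0) / 2.0
    pos = x[x > 0]
    ec0 = float(pos[np.argmin(np.abs(y[x > 0] - mid))]) if len(pos) else 1.0
    ec0 = max(ec0, 1e-6)

    if variable_slope:
        def model(x, bottom, top, ec50, hill):
            xh = np.power(np.clip(x, 1e-12, None), hill)
            return bottom + xh * (top - bottom) / (ec50 ** hill + xh)
        p0 = [b0, t0, ec0, 1.0]
        bounds = ([-np.inf, -np.inf, 1e-12, 0.1], [np.inf, np.inf, np.inf, 10.0])
    else:
        model = stimulation_model
        p0 = [b0, t0, ec0]
        bounds = ([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf])

    converged = True
    try:
        popt, _ = optimize.curve_fit(
            model, x, y, p0=p0, bounds=bounds, maxfev=20000,
            xtol=1e-13, ftol=1e-13, gtol=1e-13,
        )
    except RuntimeError:
        popt = np.asarray(p0, dtype=float)
        converged = False

    resid = y - model(x, *popt)
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    hill = float(popt[3]) if variable_slope else 1.0
    return DoseResponseFit(
        bottom=float(popt[0]), top=float(popt[1]), ec50=float(popt[2]),
        r2=r2, n=len(x), converged=converged, hill=hill,
    )
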