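"""Fluorescence recovery after photobleaching (FRAP) analysis.

The bleached-region trace is corrected for acquisition photobleaching by
dividing by a reference-corral trace, normalized so the pre-bleach mean is 1,
then fit with a single-exponential recovery

    I(t) = I_0+ + (I_inf - I_0+) * (1 - exp(-k t)),

from which the mobile fraction (I_inf - I_0+) / (I_pre - I_0+) and the
recovery halftime ln2 / k follow.  The single-exponential model is a
deliberate simplification: no bleach-spot geometry is assumed, so absolute
diffusion coefficients are out of scope and mobilities are compared through
rate-constant ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import lmfit

__all__ = ["FrapSeries", "FrapResult", "correct_trace", "fit_recovery",
           "compare_mobility"]


@dataclass
class FrapSeries:
    """Bleach-ROI and reference-ROI mean-intensity traces."""

    t_s: np.ndarray
    bleach: np.ndarray
    reference: np.ndarray
    n_prebleach: int
    channel: str = "Chl"
    background: float = 0.0  # camera offset, subtracted before correction

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.bleach = np.asarray(self.bleach, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if not (len(self.t_s) == len(self.bleach) == len(self.reference)):
            raise ValueError("traces must share one time axis")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")
        if np.any(self.bleach - self.background < -1e-12):
            raise ValueError("intensities must be >= background")

    @classmethod
    def from_csv(cls, path, n_prebleach: int, **kwargs) -> "FrapSeries":
        """Read (t_s, bleach_intensity, reference_intensity[, background])."""
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        bg = float(arr[:, 3].mean()) if arr.shape[1] > 3 else 0.0
        return cls(t_s=arr[:, 0], bleach=arr[:, 1], reference=arr[:, 2],
                   n_prebleach=n_prebleach, background=bg, **kwargs)


@dataclass
class FrapResult:
    """Mobile fraction and recovery kinetics from a corrected trace."""

    mobile_fraction: float
    recovery_halftime_s: float
    rate_per_s: float
    corrected: np.ndarray
    t_s: np.ndarray
    n_prebleach: int
    rss: float
    mobile_fraction_stderr: float = float("nan")
    rate_stderr: float = float("nan")
    converged: bool = True

    def __post_init__(self):
        if self.converged and not 0.0 <= self.mobile_fraction <= 1.0 + 1e-9:
            raise ValueError("mobile fraction must lie in [0, 1]")


def correct_trace(series: FrapSeries) -> np.ndarray:
    """Reference-corrected, pre-bleach-normalized recovery trace.

    corrected(t) = [bleach(t) / reference(t)] scaled so that the mean over
    the pre-bleach frames equals 1.  Any multiplicative global decay shared
    by both ROIs cancels exactly.
    """
    ref = series.reference - series.background
    if np.any(ref <= 0):
        raise ValueError("reference trace must be strictly positive "
                         "(dropout frame?)")
    raw = (series.bleach - series.background) / ref
    pre = raw[: series.n_prebleach].mean()
    if pre <= 0:
        raise ValueError("pre-bleach level must be positive")
    return raw / pre


def fit_recovery(series: FrapSeries) -> FrapResult:
    """Fit the single-exponential recovery to the corrected trace.

    ``I_0+`` is the first post-bleach frame; ``I_inf`` comes from the fit
    asymptote.  Requires >= 5 post-bleach points.  Non-convergence is
    flagged on the result, never silent.
    """
    corrected = correct_trace(series)
    npre = series.n_prebleach
    post = corrected[npre:]
    t_post = series.t_s[npre:] - series.t_s[npre]
    if len(post) < 5:
        raise ValueError("need >= 5 post-bleach points")

    i0 = float(post[0])
    params = lmfit.Parameters()
    params.add("i_inf", value=max(float(post[-1]), i0 + 1e-6), min=0.0)
    params.add("i0", value=i0, min=0.0, max=1.5)
    dt = np.median(np.diff(t_post)) if len(t_post) > 1 else 1.0
    params.add("rate", value=1.0 / max(t_post[-1] / 3.0, dt), min=1e-9)

    def residual(p):
        return post - (p["i0"].value
                       + (p["i_inf"].value - p["i0"].value)
                       * (1.0 - np.exp(-p["rate"].value * t_post)))

    res = lmfit.minimize(residual, params, method="leastsq", max_nfev=10000)
    p = res.params
    i0_fit = float(p["i0"].value)
    i_inf = float(p["i_inf"].value)
    k = float(p["rate"].value)
    # pre-bleach level is 1 by construction of the corrected trace
    mf = (i_inf - i0_fit) / (1.0 - i0_fit) if i0_fit < 1.0 else 1.0
    mf = float(np.clip(mf, 0.0, 1.0))

    mf_err = float("nan")
    if p["i_inf"].stderr is not None and i0_fit < 1.0:
        mf_err = p["i_inf"].stderr / (1.0 - i0_fit)
    return FrapResult(
        mobile_fraction=mf,
        recovery_halftime_s=float(np.log(2.0) / k),
        rate_per_s=k,
        corrected=corrected,
        t_s=series.t_s,
        n_prebleach=npre,
        rss=float(np.sum(res.residual ** 2)),
        mobile_fraction_stderr=mf_err,
        rate_stderr=float(p["rate"].stderr or np.nan),
        converged=bool(res.success),
    )


def compare_mobility(result_a: FrapResult, result_b: FrapResult):
    """Recovery-rate ratio k_a / k_b with first-order uncertainty.

    The ratio is invariant to any common rescaling of the raw traces.
    Returns ``(ratio, ratio_sigma)``.
    """
    if not (result_a.converged and result_b.converged):
        raise ValueError("both recovery fits must have converged")
    ratio = result_a.rate_per_s / result_b.rate_per_s
    ra = result_a.rate_stderr / result_a.rate_per_s
    rb = result_b.rate_stderr / result_b.rate_per_s
    terms = [r for r in (ra, rb) if np.isfinite(r)]
    sigma = abs(ratio) * np.sqrt(sum(r ** 2 for r in terms)) if terms \
        else float("nan")
    return float(ratio), float(sigma)
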