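"""Primary curve fits: the one-exponential transient model and linear fits.

Every stopped-flow transient is reduced to the apparent rate of

    F(t) = F_inf + A * exp(-k_app * t)

by nonlinear least squares; the sign of ``A`` is free, so rising
association transients and decaying chase transients share one code path.
Secondary analyses (apparent rate versus concentration, initial rates)
use weighted or ordinary linear regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lmfit import Model
import statsmodels.api as sm

__all__ = ["ExponentialFit", "LinearFit", "fit_single_exponential", "linear_fit"]


@dataclass(frozen=True)
class ExponentialFit:
    """Result of a one-exponential transient fit."""

    f_inf: float
    amplitude: float
    k_app: float
    se_f_inf: float
    se_amplitude: float
    se_k_app: float
    residual_sd: float
    n_points: int
    success: bool
    message: str = ""


@dataclass(frozen=True)
class LinearFit:
    """Result of a (possibly weighted) straight-line fit."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    n_points: int
    weighting: str  # "ols" or "wls"


def _exp_model(t, f_inf, amplitude, k_app):
    return f_inf + amplitude * np.exp(-k_app * t)


def _initial_guess(t: np.ndarray, y: np.ndarray):
    """Heuristic start values: plateau from the tail, rate from a log fit."""
    n_tail = max(3, len(y) // 10)
    f_inf = float(np.mean(y[-n_tail:]))
    amp = float(y[0] - f_inf)
    # log-linear rate estimate over the first half of the trace
    half = slice(0, max(4, len(y) // 2))
    dev = y[half] - f_inf
    sign = np.sign(amp) if amp != 0 else 1.0
    dev = sign * dev
    mask = dev > max(1e-12, 1e-3 * abs(amp))
    if mask.sum() >= 3:
        coef = np.polyfit(t[half][mask], np.log(dev[mask]), 1)
        k0 = max(-coef[0], 1e-12)
    else:
        k0 = 1.0 / max(t[-1] - t[0], 1e-12)
    return f_inf, amp, k0


def fit_single_exponential(trace) -> ExponentialFit:
    """Fit the one-exponential model to a time-course record.

    Accepts a :class:`~nexkin.records.TimeCourseRecord` (or any object with
    ``time_s`` and ``signal`` arrays).  Non-convergence after jittered
    restarts, or an amplitude indistinguishable from the residual noise,
    yields a failure result with diagnostics — never a silent fallback.
    Warns post hoc if the trace is short (fewer than 10 points or spanning
    less than 2 / k_app).
    """
    t = np.asarray(trace.time_s, dtype=float)
    y = np.asarray(trace.signal, dtype=float)
    if t.size < 4:
        return ExponentialFit(
            np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            t.size, False, "too few points for a 3-parameter fit",
        )
    t0 = t - t[0]  # shift so amplitude refers to the first recorded point
    f_inf0, amp0, k0 = _initial_guess(t0, y)
    model = Model(_exp_model)
    rng = np.random.default_rng(12345)  # jitter source for restarts only
    last_msg = "did not converge"
    for attempt in range(4):
        jitter = 1.0 if attempt == 0 else float(rng.uniform(0.3, 3.0))
        params = model.make_params(
            f_inf=f_inf0,
            amplitude=amp0 if amp0 != 0 else 0.1 * (np.ptp(y) or 1.0),
            k_app={"value": k0 * jitter, "min": 1e-12},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(y, params, t=t0)
        if result.success and result.errorbars:
            resid_sd = float(np.std(result.residual, ddof=3))
            amp = result.params["amplitude"]
            if abs(amp.value) < 2.0 * resid_sd:
                return ExponentialFit(
                    float(result.params["f_inf"].value), float(amp.value),
                    float(result.params["k_app"].value),
                    np.nan, np.nan, np.nan, resid_sd, t.size, False,
                    "amplitude indistinguishable from noise",
                )
            k = result.params["k_app"]
            span = t0[-1]
            if t.size < 10 or span < 2.0 / max(k.value, 1e-300):
                warnings.warn(
                    f"trace has {t.size} points spanning {span:.3g} s, less "
                    f"than 2/k_app = {2.0 / k.value:.3g} s; rate poorly "
                    "constrained",
                    stacklevel=2,
                )
            return ExponentialFit(
                f_inf=float(result.params["f_inf"].value),
                amplitude=float(amp.value),
                k_app=float(k.value),
                se_f_inf=float(result.params["f_inf"].stderr),
                se_amplitude=float(amp.stderr),
                se_k_app=float(k.stderr),
                residual_sd=resid_sd,
                n_points=int(t.size),
                success=True,
            )
        last_msg = result.message if hasattr(result, "message") else last_msg
    return ExponentialFit(
        np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
        t.size, False, f"no convergence after restarts: {last_msg}",
    )


def linear_fit(
    x, y, se_y=None, weighting: str | None = None
) -> LinearFit:
    """Straight-line fit, weighted by 1/SE^2 when point errors are given.

    With known point errors the parameter uncertainty is propagated from
    those errors and inflated by the scale factor ``max(1, sqrt(chi2/dof))``
    — the usual convention when error bars are trusted but possible excess
    scatter should widen, never narrow, the quoted uncertainty.  (Pure
    residual-based scaling from 3-4 points is itself so noisy that it
    routinely understates the error.)  Falls back to OLS with
    residual-based errors when ``se_y`` is absent, contains zeros, or
    ``weighting='ols'`` is forced.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("a linear fit requires >= 3 points")
    X = sm.add_constant(x)
    use_wls = (
        weighting != "ols"
        and se_y is not None
        and np.all(np.isfinite(se_y))
        and np.all(np.asarray(se_y) > 0)
    )
    if use_wls:
        w = 1.0 / np.asarray(se_y, dtype=float) ** 2
        res = sm.WLS(y, X, weights=w).fit()
        # propagated (fixed-scale) covariance, times the PDG-style factor
        chi2_red = float(res.ssr) / max(res.df_resid, 1)
        inflate = max(1.0, np.sqrt(chi2_red))
        bse = res.bse / np.sqrt(res.scale) * inflate
        mode = "wls"
    else:
        res = sm.OLS(y, X).fit()
        bse = res.bse
        mode = "ols"
    return LinearFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        se_slope=float(bse[1]),
        se_intercept=float(bse[0]),
        n_points=int(x.size),
        weighting=mode,
    )
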