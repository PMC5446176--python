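"""Staged kinetic analysis: from fitted transients to rate constants.

The analysis mirrors standard stopped-flow practice.  Individual traces
are reduced to apparent rates with the one-exponential model; secondary
plots then yield the constants: the slope of mean k_app versus nucleotide
concentration gives the association constant, the mean chase rate gives
the spontaneous off-rate, and the initial linear slope of k_app versus
[EF-Ts] gives the effective stimulated-release constant.  GTPase quench
series are reduced to initial rates after pointwise background
subtraction, and protection decays to first-order half-lives.  Replicate
scatter (standard error of the mean) is the reported uncertainty wherever
replicates exist, matching how such experiments are usually summarized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .designs import (
    AssociationDesign,
    ChaseDesign,
    GtpaseDesign,
    ProtectionDesign,
    TsTitrationDesign,
)
from .fitting import ExponentialFit, LinearFit, fit_single_exponential, linear_fit
from .generate import (
    GtpaseSeries,
    generate_association_set,
    generate_chase_set,
    generate_gtpase_timecourse,
    generate_protection_decay,
    generate_ts_titration_set,
)
from .records import TimeCourseRecord
from .truth import GroundTruth

__all__ = [
    "RateEstimate",
    "ComparisonResult",
    "AnalysisError",
    "association_analysis",
    "chase_analysis",
    "exchange_relaxation_correction",
    "ts_titration_analysis",
    "gtpase_initial_rate",
    "gtpase_rate_from_replicates",
    "protection_halflife",
    "compare_conditions",
    "power_of_detection",
    "run_assay",
    "group_fits",
]


class AnalysisError(RuntimeError):
    """Raised when an analysis precondition fails (e.g. too few points)."""


@dataclass(frozen=True)
class RateEstimate:
    """A named rate constant (or half-life) with its uncertainty."""

    name: str
    value: float
    se: float
    units: str
    n: int
    condition: tuple = ()       # ((key, value), ...) experiment condition
    flags: tuple = ()

    def condition_dict(self) -> dict:
        return dict(self.condition)


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sided z comparison of two estimates of the same constant."""

    difference: float
    pooled_se: float
    z: float
    p_value: float
    alpha: float
    detected: bool

    @property
    def verdict(self) -> str:
        return "difference detected" if self.detected else "no detected difference"


# ---------------------------------------------------------------------------
# helpers

def group_fits(records: list[TimeCourseRecord], by: str) -> dict:
    """Fit every record and group the fits by a metadata key."""
    groups: dict = {}
    for rec in records:
        key = rec.meta.get(by)
        groups.setdefault(key, []).append(fit_single_exponential(rec))
    return dict(sorted(groups.items()))


def small_sample_se_factor(dof: int) -> float:
    """Student-t widening of a quoted SE estimated with few degrees of freedom.

    An SE estimated from n replicates is itself noisy; a +-2 SE interval
    built from it covers less than its nominal 95% (t tails).  Quoted SEs
    are therefore widened by ``t_{0.975,dof} / z_{0.975}`` so that +-2 SE
    keeps near-nominal coverage at any replicate count.
    """
    if dof < 1:
        return float("nan")
    return float(stats.t.ppf(0.975, dof) / stats.norm.ppf(0.975))


def _mean_sem(values: np.ndarray):
    """Mean and small-sample-adjusted standard error of the mean."""
    values = np.asarray(values, dtype=float)
    n = values.size
    mean = float(np.mean(values))
    if n > 1:
        sem = float(np.std(values, ddof=1) / math.sqrt(n))
        sem *= small_sample_se_factor(n - 1)
    else:
        sem = float("nan")
    return mean, sem, n


def _require_converged(fits, context: str):
    good = [f for f in fits if f.success]
    if not good:
        raise AnalysisError(f"{context}: no converged exponential fits")
    return good


# ---------------------------------------------------------------------------
# secondary analyses

#: declared precision of titration-point concentrations (pipetting CV);
#: propagated into secondary-plot fits by effective-variance weighting
TITRATION_CONC_CV = 0.02


def _secondary_plot_fit(x, y, sems, conc_cv: float) -> LinearFit:
    """Weighted line fit with concentration errors folded into each point.

    A titration point's concentration error moves its apparent rate by
    ``slope * x * cv``, which replicate error bars cannot see; the
    effective-variance method adds that term in quadrature to the
    replicate SEM and iterates the weights with the slope estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sems = np.asarray(sems, dtype=float)
    sems = np.where(np.isfinite(sems), sems, 0.0)
    lf = linear_fit(x, y, weighting="ols")
    if conc_cv <= 0 and np.all(sems > 0):
        return linear_fit(x, y, se_y=sems)
    for _ in range(2):
        sig = np.sqrt(sems**2 + (lf.slope * x * conc_cv) ** 2)
        if np.any(sig <= 0):
            return lf
        lf = linear_fit(x, y, se_y=sig)
    return lf


def association_analysis(
    fits_by_conc_uM: dict,
    nucleotide: str = "GDP",
    condition: tuple = (),
    tu_conc_uM: float | None = None,
):
    """Association constant from the secondary plot of k_app vs [ligand].

    ``fits_by_conc_uM`` maps ligand concentration (uM) to the replicate
    exponential fits at that concentration.  Replicates are averaged per
    concentration with the SE of the mean; the weighted linear fit's slope
    is the association constant (M^-1 s^-1) and its intercept estimates
    the dissociation rate (s^-1).

    When the EF-Tu concentration is known, concentrations below five-fold
    excess are excluded (provided at least three survive): there ligand
    depletion visibly bends the apparent rate off the secondary-plot line.
    Between five- and ten-fold excess the depletion shifts the apparent
    rate by a nearly concentration-independent offset — the closed-form
    relaxation rate is k_on*([L]-[Tu]) + k_off in the tight-binding limit —
    which moves the intercept but leaves the slope, the reported
    association constant, essentially unbiased.
    """
    if len(fits_by_conc_uM) < 3:
        raise AnalysisError("association analysis needs >= 3 concentrations")
    items = sorted(fits_by_conc_uM.items())
    flags = []
    if tu_conc_uM is not None:
        valid = [(c, f) for c, f in items if c >= 5.0 * tu_conc_uM]
        if len(valid) >= 3 and len(valid) < len(items):
            flags.append(
                f"pseudo-first-order selection: {len(valid)}/{len(items)} "
                "concentrations"
            )
            items = valid
    concs, means, sems = [], [], []
    for conc, fits in items:
        good = _require_converged(fits, f"association at {conc} uM")
        m, s, _ = _mean_sem([f.k_app for f in good])
        concs.append(conc * 1e-6)  # to molar
        means.append(m)
        sems.append(s)
    lf = _secondary_plot_fit(concs, means, sems, TITRATION_CONC_CV)
    name = "k1" if nucleotide == "GDP" else "k5"
    n_total = sum(len(v) for _, v in items)
    flags.append(lf.weighting)
    slope = RateEstimate(
        name=name, value=lf.slope, se=lf.se_slope, units="M^-1 s^-1",
        n=n_total, condition=condition, flags=tuple(flags),
    )
    intercept = RateEstimate(
        name=name + "_intercept", value=lf.intercept, se=lf.se_intercept,
        units="s^-1", n=n_total, condition=condition,
    )
    return slope, intercept


def exchange_relaxation_correction(meta: dict) -> float:
    """Rebinding correction for a chase fit, from record metadata.

    With a finite chase excess the observed decay relaxes toward an
    exchange equilibrium at rate k_off * (1 + B/F), where B is the bound
    nucleotide pool and F the total free pool; dividing the fitted rate by
    that factor recovers the elementary off-rate.  Returns 1.0 when the
    metadata does not carry the pool sizes.
    """
    bound = meta.get("tu_postmix_uM")
    labeled = meta.get("labeled_total_uM")
    chase = meta.get("chase_total_uM")
    if bound is None or labeled is None or chase is None:
        return 1.0
    free = labeled + chase - bound
    if free <= 0:
        return 1.0
    return 1.0 / (1.0 + bound / free)


def chase_analysis(
    fits: list,
    nucleotide: str = "GDP",
    condition: tuple = (),
    rebinding_correction: float = 1.0,
) -> RateEstimate:
    """Spontaneous dissociation rate: mean apparent chase rate +- SEM.

    ``rebinding_correction`` (see :func:`exchange_relaxation_correction`)
    rescales the observed exchange-relaxation rate to the elementary
    off-rate; it is a ~1% effect at the standard 10x chase excess.
    """
    good = _require_converged(fits, "chase analysis")
    mean, sem, n = _mean_sem([f.k_app for f in good])
    mean *= rebinding_correction
    sem *= rebinding_correction
    flags = () if n > 1 else ("single-replicate: SE undefined",)
    name = "k1r" if nucleotide == "GDP" else "k5r"
    return RateEstimate(
        name=name, value=mean, se=sem, units="s^-1", n=n,
        condition=condition, flags=flags,
    )


def _curvature_significant(x, y, sems, alpha: float) -> bool:
    """Quadratic-term significance test on a candidate point set."""
    X = np.column_stack([np.ones_like(x), x, x * x])
    if np.all(np.isfinite(sems)) and np.all(sems > 0):
        res = sm.WLS(y, X, weights=1.0 / sems**2).fit()
    else:
        res = sm.OLS(y, X).fit()
    p = res.pvalues[2]
    return bool(np.isfinite(p) and p < alpha)


def ts_titration_analysis(
    fits_by_ts_uM: dict,
    nucleotide: str = "GDP",
    condition: tuple = (),
    alpha: float = 0.05,
) -> RateEstimate:
    """Effective stimulated-release constant from the k_app vs [EF-Ts] slope.

    Points are taken in ascending [EF-Ts] while the running quadratic
    curvature test stays insignificant (minimum 4 points); the weighted
    linear fit over the retained, linear-regime points gives the combined
    constant ``k_on,Ts / (1 + k_off,Ts / k_release)`` in M^-1 s^-1.
    """
    if len(fits_by_ts_uM) < 4:
        raise AnalysisError("EF-Ts titration needs >= 4 concentrations")
    concs, means, sems = [], [], []
    for conc, fits in sorted(fits_by_ts_uM.items()):
        good = _require_converged(fits, f"titration at {conc} uM EF-Ts")
        m, s, _ = _mean_sem([f.k_app for f in good])
        concs.append(conc * 1e-6)
        means.append(m)
        sems.append(s)
    x = np.asarray(concs)
    y = np.asarray(means)
    se = np.asarray(sems)
    keep = len(x)
    for m in range(5, len(x) + 1):
        if _curvature_significant(x[:m], y[:m], se[:m], alpha):
            keep = m - 1
            break
    if keep < 4:
        raise AnalysisError(
            "fewer than 4 points survive linear-regime selection; "
            "lower the EF-Ts concentration range"
        )
    lf = _secondary_plot_fit(x[:keep], y[:keep], se[:keep], TITRATION_CONC_CV)
    name = "combined_gdp" if nucleotide == "GDP" else "combined_gtp"
    n_total = sum(len(v) for v in fits_by_ts_uM.values())
    flags = () if keep == len(x) else (f"linear regime: {keep}/{len(x)} points",)
    return RateEstimate(
        name=name, value=lf.slope, se=lf.se_slope, units="M^-1 s^-1",
        n=n_total, condition=condition, flags=flags,
    )


# ---------------------------------------------------------------------------
# GTPase and protection

def gtpase_initial_rate(
    series: TimeCourseRecord,
    background: TimeCourseRecord,
    condition: tuple = (),
) -> RateEstimate:
    """Initial-phase turnover rate after pointwise background subtraction.

    Retains quench points with at most 10% of the total GTP hydrolyzed
    (after subtraction) and fits a straight line through them; the slope is
    the multiple-turnover rate in uM/s.
    """
    if not np.allclose(series.time_s, background.time_s):
        raise AnalysisError("background series must share quench times")
    s0 = series.meta.get("gtp_total_uM")
    if s0 is None:
        raise AnalysisError("series metadata lacks gtp_total_uM")
    corrected = series.signal - background.signal
    initial = corrected <= 0.10 * s0
    if initial.sum() < 4:
        raise AnalysisError(
            f"only {int(initial.sum())} initial-phase points (< 4); "
            "add earlier quench times"
        )
    lf = linear_fit(series.time_s[initial], corrected[initial], weighting="ols")
    # first-order depletion correction: the line's slope reflects the rate
    # at the mean consumed fraction of the window, not at zero consumption
    f_mean = float(np.mean(series.signal[initial])) / s0
    corr = 1.0 / (1.0 - min(f_mean, 0.5))
    cond_name = series.meta.get("condition", "unknown")
    return RateEstimate(
        name=f"kGTPase_{cond_name}", value=lf.slope * corr,
        se=lf.se_slope * corr, units="uM/s", n=int(initial.sum()),
        condition=condition, flags=("depletion-corrected",),
    )


def gtpase_rate_from_replicates(
    suite: GtpaseSeries, condition: tuple = ()
) -> RateEstimate:
    """Turnover rate pooled over replicate quench series.

    All replicates' background-subtracted initial-phase points enter one
    regression, so the slope uncertainty rests on every quench point
    rather than on the scatter of only three per-replicate slopes (whose
    SEM is itself too uncertain to support a meaningful 2-sigma interval).
    """
    ts, ys, fracs = [], [], []
    s0 = None
    for rxn, bg in suite.pairs():
        if not np.allclose(rxn.time_s, bg.time_s):
            raise AnalysisError("background series must share quench times")
        s0 = rxn.meta.get("gtp_total_uM")
        if s0 is None:
            raise AnalysisError("series metadata lacks gtp_total_uM")
        corrected = rxn.signal - bg.signal
        initial = corrected <= 0.10 * s0
        ts.append(rxn.time_s[initial])
        ys.append(corrected[initial])
        fracs.append(rxn.signal[initial] / s0)
    t = np.concatenate(ts)
    y = np.concatenate(ys)
    if t.size < 4:
        raise AnalysisError("fewer than 4 pooled initial-phase points")
    lf = linear_fit(t, y, weighting="ols")
    # same first-order depletion correction as the per-replicate estimator
    f_mean = float(np.mean(np.concatenate(fracs)))
    corr = 1.0 / (1.0 - min(f_mean, 0.5))
    se_adj = small_sample_se_factor(t.size - 2)
    cond_name = suite.reaction[0].meta.get("condition", "unknown")
    return RateEstimate(
        name=f"kGTPase_{cond_name}", value=lf.slope * corr,
        se=lf.se_slope * corr * se_adj, units="uM/s", n=len(suite.reaction),
        condition=condition, flags=("pooled replicates", "depletion-corrected"),
    )


def protection_halflife(
    series: TimeCourseRecord, condition: tuple = ()
) -> RateEstimate:
    """First-order decay half-life of the intact aminoacyl fraction.

    Log-linear weighted fit of ln(intact) versus time — exact for
    multiplicative noise — with t1/2 = ln 2 / k and its SE by error
    propagation.  Requires >= 5 points with intact fraction in (0, 1].
    """
    t = series.time_s
    y = series.signal
    if t.size < 5:
        raise AnalysisError("protection fit needs >= 5 time points")
    if np.any(y <= 0) or np.any(y > 1.5):
        raise AnalysisError("intact fraction must lie in (0, 1] (up to noise)")
    X = sm.add_constant(t)
    res = sm.OLS(np.log(y), X).fit()
    k = -float(res.params[1])
    se_k = float(res.bse[1])
    if k <= 0:
        raise AnalysisError("fitted decay rate is not positive")
    t_half = math.log(2.0) / k
    se_t_half = math.log(2.0) / k**2 * se_k * small_sample_se_factor(t.size - 2)
    name = "t_half_protected" if series.meta.get("protected") else "t_half_free"
    return RateEstimate(
        name=name, value=t_half, se=se_t_half, units="min",
        n=int(t.size), condition=condition,
    )


# ---------------------------------------------------------------------------
# condition comparison and power

def compare_conditions(
    a: RateEstimate, b: RateEstimate, alpha: float = 0.05
) -> ComparisonResult:
    """Two-sided z-test on the difference of two independent estimates."""
    if a.name != b.name or a.units != b.units:
        raise ValueError(
            f"cannot compare {a.name} [{a.units}] with {b.name} [{b.units}]"
        )
    if not (np.isfinite(a.se) and np.isfinite(b.se)):
        raise ValueError("both estimates need finite standard errors")
    diff = a.value - b.value
    pooled = math.sqrt(a.se**2 + b.se**2)
    z = diff / pooled if pooled > 0 else math.inf * np.sign(diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return ComparisonResult(
        difference=diff, pooled_se=pooled, z=z, p_value=p,
        alpha=alpha, detected=bool(p < alpha),
    )


def run_assay(design, truth: GroundTruth, seed) -> RateEstimate:
    """Generate one synthetic assay under ``truth`` and analyze it.

    Dispatches on the design type: association titration, dissociation
    chase, EF-Ts titration, GTPase quench series, or protection decay.
    """
    cond = (("tet_uM", truth.tet_level_uM),)
    if isinstance(design, AssociationDesign):
        recs = generate_association_set(design, truth, seed)
        slope, _ = association_analysis(
            group_fits(recs, "ligand_conc_uM"), design.nucleotide, cond,
            tu_conc_uM=design.tu_conc_uM,
        )
        return slope
    if isinstance(design, TsTitrationDesign):
        recs = generate_ts_titration_set(design, truth, seed)
        return ts_titration_analysis(
            group_fits(recs, "ts_conc_uM"), design.nucleotide, cond
        )
    if isinstance(design, ChaseDesign):
        recs = generate_chase_set(design, truth, seed)
        fits = [fit_single_exponential(r) for r in recs]
        return chase_analysis(
            fits, design.nucleotide, cond,
            rebinding_correction=exchange_relaxation_correction(recs[0].meta),
        )
    if isinstance(design, GtpaseDesign):
        suite = generate_gtpase_timecourse(design, truth, seed)
        return gtpase_rate_from_replicates(suite, cond)
    if isinstance(design, ProtectionDesign):
        rec = generate_protection_decay(design, truth, seed)
        return protection_halflife(rec, cond)
    raise TypeError(f"unknown design type {type(design).__name__}")


#: power-analysis hook: which generating parameter an estimate's name maps to
_EFFECT_TARGET = {
    "k1": "k1", "k5": "k5", "k1r": "k1r", "k5r": "k5r",
    "combined_gdp": "k3", "combined_gtp": "k6",
    "t_half_free": "halflife_free", "t_half_protected": "halflife_protected",
}


def power_of_detection(
    constant: str,
    effect: float,
    design,
    truth: GroundTruth,
    n_sim: int = 200,
    seed=0,
    alpha: float = 0.05,
) -> float:
    """Monte-Carlo power to detect a multiplicative effect on one constant.

    Simulates ``n_sim`` experiment pairs — one arm under ``truth``, one
    under ``truth`` with ``constant`` scaled by ``effect`` — analyzes each
    arm, and returns the fraction of pairs in which
    :func:`compare_conditions` declares a difference at level ``alpha``.
    With ``effect = 1`` this estimates the false-detection rate, which
    should sit near ``alpha``.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for a stable power estimate")
    target = _EFFECT_TARGET.get(constant)
    if target is None and constant in dict(truth.gtpase_rates_uM_s):
        target = constant
    if target is None:
        raise KeyError(f"no effect hook for constant {constant!r}")
    truth_b = truth.with_effect(**{target: effect})
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_sim)
    hits = 0
    for i in range(n_sim):
        est_a = run_assay(design, truth, children[2 * i])
        est_b = run_assay(design, truth_b, children[2 * i + 1])
        if compare_conditions(est_a, est_b, alpha).detected:
            hits += 1
    return hits / n_sim
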