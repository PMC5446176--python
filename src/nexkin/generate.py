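"""Synthetic experiment suites generated from a declared ground truth.

Every generator is a pure function of ``(design, truth, seed)``: the
deterministic part (ODE trajectories, equilibration) is memoized per
(design, truth), and all stochasticity flows from a
``numpy.random.SeedSequence`` spawned from the seed, one child per trace.

Association and chase/titration traces are produced by integrating the
full exchange scheme and rendering the FRET observable through the
observation model.  GTPase quench series and protection decays use the
empirical closed forms the corresponding analyses assume: linear
multiple-turnover hydrolysis with single-exponential substrate depletion,
and first-order aminoacyl-ester decay.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import replace

import numpy as np

from .designs import (
    AssociationDesign,
    ChaseDesign,
    GtpaseDesign,
    ProtectionDesign,
    TsTitrationDesign,
)
from .observe import trajectory_to_signal
from .params import predicted_kapp
from .records import TimeCourseRecord
from .scheme import (
    IDX,
    assemble_scheme,
    equilibrium_state,
    simulate_trajectory,
    state_from_totals,
)
from .truth import GroundTruth

__all__ = [
    "generate_association_set",
    "generate_chase_set",
    "generate_ts_titration_set",
    "generate_gtpase_timecourse",
    "generate_protection_decay",
    "GtpaseSeries",
]

_TRAJ_CACHE: dict = {}


def _cached_trajectory(key, builder):
    if key not in _TRAJ_CACHE:
        _TRAJ_CACHE[key] = builder()
    return _TRAJ_CACHE[key]


def clear_cache() -> None:
    _TRAJ_CACHE.clear()


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _conc_error_scales(seed_seq, truth: GroundTruth, n_conc: int):
    """Per-titration-point concentration-error factors, shared by replicates.

    A mis-prepared titration point shifts that point's pseudo-first-order
    rate in proportion to its concentration error; the factor is drawn once
    per point (clipped at 3 sigma) and applied as a rate scale to every
    replicate trace of that point.
    """
    cv = truth.observation.conc_error_cv
    if cv <= 0:
        return np.ones(n_conc)
    rng = np.random.default_rng(seed_seq)
    return 1.0 + np.clip(rng.normal(0.0, cv, size=n_conc), -3 * cv, 3 * cv)


def _nuc_names(nucleotide: str, labeled: bool):
    return ("GDPm" if labeled else "GDP") if nucleotide == "GDP" else (
        "GTPm" if labeled else "GTP"
    )


def _on_off(truth: GroundTruth, nucleotide: str):
    r = truth.rates
    return (r.k1, r.k1r) if nucleotide == "GDP" else (r.k5, r.k5r)


def _combined(truth: GroundTruth, nucleotide: str) -> float:
    return (
        truth.rates.combined_gdp() if nucleotide == "GDP"
        else truth.rates.combined_gtp()
    )


# ---------------------------------------------------------------------------
# association titration

def _association_trajectory(design: AssociationDesign, truth: GroundTruth, conc_uM):
    kon, koff = _on_off(truth, design.nucleotide)
    # time to cover the transient even with ligand depletion slowing it down
    eff = kon * max(conc_uM - design.tu_conc_uM, 0.3 * conc_uM) * 1e-6 + koff
    t_end = 6.0 / eff

    def build():
        system = assemble_scheme(truth.rates)
        y0 = state_from_totals(
            Tu=design.tu_conc_uM * 1e-6,
            **{_nuc_names(design.nucleotide, True): conc_uM * 1e-6},
        )
        # margin past the recording window so rate jitter and titration
        # concentration error can be sampled off the simulated grid
        return simulate_trajectory(
            system, y0, 1.3 * t_end, n_points=int(1.3 * design.n_points)
        )

    key = ("assoc", truth.rates, design.nucleotide, design.tu_conc_uM,
           conc_uM, design.n_points)
    return _cached_trajectory(key, build), t_end


def generate_association_set(
    design: AssociationDesign, truth: GroundTruth, seed
) -> list[TimeCourseRecord]:
    """One trace per (ligand concentration, replicate).

    Logs a warning for concentrations below the 10x pseudo-first-order
    margin over EF-Tu; those points are still generated (the full ODE does
    not need the approximation) but their single-exponential fits report a
    depletion-shifted apparent rate.
    """
    for c in design.ligand_concs_uM:
        if c < 10.0 * design.tu_conc_uM:
            warnings.warn(
                f"[{design.nucleotide}] = {c} uM is below 10 x [EF-Tu] "
                f"({design.tu_conc_uM} uM); pseudo-first-order approximation "
                "is degraded at this point",
                stacklevel=2,
            )
    ss = _as_seedseq(seed)
    n_conc = len(design.ligand_concs_uM)
    children = ss.spawn(n_conc * design.replicates + 1)
    conc_scales = _conc_error_scales(children[-1], truth, n_conc)
    records = []
    i = 0
    for j, conc in enumerate(design.ligand_concs_uM):
        traj, t_end = _association_trajectory(design, truth, conc)
        for rep in range(design.replicates):
            rec = trajectory_to_signal(
                traj,
                truth.observation,
                tet_conc_uM=truth.tet_level_uM,
                seed=children[i],
                t_window=t_end,
                extra_rate_scale=conc_scales[j],
                meta={
                    "family": "association",
                    "nucleotide": design.nucleotide,
                    "ligand_conc_uM": conc,
                    "tu_conc_uM": design.tu_conc_uM,
                    "replicate": rep,
                },
            )
            records.append(rec)
            i += 1
    return records


# ---------------------------------------------------------------------------
# dissociation chase and EF-Ts titration

def _preformed_complex(truth: GroundTruth, nucleotide: str,
                       tu_syringe_uM: float, mant_syringe_uM: float):
    """Equilibrated labeled-complex syringe content (molar state vector)."""

    def build():
        system = assemble_scheme(truth.rates)
        y0 = state_from_totals(
            Tu=tu_syringe_uM * 1e-6,
            **{_nuc_names(nucleotide, True): mant_syringe_uM * 1e-6},
        )
        return equilibrium_state(system, y0)

    key = ("preform", truth.rates, nucleotide, tu_syringe_uM, mant_syringe_uM)
    return _cached_trajectory(key, build)


def _chase_trajectory(truth: GroundTruth, nucleotide: str, tu_syringe_uM,
                      mant_syringe_uM, chase_syringe_uM, ts_conc_uM,
                      n_points, t_end):
    def build():
        system = assemble_scheme(truth.rates)
        y = 0.5 * _preformed_complex(truth, nucleotide, tu_syringe_uM,
                                     mant_syringe_uM)
        y = y.copy()
        y[IDX[_nuc_names(nucleotide, False)]] += chase_syringe_uM * 0.5e-6
        y[IDX["Ts"]] += ts_conc_uM * 1e-6
        return simulate_trajectory(
            system, y, 1.3 * t_end, n_points=int(1.3 * n_points)
        )

    key = ("chase", truth.rates, nucleotide, tu_syringe_uM, mant_syringe_uM,
           chase_syringe_uM, ts_conc_uM, n_points, round(t_end, 9))
    return _cached_trajectory(key, build)


def generate_chase_set(
    design: ChaseDesign, truth: GroundTruth, seed
) -> list[TimeCourseRecord]:
    """Dissociation chase traces dominated by the labeled off-rate.

    The labeled complex is equilibrated at syringe concentrations, mixed
    1:1 with the unlabeled chase, and the full scheme is integrated; the
    observed decay of bound mant-nucleotide relaxes at the spontaneous
    dissociation rate (rebinding only shifts the equilibrium floor).
    """
    if design.chase_excess < 10.0:
        warnings.warn(
            f"chase excess {design.chase_excess:.2g}x is below 10x; labeled "
            "rebinding will bias the fitted rate below the true off-rate",
            stacklevel=2,
        )
    _, koff = _on_off(truth, design.nucleotide)
    t_end = 5.0 / koff
    traj = _chase_trajectory(
        truth, design.nucleotide, design.tu_syringe_uM, design.mant_syringe_uM,
        design.chase_syringe_uM, 0.0, design.n_points, t_end,
    )
    ss = _as_seedseq(seed)
    children = ss.spawn(design.replicates)
    return [
        trajectory_to_signal(
            traj,
            truth.observation,
            tet_conc_uM=truth.tet_level_uM,
            seed=children[rep],
            t_window=t_end,
            meta={
                "family": "chase",
                "nucleotide": design.nucleotide,
                "chase_excess": design.chase_excess,
                "tu_postmix_uM": design.tu_syringe_uM / 2.0,
                "labeled_total_uM": design.mant_syringe_uM / 2.0,
                "chase_total_uM": design.chase_syringe_uM / 2.0,
                "replicate": rep,
            },
        )
        for rep in range(design.replicates)
    ]


def generate_ts_titration_set(
    design: TsTitrationDesign, truth: GroundTruth, seed
) -> list[TimeCourseRecord]:
    """EF-Ts titration traces on the full scheme (chase + EF-Ts).

    The grid must stay in the linear regime: the predicted apparent rate at
    the top concentration may not exceed 20% of the nucleotide-release step
    of the ternary complex, where saturation of the flux partition bends
    the secondary plot.
    """
    kc = _combined(truth, design.nucleotide)
    _, koff = _on_off(truth, design.nucleotide)
    k_release = truth.rates.k4r if design.nucleotide == "GDP" else truth.rates.k7r
    top = max(design.ts_concs_uM)
    if top > 0 and predicted_kapp(kc, koff, top * 1e-6) > 0.2 * k_release:
        raise ValueError(
            f"top EF-Ts concentration {top} uM leaves the linear regime "
            f"(predicted k_app exceeds 20% of the nucleotide-release step "
            f"{k_release} s^-1)"
        )
    ss = _as_seedseq(seed)
    n_conc = len(design.ts_concs_uM)
    children = ss.spawn(n_conc * design.replicates + 1)
    conc_scales = _conc_error_scales(children[-1], truth, n_conc)
    records = []
    i = 0
    for j, ts in enumerate(design.ts_concs_uM):
        k_pred = max(predicted_kapp(kc, koff, ts * 1e-6), koff)
        t_end = 5.0 / k_pred
        traj = _chase_trajectory(
            truth, design.nucleotide, design.tu_syringe_uM,
            design.mant_syringe_uM, design.chase_syringe_uM, ts,
            design.n_points, t_end,
        )
        for rep in range(design.replicates):
            records.append(
                trajectory_to_signal(
                    traj,
                    truth.observation,
                    tet_conc_uM=truth.tet_level_uM,
                    seed=children[i],
                    t_window=t_end,
                    extra_rate_scale=conc_scales[j],
                    meta={
                        "family": "ts_titration",
                        "nucleotide": design.nucleotide,
                        "ts_conc_uM": ts,
                        "replicate": rep,
                    },
                )
            )
            i += 1
    return records


# ---------------------------------------------------------------------------
# GTPase quench series

class GtpaseSeries:
    """Paired reaction and no-enzyme background quench series per replicate."""

    def __init__(self, reaction: list, background: list):
        self.reaction = reaction
        self.background = background

    def pairs(self):
        return list(zip(self.reaction, self.background))


def _gtpase_clean(t: np.ndarray, total_rate_uM_s: float, s0_uM: float):
    """Hydrolyzed GTP (uM): initial-rate kinetics with exponential depletion."""
    if total_rate_uM_s == 0:
        return np.zeros_like(t)
    return s0_uM * (1.0 - np.exp(-total_rate_uM_s * t / s0_uM))


def generate_gtpase_timecourse(
    design: GtpaseDesign, truth: GroundTruth, seed
) -> GtpaseSeries:
    """Multiple-turnover quench series plus paired no-enzyme background.

    Quench times are placed by target substrate consumption under the
    condition's nominal total rate (enzymatic + background): the early
    points sit well inside the initial linear phase and the saturating
    points show depletion.  Gaussian counting noise has
    sd = max(noise_frac * signal, noise_floor_uM), both from the design.
    """
    v_cond = truth.gtpase_rate(design.condition) if design.tu_conc_uM > 0 else 0.0
    v_bg = truth.background_hydrolysis_uM_s
    v_tot = v_cond + v_bg
    s0 = design.gtp_total_uM
    turnover = s0 / v_tot if v_tot > 0 else 1.0
    times = np.array(
        [f * turnover for f in design.quench_fractions]
        + [f * turnover for f in design.saturating_fractions]
    )
    clean_rxn = _gtpase_clean(times, v_tot, s0)
    clean_bg = _gtpase_clean(times, v_bg, s0)
    ss = _as_seedseq(seed)
    children = ss.spawn(2 * design.replicates)
    reaction, background = [], []
    for rep in range(design.replicates):
        for clean, store, kind, child in (
            (clean_rxn, reaction, "reaction", children[2 * rep]),
            (clean_bg, background, "background", children[2 * rep + 1]),
        ):
            rng = np.random.default_rng(child)
            sd = np.maximum(design.noise_frac * clean, design.noise_floor_uM)
            noisy = clean + rng.normal(0.0, sd) if np.any(sd > 0) else clean.copy()
            store.append(
                TimeCourseRecord(
                    time_s=times,
                    signal=noisy,
                    meta={
                        "family": "gtpase",
                        "series": kind,
                        "condition": design.condition,
                        "gtp_total_uM": s0,
                        "replicate": rep,
                    },
                )
            )
    return GtpaseSeries(reaction, background)


# ---------------------------------------------------------------------------
# protection decay

def generate_protection_decay(
    design: ProtectionDesign, truth: GroundTruth, seed
) -> TimeCourseRecord:
    """First-order aminoacyl-ester decay, log-spaced sampling in minutes.

    Uses the protected half-life when EF-Tu is present in the design, the
    spontaneous one otherwise; noise is multiplicative log-normal with the
    design's coefficient of variation.
    """
    protected = design.tu_conc_uM > 0
    t_half = (
        truth.halflife_protected_min if protected else truth.halflife_free_min
    )
    if t_half <= 0:
        raise ValueError("half-life must be > 0")
    t = np.geomspace(0.1, design.span_halflives, design.n_times) * t_half
    clean = np.exp(-math.log(2.0) * t / t_half)
    rng = np.random.default_rng(_as_seedseq(seed))
    noisy = clean * np.exp(rng.normal(0.0, design.noise_cv, size=t.shape)) \
        if design.noise_cv > 0 else clean
    # record times in minutes; the analysis reports half-lives in minutes
    return TimeCourseRecord(
        time_s=t,
        signal=noisy,
        meta={
            "family": "protection",
            "time_unit": "min",
            "tu_conc_uM": design.tu_conc_uM,
            "trna_conc_uM": design.trna_conc_uM,
            "protected": protected,
        },
    )
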