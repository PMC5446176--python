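import dataclasses
import math

import numpy as np
import pytest

from nexkin.analyze import (
    AnalysisError,
    RateEstimate,
    association_analysis,
    chase_analysis,
    compare_conditions,
    exchange_relaxation_correction,
    group_fits,
    gtpase_initial_rate,
    gtpase_rate_from_replicates,
    power_of_detection,
    protection_halflife,
    run_assay,
    ts_titration_analysis,
)
from nexkin.designs import (
    AssociationDesign,
    ChaseDesign,
    GtpaseDesign,
    ProtectionDesign,
    TsTitrationDesign,
)
from nexkin.fitting import fit_single_exponential
from nexkin.generate import (
    generate_association_set,
    generate_chase_set,
    generate_gtpase_timecourse,
    generate_protection_decay,
)
from nexkin.records import TimeCourseRecord


def test_association_recovers_k1(truth):
    # single-seed sanity check at 3 SE; the 2 SE / 20-seed criterion lives
    # in the acceptance suite
    est = run_assay(AssociationDesign(), truth, 11)
    assert est.name == "k1"
    assert abs(est.value - 2.1e6) <= 3 * est.se


def test_association_recovers_k5(truth):
    est = run_assay(
        AssociationDesign(nucleotide="GTP", ligand_concs_uM=(1, 2, 4, 6, 8, 10)),
        truth, 11,
    )
    assert est.name == "k5"
    assert abs(est.value - 3.9e5) <= 3 * est.se


def test_association_intercept_zero_when_off_rate_zero(truth):
    """With no dissociation the secondary plot passes through the origin;
    probed at high ligand excess where depletion does not shift it."""
    rates = dataclasses.replace(truth.rates, k1r=0.0)
    t0 = dataclasses.replace(truth, rates=rates)
    design = AssociationDesign(tu_conc_uM=0.02, ligand_concs_uM=(1, 2, 3, 4, 5))
    recs = generate_association_set(design, t0, 5)
    _, intercept = association_analysis(
        group_fits(recs, "ligand_conc_uM"), "GDP", tu_conc_uM=0.02
    )
    assert abs(intercept.value) <= 2 * max(intercept.se, 1e-3)


def test_association_needs_three_concentrations():
    with pytest.raises(AnalysisError):
        association_analysis({1.0: [], 2.0: []})


def test_chase_estimates_both_off_rates(truth):
    for nuc, koff in (("GDP", 1.4e-3), ("GTP", 1.4e-2)):
        est = run_assay(ChaseDesign(nucleotide=nuc), truth, 21)
        assert abs(est.value - koff) <= 3 * est.se


def test_chase_single_replicate_is_flagged(quiet_truth):
    recs = generate_chase_set(ChaseDesign(replicates=1), quiet_truth, 0)
    est = chase_analysis([fit_single_exponential(r) for r in recs])
    assert est.n == 1
    assert math.isnan(est.se)
    assert any("single-replicate" in f for f in est.flags)


def test_exchange_relaxation_correction_magnitude():
    meta = {"tu_postmix_uM": 0.3, "labeled_total_uM": 3.0, "chase_total_uM": 30.0}
    corr = exchange_relaxation_correction(meta)
    assert corr == pytest.approx(1 / (1 + 0.3 / 32.7))
    assert exchange_relaxation_correction({}) == 1.0


def test_ts_titration_recovers_both_combined_constants(truth):
    for nuc, expected in (("GDP", 13.4e6), ("GTP", 21.9e6)):
        est = run_assay(TsTitrationDesign(nucleotide=nuc), truth, 31)
        assert abs(est.value - expected) <= 3 * est.se


def test_ts_titration_requires_four_surviving_points():
    with pytest.raises(AnalysisError):
        ts_titration_analysis({0.1: [], 0.2: [], 0.3: []})


def test_gtpase_recovery_and_trivial_zero(truth):
    suite = generate_gtpase_timecourse(GtpaseDesign(condition="intrinsic"), truth, 41)
    est = gtpase_rate_from_replicates(suite)
    assert abs(est.value - 7.67e-4) <= 3 * est.se
    # reaction identical to background -> rate zero within SE
    rec = suite.background[0]
    zero = gtpase_initial_rate(rec, rec)
    assert abs(zero.value) <= 2 * max(zero.se, 1e-9)


def test_gtpase_mismatched_quench_times_rejected(truth):
    suite = generate_gtpase_timecourse(GtpaseDesign(), truth, 1)
    shifted = TimeCourseRecord(
        suite.background[0].time_s + 1.0, suite.background[0].signal,
        suite.background[0].meta,
    )
    with pytest.raises(AnalysisError):
        gtpase_initial_rate(suite.reaction[0], shifted)


def test_protection_halflife_analytic_identity():
    # decay at k = ln 2 per minute has a one-minute half-life exactly
    t = np.linspace(0.2, 3.0, 8)
    rec = TimeCourseRecord(t, np.exp(-math.log(2.0) * t), {"protected": False})
    est = protection_halflife(rec)
    assert est.value == pytest.approx(1.0, rel=1e-9)


def test_protection_halflives_recovered(truth):
    free = run_assay(ProtectionDesign(tu_conc_uM=0.0), truth, 51)
    prot = run_assay(ProtectionDesign(), truth, 52)
    assert abs(free.value - 35.0) <= 3 * free.se
    assert abs(prot.value - 382.0) <= 3 * prot.se
    assert prot.value / free.value == pytest.approx(382 / 35, rel=0.1)


def test_protection_rejects_bad_fractions():
    t = np.linspace(1, 10, 6)
    with pytest.raises(AnalysisError):
        protection_halflife(TimeCourseRecord(t, np.full(6, 2.0)))
    with pytest.raises(AnalysisError):
        protection_halflife(TimeCourseRecord(t[:4], np.full(4, 0.5)))


def test_compare_conditions_examples():
    def est(v, se):
        return RateEstimate("k1", v, se, "M^-1 s^-1", 10)

    same = compare_conditions(est(2.1e6, 0.1e6), est(2.1e6, 0.1e6))
    assert same.z == 0 and not same.detected
    # the published pair of k1 values at 0 and 100 uM tetracycline
    table = compare_conditions(est(2.1e6, 0.1e6), est(2.1e6, 0.3e6))
    assert not table.detected
    far = compare_conditions(est(1.0, 0.1), est(2.0, 0.1))
    assert far.detected and abs(far.z) > 5

    with pytest.raises(ValueError):
        compare_conditions(est(1, 0.1), RateEstimate("k5", 1, 0.1, "M^-1 s^-1", 1))


def test_power_null_calibration_and_limits(truth):
    """At effect 1 the detection rate stays at or below the nominal alpha
    (quoted SEs are slightly conservative by design); a five-fold effect
    is always caught."""
    p_null = power_of_detection(
        "t_half_protected", 1.0, ProtectionDesign(), truth, n_sim=300, seed=5
    )
    sigma = math.sqrt(0.05 * 0.95 / 300)
    assert p_null <= 0.05 + 2 * sigma
    p_big = power_of_detection(
        "t_half_protected", 5.0, ProtectionDesign(), truth, n_sim=100, seed=5
    )
    assert p_big > 0.99


def test_power_monotone_in_effect_size(truth):
    """Power grows with the effect size (common random numbers)."""
    powers = [
        power_of_detection(
            "t_half_protected", e, ProtectionDesign(), truth, n_sim=150, seed=9
        )
        for e in (1.0, 1.05, 1.2, 2.0)
    ]
    for lo, hi in zip(powers, powers[1:]):
        assert hi >= lo - 0.02
    assert powers[-1] > powers[0]


def test_power_input_validation(truth):
    with pytest.raises(ValueError):
        power_of_detection("k1r", 2.0, ChaseDesign(), truth, n_sim=10, seed=0)
    with pytest.raises(KeyError):
        power_of_detection("nonsense", 2.0, ChaseDesign(), truth, n_sim=100, seed=0)


def test_run_assay_rejects_unknown_design(truth):
    with pytest.raises(TypeError):
        run_assay(object(), truth, 0)
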