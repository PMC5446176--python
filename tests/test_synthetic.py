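import dataclasses
import math

import numpy as np
import pytest

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
    generate_ts_titration_set,
)
from nexkin.params import predicted_kapp
from nexkin.truth import default_truth


def test_default_truth_mirrors_published_values(truth):
    assert truth.rates.k1 == 2.1e6
    assert truth.rates.k5 == 3.9e5
    assert truth.rates.k1r == 1.4e-3
    assert truth.rates.k5r == 1.4e-2
    assert truth.gtpase_rate("intrinsic") == 7.67e-4
    assert truth.gtpase_rate("70S") == 2.67e-3
    assert truth.halflife_free_min == 35.0
    assert truth.halflife_protected_min == 382.0


def test_tetracycline_level_never_touches_kinetics():
    assert default_truth(100.0).rates == default_truth(0.0).rates
    assert default_truth(100.0).halflife_protected_min == \
        default_truth(0.0).halflife_protected_min
    with pytest.raises(ValueError):
        default_truth(-1.0)


def test_effect_hook_scales_named_quantities(truth):
    t2 = truth.with_effect(k1r=5.0, intrinsic=2.0, halflife_free=0.5)
    assert t2.rates.k1r == pytest.approx(5 * truth.rates.k1r)
    assert t2.gtpase_rate("intrinsic") == pytest.approx(2 * 7.67e-4)
    assert t2.halflife_free_min == pytest.approx(17.5)


def test_association_set_counts_and_metadata(truth):
    design = AssociationDesign(replicates=10)
    recs = generate_association_set(design, truth, 0)
    assert len(recs) == 60
    assert {r.meta["ligand_conc_uM"] for r in recs} == set(design.ligand_concs_uM)


def test_generators_are_pure_functions_of_design_truth_seed(truth):
    design = ChaseDesign(replicates=2)
    a = generate_chase_set(design, truth, 7)
    b = generate_chase_set(design, truth, 7)
    c = generate_chase_set(design, truth, 8)
    assert all(x == y for x, y in zip(a, b))
    assert not np.array_equal(a[0].signal, c[0].signal)


def test_chase_noiseless_recovers_off_rate_within_2pct(quiet_truth):
    for nuc, koff in (("GDP", 1.4e-3), ("GTP", 1.4e-2)):
        rec = generate_chase_set(
            ChaseDesign(nucleotide=nuc, replicates=1), quiet_truth, 0
        )[0]
        fit = fit_single_exponential(rec)
        assert fit.success
        assert fit.k_app == pytest.approx(koff, rel=0.02)


def test_no_chase_degenerate_case_warns(quiet_truth):
    with pytest.warns(UserWarning, match="chase excess"):
        generate_chase_set(
            ChaseDesign(chase_syringe_uM=0.0, replicates=1), quiet_truth, 0
        )


def test_chase_rate_is_tetracycline_invariant():
    fits = []
    for tet in (0.0, 100.0):
        truth = default_truth(tet)
        rec = generate_chase_set(
            ChaseDesign(nucleotide="GTP", replicates=1), truth, 3
        )[0]
        fits.append(fit_single_exponential(rec))
    assert fits[0].k_app == pytest.approx(fits[1].k_app, rel=1e-9)


def test_ts_titration_zero_ts_reduces_to_spontaneous_chase(quiet_truth):
    design = TsTitrationDesign(ts_concs_uM=(0.0, 0.05, 0.1, 0.2), replicates=1)
    recs = generate_ts_titration_set(design, quiet_truth, 0)
    rec0 = [r for r in recs if r.meta["ts_conc_uM"] == 0.0][0]
    fit = fit_single_exponential(rec0)
    assert fit.k_app == pytest.approx(quiet_truth.rates.k1r, rel=0.02)


def test_ts_titration_counts(truth):
    design = TsTitrationDesign(
        ts_concs_uM=(0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4),
        replicates=11,
    )
    recs = generate_ts_titration_set(design, truth, 0)
    assert len(recs) == 88


def test_ts_titration_rejects_grid_outside_linear_regime(truth):
    # top concentration pushing k_app past 20% of the release step
    with pytest.raises(ValueError, match="linear regime"):
        generate_ts_titration_set(
            TsTitrationDesign(ts_concs_uM=(5.0, 10.0, 20.0, 40.0)), truth, 0
        )


def test_gtpase_zero_enzyme_equals_background(truth):
    design = GtpaseDesign(
        condition="intrinsic", tu_conc_uM=0.0, replicates=1,
        noise_floor_uM=0.0, noise_frac=0.0,
    )
    suite = generate_gtpase_timecourse(design, truth, 0)
    assert np.allclose(suite.reaction[0].signal, suite.background[0].signal)


def test_gtpase_noiseless_initial_slope_is_total_rate(truth):
    design = GtpaseDesign(
        condition="intrinsic", replicates=1, noise_floor_uM=0.0, noise_frac=0.0
    )
    suite = generate_gtpase_timecourse(design, truth, 0)
    rxn, bg = suite.reaction[0], suite.background[0]
    corrected = rxn.signal - bg.signal
    early = rxn.time_s <= rxn.time_s[1]
    slope = corrected[1] / rxn.time_s[1]
    v = truth.gtpase_rate("intrinsic")
    assert slope == pytest.approx(v, rel=0.02)


def test_gtpase_saturates_at_total_substrate(truth):
    design = GtpaseDesign(
        condition="70S", replicates=1, saturating_fractions=(20.0,),
        noise_floor_uM=0.0, noise_frac=0.0,
    )
    suite = generate_gtpase_timecourse(design, truth, 0)
    assert suite.reaction[0].signal[-1] == pytest.approx(20.0, rel=1e-6)


def test_protection_noiseless_decay_and_halflife(quiet_truth):
    design = ProtectionDesign(tu_conc_uM=0.0, noise_cv=0.0)
    rec = generate_protection_decay(design, quiet_truth, 0)
    t_half = quiet_truth.halflife_free_min
    assert np.allclose(rec.signal, np.exp(-math.log(2) * rec.time_s / t_half))
    # noiseless log-linear fit returns the generating half-life exactly
    from nexkin.analyze import protection_halflife
    est = protection_halflife(rec)
    assert est.value == pytest.approx(t_half, rel=1e-9)


def test_protection_ratio_of_default_halflives(truth):
    assert truth.halflife_protected_min / truth.halflife_free_min == \
        pytest.approx(382 / 35, rel=1e-12)


def test_syringe_convention_halves_concentrations():
    d = AssociationDesign.from_syringe(
        tu_conc_uM=0.6, ligand_concs_uM=(1.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    )
    assert d.tu_conc_uM == 0.3
    assert d.ligand_concs_uM == (0.5, 1.0, 2.0, 3.0, 4.0, 5.0)


def test_design_validation():
    with pytest.raises(ValueError):
        AssociationDesign(nucleotide="ATP")
    with pytest.raises(ValueError):
        ChaseDesign(replicates=0)
    with pytest.raises(ValueError):
        GtpaseDesign(quench_fractions=(0.05, 0.2, 0.01, 0.02))
    with pytest.raises(ValueError):
        ProtectionDesign(n_times=3)
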