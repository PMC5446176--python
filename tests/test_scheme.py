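import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nexkin.params import RateParameterSet, predicted_kapp
from nexkin.scheme import (
    IDX,
    SPECIES,
    assemble_scheme,
    conserved_totals,
    equilibrium_state,
    simulate_trajectory,
    state_from_totals,
)
from nexkin.truth import default_truth


def _zero_rates(**overrides):
    kw = {k: 0.0 for k in default_truth(0.0).rates.as_dict()}
    kw.update(overrides)
    return RateParameterSet(**kw)


def test_scheme_structure_species_and_reaction_counts(truth):
    system = assemble_scheme(truth.rates, include_direct_ts_path=True)
    assert len(SPECIES) == 15
    # six nucleotide-coupled reversible reactions per label pool + direct path
    assert len(system.reactions) == 13
    assert len(assemble_scheme(truth.rates, include_direct_ts_path=False).reactions) == 12


def test_all_zero_rates_give_constant_trajectory():
    system = assemble_scheme(_zero_rates())
    y0 = state_from_totals(Tu=1e-6, GDPm=2e-6, Ts=5e-7)
    traj = simulate_trajectory(system, y0, 10.0, n_points=20)
    assert np.allclose(traj.concentrations, y0, atol=1e-15)


def test_absent_reverse_step_freezes_ternary_complex():
    # only k3 active with k3r = 0: a preformed Tu.GDP.Ts complex never reverts
    system = assemble_scheme(_zero_rates(k3=1e7))
    y0 = np.zeros(len(SPECIES))
    y0[IDX["Tu.GDP.Ts"]] = 1e-6
    traj = simulate_trajectory(system, y0, 100.0, n_points=10)
    assert np.allclose(traj.species("Tu.GDP.Ts"), 1e-6, rtol=1e-9)


def test_two_species_binding_matches_closed_form(truth):
    """Reversible bimolecular binding against the exact rational-exponential
    solution, at concentrations where ligand depletion matters."""
    r = truth.rates
    system = assemble_scheme(_zero_rates(k1=r.k1, k1r=r.k1r))
    tu, lig = 0.3e-6, 3e-6
    y0 = state_from_totals(Tu=tu, GDPm=lig)
    traj = simulate_trajectory(system, y0, 10.0, n_points=200)
    # roots of k1*c^2 - (k1(L+T)+k1r)c + k1*L*T = 0
    b = r.k1 * (lig + tu) + r.k1r
    disc = np.sqrt(b**2 - 4 * r.k1**2 * lig * tu)
    c1, c2 = (b - disc) / (2 * r.k1), (b + disc) / (2 * r.k1)
    lam = r.k1 * (c2 - c1)
    t = traj.times
    expected = c1 * c2 * (1 - np.exp(-lam * t)) / (c2 - c1 * np.exp(-lam * t))
    assert np.allclose(traj.species("Tu.GDPm"), expected, rtol=1e-3)


def test_pseudo_first_order_rate_at_high_excess(truth):
    """With [L] >> [Tu] the transient is single-exponential at kon*L + koff."""
    from nexkin.fitting import fit_single_exponential
    from nexkin.records import TimeCourseRecord

    r = truth.rates
    system = assemble_scheme(_zero_rates(k1=r.k1, k1r=r.k1r))
    lig = 30e-6  # 100 x EF-Tu
    y0 = state_from_totals(Tu=0.3e-6, GDPm=lig)
    k_pred = predicted_kapp(r.k1, r.k1r, lig)
    traj = simulate_trajectory(system, y0, 5.0 / k_pred, n_points=300)
    fit = fit_single_exponential(
        TimeCourseRecord(traj.times[1:], traj.species("Tu.GDPm")[1:])
    )
    assert fit.success
    assert fit.k_app == pytest.approx(k_pred, rel=0.01)


def test_long_time_limit_reaches_equilibrium_state(truth):
    system = assemble_scheme(truth.rates)
    y0 = state_from_totals(Tu=0.5e-6, GDPm=2e-6, GTP=1e-6, Ts=0.3e-6)
    eq = equilibrium_state(system, y0)
    slowest = min(truth.rates.k1r, truth.rates.k2r)
    traj = simulate_trajectory(system, y0, 20.0 / slowest, n_points=5)
    final = traj.final_state()
    scale = max(y0.max(), 1e-12)
    assert np.all(np.abs(final - eq) <= 5e-3 * np.maximum(eq, 1e-3 * scale))


def test_equilibrium_matches_quadratic_binding_isotherm(truth):
    r = truth.rates
    system = assemble_scheme(_zero_rates(k1=r.k1, k1r=r.k1r))
    tu, lig = 1e-6, 1e-6
    eq = equilibrium_state(system, state_from_totals(Tu=tu, GDPm=lig))
    kd = r.k1r / r.k1
    s = tu + lig + kd
    expected = (s - np.sqrt(s**2 - 4 * tu * lig)) / 2
    assert eq[IDX["Tu.GDPm"]] == pytest.approx(expected, rel=1e-6)


def test_equilibrium_zero_ts_leaves_ts_species_empty(truth):
    system = assemble_scheme(truth.rates)
    eq = equilibrium_state(system, state_from_totals(Tu=1e-6, GDP=1e-6))
    for name in ("Ts", "Tu.Ts", "Tu.GDP.Ts", "Tu.GTP.Ts"):
        assert eq[IDX[name]] == pytest.approx(0.0, abs=1e-15)


def test_equilibrium_symmetric_nucleotides_partition_equally():
    base = default_truth(0.0).rates
    sym = _zero_rates(k1=base.k1, k1r=base.k1r, k5=base.k1, k5r=base.k1r)
    system = assemble_scheme(sym)
    eq = equilibrium_state(
        system, state_from_totals(Tu=1e-6, GDPm=2e-6, GTPm=2e-6)
    )
    assert eq[IDX["Tu.GDPm"]] == pytest.approx(eq[IDX["Tu.GTPm"]], rel=1e-6)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    scale=st.floats(0.2, 5.0),
    tu=st.floats(0.05, 2.0),
    ts=st.floats(0.01, 1.0),
    gdp=st.floats(0.01, 5.0),
    gtp=st.floats(0.01, 5.0),
)
def test_conservation_of_all_moieties(scale, tu, ts, gdp, gtp):
    """EF-Tu, EF-Ts and each nucleotide pool are conserved to 1e-9 relative."""
    rates = default_truth(0.0).rates.scaled(
        **{k: scale for k in ("k1", "k1r", "k5", "k5r", "k3", "k6")}
    )
    system = assemble_scheme(rates)
    y0 = state_from_totals(
        Tu=tu * 1e-6, Ts=ts * 1e-6, GDPm=gdp * 1e-6, GTP=gtp * 1e-6
    )
    traj = simulate_trajectory(system, y0, 5.0, n_points=30)
    t0 = conserved_totals(y0)
    for row in traj.concentrations:
        tt = conserved_totals(row)
        for key, ref in t0.items():
            if ref > 0:
                assert abs(tt[key] - ref) <= 1e-9 * ref


def test_label_swap_permutes_but_does_not_change_kinetics(truth):
    """The mant label is kinetically silent: exchanging labeled and
    unlabeled pools in the initial state permutes the trajectory."""
    system = assemble_scheme(truth.rates)
    y0 = state_from_totals(Tu=0.3e-6, GDPm=1e-6, GDP=2e-6, Ts=0.1e-6)
    swapped = y0.copy()
    pairs = [
        ("GDPm", "GDP"), ("GTPm", "GTP"), ("Tu.GDPm", "Tu.GDP"),
        ("Tu.GTPm", "Tu.GTP"), ("Tu.GDPm.Ts", "Tu.GDP.Ts"),
        ("Tu.GTPm.Ts", "Tu.GTP.Ts"),
    ]
    for a, b in pairs:
        swapped[IDX[a]], swapped[IDX[b]] = y0[IDX[b]], y0[IDX[a]]
    t1 = simulate_trajectory(system, y0, 5.0, n_points=50, rtol=1e-10, atol=1e-16)
    t2 = simulate_trajectory(system, swapped, 5.0, n_points=50, rtol=1e-10, atol=1e-16)
    for a, b in pairs:
        assert np.allclose(t1.species(a), t2.species(b), rtol=1e-5, atol=1e-14)
        assert np.allclose(t1.species(b), t2.species(a), rtol=1e-5, atol=1e-14)


def test_flux_partition_identity_low_ts_slope(quiet_truth):
    """The ODE-derived initial slope of chase k_app versus [EF-Ts] matches
    the analytic flux-partitioned constant within 5% — the module's
    hardest correctness check."""
    from nexkin.fitting import fit_single_exponential
    from nexkin.generate import _chase_trajectory
    from nexkin.records import TimeCourseRecord

    kc = quiet_truth.rates.combined_gdp()
    koff = quiet_truth.rates.k1r
    ks, ts_list = [], (0.02, 0.04, 0.06)
    for ts in ts_list:
        k_pred = predicted_kapp(kc, koff, ts * 1e-6)
        traj = _chase_trajectory(
            quiet_truth, "GDP", 0.3, 3.0, 60.0, ts, 300, 5.0 / k_pred
        )
        keep = traj.times <= 5.0 / k_pred
        fit = fit_single_exponential(
            TimeCourseRecord(traj.times[keep][1:], traj.mant_bound()[keep][1:])
        )
        assert fit.success
        ks.append(fit.k_app)
    slope = np.polyfit(np.array(ts_list) * 1e-6, ks, 1)[0]
    assert slope == pytest.approx(kc, rel=0.05)


def test_simulation_input_validation(truth):
    system = assemble_scheme(truth.rates)
    with pytest.raises(ValueError):
        simulate_trajectory(system, -np.ones(len(SPECIES)) * 1e-9, 1.0)
    with pytest.raises(ValueError):
        simulate_trajectory(system, np.zeros(len(SPECIES)), -1.0)
    with pytest.raises(KeyError):
        state_from_totals(NotASpecies=1e-6)
    with pytest.raises(ValueError):
        state_from_totals(Tu=-1e-6)
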