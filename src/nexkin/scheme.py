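"""Mass-action model of the EF-Tu / EF-Ts nucleotide-exchange scheme.

The scheme is realized over fifteen species.  Each nucleotide exists in two
chemically identical pools, a fluorescent (mant-labeled, suffix ``m``) and
an unlabeled one; the label is assumed kinetically silent, so every
reaction involving a nucleotide appears once per pool with the same rate
constants.  Internal concentration units are molar, time is seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .params import RateParameterSet

__all__ = [
    "SPECIES",
    "ReactionSystem",
    "Trajectory",
    "IntegrationError",
    "assemble_scheme",
    "simulate_trajectory",
    "equilibrium_state",
    "state_from_totals",
    "conserved_totals",
    "mant_bound",
]

#: canonical species order; ``m`` marks the mant-labeled nucleotide pool
SPECIES = (
    "Tu",
    "Tu.GDPm",
    "Tu.GDP",
    "Tu.GTPm",
    "Tu.GTP",
    "Tu.Ts",
    "Tu.GDPm.Ts",
    "Tu.GDP.Ts",
    "Tu.GTPm.Ts",
    "Tu.GTP.Ts",
    "GDPm",
    "GDP",
    "GTPm",
    "GTP",
    "Ts",
)

IDX = {name: i for i, name in enumerate(SPECIES)}

#: conserved moieties -> species carrying one copy each
CONSERVED = {
    "Tu": [
        "Tu", "Tu.GDPm", "Tu.GDP", "Tu.GTPm", "Tu.GTP",
        "Tu.Ts", "Tu.GDPm.Ts", "Tu.GDP.Ts", "Tu.GTPm.Ts", "Tu.GTP.Ts",
    ],
    "Ts": ["Ts", "Tu.Ts", "Tu.GDPm.Ts", "Tu.GDP.Ts", "Tu.GTPm.Ts", "Tu.GTP.Ts"],
    "GDPm": ["GDPm", "Tu.GDPm", "Tu.GDPm.Ts"],
    "GDP": ["GDP", "Tu.GDP", "Tu.GDP.Ts"],
    "GTPm": ["GTPm", "Tu.GTPm", "Tu.GTPm.Ts"],
    "GTP": ["GTP", "Tu.GTP", "Tu.GTP.Ts"],
}

#: species summed into the FRET observable (mant-nucleotide bound to EF-Tu)
MANT_BOUND = ("Tu.GDPm", "Tu.GDPm.Ts", "Tu.GTPm", "Tu.GTPm.Ts")


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails; carries the last accepted time."""

    def __init__(self, message: str, last_t: float):
        super().__init__(f"{message} (last accepted t = {last_t:.6g} s)")
        self.last_t = last_t


@dataclass(frozen=True)
class ReactionSystem:
    """Reversible mass-action reactions over the fixed species set.

    ``reactions`` holds tuples ``(reactant_indices, product_indices, kf, kr)``
    with elementary (one or two reactant) stoichiometry.
    """

    params: RateParameterSet
    include_direct_ts_path: bool
    reactions: tuple
    stoich: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def n_species(self) -> int:
        return len(SPECIES)

    def rates(self, y: np.ndarray) -> np.ndarray:
        """Net rate of each reversible reaction at state ``y`` (M/s)."""
        v = np.empty(len(self.reactions))
        for j, (ri, pi, kf, kr) in enumerate(self.reactions):
            fwd = kf
            for i in ri:
                fwd *= y[i]
            rev = kr
            for i in pi:
                rev *= y[i]
            v[j] = fwd - rev
        return v

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.stoich @ self.rates(y)


@dataclass(frozen=True)
class Trajectory:
    """Species concentrations on a time grid, with integrator diagnostics."""

    times: np.ndarray          # seconds, starting at 0, strictly increasing
    concentrations: np.ndarray  # shape (n_times, n_species), molar
    system: ReactionSystem

    def species(self, name: str) -> np.ndarray:
        return self.concentrations[:, IDX[name]]

    def mant_bound(self) -> np.ndarray:
        """Total EF-Tu-bound mant-nucleotide (M), the FRET-visible pool."""
        cols = [IDX[s] for s in MANT_BOUND]
        return self.concentrations[:, cols].sum(axis=1)

    def final_state(self) -> np.ndarray:
        return self.concentrations[-1].copy()


def _reaction_list(p: RateParameterSet, include_direct: bool):
    """Build the reversible reactions, duplicating nucleotide steps per pool."""
    rxns = []

    def add(reactants, products, kf, kr):
        if kf == 0.0 and kr == 0.0:
            return  # absent reaction
        rxns.append(
            (tuple(IDX[s] for s in reactants), tuple(IDX[s] for s in products), kf, kr)
        )

    for tag in ("m", ""):  # labeled, unlabeled nucleotide pools
        gdp, gtp = "GDP" + tag, "GTP" + tag
        add(("Tu", gdp), (f"Tu.{gdp}",), p.k1, p.k1r)
        add((f"Tu.{gdp}", "Ts"), (f"Tu.{gdp}.Ts",), p.k3, p.k3r)
        add(("Tu.Ts", gdp), (f"Tu.{gdp}.Ts",), p.k4, p.k4r)
        add(("Tu", gtp), (f"Tu.{gtp}",), p.k5, p.k5r)
        add((f"Tu.{gtp}", "Ts"), (f"Tu.{gtp}.Ts",), p.k6, p.k6r)
        add(("Tu.Ts", gtp), (f"Tu.{gtp}.Ts",), p.k7, p.k7r)
    if include_direct:
        add(("Tu", "Ts"), ("Tu.Ts",), p.k2, p.k2r)
    return tuple(rxns)


def assemble_scheme(
    params: RateParameterSet, include_direct_ts_path: bool = True
) -> ReactionSystem:
    """Build the reaction system for a parameter set.

    When ``include_direct_ts_path`` is false the direct ``Tu + Ts <-> Tu.Ts``
    binding step (k2/k2r) is omitted and EF-Ts reaches the free factor only
    through the nucleotide-bound intermediates; the binding graph is then a
    tree and detailed balance holds for any parameter values.
    """
    rxns = _reaction_list(params, include_direct_ts_path)
    stoich = np.zeros((len(SPECIES), len(rxns)))
    for j, (ri, pi, _, _) in enumerate(rxns):
        for i in ri:
            stoich[i, j] -= 1.0
        for i in pi:
            stoich[i, j] += 1.0
    return ReactionSystem(
        params=params,
        include_direct_ts_path=include_direct_ts_path,
        reactions=rxns,
        stoich=stoich,
    )


def state_from_totals(**conc: float) -> np.ndarray:
    """Initial state vector (molar) from named species concentrations."""
    y0 = np.zeros(len(SPECIES))
    for name, c in conc.items():
        if name not in IDX:
            raise KeyError(f"unknown species {name!r}")
        if c < 0:
            raise ValueError(f"negative concentration for {name}: {c}")
        y0[IDX[name]] = c
    return y0


def conserved_totals(y: np.ndarray) -> dict:
    """Totals of the conserved moieties (EF-Tu, EF-Ts, each nucleotide pool)."""
    return {k: float(sum(y[IDX[s]] for s in members)) for k, members in CONSERVED.items()}


def simulate_trajectory(
    system: ReactionSystem,
    initial: np.ndarray,
    t_end: float,
    n_points: int = 400,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the scheme from ``initial`` over ``[0, t_end]``.

    The default grid is ``n_points`` evenly spaced samples; pass ``t_eval``
    for custom (e.g. log-spaced) sampling.  Tolerances default to
    rtol=1e-8, atol=1e-12 M — the nucleotide-release steps make the system
    moderately stiff when EF-Ts is present, which LSODA handles by
    switching to BDF.
    """
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (len(SPECIES),):
        raise ValueError(f"initial state must have shape ({len(SPECIES)},)")
    if np.any(initial < 0):
        raise ValueError("initial concentrations must be >= 0")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        system.rhs,
        (0.0, float(t_end)),
        initial,
        t_eval=t_eval,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last_t = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"integrator failed: {sol.message}", last_t)
    conc = np.clip(sol.y.T, 0.0, None)  # clip solver noise at -atol scale
    return Trajectory(times=sol.t.copy(), concentrations=conc, system=system)


def equilibrium_state(
    system: ReactionSystem,
    initial: np.ndarray,
    rtol: float = 1e-10,
) -> np.ndarray:
    """Long-time steady state reachable from ``initial``.

    Integrates with geometrically increasing horizons until the state stops
    moving, then polishes with a bounded least-squares solve of
    ``dy/dt = 0`` subject to the conserved totals of the initial state.
    For this (tree-structured, when the direct EF-Ts path is absent)
    binding scheme the fixed point satisfies detailed balance.
    """
    initial = np.asarray(initial, dtype=float)
    totals0 = conserved_totals(initial)
    scale = max(initial.max(), 1e-12)

    # pick a horizon from the slowest nonzero unimolecular rate
    rates = []
    for (_, _, kf, kr) in system.reactions:
        for k in (kf, kr):
            if 0 < k < 1e4:  # unimolecular magnitudes
                rates.append(k)
    slow = min(rates) if rates else 1.0
    t_hor = 10.0 / slow
    y = initial
    for _ in range(8):
        traj = simulate_trajectory(
            system, y, t_hor, n_points=2, rtol=1e-10, atol=1e-14
        )
        y_new = traj.final_state()
        drift = np.max(np.abs(y_new - y)) / scale
        y = y_new
        if drift < rtol:
            break
        t_hor *= 4.0

    # polish: dy/dt = 0 plus conservation pinning
    members = {k: [IDX[s] for s in v] for k, v in CONSERVED.items()}

    def resid(x):
        r_kin = system.rhs(0.0, x) / max(slow * scale, 1e-30)
        r_con = [
            (sum(x[i] for i in idxs) - totals0[k]) / scale
            for k, idxs in members.items()
        ]
        return np.concatenate([r_kin, r_con])

    sol = least_squares(resid, y, bounds=(0.0, np.inf), xtol=1e-15, ftol=1e-15,
                        gtol=1e-15)
    # keep the polish only if it actually reduced the flux residual
    best = min(
        (np.clip(sol.x, 0.0, None), y),
        key=lambda x: float(np.linalg.norm(system.rhs(0.0, x))),
    )
    res_norm = float(np.linalg.norm(system.rhs(0.0, best)))
    if res_norm > slow * scale * 1e-3:
        raise RuntimeError(
            f"equilibrium solve did not converge (residual norm {res_norm:.3g} M/s)"
        )
    return best


def mant_bound(y: np.ndarray) -> float:
    """EF-Tu-bound mant-nucleotide (M) in a single state vector."""
    return float(sum(y[IDX[s]] for s in MANT_BOUND))
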