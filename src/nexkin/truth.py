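"""Declared ground truth for synthetic experiment suites.

The default truth carries the published kinetics of E. coli EF-Tu
nucleotide exchange under physiological buffer conditions: spontaneous
association/dissociation constants for GDP and GTP, effective
EF-Ts-stimulated release constants of 13.4e6 (GDP) and 21.9e6 (GTP)
M^-1 s^-1, multiple-turnover GTPase rates for the intrinsic, EF-Ts and
ribosome-stimulated conditions, and aminoacyl-ester decay half-lives with
and without EF-Tu protection.

Only the *combinations* k3/(1+k3r/k4r) and k6/(1+k6r/k7r) are identifiable
from an EF-Ts titration, so the individual ternary-complex constants are
package constants with order-one partition ratios, chosen so that EF-Ts
cycles catalytically — fast enough through the ternary complexes and the
EF-Tu.Ts intermediate that sub-stoichiometric EF-Ts is not sequestered on
the time scale of observed exchange.  The nucleotide-binding constants of
the EF-Tu.Ts complex (k4, k7) follow from detailed balance around the
exchange cycles given an EF-Tu/EF-Ts affinity of 30 nM.

Tetracycline is deliberately NOT a kinetic species: the default truth is
identical at every tetracycline level, and the drug enters only as an
additive autofluorescence background in the observation model.  This
encodes the null result the pipeline is built to interrogate; the
``effect`` argument provides the hook to break it for power analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .observe import ObservationParams
from .params import RateParameterSet

__all__ = ["GroundTruth", "default_truth", "GTPASE_CONDITIONS"]

# effective stimulated-release constants (M^-1 s^-1)
_COMBINED_GDP = 13.4e6
_COMBINED_GTP = 21.9e6

# package constants for the ternary-complex steps (s^-1).  The release
# steps are fast so that EF-Ts cycles catalytically: sub-stoichiometric
# EF-Ts must not be sequestered in intermediates on the time scale of the
# observed exchange, which is what the linear titration analysis assumes.
_K3R = 2000.0  # EF-Ts release from Tu.GDP.Ts
_K4R = 2000.0  # GDP release from Tu.GDP.Ts
_K6R = 1500.0  # EF-Ts release from Tu.GTP.Ts
_K7R = 4500.0  # GTP release from Tu.GTP.Ts (release-committed partition)
_K2 = 1.0e7    # EF-Ts association to free EF-Tu (M^-1 s^-1)
_KD_TU_TS = 3.0e-8  # EF-Tu/EF-Ts dissociation constant (M)

#: GTPase assay conditions -> default multiple-turnover rate (uM/s)
GTPASE_CONDITIONS = {
    "intrinsic": 7.67e-4,
    "EF-Ts_0.02uM": 5.33e-4,
    "EF-Ts_0.2uM": 5.33e-4,
    "70S": 2.67e-3,
    "50S": 1.0e-3,
}

#: no-enzyme background hydrolysis rate (uM/s); not separately published,
#: chosen small relative to the slowest enzymatic condition
BACKGROUND_HYDROLYSIS = 1.0e-4


def _default_rates() -> RateParameterSet:
    k1, k1r = 2.1e6, 1.4e-3
    k5, k5r = 3.9e5, 1.4e-2
    # combined = k_on/(1 + k_off/k_release); with k3r == k4r the on-constant
    # is exactly twice the effective constant
    k3 = _COMBINED_GDP * (1.0 + _K3R / _K4R)
    k6 = _COMBINED_GTP * (1.0 + _K6R / _K7R)
    K2 = 1.0 / _KD_TU_TS
    k2r = _K2 / K2
    # detailed balance around each exchange cycle:
    #   K1 * K3 = K2 * K4  and  K5 * K6 = K2 * K7
    K1, K3 = k1 / k1r, k3 / _K3R
    K5, K6 = k5 / k5r, k6 / _K6R
    k4 = (K1 * K3 / K2) * _K4R
    k7 = (K5 * K6 / K2) * _K7R
    return RateParameterSet(
        k1=k1, k1r=k1r,
        k2=_K2, k2r=k2r,
        k3=k3, k3r=_K3R,
        k4=k4, k4r=_K4R,
        k5=k5, k5r=k5r,
        k6=k6, k6r=_K6R,
        k7=k7, k7r=_K7R,
    )


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for every synthetic assay family.

    ``gtpase_rates_uM_s`` maps condition names (see
    :data:`GTPASE_CONDITIONS`) to multiple-turnover rates in uM/s;
    half-lives are in minutes.  Hashable, so generators can cache the
    deterministic (noiseless) part of a suite per truth.
    """

    rates: RateParameterSet
    gtpase_rates_uM_s: tuple            # ((condition, rate), ...)
    background_hydrolysis_uM_s: float
    halflife_free_min: float            # aminoacyl-ester decay, no EF-Tu
    halflife_protected_min: float       # in the EF-Tu.GTP ternary complex
    observation: ObservationParams
    tet_level_uM: float = 0.0

    def gtpase_rate(self, condition: str) -> float:
        d = dict(self.gtpase_rates_uM_s)
        if condition not in d:
            raise KeyError(
                f"unknown GTPase condition {condition!r}; "
                f"known: {sorted(d)}"
            )
        return d[condition]

    def with_effect(self, **factors: float) -> "GroundTruth":
        """Scale named kinetic constants or half-lives (power-analysis hook).

        Keys are rate-constant names (``k1`` .. ``k7r``), GTPase condition
        names, or ``halflife_free`` / ``halflife_protected``.
        """
        rates = self.rates
        updates: dict = {}
        gtp = dict(self.gtpase_rates_uM_s)
        rate_factors = {}
        for name, fac in factors.items():
            if name in ("halflife_free", "halflife_protected"):
                updates[name + "_min"] = getattr(self, name + "_min") * fac
            elif name in gtp:
                gtp[name] = gtp[name] * fac
            else:
                rate_factors[name] = fac
        if rate_factors:
            rates = rates.scaled(**rate_factors)
        return replace(
            self,
            rates=rates,
            gtpase_rates_uM_s=tuple(sorted(gtp.items())),
            **updates,
        )


def default_truth(tet_level_uM: float = 0.0) -> GroundTruth:
    """Paper-consistent ground truth at a given tetracycline level.

    The kinetic parameters are tetracycline-invariant by construction; the
    only tetracycline-dependent default is the additive observation
    background, so two truths at different levels generate traces that
    differ by a constant offset only.
    """
    if tet_level_uM < 0:
        raise ValueError("tetracycline level must be >= 0 uM")
    return GroundTruth(
        rates=_default_rates(),
        gtpase_rates_uM_s=tuple(sorted(GTPASE_CONDITIONS.items())),
        background_hydrolysis_uM_s=BACKGROUND_HYDROLYSIS,
        halflife_free_min=35.0,
        halflife_protected_min=382.0,
        observation=ObservationParams(),
        tet_level_uM=float(tet_level_uM),
    )
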