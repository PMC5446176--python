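"""Elementary rate constants of the EF-Tu nucleotide-exchange scheme.

The exchange cycle couples nucleotide binding to EF-Tu with EF-Ts binding
to both the free factor and its nucleotide complexes:

    Tu + GDP        <-> Tu.GDP          (k1 / k1r)
    Tu + Ts         <-> Tu.Ts           (k2 / k2r, optional direct path)
    Tu.GDP + Ts     <-> Tu.GDP.Ts       (k3 / k3r)
    Tu.Ts + GDP     <-> Tu.GDP.Ts       (k4 / k4r)
    Tu + GTP        <-> Tu.GTP          (k5 / k5r)
    Tu.GTP + Ts     <-> Tu.GTP.Ts       (k6 / k6r)
    Tu.Ts + GTP     <-> Tu.GTP.Ts       (k7 / k7r)

``k4r`` and ``k7r`` are the nucleotide-release steps from the ternary
EF-Tu.nucleotide.EF-Ts complexes.  Only the combinations
``k3/(1 + k3r/k4r)`` and ``k6/(1 + k6r/k7r)`` — the effective second-order
constants for EF-Ts-stimulated nucleotide release — are identifiable from
an EF-Ts titration; the individual ternary-complex constants are package
defaults chosen to reproduce those combinations.

All values are stored in SI-like solution units: per-molar per-second for
bimolecular association steps and per-second for unimolecular steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

__all__ = [
    "RateParameterSet",
    "predicted_kapp",
    "effective_stimulated_constant",
    "read_params",
    "write_params",
]

#: names of bimolecular constants (per-molar per-second)
BIMOLECULAR = ("k1", "k2", "k3", "k4", "k5", "k6", "k7")
#: names of unimolecular constants (per-second)
UNIMOLECULAR = ("k1r", "k2r", "k3r", "k4r", "k5r", "k6r", "k7r")


@dataclass(frozen=True)
class RateParameterSet:
    """The fourteen elementary rate constants of the exchange scheme.

    Association constants (``k1``..``k7``) are in M^-1 s^-1, dissociation /
    release constants (``k1r``..``k7r``) in s^-1.  Instances are immutable
    and hashable so they can key simulation caches.
    """

    k1: float   # GDP association to free EF-Tu
    k1r: float  # GDP dissociation from EF-Tu.GDP
    k2: float   # EF-Ts binding to free EF-Tu (direct path)
    k2r: float  # EF-Ts release from EF-Tu.Ts
    k3: float   # EF-Ts binding to EF-Tu.GDP
    k3r: float  # EF-Ts release from EF-Tu.GDP.Ts
    k4: float   # GDP binding to EF-Tu.Ts
    k4r: float  # GDP release from EF-Tu.GDP.Ts
    k5: float   # GTP association to free EF-Tu
    k5r: float  # GTP dissociation from EF-Tu.GTP
    k6: float   # EF-Ts binding to EF-Tu.GTP
    k6r: float  # EF-Ts release from EF-Tu.GTP.Ts
    k7: float   # GTP binding to EF-Tu.Ts
    k7r: float  # GTP release from EF-Tu.GTP.Ts

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"rate constant {f.name} must be finite and >= 0, got {v!r}"
                )

    def combined_gdp(self) -> float:
        """Effective constant for EF-Ts-stimulated GDP release (M^-1 s^-1)."""
        return effective_stimulated_constant(self.k3, self.k3r, self.k4r)

    def combined_gtp(self) -> float:
        """Effective constant for EF-Ts-stimulated GTP release (M^-1 s^-1)."""
        return effective_stimulated_constant(self.k6, self.k6r, self.k7r)

    def scaled(self, **factors: float) -> "RateParameterSet":
        """Return a copy with named constants multiplied by a factor.

        This is the effect hook used in power analyses: e.g.
        ``params.scaled(k1r=5.0)`` models an agent that slows GDP release
        five-fold while leaving every other step untouched.
        """
        updates = {}
        for name, fac in factors.items():
            if name not in {f.name for f in fields(self)}:
                raise KeyError(f"unknown rate constant {name!r}")
            updates[name] = getattr(self, name) * fac
        return replace(self, **updates)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def predicted_kapp(kon: float, koff: float, ligand: float) -> float:
    """Apparent pseudo-first-order rate ``kon * [L] + koff`` (s^-1).

    Under ligand excess the binding transient relaxes single-exponentially
    with this rate; plotting it against [L] gives ``kon`` as slope and
    ``koff`` as intercept.
    """
    if kon < 0 or koff < 0 or ligand < 0:
        raise ValueError("kon, koff and ligand concentration must be >= 0")
    return kon * ligand + koff


def effective_stimulated_constant(
    k_on_ts: float, k_off_ts: float, k_nuc_release: float
) -> float:
    """Flux-partitioned constant for GEF-stimulated nucleotide release.

    An EF-Ts encounter with the nucleotide-bound factor commits to
    nucleotide release with probability ``k_nuc_release / (k_off_ts +
    k_nuc_release)``, so the apparent second-order constant for stimulated
    release is ``k_on_ts / (1 + k_off_ts / k_nuc_release)`` (M^-1 s^-1).
    """
    if k_on_ts < 0 or k_off_ts < 0 or k_nuc_release < 0:
        raise ValueError("rate constants must be >= 0")
    if k_off_ts + k_nuc_release == 0:
        raise ZeroDivisionError(
            "flux partition undefined: k_off_ts + k_nuc_release == 0"
        )
    return k_on_ts * k_nuc_release / (k_off_ts + k_nuc_release)


def write_params(params: RateParameterSet, path) -> None:
    """Serialize to a flat ``key = value`` config, 12 significant digits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# nexkin rate parameters (M^-1 s^-1 / s^-1)\n")
        for name, value in params.as_dict().items():
            fh.write(f"{name} = {value:.12g}\n")


def read_params(path) -> RateParameterSet:
    """Read a flat ``key = value`` config written by :func:`write_params`."""
    values: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = line.partition("=")
            values[key.strip()] = float(raw)
    expected = {f.name for f in fields(RateParameterSet)}
    missing = expected - values.keys()
    extra = values.keys() - expected
    if missing or extra:
        raise ValueError(
            f"{path}: missing keys {sorted(missing)}, unknown keys {sorted(extra)}"
        )
    return RateParameterSet(**values)
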