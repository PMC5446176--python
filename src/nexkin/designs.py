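"""Experiment designs for the five synthetic assay families.

All concentrations are *post-mix* (in the observation cell) unless a
design is constructed through its ``from_syringe`` helper, which applies
the factor-of-two dilution of 1:1 stopped-flow mixing.  Designs are frozen
and hashable so the deterministic part of a suite can be cached per
(design, truth).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "AssociationDesign",
    "ChaseDesign",
    "TsTitrationDesign",
    "GtpaseDesign",
    "ProtectionDesign",
]


def _check_positive(name, value):
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value}")


@dataclass(frozen=True)
class AssociationDesign:
    """Pseudo-first-order titration: mant-nucleotide against constant EF-Tu."""

    nucleotide: str = "GDP"                 # "GDP" or "GTP"
    tu_conc_uM: float = 0.3
    ligand_concs_uM: tuple = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0)
    replicates: int = 11                    # n > 10 traces averaged per point
    n_points: int = 400

    def __post_init__(self):
        if self.nucleotide not in ("GDP", "GTP"):
            raise ValueError("nucleotide must be 'GDP' or 'GTP'")
        _check_positive("tu_conc_uM", self.tu_conc_uM)
        for c in self.ligand_concs_uM:
            _check_positive("ligand conc", c)
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @classmethod
    def from_syringe(cls, **kw) -> "AssociationDesign":
        d = cls(**kw)
        return replace(
            d,
            tu_conc_uM=d.tu_conc_uM / 2.0,
            ligand_concs_uM=tuple(c / 2.0 for c in d.ligand_concs_uM),
        )


@dataclass(frozen=True)
class ChaseDesign:
    """Dissociation chase: preformed labeled complex vs excess unlabeled.

    The labeled complex is equilibrated at syringe concentrations (0.6 uM
    EF-Tu + 6 uM mant-nucleotide by default) and mixed 1:1 with the chase
    syringe (60 uM unlabeled nucleotide), halving everything.
    """

    nucleotide: str = "GDP"
    tu_syringe_uM: float = 0.6
    mant_syringe_uM: float = 6.0
    chase_syringe_uM: float = 60.0
    replicates: int = 10                    # n > 9 traces per rate constant
    n_points: int = 400

    def __post_init__(self):
        if self.nucleotide not in ("GDP", "GTP"):
            raise ValueError("nucleotide must be 'GDP' or 'GTP'")
        for name in ("tu_syringe_uM", "mant_syringe_uM", "chase_syringe_uM"):
            _check_positive(name, getattr(self, name))
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def chase_excess(self) -> float:
        """Chase over labeled nucleotide; should be >= 10 for a clean chase."""
        if self.mant_syringe_uM == 0:
            return float("inf")
        return self.chase_syringe_uM / self.mant_syringe_uM


@dataclass(frozen=True)
class TsTitrationDesign:
    """EF-Ts titration of stimulated nucleotide release.

    A constant EF-Tu.mant-nucleotide complex (0.15 uM post-mix) is mixed
    with EF-Ts at increasing concentrations plus an unlabeled-nucleotide
    chase; the apparent dissociation rate grows linearly with [EF-Ts] while
    it stays well below the nucleotide-release step of the ternary complex.
    """

    nucleotide: str = "GDP"
    tu_syringe_uM: float = 0.3              # -> 0.15 uM complex post-mix
    mant_syringe_uM: float = 3.0
    chase_syringe_uM: float = 60.0
    ts_concs_uM: tuple = (0.05, 0.1, 0.175, 0.25, 0.35, 0.45)  # post-mix
    replicates: int = 12                    # n > 11 traces per concentration
    n_points: int = 400

    def __post_init__(self):
        if self.nucleotide not in ("GDP", "GTP"):
            raise ValueError("nucleotide must be 'GDP' or 'GTP'")
        for c in self.ts_concs_uM:
            _check_positive("EF-Ts conc", c)
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class GtpaseDesign:
    """Multiple-turnover GTP-hydrolysis quench series.

    ``quench_fractions`` place the early points by target substrate
    consumption (all well inside the initial linear phase);
    ``saturating_fractions`` add late points, in units of the nominal
    turnover time, where depletion is visible.  ``None`` quench times mean
    "derive from the condition's nominal rate at generation time".
    """

    condition: str = "intrinsic"
    tu_conc_uM: float = 10.0
    gtp_total_uM: float = 20.0
    quench_fractions: tuple = (0.005, 0.01, 0.015, 0.02, 0.03, 0.04)
    saturating_fractions: tuple = (0.5, 1.5, 3.0)
    replicates: int = 3
    noise_frac: float = 0.02        # counting noise, fraction of signal
    noise_floor_uM: float = 0.02    # absolute counting-noise floor (0.1% of S0)

    def __post_init__(self):
        _check_positive("gtp_total_uM", self.gtp_total_uM)
        _check_positive("noise_frac", self.noise_frac)
        _check_positive("noise_floor_uM", self.noise_floor_uM)
        if len(self.quench_fractions) < 4:
            raise ValueError(">= 4 early quench points are required")
        if any(f >= 0.1 for f in self.quench_fractions):
            raise ValueError("early quench points must stay below 10% consumption")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class ProtectionDesign:
    """Aminoacyl-ester stability assay with or without EF-Tu."""

    trna_conc_uM: float = 1.08
    tu_conc_uM: float = 1.5                 # 0.0 for the unprotected series
    n_times: int = 8                        # log-spaced sampling points
    span_halflives: float = 3.0             # time window in units of t1/2
    noise_cv: float = 0.02                  # multiplicative noise

    def __post_init__(self):
        _check_positive("trna_conc_uM", self.trna_conc_uM)
        _check_positive("tu_conc_uM", self.tu_conc_uM)
        if self.n_times < 5:
            raise ValueError(">= 5 sampling times are required for a decay fit")
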