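"""From species trajectories to stopped-flow fluorescence traces.

Binding of a mant-nucleotide to EF-Tu is observed by FRET from the single
tryptophan of the factor to the mant group, collected through a narrow
band-pass filter.  Tetracycline autofluorescence, which overlaps the mant
emission, enters the recorded signal as an additive, time-independent
background whose size is set by how much of the tetracycline emission
spectrum leaks through the passband — the filter is chosen to make that
leakage small while retaining most of the mant emission.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import TimeCourseRecord
from .scheme import Trajectory

__all__ = [
    "ObservationParams",
    "SpectralTable",
    "passband_fraction",
    "trajectory_to_signal",
    "default_tet_spectrum",
    "default_mant_spectrum",
]


@dataclass(frozen=True)
class SpectralTable:
    """Relative emission intensity versus wavelength (nm), ascending."""

    wavelength_nm: tuple
    intensity: tuple

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        if wl.size < 2 or wl.size != it.size:
            raise ValueError("spectrum needs >= 2 (wavelength, intensity) pairs")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(it < 0):
            raise ValueError("intensities must be >= 0")

    @classmethod
    def from_arrays(cls, wavelength_nm, intensity) -> "SpectralTable":
        return cls(tuple(float(w) for w in wavelength_nm),
                   tuple(float(i) for i in intensity))

    @classmethod
    def read_csv(cls, path) -> "SpectralTable":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls.from_arrays(data[:, 0], data[:, 1])

    def write_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("wavelength_nm,intensity\n")
            for w, i in zip(self.wavelength_nm, self.intensity):
                fh.write(f"{w:.12g},{i:.12g}\n")


@dataclass(frozen=True)
class ObservationParams:
    """Instrument and signal model for rendering fluorescence traces.

    ``noise_sd`` is interpreted as a fraction of the noiseless trace's
    dynamic range when ``noise_is_fraction`` is true (the default), else as
    an absolute standard deviation in signal units.

    ``rate_jitter_cv`` models shot-to-shot variability between replicate
    mixes (temperature drift, mixing-ratio error): each rendered trace
    carries one multiplicative perturbation of its time scale, i.e. of the
    apparent rate.  This is the replicate scatter that averaging many time
    courses per condition — and quoting the standard error of that mean —
    is designed to beat down; with white point noise alone, replicate
    apparent rates would agree to a fraction of a percent and replicate
    averaging would be pointless.

    ``conc_error_cv`` models the preparation error of each titration
    point's ligand or EF-Ts concentration.  It is shared by all replicates
    of that point (they come from the same dilution), so it does not show
    in replicate error bars; it is the reason points in a secondary plot
    scatter about the fitted line by more than those error bars.
    """

    baseline: float = 0.2            # signal units
    tet_background_coeff: float = 1.2e-3  # signal units per uM tetracycline
    fret_amplitude: float = 1.0      # signal units per uM bound mant-nucleotide
    noise_sd: float = 0.005          # fraction of dynamic range (see above)
    noise_is_fraction: bool = True
    rate_jitter_cv: float = 0.03     # shot-to-shot rate variability (CV)
    conc_error_cv: float = 0.02      # titration-point concentration error (CV)
    dead_time: float = 1.5e-3        # s, points before this are discarded
    sampling_hz: float = 1000.0      # nominal acquisition rate
    passband_center_nm: float = 430.0
    passband_halfwidth_nm: float = 10.0

    def __post_init__(self):
        if self.noise_sd < 0 or self.rate_jitter_cv < 0:
            raise ValueError("noise_sd and rate_jitter_cv must be >= 0")
        if self.dead_time < 0:
            raise ValueError("dead_time must be >= 0")
        if self.passband_halfwidth_nm <= 0:
            raise ValueError("passband half-width must be > 0")


def passband_fraction(
    spectrum: SpectralTable, center_nm: float, halfwidth_nm: float
) -> float:
    """Fraction of a spectrum's total emission inside a band-pass window.

    Trapezoidal integral of intensity over ``center +- halfwidth`` divided
    by the integral over the spectrum's full support; a window with no
    overlap returns 0.0.
    """
    if halfwidth_nm <= 0:
        raise ValueError("passband half-width must be > 0")
    wl = np.asarray(spectrum.wavelength_nm)
    it = np.asarray(spectrum.intensity)
    total = np.trapezoid(it, wl)
    if total <= 0:
        return 0.0
    lo = max(center_nm - halfwidth_nm, wl[0])
    hi = min(center_nm + halfwidth_nm, wl[-1])
    if hi <= lo:
        return 0.0
    # dense grid inside the window, interpolated linearly (trapezoid-exact)
    grid = np.unique(np.concatenate([[lo, hi], wl[(wl > lo) & (wl < hi)]]))
    inside = np.trapezoid(np.interp(grid, wl, it), grid)
    return float(inside / total)


def tet_background_coeff(
    spectrum: SpectralTable,
    center_nm: float = 430.0,
    halfwidth_nm: float = 10.0,
    brightness_scale: float = 0.05,
) -> float:
    """Tetracycline background per uM from its emission spectrum.

    The additive background coefficient is the passband leakage fraction of
    the supplied tetracycline spectrum times an overall brightness scale
    (signal units per uM at full spectral collection).  The absolute
    brightness of tetracycline relative to mant under the FRET excitation
    scheme is a free calibration of the instrument model.
    """
    return brightness_scale * passband_fraction(spectrum, center_nm, halfwidth_nm)


def _gaussian_spectrum(center: float, sigma: float) -> SpectralTable:
    wl = np.arange(360.0, 651.0, 2.0)
    return SpectralTable.from_arrays(wl, np.exp(-0.5 * ((wl - center) / sigma) ** 2))


def default_tet_spectrum() -> SpectralTable:
    """Synthetic stand-in for a tetracycline emission spectrum.

    A Gaussian centered at 520 nm (sigma 45 nm): most of the emission lies
    above 450 nm, so only a small tail leaks through a 430 +- 10 nm filter.
    Synthetic — use :meth:`SpectralTable.read_csv` to supply a measured one.
    """
    return _gaussian_spectrum(520.0, 45.0)


def default_mant_spectrum() -> SpectralTable:
    """Synthetic stand-in for a mant-nucleotide emission spectrum.

    A Gaussian centered at 440 nm (sigma 35 nm), matching the mant emission
    maximum; most of it falls inside the 430 +- 10 nm passband region.
    Synthetic — supply a measured table for quantitative filter design.
    """
    return _gaussian_spectrum(440.0, 35.0)


def trajectory_to_signal(
    traj: Trajectory,
    obs: ObservationParams,
    tet_conc_uM: float = 0.0,
    seed=None,
    meta: dict | None = None,
    t_window: float | None = None,
    extra_rate_scale: float = 1.0,
) -> TimeCourseRecord:
    """Render a species trajectory as a noisy stopped-flow trace.

    signal(t) = baseline + tet_coeff * [tet] + fret_amplitude * [mant bound](t)
    plus shot-to-shot rate jitter and i.i.d. Gaussian point noise; points
    earlier than the instrument dead time are discarded, points after
    ``t_window`` (if given) as well.  Deterministic for a fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    bound_uM = traj.mant_bound() * 1e6
    t_all = traj.times
    keep = t_all >= obs.dead_time
    if t_window is not None:
        keep &= t_all <= t_window
    if not np.any(keep):
        raise ValueError("trajectory ends before the instrument dead time")
    t = t_all[keep]
    scale = extra_rate_scale
    if obs.rate_jitter_cv > 0:
        # one time-scale perturbation per trace == one apparent-rate factor;
        # clipped at 5 sigma, sampled off the simulated grid
        scale *= 1.0 + float(np.clip(rng.normal(0.0, obs.rate_jitter_cv),
                                     -5 * obs.rate_jitter_cv,
                                     5 * obs.rate_jitter_cv))
    if scale != 1.0:
        bound_t = np.interp(t * scale, t_all, bound_uM)
    else:
        bound_t = bound_uM[keep]
    clean = (
        obs.baseline
        + obs.tet_background_coeff * tet_conc_uM
        + obs.fret_amplitude * bound_t
    )
    if obs.noise_is_fraction:
        dyn = float(np.ptp(clean))
        sd = obs.noise_sd * dyn
    else:
        sd = obs.noise_sd
    signal = clean + rng.normal(0.0, sd, size=clean.shape) if sd > 0 else clean.copy()
    md = {
        "experiment": "fluorescence",
        "tet_conc_uM": tet_conc_uM,
        "noise_sd_abs": sd,
        "dead_time_s": obs.dead_time,
    }
    if meta:
        md.update(meta)
    return TimeCourseRecord(time_s=t, signal=signal, meta=md)
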