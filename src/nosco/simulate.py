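"""Forward simulation of reference and complementary-NUS titration FIDs.

A well-separated 2D signal is modelled as a complex exponential in both
time dimensions,

    S(t1, t2) = A * exp(i 2 pi nu_N t1 + i 2 pi nu_H t2)
                  * exp(-R2_N t1 - R2_H t2),

with t1 the indirect (15N) and t2 the direct (1H) dimension.  In a
titration the frequencies move with the ligand-to-protein ratio x via the
fast-exchange binding model (see :mod:`nosco.binding`); because each x owns
a unique set of t1 increments, the co-processed signal becomes
*non-stationary*: its frequencies depend on t1 through x(t1).  Amplitudes
may additionally scale with a per-titration-point dilution factor A(x).

The simulator is the package's ground-truth source: every frequency placed
in a dataset is computed with :func:`nosco.binding.observed_shift`, so
recovery tests compare against exactly known parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .binding import BindingParameters, TitrationScheme, bound_fraction, observed_shift
from .schedules import SamplingScheduleSet, make_complementary_schedules

__all__ = [
    "PeakGroundTruth",
    "AcquisitionParams",
    "PseudoThreeDData",
    "Scenario",
    "simulate_reference_fid",
    "simulate_titration_point_fid",
    "simulate_nosco_dataset",
    "make_scenario",
    "save_pseudo3d",
    "load_pseudo3d",
]


@dataclass(frozen=True)
class PeakGroundTruth:
    """One signal's true parameters.

    Frequencies are carrier-centered offsets in Hz; ``amplitude`` is a
    unitless intensity; R2 rates in 1/s (0 = no relaxation, matching the
    idealized non-stationary signal model).
    """

    label: str
    nu_n0: float
    nu_h0: float
    delta_nu_n: float = 0.0
    delta_nu_h: float = 0.0
    amplitude: float = 1.0
    r2_n: float = 0.0
    r2_h: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.r2_n < 0 or self.r2_h < 0:
            raise ValueError("R2 rates must be >= 0")


@dataclass(frozen=True)
class AcquisitionParams:
    """Grid sizes, spectral widths (Hz), noise level and dilution factors.

    Dwell times are 1/SW; the direct dimension t2 is always fully sampled.
    ``noise_sigma`` is the standard deviation of the complex circular
    Gaussian noise per time-domain point (quote it relative to a peak
    amplitude to set an SNR).  ``dilution_factors`` scale each titration
    point's amplitude, in (0, 1].
    """

    n1: int
    n2: int
    sw1: float
    sw2: float
    noise_sigma: float = 0.0
    dilution_factors: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("grid sizes must be >= 1")
        if self.sw1 <= 0 or self.sw2 <= 0:
            raise ValueError("spectral widths must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.dilution_factors is not None:
            d = np.asarray(self.dilution_factors, dtype=float)
            if np.any((d <= 0) | (d > 1)):
                raise ValueError("dilution factors must be in (0, 1]")
            object.__setattr__(self, "dilution_factors", d)

    @property
    def t1(self) -> np.ndarray:
        return np.arange(self.n1) / self.sw1

    @property
    def t2(self) -> np.ndarray:
        return np.arange(self.n2) / self.sw2


@dataclass
class PseudoThreeDData:
    """Complex time-domain matrix indexed (titration point, t1, t2).

    ``values[k, i, :]`` is populated iff t1 index i belongs to schedule k;
    all other slots are zero and are never read (ownership lives in
    ``schedule_set``).  x acts as the third, pseudo dimension.
    """

    values: np.ndarray
    schedule_set: SamplingScheduleSet
    acquisition: AcquisitionParams
    scheme: TitrationScheme

    def __post_init__(self) -> None:
        nx, n1, n2 = self.values.shape
        if nx != self.schedule_set.n_x or nx != self.scheme.n_x:
            raise ValueError("titration axis inconsistent across fields")
        if n1 != self.schedule_set.grid_size or n1 != self.acquisition.n1:
            raise ValueError("t1 grid inconsistent across fields")
        if n2 != self.acquisition.n2:
            raise ValueError("t2 grid inconsistent across fields")


def _check_alias(freq: float, sw: float, allow_alias: bool, what: str) -> None:
    if not allow_alias and abs(freq) >= sw / 2:
        raise ValueError(
            f"{what} frequency {freq:g} Hz lies outside +/-SW/2 = "
            f"{sw / 2:g} Hz and would alias (pass allow_alias=True to wrap)"
        )


def _peak_matrix(
    peak: PeakGroundTruth,
    nu_n: float,
    nu_h: float,
    acq: AcquisitionParams,
    allow_alias: bool,
) -> np.ndarray:
    _check_alias(nu_n, acq.sw1, allow_alias, f"peak {peak.label} t1")
    _check_alias(nu_h, acq.sw2, allow_alias, f"peak {peak.label} t2")
    e1 = np.exp((2j * np.pi * nu_n - peak.r2_n) * acq.t1)
    e2 = np.exp((2j * np.pi * nu_h - peak.r2_h) * acq.t2)
    return peak.amplitude * np.outer(e1, e2)


def _complex_noise(rng: np.random.Generator, sigma: float, shape) -> np.ndarray:
    return sigma * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))


def simulate_reference_fid(
    peaks: list[PeakGroundTruth],
    acq: AcquisitionParams,
    allow_alias: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Fully sampled apo (no-ligand) FID at the reference frequencies.

    Deterministic for a given ``acq.seed`` (or supplied generator).
    """
    rng = np.random.default_rng(acq.seed) if rng is None else rng
    fid = np.zeros((acq.n1, acq.n2), dtype=complex)
    for p in peaks:
        fid += _peak_matrix(p, p.nu_n0, p.nu_h0, acq, allow_alias)
    if acq.noise_sigma > 0:
        fid += _complex_noise(rng, acq.noise_sigma, fid.shape)
    return fid


def simulate_titration_point_fid(
    peaks: list[PeakGroundTruth],
    binding: dict[str, BindingParameters],
    x: float,
    c_p: float,
    acq: AcquisitionParams,
    dilution: float = 1.0,
    allow_alias: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Fully sampled FID at one ligand-to-protein ratio (conventional mode)."""
    rng = np.random.default_rng(acq.seed) if rng is None else rng
    fid = np.zeros((acq.n1, acq.n2), dtype=complex)
    for p in peaks:
        bp = binding[p.label]
        nu_n = observed_shift(p.nu_n0, bp.delta_nu_n, x, bp.k_d, c_p)
        nu_h = observed_shift(p.nu_h0, bp.delta_nu_h, x, bp.k_d, c_p)
        fid += dilution * _peak_matrix(p, nu_n, nu_h, acq, allow_alias)
    if acq.noise_sigma > 0:
        fid += _complex_noise(rng, acq.noise_sigma, fid.shape)
    return fid


def simulate_nosco_dataset(
    peaks: list[PeakGroundTruth],
    acq: AcquisitionParams,
    scheme: TitrationScheme,
    schedule_set: SamplingScheduleSet,
    binding: dict[str, BindingParameters],
    allow_alias: bool = False,
) -> PseudoThreeDData:
    """Simulate a complementary-NUS pseudo-3D titration dataset.

    For titration point k (ratio x_k, protein concentration c_P[k]) the FID
    rows at the t1 indices owned by schedule k carry the fast-exchange
    frequencies nu_0 + f(x_k, K_D) * delta_nu in both dimensions, scaled by
    the dilution factor A(x_k).  Noise is i.i.d. complex Gaussian on the
    sampled slots only.  Deterministic given ``acq.seed``.
    """
    if schedule_set.n_x != scheme.n_x:
        raise ValueError("schedule set and titration scheme disagree on n_x")
    if schedule_set.x_per_schedule is not None and not np.allclose(
        schedule_set.x_per_schedule, scheme.x_values
    ):
        raise ValueError("schedule x binding does not match the scheme")
    rng = np.random.default_rng(acq.seed)
    dil = (
        np.ones(scheme.n_x)
        if acq.dilution_factors is None
        else np.asarray(acq.dilution_factors, dtype=float)
    )
    if len(dil) != scheme.n_x:
        raise ValueError("need one dilution factor per titration point")

    values = np.zeros((scheme.n_x, acq.n1, acq.n2), dtype=complex)
    for k in range(scheme.n_x):
        x_k = scheme.x_values[k]
        cp_k = scheme.c_p[k]
        full = np.zeros((acq.n1, acq.n2), dtype=complex)
        for p in peaks:
            bp = binding[p.label]
            nu_n = observed_shift(p.nu_n0, bp.delta_nu_n, x_k, bp.k_d, cp_k)
            nu_h = observed_shift(p.nu_h0, bp.delta_nu_h, x_k, bp.k_d, cp_k)
            full += dil[k] * _peak_matrix(p, nu_n, nu_h, acq, allow_alias)
        own = schedule_set.schedules[k]
        values[k, own, :] = full[own, :]
        if acq.noise_sigma > 0:
            values[k, own, :] += _complex_noise(
                rng, acq.noise_sigma, (len(own), acq.n2)
            )
    bound = (
        schedule_set
        if schedule_set.x_per_schedule is not None
        else schedule_set.with_x(scheme.x_values)
    )
    return PseudoThreeDData(
        values=values, schedule_set=bound, acquisition=acq, scheme=scheme
    )


@dataclass
class Scenario:
    """A complete synthetic study: ground truth plus acquisition settings.

    ``windows`` maps peak label -> (center (nu_N, nu_H), half-widths) in Hz
    for single-peak region selection; ``bounds`` is the {delta_nu_N,
    delta_nu_H, K_D} search box used by the refocusing optimizer.
    """

    name: str
    units: str
    kd_truth: float
    peaks: list[PeakGroundTruth]
    binding: dict[str, BindingParameters]
    acq: AcquisitionParams
    scheme: TitrationScheme
    schedule_set: SamplingScheduleSet
    windows: dict[str, tuple[tuple[float, float], tuple[float, float]]]
    bounds: np.ndarray  # rows (lo, hi) for (delta_nu_N, delta_nu_H, K_D)


def make_scenario(name: str, seed: int = 0, snr: float | None = None) -> Scenario:
    """Build one of the two stock titration regimes.

    ``"weak"`` emulates a small, well-resolved protein binding a peptide
    very weakly (K_D = 9 in mM units, n_x = 8 ratios, no CSP curve near its
    plateau, mild relaxation, default time-domain SNR 20).  ``"moderate"``
    emulates a large protein with stronger binding (K_D = 130 in uM units,
    n_x = 6 ratios, lower SNR, heavier line broadening, stronger dilution).
    ``snr`` is peak amplitude over time-domain noise sigma; ``None`` keeps
    the regime default, ``np.inf`` gives noiseless data.  Deterministic for
    a given seed.
    """
    if name == "weak":
        units, kd = "mM", 9.0
        n1 = n2 = 64
        sw1, sw2 = 600.0, 900.0
        x = np.array([1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 24.0, 32.0])
        dil = np.linspace(1.0, 0.85, len(x))
        scheme = TitrationScheme(x_values=x, c_p=0.5 * dil, units=units)
        peaks = [
            PeakGroundTruth("G10", -150.0, 120.0, 25.0, -35.0, 1.0, 4.0, 4.0),
            PeakGroundTruth("A23", 100.0, -200.0, -18.0, 28.0, 0.9, 4.0, 4.0),
            PeakGroundTruth("L41", 200.0, 260.0, 32.0, 22.0, 1.1, 4.0, 4.0),
            PeakGroundTruth("K55", -60.0, -80.0, 12.0, 40.0, 1.0, 4.0, 4.0),
        ]
        bounds = np.array([[-60.0, 60.0], [-60.0, 60.0], [0.5, 500.0]])
        default_snr = 20.0
    elif name == "moderate":
        units, kd = "uM", 130.0
        n1, n2 = 96, 48
        sw1, sw2 = 700.0, 1000.0
        x = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0])
        dil = np.linspace(1.0, 0.75, len(x))
        scheme = TitrationScheme(x_values=x, c_p=80.0 * dil, units=units)
        peaks = [
            PeakGroundTruth("R5", -180.0, 150.0, 40.0, -50.0, 1.0, 12.0, 12.0),
            PeakGroundTruth("D12", 100.0, -220.0, -30.0, 45.0, 0.8, 12.0, 12.0),
            PeakGroundTruth("S30", 250.0, 320.0, 22.0, 30.0, 0.9, 12.0, 12.0),
        ]
        bounds = np.array([[-80.0, 80.0], [-80.0, 80.0], [5.0, 5000.0]])
        default_snr = 8.0
    else:
        raise ValueError(f"unknown scenario {name!r}; use 'weak' or 'moderate'")

    snr = default_snr if snr is None else snr
    sigma = 0.0 if not np.isfinite(snr) else 1.0 / snr
    acq = AcquisitionParams(
        n1=n1, n2=n2, sw1=sw1, sw2=sw2,
        noise_sigma=sigma, dilution_factors=dil, seed=seed,
    )
    schedule_set = make_complementary_schedules(
        n1, scheme.n_x, seed=seed, mode="partition", x_values=scheme.x_values
    )
    binding = {
        p.label: BindingParameters(kd, p.delta_nu_n, p.delta_nu_h) for p in peaks
    }
    windows = {
        p.label: (
            (p.nu_n0, p.nu_h0),
            (abs(p.delta_nu_n) + 45.0, abs(p.delta_nu_h) + 45.0),
        )
        for p in peaks
    }
    return Scenario(
        name=name, units=units, kd_truth=kd, peaks=peaks, binding=binding,
        acq=acq, scheme=scheme, schedule_set=schedule_set, windows=windows,
        bounds=bounds,
    )


def save_pseudo3d(path, data: PseudoThreeDData) -> None:
    """Serialize a dataset to a portable .npz container (complex matrix
    plus flat metadata; schedules stored as separate integer arrays)."""
    sched = {
        f"nuslist_{k:02d}": s for k, s in enumerate(data.schedule_set.schedules)
    }
    np.savez(
        path,
        values=data.values,
        x_values=data.scheme.x_values,
        c_p=data.scheme.c_p,
        units=np.array(data.scheme.units),
        mode=np.array(data.schedule_set.mode),
        schedule_seed=np.array(data.schedule_set.seed),
        acq=np.array(
            [
                data.acquisition.n1,
                data.acquisition.n2,
                data.acquisition.sw1,
                data.acquisition.sw2,
                data.acquisition.noise_sigma,
                data.acquisition.seed,
            ]
        ),
        dilution=(
            np.ones(data.scheme.n_x)
            if data.acquisition.dilution_factors is None
            else data.acquisition.dilution_factors
        ),
        **sched,
    )


def load_pseudo3d(path) -> PseudoThreeDData:
    with np.load(path, allow_pickle=False) as z:
        x_values = z["x_values"]
        scheme = TitrationScheme(
            x_values=x_values, c_p=z["c_p"], units=str(z["units"])
        )
        n1 = int(z["acq"][0])
        schedules = [
            z[k] for k in sorted(z.files) if k.startswith("nuslist_")
        ]
        ss = SamplingScheduleSet(
            grid_size=n1,
            schedules=schedules,
            mode=str(z["mode"]),
            seed=int(z["schedule_seed"]),
            x_per_schedule=x_values,
        )
        acq = AcquisitionParams(
            n1=n1,
            n2=int(z["acq"][1]),
            sw1=float(z["acq"][2]),
            sw2=float(z["acq"][3]),
            noise_sigma=float(z["acq"][4]),
            dilution_factors=z["dilution"],
            seed=int(z["acq"][5]),
        )
        return PseudoThreeDData(
            values=z["values"], schedule_set=ss, acquisition=acq, scheme=scheme
        )
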