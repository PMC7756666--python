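"""2D spectral processing: co-projection, peak regions, peak heights.

Co-processing assembles the pseudo-3D complementary-NUS matrix into one
full-grid 2D FID (each t1 row taken from the unique titration point that
sampled it, divided by its dilution factor), then applies an apodization
window, zero filling, and a 2D FFT.  Signals unaffected by ligand keep
their reference position; signals with large CSP appear smeared because
successive t1 rows carry different frequencies.

Conventions: synthesis uses exp(+i 2 pi nu t), so analysis is numpy's
forward FFT (a peak synthesized at +nu Hz appears at +nu on the axis);
spectra are fftshift-ed with carrier-centered, ascending Hz axes; peak
height is the maximum of the real part (the simulator is zero-phase by
construction), with a magnitude mode for unphased external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .simulate import PseudoThreeDData

__all__ = [
    "Spectrum2D",
    "PeakRegion",
    "window_vector",
    "assemble_fid",
    "process_fid",
    "coprocess",
    "extract_peak_region",
    "isolated_fid",
    "peak_height",
]


def window_vector(n: int, kind: str | None) -> np.ndarray:
    """Apodization vector of length n: None (rectangular) or 'cos2'
    (cosine-squared, the usual HSQC choice)."""
    if kind is None or kind == "none":
        return np.ones(n)
    if kind == "cos2":
        return np.cos(np.pi * np.arange(n) / (2 * n)) ** 2
    raise ValueError(f"unknown window {kind!r}")


@dataclass
class Spectrum2D:
    """Frequency-domain 2D matrix with carrier-centered Hz axes.

    ``values[i, j]`` corresponds to ``(axis1[i], axis2[j])``; both axes are
    ascending and of length zero_fill * original grid size.
    """

    values: np.ndarray
    axis1: np.ndarray
    axis2: np.ndarray
    zero_fill: int
    window: str | None = None

    @property
    def df1(self) -> float:
        return float(self.axis1[1] - self.axis1[0])

    @property
    def df2(self) -> float:
        return float(self.axis2[1] - self.axis2[0])

    def index_of(self, nu1: float, nu2: float) -> tuple[int, int]:
        """Nearest grid indices to a frequency pair (Hz)."""
        i = int(round((nu1 - self.axis1[0]) / self.df1))
        j = int(round((nu2 - self.axis2[0]) / self.df2))
        if not (0 <= i < len(self.axis1) and 0 <= j < len(self.axis2)):
            raise ValueError(f"frequency ({nu1}, {nu2}) Hz outside the spectrum")
        return i, j

    def window_slices(
        self, center: tuple[float, float], half_widths: tuple[float, float]
    ) -> tuple[slice, slice]:
        """Half-open index slices covering center +/- half_widths (Hz).

        Raises if the window clips the spectrum edge.
        """
        (c1, c2), (w1, w2) = center, half_widths
        if w1 <= 0 or w2 <= 0:
            raise ValueError("half widths must be > 0")
        eps = 1e-6  # absorb float residue so exact bin edges stay inclusive
        lo1 = (c1 - w1 - self.axis1[0]) / self.df1
        hi1 = (c1 + w1 - self.axis1[0]) / self.df1
        lo2 = (c2 - w2 - self.axis2[0]) / self.df2
        hi2 = (c2 + w2 - self.axis2[0]) / self.df2
        i0, i1 = int(np.ceil(lo1 - eps)), int(np.floor(hi1 + eps)) + 1
        j0, j1 = int(np.ceil(lo2 - eps)), int(np.floor(hi2 + eps)) + 1
        if i0 < 0 or j0 < 0 or i1 > len(self.axis1) or j1 > len(self.axis2):
            raise ValueError(
                "peak window clips the spectrum edge; shrink the window or "
                "move the carrier"
            )
        return slice(i0, i1), slice(j0, j1)


def assemble_fid(data: PseudoThreeDData, compensate_dilution: bool = True) -> np.ndarray:
    """Collapse a partition-mode pseudo-3D matrix onto one full 2D FID.

    Each t1 grid row is copied from the unique schedule owning it; with
    ``compensate_dilution`` the row is divided by that titration point's
    dilution factor so stationary signals recover their reference
    amplitude.  Unowned rows (corrupt partition data) raise.
    """
    ss = data.schedule_set
    if ss.mode != "partition":
        raise ValueError(
            "co-processing requires partition-mode data; undersampled data "
            "needs a compressed-sensing reconstruction (not implemented)"
        )
    acq = data.acquisition
    dil = (
        np.ones(ss.n_x)
        if acq.dilution_factors is None
        else np.asarray(acq.dilution_factors, dtype=float)
    )
    fid = np.empty((acq.n1, acq.n2), dtype=complex)
    for i in range(acq.n1):
        k = ss.owner_of(i)
        if k < 0:
            raise ValueError(f"t1 index {i} unpopulated in partition-mode data")
        row = data.values[k, i, :]
        fid[i] = row / dil[k] if compensate_dilution else row
    return fid


def process_fid(
    fid: np.ndarray,
    sw1: float,
    sw2: float,
    zero_fill: int = 4,
    window: str | None = "cos2",
) -> Spectrum2D:
    """Window, zero-fill and 2D-FFT a full-grid FID into a Spectrum2D."""
    if zero_fill < 1:
        raise ValueError("zero_fill factor must be >= 1")
    n1, n2 = fid.shape
    w = np.outer(window_vector(n1, window), window_vector(n2, window))
    padded = np.zeros((zero_fill * n1, zero_fill * n2), dtype=complex)
    padded[:n1, :n2] = fid * w
    spec = np.fft.fftshift(np.fft.fft2(padded))
    axis1 = np.fft.fftshift(np.fft.fftfreq(zero_fill * n1, d=1.0 / sw1))
    axis2 = np.fft.fftshift(np.fft.fftfreq(zero_fill * n2, d=1.0 / sw2))
    return Spectrum2D(
        values=spec, axis1=axis1, axis2=axis2, zero_fill=zero_fill, window=window
    )


def coprocess(
    data: PseudoThreeDData,
    zero_fill: int = 4,
    window: str | None = "cos2",
    compensate_dilution: bool = True,
) -> Spectrum2D:
    """Co-process a complementary-NUS titration dataset into one projected
    2D spectrum (assemble, dilution-compensate, window, zero-fill, FFT)."""
    fid = assemble_fid(data, compensate_dilution=compensate_dilution)
    return process_fid(
        fid, data.acquisition.sw1, data.acquisition.sw2,
        zero_fill=zero_fill, window=window,
    )


@dataclass
class PeakRegion:
    """A rectangular single-peak window of a spectrum and its time-domain
    counterpart.

    ``time_domain`` is the inverse 2D FFT of the region submatrix on the
    region's own conjugate grid, demodulated to the region center (the
    center bin is moved to frequency zero before the inverse transform).
    ``multiple_maxima`` flags regions whose validation found more than one
    strong local maximum — the single-peak assumption is then suspect.
    """

    bounds: tuple[slice, slice]
    region_values: np.ndarray
    time_domain: np.ndarray
    parent_shape: tuple[int, int]
    multiple_maxima: bool = False


def _count_local_maxima(mag: np.ndarray, rel_threshold: float = 0.3) -> int:
    """Count interior points that dominate their 8-neighborhood and exceed
    rel_threshold * max."""
    if mag.shape[0] < 3 or mag.shape[1] < 3:
        return 1
    c = mag[1:-1, 1:-1]
    neigh = np.stack(
        [
            mag[:-2, :-2], mag[:-2, 1:-1], mag[:-2, 2:],
            mag[1:-1, :-2], mag[1:-1, 2:],
            mag[2:, :-2], mag[2:, 1:-1], mag[2:, 2:],
        ]
    )
    is_max = (c > neigh.max(axis=0)) & (c > rel_threshold * mag.max())
    return int(is_max.sum())


def extract_peak_region(
    spec: Spectrum2D,
    center: tuple[float, float],
    half_widths: tuple[float, float],
) -> PeakRegion:
    """Cut a single-peak frequency window and inverse-transform it.

    The window must contain the peak's full smear trajectory (center +/-
    at least the CSP amplitude bound).  The inverse FFT of the windowed
    submatrix yields the non-stationary time-domain signal on the region's
    conjugate grid; a second strong local maximum sets ``multiple_maxima``.
    """
    s1, s2 = spec.window_slices(center, half_widths)
    sub = spec.values[s1, s2].copy()
    n_max = _count_local_maxima(np.abs(sub))
    if n_max > 1:
        warnings.warn(
            f"peak region at {center} contains {n_max} local maxima; "
            "single-peak assumption may be violated",
            RuntimeWarning,
            stacklevel=2,
        )
    td = np.fft.ifft2(np.fft.ifftshift(sub))
    return PeakRegion(
        bounds=(s1, s2),
        region_values=sub,
        time_domain=td,
        parent_shape=spec.values.shape,
        multiple_maxima=n_max > 1,
    )


def isolated_fid(
    spec: Spectrum2D, region: PeakRegion, original_shape: tuple[int, int]
) -> np.ndarray:
    """Band-isolate one peak back onto the acquisition time grid.

    Zeroes the spectrum outside the region, inverse-transforms the full
    grid and crops to the original (pre-zero-fill) FID size.  Only valid
    for rectangular-window processing (the window cannot be divided out
    stably near its zeros).
    """
    if region.parent_shape != spec.values.shape:
        raise ValueError("region does not belong to this spectrum")
    if spec.window not in (None, "none"):
        raise ValueError("band isolation requires window=None processing")
    masked = np.zeros_like(spec.values)
    s1, s2 = region.bounds
    masked[s1, s2] = spec.values[s1, s2]
    fid_full = np.fft.ifft2(np.fft.ifftshift(masked))
    n1, n2 = original_shape
    return fid_full[:n1, :n2]


def peak_height(obj, mode: str = "real") -> float:
    """Peak height: max of the real part (default) or magnitude.

    Accepts a Spectrum2D, PeakRegion or bare complex matrix.
    """
    if isinstance(obj, Spectrum2D):
        values = obj.values
    elif isinstance(obj, PeakRegion):
        values = obj.region_values
    else:
        values = np.asarray(obj)
    if values.size == 0:
        raise ValueError("empty matrix has no peak height")
    if mode == "real":
        return float(values.real.max())
    if mode == "magnitude":
        return float(np.abs(values).max())
    raise ValueError(f"unknown height mode {mode!r}")
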