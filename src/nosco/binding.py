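"""Single-site binding thermodynamics for NMR titration analysis.

A protein P at total concentration ``c_P`` is titrated with ligand L at
total concentration ``c_L = x * c_P``, where ``x`` is the ligand-to-protein
molar ratio.  Under fast exchange a signal's observed chemical shift is the
population-weighted average

    nu_obs(x) = nu_0 + f(x, K_D) * delta_nu

with ``f`` the bound fraction of protein obtained from the mass-action
equilibrium ``[P][L]/[PL] = K_D``:

    f(x, K_D) = [K_D + (1+x) c_P - sqrt((K_D + (1+x) c_P)^2 - 4 c_P^2 x)]
                / (2 c_P)

``delta_nu`` is the maximal chemical-shift-perturbation (CSP) amplitude in
Hz, reached at ligand saturation.  K_D and c_P share one concentration unit
chosen per dataset (mM or uM); frequencies are always in Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "TitrationScheme",
    "BindingParameters",
    "CspCurveFit",
    "bound_fraction",
    "observed_shift",
    "fit_csp_curve",
    "aggregate_kd",
]


@dataclass(frozen=True)
class TitrationScheme:
    """Ligand-to-protein ratios and protein concentrations of one series.

    Parameters
    ----------
    x_values
        Molar ratios c_L/c_P, dimensionless, non-negative and strictly
        increasing.
    c_p
        Total protein concentration at each titration point.  A scalar is
        broadcast to all points; per-point values model dilution.
    units
        Concentration unit tag carried through to reports ("mM", "uM", ...).
    """

    x_values: np.ndarray
    c_p: np.ndarray
    units: str = "mM"

    def __post_init__(self) -> None:
        x = np.atleast_1d(np.asarray(self.x_values, dtype=float))
        cp = np.broadcast_to(
            np.asarray(self.c_p, dtype=float), x.shape
        ).copy()
        if np.any(x < 0):
            raise ValueError("molar ratios x must be >= 0")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x_values must be strictly increasing")
        if np.any(cp <= 0):
            raise ValueError("protein concentrations must be > 0")
        object.__setattr__(self, "x_values", x)
        object.__setattr__(self, "c_p", cp)

    @property
    def n_x(self) -> int:
        return len(self.x_values)


@dataclass(frozen=True)
class BindingParameters:
    """Fitted per-signal triplet {K_D, delta_nu_N, delta_nu_H}.

    ``k_d`` shares the dataset's concentration unit; CSP amplitudes are in
    Hz and may be negative (upfield shifts).
    """

    k_d: float
    delta_nu_n: float
    delta_nu_h: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.k_d) or self.k_d <= 0:
            raise ValueError(f"K_D must be finite and > 0, got {self.k_d}")
        if not (np.isfinite(self.delta_nu_n) and np.isfinite(self.delta_nu_h)):
            raise ValueError("CSP amplitudes must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.delta_nu_n, self.delta_nu_h, self.k_d])


@dataclass
class CspCurveFit:
    """Result of least-squares fitting of the shift-vs-x titration curve.

    ``params`` is ``None`` when the signal moved too little for K_D to be
    identifiable (``unidentifiable`` flag set).  ``nu_ref`` holds the fitted
    reference shifts nu_0 per dimension; the model curve equals ``nu_ref``
    exactly at x = 0 because f(0) = 0.
    """

    params: BindingParameters | None
    nu_ref: np.ndarray
    residual_norm: float
    per_point_shifts: np.ndarray
    unidentifiable: bool = False
    dims: tuple[str, ...] = ("N", "H")

    def predict(self, x: np.ndarray, c_p: np.ndarray | float) -> np.ndarray:
        if self.params is None:
            raise ValueError("unidentifiable fit has no model curve")
        f = bound_fraction(np.asarray(x, float), self.params.k_d, c_p)
        amps = {"N": self.params.delta_nu_n, "H": self.params.delta_nu_h}
        cols = [self.nu_ref[i] + f * amps[d] for i, d in enumerate(self.dims)]
        return np.stack(cols, axis=-1)


def bound_fraction(x, k_d, c_p):
    """Bound fraction of protein for single-site binding.

    Evaluates the physical root of the mass-action quadratic in the
    numerically stable form ``f = 2 c_P x / (b + sqrt(b^2 - 4 c_P^2 x))``
    with ``b = K_D + (1+x) c_P`` (avoids cancellation for K_D >> c_P).
    Broadcasts over array arguments.  The result lies in [0, min(1, x)],
    is non-decreasing in x and non-increasing in K_D.
    """
    x = np.asarray(x, dtype=float)
    k_d = np.asarray(k_d, dtype=float)
    c_p = np.asarray(c_p, dtype=float)
    if np.any(x < 0):
        raise ValueError("molar ratio x must be >= 0")
    if np.any(c_p <= 0):
        raise ValueError("protein concentration must be > 0")
    if np.any(k_d < 0):
        raise ValueError("K_D must be >= 0")
    b = k_d + (1.0 + x) * c_p
    disc = b * b - 4.0 * c_p * c_p * x
    if np.any(disc < 0):
        warnings.warn(
            "negative discriminant in bound_fraction clamped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        disc = np.clip(disc, 0.0, None)
    f = 2.0 * c_p * x / (b + np.sqrt(disc))
    return f if f.ndim else float(f)


def observed_shift(nu_ref, delta_nu, x, k_d, c_p):
    """Observed fast-exchange shift nu_ref + f(x, K_D) * delta_nu, in Hz."""
    return nu_ref + bound_fraction(x, k_d, c_p) * delta_nu


def _profile_solve(f: np.ndarray, shifts: np.ndarray):
    """Solve the linear subproblem (nu_0, delta_nu) per dimension for fixed f.

    Returns (nu0 per dim, dnu per dim, rss)."""
    design = np.column_stack([np.ones_like(f), f])
    coef, *_ = np.linalg.lstsq(design, shifts, rcond=None)
    resid = shifts - design @ coef
    return coef[0], coef[1], float(np.sum(resid * resid))


def fit_csp_curve(
    shifts_per_x: np.ndarray,
    scheme: TitrationScheme,
    kd_bounds: tuple[float, float] | None = None,
    noise_floor: float = 0.0,
    n_scan: int = 256,
) -> CspCurveFit:
    """Least-squares fit of the titration curve to the single-site model.

    Parameters
    ----------
    shifts_per_x
        Observed shifts in Hz; shape ``(n_x,)`` for one dimension or
        ``(n_x, 2)`` with columns (15N, 1H).  Both dimensions share K_D.
    scheme
        Titration scheme providing x and per-point c_P.
    kd_bounds
        Search interval for K_D; defaults to (1e-3, 1e4) times the median
        protein concentration.
    noise_floor
        Shift measurement noise in Hz.  A signal whose total excursion in
        every dimension is below 3x this floor is flagged unidentifiable.

    The two linear parameters per dimension (nu_0, delta_nu) are profiled
    out analytically for each trial K_D, so only K_D is searched: a dense
    log-spaced scan over ``kd_bounds`` followed by bounded scalar
    refinement.  Requires at least 3 titration points.
    """
    shifts = np.asarray(shifts_per_x, dtype=float)
    one_dim = shifts.ndim == 1
    if one_dim:
        shifts = shifts[:, None]
    if shifts.shape[0] != scheme.n_x:
        raise ValueError("shifts_per_x length must match scheme.n_x")
    if shifts.shape[0] < 3:
        raise ValueError("need at least 3 titration points to fit 3 parameters")
    if not np.all(np.isfinite(shifts)):
        raise ValueError("shifts must be finite")

    dims = ("N",) if one_dim else ("N", "H")
    excursion = np.max(shifts.max(axis=0) - shifts.min(axis=0))
    if excursion <= 3.0 * noise_floor:
        return CspCurveFit(
            params=None,
            nu_ref=shifts[0].copy(),
            residual_norm=float("nan"),
            per_point_shifts=shifts if not one_dim else shifts[:, 0],
            unidentifiable=True,
            dims=dims,
        )

    if kd_bounds is None:
        c_ref = float(np.median(scheme.c_p))
        kd_bounds = (1e-3 * c_ref, 1e4 * c_ref)
    lo, hi = kd_bounds
    if not (0 < lo < hi):
        raise ValueError("kd_bounds must satisfy 0 < lo < hi")

    x, cp = scheme.x_values, scheme.c_p

    def rss_of_logkd(logkd: float) -> float:
        f = bound_fraction(x, 10.0 ** logkd, cp)
        return _profile_solve(f, shifts)[2]

    grid = np.linspace(np.log10(lo), np.log10(hi), n_scan)
    rss = np.array([rss_of_logkd(g) for g in grid])
    i = int(np.argmin(rss))
    bl = grid[max(i - 1, 0)]
    bh = grid[min(i + 1, n_scan - 1)]
    res = minimize_scalar(
        rss_of_logkd, bounds=(bl, bh), method="bounded",
        options={"xatol": 1e-13},
    )
    logkd = float(res.x) if res.fun <= rss[i] else grid[i]
    kd = 10.0 ** logkd

    f = bound_fraction(x, kd, cp)
    nu0, dnu, rss_best = _profile_solve(f, shifts)
    if one_dim:
        params = BindingParameters(kd, float(dnu[0]), 0.0)
    else:
        params = BindingParameters(kd, float(dnu[0]), float(dnu[1]))
    return CspCurveFit(
        params=params,
        nu_ref=np.atleast_1d(nu0),
        residual_norm=rss_best,
        per_point_shifts=shifts if not one_dim else shifts[:, 0],
        unidentifiable=False,
        dims=dims,
    )


def aggregate_kd(per_residue) -> tuple[float, float, int]:
    """Mean and sample standard deviation of per-residue K_D estimates.

    Mirrors the convention of reporting a final K_D as the average over all
    selected signals with its standard deviation.  Returns ``(mean, std, n)``;
    std is NaN for a single estimate.  Non-finite entries are rejected
    (unidentifiable residues must be excluded upstream).
    """
    vals = np.asarray(list(per_residue), dtype=float)
    if vals.size == 0:
        raise ValueError("no K_D estimates to aggregate")
    if not np.all(np.isfinite(vals)):
        raise ValueError("K_D estimates must be finite")
    mean = float(np.mean(vals))
    std = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
    return mean, std, int(vals.size)
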