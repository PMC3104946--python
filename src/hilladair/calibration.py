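"""Calibrating a Hill model against a given Adair-Klotz model.

At equilibrium the similarity ``delta_inf`` depends only on the
dissociation constants, so the Hill constant ``K0`` is chosen to maximize
it for a given ``(K_1, ..., K_h)``; the maximized value is ``delta_max``.
For time-dependent comparisons the remaining freedom in ``alpha`` is
fixed by matching the lifetime of the pure initial state in the two
models (``beta`` is then ``K0 * alpha``).

Parameter-space maps evaluate ``delta_max`` on 2-D grids — over pairs of
stepwise constants or over ``(K1, xi)`` with the geometric cooperativity
parameterization ``K_i = K1 / xi^(i-1)`` — and extract level-set
boundaries of the safe-substitution region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
from skimage import measure

from .master_equation import (
    AdairRates,
    HillRates,
    build_generator,
    stationary_distribution,
)
from .similarity import main_similarity
from .state_space import (
    build_common_state_map,
    enumerate_adair_space,
    enumerate_hill_space,
)

__all__ = [
    "CalibrationResult",
    "ScanAxis",
    "ScanGrid",
    "PeakResult",
    "delta_infinity",
    "optimize_K0",
    "match_alpha",
    "calibrate_hill",
    "xi_parameterization",
    "delta_max_grid",
    "boundary_at_level",
    "hill_dose_response",
    "peak_time",
]

_LOG_K0_LO, _LOG_K0_HI, _PRESCAN_POINTS = -6.0, 6.0, 61
_GOLDEN = (np.sqrt(5) - 1) / 2


@dataclass(frozen=True)
class CalibrationResult:
    """Optimized Hill parameters for a given Adair-Klotz model.

    ``alpha`` and ``beta`` are filled only when the initial-state
    lifetime rule has been applied (time-dependent calibration);
    ``flat_objective`` flags a K0 scan on which the equilibrium
    similarity was constant, in which case ``K0_opt`` is the scan-range
    midpoint by convention.
    """

    K0_opt: float
    delta_max: float
    alpha: float | None = None
    beta: float | None = None
    flat_objective: bool = False


def _equilibrium_setup(h: int, P0: int, L0: int, K_list: Sequence[float]):
    K_list = tuple(float(k) for k in K_list)
    if len(K_list) != h:
        raise ValueError(f"expected {h} dissociation constants, got {len(K_list)}")
    if any(k <= 0 for k in K_list):
        raise ValueError("dissociation constants must be positive")
    hill_space = enumerate_hill_space(h, P0, L0)
    adair_space = enumerate_adair_space(h, P0, L0)
    cmap = build_common_state_map(hill_space, adair_space)
    pi_adair = stationary_distribution(
        build_generator(adair_space, AdairRates.from_Ks(K_list))
    )
    return hill_space, cmap, pi_adair


def _hill_equilibrium_delta(hill_space, cmap, pi_adair, K0: float) -> float:
    pi_hill = stationary_distribution(
        build_generator(hill_space, HillRates(alpha=1.0, beta=K0))
    )
    return main_similarity(pi_hill, pi_adair, cmap)


def delta_infinity(h: int, P0: int, L0: int, K0: float, K_list: Sequence[float]) -> float:
    """Equilibrium similarity for given Hill and Adair-Klotz constants.

    Both models are built with unit forward rates and back rates set by
    the dissociation constants; the stationary distributions do not
    depend on this overall rate scale.
    """
    if not K0 > 0:
        raise ValueError("K0 must be positive")
    hill_space, cmap, pi_adair = _equilibrium_setup(h, P0, L0, K_list)
    return _hill_equilibrium_delta(hill_space, cmap, pi_adair, K0)


def optimize_K0(
    h: int, P0: int, L0: int, K_list: Sequence[float], rel_tol: float = 1e-8
) -> CalibrationResult:
    """Maximize the equilibrium similarity over the Hill constant K0.

    A coarse log-spaced pre-scan over K0 in [1e-6, 1e6] brackets the
    maximum (guarding against local maxima), then golden-section search
    on log10(K0) refines it to the requested relative tolerance.
    """
    hill_space, cmap, pi_adair = _equilibrium_setup(h, P0, L0, K_list)

    def objective(log_k0: float) -> float:
        return _hill_equilibrium_delta(hill_space, cmap, pi_adair, 10.0**log_k0)

    grid = np.linspace(_LOG_K0_LO, _LOG_K0_HI, _PRESCAN_POINTS)
    values = np.array([objective(x) for x in grid])
    if values.max() - values.min() < 1e-13:
        mid = 10.0 ** ((_LOG_K0_LO + _LOG_K0_HI) / 2)
        return CalibrationResult(mid, float(values[0]), flat_objective=True)
    best = int(np.argmax(values))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]

    # golden-section maximization on log10(K0)
    xtol = rel_tol / np.log(10)
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = objective(c), objective(d)
    while (b - a) > xtol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = objective(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = objective(d)
    log_k0 = (a + b) / 2
    return CalibrationResult(float(10.0**log_k0), float(objective(log_k0)))


def match_alpha(adair_rates: AdairRates, h: int, P0: int, L0: int) -> float:
    """Hill forward rate equating the pure initial state's lifetime.

    The initial-state escape rates are ``alpha * P0 * C(L0, h)`` (Hill)
    and ``alpha_1 * P0 * L0`` (Adair-Klotz), giving
    ``alpha = alpha_1 * L0 / C(L0, h)`` independently of P0.
    """
    if adair_rates.h != h:
        raise ValueError("rates define a different number of binding steps")
    if L0 < h:
        raise ValueError(
            f"L0={L0} < h={h}: the Hill model has no forward reaction to match"
        )
    return adair_rates.alphas[0] * L0 / comb(L0, h)


def calibrate_hill(adair_rates: AdairRates, P0: int, L0: int) -> CalibrationResult:
    """Full time-dependent calibration: optimized K0 plus matched alpha.

    ``beta`` is set to ``K0_opt * alpha``.
    """
    h = adair_rates.h
    result = optimize_K0(h, P0, L0, adair_rates.Ks)
    alpha = match_alpha(adair_rates, h, P0, L0)
    return CalibrationResult(
        result.K0_opt,
        result.delta_max,
        alpha=alpha,
        beta=result.K0_opt * alpha,
        flat_objective=result.flat_objective,
    )


def xi_parameterization(K1: float, xi: float, h: int) -> tuple[float, ...]:
    """Geometric cooperativity ladder ``K_i = K1 / xi^(i-1)``.

    ``xi >> 1`` encodes strong cooperativity (each binding step much more
    favourable than the last); ``xi = 1`` gives equal constants.
    """
    if not K1 > 0 or not xi > 0:
        raise ValueError("K1 and xi must be positive")
    return tuple(K1 / xi ** (i - 1) for i in range(1, h + 1))


@dataclass(frozen=True)
class ScanAxis:
    """One scan dimension: parameter name and grid values."""

    name: str  # "K1", "K2", "K3", "K4" or "xi"
    values: np.ndarray

    @classmethod
    def log(cls, name: str, lo: float, hi: float, n: int) -> "ScanAxis":
        return cls(name, np.logspace(np.log10(lo), np.log10(hi), n))


@dataclass(frozen=True)
class ScanGrid:
    """delta_max evaluated over a 2-D parameter grid.

    ``delta_max[i, j]`` corresponds to ``x_axis.values[i]`` and
    ``y_axis.values[j]``; grid points whose per-point optimization failed
    hold NaN and are listed in ``failures``.
    """

    h: int
    P0: int
    L0: int
    x_axis: ScanAxis
    y_axis: ScanAxis
    fixed: dict[str, float]
    delta_max: np.ndarray
    K0_opt: np.ndarray
    failures: tuple[tuple[int, int, str], ...] = field(default_factory=tuple)


def _k_list_for_point(h: int, x_axis: str, x: float, y_axis: str, y: float, fixed: dict) -> tuple[float, ...]:
    params = dict(fixed)
    params[x_axis] = x
    params[y_axis] = y
    if "xi" in params:
        return xi_parameterization(params["K1"], params["xi"], h)
    try:
        return tuple(params[f"K{i}"] for i in range(1, h + 1))
    except KeyError as exc:
        raise ValueError(f"missing dissociation constant {exc} for h={h}") from exc


def delta_max_grid(
    h: int,
    P0: int,
    L0: int,
    x_axis: ScanAxis,
    y_axis: ScanAxis,
    fixed: dict[str, float] | None = None,
) -> ScanGrid:
    """Evaluate the K0-optimized equilibrium similarity on a 2-D grid.

    Traversal is row-major over (x, y); each point is an independent
    :func:`optimize_K0` call, so any cell reproduces a direct call
    bit-identically.  Per-point failures are recorded, not fatal.
    """
    fixed = dict(fixed or {})
    nx, ny = len(x_axis.values), len(y_axis.values)
    dmax = np.full((nx, ny), np.nan)
    k0 = np.full((nx, ny), np.nan)
    failures: list[tuple[int, int, str]] = []
    for i, x in enumerate(x_axis.values):
        for j, y in enumerate(y_axis.values):
            try:
                Ks = _k_list_for_point(h, x_axis.name, float(x), y_axis.name, float(y), fixed)
                res = optimize_K0(h, P0, L0, Ks)
                dmax[i, j] = res.delta_max
                k0[i, j] = res.K0_opt
            except (ValueError, RuntimeError, FloatingPointError) as exc:
                failures.append((i, j, str(exc)))
    return ScanGrid(h, P0, L0, x_axis, y_axis, fixed, dmax, k0, tuple(failures))


def boundary_at_level(grid: ScanGrid, level: float = 0.9) -> list[np.ndarray]:
    """Level-set boundaries of ``delta_max = level`` in axis coordinates.

    Marching-squares contours with linear interpolation between grid
    nodes; fractional grid indices are mapped onto the axes by
    interpolating in log10 of the axis values (the scan axes are
    log-spaced).  Returns one ``(n_points, 2)`` array of ``(x, y)``
    vertices per boundary; empty list if the level is outside the data
    range.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    data = grid.delta_max
    finite = data[np.isfinite(data)]
    if finite.size == 0 or level <= finite.min() or level >= finite.max():
        return []
    contours = measure.find_contours(data, level)
    lx = np.log10(grid.x_axis.values)
    ly = np.log10(grid.y_axis.values)
    out = []
    for c in contours:
        x = 10.0 ** np.interp(c[:, 0], np.arange(len(lx)), lx)
        y = 10.0 ** np.interp(c[:, 1], np.arange(len(ly)), ly)
        out.append(np.column_stack([x, y]))
    return out


def hill_dose_response(a: float, K0: float, h: int) -> float:
    """Fraction of ligand-bound protein at free-ligand amount ``a``.

    ``phi = a^h / (K0 + a^h)``: zero at ``a = 0``, one half where
    ``a^h = K0``, saturating at one.
    """
    if a < 0:
        raise ValueError("ligand amount must be non-negative")
    ah = float(a) ** h
    return ah / (K0 + ah)


@dataclass(frozen=True)
class PeakResult:
    """Location of a series maximum; ``interior`` is False at a grid edge."""

    time: float
    value: float
    interior: bool


def peak_time(times: Sequence[float], values: Sequence[float]) -> PeakResult:
    """First interior maximum of a sampled time series.

    Finds the first index that is a local maximum (strictly above its
    right neighbour, not below its left), falling back to the global
    argmax, and refines the location by parabolic interpolation through
    the three surrounding points.  A maximum on the grid edge is returned
    with ``interior=False`` and no refinement.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    peak = None
    for i in range(1, len(v) - 1):
        if v[i] >= v[i - 1] and v[i] > v[i + 1]:
            peak = i
            break
    if peak is None:
        peak = int(np.argmax(v))
    if peak == 0 or peak == len(v) - 1:
        return PeakResult(float(t[peak]), float(v[peak]), interior=False)
    # parabola through (t[i-1..i+1], v[i-1..i+1])
    coeffs = np.polyfit(t[peak - 1 : peak + 2], v[peak - 1 : peak + 2], 2)
    if coeffs[0] < 0:
        t_star = -coeffs[1] / (2 * coeffs[0])
        v_star = np.polyval(coeffs, t_star)
    else:  # degenerate (flat) neighbourhood
        t_star, v_star = t[peak], v[peak]
    return PeakResult(float(t_star), float(v_star), interior=True)
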