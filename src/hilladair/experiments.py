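"""Runnable experiments: time courses, equilibrium scans, backend checks.

These drivers tie the state-space, master-equation, similarity and
calibration layers into reproducible runs.  CSV files are the canonical
outputs; every run writes a JSON sidecar with the fully resolved
configuration so any output can be regenerated exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    ScanAxis,
    boundary_at_level,
    calibrate_hill,
    delta_max_grid,
)
from .master_equation import (
    AdairRates,
    HillRates,
    build_generator,
    evolve,
    evolve_laplace_durbin,
    simulate_ssa,
)
from .similarity import similarity_trajectory
from .state_space import (
    build_common_state_map,
    enumerate_adair_space,
    enumerate_hill_space,
    initial_distribution,
)

__all__ = [
    "TimecourseConfig",
    "ScanConfig",
    "BackendReport",
    "run_timecourse",
    "run_scan",
    "validate_backends",
    "load_config",
]

logger = logging.getLogger("hilladair")


@dataclass
class TimecourseConfig:
    """Configuration of a similarity time-course run.

    The Adair-Klotz model is specified by per-step rates; the Hill
    partner is auto-calibrated (K0 optimization + lifetime-matched
    alpha) unless ``alpha``/``beta`` are given explicitly.
    """

    h: int
    P0: int
    L0: int
    alphas: tuple[float, ...]
    betas: tuple[float, ...]
    t_max: float = 2.0
    t_points: int = 401
    alpha: float | None = None
    beta: float | None = None
    backend: str = "expm"  # or "durbin"
    out: str = "timecourse.csv"
    distributions_out: str | None = None

    def __post_init__(self) -> None:
        if self.h < 1:
            raise ValueError("h must be >= 1")
        if len(self.alphas) != self.h or len(self.betas) != self.h:
            raise ValueError(f"need exactly h={self.h} forward and back rates")
        if self.t_max <= 0 or self.t_points < 2:
            raise ValueError("time grid must have t_max > 0 and >= 2 points")
        if self.backend not in ("expm", "durbin"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if (self.alpha is None) != (self.beta is None):
            raise ValueError("give both alpha and beta, or neither")

    @property
    def adair_rates(self) -> AdairRates:
        return AdairRates(tuple(self.alphas), tuple(self.betas))

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.t_max, self.t_points)


@dataclass
class ScanConfig:
    """Configuration of a delta_max parameter-space scan."""

    h: int
    P0: int
    L0: int
    x_name: str
    x_lo: float
    x_hi: float
    x_points: int
    y_name: str
    y_lo: float
    y_hi: float
    y_points: int
    fixed: dict[str, float] = field(default_factory=dict)
    level: float = 0.9
    out: str = "scan.csv"
    boundary_out: str | None = None

    def axes(self) -> tuple[ScanAxis, ScanAxis]:
        return (
            ScanAxis.log(self.x_name, self.x_lo, self.x_hi, self.x_points),
            ScanAxis.log(self.y_name, self.y_lo, self.y_hi, self.y_points),
        )


def _write_sidecar(path: str | Path, config, extra: dict | None = None) -> None:
    meta = {"config": asdict(config), "version": __version__}
    if extra:
        meta.update(extra)
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def _solve(backend: str, Q, p0, times):
    if backend == "durbin":
        return evolve_laplace_durbin(Q, p0, times)
    return evolve(Q, p0, times)


def _build_problem(config: TimecourseConfig):
    hill_space = enumerate_hill_space(config.h, config.P0, config.L0)
    adair_space = enumerate_adair_space(config.h, config.P0, config.L0)
    cmap = build_common_state_map(hill_space, adair_space)
    logger.info(
        "enumerated spaces: |S_H|=%d, |S_A|=%d, complement=%d",
        len(hill_space),
        len(adair_space),
        len(cmap.complement_indices),
    )
    if config.alpha is not None:
        hill_rates = HillRates(config.alpha, config.beta)
    else:
        cal = calibrate_hill(config.adair_rates, config.P0, config.L0)
        hill_rates = HillRates(cal.alpha, cal.beta)
        logger.info(
            "calibrated Hill model: K0=%.6g, alpha=%.6g /s, beta=%.6g /s, delta_max=%.6g",
            cal.K0_opt,
            cal.alpha,
            cal.beta,
            cal.delta_max,
        )
    return hill_space, adair_space, cmap, hill_rates


def run_timecourse(config: TimecourseConfig) -> pd.DataFrame:
    """Compute and write the (t, delta, delta_bar, delta_tilde) table."""
    hill_space, adair_space, cmap, hill_rates = _build_problem(config)
    times = config.times
    hill_traj = _solve(
        config.backend,
        build_generator(hill_space, hill_rates),
        initial_distribution(hill_space),
        times,
    )
    adair_traj = _solve(
        config.backend,
        build_generator(adair_space, config.adair_rates),
        initial_distribution(adair_space),
        times,
    )
    sim = similarity_trajectory(hill_traj, adair_traj, cmap)
    table = pd.DataFrame(
        {
            "time": sim.times,
            "delta": sim.delta,
            "delta_bar": sim.delta_bar,
            "delta_tilde": sim.delta_tilde,
        }
    )
    table.to_csv(config.out, index=False, lineterminator="\r\n")
    _write_sidecar(
        config.out,
        config,
        {"hill_alpha": hill_rates.alpha, "hill_beta": hill_rates.beta, "hill_K0": hill_rates.K0},
    )
    if config.distributions_out:
        dist = pd.DataFrame(
            adair_traj.distributions,
            columns=[str(s) for s in adair_space.states],
        )
        dist.insert(0, "time", times)
        dist.to_csv(config.distributions_out, index=False, lineterminator="\r\n")
    logger.info("wrote %s (%d time points)", config.out, len(times))
    return table


def run_scan(config: ScanConfig) -> pd.DataFrame:
    """Evaluate a delta_max grid, write it and its level boundaries."""
    x_axis, y_axis = config.axes()
    grid = delta_max_grid(config.h, config.P0, config.L0, x_axis, y_axis, config.fixed)
    rows = []
    for i, x in enumerate(x_axis.values):
        for j, y in enumerate(y_axis.values):
            rows.append(
                {
                    x_axis.name: x,
                    y_axis.name: y,
                    "K0_opt": grid.K0_opt[i, j],
                    "delta_max": grid.delta_max[i, j],
                }
            )
        logger.info("scan row %d/%d done", i + 1, len(x_axis.values))
    table = pd.DataFrame(rows)
    table.to_csv(config.out, index=False, lineterminator="\r\n")
    _write_sidecar(config.out, config, {"n_failures": len(grid.failures)})
    if config.boundary_out:
        segments = boundary_at_level(grid, config.level)
        brows = []
        for seg_id, seg in enumerate(segments):
            for x, y in seg:
                brows.append({"x": x, "y": y, "segment_id": seg_id})
        pd.DataFrame(brows, columns=["x", "y", "segment_id"]).to_csv(
            config.boundary_out, index=False, lineterminator="\r\n"
        )
    return table


@dataclass(frozen=True)
class BackendReport:
    """Cross-validation of the master-equation solution backends."""

    max_rel_expm_durbin: float
    ssa_total_variation: float | None
    passed: bool


def validate_backends(
    config: TimecourseConfig,
    ssa_replicates: int = 0,
    seed: int = 0,
    rel_tol: float = 0.01,
) -> BackendReport:
    """Compare expm against the Durbin Laplace backend (and optionally SSA).

    The run fails if any state with probability above 1e-6 differs by
    more than ``rel_tol`` (default the 1% convergence rule) between the
    two deterministic backends.  If ``ssa_replicates > 0``, a Gillespie
    estimate of the Adair-Klotz distribution at the final time is
    compared by total-variation distance (reported, not gated: it is
    Monte-Carlo limited).
    """
    _, adair_space, _, _ = _build_problem(config)
    Q = build_generator(adair_space, config.adair_rates)
    p0 = initial_distribution(adair_space)
    times = config.times[1:]  # skip t=0 (both backends return p0 exactly)
    ref = evolve(Q, p0, times)
    alt = evolve_laplace_durbin(Q, p0, times)
    scale = np.maximum(ref.distributions, 1e-6)
    mask = ref.distributions > 1e-6
    rel = np.abs(alt.distributions - ref.distributions) / scale
    max_rel = float(rel[mask].max()) if mask.any() else 0.0
    tv = None
    if ssa_replicates > 0:
        emp = simulate_ssa(
            adair_space, config.adair_rates, p0, float(times[-1]), ssa_replicates, seed
        )
        tv = float(0.5 * np.abs(emp - ref.distributions[-1]).sum())
    passed = max_rel <= rel_tol
    logger.info(
        "backend validation: max relative expm-vs-Durbin discrepancy %.3g (%s)",
        max_rel,
        "pass" if passed else "FAIL",
    )
    return BackendReport(max_rel, tv, passed)


_CONFIG_KINDS = {"timecourse": TimecourseConfig, "scan": ScanConfig}


def load_config(path: str | Path):
    """Load a flat YAML config; the ``command`` key selects the run type."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kind = raw.pop("command", "timecourse")
    if kind not in _CONFIG_KINDS:
        raise ValueError(f"unknown command {kind!r}")
    cls = _CONFIG_KINDS[kind]
    for key in ("alphas", "betas"):
        if key in raw:
            raw[key] = tuple(raw[key])
    try:
        return cls(**raw)
    except TypeError as exc:
        raise ValueError(f"invalid config for {kind}: {exc}") from exc
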