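"""Ordered parameter-space exploration by variance maximization.

The biophysical parameters are fitted per subject by exhaustive grid
sweeps that maximize the variance of the simulated BOLD signal (mean
over regions of each region's temporal variance).  The staged order is:

1. joint sweep of long-range coupling G and conduction velocity v
   (ranges 0.001–0.1 and 1–100),
2. K12 (excitatory→inhibitory, range 0–1) at the fitted (G, v),
3. K21 (inhibitory→excitatory) at the fitted K12,
4. K11 (excitatory→excitatory).

Each stage fixes all previously fitted values.  The objective in each
grid cell is averaged over ``seeds_per_cell`` replicate noise seeds;
cells whose simulation diverges are recorded as NaN and excluded from
the argmax.  Ties break toward the smallest parameter value
(lexicographically for joint grids) for reproducibility.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .connectome import StructuralConnectome
from .simulator import (
    BOLDSeries,
    IntegrationDivergenceError,
    SimulationConfig,
    simulate_bold,
    simulate_neural,
)

logger = logging.getLogger("neuromass")

__all__ = [
    "ParameterMap",
    "FittedParameters",
    "ExplorationGridSpec",
    "variance_objective",
    "sweep",
    "fit_subject",
    "PARAM_RANGES",
]

PARAM_RANGES = {
    "G": (0.001, 0.1),
    "v": (1.0, 100.0),
    "K11": (0.0, 1.0),
    "K12": (0.0, 1.0),
    "K21": (0.0, 1.0),
}

_SIM_PARAMS = ("G", "v")
_LOCAL_PARAMS = ("K11", "K12", "K21")


def variance_objective(bold: BOLDSeries, *, on: str = "bold",
                       neural: np.ndarray | None = None) -> float:
    """Mean over regions of the unbiased temporal variance.

    ``on='neural'`` with a raw trajectory computes the same statistic on
    the neural signal instead (config switch; BOLD is the default).
    """
    if on == "neural":
        if neural is None:
            raise ValueError("neural trajectory required for on='neural'")
        data = np.asarray(neural, dtype=float).T
    else:
        data = bold.data
    if data.shape[1] < 2:
        raise ValueError("variance objective needs at least 2 time points")
    return float(np.mean(np.var(data, axis=1, ddof=1)))


@dataclass
class ParameterMap:
    """Grid of explored values with the variance objective per cell."""

    param_names: list[str]
    grid_values: list[np.ndarray]
    objective: np.ndarray
    argmax: tuple
    seeds_per_cell: int

    def argmax_indices(self) -> tuple:
        valid = np.where(np.isnan(self.objective), -np.inf, self.objective)
        flat = int(np.argmax(valid))  # first occurrence = smallest params
        return np.unravel_index(flat, self.objective.shape)

    def to_dict(self) -> dict:
        return {
            "param_names": list(self.param_names),
            "grid_values": [list(map(float, g)) for g in self.grid_values],
            "objective": self.objective.tolist(),
            "argmax": [float(a) for a in self.argmax],
            "seeds_per_cell": self.seeds_per_cell,
        }


@dataclass
class FittedParameters:
    """Per-subject fitted biophysical parameters with stage provenance."""

    subject_id: str
    G: float
    v: float
    K12: float
    K21: float
    K11: float
    stages: dict = field(default_factory=dict)  # name -> ParameterMap

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "G": self.G,
            "v": self.v,
            "K12": self.K12,
            "K21": self.K21,
            "K11": self.K11,
            "stages": {k: m.to_dict() for k, m in self.stages.items()},
        }


def _with_params(config: SimulationConfig, assignment: dict) -> SimulationConfig:
    sim_kw = {k: v for k, v in assignment.items() if k in _SIM_PARAMS}
    loc_kw = {k: v for k, v in assignment.items() if k in _LOCAL_PARAMS}
    cfg = config
    if loc_kw:
        params = cfg.params
        d = params.to_dict()
        d.update(loc_kw)
        cfg = cfg.replace(params=type(params).from_dict(d))
    if sim_kw:
        cfg = cfg.replace(**sim_kw)
    return cfg


def _cell_seed(base_seed: int, cell: tuple, rep: int) -> int:
    ss = np.random.SeedSequence(entropy=int(base_seed),
                                spawn_key=tuple(int(i) for i in cell) + (rep,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def sweep(
    c: StructuralConnectome,
    base_config: SimulationConfig,
    param_specs: list[tuple],
    seeds_per_cell: int = 3,
    *,
    objective_on: str = "bold",
    cache: dict | None = None,
) -> ParameterMap:
    """Exhaustively evaluate a 1-D or 2-D parameter grid.

    ``param_specs`` is a list of up to two ``(name, (lo, hi), n_points)``
    tuples.  Cell seeds are a pure function of (config seed, cell
    indices, replicate), so the objective matrix is independent of
    evaluation order; ``cache`` (a dict) makes repeated sweeps
    resumable, keyed by (connectome id, config hash, cell, replicate).
    """
    if not 1 <= len(param_specs) <= 2:
        raise ValueError("sweep supports 1 or 2 parameters")
    names = [s[0] for s in param_specs]
    for name in names:
        if name not in PARAM_RANGES:
            raise ValueError(f"unknown parameter {name!r}")
    grids = [np.linspace(s[1][0], s[1][1], s[2]) for s in param_specs]
    shape = tuple(len(g) for g in grids)
    objective = np.full(shape, np.nan)
    base_hash = base_config.config_hash()
    for cell in itertools.product(*(range(k) for k in shape)):
        assignment = {names[d]: float(grids[d][cell[d]]) for d in range(len(names))}
        vals = []
        diverged = False
        for rep in range(seeds_per_cell):
            key = (c.subject_id, base_hash, cell, rep)
            if cache is not None and key in cache:
                vals.append(cache[key])
                continue
            seed = _cell_seed(base_config.seed, cell, rep)
            cfg = _with_params(base_config, assignment).replace(seed=seed)
            try:
                if objective_on == "neural":
                    neural = simulate_neural(c, cfg)
                    val = variance_objective(None, on="neural", neural=neural)
                else:
                    val = variance_objective(simulate_bold(c, cfg))
            except IntegrationDivergenceError as exc:
                logger.warning("cell %s diverged (%s); marked invalid", cell, exc)
                diverged = True
                break
            if cache is not None:
                cache[key] = val
            vals.append(val)
        if not diverged and vals:
            objective[cell] = float(np.mean(vals))
    if np.all(np.isnan(objective)):
        raise RuntimeError(
            f"all cells of the {'x'.join(names)} sweep diverged"
        )
    valid = np.where(np.isnan(objective), -np.inf, objective)
    best = np.unravel_index(int(np.argmax(valid)), shape)
    argmax = tuple(float(grids[d][best[d]]) for d in range(len(names)))
    return ParameterMap(
        param_names=names,
        grid_values=grids,
        objective=objective,
        argmax=argmax,
        seeds_per_cell=seeds_per_cell,
    )


@dataclass
class ExplorationGridSpec:
    """Grid sizes and ranges for the staged fit.

    ``n_points`` applies per axis (the joint (G, v) stage is
    ``n_points x n_points``).  ``stage_duration_s``, when set, runs the
    sweeps at a reduced simulated duration (scaled exploration mode);
    the returned fitted values are unaffected in meaning.
    """

    n_points: int = 10
    seeds_per_cell: int = 3
    ranges: dict = field(default_factory=lambda: dict(PARAM_RANGES))
    n_points_by_param: dict = field(default_factory=dict)
    stage_duration_s: float | None = None

    def points(self, name: str) -> int:
        return int(self.n_points_by_param.get(name, self.n_points))


def fit_subject(
    c: StructuralConnectome,
    base_config: SimulationConfig,
    grid_spec: ExplorationGridSpec | None = None,
    *,
    objective_on: str = "bold",
    cache: dict | None = None,
) -> FittedParameters:
    """Run the full staged exploration for one subject.

    Stage order is fixed: joint (G, v), then K12, then K21, then K11,
    each at the previously fitted values.  Raises if any stage has no
    valid cell, naming the stage.
    """
    spec = grid_spec or ExplorationGridSpec()
    cfg = base_config
    if spec.stage_duration_s is not None:
        cfg = cfg.replace(duration_s=float(spec.stage_duration_s))
    stages: dict = {}

    def run_stage(stage_name: str, specs: list[tuple], current: SimulationConfig):
        try:
            return sweep(c, current, specs, spec.seeds_per_cell,
                         objective_on=objective_on, cache=cache)
        except RuntimeError as exc:
            raise RuntimeError(f"stage {stage_name}: {exc}") from exc

    gv_specs = [
        ("G", spec.ranges["G"], spec.points("G")),
        ("v", spec.ranges["v"], spec.points("v")),
    ]
    m_gv = run_stage("(G,v)", gv_specs, cfg)
    g_fit, v_fit = m_gv.argmax
    stages["(G,v)"] = m_gv
    cfg = _with_params(cfg, {"G": g_fit, "v": v_fit})

    fitted_k = {}
    for name in ("K12", "K21", "K11"):
        m = run_stage(name, [(name, spec.ranges[name], spec.points(name))], cfg)
        fitted_k[name] = m.argmax[0]
        stages[name] = m
        cfg = _with_params(cfg, {name: fitted_k[name]})

    logger.info(
        "fitted %s: G=%.4g v=%.4g K12=%.3g K21=%.3g K11=%.3g",
        c.subject_id, g_fit, v_fit,
        fitted_k["K12"], fitted_k["K21"], fitted_k["K11"],
    )
    return FittedParameters(
        subject_id=c.subject_id,
        G=g_fit,
        v=v_fit,
        K12=fitted_k["K12"],
        K21=fitted_k["K21"],
        K11=fitted_k["K11"],
        stages=stages,
    )
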