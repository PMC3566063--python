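"""Voltage-trace fitness and exhaustive grid search for the PG cell.

The error between a target voltage trace and a model trace is the
root-mean-square difference

    error = sqrt( (1/N) * sum_i (V_target,i - V_model,i)^2 )

and the region-weighted fitness places per-sample weights inside the sum,
before the root:

    fitness = sqrt( (1/N) * sum_i w(t_i) * (V_target,i - V_model,i)^2 )

so uniform weights w = c scale the plain error by sqrt(c).  The weight
schedule partitions the simulated window into intervals that emphasise
the features a fit must reproduce: the spike window (weight 10), the
injected period after the spike whose plateau level matters (weight 5),
and the no-injection periods (weight 1).

The search itself is a plain exhaustive scan over a per-parameter grid of
the five conductance densities plus the autapse conductance, evaluated in
deterministic lexicographic order (ties keep the first minimum).  A
combination whose simulation blows up numerically scores infinity and the
scan continues.  Because the experimental recording behind the original
fit is not distributable, targets are synthesized from the model itself
with known ("planted") parameters, optionally with seeded Gaussian noise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cable import NumericalBlowupError, VoltageTrace
from .cells import PGParameters, load_pg_parameters
from .experiments import detect_spikes, pg_step_response

__all__ = [
    "TargetTrace",
    "WeightSchedule",
    "SearchSpace",
    "FitResult",
    "rms_error",
    "weighted_fitness",
    "default_weight_schedule",
    "grid_search",
    "synthesize_target",
]

#: default step protocol of the fit: 100 pA at the soma for 600 ms from
#: 200 ms, 1000 ms simulated.
FIT_PROTOCOL = {"amplitude": 0.1, "onset": 200.0, "duration": 600.0, "t_stop": 1000.0}

#: grid-search parameter names: the five conductance columns (densities,
#: S/cm^2) plus the autapse maximum conductance (uS).
PARAMETER_NAMES = ("H", "K", "Na", "KA", "CaT", "autapse")


@dataclass(frozen=True)
class TargetTrace:
    """A target voltage trace (same sampling convention as VoltageTrace)."""

    times: np.ndarray
    v: np.ndarray
    provenance: str = "synthetic"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.v):
            raise ValueError("times and v must have equal length")


class ScheduleError(ValueError):
    """A sample time falls outside every weight interval."""


class AlignmentError(ValueError):
    """Target and model traces are not sampled identically."""


@dataclass(frozen=True)
class WeightSchedule:
    """Per-interval weights over a simulation of length ``t_total``.

    ``intervals`` is a sequence of (t_start, t_end, weight) tuples that
    must partition [0, t_total] (contiguous, in order).
    """

    intervals: tuple[tuple[float, float, float], ...]
    t_total: float

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("empty weight schedule")
        cursor = 0.0
        for lo, hi, w in self.intervals:
            if not math.isclose(lo, cursor, abs_tol=1e-9):
                raise ValueError("weight intervals must partition [0, T] contiguously")
            if hi <= lo:
                raise ValueError("weight interval must have positive length")
            if w <= 0:
                raise ValueError("weights must be positive")
            cursor = hi
        if not math.isclose(cursor, self.t_total, abs_tol=1e-9):
            raise ValueError("weight intervals must cover [0, T]")

    def weights_for(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        out = np.full(times.shape, np.nan)
        for lo, hi, w in self.intervals:
            mask = (times >= lo - 1e-9) & (times < hi - 1e-9)
            out[mask] = w
        # close the right edge of the last interval
        out[np.isclose(times, self.t_total)] = self.intervals[-1][2]
        if np.any(np.isnan(out)):
            raise ScheduleError("sample time outside every weight interval")
        return out


def _model_v(model: VoltageTrace | TargetTrace) -> np.ndarray:
    if isinstance(model, VoltageTrace):
        return model[model.labels[0]]
    return np.asarray(model.v, dtype=float)


def _check_aligned(target: TargetTrace, model) -> tuple[np.ndarray, np.ndarray]:
    v_m = _model_v(model)
    if len(v_m) != len(target.v):
        raise AlignmentError(
            f"trace length mismatch: target {len(target.v)}, model {len(v_m)}"
        )
    return np.asarray(target.v, dtype=float), v_m


def rms_error(target: TargetTrace, model: VoltageTrace | TargetTrace) -> float:
    """Root-mean-square voltage difference over all N aligned samples."""
    v_t, v_m = _check_aligned(target, model)
    return float(np.sqrt(np.mean((v_t - v_m) ** 2)))


def weighted_fitness(
    target: TargetTrace,
    model: VoltageTrace | TargetTrace,
    weights: WeightSchedule,
) -> float:
    """Region-weighted RMS difference (weights inside the sum, before the
    root)."""
    v_t, v_m = _check_aligned(target, model)
    w = weights.weights_for(target.times)
    return float(np.sqrt(np.mean(w * (v_t - v_m) ** 2)))


def default_weight_schedule(
    target: TargetTrace,
    onset: float = FIT_PROTOCOL["onset"],
    duration: float = FIT_PROTOCOL["duration"],
    t_total: float = FIT_PROTOCOL["t_stop"],
    w_rest: float = 1.0,
    w_spike: float = 10.0,
    w_plateau: float = 5.0,
    spike_halfwidth: float = 5.0,
) -> WeightSchedule:
    """Weight schedule with the spike window auto-located around the
    target's spike peak (+-5 ms).  Injected time before the spike keeps the
    no-injection weight; the injected period after the spike carries the
    plateau weight."""
    spikes = detect_spikes((target.times, target.v))
    end = onset + duration
    if len(spikes) == 0:
        intervals = [(0.0, onset, w_rest), (onset, end, w_plateau),
                     (end, t_total, w_rest)]
    else:
        t_sp = float(spikes[0])
        lo = max(onset, t_sp - spike_halfwidth)
        hi = min(end, t_sp + spike_halfwidth)
        intervals = [(0.0, onset, w_rest)]
        if lo > onset:
            intervals.append((onset, lo, w_rest))
        intervals.append((lo, hi, w_spike))
        if end > hi:
            intervals.append((hi, end, w_plateau))
        intervals.append((end, t_total, w_rest))
    return WeightSchedule(tuple(intervals), t_total)


# ---------------------------------------------------------------------------
# search space and grid search


@dataclass(frozen=True)
class SearchSpace:
    """Per-parameter value grids (order follows :data:`PARAMETER_NAMES`;
    omitted parameters stay at the base value)."""

    grids: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        unknown = set(self.grids) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown search parameters: {sorted(unknown)}")
        for name, values in self.grids.items():
            if len(values) == 0:
                raise ValueError(f"empty grid for {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n in PARAMETER_NAMES if n in self.grids)

    @property
    def size(self) -> int:
        return int(np.prod([len(self.grids[n]) for n in self.names]))

    def combinations(self):
        names = self.names
        for values in itertools.product(*(self.grids[n] for n in names)):
            yield dict(zip(names, (float(v) for v in values)))

    @classmethod
    def centered(cls, base: PGParameters, factors: Sequence[float],
                 parameters: Sequence[str] = PARAMETER_NAMES) -> "SearchSpace":
        """Multiplicative grid around a base parameter set."""
        densities = base.densities
        grids = {}
        for name in parameters:
            center = base.autapse_gmax if name == "autapse" else densities[name]
            grids[name] = tuple(float(center * f) for f in factors)
        return cls(grids)


@dataclass(frozen=True)
class FitResult:
    best_parameters: dict[str, float]
    best_error: float
    table: pd.DataFrame  # one row per evaluated combination

    @property
    def n_evaluated(self) -> int:
        return len(self.table)


class _PGEvaluator:
    """Evaluate PG parameter combinations on a single prebuilt network.

    Only maximum conductances change between grid points, so the cell is
    assembled (and its gate kinetics tabulated) once; per combination the
    per-channel conductances and the autapse strength are rewritten in
    place.  This keeps an exhaustive 3^6 search at desk scale.
    """

    def __init__(self, base: PGParameters, protocol: Mapping | None = None,
                 dt: float = 0.05):
        from .cable import Network, SolverConfig, CurrentPulse
        from .cells import build_pg, pg_autapse

        self.base = base
        proto = dict(FIT_PROTOCOL)
        if protocol:
            proto.update(protocol)
        self.protocol = proto
        cell = build_pg(base)
        self.network = Network(cell, [pg_autapse(cell, base)])
        self.config = SolverConfig(dt=dt, t_stop=proto["t_stop"])
        self.pulses = [CurrentPulse((None, proto.get("target", "soma")),
                                    proto["amplitude"], proto["onset"],
                                    proto["duration"])]
        # channel index -> (column, area_cm2)
        self._chan_info = []
        idx = 0
        kind_to_col = {base.channel_map[c]: c for c in base.column_order}
        for comp_name, spec in cell.channels:
            area = cell.compartment(comp_name).area_cm2
            self._chan_info.append((idx, kind_to_col[spec.name], area))
            idx += 1
        self._base_densities = dict(base.densities)

    def run(self, combo: Mapping[str, float]):
        net = self.network
        dens = dict(self._base_densities)
        for name, value in combo.items():
            if name != "autapse":
                dens[name] = value
        gbar = net._channels[1]
        for i, column, area in self._chan_info:
            gbar[i] = dens[column] * area * 1e6
        if net._syn_static[2].size:
            net._syn_static[2][0] = combo.get("autapse", self.base.autapse_gmax)
        return net.run(self.config, self.pulses, record=[self.protocol.get("target", "soma")])


def _apply_combination(base: PGParameters, combo: Mapping[str, float]) -> PGParameters:
    p = base
    for name, value in combo.items():
        if name == "autapse":
            p = p.with_autapse(value)
        else:
            p = p.with_density(name, value)
    return p


def simulate_candidate(params: PGParameters, protocol: Mapping | None = None,
                       dt: float = 0.05) -> VoltageTrace:
    proto = dict(FIT_PROTOCOL)
    if protocol:
        proto.update(protocol)
    return pg_step_response(params, dt=dt, **proto)


def synthesize_target(
    params: PGParameters | None = None,
    protocol: Mapping | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dt: float = 0.05,
) -> TargetTrace:
    """Run the PG model with the given (planted) parameters and optionally
    add seeded Gaussian noise, recording provenance and seed."""
    if params is None:
        params = load_pg_parameters()
    trace = simulate_candidate(params, protocol, dt=dt)
    v = trace[trace.labels[0]].copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    return TargetTrace(
        times=trace.times,
        v=v,
        provenance="synthetic",
        metadata={"noise_sd": noise_sd, "seed": seed,
                  "protocol": dict(FIT_PROTOCOL, **(protocol or {}))},
    )


def evaluate_space(
    space: SearchSpace,
    base: PGParameters | None = None,
    protocol: Mapping | None = None,
    dt: float = 0.05,
) -> list[tuple[dict[str, float], VoltageTrace | None]]:
    """Simulate every combination of the space once, in lexicographic
    order.  The model traces do not depend on the fitting target, so a
    cached evaluation can be scored against many targets (e.g. repeated
    parameter-recovery runs); a combination whose simulation blows up is
    stored as None."""
    if base is None:
        base = load_pg_parameters()
    evaluator = _PGEvaluator(base, protocol, dt=dt)
    out = []
    for combo in space.combinations():
        try:
            trace = evaluator.run(combo)
        except NumericalBlowupError:
            trace = None
        out.append((combo, trace))
    return out


def grid_search(
    space: SearchSpace,
    target: TargetTrace,
    weights: WeightSchedule | None = None,
    base: PGParameters | None = None,
    protocol: Mapping | None = None,
    dt: float = 0.05,
    keep_table: bool = True,
    trace_cache: list[tuple[dict, VoltageTrace | None]] | None = None,
) -> FitResult:
    """Exhaustive scan of the search space against a target trace.

    Deterministic: combinations are evaluated in lexicographic order of
    the parameter grids and ties keep the earlier combination.  Passing a
    ``trace_cache`` from :func:`evaluate_space` skips re-simulating.
    """
    if base is None:
        base = load_pg_parameters()
    if weights is None:
        weights = default_weight_schedule(target)
    if space.size == 0:
        raise ValueError("empty search space")
    if trace_cache is None:
        trace_cache = evaluate_space(space, base, protocol, dt=dt)
    rows = []
    best_combo: dict[str, float] | None = None
    best_error = np.inf
    for combo, model in trace_cache:
        if model is None:
            error = np.inf
        else:
            error = weighted_fitness(target, model, weights)
        if keep_table:
            rows.append(dict(combo, error=error))
        if error < best_error:
            best_error = error
            best_combo = dict(combo)
    table = pd.DataFrame(rows) if keep_table else pd.DataFrame()
    return FitResult(best_parameters=best_combo, best_error=float(best_error),
                     table=table)
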