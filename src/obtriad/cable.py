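"""Multicompartment cells and the fixed-step implicit cable integrator.

A cell is a tree of isopotential cylindrical compartments; neighbouring
compartments are coupled through the series resistance of their two half
cylinders.  The coupled membrane equations are advanced with backward
Euler at a fixed step (default 0.05 ms): gating variables are updated
first by their exact exponential relaxation using the previous voltage,
then the voltages of all compartments are solved implicitly from the
tree-structured linear system.  The scheme is unconditionally stable and
first-order accurate in the step size.

Units convention (used throughout the package): mV, ms, nA, uS, nF;
geometry in um; densities in S/cm^2 and uF/cm^2; axial resistivity in
Ohm*cm.  All conversions happen in this module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .channels import (
    DEFAULT_TEMPERATURE_K,
    CalciumPool,
    ChannelSpec,
    FARADAY,
    GAS_CONSTANT,
    INSTANTANEOUS,
)
from .synapses import GradedSynapse

__all__ = [
    "CompartmentGeometry",
    "PassiveParameters",
    "CellModel",
    "SolverConfig",
    "SimulationState",
    "VoltageTrace",
    "CurrentPulse",
    "StructuralError",
    "NumericalBlowupError",
    "axial_coupling",
    "Network",
    "run",
]

UM2_TO_CM2 = 1e-8


class StructuralError(ValueError):
    """The compartment graph or a reference into it is invalid."""


class NumericalBlowupError(RuntimeError):
    """Voltage left the physical range; names the compartment and time."""


@dataclass(frozen=True)
class CompartmentGeometry:
    """A cylindrical isopotential compartment; ``parent`` wires the tree."""

    name: str
    length_um: float
    diameter_um: float
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.diameter_um <= 0:
            raise ValueError(f"compartment {self.name!r}: length and diameter must be > 0")

    @property
    def area_um2(self) -> float:
        """Lateral (side) surface area of the cylinder."""
        return math.pi * self.diameter_um * self.length_um

    @property
    def area_cm2(self) -> float:
        return self.area_um2 * UM2_TO_CM2

    def half_axial_resistance_MOhm(self, axial_resistivity: float) -> float:
        """Axial resistance of one half cylinder, in MOhm."""
        length_cm = self.length_um * 1e-4 / 2.0
        radius_cm = self.diameter_um * 1e-4 / 2.0
        r_ohm = axial_resistivity * length_cm / (math.pi * radius_cm**2)
        return r_ohm * 1e-6


@dataclass(frozen=True)
class PassiveParameters:
    """Passive membrane and cytoplasm parameters.

    The printed passive constants of the periglomerular cell are treated as
    calibration knobs (see docs/methods.md); defaults here are generic.
    """

    axial_resistivity: float = 150.0  # Ohm*cm
    specific_capacitance: float = 1.0  # uF/cm^2
    leak_conductance_density: float = 2.0e-4  # S/cm^2
    leak_reversal: float = -65.0  # mV
    resting_potential: float = -65.0  # mV

    def __post_init__(self) -> None:
        if self.axial_resistivity <= 0:
            raise ValueError("axial_resistivity must be > 0")
        if self.specific_capacitance < 0 or self.leak_conductance_density < 0:
            raise ValueError("capacitance and conductance densities must be >= 0")


@dataclass(frozen=True)
class SolverConfig:
    dt: float = 0.05  # ms
    t_stop: float = 1000.0  # ms
    scheme: str = "implicit-euler"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_stop < self.dt:
            raise ValueError("t_stop must be >= dt")
        if self.scheme != "implicit-euler":
            raise ValueError("only the implicit-euler scheme is implemented")

    @property
    def nsteps(self) -> int:
        return int(round(self.t_stop / self.dt))


@dataclass(frozen=True)
class CurrentPulse:
    """A rectangular current step.  ``target`` is (cell, compartment); the
    cell part may be None for single-cell simulations."""

    target: tuple[str | None, str]
    amplitude: float  # nA
    onset: float  # ms
    duration: float  # ms

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class CellModel:
    """A compartment tree plus its channels, calcium pools and synapse sites."""

    name: str
    compartments: tuple[CompartmentGeometry, ...]
    passive: PassiveParameters
    channels: tuple[tuple[str, ChannelSpec], ...] = ()
    calcium_pools: Mapping[str, CalciumPool] = field(default_factory=dict)
    synapse_sites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise StructuralError(f"cell {self.name!r}: duplicate compartment names")
        name_set = set(names)
        roots = [c for c in self.compartments if c.parent is None]
        if len(roots) != 1:
            raise StructuralError(
                f"cell {self.name!r}: expected exactly one root, found {len(roots)}"
            )
        for c in self.compartments:
            if c.parent is not None and c.parent not in name_set:
                raise StructuralError(
                    f"cell {self.name!r}: compartment {c.name!r} has unknown parent"
                    f" {c.parent!r}"
                )
        # cycle check / connectivity via parent walk
        by_name = {c.name: c for c in self.compartments}
        for c in self.compartments:
            seen = set()
            node = c
            while node.parent is not None:
                if node.name in seen:
                    raise StructuralError(f"cell {self.name!r}: cycle at {node.name!r}")
                seen.add(node.name)
                node = by_name[node.parent]
        for comp, spec in self.channels:
            if comp not in name_set:
                raise StructuralError(
                    f"cell {self.name!r}: channel {spec.name!r} on unknown"
                    f" compartment {comp!r}"
                )
            if spec.uses_nernst and comp not in self.calcium_pools:
                raise StructuralError(
                    f"cell {self.name!r}: channel {spec.name!r} needs a calcium pool"
                    f" on {comp!r}"
                )
        for comp in self.calcium_pools:
            if comp not in name_set:
                raise StructuralError(f"cell {self.name!r}: pool on unknown {comp!r}")
        for comp in self.synapse_sites:
            if comp not in name_set:
                raise StructuralError(f"cell {self.name!r}: site on unknown {comp!r}")

    # -- helpers ----------------------------------------------------------
    @property
    def compartment_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.compartments)

    def compartment(self, name: str) -> CompartmentGeometry:
        for c in self.compartments:
            if c.name == name:
                return c
        raise StructuralError(f"cell {self.name!r} has no compartment {name!r}")

    @property
    def total_area_um2(self) -> float:
        return sum(c.area_um2 for c in self.compartments)

    def topological_order(self) -> list[CompartmentGeometry]:
        """Compartments ordered with every parent before its children."""
        by_name = {c.name: c for c in self.compartments}
        children: dict[str | None, list[str]] = {}
        for c in self.compartments:
            children.setdefault(c.parent, []).append(c.name)
        order: list[CompartmentGeometry] = []
        stack = list(reversed(children.get(None, [])))
        while stack:
            name = stack.pop()
            order.append(by_name[name])
            stack.extend(reversed(children.get(name, [])))
        if len(order) != len(self.compartments):
            raise StructuralError(f"cell {self.name!r}: disconnected compartments")
        return order


def axial_coupling(cell: CellModel) -> dict[tuple[str, str], float]:
    """Pairwise axial conductances (uS) between connected compartments.

    ``g = 1 / (R_half_child + R_half_parent)`` with each half resistance
    ``R_a * (L/2) / (pi r^2)``.  The table is symmetric: both (a, b) and
    (b, a) keys are present.
    """
    ra = cell.passive.axial_resistivity
    table: dict[tuple[str, str], float] = {}
    for comp in cell.compartments:
        if comp.parent is None:
            continue
        parent = cell.compartment(comp.parent)
        r_total = comp.half_axial_resistance_MOhm(ra) + parent.half_axial_resistance_MOhm(ra)
        g = 1.0 / r_total  # uS
        table[(comp.name, parent.name)] = g
        table[(parent.name, comp.name)] = g
    return table


@dataclass
class SimulationState:
    """Mutable state advanced by the solver."""

    t: float
    v: np.ndarray  # mV, per compartment
    gates: np.ndarray  # per gate instance, in [0, 1]
    syn_states: np.ndarray  # per synapse, in [0, 1]
    ca: np.ndarray  # mM, per compartment (resting value where no pool)

    def copy(self) -> "SimulationState":
        return SimulationState(self.t, self.v.copy(), self.gates.copy(),
                               self.syn_states.copy(), self.ca.copy())


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane-potential traces plus protocol metadata."""

    times: np.ndarray
    v: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        diffs = np.diff(self.times)
        if len(diffs) and (np.any(diffs <= 0) or not np.allclose(diffs, diffs[0])):
            raise ValueError("times must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __getitem__(self, label: str) -> np.ndarray:
        return self.v[label]

    @property
    def labels(self) -> list[str]:
        return list(self.v)

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ms": self.times}
        data.update(self.v)
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "VoltageTrace":
        frame = pd.read_csv(path)
        times = frame.pop("time_ms").to_numpy()
        return cls(times=times, v={c: frame[c].to_numpy() for c in frame.columns})


# ---------------------------------------------------------------------------
# network assembly and integration


class Network:
    """One or more cells plus graded synapses, flattened for the solver.

    Compartment labels are plain compartment names when the network holds a
    single cell, and ``"cell/compartment"`` otherwise.
    """

    def __init__(
        self,
        cells: Sequence[CellModel] | CellModel,
        synapses: Sequence[GradedSynapse] = (),
        temperature_K: float = DEFAULT_TEMPERATURE_K,
    ) -> None:
        if isinstance(cells, CellModel):
            cells = [cells]
        if not cells:
            raise StructuralError("network needs at least one cell")
        names = [c.name for c in cells]
        if len(set(names)) != len(names):
            raise StructuralError("duplicate cell names in network")
        self.cells = tuple(cells)
        self.synapses = tuple(synapses)
        self.temperature_K = temperature_K
        self._single = len(self.cells) == 1
        self._build()

    # -- labels -----------------------------------------------------------
    def label(self, cell: str | None, comp: str) -> str:
        if self._single:
            return comp
        if cell is None:
            raise StructuralError("multi-cell network: compartment reference "
                                  f"{comp!r} needs a cell name")
        return f"{cell}/{comp}"

    def index(self, cell: str | None, comp: str) -> int:
        key = (cell if cell is not None or not self._single else self.cells[0].name, comp)
        if key[0] is None:
            key = (self.cells[0].name, comp)
        try:
            return self._index[key]
        except KeyError:
            raise StructuralError(f"no compartment {comp!r} in cell {key[0]!r}") from None

    # -- assembly ---------------------------------------------------------
    def _build(self) -> None:
        parent, gax, cap, gleak, eleak, area = [], [], [], [], [], []
        self._index: dict[tuple[str, str], int] = {}
        self._labels: list[str] = []
        self._rest: list[float] = []
        comp_cell: list[CellModel] = []

        for cell in self.cells:
            coupling = axial_coupling(cell)
            base = {}
            for comp in cell.topological_order():
                idx = len(parent)
                self._index[(cell.name, comp.name)] = idx
                self._labels.append(self.label(cell.name, comp.name))
                base[comp.name] = idx
                if comp.parent is None:
                    parent.append(-1)
                    gax.append(0.0)
                else:
                    parent.append(base[comp.parent])
                    gax.append(coupling[(comp.name, comp.parent)])
                a_cm2 = comp.area_cm2
                area.append(a_cm2)
                cap.append(cell.passive.specific_capacitance * a_cm2 * 1e3)  # nF
                gleak.append(cell.passive.leak_conductance_density * a_cm2 * 1e6)  # uS
                eleak.append(cell.passive.leak_reversal)
                self._rest.append(cell.passive.resting_potential)
                comp_cell.append(cell)

        nc = len(parent)
        self.nc = nc
        self._parent = np.asarray(parent, dtype=np.int64)
        self._gax = np.asarray(gax)
        self._cap = np.asarray(cap)
        self._gleak = np.asarray(gleak)
        self._eleak = np.asarray(eleak)
        self._area = np.asarray(area)

        # calcium pools
        has_pool = np.zeros(nc, dtype=np.bool_)
        p_depth = np.ones(nc)
        p_tau = np.ones(nc)
        p_rest = np.full(nc, 2.4e-4)
        p_out = np.full(nc, 2.0)
        p_floor = np.full(nc, 1e-8)
        for cell in self.cells:
            for comp, pool in cell.calcium_pools.items():
                i = self._index[(cell.name, comp)]
                has_pool[i] = True
                p_depth[i] = pool.shell_depth_um
                p_tau[i] = pool.removal_tau_ms
                p_rest[i] = pool.resting_mM
                p_out[i] = pool.external_mM
                p_floor[i] = pool.floor_mM
        self._pool = (has_pool, p_depth, p_tau, p_rest, p_out, p_floor)

        # channels and gates
        vgrid = np.linspace(_kernel.VGRID_MIN, _kernel.VGRID_MAX, _kernel.NV)
        self.vgrid = vgrid
        ch_comp, ch_gbar, ch_e, ch_nernst, ch_feed, ch_g0, ch_g1 = [], [], [], [], [], [], []
        gt_comp, gt_pow, gt_kind, gt_a, gt_b = [], [], [], [], []
        inf_rows, tau_rows = [], []
        self._gate_rules = []
        for cell in self.cells:
            for comp, spec in cell.channels:
                ci = len(ch_comp)
                idx = self._index[(cell.name, comp)]
                a_cm2 = self._area[idx]
                ch_comp.append(idx)
                ch_gbar.append(spec.gbar * a_cm2 * 1e6)  # S/cm^2 -> uS
                ch_e.append(0.0 if spec.uses_nernst else float(spec.reversal))
                ch_nernst.append(spec.uses_nernst)
                ch_feed.append(spec.feeds_calcium)
                ch_g0.append(len(gt_comp))
                for rule in spec.gates:
                    gt_comp.append(idx)
                    gt_pow.append(rule.power)
                    self._gate_rules.append(rule)
                    if rule.is_calcium_gated:
                        gt_kind.append(_kernel.GATE_CALCIUM)
                        gt_a.append(rule.ca_rates[0])
                        gt_b.append(rule.ca_rates[1])
                        inf_rows.append(np.zeros_like(vgrid))
                        tau_rows.append(np.ones_like(vgrid))
                    else:
                        gt_a.append(0.0)
                        gt_b.append(0.0)
                        inf_rows.append(np.asarray(rule.steady_state(vgrid), dtype=float))
                        if rule.is_instantaneous:
                            gt_kind.append(_kernel.GATE_INSTANT)
                            tau_rows.append(np.ones_like(vgrid))
                        else:
                            gt_kind.append(_kernel.GATE_VOLTAGE)
                            tau = np.asarray(rule.time_constant(vgrid), dtype=float)
                            if np.any(tau <= 0):
                                raise ValueError(
                                    f"channel {spec.name!r}: non-positive time constant"
                                )
                            tau_rows.append(tau)
                ch_g1.append(len(gt_comp))

        self._channels = (
            np.asarray(ch_comp, dtype=np.int64),
            np.asarray(ch_gbar, dtype=float),
            np.asarray(ch_e, dtype=float),
            np.asarray(ch_nernst, dtype=np.bool_),
            np.asarray(ch_feed, dtype=np.bool_),
            np.asarray(ch_g0, dtype=np.int64),
            np.asarray(ch_g1, dtype=np.int64),
        )
        ngates = len(gt_comp)
        self._gates_static = (
            np.asarray(gt_comp, dtype=np.int64),
            np.asarray(gt_pow, dtype=np.int64),
            np.asarray(gt_kind, dtype=np.int64),
            np.vstack(inf_rows) if ngates else np.zeros((0, _kernel.NV)),
            np.vstack(tau_rows) if ngates else np.zeros((0, _kernel.NV)),
            np.asarray(gt_a, dtype=float),
            np.asarray(gt_b, dtype=float),
        )
        self.ngates = ngates

        # synapses
        sy_pre, sy_post = [], []
        for syn in self.synapses:
            pre_cell, pre_comp = syn.pre
            post_cell, post_comp = syn.post
            sy_pre.append(self.index(pre_cell, pre_comp))
            sy_post.append(self.index(post_cell, post_comp))
        self._syn_static = (
            np.asarray(sy_pre, dtype=np.int64),
            np.asarray(sy_post, dtype=np.int64),
            np.asarray([s.gmax for s in self.synapses], dtype=float),
            np.asarray([s.reversal for s in self.synapses], dtype=float),
            np.asarray([s.threshold for s in self.synapses], dtype=float),
            np.asarray([s.slope for s in self.synapses], dtype=float),
            np.asarray([s.tau for s in self.synapses], dtype=float),
        )

        self._rtf2 = 1e3 * GAS_CONSTANT * self.temperature_K / (2.0 * FARADAY)

    # -- state ------------------------------------------------------------
    def init_state(self, v0: float | np.ndarray | None = None) -> SimulationState:
        """State at rest: gates at steady state for the resting potential,
        calcium at its resting concentration, synapses at their resting
        activation."""
        v = np.array(self._rest, dtype=float) if v0 is None else \
            np.broadcast_to(np.asarray(v0, dtype=float), (self.nc,)).copy()
        gt_comp = self._gates_static[0]
        gates = np.empty(self.ngates)
        ca = self._pool[3].copy()
        for gi, rule in enumerate(self._gate_rules):
            vc = v[gt_comp[gi]]
            if rule.is_calcium_gated:
                a = rule.ca_rates[0] * ca[gt_comp[gi]]
                gates[gi] = a / (a + rule.ca_rates[1])
            else:
                gates[gi] = float(np.clip(rule.steady_state(np.asarray(vc)), 0.0, 1.0))
        s = np.array([float(syn.steady_state(v[self._syn_static[0][i]]))
                      for i, syn in enumerate(self.synapses)])
        return SimulationState(t=0.0, v=v, gates=gates, syn_states=s, ca=ca)

    def _stim_arrays(self, stimuli: Sequence[CurrentPulse], t_stop: float):
        comp, amp, on, off = [], [], [], []
        for pulse in stimuli:
            cell, compartment = pulse.target
            comp.append(self.index(cell, compartment))
            amp.append(pulse.amplitude)
            on.append(pulse.onset)
            off.append(pulse.offset)
            if pulse.offset > t_stop + 1e-9:
                warnings.warn(
                    f"stimulus on {compartment!r} extends past t_stop and is truncated",
                    stacklevel=3,
                )
        return (np.asarray(comp, dtype=np.int64), np.asarray(amp, dtype=float),
                np.asarray(on, dtype=float), np.asarray(off, dtype=float))

    def _integrate(self, state: SimulationState, nsteps: int, dt: float, stim_arrays):
        vrec = np.empty((nsteps + 1, self.nc))
        status, bad = _kernel.simulate(
            nsteps, dt,
            self._parent, self._gax, self._cap, self._gleak, self._eleak, self._area,
            *stim_arrays,
            *self._channels,
            *self._gates_static,
            *self._pool,
            *self._syn_static,
            state.v, state.gates, state.syn_states, state.ca,
            self._rtf2,
            vrec,
        )
        if status >= 0:
            t_bad = state.t + status * dt
            raise NumericalBlowupError(
                f"voltage blow-up in compartment {self._labels[bad]!r} "
                f"at t = {t_bad:.3f} ms"
            )
        state.t += nsteps * dt
        return vrec

    def step(self, state: SimulationState, drive: np.ndarray | None = None,
             dt: float = 0.05) -> SimulationState:
        """Advance the state by a single time step.

        ``drive`` is an optional per-compartment applied current (nA).
        Returns the same (mutated) state object for chaining.
        """
        if drive is None:
            stim = (np.zeros(0, dtype=np.int64), np.zeros(0), np.zeros(0), np.zeros(0))
        else:
            drive = np.asarray(drive, dtype=float)
            comp = np.flatnonzero(drive)
            stim = (comp.astype(np.int64), drive[comp],
                    np.full(comp.size, -1.0), np.full(comp.size, dt * 2))
        self._integrate(state, 1, dt, stim)
        return state

    def run(
        self,
        config: SolverConfig,
        stimuli: Sequence[CurrentPulse] = (),
        record: Sequence[str] | None = None,
        state: SimulationState | None = None,
    ) -> VoltageTrace:
        """Integrate from rest (or from ``state``) and return the recorded
        voltage traces.  ``record`` lists compartment labels (plain names
        for a single-cell network, ``"cell/comp"`` otherwise); default all.
        """
        if state is None:
            state = self.init_state()
        stim_arrays = self._stim_arrays(stimuli, config.t_stop)
        nsteps = config.nsteps
        vrec = self._integrate(state, nsteps, config.dt, stim_arrays)
        times = np.arange(nsteps + 1) * config.dt
        if record is None:
            record = self._labels
        label_to_col = {lab: i for i, lab in enumerate(self._labels)}
        missing = [lab for lab in record if lab not in label_to_col]
        if missing:
            raise StructuralError(f"unknown record labels: {missing}")
        v = {lab: vrec[:, label_to_col[lab]].copy() for lab in record}
        metadata = {
            "dt": config.dt,
            "t_stop": config.t_stop,
            "cells": [c.name for c in self.cells],
            "stimuli": [
                {"target": list(p.target), "amplitude": p.amplitude,
                 "onset": p.onset, "duration": p.duration}
                for p in stimuli
            ],
            "synapses": len(self.synapses),
        }
        return VoltageTrace(times=times, v=v, metadata=metadata)


def run(
    cell: CellModel,
    stimuli: Sequence[CurrentPulse] = (),
    synapses: Sequence[GradedSynapse] = (),
    config: SolverConfig = SolverConfig(),
    record: Sequence[str] | None = None,
) -> VoltageTrace:
    """Single-cell convenience wrapper around :class:`Network`.

    ``synapses`` may contain autapses onto the cell itself.  The dynamics
    contain no randomness, so repeated runs are bitwise identical.
    """
    net = Network(cell, synapses)
    return net.run(config, stimuli, record)
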