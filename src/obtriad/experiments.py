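"""Stimulation protocols, trace measurements and parameter sweeps.

Encodes, as parameterized functions, the standard experiments on the
glomerular microcircuit: the somatic current-step characterization of the
periglomerular (PG) cell, the current-injection benchmarks of the mitral
and granule cells, the reciprocally coupled mitral-PG pair, the full
mitral-PG-granule triad, and the stimulus-onset-interval studies.  All
experiments are deterministic.

Conventions: spikes are upward crossings of a 0 mV threshold refined to
the local maximum, with a 2 ms minimum separation; firing frequency is
the spike count inside the stimulus window divided by the stimulus
duration; the plateau level is the mean voltage over the last 100 ms of
the stimulus with +-10 ms around each spike excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cable import CurrentPulse, Network, SolverConfig, VoltageTrace
from .cells import (
    GranuleParameters,
    MitralParameters,
    PGParameters,
    build_granule,
    build_mitral,
    build_pg,
    load_granule_parameters,
    load_mitral_parameters,
    load_pg_parameters,
    pg_autapse,
)
from .synapses import wire_reciprocal

__all__ = [
    "SPIKE_THRESHOLD",
    "TraceFeatures",
    "TriadConfig",
    "detect_spikes",
    "firing_frequency",
    "plateau_level",
    "extract_features",
    "pg_step_response",
    "pg_conductance_sweep",
    "isolated_mitral_response",
    "isolated_granule_response",
    "build_triad",
    "standard_triad_pulses",
    "triad_response",
    "coupled_pair_features",
    "frequency_vs_inhibition",
    "sweep_2d",
    "triad_frequency_grid",
    "pg_onset_latency_study",
    "max_plateau_lower_edge",
    "pg_granule_onset_grid",
    "cat_latency_study",
]

#: default spike-detection threshold.  The periglomerular cell fires
#: low-threshold calcium spikes with a sodium component whose overshoot is
#: modest, so the detection level sits between every spike peak and every
#: subthreshold plateau of the modeled protocols; config-exposed.
SPIKE_THRESHOLD = -25.0  # mV
MIN_SPIKE_SEPARATION = 2.0  # ms


@dataclass(frozen=True)
class TraceFeatures:
    """Derived measurements of one voltage trace."""

    spike_times: np.ndarray  # ms, absolute
    spike_peaks: np.ndarray  # mV
    first_spike_time: float | None  # ms, absolute
    first_spike_latency: float | None  # ms, from stimulus onset
    firing_frequency: float  # Hz over the stimulus window
    plateau_level: float | None  # mV
    delta_l: float | None = None  # ms, coupled minus isolated first spike

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


def detect_spikes(
    trace: VoltageTrace | tuple[np.ndarray, np.ndarray],
    threshold: float = SPIKE_THRESHOLD,
    label: str | None = None,
    min_separation: float = MIN_SPIKE_SEPARATION,
    return_peaks: bool = False,
):
    """Spike times: upward threshold crossings refined to the local maximum
    of each suprathreshold excursion, separated by at least
    ``min_separation`` ms."""
    if isinstance(trace, VoltageTrace):
        times = trace.times
        v = trace[label] if label is not None else trace[trace.labels[0]]
    else:
        times, v = trace
        times = np.asarray(times, dtype=float)
        v = np.asarray(v, dtype=float)
    above = v >= threshold
    starts = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    ends = np.flatnonzero(~above[1:] & above[:-1]) + 1
    spike_t, spike_v = [], []
    for s in starts:
        e_candidates = ends[ends > s]
        e = e_candidates[0] if len(e_candidates) else len(v)
        seg = slice(s, e)
        peak = s + int(np.argmax(v[seg]))
        t_peak = times[peak]
        if spike_t and t_peak - spike_t[-1] < min_separation:
            continue
        spike_t.append(t_peak)
        spike_v.append(v[peak])
    spike_t = np.asarray(spike_t)
    spike_v = np.asarray(spike_v)
    if return_peaks:
        return spike_t, spike_v
    return spike_t


def firing_frequency(spike_times, stim_onset: float, stim_duration: float) -> float:
    """Spikes inside [onset, onset + duration], per second (Hz)."""
    spike_times = np.asarray(spike_times, dtype=float)
    in_window = (spike_times >= stim_onset) & (spike_times <= stim_onset + stim_duration)
    return float(np.count_nonzero(in_window)) / stim_duration * 1e3


def plateau_level(
    trace: VoltageTrace,
    window: tuple[float, float] | None = None,
    label: str | None = None,
    threshold: float = SPIKE_THRESHOLD,
    spike_exclusion_ms: float = 10.0,
) -> float | None:
    """Mean voltage over ``window`` (default: last 100 ms of the stimulus),
    with samples within +-10 ms of any spike excluded."""
    lab = label if label is not None else trace.labels[0]
    v = trace[lab]
    if window is None:
        stims = trace.metadata.get("stimuli", [])
        if not stims:
            raise ValueError("no stimulus metadata; pass a window explicitly")
        end = max(s["onset"] + s["duration"] for s in stims)
        window = (end - 100.0, end)
    lo, hi = window
    mask = (trace.times >= lo) & (trace.times <= hi)
    spikes = detect_spikes(trace, threshold, label=lab)
    for t_sp in spikes:
        mask &= np.abs(trace.times - t_sp) > spike_exclusion_ms
    if not np.any(mask):
        return None
    return float(np.mean(v[mask]))


def extract_features(
    trace: VoltageTrace,
    stim_onset: float,
    stim_duration: float,
    label: str | None = None,
    threshold: float = SPIKE_THRESHOLD,
    plateau_window: tuple[float, float] | None = None,
) -> TraceFeatures:
    lab = label if label is not None else trace.labels[0]
    spikes, peaks = detect_spikes(trace, threshold, label=lab, return_peaks=True)
    first = float(spikes[0]) if len(spikes) else None
    if plateau_window is None:
        plateau_window = (stim_onset + stim_duration - 100.0, stim_onset + stim_duration)
    return TraceFeatures(
        spike_times=spikes,
        spike_peaks=peaks,
        first_spike_time=first,
        first_spike_latency=None if first is None else first - stim_onset,
        firing_frequency=firing_frequency(spikes, stim_onset, stim_duration),
        plateau_level=plateau_level(trace, plateau_window, label=lab,
                                    threshold=threshold),
    )


# ---------------------------------------------------------------------------
# single-cell protocols


def pg_step_response(
    params: PGParameters | None = None,
    amplitude: float = 0.1,
    onset: float = 200.0,
    duration: float = 600.0,
    t_stop: float = 1000.0,
    dt: float = 0.05,
    target: str = "soma",
) -> VoltageTrace:
    """Somatic current-step characterization of the PG cell (default
    100 pA for 600 ms from 200 ms, 1 s of simulated time), autapse
    included.  Records the soma."""
    if params is None:
        params = load_pg_parameters()
    cell = build_pg(params)
    syn = [pg_autapse(cell, params)] if params.autapse_gmax > 0 else []
    net = Network(cell, syn)
    pulse = CurrentPulse((None, target), amplitude, onset, duration)
    return net.run(SolverConfig(dt=dt, t_stop=t_stop), [pulse], record=["soma"])


def pg_conductance_sweep(
    column: str,
    values: Sequence[float],
    params: PGParameters | None = None,
    **protocol,
) -> list[tuple[float, TraceFeatures]]:
    """Vary one PG maximum conductance (table column, or ``"autapse"`` in
    uS) with everything else at the fitted values, and measure the somatic
    step response for each value."""
    if params is None:
        params = load_pg_parameters()
    onset = protocol.get("onset", 200.0)
    duration = protocol.get("duration", 600.0)
    out = []
    for value in values:
        if column == "autapse":
            p = params.with_autapse(value)
        else:
            p = params.with_density(column, value)
        trace = pg_step_response(p, **protocol)
        out.append((float(value), extract_features(trace, onset, duration)))
    return out


def isolated_mitral_response(
    params: MitralParameters | None = None,
    amplitude: float = 0.37,
    onset: float = 50.0,
    duration: float = 600.0,
    t_stop: float = 1000.0,
    dt: float = 0.05,
    target: str = "tuft",
) -> VoltageTrace:
    """Mitral cell alone, driven at the glomerular tuft.  Records the soma."""
    cell = build_mitral(params)
    net = Network(cell)
    pulse = CurrentPulse((None, target), amplitude, onset, duration)
    return net.run(SolverConfig(dt=dt, t_stop=t_stop), [pulse], record=["soma"])


def isolated_granule_response(
    params: GranuleParameters | None = None,
    amplitude: float = 0.0625,
    onset: float = 50.0,
    duration: float = 2500.0,
    t_stop: float = 3000.0,
    dt: float = 0.05,
    target: str = "soma",
) -> VoltageTrace:
    """Granule cell alone, driven at the soma.  Records the soma."""
    cell = build_granule(params)
    net = Network(cell)
    pulse = CurrentPulse((None, target), amplitude, onset, duration)
    return net.run(SolverConfig(dt=dt, t_stop=t_stop), [pulse], record=["soma"])


# ---------------------------------------------------------------------------
# coupled circuits


@dataclass(frozen=True)
class TriadConfig:
    """Synaptic conductances (uS) and current pulses of the microcircuit.

    The reciprocal mitral-PG contact couples the mitral primary dendrite
    with the PG gemmule; the mitral-granule contact couples the mitral
    lateral dendrite with the granule peripheral dendrite.  Setting
    ``include_granule`` False gives the two-cell (mitral + PG) circuit.
    """

    g_m_to_pg: float = 0.06
    g_pg_to_m: float = 0.06
    g_m_to_gr: float = 0.06
    g_gr_to_m: float = 0.06
    include_granule: bool = True
    pulses: tuple[CurrentPulse, ...] = ()

    def __post_init__(self) -> None:
        for name in ("g_m_to_pg", "g_pg_to_m", "g_m_to_gr", "g_gr_to_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def standard_triad_pulses(
    i_m: float = 0.37,
    i_pg: float = 0.18,
    i_gr: float = 0.0625,
    onset_m: float = 50.0,
    onset_pg: float | None = None,
    onset_gr: float | None = None,
    dur_m: float = 600.0,
    dur_pg: float | None = None,
    dur_gr: float | None = None,
    include_granule: bool = True,
) -> tuple[CurrentPulse, ...]:
    """Receptor-input pulses: mitral tuft, PG gemmule, granule soma; by
    default all share the mitral onset and duration."""
    onset_pg = onset_m if onset_pg is None else onset_pg
    onset_gr = onset_m if onset_gr is None else onset_gr
    dur_pg = dur_m if dur_pg is None else dur_pg
    dur_gr = dur_m if dur_gr is None else dur_gr
    pulses = [
        CurrentPulse(("mitral", "tuft"), i_m, onset_m, dur_m),
        CurrentPulse(("pg", "gemmule"), i_pg, onset_pg, dur_pg),
    ]
    if include_granule and i_gr != 0:
        pulses.append(CurrentPulse(("granule", "soma"), i_gr, onset_gr, dur_gr))
    return tuple(pulses)


def build_triad(
    config: TriadConfig,
    pg_params: PGParameters | None = None,
    mitral_params: MitralParameters | None = None,
    granule_params: GranuleParameters | None = None,
) -> Network:
    if pg_params is None:
        pg_params = load_pg_parameters()
    mitral = build_mitral(mitral_params)
    pg = build_pg(pg_params)
    synapses = list(
        wire_reciprocal(mitral, "primary", pg, "gemmule",
                        config.g_m_to_pg, config.g_pg_to_m)
    )
    if pg_params.autapse_gmax > 0:
        synapses.append(pg_autapse(pg, pg_params))
    cells = [mitral, pg]
    if config.include_granule:
        from .synapses import GRANULE_THRESHOLD

        granule = build_granule(granule_params)
        # both granule-path terminals are spike-gated: the mitral lateral
        # dendrite releases on spikes, and the granule has no release
        # plateau of its own
        synapses.extend(
            wire_reciprocal(mitral, "lateral", granule, "peripheral",
                            config.g_m_to_gr, config.g_gr_to_m,
                            threshold_exc=-40.0,
                            threshold_inh=GRANULE_THRESHOLD)
        )
        cells.append(granule)
    return Network(cells, synapses)


def triad_response(
    config: TriadConfig,
    t_stop: float = 1000.0,
    dt: float = 0.05,
    record: Sequence[str] = ("mitral/soma", "pg/soma"),
    pg_params: PGParameters | None = None,
    mitral_params: MitralParameters | None = None,
    granule_params: GranuleParameters | None = None,
) -> VoltageTrace:
    net = build_triad(config, pg_params, mitral_params, granule_params)
    rec = list(record)
    if not config.include_granule:
        rec = [r for r in rec if not r.startswith("granule/")]
    elif "granule/soma" not in rec and record == ("mitral/soma", "pg/soma"):
        rec.append("granule/soma")
    return net.run(SolverConfig(dt=dt, t_stop=t_stop), list(config.pulses), record=rec)


def coupled_pair_features(
    g_pg_to_m: float = 0.06,
    g_m_to_pg: float = 0.06,
    i_m: float = 0.37,
    i_pg: float = 0.18,
    onset_m: float = 50.0,
    onset_pg: float | None = None,
    dur_m: float = 600.0,
    dur_pg: float | None = None,
    t_stop: float = 1000.0,
    dt: float = 0.05,
    pg_params: PGParameters | None = None,
) -> TraceFeatures:
    """Mitral-cell features in the reciprocally coupled mitral-PG pair."""
    pulses = standard_triad_pulses(
        i_m=i_m, i_pg=i_pg, onset_m=onset_m, onset_pg=onset_pg,
        dur_m=dur_m, dur_pg=dur_pg, include_granule=False,
    )
    cfg = TriadConfig(g_m_to_pg=g_m_to_pg, g_pg_to_m=g_pg_to_m,
                      include_granule=False, pulses=pulses)
    trace = triad_response(cfg, t_stop=t_stop, dt=dt,
                           record=("mitral/soma",), pg_params=pg_params)
    return extract_features(trace, onset_m, dur_m, label="mitral/soma")


def frequency_vs_inhibition(
    g_values: Sequence[float],
    **kwargs,
) -> pd.DataFrame:
    """Mitral firing frequency as a function of the PG inhibitory
    conductance, everything else fixed."""
    rows = [
        {"g_pg_to_m": float(g),
         "frequency_hz": coupled_pair_features(g_pg_to_m=g, **kwargs).firing_frequency}
        for g in g_values
    ]
    return pd.DataFrame(rows)


def sweep_2d(
    xs: Sequence[float],
    ys: Sequence[float],
    measure: Callable[[float, float], float],
) -> np.ndarray:
    """Dense 2-D sweep: ``grid[i, j] = measure(xs[i], ys[j])``."""
    grid = np.empty((len(xs), len(ys)))
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            grid[i, j] = measure(float(x), float(y))
    return grid


def grid_frame(xs, ys, grid, x_name: str, y_name: str) -> pd.DataFrame:
    """Grid as a CSV-friendly matrix with axis headers (rows = xs)."""
    frame = pd.DataFrame(grid, index=pd.Index(xs, name=x_name),
                         columns=pd.Index(ys, name=y_name))
    return frame


def triad_frequency_grid(
    g_gr_values: Sequence[float],
    g_pg_values: Sequence[float],
    i_m: float = 0.37,
    i_pg: float = 0.18,
    i_gr: float = 0.0625,
    onset: float = 50.0,
    duration: float = 600.0,
    t_stop: float = 1000.0,
    dt: float = 0.05,
    measure: str = "frequency",
    pg_params: PGParameters | None = None,
) -> pd.DataFrame:
    """Mitral firing frequency (or first-spike time) over the plane of the
    two inhibitory conductances in the full triad."""
    if pg_params is None:
        pg_params = load_pg_parameters()
    pulses = standard_triad_pulses(i_m=i_m, i_pg=i_pg, i_gr=i_gr,
                                   onset_m=onset, dur_m=duration)

    def one(g_gr: float, g_pg: float) -> float:
        cfg = TriadConfig(g_pg_to_m=g_pg, g_gr_to_m=g_gr, pulses=pulses)
        trace = triad_response(cfg, t_stop=t_stop, dt=dt,
                               record=("mitral/soma",), pg_params=pg_params)
        feats = extract_features(trace, onset, duration, label="mitral/soma")
        if measure == "frequency":
            return feats.firing_frequency
        if measure == "first_spike_time":
            return np.nan if feats.first_spike_time is None else feats.first_spike_time
        raise ValueError(f"unknown measure {measure!r}")

    grid = sweep_2d(g_gr_values, g_pg_values, one)
    return grid_frame(g_gr_values, g_pg_values, grid, "g_gr_to_m", "g_pg_to_m")


# ---------------------------------------------------------------------------
# stimulus-onset-interval studies


def pg_onset_latency_study(
    pg_onsets: Sequence[float] = tuple(np.arange(60.0, 251.0, 5.0)),
    g: float = 0.06,
    i_m: float = 0.37,
    i_pg: float = 0.18,
    mitral_onset: float = 200.0,
    mitral_duration: float = 600.0,
    t_stop: float = 1000.0,
    dt: float = 0.05,
    pg_params: PGParameters | None = None,
) -> pd.DataFrame:
    """Effect of the PG-vs-mitral stimulus-onset interval on the mitral
    first spike, in the coupled pair.

    The PG pulse always ends together with the mitral pulse; ``delta_t_pm``
    is (PG onset - mitral onset) and ``delta_l`` the coupled-minus-isolated
    first-spike-time difference, the isolated reference being measured once
    under the identical mitral protocol.
    """
    iso = isolated_mitral_response(amplitude=i_m, onset=mitral_onset,
                                   duration=mitral_duration, t_stop=t_stop, dt=dt)
    iso_first = extract_features(iso, mitral_onset, mitral_duration).first_spike_time
    stim_end = mitral_onset + mitral_duration
    rows = []
    for onset_pg in pg_onsets:
        feats = coupled_pair_features(
            g_pg_to_m=g, g_m_to_pg=g, i_m=i_m, i_pg=i_pg,
            onset_m=mitral_onset, onset_pg=float(onset_pg),
            dur_m=mitral_duration, dur_pg=stim_end - float(onset_pg),
            t_stop=t_stop, dt=dt, pg_params=pg_params,
        )
        first = feats.first_spike_time
        rows.append({
            "pg_onset": float(onset_pg),
            "delta_t_pm": float(onset_pg) - mitral_onset,
            "first_spike_time": np.nan if first is None else first,
            "delta_l": np.nan if first is None or iso_first is None
            else first - iso_first,
        })
    frame = pd.DataFrame(rows)
    frame.attrs["isolated_first_spike_time"] = iso_first
    return frame


def max_plateau_lower_edge(delta_t, delta_l, tol: float = 0.1) -> float:
    """Smallest onset interval on the maximum plateau of the latency-shift
    curve (all points within ``tol`` ms of the maximum)."""
    delta_t = np.asarray(delta_t, dtype=float)
    delta_l = np.asarray(delta_l, dtype=float)
    finite = np.isfinite(delta_l)
    top = delta_l >= np.nanmax(delta_l[finite]) - tol
    return float(np.min(delta_t[finite & top]))


def pg_granule_onset_grid(
    pg_onsets: Sequence[float] = tuple(np.arange(50.0, 501.0, 10.0)),
    g_pg_values: Sequence[float] = tuple(np.linspace(0.0, 0.2, 21)),
    g_gr_to_m: float = 0.06,
    i_m: float = 0.37,
    i_pg: float = 0.18,
    i_gr: float = 0.0625,
    mitral_onset: float = 200.0,
    mitral_duration: float = 600.0,
    granule_onset: float = 50.0,
    t_stop: float = 1000.0,
    dt: float = 0.05,
    pg_params: PGParameters | None = None,
) -> pd.DataFrame:
    """Mitral firing frequency versus the PG-vs-granule onset interval and
    the PG inhibitory conductance, in the full triad.  PG and granule
    pulses last until the end of the mitral pulse."""
    if pg_params is None:
        pg_params = load_pg_parameters()
    stim_end = mitral_onset + mitral_duration

    def one(onset_pg: float, g_pg: float) -> float:
        pulses = standard_triad_pulses(
            i_m=i_m, i_pg=i_pg, i_gr=i_gr,
            onset_m=mitral_onset, onset_pg=onset_pg, onset_gr=granule_onset,
            dur_m=mitral_duration, dur_pg=stim_end - onset_pg,
            dur_gr=stim_end - granule_onset,
        )
        cfg = TriadConfig(g_pg_to_m=g_pg, g_gr_to_m=g_gr_to_m, pulses=pulses)
        trace = triad_response(cfg, t_stop=t_stop, dt=dt,
                               record=("mitral/soma",), pg_params=pg_params)
        return extract_features(trace, mitral_onset, mitral_duration,
                                label="mitral/soma").firing_frequency

    grid = sweep_2d(pg_onsets, g_pg_values, one)
    frame = grid_frame(pg_onsets, g_pg_values, grid, "pg_onset", "g_pg_to_m")
    frame.index = frame.index - granule_onset
    frame.index.name = "delta_t_pg"
    return frame


def cat_latency_study(
    g_cat_values: Sequence[float],
    onset: float = 50.0,
    duration: float = 600.0,
    t_stop: float = 1000.0,
    dt: float = 0.05,
    pg_params: PGParameters | None = None,
) -> pd.DataFrame:
    """Mitral first-spike time in the full triad as a function of the PG
    T-type calcium conductance density (S/cm^2)."""
    if pg_params is None:
        pg_params = load_pg_parameters()
    pulses = standard_triad_pulses(onset_m=onset, dur_m=duration)
    rows = []
    for g_cat in g_cat_values:
        p = pg_params.with_density("CaT", float(g_cat))
        cfg = TriadConfig(pulses=pulses)
        trace = triad_response(cfg, t_stop=t_stop, dt=dt,
                               record=("mitral/soma",), pg_params=p)
        feats = extract_features(trace, onset, duration, label="mitral/soma")
        rows.append({
            "g_cat": float(g_cat),
            "first_spike_time": np.nan if feats.first_spike_time is None
            else feats.first_spike_time,
        })
    return pd.DataFrame(rows)
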