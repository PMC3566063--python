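"""Graded, thresholded dendrodendritic synapses.

A single mechanism serves both the excitatory (mitral -> interneuron) and
inhibitory (interneuron -> mitral, and the periglomerular autapse)
contacts: transmitter release is a continuous sigmoidal function of
presynaptic voltage rather than being triggered by spikes.  The activation
state relaxes with a 1 ms time constant toward

    s_inf(v_pre) = 1 / (1 + exp(-(v_pre - threshold) / slope))

and the postsynaptic current is ``I = gmax * s * (v_post - reversal)``
(positive outward, nA for gmax in uS and voltages in mV).

Reversal potential defaults are the standard combined AMPA/NMDA value
(0 mV) for excitation and the GABA-A value (-80 mV) for inhibition; the
sigmoid midpoint (-40 mV) and slope (2 mV) place graded release in the
subthreshold-depolarization range.  All four are plain fields, exposed for
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "E_EXCITATORY",
    "E_INHIBITORY",
    "GradedSynapse",
    "synaptic_activation",
    "synaptic_current",
    "wire_reciprocal",
]

E_EXCITATORY = 0.0  # mV, combined AMPA/NMDA mechanism (no Mg block)
E_INHIBITORY = -80.0  # mV, GABA-A
DEFAULT_THRESHOLD = -45.0  # mV, release threshold for mitral terminals; engages
#                            during the late subthreshold ramp, so the
#                            reciprocal loop operates before the spike
#: release threshold for interneuron terminals; graded dendrodendritic
#: GABA release engages at the interneurons' subthreshold plateau
INHIBITORY_THRESHOLD = -43.0  # mV
#: release threshold for the granule-cell terminal.  The granule cell is a
#: regularly spiking interneuron (no sustained plateau), so its GABA
#: release is gated by its spikes; this is what limits its inhibitory
#: reach compared with the plateau-releasing periglomerular cell.
GRANULE_THRESHOLD = -30.0  # mV
DEFAULT_SLOPE = 2.0  # mV
#: slope of the interneuron release sigmoid; steeper than the excitatory
#: one so release switches off cleanly once the presynaptic plateau decays
INHIBITORY_SLOPE = 1.2  # mV
DEFAULT_TAU = 1.0  # ms


@dataclass(frozen=True)
class GradedSynapse:
    """One graded contact.  ``pre``/``post`` are (cell, compartment) pairs;
    an autapse (pre cell == post cell) is allowed."""

    pre: tuple[str, str]
    post: tuple[str, str]
    gmax: float  # uS
    reversal: float  # mV
    threshold: float = DEFAULT_THRESHOLD
    slope: float = DEFAULT_SLOPE
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        if self.gmax < 0:
            raise ValueError("gmax must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.slope == 0:
            raise ValueError("slope must be nonzero")

    def steady_state(self, v_pre):
        return 1.0 / (1.0 + np.exp(-(np.asarray(v_pre, dtype=float) - self.threshold)
                                   / self.slope))

    def with_gmax(self, gmax: float) -> "GradedSynapse":
        return replace(self, gmax=gmax)


def synaptic_activation(v_pre, syn: GradedSynapse, s, dt: float):
    """Advance the activation state by ``dt`` (exact exponential update)."""
    s_inf = syn.steady_state(v_pre)
    out = s_inf + (s - s_inf) * np.exp(-dt / syn.tau)
    return np.clip(out, 0.0, 1.0)


def synaptic_current(syn: GradedSynapse, v_post, s):
    """Postsynaptic current in nA, positive outward."""
    return syn.gmax * s * (np.asarray(v_post, dtype=float) - syn.reversal)


class WiringError(ValueError):
    """A synapse references a compartment that does not exist."""


def _check_site(cell, site: str) -> None:
    names = {c.name for c in cell.compartments}
    if site not in names:
        raise WiringError(f"cell {cell.name!r} has no compartment {site!r}")


def wire_reciprocal(
    cell_exc,
    site_exc: str,
    cell_inh,
    site_inh: str,
    g_exc_to_inh: float,
    g_inh_to_exc: float,
    *,
    e_exc: float = E_EXCITATORY,
    e_inh: float = E_INHIBITORY,
    threshold_exc: float | None = None,
    threshold_inh: float | None = None,
    slope: float = DEFAULT_SLOPE,
    slope_inh: float | None = None,
    tau: float = DEFAULT_TAU,
) -> tuple[GradedSynapse, GradedSynapse]:
    """Build a reciprocal dendrodendritic pair between a principal cell and
    an interneuron: excitatory from ``cell_exc`` onto ``cell_inh`` and
    inhibitory back onto ``cell_exc``, both at the stated sites."""
    _check_site(cell_exc, site_exc)
    _check_site(cell_inh, site_inh)
    if threshold_exc is None:
        threshold_exc = DEFAULT_THRESHOLD
    if threshold_inh is None:
        threshold_inh = INHIBITORY_THRESHOLD
    if slope_inh is None:
        slope_inh = INHIBITORY_SLOPE
    exc = GradedSynapse(
        pre=(cell_exc.name, site_exc),
        post=(cell_inh.name, site_inh),
        gmax=g_exc_to_inh,
        reversal=e_exc,
        threshold=threshold_exc,
        slope=slope,
        tau=tau,
    )
    inh = GradedSynapse(
        pre=(cell_inh.name, site_inh),
        post=(cell_exc.name, site_exc),
        gmax=g_inh_to_exc,
        reversal=e_inh,
        threshold=threshold_inh,
        slope=slope_inh,
        tau=tau,
    )
    return exc, inh


def autapse(cell, site: str, gmax: float, *,
            reversal: float = E_INHIBITORY,
            threshold: float = DEFAULT_THRESHOLD,
            slope: float = DEFAULT_SLOPE,
            tau: float = DEFAULT_TAU) -> GradedSynapse:
    """Self-inhibitory graded synapse (used on the periglomerular gemmule)."""
    _check_site(cell, site)
    return GradedSynapse(
        pre=(cell.name, site),
        post=(cell.name, site),
        gmax=gmax,
        reversal=reversal,
        threshold=threshold,
        slope=slope,
        tau=tau,
    )
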