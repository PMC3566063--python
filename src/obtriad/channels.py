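"""Hodgkin-Huxley-formalism ionic current definitions.

Every current is ``I = gbar * prod(gate**power) * (V - E)`` with positive
current flowing outward.  Gates relax as ``dg/dt = (g_inf(V) - g)/tau(V)``
and are advanced with the exact exponential update, which is stable for any
time step and preserves the fixed point ``g = g_inf(V)``.

The kinetics catalog is data-driven: :data:`configs/channels.yaml` declares
each channel as a set of gates whose rate functions are built from a small
registry of closed forms (linoid, exponential, sigmoid, thermodynamic
A-current rates, the piecewise T-type inactivation time constant).  The
catalog follows the published formulations of the source lineages used for
olfactory-bulb cells: Traub-type sodium and delayed-rectifier rates, the
Huguenard-McCormick/Destexhe low-threshold T-type calcium current with a
submembrane calcium shell, a thermodynamic (Migliore-style) A-type
potassium current, an HCN (h) current, M-type and calcium-activated
potassium currents for the mitral/granule sets, and a high-threshold
calcium current of the Bhalla-Bower form.  Kinetic constants live in the
YAML file so they can be inspected and overridden without code changes.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import yaml

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "GatingRule",
    "ChannelSpec",
    "CalciumPool",
    "CatalogError",
    "channel_current",
    "update_gate",
    "calcium_update",
    "nernst_ca",
    "load_catalog",
    "catalog_kinds",
    "make_channel",
]

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446262  # J/(mol K)

#: temperature (Kelvin) used for thermodynamic rate expressions and the
#: calcium Nernst potential unless overridden; 24 degrees C, matching the
#: room-temperature recordings the cell models derive from.
DEFAULT_TEMPERATURE_K = 297.15

_CATALOG_PATH = Path(__file__).parent / "configs" / "channels.yaml"

INSTANTANEOUS = "instantaneous"


class CatalogError(KeyError):
    """Requested channel kind is not in the kinetics catalog."""


@dataclass(frozen=True)
class GatingRule:
    """One activation/inactivation variable of a channel.

    ``steady_state`` and ``time_constant`` are vectorized functions of
    membrane potential (mV -> dimensionless / ms).  ``time_constant`` may be
    the string ``"instantaneous"``.  Calcium-activated gates instead carry
    ``ca_rates = (alpha_per_mM_ms, beta_per_ms)`` with first-order kinetics
    ``alpha(Ca) = a * Ca``.
    """

    steady_state: Callable[[np.ndarray], np.ndarray] | None
    time_constant: Callable[[np.ndarray], np.ndarray] | str | None
    power: int = 1
    ca_rates: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.power < 0:
            raise ValueError("gate power must be non-negative")
        if self.ca_rates is None and self.steady_state is None:
            raise ValueError("voltage-dependent gate needs a steady_state function")

    @property
    def is_instantaneous(self) -> bool:
        return self.time_constant == INSTANTANEOUS

    @property
    def is_calcium_gated(self) -> bool:
        return self.ca_rates is not None


@dataclass(frozen=True)
class ChannelSpec:
    """A channel kind with its gates, density and reversal rule.

    ``reversal`` is either a fixed potential in mV or the tag
    ``"nernst-ca"`` for a calcium current whose reversal tracks the
    submembrane calcium concentration.  ``feeds_calcium`` marks currents
    whose influx drives the compartment's :class:`CalciumPool`.
    """

    name: str
    gates: tuple[GatingRule, ...]
    gbar: float  # S/cm^2
    reversal: float | str
    feeds_calcium: bool = False

    def __post_init__(self) -> None:
        if self.gbar < 0:
            raise ValueError(f"gbar must be >= 0, got {self.gbar}")
        if isinstance(self.reversal, str) and self.reversal != "nernst-ca":
            raise ValueError(f"unknown reversal rule {self.reversal!r}")
        if self.reversal == "nernst-ca" and not self.feeds_calcium:
            raise ValueError("a nernst-ca channel must feed a calcium pool")

    @property
    def uses_nernst(self) -> bool:
        return self.reversal == "nernst-ca"


@dataclass(frozen=True)
class CalciumPool:
    """Submembrane calcium shell with first-order removal.

    ``d[Ca]/dt = -I_Ca / (2 F depth) + ([Ca]_rest - [Ca]) / tau`` with the
    influx term clipped at zero (outward calcium current does not deplete
    the shell), and the concentration floored so the Nernst term stays
    defined.
    """

    shell_depth_um: float = 0.1
    removal_tau_ms: float = 5.0
    resting_mM: float = 2.4e-4
    external_mM: float = 2.0
    floor_mM: float = 1e-8

    def __post_init__(self) -> None:
        for name in ("shell_depth_um", "removal_tau_ms", "resting_mM", "external_mM"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# elementary operations


def channel_current(spec: ChannelSpec, v, gate_values, reversal: float):
    """Current density in mA/cm^2 (positive outward) for given gate values."""
    open_fraction = 1.0
    for rule, g in zip(spec.gates, gate_values):
        open_fraction = open_fraction * np.asarray(g) ** rule.power
    return spec.gbar * open_fraction * (np.asarray(v) - reversal)


def update_gate(rule: GatingRule, g, v, dt: float, ca: float | None = None):
    """Advance a gate by ``dt`` with the exact exponential update."""
    if rule.is_calcium_gated:
        if ca is None:
            raise ValueError("calcium-gated rule needs a calcium concentration")
        a, b = rule.ca_rates
        alpha = a * ca
        inf = alpha / (alpha + b)
        tau = 1.0 / (alpha + b)
    else:
        inf = rule.steady_state(np.asarray(v, dtype=float))
        if rule.is_instantaneous:
            return np.clip(inf, 0.0, 1.0)
        tau = rule.time_constant(np.asarray(v, dtype=float))
    out = inf + (g - inf) * np.exp(-dt / tau)
    return np.clip(out, 0.0, 1.0)


def calcium_update(pool: CalciumPool, i_ca, ca, dt: float):
    """Advance the shell concentration (mM) given a current density in mA/cm^2.

    Inward (negative) calcium current raises the concentration; removal is
    integrated implicitly so the update is stable for any ``dt``.
    """
    depth_cm = pool.shell_depth_um * 1e-4
    drive = -np.asarray(i_ca, dtype=float) / (2.0 * FARADAY * depth_cm)  # mM/ms
    drive = np.maximum(drive, 0.0)
    tau = pool.removal_tau_ms
    new = (ca + dt * (drive + pool.resting_mM / tau)) / (1.0 + dt / tau)
    return np.maximum(new, pool.floor_mM)


def nernst_ca(ca_in, ca_out, temperature_K: float = DEFAULT_TEMPERATURE_K):
    """Calcium reversal potential in mV for a divalent ion."""
    ca_in = np.asarray(ca_in, dtype=float)
    ca_out = np.asarray(ca_out, dtype=float)
    if np.any(ca_in <= 0) or np.any(ca_out <= 0):
        raise ValueError("concentrations must be positive")
    rt_over_2f = 1e3 * GAS_CONSTANT * temperature_K / (2.0 * FARADAY)
    return rt_over_2f * np.log(ca_out / ca_in)


# ---------------------------------------------------------------------------
# rate-form registry (used to build GatingRule callables from the catalog)


def _rate_closure(cfg: Mapping) -> Callable[[np.ndarray], np.ndarray]:
    kind = cfg["kind"]
    a = float(cfg.get("a", 1.0))
    vh = float(cfg.get("vh", 0.0))
    k = float(cfg.get("k", 1.0))
    if kind == "linoid":
        # a * (v - vh) / (1 - exp(-(v - vh)/k)); limit a*k at v == vh

        def rate(v):
            x = (np.asarray(v, dtype=float) - vh) / k
            small = np.abs(x) < 1e-7
            safe = np.where(small, 1.0, x)
            out = a * k * safe / (1.0 - np.exp(-safe))
            return np.where(small, a * k * (1.0 + x / 2.0), out)

    elif kind == "expo":

        def rate(v):
            return a * np.exp((np.asarray(v, dtype=float) - vh) / k)

    elif kind == "sigmoid":

        def rate(v):
            return a / (1.0 + np.exp(-(np.asarray(v, dtype=float) - vh) / k))

    elif kind == "const":

        def rate(v):
            return np.full_like(np.asarray(v, dtype=float), a)

    else:
        raise CatalogError(f"unknown rate kind {kind!r}")
    return rate


def _sigmoid_inf(vh: float, k: float) -> Callable:
    def inf(v):
        return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - vh) / k))

    return inf


def _tau_closure(cfg: Mapping) -> Callable | str:
    form = cfg["form"]
    if form == "instantaneous":
        return INSTANTANEOUS
    if form == "const":
        value = float(cfg["value"])

        def tau(v):
            return np.full_like(np.asarray(v, dtype=float), value)

        return tau
    if form == "dualexp":
        # base + scale / (exp((v-vh1)/k1) + exp((v-vh2)/k2))
        base = float(cfg.get("base", 0.0))
        scale = float(cfg.get("scale", 1.0))
        vh1, k1 = float(cfg["vh1"]), float(cfg["k1"])
        vh2, k2 = float(cfg["vh2"]), float(cfg["k2"])

        def tau(v):
            v = np.asarray(v, dtype=float)
            return base + scale / (np.exp((v - vh1) / k1) + np.exp((v - vh2) / k2))

        return tau
    if form == "cat_h":
        # piecewise inactivation time constant of the low-threshold calcium
        # current: slow de-inactivation below -80 mV, fast inactivation above
        scale = float(cfg.get("scale", 1.0))

        def tau(v):
            v = np.asarray(v, dtype=float)
            slow = np.exp((v + 467.0) / 66.6)
            fast = 28.0 + np.exp(-(v + 22.0) / 10.5)
            return scale * np.where(v < -80.0, slow, fast)

        return tau
    if form == "linear_min":
        slope = float(cfg["slope"])
        v0 = float(cfg["v0"])
        floor = float(cfg["min"])

        def tau(v):
            v = np.asarray(v, dtype=float)
            return np.maximum(slope * (v - v0), floor)

        return tau
    raise CatalogError(f"unknown tau form {form!r}")


def _thermo_exponent(v, vh, zeta, temperature_K):
    return np.exp(1e-3 * zeta * (np.asarray(v, dtype=float) - vh) * FARADAY
                  / (GAS_CONSTANT * temperature_K))


def _ka_thermo_gates(params: Mapping, inact: bool) -> tuple[Callable, Callable]:
    """Thermodynamic A-current gate (Borg-Graham/Migliore form)."""
    vh = float(params["vhalf"])
    zeta0 = float(params["zeta"])
    temperature = float(params.get("temperature_K", DEFAULT_TEMPERATURE_K))
    if inact:
        slope = float(params.get("taul_slope", 0.26))
        v0 = float(params.get("taul_v0", -50.0))
        tmin = float(params.get("tmin", 2.0))

        def inf(v):
            return 1.0 / (1.0 + _thermo_exponent(v, vh, zeta0, temperature))

        def tau(v):
            v = np.asarray(v, dtype=float)
            return np.maximum(slope * (v - v0), tmin)

        return inf, tau

    pw = float(params.get("pw", -1.0))
    tq = float(params.get("tq", -40.0))
    qq = float(params.get("qq", 5.0))
    gm = float(params.get("gm", 0.55))
    a0 = float(params.get("a0", 0.05))
    tmin = float(params.get("tmin", 0.1))
    qt = float(params.get("qt", 1.0))

    def zeta(v):
        return zeta0 + pw / (1.0 + np.exp((np.asarray(v, dtype=float) - tq) / qq))

    def inf(v):
        return 1.0 / (1.0 + _thermo_exponent(v, vh, zeta(v), temperature))

    def tau(v):
        alp = _thermo_exponent(v, vh, zeta(v), temperature)
        bet = _thermo_exponent(v, vh, zeta(v) * gm, temperature)
        return np.maximum(bet / (qt * a0 * (1.0 + alp)), tmin)

    return inf, tau


def _build_gate(cfg: Mapping) -> GatingRule:
    power = int(cfg.get("power", 1))
    if "form" in cfg:
        form = cfg["form"]
        params = cfg.get("params", {})
        if form == "ka_thermo_act":
            inf, tau = _ka_thermo_gates(params, inact=False)
        elif form == "ka_thermo_inact":
            inf, tau = _ka_thermo_gates(params, inact=True)
        elif form == "ca_linear":
            return GatingRule(
                steady_state=None,
                time_constant=None,
                power=power,
                ca_rates=(float(params["a"]), float(params["b"])),
            )
        else:
            raise CatalogError(f"unknown gate form {form!r}")
        return GatingRule(steady_state=inf, time_constant=tau, power=power)
    if "alpha" in cfg:
        alpha = _rate_closure(cfg["alpha"])
        beta = _rate_closure(cfg["beta"])

        def inf(v):
            av, bv = alpha(v), beta(v)
            return av / (av + bv)

        def tau(v):
            return 1.0 / (alpha(v) + beta(v))

        return GatingRule(steady_state=inf, time_constant=tau, power=power)
    inf_cfg = cfg["inf"]
    inf = _sigmoid_inf(float(inf_cfg["vh"]), float(inf_cfg["k"]))
    tau = _tau_closure(cfg["tau"])
    return GatingRule(steady_state=inf, time_constant=tau, power=power)


# ---------------------------------------------------------------------------
# catalog


@functools.lru_cache(maxsize=1)
def _default_catalog_raw() -> dict:
    with open(_CATALOG_PATH) as fh:
        return yaml.safe_load(fh)


def load_catalog(path: str | Path | None = None) -> dict:
    """Raw catalog mapping (channel kind -> kinetics declaration)."""
    if path is None:
        return _default_catalog_raw()
    with open(path) as fh:
        return yaml.safe_load(fh)


def catalog_kinds(catalog: dict | None = None) -> list[str]:
    return sorted((catalog or _default_catalog_raw()).keys())


@functools.lru_cache(maxsize=256)
def _make_channel_default(kind: str, gbar: float) -> ChannelSpec:
    return _make_channel_from(_default_catalog_raw(), kind, gbar)


def _make_channel_from(catalog: dict, kind: str, gbar: float) -> ChannelSpec:
    try:
        entry = catalog[kind]
    except KeyError:
        raise CatalogError(
            f"unknown channel kind {kind!r}; known kinds: {sorted(catalog)}"
        ) from None
    gates = tuple(_build_gate(g) for g in entry["gates"])
    reversal = entry["reversal"]
    if not isinstance(reversal, str):
        reversal = float(reversal)
    return ChannelSpec(
        name=kind,
        gates=gates,
        gbar=float(gbar),
        reversal=reversal,
        feeds_calcium=bool(entry.get("feeds_calcium", False)),
    )


def make_channel(kind: str, gbar: float, catalog: dict | None = None) -> ChannelSpec:
    """Instantiate a catalog channel at the requested maximum conductance
    density (S/cm^2).  With the default catalog, repeated calls with the same
    arguments return the identical object, so cells built from the catalog
    compare equal structurally.
    """
    if gbar < 0:
        raise ValueError("gbar must be >= 0")
    if catalog is None:
        return _make_channel_default(kind, float(gbar))
    return _make_channel_from(catalog, kind, float(gbar))
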