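"""Builders for the three cell models of the glomerular microcircuit.

The periglomerular (PG) cell is a six-compartment interneuron carrying an
HCN current, delayed-rectifier and A-type potassium, fast sodium and a
low-threshold T-type calcium current plus a graded GABAergic autapse on
its gemmule.  The mitral (4 compartments) and granule (3 compartments)
cells follow the published reduced models; only their printed conductance
density tables are taken as-is, everything unprinted (passive constants,
kinetic constants) is a calibration value documented in docs/methods.md.

Parameter sets are versioned YAML fixtures under ``configs/`` and parse
into small dataclasses, so any value can be overridden without touching
code.
"""

from __future__ import annotations

import copy
import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

from .cable import CellModel, CompartmentGeometry, PassiveParameters
from .channels import CalciumPool, make_channel
from .synapses import GradedSynapse, autapse

__all__ = [
    "PGParameters",
    "MitralParameters",
    "GranuleParameters",
    "load_pg_parameters",
    "load_mitral_parameters",
    "load_granule_parameters",
    "build_pg",
    "build_mitral",
    "build_granule",
    "pg_autapse",
]

_CONFIG_DIR = Path(__file__).parent / "configs"


def _load_yaml(source) -> dict:
    if isinstance(source, Mapping):
        return copy.deepcopy(dict(source))
    with open(source) as fh:
        return yaml.safe_load(fh)


def _parse_geometry(entries) -> tuple[CompartmentGeometry, ...]:
    return tuple(
        CompartmentGeometry(
            name=e["name"],
            length_um=float(e["length_um"]),
            diameter_um=float(e["diameter_um"]),
            parent=e.get("parent"),
        )
        for e in entries
    )


def _parse_passive(entry) -> PassiveParameters:
    return PassiveParameters(
        axial_resistivity=float(entry["axial_resistivity"]),
        specific_capacitance=float(entry["specific_capacitance"]),
        leak_conductance_density=float(entry["leak_conductance_density"]),
        leak_reversal=float(entry["leak_reversal"]),
        resting_potential=float(entry["resting_potential"]),
    )


def _parse_pool(entry) -> CalciumPool:
    if entry is None:
        return CalciumPool()
    return CalciumPool(
        shell_depth_um=float(entry.get("shell_depth_um", 0.1)),
        removal_tau_ms=float(entry.get("removal_tau_ms", 5.0)),
        resting_mM=float(entry.get("resting_mM", 2.4e-4)),
        external_mM=float(entry.get("external_mM", 2.0)),
        floor_mM=float(entry.get("floor_mM", 1e-8)),
    )


# ---------------------------------------------------------------------------
# periglomerular cell


@dataclass(frozen=True)
class PGParameters:
    """Fitted PG-cell parameter set.

    ``conductances_nS`` is the per-compartment table of maximum
    conductances; ``densities`` (S/cm^2) are derived from the soma row and
    the soma area, since every current is distributed uniformly.
    ``channel_map`` maps the table columns onto catalog channel kinds and
    can be permuted in the config if an alternative column reading is to
    be explored.
    """

    geometry: tuple[CompartmentGeometry, ...]
    passive: PassiveParameters
    conductances_nS: Mapping[str, Mapping[str, float]]
    channel_map: Mapping[str, str]
    column_order: tuple[str, ...]
    autapse_site: str
    autapse_gmax: float  # uS
    autapse_reversal: float
    autapse_threshold: float
    autapse_slope: float
    autapse_tau: float
    calcium_pool: CalciumPool

    @property
    def densities(self) -> dict[str, float]:
        soma = next(c for c in self.geometry if c.parent is None)
        soma_row = self.conductances_nS[soma.name]
        return {col: soma_row[col] * 1e-9 / soma.area_cm2 for col in self.column_order}

    def with_density(self, column: str, value: float) -> "PGParameters":
        """Copy with one current's uniform density (S/cm^2) replaced."""
        soma = next(c for c in self.geometry if c.parent is None)
        table = {comp: dict(row) for comp, row in self.conductances_nS.items()}
        for comp in table:
            area = next(c for c in self.geometry if c.name == comp).area_cm2
            table[comp][column] = value * area * 1e9
        return replace(self, conductances_nS=table)

    def with_autapse(self, gmax: float) -> "PGParameters":
        return replace(self, autapse_gmax=gmax)

    def to_dict(self) -> dict:
        return {
            "cell": "pg",
            "geometry": [
                {"name": c.name, "length_um": c.length_um,
                 "diameter_um": c.diameter_um, "parent": c.parent}
                for c in self.geometry
            ],
            "passive": {
                "axial_resistivity": self.passive.axial_resistivity,
                "specific_capacitance": self.passive.specific_capacitance,
                "leak_conductance_density": self.passive.leak_conductance_density,
                "leak_reversal": self.passive.leak_reversal,
                "resting_potential": self.passive.resting_potential,
            },
            "column_order": list(self.column_order),
            "channel_map": dict(self.channel_map),
            "conductances_nS": {c: dict(r) for c, r in self.conductances_nS.items()},
            "autapse": {
                "site": self.autapse_site,
                "gmax": self.autapse_gmax,
                "reversal": self.autapse_reversal,
                "threshold": self.autapse_threshold,
                "slope": self.autapse_slope,
                "tau": self.autapse_tau,
            },
            "calcium_pool": {
                "shell_depth_um": self.calcium_pool.shell_depth_um,
                "removal_tau_ms": self.calcium_pool.removal_tau_ms,
                "resting_mM": self.calcium_pool.resting_mM,
                "external_mM": self.calcium_pool.external_mM,
                "floor_mM": self.calcium_pool.floor_mM,
            },
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def load_pg_parameters(source=None) -> PGParameters:
    """Parse a PG parameter config (default: the packaged fitted set)."""
    raw = _load_yaml(source if source is not None else _CONFIG_DIR / "pg_table1.yaml")
    aut = raw["autapse"]
    return PGParameters(
        geometry=_parse_geometry(raw["geometry"]),
        passive=_parse_passive(raw["passive"]),
        conductances_nS={c: dict(r) for c, r in raw["conductances_nS"].items()},
        channel_map=dict(raw["channel_map"]),
        column_order=tuple(raw["column_order"]),
        autapse_site=aut["site"],
        autapse_gmax=float(aut["gmax"]),
        autapse_reversal=float(aut["reversal"]),
        autapse_threshold=float(aut["threshold"]),
        autapse_slope=float(aut["slope"]),
        autapse_tau=float(aut["tau"]),
        calcium_pool=_parse_pool(raw.get("calcium_pool")),
    )


def build_pg(params: PGParameters | None = None) -> CellModel:
    """Six-compartment PG cell with every current on every compartment at
    its uniform density, a calcium pool wherever the T-type current sits,
    and the gemmule marked as the synaptic site."""
    if params is None:
        params = load_pg_parameters()
    densities = params.densities
    channels = []
    pools = {}
    for comp in params.geometry:
        for column in params.column_order:
            kind = params.channel_map[column]
            channels.append((comp.name, make_channel(kind, densities[column])))
            if kind == "pg_cat":
                pools[comp.name] = params.calcium_pool
    return CellModel(
        name="pg",
        compartments=params.geometry,
        passive=params.passive,
        channels=tuple(channels),
        calcium_pools=pools,
        synapse_sites=(params.autapse_site,),
    )


def pg_autapse(cell: CellModel, params: PGParameters | None = None) -> GradedSynapse:
    """The PG cell's graded self-inhibitory synapse on its gemmule."""
    if params is None:
        params = load_pg_parameters()
    return autapse(
        cell,
        params.autapse_site,
        params.autapse_gmax,
        reversal=params.autapse_reversal,
        threshold=params.autapse_threshold,
        slope=params.autapse_slope,
        tau=params.autapse_tau,
    )


# ---------------------------------------------------------------------------
# mitral and granule cells


@dataclass(frozen=True)
class _TabulatedCell:
    geometry: tuple[CompartmentGeometry, ...]
    passive: PassiveParameters
    densities: Mapping[str, Mapping[str, float]]  # column -> comp -> S/cm^2
    channel_map: Mapping[str, str]
    calcium_pool: CalciumPool | None
    synapse_sites: tuple[str, ...]

    def with_density(self, column: str, comp: str, value: float):
        table = {col: dict(row) for col, row in self.densities.items()}
        table[column][comp] = value
        return replace(self, densities=table)

    def to_dict(self) -> dict:
        out = {
            "geometry": [
                {"name": c.name, "length_um": c.length_um,
                 "diameter_um": c.diameter_um, "parent": c.parent}
                for c in self.geometry
            ],
            "passive": {
                "axial_resistivity": self.passive.axial_resistivity,
                "specific_capacitance": self.passive.specific_capacitance,
                "leak_conductance_density": self.passive.leak_conductance_density,
                "leak_reversal": self.passive.leak_reversal,
                "resting_potential": self.passive.resting_potential,
            },
            "channel_map": dict(self.channel_map),
            "densities": {c: dict(r) for c, r in self.densities.items()},
            "synapse_sites": list(self.synapse_sites),
        }
        if self.calcium_pool is not None:
            out["calcium_pool"] = {
                "shell_depth_um": self.calcium_pool.shell_depth_um,
                "removal_tau_ms": self.calcium_pool.removal_tau_ms,
                "resting_mM": self.calcium_pool.resting_mM,
                "external_mM": self.calcium_pool.external_mM,
                "floor_mM": self.calcium_pool.floor_mM,
            }
        return out

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


@dataclass(frozen=True)
class MitralParameters(_TabulatedCell):
    pass


@dataclass(frozen=True)
class GranuleParameters(_TabulatedCell):
    pass


def _load_tabulated(source, cls, default_name):
    raw = _load_yaml(source if source is not None else _CONFIG_DIR / default_name)
    pool = raw.get("calcium_pool")
    return cls(
        geometry=_parse_geometry(raw["geometry"]),
        passive=_parse_passive(raw["passive"]),
        densities={c: dict(r) for c, r in raw["densities"].items()},
        channel_map=dict(raw["channel_map"]),
        calcium_pool=_parse_pool(pool) if pool is not None else None,
        synapse_sites=tuple(raw.get("synapse_sites", ())),
    )


def load_mitral_parameters(source=None) -> MitralParameters:
    return _load_tabulated(source, MitralParameters, "mitral_table3.yaml")


def load_granule_parameters(source=None) -> GranuleParameters:
    return _load_tabulated(source, GranuleParameters, "granule_table4.yaml")


def _build_tabulated(name: str, params: _TabulatedCell,
                     pool_columns: tuple[str, ...] = ()) -> CellModel:
    channels = []
    pools = {}
    for column, row in params.densities.items():
        kind = params.channel_map[column]
        for comp_name, density in row.items():
            if density > 0:
                channels.append((comp_name, make_channel(kind, density)))
                if column in pool_columns and params.calcium_pool is not None:
                    pools[comp_name] = params.calcium_pool
    return CellModel(
        name=name,
        compartments=params.geometry,
        passive=params.passive,
        channels=tuple(channels),
        calcium_pools=pools,
        synapse_sites=params.synapse_sites,
    )


def build_mitral(params: MitralParameters | None = None) -> CellModel:
    """Four-compartment mitral cell (tuft - primary - soma - lateral chain,
    rooted at the soma), with calcium pools wherever the L-type current
    provides influx (feeding the somatic KCa current)."""
    if params is None:
        params = load_mitral_parameters()
    return _build_tabulated("mitral", params, pool_columns=("LCa",))


def build_granule(params: GranuleParameters | None = None) -> CellModel:
    """Three-compartment granule cell (peripheral dendrite, soma, deep
    dendrite)."""
    if params is None:
        params = load_granule_parameters()
    return _build_tabulated("granule", params)
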