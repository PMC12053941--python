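"""Catalyst/ligand/solvent registry and catalyst-ligand parameter lookup.

The registry assigns the integer codes used as experimental-condition
features.  Codes attested in the source literature are fixed
(``[Cp*RuCl2]2`` = 1; no added ligand = 1; ``dtbpy`` = 2); the rest of the
roster follows a conventional order shipped with the package.

The catalyst-ligand parameter table carries steric/geometric descriptors of
the catalytically active complex (percent buried volume, Sterimol B1/B5/L,
pyramidalization about the metal, SASA, volume).  The shipped CSV holds
*synthetic placeholder* values -- plausible magnitudes, flagged
non-authoritative -- because the underlying computed values are not
published as a table; supply your own CSV for real work.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import schema
from .errors import ParameterLookupError, RegistryError


@dataclass(frozen=True)
class ConditionBlock:
    """Integer-encoded experimental conditions for one substrate entry."""

    catalyst_code: int
    ligand_code: int
    active_catalyst_code: int
    boron_source_code: int
    solvent_code: int
    temperature_c: float

    def as_dict(self) -> dict:
        return {
            "catalyst_code": self.catalyst_code,
            "ligand_code": self.ligand_code,
            "active_catalyst_code": self.active_catalyst_code,
            "boron_source_code": self.boron_source_code,
            "solvent_code": self.solvent_code,
            "temperature_c": self.temperature_c,
        }


@dataclass(frozen=True)
class CatalystParams:
    """Steric/geometric parameters of an active catalyst-ligand complex."""

    percent_buried_volume: float
    sterimol_B1: float
    sterimol_B5: float
    sterimol_L: float
    pyramidalization: float
    sasa: float
    volume: float

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in schema.CATALYST_PARAM_COLUMNS}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("borylsite").joinpath("data", name)))


class Registry:
    """Name -> code registry for catalysts, ligands, boron sources, solvents."""

    def __init__(self, path: str | Path | None = None):
        path = _data_path("registry.yaml") if path is None else Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        self.catalysts: dict[str, int] = dict(raw["catalysts"])
        self.ligands: dict[str, int] = dict(raw["ligands"])
        self.boron_sources: dict[str, int] = dict(raw["boron_sources"])
        self.solvents: dict[str, int] = dict(raw["solvents"])
        self.active_catalysts: dict[str, int] = dict(raw.get("active_catalysts", {}))

    def _code(self, table: dict[str, int], name: str, kind: str) -> int:
        try:
            return table[name]
        except KeyError:
            known = ", ".join(sorted(table))
            raise RegistryError(f"unknown {kind} {name!r}; known: {known}") from None

    def active_catalyst_code(self, catalyst: str, ligand: str) -> int:
        key = f"{catalyst}|{ligand}"
        if key in self.active_catalysts:
            return self.active_catalysts[key]
        # deterministic fallback for unlisted pairs, offset past listed codes
        base = max(self.active_catalysts.values(), default=0)
        cat = self._code(self.catalysts, catalyst, "catalyst")
        lig = self._code(self.ligands, ligand, "ligand")
        return base + (cat - 1) * len(self.ligands) + lig

    def encode_conditions(
        self,
        catalyst_name: str,
        ligand_name: str,
        boron_source: str,
        solvent_name: str,
        temperature: float,
    ) -> ConditionBlock:
        """Encode a named condition set as integer codes.

        Raises :class:`RegistryError` for any unknown name, listing the
        known entries of that registry section.
        """
        return ConditionBlock(
            catalyst_code=self._code(self.catalysts, catalyst_name, "catalyst"),
            ligand_code=self._code(self.ligands, ligand_name, "ligand"),
            active_catalyst_code=self.active_catalyst_code(catalyst_name, ligand_name),
            boron_source_code=self._code(self.boron_sources, boron_source, "boron source"),
            solvent_code=self._code(self.solvents, solvent_name, "solvent"),
            temperature_c=float(temperature),
        )


_DEFAULT_REGISTRY: Registry | None = None


def default_registry() -> Registry:
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = Registry()
    return _DEFAULT_REGISTRY


def encode_conditions(
    catalyst_name: str,
    ligand_name: str,
    boron_source: str,
    solvent_name: str,
    temperature: float,
    registry: Registry | None = None,
) -> ConditionBlock:
    """Module-level convenience wrapper over :meth:`Registry.encode_conditions`."""
    reg = registry or default_registry()
    return reg.encode_conditions(
        catalyst_name, ligand_name, boron_source, solvent_name, temperature
    )


def load_catalyst_param_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a catalyst-ligand parameter CSV (default: shipped synthetic table)."""
    path = _data_path("catalyst_params_synthetic.csv") if path is None else Path(path)
    return pd.read_csv(path)


def lookup_catalyst_params(
    catalyst_code: int,
    ligand_code: int,
    table: pd.DataFrame,
    registry: Registry | None = None,
) -> CatalystParams:
    """Look up the parameter vector for a (catalyst, ligand) code pair.

    Pairs that form the same active catalyst share one parameter vector by
    construction of the table.

    Raises :class:`ParameterLookupError` if the pair has no row.
    """
    reg = registry or default_registry()
    cat_by_code = {v: k for k, v in reg.catalysts.items()}
    lig_by_code = {v: k for k, v in reg.ligands.items()}
    cat = cat_by_code.get(catalyst_code)
    lig = lig_by_code.get(ligand_code)
    if cat is None or lig is None:
        raise ParameterLookupError(
            f"unresolvable codes (catalyst={catalyst_code}, ligand={ligand_code})"
        )
    rows = table[(table["catalyst"] == cat) & (table["ligand"] == lig)]
    if rows.empty:
        raise ParameterLookupError(f"no parameter row for pair ({cat!r}, {lig!r})")
    row = rows.iloc[0]
    return CatalystParams(**{c: float(row[c]) for c in schema.CATALYST_PARAM_COLUMNS})
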