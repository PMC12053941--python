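"""Substrate parsing, candidate C-H site enumeration and site-table I/O.

A *candidate site* is any sp2 or sp3 carbon bearing at least one hydrogen;
these are the positions a transition-metal boryl complex could in principle
functionalize.  Symmetry-equivalent positions (e.g. the six CH of benzene)
are collapsed to one representative using topological (graph-automorphism)
equivalence, matching how unique positions are counted in a curated
reaction database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.rdchem import HybridizationType

from . import schema
from .errors import IntegrityError, ParseError, SchemaError

RDLogger.DisableLog("rdApp.*")


@dataclass
class Substrate:
    """A parsed substrate with a deterministic canonical atom order.

    ``mol`` is re-built from the canonical SMILES of the input structure, so
    atom indices are stable for a given molecule regardless of how the input
    text ordered its atoms.
    """

    substrate_id: str
    structure: str
    mol: Chem.Mol
    canonical_smiles: str
    inchi: str
    conditions: Mapping | None = None


@dataclass(frozen=True)
class Site:
    """One candidate C-H borylation site (0-based canonical atom index)."""

    substrate_id: str
    atom_index: int
    h_count: int
    hybridization: str  # "sp2" | "sp3"
    symmetry_class: int


@dataclass
class SiteRecord:
    """A site together with its feature blocks and (optional) label."""

    site: Site
    charges: dict = field(default_factory=dict)
    descriptors: dict = field(default_factory=dict)
    conditions: dict = field(default_factory=dict)
    label: int | None = None


_HYBRID = {HybridizationType.SP2: "sp2", HybridizationType.SP3: "sp3"}


def parse_substrate(
    structure_text: str,
    substrate_id: str | None = None,
    conditions: Mapping | None = None,
) -> Substrate:
    """Parse an InChI or SMILES string into a :class:`Substrate`.

    The molecule is canonicalized (rebuilt from its canonical SMILES) so
    that atom indices form a deterministic join key for externally computed
    per-atom charge tables.

    Raises
    ------
    ParseError
        If the text is empty or does not parse to a valid molecule.
    """
    text = (structure_text or "").strip()
    if not text:
        raise ParseError(structure_text, "empty structure string")
    if text.startswith("InChI="):
        mol = Chem.MolFromInchi(text)
    else:
        mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ParseError(text)
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:  # pragma: no cover - canonical SMILES always re-parses
        raise ParseError(text, f"canonical SMILES failed to re-parse: {canonical!r}")
    inchi = Chem.MolToInchi(mol) or ""
    if substrate_id is None:
        substrate_id = Chem.MolToInchiKey(mol) or canonical
    return Substrate(
        substrate_id=substrate_id,
        structure=structure_text,
        mol=mol,
        canonical_smiles=canonical,
        inchi=inchi,
        conditions=conditions,
    )


def _is_aldehydic(atom: Chem.Atom) -> bool:
    """Formyl-type carbon: double bond from C to O (out of C-H scope)."""
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        if other.GetAtomicNum() == 8 and bond.GetBondType() == Chem.BondType.DOUBLE:
            return True
    return False


def enumerate_candidate_sites(
    substrate: Substrate, collapse_symmetry: bool = True
) -> list[Site]:
    """Enumerate candidate C-H borylation sites of a substrate.

    Eligible atoms are sp2 or sp3 carbons with >= 1 bonded hydrogen;
    sp carbons, H-free carbons and aldehydic carbons are excluded.  With
    ``collapse_symmetry`` one site is returned per topological symmetry
    class (canonical-rank equivalence without tie-breaking); the site with
    the lowest atom index represents its class.
    """
    mol = substrate.mol
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    sites: list[Site] = []
    seen_classes: set[int] = set()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6:
            continue
        if atom.GetTotalNumHs() < 1:
            continue
        hyb = _HYBRID.get(atom.GetHybridization())
        if hyb is None:
            continue
        if _is_aldehydic(atom):
            continue
        cls = ranks[atom.GetIdx()]
        if collapse_symmetry and cls in seen_classes:
            continue
        seen_classes.add(cls)
        sites.append(
            Site(
                substrate_id=substrate.substrate_id,
                atom_index=atom.GetIdx(),
                h_count=atom.GetTotalNumHs(),
                hybridization=hyb,
                symmetry_class=cls,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# site-table I/O
# ---------------------------------------------------------------------------

def records_to_table(records: Iterable[SiteRecord]) -> pd.DataFrame:
    """Flatten :class:`SiteRecord` objects into the site-table DataFrame."""
    rows = []
    for rec in records:
        row: dict = {
            "substrate_id": rec.site.substrate_id,
            "inchi": "",
            "atom_index": rec.site.atom_index,
            "hybridization": rec.site.hybridization,
            "h_count": rec.site.h_count,
            "symmetry_class": rec.site.symmetry_class,
        }
        row.update(rec.charges)
        row.update(rec.conditions)
        row.update(rec.descriptors)
        if rec.label is not None:
            row["label"] = rec.label
        rows.append(row)
    return pd.DataFrame(rows)


def table_to_records(table: pd.DataFrame) -> list[SiteRecord]:
    """Inverse of :func:`records_to_table` (columns routed by name)."""
    records = []
    charge_cols = [c for c in table.columns if schema.is_charge_column(c)]
    cond_cols = [c for c in table.columns if c in schema.CONDITION_COLUMNS
                 or c in schema.CATALYST_PARAM_COLUMNS]
    skip = set(schema.META_COLUMNS) | {schema.LABEL_COLUMN} | set(charge_cols) | set(cond_cols)
    desc_cols = [c for c in table.columns if c not in skip]
    for _, row in table.iterrows():
        site = Site(
            substrate_id=row["substrate_id"],
            atom_index=int(row["atom_index"]),
            h_count=int(row["h_count"]),
            hybridization=row["hybridization"],
            symmetry_class=int(row.get("symmetry_class", -1)),
        )
        records.append(
            SiteRecord(
                site=site,
                charges={c: row[c] for c in charge_cols},
                conditions={c: row[c] for c in cond_cols},
                descriptors={c: row[c] for c in desc_cols},
                label=int(row["label"]) if "label" in table.columns else None,
            )
        )
    return records


def validate_site_table(
    table: pd.DataFrame, training: bool = False, curated: bool = False
) -> pd.DataFrame:
    """Validate the site-table schema and dataset invariants.

    ``training`` requires the ``label`` column; ``curated`` additionally
    enforces at most one label-1 site per substrate (the curated-database
    invariant -- off by default because condition-resolved datasets hold
    the same substrate under different conditions with different selected
    sites).
    """
    missing = [c for c in schema.MANDATORY_COLUMNS if c not in table.columns]
    if training and schema.LABEL_COLUMN not in table.columns:
        missing.append(schema.LABEL_COLUMN)
    if missing:
        raise SchemaError(f"site table missing mandatory columns: {missing}")
    dup = table.duplicated(subset=["substrate_id", "atom_index"])
    if dup.any():
        pairs = table.loc[dup, ["substrate_id", "atom_index"]].values.tolist()
        raise IntegrityError(f"duplicate (substrate_id, atom_index) rows: {pairs[:5]}")
    if curated and schema.LABEL_COLUMN in table.columns:
        pos = table[table[schema.LABEL_COLUMN] == 1]
        counts = pos.groupby("substrate_id").size()
        bad = counts[counts > 1]
        if len(bad):
            raise IntegrityError(
                f"curated mode: substrates with >1 selective site: {list(bad.index)[:5]}"
            )
    return table


def read_site_table(
    path: str | Path, training: bool = False, curated: bool = False
) -> pd.DataFrame:
    """Read and validate a site-table CSV; unknown columns are preserved."""
    table = pd.read_csv(path, float_precision="round_trip")
    return validate_site_table(table, training=training, curated=curated)


def write_site_table(table: pd.DataFrame | Iterable[SiteRecord], path: str | Path) -> None:
    """Write a site table (DataFrame or records) to CSV.

    Floats are written with ``repr`` round-trip precision so that a
    write/read cycle preserves every numeric value exactly.
    """
    if not isinstance(table, pd.DataFrame):
        table = records_to_table(table)
    table.to_csv(path, index=False, float_format=lambda x: repr(float(x)))
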