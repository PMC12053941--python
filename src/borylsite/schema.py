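"""Canonical column naming for the per-site table.

One row of the site table is one candidate C-H borylation site.  The table
carries four kinds of feature columns next to the identifying metadata:

* **charges** -- computed atomic charges at the site, three values per
  charge scheme: the site hydrogen (``q_h``), the site carbon (``q_c``)
  and the "heavy atom" charge ``q_heavy`` (carbon charge with the bonded
  hydrogens summed in);
* **experimental** -- integer-encoded reaction conditions (catalyst,
  ligand, active catalyst, boron source, solvent) plus temperature and,
  when supplied, the steric/geometric catalyst-ligand parameters;
* **steric_topological** -- four per-site atom-level descriptors (steric
  effect index, atomic polarizability of the bonding carbon, distance
  degree, Dreiding energy);
* **molecular_descriptors** -- molecule-level 2-D descriptors, constant
  across the sites of one substrate.
"""

from __future__ import annotations

CHARGE_SCHEMES = ("mulliken", "npa", "mbs", "hirshfeld", "cm5", "chelpg")
CHARGE_KINDS = ("q_h", "q_c", "q_heavy")

#: Metadata columns that identify a site and are never used as features.
META_COLUMNS = (
    "substrate_id",
    "inchi",
    "atom_index",
    "hybridization",
    "h_count",
    "symmetry_class",
)

LABEL_COLUMN = "label"

#: Mandatory columns of the site-table CSV.
MANDATORY_COLUMNS = ("substrate_id", "inchi", "atom_index", "hybridization", "h_count")

CONDITION_COLUMNS = (
    "catalyst_code",
    "ligand_code",
    "active_catalyst_code",
    "boron_source_code",
    "solvent_code",
    "temperature_c",
)

CATALYST_PARAM_COLUMNS = (
    "percent_buried_volume",
    "sterimol_B1",
    "sterimol_B5",
    "sterimol_L",
    "pyramidalization",
    "sasa",
    "volume",
)

STERIC_TOPOLOGICAL_COLUMNS = (
    "steric_effect_index",
    "atomic_polarizability",
    "distance_degree",
    "dreiding_energy",
)


def charge_columns() -> list[str]:
    """All 18 charge column names (6 schemes x {q_h, q_c, q_heavy})."""
    return [f"{scheme}_{kind}" for scheme in CHARGE_SCHEMES for kind in CHARGE_KINDS]


def is_charge_column(name: str) -> bool:
    parts = name.split("_", 1)
    return len(parts) == 2 and parts[0] in CHARGE_SCHEMES and parts[1] in CHARGE_KINDS


def feature_columns(columns) -> list[str]:
    """Feature (non-metadata, non-label) column names, in table order."""
    skip = set(META_COLUMNS) | {LABEL_COLUMN}
    return [c for c in columns if c not in skip]


#: The 35 features of the final production model, in canonical order:
#: 8 atomic-charge features, 4 atom-level steric/topological features and
#: 23 molecule-level descriptors.
FINAL_FEATURE_LIST = (
    # charges
    "hirshfeld_q_heavy",
    "hirshfeld_q_c",
    "hirshfeld_q_h",
    "chelpg_q_heavy",
    "chelpg_q_h",
    "npa_q_h",
    "mulliken_q_heavy",
    "mulliken_q_h",
    # steric / topological, at the reacting carbon
    "steric_effect_index",
    "atomic_polarizability",
    "distance_degree",
    "dreiding_energy",
    # molecular descriptors
    "AATS2d",
    "AATS1s",
    "AATS2Z",
    "AATS0v",
    "AATS4p",
    "AATS1i",
    "ATSC1d",
    "ATSC2d",
    "AATSC2dv",
    "AATSC4d",
    "AATSC3Z",
    "AATSC5v",
    "AATSC1pe",
    "MATS1c",
    "MATS5s",
    "MATS1p",
    "GATS3c",
    "GATS4c",
    "GATS1v",
    "GATS2pe",
    "BCUTZ-1l",
    "RPCG",
    "FilterItLogS",
)

assert len(FINAL_FEATURE_LIST) == 35
assert len(set(FINAL_FEATURE_LIST)) == 35

#: Names of the 23 molecule-level descriptors within the final 35.
FINAL_MOLECULAR_DESCRIPTORS = FINAL_FEATURE_LIST[12:]
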