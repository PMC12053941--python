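"""Per-site feature assembly: charges, molecular descriptors, conditions.

Charge features come from external quantum-chemistry output (six schemes:
Mulliken, NPA, MBS, Hirshfeld, CM5, ChelpG; the package never computes
them).  Molecular descriptors are computed here on the 2-D molecular graph:
topological autocorrelations (Moreau-Broto ATS/AATS, centered ATSC/AATSC,
Moran MATS, Geary GATS) over ten atomic property weightings, a Burden-matrix
eigenvalue (BCUTZ-1l), the relative positive charge RPCG, and an aqueous
solubility estimate filling the FilterItLogS column slot.

Atom-level steric/topological descriptors (steric effect index, atomic
polarizability of the bonding carbon, distance degree, Dreiding energy) are
normally supplied as input columns from external software; the
``steric_topological_fallback`` surrogate fills them from graph topology
when absent and is clearly labeled as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdmolops

from . import schema
from .errors import AssemblyError, SchemaError
from .sites import Site, SiteRecord, Substrate

# ---------------------------------------------------------------------------
# charges
# ---------------------------------------------------------------------------

HEAVY_CHARGE_TOL = 1e-9


def heavy_atom_charge(q_c: float, q_h_list: Sequence[float]) -> float:
    """Carbon charge with the bonded hydrogens' charges summed in (e).

    An empty hydrogen list returns the carbon charge unchanged.
    """
    return float(q_c) + float(np.sum(q_h_list)) if len(q_h_list) else float(q_c)


@dataclass(frozen=True)
class SchemeCharges:
    """Charges of one scheme at one site: hydrogen, carbon, heavy atom (e)."""

    q_h: float
    q_c: float
    q_heavy: float


def charge_block(
    per_scheme: Mapping[str, tuple[float, Sequence[float]]]
) -> dict[str, SchemeCharges]:
    """Build a per-scheme charge block from (q_C, [q_H...]) inputs.

    The heavy-atom charge is derived as q_C + sum(q_H); the stored q_h is
    the charge of the (symmetry-equivalent) site hydrogen, taken as the
    first entry of the list.
    """
    block = {}
    for scheme, (q_c, q_h_list) in per_scheme.items():
        if scheme not in schema.CHARGE_SCHEMES:
            raise SchemaError(f"unknown charge scheme {scheme!r}")
        q_h = float(q_h_list[0]) if len(q_h_list) else 0.0
        block[scheme] = SchemeCharges(
            q_h=q_h, q_c=float(q_c), q_heavy=heavy_atom_charge(q_c, q_h_list)
        )
    return block


def read_charge_table(path, site_h_counts: Mapping[tuple[str, int], int]) -> pd.DataFrame:
    """Read a long-format charges CSV into wide per-site charge columns.

    Input columns: ``substrate_id, atom_index, scheme, q_H, q_C``.  The
    heavy-atom charge is derived as ``q_C + h_count * q_H`` using the site's
    hydrogen count (site hydrogens are symmetry-equivalent, so one q_H value
    represents them all).
    """
    long = pd.read_csv(path)
    required = {"substrate_id", "atom_index", "scheme", "q_H", "q_C"}
    missing = required - set(long.columns)
    if missing:
        raise SchemaError(f"charges CSV missing columns: {sorted(missing)}")
    rows: dict[tuple[str, int], dict] = {}
    for _, r in long.iterrows():
        key = (r["substrate_id"], int(r["atom_index"]))
        scheme = str(r["scheme"]).lower()
        if scheme not in schema.CHARGE_SCHEMES:
            raise SchemaError(f"unknown charge scheme {r['scheme']!r}")
        h_count = site_h_counts.get(key, 1)
        entry = rows.setdefault(key, {"substrate_id": key[0], "atom_index": key[1]})
        entry[f"{scheme}_q_h"] = float(r["q_H"])
        entry[f"{scheme}_q_c"] = float(r["q_C"])
        entry[f"{scheme}_q_heavy"] = heavy_atom_charge(
            float(r["q_C"]), [float(r["q_H"])] * h_count
        )
    return pd.DataFrame(list(rows.values()))


# ---------------------------------------------------------------------------
# atomic property weightings for autocorrelation descriptors
# ---------------------------------------------------------------------------

# element constants for common organic elements; vdW radii (Bondi/Alvarez, A),
# polarizability (1e-24 cm^3), ionization energy (eV), Pauling EN, mass (u)
_ELEMENTS = {
    #  Z: (vdw_r, alpha, ie, en, mass)
    1: (1.20, 0.667, 13.598, 2.20, 1.008),
    5: (1.92, 3.03, 8.298, 2.04, 10.811),
    6: (1.70, 1.76, 11.260, 2.55, 12.011),
    7: (1.55, 1.10, 14.534, 3.04, 14.007),
    8: (1.52, 0.802, 13.618, 3.44, 15.999),
    9: (1.47, 0.557, 17.423, 3.98, 18.998),
    14: (2.10, 5.38, 8.152, 1.90, 28.086),
    15: (1.80, 3.63, 10.487, 2.19, 30.974),
    16: (1.80, 2.90, 10.360, 2.58, 32.06),
    17: (1.75, 2.18, 12.968, 3.16, 35.45),
    35: (1.85, 3.05, 11.814, 2.96, 79.904),
    53: (1.98, 5.35, 10.451, 2.66, 126.904),
}

_COVALENT_R = {1: 0.31, 5: 0.84, 6: 0.76, 7: 0.71, 8: 0.66, 9: 0.57, 14: 1.11,
               15: 1.07, 16: 1.05, 17: 1.02, 35: 1.20, 53: 1.39}

#: weighting codes used in descriptor names, in Mordred-style notation
WEIGHT_CODES = ("c", "dv", "d", "s", "Z", "m", "v", "pe", "p", "i")


def _principal_quantum_number(z: int) -> int:
    for n, top in ((1, 2), (2, 10), (3, 18), (4, 36), (5, 54)):
        if z <= top:
            return n
    return 6


def _element(z: int):
    if z not in _ELEMENTS:
        return None
    return _ELEMENTS[z]


def _atom_weights(mol_h: Chem.Mol) -> dict[str, np.ndarray]:
    """Per-atom property vectors on the explicit-hydrogen graph.

    c: Gasteiger partial charge; dv: valence-electron count minus bonded H
    (Kier-Hall delta-v); d: heavy-atom degree (sigma skeleton); s: Kier-Hall
    intrinsic state; Z: atomic number; m: mass; v: van der Waals volume;
    pe: Pauling electronegativity; p: atomic polarizability; i: first
    ionization energy.  Atoms of elements outside the table yield NaN,
    which propagates to a flagged missing descriptor.
    """
    n = mol_h.GetNumAtoms()
    Chem.rdPartialCharges.ComputeGasteigerCharges(mol_h)
    w = {code: np.full(n, np.nan) for code in WEIGHT_CODES}
    pt = Chem.GetPeriodicTable()
    for atom in mol_h.GetAtoms():
        idx = atom.GetIdx()
        z = atom.GetAtomicNum()
        g = atom.GetDoubleProp("_GasteigerCharge")
        w["c"][idx] = g
        w["Z"][idx] = z
        n_h = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 1)
        zv = pt.GetNOuterElecs(z)
        dv = max(zv - n_h, 1) if z > 1 else 1
        d = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1)
        w["dv"][idx] = dv
        w["d"][idx] = d
        pqn = _principal_quantum_number(z)
        w["s"][idx] = ((2.0 / pqn) ** 2 * dv + 1.0) / d if d > 0 else 0.0
        el = _element(z)
        if el is not None:
            vdw_r, alpha, ie, en, mass = el
            w["m"][idx] = mass
            w["v"][idx] = 4.0 / 3.0 * pi * vdw_r**3
            w["pe"][idx] = en
            w["p"][idx] = alpha
            w["i"][idx] = ie
    return w


# ---------------------------------------------------------------------------
# autocorrelation descriptors
# ---------------------------------------------------------------------------

MAX_LAG = 5


def _autocorrelations(dist: np.ndarray, w: np.ndarray, max_lag: int = MAX_LAG) -> dict[str, float]:
    """All autocorrelation statistics of one weight vector.

    Returns a dict keyed by descriptor family+lag (without the weight code):
    ATS{k}, AATS{k} for k = 0..max_lag and ATSC{k}, AATSC{k}, MATS{k} (k>=1),
    GATS{k} (k>=1).  Lags with no atom pairs, or weights with zero variance
    (for MATS/GATS), give NaN -- a flagged missing value, never a silent 0.
    """
    n = len(w)
    out: dict[str, float] = {}
    if np.any(np.isnan(w)):
        for k in range(max_lag + 1):
            out[f"ATS{k}"] = out[f"AATS{k}"] = out[f"ATSC{k}"] = out[f"AATSC{k}"] = np.nan
            if k >= 1:
                out[f"MATS{k}"] = out[f"GATS{k}"] = np.nan
        return out
    wc = w - w.mean()
    var = float(np.mean(wc**2))  # biased variance, matches AATSC0
    denom_geary = float(np.sum(wc**2) / (n - 1)) if n > 1 else np.nan
    iu = np.triu_indices(n, k=1)
    d_pairs = dist[iu]
    for k in range(max_lag + 1):
        if k == 0:
            out["ATS0"] = float(np.sum(w**2))
            out["AATS0"] = out["ATS0"] / n
            out["ATSC0"] = float(np.sum(wc**2))
            out["AATSC0"] = out["ATSC0"] / n
            continue
        mask = d_pairs == k
        n_k = int(mask.sum())
        if n_k == 0:
            out[f"ATS{k}"] = out[f"AATS{k}"] = out[f"ATSC{k}"] = out[f"AATSC{k}"] = np.nan
            out[f"MATS{k}"] = out[f"GATS{k}"] = np.nan
            continue
        wi, wj = w[iu[0][mask]], w[iu[1][mask]]
        wci, wcj = wc[iu[0][mask]], wc[iu[1][mask]]
        out[f"ATS{k}"] = float(np.sum(wi * wj))
        out[f"AATS{k}"] = out[f"ATS{k}"] / n_k
        out[f"ATSC{k}"] = float(np.sum(wci * wcj))
        out[f"AATSC{k}"] = out[f"ATSC{k}"] / n_k
        out[f"MATS{k}"] = out[f"AATSC{k}"] / var if var > 0 else np.nan
        gnum = float(np.sum((wi - wj) ** 2) / (2 * n_k))
        out[f"GATS{k}"] = gnum / denom_geary if denom_geary and denom_geary > 0 else np.nan
    return out


def _burden_lowest_eigenvalue(mol: Chem.Mol) -> float:
    """Lowest eigenvalue of the Burden matrix with atomic number diagonal.

    Hydrogen-suppressed graph; off-diagonal 0.1 x bond order for bonded
    pairs (1.5 for aromatic), 0.001 otherwise.
    """
    n = mol.GetNumAtoms()
    if n == 0:
        return np.nan
    b = np.full((n, n), 0.001)
    for i in range(n):
        b[i, i] = mol.GetAtomWithIdx(i).GetAtomicNum()
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        order = bond.GetBondTypeAsDouble()
        b[i, j] = b[j, i] = 0.1 * order
    return float(np.min(np.linalg.eigvalsh(b)))


def _relative_positive_charge(mol_h: Chem.Mol) -> float:
    """RPCG: largest positive Gasteiger charge / sum of positive charges."""
    Chem.rdPartialCharges.ComputeGasteigerCharges(mol_h)
    q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in mol_h.GetAtoms()])
    q = q[np.isfinite(q)]
    pos = q[q > 0]
    if pos.size == 0:
        return 0.0
    return float(pos.max() / pos.sum())


def _log_solubility(mol: Chem.Mol) -> float:
    """Estimated aqueous solubility logS (mol/L), ESOL-style linear model.

    logS = 0.16 - 0.63 clogP - 0.0062 MW + 0.066 RB - 0.74 AP, where AP is
    the aromatic proportion of heavy atoms.  Fills the FilterItLogS column
    slot of the final feature list.
    """
    clogp = Crippen.MolLogP(mol)
    mw = Descriptors.MolWt(mol)
    rb = Descriptors.NumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    arom = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    ap = arom / heavy if heavy else 0.0
    return 0.16 - 0.63 * clogp - 0.0062 * mw + 0.066 * rb - 0.74 * ap


def compute_molecular_descriptors(substrate: Substrate, max_lag: int = MAX_LAG) -> dict[str, float]:
    """Molecule-level descriptor map for one substrate.

    Contains every autocorrelation family x lag x weighting combination
    (names like ``AATS2d``, ``MATS1c``, ``GATS4c``), ``BCUTZ-1l``, ``RPCG``
    and ``FilterItLogS`` -- a superset of the 23 molecular descriptors of
    the final feature list.  Values are identical for all sites of the
    substrate.  Undefined descriptors are NaN (flagged missing).
    """
    mol_h = Chem.AddHs(substrate.mol)
    dist = rdmolops.GetDistanceMatrix(mol_h)
    weights = _atom_weights(mol_h)
    out: dict[str, float] = {}
    for code, w in weights.items():
        for stem, value in _autocorrelations(dist, w, max_lag).items():
            out[f"{stem}{code}"] = value
    out["BCUTZ-1l"] = _burden_lowest_eigenvalue(substrate.mol)
    out["RPCG"] = _relative_positive_charge(mol_h)
    out["FilterItLogS"] = _log_solubility(substrate.mol)
    return out


# ---------------------------------------------------------------------------
# atom-level steric/topological surrogates
# ---------------------------------------------------------------------------

def steric_topological_fallback(substrate: Substrate, site: Site) -> dict[str, float]:
    """Topological surrogates for the four external atom-level descriptors.

    These stand in for values normally supplied as input columns and are
    *surrogates*, not reimplementations: steric effect index as a
    distance-weighted covalent-volume sum around the reacting carbon;
    atomic polarizability as a distance-damped sum of element
    polarizabilities; distance degree as the graph distance sum from the
    site carbon; Dreiding energy as a topological flexibility/ring
    surrogate at molecule level.
    """
    mol = substrate.mol
    dist = rdmolops.GetDistanceMatrix(mol)
    c = site.atom_index
    sei = 0.0
    pol = 0.0
    for atom in mol.GetAtoms():
        j = atom.GetIdx()
        z = atom.GetAtomicNum()
        r_cov = _COVALENT_R.get(z, 1.0)
        el = _element(z)
        alpha = el[1] if el else 1.5
        if j == c:
            pol += alpha
            continue
        d = dist[c, j]
        sei += r_cov**3 / d**3
        pol += alpha / 2.0**d
    ddeg = float(dist[c].sum())
    ring_info = mol.GetRingInfo()
    dreiding = (
        0.3 * mol.GetNumHeavyAtoms()
        + 1.2 * ring_info.NumRings()
        + 0.5 * Descriptors.NumRotatableBonds(mol)
    )
    return {
        "steric_effect_index": sei,
        "atomic_polarizability": pol,
        "distance_degree": ddeg,
        "dreiding_energy": dreiding,
    }


# ---------------------------------------------------------------------------
# feature-matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Labeled design matrix with substrate grouping.

    ``X`` holds one row per site in the requested feature order; ``y`` the
    binary labels (None for unlabeled prediction sets); ``groups`` the
    substrate id of each row, used for substrate-grouped splitting.
    """

    X: pd.DataFrame
    y: pd.Series | None
    groups: pd.Series

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def __len__(self) -> int:
        return len(self.X)


def assemble_feature_matrix(
    records: "pd.DataFrame | Iterable[SiteRecord]",
    feature_set: Sequence[str],
    require_label: bool = True,
) -> FeatureMatrix:
    """Assemble the design matrix from site records or a site table.

    Columns follow ``feature_set`` order exactly.  A feature missing from
    any record, or a NaN in a requested column, raises
    :class:`AssemblyError` naming the offending row and column.
    """
    if not isinstance(records, pd.DataFrame):
        from .sites import records_to_table

        table = records_to_table(list(records))
    else:
        table = records
    if len(table) == 0:
        empty = pd.DataFrame(columns=list(feature_set), dtype=float)
        return FeatureMatrix(X=empty, y=pd.Series(dtype=int) if require_label else None,
                             groups=pd.Series(dtype=object))
    missing_cols = [c for c in feature_set if c not in table.columns]
    if missing_cols:
        raise AssemblyError(f"features absent from records: {missing_cols}")
    X = table.loc[:, list(feature_set)].astype(float).reset_index(drop=True)
    bad = X.columns[X.isna().any()]
    if len(bad):
        row = int(X[bad[0]].isna().idxmax())
        sid = table.iloc[row]["substrate_id"] if "substrate_id" in table.columns else row
        raise AssemblyError(f"missing value in feature {bad[0]!r} (substrate {sid!r})")
    groups = table["substrate_id"].reset_index(drop=True)
    y = None
    if schema.LABEL_COLUMN in table.columns:
        y = table[schema.LABEL_COLUMN].astype(int).reset_index(drop=True)
    elif require_label:
        raise AssemblyError("records carry no labels but require_label=True")
    return FeatureMatrix(X=X, y=y, groups=groups)
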