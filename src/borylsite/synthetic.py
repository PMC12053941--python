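"""Seeded synthetic site-level datasets with a planted charge-window rule.

The generator emulates the statistical structure a borylation-selectivity
classifier exploits, without requiring any quantum-chemistry input:

* one borylating (label-1) site per substrate, several nonborylating
  sites, giving roughly a 1:4.2 class imbalance (189 substrates with a
  mean of ~5.2 sites each yields ~189 positive and ~798 negative rows);
* borylating sites draw their key charges inside the empirical windows
  observed for site-selective borylation -- Hirshfeld H in [0.04, 0.06] e,
  ChelpG (ESP) heavy atom in [-0.2, 0.1] e, Mulliken H in [0.10, 0.14] e
  (closed intervals) -- while nonborylating sites draw from wider,
  partially overlapping spreads but never inside all three windows at
  once, so the window rule is Bayes-optimal on noiseless data;
* linear charge-charge trends (NPA-H and Hirshfeld-heavy coupled to
  Hirshfeld-H), condition columns sampled from the shipped registry, and
  molecule-level nuisance descriptors that carry no signal.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from .errors import ConfigError, SchemaError
from .registry import Registry, default_registry

#: default charge windows of the planted selectivity rule (closed intervals, e)
DEFAULT_WINDOWS = {
    "hirshfeld_q_h": (0.04, 0.06),
    "chelpg_q_heavy": (-0.2, 0.1),
    "mulliken_q_h": (0.10, 0.14),
}

#: wider spreads the nonborylating sites draw from (overlap the windows)
DEFAULT_SPREADS = {
    "hirshfeld_q_h": (0.00, 0.12),
    "chelpg_q_heavy": (-0.45, 0.35),
    "mulliken_q_h": (0.02, 0.24),
}


@dataclass
class SyntheticConfig:
    """Study-condition defaults: 189 substrates, ~987 sites, 5% label noise."""

    n_substrates: int = 189
    mean_extra_sites: float = 4.22  # sites/substrate = 1 + Poisson(mean)
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    spreads: dict = field(default_factory=lambda: dict(DEFAULT_SPREADS))
    # linear couplings: value = slope * hirshfeld_q_h + intercept + N(0, sd)
    npa_coupling: tuple[float, float, float] = (4.0, 0.01, 0.010)
    hirshfeld_heavy_coupling: tuple[float, float, float] = (1.5, -0.12, 0.010)
    label_noise: float = 0.05
    n_noise_descriptors: int = 40
    n_duplicate_descriptors: int = 3
    n_constant_descriptors: int = 1
    include_final_descriptor_names: bool = True
    ligand_switch: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name, (lo, hi) in self.windows.items():
            if not lo < hi:
                raise ConfigError(f"degenerate window for {name}: [{lo}, {hi}]")
        for name, (lo, hi) in self.spreads.items():
            if not lo < hi:
                raise ConfigError(f"degenerate spread for {name}: [{lo}, {hi}]")
        if not 0.0 <= self.label_noise < 0.5:
            raise ConfigError("label_noise must be in [0, 0.5)")
        if self.n_substrates < 2:
            raise ConfigError("need at least 2 substrates")


def _in_window(value: float, window: tuple[float, float]) -> bool:
    return window[0] <= value <= window[1]


def planted_rule_classifier(record, windows: dict | None = None) -> int:
    """The planted selectivity rule: 1 iff all three charge windows hold.

    ``record`` is a mapping (table row, dict or Series) that must contain
    ``hirshfeld_q_h``, ``chelpg_q_heavy`` and ``mulliken_q_h``.  Windows are
    closed intervals, so boundary values classify as borylating.
    """
    windows = windows or DEFAULT_WINDOWS
    try:
        values = {name: float(record[name]) for name in windows}
    except (KeyError, IndexError) as exc:
        raise SchemaError(f"record missing charge feature: {exc}") from exc
    for name, window in windows.items():
        if np.isnan(values[name]):
            raise SchemaError(f"record has missing charge value for {name!r}")
        if not _in_window(values[name], window):
            return 0
    return 1


def _draw_borylating(rng: np.random.Generator, cfg: SyntheticConfig) -> dict[str, float]:
    return {
        name: rng.uniform(lo, hi) for name, (lo, hi) in cfg.windows.items()
    }


def _draw_nonborylating(rng: np.random.Generator, cfg: SyntheticConfig) -> dict[str, float]:
    # rejection sampling: at least one of the three key charges must fall
    # outside its window, so the planted rule stays exact on clean labels
    while True:
        draw = {name: rng.uniform(*cfg.spreads[name]) for name in cfg.windows}
        if not all(_in_window(draw[k], cfg.windows[k]) for k in cfg.windows):
            return draw


def _condition_row(rng: np.random.Generator, registry: Registry) -> dict[str, float]:
    pairs = list(registry.active_catalysts)
    key = pairs[rng.integers(len(pairs))]
    catalyst, ligand = key.split("|")
    block = registry.encode_conditions(
        catalyst_name=catalyst,
        ligand_name=ligand,
        boron_source=("HBpin", "B2pin2")[rng.integers(2)],
        solvent_name=list(registry.solvents)[rng.integers(len(registry.solvents))],
        temperature=float(rng.choice([25.0, 60.0, 80.0, 100.0, 120.0])),
    )
    return block.as_dict()


def generate_dataset(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Generate a synthetic site table under the planted charge-window rule.

    Exactly one label-1 site per substrate before label noise; label noise
    then flips each row's label independently with the configured
    probability.  Returns the standard site-table DataFrame.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    registry = default_registry()
    rows: list[dict] = []
    other_schemes = ("mbs", "cm5")
    for s in range(cfg.n_substrates):
        sid = f"S{s:04d}"
        n_sites = 1 + int(rng.poisson(cfg.mean_extra_sites))
        selected = int(rng.integers(n_sites))
        conditions = _condition_row(rng, registry)
        substrate_rows: list[dict] = []
        n_desc = (
            cfg.n_noise_descriptors
            + (len(schema.FINAL_MOLECULAR_DESCRIPTORS) if cfg.include_final_descriptor_names else 0)
        )
        mol_desc = rng.normal(0.0, 1.0, size=n_desc)
        dreiding = float(rng.normal(50.0, 12.0))
        for a in range(n_sites):
            label = int(a == selected)
            key = _draw_borylating(rng, cfg) if label else _draw_nonborylating(rng, cfg)
            h_count = int(rng.choice([1, 1, 1, 2, 3]))
            row: dict = {
                "substrate_id": sid,
                "inchi": f"SYNTH-{sid}",
                "atom_index": a,
                "hybridization": "sp2" if rng.random() < 0.7 else "sp3",
                "h_count": h_count,
                "symmetry_class": a,
            }
            hh = key["hirshfeld_q_h"]
            s_npa, i_npa, sd_npa = cfg.npa_coupling
            s_hv, i_hv, sd_hv = cfg.hirshfeld_heavy_coupling
            hirshfeld_heavy = s_hv * hh + i_hv + rng.normal(0.0, sd_hv)
            chelpg_heavy = key["chelpg_q_heavy"]
            chelpg_h = rng.normal(0.1, 0.04)
            row.update(
                {
                    "hirshfeld_q_h": hh,
                    "hirshfeld_q_heavy": hirshfeld_heavy,
                    "hirshfeld_q_c": hirshfeld_heavy - h_count * hh,
                    "npa_q_h": s_npa * hh + i_npa + rng.normal(0.0, sd_npa),
                    "mulliken_q_h": key["mulliken_q_h"],
                    "chelpg_q_heavy": chelpg_heavy,
                    "chelpg_q_h": chelpg_h,
                    "chelpg_q_c": chelpg_heavy - h_count * chelpg_h,
                }
            )
            # remaining schemes: weakly informative noise around the
            # hirshfeld trend, plus self-consistent q_c/q_heavy pairs
            mull_c = rng.normal(-0.2, 0.15)
            row["mulliken_q_c"] = mull_c
            row["mulliken_q_heavy"] = mull_c + h_count * row["mulliken_q_h"]
            npa_c = rng.normal(-0.35, 0.1)
            row["npa_q_c"] = npa_c
            row["npa_q_heavy"] = npa_c + h_count * row["npa_q_h"]
            for sch in other_schemes:
                q_h = 0.5 * hh + rng.normal(0.05, 0.03)
                q_c = rng.normal(-0.15, 0.1)
                row[f"{sch}_q_h"] = q_h
                row[f"{sch}_q_c"] = q_c
                row[f"{sch}_q_heavy"] = q_c + h_count * q_h
            row.update(conditions)
            row.update(
                {
                    "steric_effect_index": float(rng.lognormal(0.0, 0.4)),
                    "atomic_polarizability": float(rng.normal(1.76, 0.2)),
                    "distance_degree": float(rng.integers(10, 80)),
                    "dreiding_energy": dreiding,
                }
            )
            names = [f"noise_desc_{i:02d}" for i in range(cfg.n_noise_descriptors)]
            if cfg.include_final_descriptor_names:
                names += list(schema.FINAL_MOLECULAR_DESCRIPTORS)
            for name, value in zip(names, mol_desc):
                row[name] = float(value)
            for i in range(min(cfg.n_duplicate_descriptors, cfg.n_noise_descriptors)):
                row[f"noise_dup_{i:02d}"] = row[f"noise_desc_{i:02d}"]
            for i in range(cfg.n_constant_descriptors):
                row[f"noise_const_{i:02d}"] = 1.0
            row["label"] = label
            substrate_rows.append(row)
        rows.extend(substrate_rows)
        # ligand-switch mode: re-emit some substrates under a different
        # catalyst-ligand pair with the selected site moved, emulating
        # condition-dependent regiochemistry (separate dataset entry)
        if cfg.ligand_switch and n_sites >= 2 and rng.random() < 0.2:
            alt_conditions = _condition_row(rng, registry)
            alt_selected = int((selected + 1 + rng.integers(n_sites - 1)) % n_sites)
            for row in substrate_rows:
                alt = dict(row)
                alt["substrate_id"] = f"{sid}L"
                alt["inchi"] = f"SYNTH-{sid}"
                alt.update(alt_conditions)
                alt["label"] = int(alt["atom_index"] == alt_selected)
                rows.append(alt)
    table = pd.DataFrame(rows)
    if cfg.label_noise > 0:
        flip = rng.random(len(table)) < cfg.label_noise
        table.loc[flip, "label"] = 1 - table.loc[flip, "label"]
    return table
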