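"""Ablation matrix, shuffle controls, selectivity interpretation, Spearman.

Ablations retrain the full multi-run protocol on subsets of the feature
groups (charges / experimental conditions / molecular descriptors /
steric-topological) to attribute predictive power; two controls bound the
model's honesty: shuffling the target labels should collapse borylating-class
F1 toward chance, while shuffling the column order of the features should
leave a permutation-invariant learner statistically unchanged.

The interpretation layer maps per-substrate vote fractions to a selectivity
verdict: one positive site = selective (>= 5:1 expected), two = moderately
selective (<= 4:1, both viable sites flagged), zero or three-plus = no
selective borylation expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import schema
from .classify import ModelConfig, RunSummary, child_seed, format_mean_sd, run_protocol
from .errors import ConfigError

FEATURE_GROUPS = ("charges", "experimental", "molecular_descriptors", "steric_topological")


def resolve_feature_groups(table: pd.DataFrame, groups: Sequence[str]) -> list[str]:
    """Map feature-group names to concrete columns of a site table."""
    unknown = [g for g in groups if g not in FEATURE_GROUPS]
    if unknown:
        raise ConfigError(f"unknown feature groups {unknown}; known: {FEATURE_GROUPS}")
    feats = schema.feature_columns(table.columns)
    charge = [c for c in feats if schema.is_charge_column(c)]
    experimental = [
        c for c in feats
        if c in schema.CONDITION_COLUMNS or c in schema.CATALYST_PARAM_COLUMNS
    ]
    steric = [c for c in feats if c in schema.STERIC_TOPOLOGICAL_COLUMNS]
    routed = set(charge) | set(experimental) | set(steric)
    molecular = [
        c for c in feats
        if c not in routed and pd.api.types.is_numeric_dtype(table[c])
    ]
    by_group = {
        "charges": charge,
        "experimental": experimental,
        "steric_topological": steric,
        "molecular_descriptors": molecular,
    }
    out: list[str] = []
    for g in groups:
        out.extend(c for c in by_group[g] if c not in out)
    return out


@dataclass
class AblationSpec:
    """One row of the ablation matrix."""

    name: str
    feature_groups: tuple[str, ...] = FEATURE_GROUPS
    mode: str = "normal"  # normal | shuffled_targets | shuffled_feature_order | no_feature_selection

    MODES = ("normal", "shuffled_targets", "shuffled_feature_order", "no_feature_selection")


def control_shuffle_targets(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Permute the label assignment; the label multiset and every feature
    column are untouched."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    out[schema.LABEL_COLUMN] = rng.permutation(out[schema.LABEL_COLUMN].to_numpy())
    return out


def control_shuffle_feature_order(X: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Permute column order only; values and names are unchanged."""
    rng = np.random.default_rng(seed)
    cols = list(X.columns)
    order = rng.permutation(len(cols))
    return X.loc[:, [cols[i] for i in order]]


def run_ablation_suite(
    table: pd.DataFrame,
    specs: Sequence[AblationSpec],
    config: ModelConfig | None = None,
    master_seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, RunSummary]]:
    """Run one independent multi-run protocol per ablation spec.

    Returns a results table (one formatted row per spec, metrics as
    ``mean ± SD`` pairs per class) plus the raw :class:`RunSummary` per
    spec name.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate ablation spec names in {names}")
    config = config or ModelConfig()
    rows = []
    summaries: dict[str, RunSummary] = {}
    for spec in specs:
        if spec.mode not in AblationSpec.MODES:
            raise ConfigError(f"unknown ablation mode {spec.mode!r}")
        feats = resolve_feature_groups(table, spec.feature_groups)
        if not feats and spec.mode == "normal":
            raise ConfigError(f"spec {spec.name!r}: empty feature union")
        data = table
        spec_seed = child_seed(master_seed, f"ablation:{spec.name}")
        if spec.mode == "shuffled_targets":
            data = control_shuffle_targets(table, seed=spec_seed)
        # the feature-order control permutes the *selected* columns inside
        # each run, after feature selection, mirroring a shuffle of the
        # final parameter order rather than of the raw table
        permute_seed = spec_seed if spec.mode == "shuffled_feature_order" else None
        run_config = config
        if spec.mode == "no_feature_selection":
            run_config = ModelConfig(**{**config.__dict__, "cascade": None})
        summary = run_protocol(
            data, run_config, master_seed=master_seed, feature_names=feats,
            permute_feature_order_seed=permute_seed,
        )
        summaries[spec.name] = summary
        rows.append(
            {
                "name": spec.name,
                "mode": spec.mode,
                "accuracy": format_mean_sd(summary.mean["accuracy"], summary.sd["accuracy"]),
                "precision (nonborylating/borylating)": (
                    format_mean_sd(summary.mean["precision_0"], summary.sd["precision_0"])
                    + "/"
                    + format_mean_sd(summary.mean["precision_1"], summary.sd["precision_1"])
                ),
                "recall (nonborylating/borylating)": (
                    format_mean_sd(summary.mean["recall_0"], summary.sd["recall_0"])
                    + "/"
                    + format_mean_sd(summary.mean["recall_1"], summary.sd["recall_1"])
                ),
                "F1 (nonborylating/borylating)": (
                    format_mean_sd(summary.mean["f1_0"], summary.sd["f1_0"])
                    + "/"
                    + format_mean_sd(summary.mean["f1_1"], summary.sd["f1_1"])
                ),
            }
        )
    return pd.DataFrame(rows), summaries


@dataclass
class SelectivityCall:
    """Per-substrate selectivity verdict with its supporting sites."""

    substrate_id: str
    verdict: str  # selective | moderately_selective | nonselective
    positive_sites: list[tuple[int, float]] = field(default_factory=list)


def interpret_selectivity(
    vote_fractions: Mapping[int, float],
    substrate_id: str = "",
    call_threshold: float = 0.5,
) -> SelectivityCall:
    """Turn a substrate's per-site vote fractions into a selectivity verdict.

    Sites with vote fraction strictly above ``call_threshold`` count as
    predicted borylation sites: exactly one such site means a selective
    (>= 5:1) borylation is expected, exactly two means moderately selective
    (<= 4:1, both sites viable), and zero or three-plus means no selective
    borylation is indicated.  Pure function of the vote fractions.
    """
    if not len(vote_fractions):
        raise ConfigError(f"no scored sites for substrate {substrate_id!r}")
    for k, v in vote_fractions.items():
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ConfigError(f"missing vote fraction for site {k} of {substrate_id!r}")
    positives = sorted(
        ((int(k), float(v)) for k, v in vote_fractions.items() if v > call_threshold),
        key=lambda kv: (-kv[1], kv[0]),
    )
    if len(positives) == 1:
        verdict = "selective"
    elif len(positives) == 2:
        verdict = "moderately_selective"
    else:
        verdict = "nonselective"
    return SelectivityCall(substrate_id=substrate_id, verdict=verdict,
                           positive_sites=positives)


def interpret_selectivity_table(
    vote_fractions: pd.DataFrame, call_threshold: float = 0.5
) -> list[SelectivityCall]:
    """Apply :func:`interpret_selectivity` per substrate of a vote table
    (columns ``substrate_id, atom_index, vote_fraction``)."""
    calls = []
    for sid, grp in vote_fractions.groupby("substrate_id", sort=True):
        votes = dict(zip(grp["atom_index"].astype(int), grp["vote_fraction"]))
        calls.append(interpret_selectivity(votes, substrate_id=str(sid),
                                           call_threshold=call_threshold))
    return calls


def spearman_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Spearman rank-correlation matrix of the feature columns.

    Ties receive average ranks.  Constant columns have undefined rank
    correlation; their entries (including the diagonal) are NaN and a
    warning is attached via the returned frame's ``attrs['constant']``.
    """
    if X.shape[1] < 2:
        raise ConfigError("Spearman matrix needs at least 2 columns")
    ranks = X.rank(axis=0, method="average").to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    out = pd.DataFrame(corr, index=X.columns, columns=X.columns)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    out.attrs["constant"] = constant
    return out
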