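"""Vote fractions, selectivity verdicts and SHAP attributions.

Scores a handful of held-out substrates with the 10-run protocol, turns
their per-site vote fractions into selectivity verdicts, and decomposes
one forest prediction into additive per-feature contributions.
"""

from borylsite import (
    ModelConfig,
    SyntheticConfig,
    generate_dataset,
    interpret_selectivity_table,
    run_protocol,
    shap_attributions,
)

table = generate_dataset(SyntheticConfig(seed=2))
holdout_ids = sorted(table["substrate_id"].unique())[-5:]
holdout = table[table["substrate_id"].isin(holdout_ids)]
train = table[~table["substrate_id"].isin(holdout_ids)]

summary = run_protocol(train, ModelConfig(n_runs=10), master_seed=0,
                       predict_table=holdout, keep_models=True)

print("per-site vote fractions (fraction of 10 runs voting 'borylating'):")
print(summary.vote_fractions.to_string(index=False))

print("\nselectivity verdicts:")
for call in interpret_selectivity_table(summary.vote_fractions):
    sites = ", ".join(f"site {a} ({v:.0%})" for a, v in call.positive_sites) or "-"
    print(f"  {call.substrate_id}: {call.verdict}  [{sites}]")

# SHAP decomposition of the last run's model on one holdout site: the
# contributions sum with the base value (~0.5 after class balancing) to
# the forest's predicted borylation probability.
model = summary.models[-1]
row_table = holdout.iloc[[0]]
prepared = model.cascade.apply(row_table.loc[:, model.cascade.selected
                               if model.cascade else model.columns]) \
    if model.cascade else row_table.loc[:, model.columns]
contrib, base = shap_attributions(model, prepared.iloc[0])
proba = model.predict_proba(row_table)[0]
print(f"\nSHAP for {row_table['substrate_id'].iloc[0]} site "
      f"{int(row_table['atom_index'].iloc[0])}: "
      f"base {base:.3f} + contributions {contrib.sum():+.3f} "
      f"= probability {proba:.3f}")
print("top contributions:")
print(contrib.reindex(contrib.abs().sort_values(ascending=False).index).head(5)
      .to_string())
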