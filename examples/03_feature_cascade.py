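"""Walk the four-stage feature-reduction cascade and show each report.

The cascade mirrors production feature engineering: zero-variance filter,
95% correlation filter, above-mean forest importance, Ward clustering of
collinear survivors.  Watch the column count shrink stage by stage.
"""

from borylsite import CascadeConfig, SyntheticConfig, fit_cascade, generate_dataset
from borylsite.schema import feature_columns

table = generate_dataset(SyntheticConfig(seed=1))
feats = [c for c in feature_columns(table.columns)
         if table[c].dtype.kind in "fi"]
X, y = table[feats], table["label"]
print(f"starting columns: {len(feats)}")

cascade = fit_cascade(X, y, CascadeConfig(ward_threshold=0.5), seed=0)
for report in cascade.reports:
    print(f"{report.stage:>22}: kept {len(report.retained):3d}  "
          f"dropped {len(report.dropped):3d}  {report.parameters.get('threshold', '')}")
print("final selection:", cascade.selected)

# The duplicated noise columns fall at the correlation stage, the constant
# column at the variance stage, and the importance stage concentrates the
# selection on the charge features that carry the planted signal.
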