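"""Worked example on the packaged study tables.

Reproduces the dataset-level arithmetic of the continental vole survey from
the packaged per-population, per-primer and low-F_ST outlier tables.
"""

import numpy as np

import aflpscan as a

t = a.load_fixture_tables()
body = t.table2_body

print(f"populations: {len(t.table1)}, individuals: {int(t.table1['n'].sum())}")
print(f"mean population-specific F_ST: {t.table1['fst'].mean():.2f}")
print(f"mean AFLP diversity: {100 * t.table1['diversity'].mean():.1f}%")
print(f"markers scored: {int(body['n_markers'].sum())} "
      f"({body['n_markers'].mean():.0f} per primer combination)")
share = t.constants["informative_markers"] / t.constants["total_markers"]
print(f"informative markers (band frequency 5-95%): "
      f"{t.constants['informative_markers']} ({100 * share:.0f}%)")
print(f"positive-selection outliers (PO > 10): {t.n_positive_outliers} "
      f"({body['n_outliers'].mean():.1f} per primer)")
print(f"low-F_ST outliers: {t.n_balancing_outliers}, "
      f"mean F_ST {t.table3['fst'].mean():.2f}")
print(f"neutral informative panel for ordination: {t.n_neutral_informative} markers")
print("\nlow-F_ST outlier triage categories:")
for cat, n in t.table3["category"].value_counts().items():
    print(f"  {cat:20s} {n}")
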