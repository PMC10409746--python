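#!/usr/bin/env python
"""Context dependence of keystone roles and conservation of strain relationships.

Reads the pipeline outputs (run 02 first), ranks dropout strains by impact in
each medium, and lists the strain pairs whose relationship category is
conserved across both media versus those that switch sign.
"""

from pathlib import Path

import pandas as pd

from dropoutkeys.io import read_relationship_table
from dropoutkeys.relationships import conserved_relationships

ROOT = Path(__file__).resolve().parents[1]
pipe = ROOT / "results" / "pipeline"
if not pipe.exists():
    raise SystemExit("run analysis/02_full_pipeline.py first")

keystones = pd.read_csv(pipe / "keystones.csv")
rel = read_relationship_table(pipe / "relationships.csv")

ranking = (
    keystones.pivot(index="focal_x", columns="environment", values="n_affected")
    .fillna(0)
    .astype(int)
    .sort_values(list(keystones["environment"].unique()), ascending=False)
)
ranking.to_csv(ROOT / "results" / "03_keystone_context.csv")

top = {env: grp.loc[grp["n_affected"].idxmax(), "focal_x"]
       for env, grp in keystones.groupby("environment")}
print("top keystone per medium:", top)
print("\nimpact matrix (rows = removed strain):")
print(ranking.to_string())

informative = rel[~rel["category"].isin(["below_DTL"])]
conserved = conserved_relationships(informative)
conserved.to_csv(ROOT / "results" / "03_conserved_relationships.csv", index=False)
switching = (
    informative.groupby(["focal_x", "affected_y"])["category"].nunique().pipe(lambda s: s[s > 1])
)
print(f"\n{len(conserved)} relationships conserved across media "
      f"(e.g. {conserved.head(3).to_dict('records')})")
print(f"{len(switching)} pairs switch category between media — "
      "strain relationships are largely not transferrable across environments")
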