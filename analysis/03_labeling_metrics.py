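"""Labeling fractions, fractional enrichment and serum-normalized enrichment.

Runs the full pipeline config emitted by 01 and summarizes the group
contrasts: tumor serine 13C labeling (normalized to the mouse-matched
serum glucose enrichment), serine 2H uptake labeling, and fatty-acid 2H
labeling with the C18:2 essential-fatty-acid zero control.
"""

import argparse
from pathlib import Path

import pandas as pd

from isotrace.pipeline import run_pipeline

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
args = parser.parse_args()

out = run_pipeline(args.cohort / "pipeline_config.toml")
metrics = pd.read_csv(out / "labeling_metrics.csv")
metrics["group"] = metrics["sample"].str.split("_").str[0]

print(f"pipeline outputs in {out}\n")
print("mean labeled fraction by track/compound/group:")
print(
    metrics.pivot_table(
        index=["track", "compound"], columns="group", values="labeled_fraction"
    ).round(4)
)

normalized = pd.read_csv(out / "normalized_enrichment.csv")
normalized["group"] = normalized["sample"].str.split("_").str[0]
print("\nserum-normalized 13C labeling (tumor metabolite / serum glucose enrichment):")
print(normalized.pivot_table(index="compound", columns="group", values="normalized_value").round(4))

c18 = metrics[(metrics["compound"] == "C18:2")]["labeled_fraction"]
print(f"\nessential fatty acid C18:2 labeled fraction: max {c18.max():.2e} "
      "(zero-synthesis control sits at the noise floor)")
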