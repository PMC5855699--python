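#!/usr/bin/env python
"""Summarize the enrichment results in the published table layout.

Pivots the long-format enrichment output into one block per reference
universe, with pathway rows and (window x p-basis) columns holding the
significant proportion and the combined risk ratio with its CI.
"""

import argparse
from pathlib import Path

import pandas as pd

parser = argparse.ArgumentParser()
parser.add_argument("--pipeline", default="results/pipeline")
args = parser.parse_args()

enr = pd.read_csv(Path(args.pipeline) / "enrichment.tsv", sep="\t")
enr["cell"] = (
    enr["proportion"].map("{:.1f}".format)
    + " | RR " + enr["combined_RR"].map("{:.2f}".format)
    + " (" + enr["CI_low"].map("{:.2f}".format)
    + "-" + enr["CI_high"].map("{:.2f}".format) + ")"
)
for universe, block in enr.groupby("universe"):
    wide = block.pivot_table(
        index=["pathway", "n_cpgs"], columns=["window", "p_basis"],
        values="cell", aggfunc="first",
    )
    med = block.drop_duplicates(["window", "p_basis"]).pivot_table(
        index="universe", columns=["window", "p_basis"],
        values="median_subset_proportion", aggfunc="first",
    )
    print(f"\n=== reference universe: {universe} ===")
    print(wide.to_string())
    print("median random-subset proportions:")
    print(med.to_string())

out = Path("results/enrichment_wide.tsv")
enr.to_csv(out, sep="\t", index=False)
print(f"\nlong-format table kept at {out}")
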