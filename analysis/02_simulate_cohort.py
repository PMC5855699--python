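#!/usr/bin/env python
"""Generate the synthetic cohort the rest of the analysis runs on.

Defaults emulate the study layout: 245 women at age 18, 39 with a
first-half and 35 with a second-half pregnancy sample (20 with all
three), seven blood cell types, seven batches, and pathway CpG sets of
155/77/106/10 probes. All files are plain text under results/cohort/.
"""

import argparse

from methdelta.simulate import (
    SyntheticConfig,
    generate_cohort,
    generate_manifest,
    write_cohort,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", default="results/cohort")
args = parser.parse_args()

config = SyntheticConfig(seed=args.seed)
manifest = generate_manifest(config)
matrix, sheet, reference, truth = generate_cohort(config, manifest)
write_cohort(args.out, manifest, matrix, sheet, reference, truth)

n_pathway = (manifest["pathway"] != "").sum()
print(f"cohort written to {args.out}")
print(f"  probes: {matrix.n_probes} ({n_pathway} pathway, "
      f"{(manifest['signature_cell'] != '').sum()} cell-signature)")
print(f"  samples: {matrix.n_samples} "
      f"({dict(sheet['timepoint'].value_counts())})")
print(f"  true effect rate (background CpGs): "
      f"{truth['probes']['is_true_positive_first'].mean():.3f}")
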