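#!/usr/bin/env python
"""Generate the synthetic study cohorts every later step analyses.

Writes, under scratch/synthetic/: two platforms' normal and cancer
expression matrices (500 genes, 50 planted reversal pairs, 40 samples per
class per platform, separation 2 noise-SD units, noise SD 1), the
ground-truth signature, and a progression cohort of 50 samples at each
theta level 0.1 ... 0.9.
"""

from pathlib import Path

import numpy as np

from reoscore import (
    ProgressionSpec,
    SyntheticCohortSpec,
    generate_progression_cohort,
    generate_two_class_cohorts,
    write_expression_matrix,
    write_signature,
)

SEED = 20240901
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = SyntheticCohortSpec(seed=SEED)
    cohorts, truth = generate_two_class_cohorts(spec)
    for platform, (normal, cancer) in cohorts.items():
        write_expression_matrix(normal, OUT / f"{platform}_normal.tsv")
        write_expression_matrix(cancer, OUT / f"{platform}_cancer.tsv")
        print(f"{platform}: {normal.n_samples} normal + {cancer.n_samples} cancer "
              f"samples over {normal.n_genes} genes")
    write_signature(truth, OUT / "true_signature.tsv")
    print(f"ground truth: {len(truth)} planted reversal pairs")

    prog = ProgressionSpec(
        theta_levels=tuple(np.round(np.arange(1, 10) / 10, 2)),
        n_samples_per_level=50,
        seed=SEED + 1,
    )
    eval_spec = SyntheticCohortSpec(platform_labels=("evaluation",), seed=SEED)
    matrix, theta = generate_progression_cohort(eval_spec, prog)
    write_expression_matrix(matrix, OUT / "progression.tsv")
    theta.rename_axis("sample_id").to_csv(OUT / "progression_theta.tsv", sep="\t")
    print(f"progression cohort: {matrix.n_samples} samples at theta levels "
          f"{[float(t) for t in prog.theta_levels]}")
    print(f"wrote everything to {OUT}")


if __name__ == "__main__":
    main()
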