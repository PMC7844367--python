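#!/usr/bin/env python
"""Build the reversal signature from the simulated training cohorts.

Runs the full cascade — per-platform stable pairs at the 90% threshold,
reversal pairs, cross-platform intersection, cancer-cohort consistency
filter — and reports how the recovered signature compares with the
planted ground truth. Writes results/signature.tsv and the cascade
provenance.
"""

import logging
from pathlib import Path

from reoscore import (
    StablePairParams,
    build_signature,
    read_expression_matrix,
    read_signature,
    write_signature,
)

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"
PLATFORMS = ("affymetrix", "illumina")


def main() -> None:
    if not SIM.is_dir():
        raise SystemExit("run analysis/01_simulate_cohorts.py first")
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    normal = {p: read_expression_matrix(SIM / f"{p}_normal.tsv") for p in PLATFORMS}
    cancer = {p: read_expression_matrix(SIM / f"{p}_cancer.tsv") for p in PLATFORMS}
    # the RNA-seq-style consistency check reuses the cancer cohorts
    signature = build_signature(normal, cancer, list(cancer.values()),
                                StablePairParams(0.9))
    RESULTS.mkdir(exist_ok=True)
    write_signature(signature, RESULTS / "signature.tsv")
    (RESULTS / "signature_provenance.txt").write_text(signature.provenance + "\n")

    truth = read_signature(SIM / "true_signature.tsv")
    found = set(signature.direction_by_key())
    planted = set(truth.direction_by_key())
    recall = len(found & planted) / len(planted)
    precision = len(found & planted) / len(found) if found else float("nan")
    print(f"\ncascade: {signature.provenance}")
    print(f"signature size {len(signature)}; recall of planted pairs "
          f"{recall:.2f}, precision {precision:.2f}")
    print("note: at separation 2 / noise 1, a planted pair clears the 90% "
          "stability bar in one cohort with probability ~0.8, so surviving "
          "all four cohorts loses about half the pairs; false positives "
          "stay at zero.")


if __name__ == "__main__":
    main()
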