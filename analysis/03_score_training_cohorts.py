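#!/usr/bin/env python
"""Score the training cohorts with the built signature.

Normal samples should sit near 0 and cancer samples near 1; the gap is
the signature's separation on data it was trained on. Writes
results/training_scores.tsv.
"""

from pathlib import Path

import pandas as pd

from reoscore import (
    read_expression_matrix,
    read_signature,
    score_cohort,
    scores_to_frame,
    summarize_scores,
    wilcoxon_rank_sum,
)

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"
PLATFORMS = ("affymetrix", "illumina")


def main() -> None:
    sig_path = RESULTS / "signature.tsv"
    if not sig_path.is_file():
        raise SystemExit("run analysis/02_build_signature.py first")
    signature = read_signature(sig_path)
    frames = []
    by_class: dict[str, list[float]] = {"normal": [], "cancer": []}
    for platform in PLATFORMS:
        for cls in ("normal", "cancer"):
            matrix = read_expression_matrix(SIM / f"{platform}_{cls}.tsv")
            scores = score_cohort(matrix, signature)
            frame = scores_to_frame(scores)
            frame.insert(0, "platform", platform)
            frame.insert(1, "class", cls)
            frames.append(frame)
            by_class[cls] += [s.score for s in scores]
            summary = summarize_scores(scores)
            print(f"{platform} {cls}: median score {summary.median:.4f} "
                  f"(n={summary.count}, range {summary.minimum:.4f}-{summary.maximum:.4f})")
    RESULTS.mkdir(exist_ok=True)
    pd.concat(frames).to_csv(RESULTS / "training_scores.tsv", sep="\t", index=False)
    res = wilcoxon_rank_sum(by_class["cancer"], by_class["normal"])
    print(f"\ncancer vs normal (pooled platforms): rank-sum p = {res.p_two_sided:.3g} "
          f"({res.method})")


if __name__ == "__main__":
    main()
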