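# reoscore

Rank-based qualitative transcriptional signatures for individualized
cancer-risk scoring.

Bulk expression measurements are hard to compare across platforms,
batches and laboratories, but the *ordering* of two genes' values within
one sample survives any monotone distortion of that sample's scale.
`reoscore` builds signatures from such within-sample **relative
expression orderings (REOs)**: gene pairs whose ordering is stable in
normal tissue (one direction in ≥ 90% of samples) and stably *reversed*
in cancer, detected independently on multiple measurement platforms and
confirmed in additional cancer cohorts. A sample is then scored by

    score = n / m

where *m* is the number of signature pairs evaluable in that sample and
*n* the number already showing the cancer-direction ordering. The score
lives in [0, 1], sits near 0 in normal mucosa and near 1 in carcinoma,
and grades precancerous lesions (colitis, adenomas) in between — with no
normalization of any kind, so it applies to a single sample in isolation.

The package provides the full pipeline as a library and CLI:

| module | contents |
| --- | --- |
| `reoscore.matrix`, `reoscore.io` | expression matrices (TSV/CSV, `NA` missing), probe-to-gene collapsing, signature and GMT files |
| `reoscore.signature` | stable pairs, reversal pairs, cross-platform intersection, cancer-cohort consistency filter, the `build_signature` cascade |
| `reoscore.scoring` | per-sample risk scores, cohort summaries, signature gene frequencies |
| `reoscore.stats` | Wilcoxon rank-sum comparisons, hypergeometric pathway enrichment with Benjamini–Hochberg adjustment |
| `reoscore.simulate` | synthetic cohorts with planted reversal pairs, platform distortions and a progression gradient |
| `reoscore.cli` | `reoscore build / score / compare / enrich / simulate` |

## Worked example

Everything below is synthetic and reproducible; the numbered scripts
under `analysis/` run the same workflow end to end.

```python
import reoscore as rs

# two platforms, 40 normal + 40 cancer samples each, 500 genes,
# 50 planted reversal pairs, separation 2 noise-SD units
spec = rs.SyntheticCohortSpec(seed=20240901)
cohorts, truth = rs.generate_two_class_cohorts(spec)

signature = rs.build_signature(
    {p: normal for p, (normal, cancer) in cohorts.items()},
    {p: cancer for p, (normal, cancer) in cohorts.items()},
    [cancer for (_, cancer) in cohorts.values()],   # consistency cohorts
    rs.StablePairParams(0.9),
)
print(signature.provenance)

normal, cancer = cohorts["affymetrix"]
print(rs.summarize_scores(rs.score_cohort(normal, signature)).median)
print(rs.summarize_scores(rs.score_cohort(cancer, signature)).median)
```

Output (`analysis/02_build_signature.py` / `03_score_training_cohorts.py`
print the same numbers):

```
platform=affymetrix threshold=0.9 stable_normal=119362 stable_cancer=119390 reversal=29 |
platform=illumina threshold=0.9 stable_normal=119351 stable_cancer=119369 reversal=35 |
intersection=18 | final=18
0.0556
0.9444
```

Reading the cascade: each platform has ~119k stable pairs per class
(most gene pairs keep a fixed global ordering), of which 29 and 35
reverse between classes; 18 reverse concordantly on both platforms and
all 18 survive the 90% consistency filter. All 18 are planted pairs
(precision 1.0) — at this noise level the fixed 90% threshold trades
recall for a zero false-positive rate, which is the behaviour you want
from a signature meant to travel across platforms. Scoring separates the
classes cleanly: median 0.056 in normal samples vs 0.944 in cancer.

On a progression cohort (50 samples at each level θ = 0.1 … 0.9, where θ
is the fraction of signature biology already switched to the cancer
state), `analysis/04_progression_gradient.py` prints Spearman
ρ(θ, score) = 0.96 with strictly increasing level medians
(0.16 at θ=0.1 up to 0.84 at θ=0.9) — the synthetic analogue of risk
scores increasing from remissive to active colitis and from low- to
high-grade dysplasia.

The same workflow is available from the shell:

```sh
reoscore simulate --config sim.cfg --out-dir data/
reoscore build    --config build.cfg --out-dir out/
reoscore score    --signature out/signature.tsv --matrix data/progression.tsv \
                  --groups groups.tsv --out-dir scores/
reoscore enrich   --genes genes.txt --gmt pathways.gmt --out enrichment.tsv
```

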