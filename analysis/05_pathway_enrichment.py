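#!/usr/bin/env python
"""Hypergeometric pathway enrichment of the signature genes.

Builds a synthetic pathway collection (one pathway seeded with signature
genes, the rest background), tests enrichment of the signature's member
genes and ranks genes by how many signature pairs contain them. Writes
results/enrichment.tsv and results/gene_frequencies.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from reoscore import (
    hypergeometric_enrichment,
    read_signature,
    signature_gene_frequencies,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 20240905


def main() -> None:
    sig_path = RESULTS / "signature.tsv"
    if not sig_path.is_file():
        raise SystemExit("run analysis/02_build_signature.py first")
    signature = read_signature(sig_path)
    query = sorted(signature.genes())
    print(f"signature contains {len(signature)} pairs over {len(query)} genes")

    # synthetic pathway collection: one pathway enriched for signature
    # genes, the rest drawn from a background universe
    rng = np.random.default_rng(SEED)
    background = [f"BG{i:04d}" for i in range(600)]
    universe = sorted(set(background) | set(query))
    planted_pathway = set(rng.choice(query, size=min(20, len(query)), replace=False))
    planted_pathway |= set(rng.choice(background, size=10, replace=False))
    pathways = [("signature_enriched_pathway", planted_pathway)]
    for i in range(24):
        size = int(rng.integers(15, 60))
        pathways.append((f"background_pathway_{i:02d}",
                         set(rng.choice(background, size=size, replace=False))))

    rows = hypergeometric_enrichment(query, pathways, universe)
    frame = pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in rows],
            "N": [r.universe_size for r in rows],
            "K": [r.pathway_size for r in rows],
            "n": [r.query_size for r in rows],
            "k": [r.overlap for r in rows],
            "p": [r.p_hypergeometric for r in rows],
            "p_adjusted": [r.p_adjusted for r in rows],
        }
    ).sort_values("p")
    RESULTS.mkdir(exist_ok=True)
    frame.to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)
    top = frame.iloc[0]
    print(f"top pathway: {top.pathway_id} (k={top.k}/{top.K}, "
          f"p={top.p:.3g}, adjusted {top.p_adjusted:.3g})")
    n_sig = int((frame["p_adjusted"] < 0.05).sum())
    print(f"{n_sig} of {len(frame)} pathways enriched at adjusted p < 0.05")

    freqs = signature_gene_frequencies(signature)
    pd.DataFrame(freqs, columns=["gene_id", "pair_count"]).to_csv(
        RESULTS / "gene_frequencies.tsv", sep="\t", index=False
    )
    print("top five highest-frequency signature genes:",
          ", ".join(f"{g} ({c})" for g, c in freqs[:5]))


if __name__ == "__main__":
    main()
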