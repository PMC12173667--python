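#!/usr/bin/env python
"""Annotate the quantified catalog on its reference sequences: PTM frequency
table, cleavage-site structural context (flank pLDDT vs cleaved-protein
background, Kolmogorov-Smirnov), the amyloid-beta truncation map
(Abeta_x-y with position 1 at APP residue 672) and the VGF dibasic
cleavage map with novel-site calls.

Reads results/study/ and results/quant/; writes results/annotation/.
"""

import json
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from topform import pipeline, synth

BASE = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    study = synth.read_study(os.path.join(BASE, "study"))
    catalog = pd.read_csv(os.path.join(BASE, "quant", "catalog.tsv"), sep="\t")
    outdir = os.path.join(BASE, "annotation")
    os.makedirs(outdir, exist_ok=True)
    cfg = pipeline.PipelineConfig()
    summary = pipeline.stage_annotate(cfg, catalog, study.reference, None, outdir)
    print(json.dumps(summary, indent=2, default=float))
    ptm = pd.read_csv(os.path.join(outdir, "ptm_frequencies.tsv"), sep="\t")
    print("\ntop modifications (% of proteoforms):")
    print(ptm.head(6).to_string(index=False))
    abeta_path = os.path.join(outdir, "abeta_map.tsv")
    if os.path.exists(abeta_path):
        abeta = pd.read_csv(abeta_path, sep="\t")
        print(f"\namyloid-beta proteoforms mapped: {len(abeta)}")
        print(abeta.sort_values(["y", "x"]).head(8).to_string(index=False))


if __name__ == "__main__":
    main()
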