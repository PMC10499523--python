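"""Correlate splicing-factor / transcription-factor expression with junction PSI.

SF analysis uses non-AFE DS junctions, TF analysis AFE junctions, both
restricted to junctions shared by at least two datasets with max|dPSI| >= 0.2.
Writes correlation matrices, 10-cluster assignments and the per-dataset-pair
summary under <workdir>/regulation/.
"""

import argparse
import logging
from pathlib import Path

import pandas as pd

from spliceatlas.pipeline import PipelineConfig, run


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--workdir", default="results/synthetic")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    logging.basicConfig(level=logging.INFO, format="%(message)s")

    cfg = PipelineConfig(workdir=args.workdir, seed=args.seed)
    run("regulate", cfg)

    summary = pd.read_csv(Path(args.workdir) / "regulation" / "summary.tsv", sep="\t")
    print(summary.to_string(index=False, float_format=lambda v: f"{v:.2f}"))


if __name__ == "__main__":
    main()
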