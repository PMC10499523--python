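"""Cross-dataset concordance of differential splicing calls.

For each dataset pair: shared DS junctions, correlation of max|dPSI|, and the
four comparison categories (non-significant in both / significant in one /
significant in both, same or opposite direction) over the ten harmonized
cell-type comparisons. Writes <workdir>/compare/concordance.tsv.
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
    run("compare", cfg)

    summary = pd.read_csv(Path(args.workdir) / "compare" / "concordance.tsv", sep="\t")
    print(summary.to_string(index=False, float_format=lambda v: f"{v:.2f}"))


if __name__ == "__main__":
    main()
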