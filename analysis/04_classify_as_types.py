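"""Classify DS-LCs into alternative-splicing types from geometry + annotation.

Writes <workdir>/classify/ and refreshes the call tables with AS-type labels.
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
    run("classify", cfg)

    for path in sorted(Path(args.workdir).glob("classify/*_astypes.tsv")):
        tab = pd.read_csv(path, sep="\t")
        ds = path.stem.replace("_astypes", "")
        tally = tab.types.value_counts().to_dict()
        print(f"{ds}: {tally}")


if __name__ == "__main__":
    main()
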