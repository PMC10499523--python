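"""Cross-dataset harmonization and concordance of differential splicing calls.

Clusters are defined per dataset, so datasets are compared at the junction
level: a junction is shared when its exact ``chrom:start:end:strand`` key lies
in a DS-LC of both datasets. For each shared junction the ten comparisons
between the five harmonized cell types (CD4/CD8 folded into T) are
categorized as non-significant in both, significant in one, or significant in
both with the same or opposite dPSI direction. Comparisons ineligible in
either dataset are excluded from the denominator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .ds_test import (
    HARMONIZED_CELL_TYPES,
    ClusterTestResult,
    DSCall,
    harmonized_pairwise,
)


@dataclass
class ConcordanceSummary:
    dataset_pair: tuple[str, str]
    shared_ds_junctions: int
    r_max_dpsi: float
    pct_shared_comparisons: float  # junctions with >=1 same-direction sig pair
    pct_nonsig_both: float
    pct_sig_one: float
    pct_sig_same_dir: float
    pct_sig_opposite: float

    def to_row(self) -> dict:
        return {
            "dataset_a": self.dataset_pair[0],
            "dataset_b": self.dataset_pair[1],
            "shared_ds_junctions": self.shared_ds_junctions,
            "r_max_dpsi": self.r_max_dpsi,
            "pct_shared_comparisons": self.pct_shared_comparisons,
            "pct_nonsig_both": self.pct_nonsig_both,
            "pct_sig_one": self.pct_sig_one,
            "pct_sig_same_dir": self.pct_sig_same_dir,
            "pct_sig_opposite": self.pct_sig_opposite,
        }


def _ds_junctions(calls: Mapping[str, DSCall]) -> dict[str, str]:
    """junction key -> lc_id over DS-LCs only."""
    out = {}
    for lc_id, call in calls.items():
        if call.is_ds:
            for key in call.max_dpsi.index:
                out[key] = lc_id
    return out


def match_junctions(
    calls_a: Mapping[str, DSCall], calls_b: Mapping[str, DSCall]
) -> list[str]:
    """Exact-key junctions belonging to DS-LCs in both datasets."""
    a = _ds_junctions(calls_a)
    b = _ds_junctions(calls_b)
    return sorted(set(a) & set(b))


def concordance(
    results_a: Mapping[str, ClusterTestResult],
    calls_a: Mapping[str, DSCall],
    results_b: Mapping[str, ClusterTestResult],
    calls_b: Mapping[str, DSCall],
    dataset_pair: tuple[str, str] = ("a", "b"),
    cell_types: Sequence[str] = HARMONIZED_CELL_TYPES,
    alpha: float = 0.05,
) -> ConcordanceSummary:
    shared = match_junctions(calls_a, calls_b)
    lc_of_a = _ds_junctions(calls_a)
    lc_of_b = _ds_junctions(calls_b)
    pairs = [tuple(sorted(p)) for p in itertools.combinations(cell_types, 2)]

    harm_a = {lc: harmonized_pairwise(results_a[lc], alpha) for lc in set(lc_of_a.values())}
    harm_b = {lc: harmonized_pairwise(results_b[lc], alpha) for lc in set(lc_of_b.values())}

    cats = {"nonsig_both": 0, "sig_one": 0, "same": 0, "opposite": 0}
    junction_has_shared = []
    md_a, md_b = [], []
    for key in shared:
        ha = harm_a[lc_of_a[key]]
        hb = harm_b[lc_of_b[key]]
        md_a.append(float(np.nan_to_num(calls_a[lc_of_a[key]].max_dpsi.get(key, np.nan))))
        md_b.append(float(np.nan_to_num(calls_b[lc_of_b[key]].max_dpsi.get(key, np.nan))))
        any_same = False
        for pair in pairs:
            ea, eb = ha.get(pair), hb.get(pair)
            if ea is None or eb is None:
                continue  # ineligible/untested in one dataset: out of denominator
            sig_a, dp_a = ea
            sig_b, dp_b = eb
            if not sig_a and not sig_b:
                cats["nonsig_both"] += 1
            elif sig_a != sig_b:
                cats["sig_one"] += 1
            else:
                va = dp_a.get(key, np.nan) if dp_a is not None else np.nan
                vb = dp_b.get(key, np.nan) if dp_b is not None else np.nan
                if pd.isna(va) or pd.isna(vb) or va * vb == 0:
                    cats["sig_one"] += 1  # direction unavailable; degrade
                elif va * vb > 0:
                    cats["same"] += 1
                    any_same = True
                else:
                    cats["opposite"] += 1
        junction_has_shared.append(any_same)

    total = sum(cats.values())
    pct = {k: (100.0 * v / total if total else float("nan")) for k, v in cats.items()}
    if len(shared) >= 3 and np.std(md_a) > 0 and np.std(md_b) > 0:
        r = float(pearsonr(md_a, md_b)[0])
    else:
        r = float("nan")
    return ConcordanceSummary(
        dataset_pair=dataset_pair,
        shared_ds_junctions=len(shared),
        r_max_dpsi=r,
        pct_shared_comparisons=(
            100.0 * sum(junction_has_shared) / len(shared) if shared else float("nan")
        ),
        pct_nonsig_both=pct["nonsig_both"],
        pct_sig_one=pct["sig_one"],
        pct_sig_same_dir=pct["same"],
        pct_sig_opposite=pct["opposite"],
    )
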