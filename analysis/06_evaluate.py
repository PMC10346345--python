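"""Cross-validated comparison of all five classifiers.

Reads scratch/features.tsv and scratch/cycles.npz, evaluates SVM, random
forest, gradient boosting (on selected features) and the stacked LSTM and
ChronoNet (on raw cycle tensors) with stratified 5-fold CV for the
four-class, three-class and two-class labelings, and writes one
performance table per labeling (accuracy, precision, recall, F-score,
MCC, ROC area, AUC) under results/.

Run:  python analysis/06_evaluate.py [--models random_forest,chrononet]
      [--labelings two_class] [--seed 1]
The full five-model, three-labeling sweep takes a while on one CPU; the
default arguments run the fast subset.
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from gaitstab.evaluation import crossvalidate, make_labels
from gaitstab.io_formats import FeatureTable, read_feature_table
from gaitstab.models import DEEP_KINDS, ModelSpec
from gaitstab.selection import select_features

COLUMNS = ["accuracy", "precision", "recall", "f_score", "mcc",
           "roc_area", "auc"]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--models", default="random_forest,chrononet")
    ap.add_argument("--labelings", default="two_class,four_class")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--epochs", type=int, default=25)
    args = ap.parse_args()

    table = read_feature_table(ROOT / "scratch" / "features.tsv")
    bundle = np.load(ROOT / "scratch" / "cycles.npz", allow_pickle=True)
    tensor = bundle["tensor"].astype(np.float64)

    for labeling in args.labelings.split(","):
        mask, labels = make_labels(table.conditions, labeling)
        n_classes = len(np.unique(labels))
        sub = FeatureTable(table.frame.loc[mask].reset_index(drop=True))
        sel = select_features(sub, labels)
        cols = [table.feature_names.index(f) for f in sel.selected]
        X = table.values[mask][:, cols]
        rows = []
        for kind in args.models.split(","):
            hp = ({"epochs": args.epochs, "patience": args.epochs}
                  if kind in DEEP_KINDS else {})
            spec = ModelSpec(kind, hp, seed=args.seed, n_classes=n_classes)
            data = tensor[mask] if kind in DEEP_KINDS else X
            rep = crossvalidate(data, labels, spec, k=5, seed=args.seed,
                                labeling=labeling)
            rows.append({"model": kind,
                         **{c: round(rep.metrics[c], 4) for c in COLUMNS}})
            print(f"{labeling:12s} {kind:14s} "
                  f"accuracy={rep.metrics['accuracy']:.4f}")
        frame = pd.DataFrame(rows)
        out = ROOT / "results" / f"performance_{labeling}.tsv"
        out.parent.mkdir(exist_ok=True)
        frame.to_csv(out, sep="\t", index=False)
        print(f"wrote {out}\n")


if __name__ == "__main__":
    main()
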