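"""Generate the synthetic walking cohort used by the downstream analyses.

Writes BrainVision + TSV + ground-truth fixtures for every
subject x condition trial under scratch/data/, and a cohort summary table
(stride statistics per trial) under results/.

Run:  python analysis/01_simulate.py [--seed 1] [--subjects 4]
      [--duration 120] [--out scratch/data]
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from gaitstab.synth import CONDITIONS, SessionConfig, generate_session, save_session


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--subjects", type=int, default=4)
    ap.add_argument("--duration", type=float, default=120.0)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "data")
    args = ap.parse_args()

    cfg = SessionConfig(n_subjects=args.subjects,
                        trial_duration=args.duration, seed=args.seed)
    rows = []
    for subject in range(cfg.n_subjects):
        for condition in CONDITIONS:
            session = generate_session(cfg, condition, subject)
            save_session(session, args.out)
            gaps = np.diff(session.true_events["right"])
            rows.append({
                "subject": subject, "condition": condition,
                "n_strides": len(gaps),
                "stride_mean_s": round(float(gaps.mean()), 4),
                "stride_cv": round(float(gaps.std() / gaps.mean()), 4),
            })
    frame = pd.DataFrame(rows)
    out_tsv = ROOT / "results" / "cohort_summary.tsv"
    out_tsv.parent.mkdir(exist_ok=True)
    frame.to_csv(out_tsv, sep="\t", index=False)
    print(frame.to_string(index=False))
    print(f"\nwrote fixtures to {args.out} and summary to {out_tsv}")
    print("Finding: unstable conditions (STROOP, MLP) show roughly twice "
          "the stride-time variability of stable ones, as configured.")


if __name__ == "__main__":
    main()
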