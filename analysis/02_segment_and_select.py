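"""Bin traces at 100 ms, find change points, keep single-bleach molecules.

Reports how many molecules per condition survive the selection (single
downward donor and acceptor steps terminating at background, acceptor
first) and the distribution of rejection reasons.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED, make_config

from memfret.pipeline import run_pipeline


def main() -> None:
    cfg = make_config(stages=("simulate", "segment"))
    report = run_pipeline(cfg, seed=SEED, outdir=RESULTS)
    sel = pd.read_csv(RESULTS / "selection.tsv", sep="\t")
    accepted = sel.groupby("condition").accepted.mean()
    print("acceptance rate per condition:")
    print(accepted.round(3).to_string())
    reasons = sel.loc[~sel.accepted, "rejection_reason"].value_counts()
    print("\nrejection reasons:")
    print(reasons.to_string())
    print(f"\nwrote {RESULTS / 'segments.tsv'} and selection.tsv")


if __name__ == "__main__":
    main()
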