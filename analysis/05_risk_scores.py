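#!/usr/bin/env python
"""Epoch-ensemble psychosis-risk scores.

Trains bagged classification trees on per-epoch covariance features of the
DNMnet channels (PD epochs labelled 1, HC labelled 0; UHR never trained
on), scores every subject as the mean predicted epoch label, and evaluates
the four cohort risk-accuracy indices.

Writes
    results/risks.csv         per-subject risk in [0, 1]
    results/risk_summary.csv  training/CV accuracy and risk-accuracy indices
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dnmcrit.dnmnet import DNMnet
from dnmcrit.epochs_io import read_study
from dnmcrit.risk import estimate_risk

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default=ROOT / "scratch" / "corrected_epochs")
    ap.add_argument("--dnmnet", default=ROOT / "results" / "dnmnet.json")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cohort = read_study(args.data)
    net = DNMnet.from_json(args.dnmnet)
    res = estimate_risk(cohort, net, seed=args.seed)

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    df = pd.DataFrame({
        "subject_id": res.subject_ids, "group": res.groups, "risk": res.risks,
    })
    df.to_csv(out / "risks.csv", index=False)

    summary = {
        "training_accuracy": res.training_accuracy,
        "cv_accuracy": res.cv_accuracy,
        **{f"risk_accuracy_{k}": v for k, v in res.risk_accuracy.items()},
    }
    pd.DataFrame([summary]).to_csv(out / "risk_summary.csv", index=False)

    med = df.groupby("group")["risk"].median()
    print(f"subject-grouped CV accuracy {res.cv_accuracy:.3f}, "
          f"training accuracy {res.training_accuracy:.3f}")
    print("median risk per group:", med.round(3).to_dict())
    print("risk accuracies:", {k: round(v, 3) for k, v in res.risk_accuracy.items()})


if __name__ == "__main__":
    main()
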