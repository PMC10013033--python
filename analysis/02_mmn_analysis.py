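#!/usr/bin/env python
"""Mismatch-negativity analysis across the cohort.

Computes per-subject, per-channel MMN amplitude (fixed 135-205 ms window,
duration-deviant convention) and peak latency from corrected epochs, then
contrasts amplitudes between groups channel-by-channel with Wilcoxon
rank-sum tests under Benjamini-Hochberg correction.

Writes
    results/mmn_amplitudes.csv   subject x channel amplitude/latency table
    results/mmn_group_tests.csv  per-channel p and adjusted p per contrast
"""

import argparse
from pathlib import Path

import pandas as pd

from dnmcrit.epochs_io import read_study
from dnmcrit.mmn import mmn_group_test, subject_mmn

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default=ROOT / "scratch" / "corrected_epochs")
    ap.add_argument("--deviant-kind", choices=["dD", "fD"], default="dD")
    args = ap.parse_args()

    cohort = read_study(args.data)
    results = [subject_mmn(c, args.deviant_kind) for c in cohort]

    rows = []
    for r in results:
        for ch in range(r.amplitude.size):
            rows.append({
                "subject_id": r.subject_id, "group": r.group, "channel": ch + 1,
                "amplitude_uV": r.amplitude[ch],
                "peak_latency_ms": r.peak_latency[ch],
            })
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "mmn_amplitudes.csv", index=False)

    tests = mmn_group_test(results)
    tests.to_csv(out / "mmn_group_tests.csv", index=False)

    sub = tests[tests.contrast == "HC_vs_PD"]
    sig = sorted(sub.channel[sub.p_adjusted < 0.05])
    print(f"{len(sig)} channels with significant HC vs PD MMN difference "
          f"(adjusted p < 0.05): {sig}")


if __name__ == "__main__":
    main()
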