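#!/usr/bin/env python
"""Calibration sweep for the hippocampal per-day weight decay.

Reports, for each candidate decay factor, the memory age at which blurred-cue
recall success crosses 50% and the greatest age with any success, using the
multi-day recall protocol.  The packaged default was chosen with this sweep
so that recall fails completely at ~10 days.

Usage:  python scripts/calibrate_hip_decay.py [--seeds 8] [--decays 0.93 0.945 0.96]
"""

from __future__ import annotations

import argparse

import numpy as np

from fearcons import ProtocolConfig, run_protocol


def crossing_age(by_age) -> float:
    below = by_age.index[by_age < 0.5]
    return float(below.min()) if len(below) else float("inf")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seeds", type=int, default=8)
    ap.add_argument("--decays", type=float, nargs="+",
                    default=[0.93, 0.945, 0.96])
    args = ap.parse_args()

    print(f"{'decay':>7} {'50% crossing':>13} {'max age >0%':>12}")
    for decay in args.decays:
        cfg = ProtocolConfig("recall_curve", seeds=list(range(args.seeds)),
                             model={"hip_day_decay": decay})
        res = run_protocol(cfg)
        by_age = res.traces.groupby("age").hip_ok.mean()
        positive = by_age.index[by_age > 0]
        max_age = int(positive.max()) if len(positive) else 0
        print(f"{decay:7.3f} {crossing_age(by_age):13.1f} {max_age:12d}")


if __name__ == "__main__":
    main()
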