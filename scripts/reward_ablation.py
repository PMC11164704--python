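#!/usr/bin/env python
"""Reward-shaping ablation at reduced scale.

Trains four agents that differ only in the shaping terms of the reward —
climb rate alone, climb rate + stability penalty, climb rate + centering
penalty, and the full shaped reward — under a fixed moderate wind band,
then reports the fraction of stable flight time, the fraction of time
spent inside the thermal, and the mean climb rate over the last quarter
of each training log.  The expected ordering (stability must be learned
before thermal-centering pays off) is visible already at small budgets;
run longer budgets for cleaner separation.

Usage: python scripts/reward_ablation.py --seed 1 --budget 20000 \
           --out results/ablation
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from thermosoar import (
    CurriculumSchedule,
    CurriculumStage,
    DDPGConfig,
    EpisodeConfig,
    curriculum_train,
)

VARIANTS = {
    "vz": dict(reward_stability=False, reward_center=False),
    "vz+Pstab": dict(reward_stability=True, reward_center=False),
    "vz+Pcenter": dict(reward_stability=False, reward_center=True),
    "vz+Pstab+Pcenter": dict(reward_stability=True, reward_center=True),
}


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--budget", type=float, default=20_000.0,
                    help="simulated seconds of training per variant")
    ap.add_argument("--u-min", type=float, default=2.5)
    ap.add_argument("--u-max", type=float, default=3.5)
    ap.add_argument("--out", type=Path, required=True)
    args = ap.parse_args(argv)
    args.out.mkdir(parents=True, exist_ok=True)

    schedule = CurriculumSchedule(
        (CurriculumStage(args.u_min, args.u_max, args.budget),)
    )
    summary = {}
    for name, flags in VARIANTS.items():
        res = curriculum_train(
            schedule, DDPGConfig(), EpisodeConfig(), seed=args.seed, **flags
        )
        log = res.log
        tail = log.iloc[3 * len(log) // 4:]
        summary[name] = {
            "stable_fraction": float(tail["stable_fraction"].mean()),
            "fraction_in_thermal": float(tail["fraction_in_thermal"].mean()),
            "mean_vz": float(tail["mean_vz"].mean()),
            "episodes": int(len(log)),
        }
        log.to_csv(args.out / f"log_{name.replace('+', '_')}.csv", index=False)
        print(f"{name:18s} stable {summary[name]['stable_fraction']:.2f} "
              f"in-thermal {summary[name]['fraction_in_thermal']:.2f} "
              f"vz {summary[name]['mean_vz']:+.2f}")
    (args.out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
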