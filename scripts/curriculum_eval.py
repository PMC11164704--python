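#!/usr/bin/env python
"""Reduced-scale curriculum training with a wind-range evaluation table.

Runs the three-stage wind curriculum (0-2, 0-4, 0-6 m/s; default budget
2*10^5 simulated seconds per stage, about an hour of wall time on one
CPU) and evaluates the final agent on 20 seeded runs at every integer
wind speed from 0 to 6 m/s.  Writes the training log, the checkpoints
and a JSON table of mean climb rate, soaring efficiency eta, thermal
occupancy and flight duration per wind speed.  Exits 0 when the mean
eta is positive at every tested wind speed, 1 otherwise.

Usage: python scripts/curriculum_eval.py --seed 1 --out results/curriculum \
           [--stage-budget 200000] [--n-runs 20]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from thermosoar import (
    CurriculumSchedule,
    CurriculumStage,
    DDPGConfig,
    EpisodeConfig,
    curriculum_train,
    evaluate,
)


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--stage-budget", type=float, default=200_000.0)
    ap.add_argument("--n-runs", type=int, default=20)
    ap.add_argument("--out", type=Path, required=True)
    args = ap.parse_args(argv)
    args.out.mkdir(parents=True, exist_ok=True)

    schedule = CurriculumSchedule(tuple(
        CurriculumStage(0.0, u_max, args.stage_budget)
        for u_max in (2.0, 4.0, 6.0)
    ))
    result = curriculum_train(
        schedule, DDPGConfig(), EpisodeConfig(), seed=args.seed,
        checkpoint_dir=args.out,
    )
    result.log.to_csv(args.out / "training_log.csv", index=False)
    agent = result.checkpoints[-1].agent

    table = {}
    for u in range(0, 7):
        s, trajs = evaluate(agent, u=float(u), n_runs=args.n_runs,
                            seed=args.seed + 1, keep_trajectories=True)
        table[u] = {
            "mean_vz": s.mean_vz,
            "mean_eta": float(np.mean(s.per_run_eta)),
            "fraction_in_thermal": s.fraction_in_thermal,
            "mean_duration_s": s.mean_duration,
        }
        print(f"u={u}: vz {s.mean_vz:+.3f} eta {table[u]['mean_eta']:+.3f} "
              f"in-thermal {s.fraction_in_thermal:.2f} "
              f"duration {s.mean_duration:.0f} s")
    payload = {
        "simulated_seconds": result.simulated_seconds,
        "diverged": result.diverged,
        "per_wind": table,
    }
    (args.out / "evaluation.json").write_text(json.dumps(payload, indent=2))
    ok = all(v["mean_eta"] > 0.0 for v in table.values())
    print("criterion (eta > 0 at every wind):", "PASS" if ok else "FAIL")
    return 0 if ok else 1


if __name__ == "__main__":
    raise SystemExit(main())
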