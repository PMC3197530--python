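#!/usr/bin/env python
"""Calibration harness for the shipped defaults.

Two jobs:

1. ``growth``: validate/regenerate the default Gompertz constants from the
   synthetic caliper fixture pipeline — the fitted (a, b) must drive the
   untreated virtual tumor across the 450 mm^2 sacrifice threshold between
   day 25 and day 33.
2. ``arms``: run the reduced-scale treatment battery and report the arm-level
   outcomes the free effect-size parameters are calibrated against
   (no-effect arms ~ control; partial arms reduced without rejection;
   day-3 combined rejects; day-8 combined and endothelial-KO combined fail).

Usage:  python scripts/calibrate.py growth
        python scripts/calibrate.py arms --reps 4 --lattice 100
"""

from __future__ import annotations

import argparse
import json

import numpy as np

from melimm import ScenarioConfig, run_replicate
from melimm.engine import DEFAULT_GOMPERTZ, Arm, Outcome
from melimm.tumor_growth import (
    TumorState,
    area_from_cells,
    euler_newborns,
    fit_gompertz,
    generate_growth_fixture,
)


def job_growth(args) -> None:
    rng = np.random.default_rng(args.seed)
    series = generate_growth_fixture(
        DEFAULT_GOMPERTZ, 2e5, list(range(3, 34, 3)), args.noise, rng
    )
    est, resid = fit_gompertz(series)
    st = TumorState(x_t=2e5)
    sac_day = None
    for t in range(1, 100):
        euler_newborns(st, est)
        if area_from_cells(st.x_t) >= 450.0:
            sac_day = t / 3.0
            break
    print(
        json.dumps(
            {
                "fitted_a": est.a,
                "fitted_b": est.b,
                "carrying_capacity": est.carrying_capacity,
                "residual_norm": resid,
                "sacrifice_day": sac_day,
                "inside_day_25_33_band": sac_day is not None and 25.0 <= sac_day <= 33.0,
            },
            indent=2,
        )
    )


def _summary(results) -> dict:
    def day20_area(res):
        ts = res.timeseries
        return float(ts[ts["day"] <= 20]["tumor_area_mm2"].iloc[-1])

    return {
        "mean_day20_area": float(np.mean([day20_area(r) for r in results])),
        "rejected": sum(r.outcome is Outcome.REJECTED for r in results),
        "rejection_days_by_area": [r.rejection_day_by_area() for r in results],
    }


def job_arms(args) -> None:
    battery = [(a.value, a, 3, True) for a in Arm]
    battery += [
        ("DAY8_COMBINED", Arm.OT1_ACTIVE_PLUS_CD137, 8, True),
        ("KO_COMBINED", Arm.OT1_ACTIVE_PLUS_CD137, 3, False),
    ]
    report = {}
    for name, arm, day, wt in battery:
        runs = [
            run_replicate(
                ScenarioConfig(
                    arm=arm,
                    treatment_day=day,
                    cd137_on_endothelium=wt,
                    lattice_L=args.lattice,
                    seed=args.seed + k,
                )
            )
            for k in range(args.reps)
        ]
        report[name] = _summary(runs)
    print(json.dumps(report, indent=2))


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    sub = ap.add_subparsers(dest="job", required=True)
    g = sub.add_parser("growth")
    g.add_argument("--seed", type=int, default=0)
    g.add_argument("--noise", type=float, default=0.0)
    a = sub.add_parser("arms")
    a.add_argument("--seed", type=int, default=1)
    a.add_argument("--reps", type=int, default=4)
    a.add_argument("--lattice", type=int, default=100)
    args = ap.parse_args()
    {"growth": job_growth, "arms": job_arms}[args.job](args)


if __name__ == "__main__":
    main()
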