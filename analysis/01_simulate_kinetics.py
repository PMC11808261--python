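#!/usr/bin/env python
"""Simulate the turnover-coupled inactivation model for the three characterized
variants and verify its structural invariants.

Per-variant Km and kcat are the published values; the inactivation constant is
chosen so the model's activity half-life at 40 mM substrate equals each
variant's published half-life.  Writes trajectories and an invariant summary
under results/.
"""

import argparse
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from bsadc import KineticParams, ReactionConditions, final_product, partition_ratio, simulate_progress
from bsadc.datasets import HALF_LIVES_MIN, TABLE2


def model_params(variant: str, S0: float = 40.0) -> KineticParams:
    row = TABLE2[variant]
    lam = math.log(2.0) / (HALF_LIVES_MIN[variant] * 60.0)  # effective, 1/s
    kinact = lam * (row.Km_mM + S0) / S0
    return KineticParams(Km=row.Km_mM, kcat=row.kcat_per_s, kinact=kinact)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cond = ReactionConditions(E0=1.7, S0=40.0)
    t_s = np.linspace(0.0, 7200.0, 121)
    rows, frames = [], []
    for variant in TABLE2:
        p = model_params(variant)
        traj = simulate_progress(p, cond, t_s)
        cons = float(np.max(np.abs(traj.S + traj.P - cond.S0)) / cond.S0)
        lin = float(
            np.max(np.abs(traj.Ea + p.kinact / p.kcat * traj.P * 1000.0 - cond.E0))
            / cond.E0
        )
        plateau = final_product(p, cond)
        rows.append(
            {
                "variant": variant,
                "Km_mM": p.Km,
                "kcat_per_s": p.kcat,
                "kinact_model_per_s": p.kinact,
                "partition_ratio": partition_ratio(p),
                "plateau_mM": plateau.P_inf_mM,
                "substrate_limited": plateau.substrate_limited,
                "max_conservation_err": cons,
                "max_linear_invariant_err": lin,
            }
        )
        frames.append(
            pd.DataFrame(
                {"variant": variant, "t_min": traj.t / 60.0, "S_mM": traj.S,
                 "Ea_uM": traj.Ea, "P_mM": traj.P}
            )
        )

    pd.concat(frames).to_csv(args.outdir / "trajectories.tsv", sep="\t", index=False)
    summary = pd.DataFrame(rows)
    summary.to_csv(args.outdir / "kinetics_summary.tsv", sep="\t", index=False)
    (args.outdir / "kinetics_invariants.json").write_text(
        json.dumps(
            {
                "max_conservation_err": summary["max_conservation_err"].max(),
                "max_linear_invariant_err": summary["max_linear_invariant_err"].max(),
            },
            indent=2,
        )
    )
    print(summary.to_string(index=False, float_format=lambda x: f"{x:.6g}"))
    print(
        "\nBoth conservation invariants hold to "
        f"{summary[['max_conservation_err', 'max_linear_invariant_err']].values.max():.1e} "
        "relative; product plateaus are enzyme-limited (partition ratio x E0), "
        "so longer-lived variants accumulate proportionally more product."
    )


if __name__ == "__main__":
    main()
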