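#!/usr/bin/env python
"""Mock high-throughput screening campaign.

Samples a 2000-clone library around wild-type-like kinetics (log-normal kcat
spread, a 5 % beneficial tail with boosted kcat and halved inactivation),
simulates every well's product time course, selects the top 96 wells by peak
signal, and measures how strongly the beneficial tail is enriched.
"""

import argparse
import json
import math
from pathlib import Path

from bsadc import KineticParams, LibrarySpec, gen_screen_plate, select_top


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-variants", type=int, default=2000)
    parser.add_argument("--top-k", type=int, default=96)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    lam = math.log(2.0) / (17.91 * 60.0) * (3.69 + 40.0) / 40.0
    base = KineticParams(Km=3.69, kcat=4.25, kinact=lam)
    plate = gen_screen_plate(
        args.n_variants,
        LibrarySpec(base=base),
        seed=args.seed,
        times_min=[0.0, 30.0, 60.0, 90.0, 120.0],
    )
    top = select_top(plate, args.top_k)
    by_label = {w.label: w for w in plate.wells}
    n_beneficial_total = sum(w.beneficial for w in plate.wells)
    n_beneficial_top = sum(by_label[l].beneficial for l in top)
    base_rate = n_beneficial_total / len(plate)
    hit_rate = n_beneficial_top / args.top_k
    summary = {
        "n_variants": len(plate),
        "n_beneficial_total": n_beneficial_total,
        "top_k": args.top_k,
        "n_beneficial_in_top_k": n_beneficial_top,
        "library_beneficial_rate": base_rate,
        "top_k_beneficial_rate": hit_rate,
        "enrichment_fold": hit_rate / base_rate if base_rate else None,
    }
    (args.outdir / "screen_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))
    print(
        f"\nPeak-signal selection recovers {n_beneficial_top}/{args.top_k} "
        f"beneficial clones ({hit_rate:.0%} vs {base_rate:.1%} in the library, "
        f"{hit_rate / base_rate:.1f}-fold enrichment)."
    )


if __name__ == "__main__":
    main()
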