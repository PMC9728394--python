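#!/usr/bin/env python
"""Compare WT and mutant conformational distributions per acceptor.

For each ligand, maps the screened poses onto the (d1, a1) plane after the
d2 < 4 A prefilter, computes the mutant-minus-WT density difference and the
enrichment count inside the reactive region, and summarizes reactive-pose
populations across all five acceptors with two-proportion tests.
"""

import argparse
from pathlib import Path

import numpy as np

from asase.ensemble import build_conformation_map, reactive_population_summary
from asase.geometry import ReactiveCriteria
from asase.pipeline import _plot_map, load_geometries_csv


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--screen", type=Path, default=Path("results/screen"))
    parser.add_argument("--out", type=Path, default=Path("results/compare"))
    parser.add_argument("--no-plots", action="store_true")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    criteria = ReactiveCriteria()

    ligands = sorted({p.name.rsplit("_", 1)[0] for p in args.screen.glob("*_wt.csv")})
    per_ligand = {}
    print("ligand      enrichment (mut - WT reactive poses in the box)")
    for ligand in ligands:
        gw = load_geometries_csv(args.screen / f"{ligand}_wt.csv")
        gm = load_geometries_csv(args.screen / f"{ligand}_mut.csv")
        per_ligand[ligand] = (gw, gm)
        m = build_conformation_map(gw, gm, criteria)
        np.savetxt(args.out / f"{ligand}_density_diff.csv", m.density_diff,
                   delimiter=",", fmt="%.8g")
        if not args.no_plots:
            _plot_map(m, args.out / f"{ligand}_map.png", ligand)
        print(f"{ligand:>10s}  {m.enrichment_count:+d}")

    summary = reactive_population_summary(per_ligand)
    summary.to_csv(args.out / "population_summary.tsv", sep="\t", index=False,
                   float_format="%.6g")
    print("\nper-ligand reactive fractions (WT vs mutant):")
    print(summary.to_string(index=False,
                            formatters={"frac_wt": "{:.3f}".format,
                                        "frac_mut": "{:.3f}".format,
                                        "diff": "{:+.3f}".format,
                                        "p_value": "{:.2e}".format}))
    direction = "consistent" if summary.attrs["consistent_direction"] else "NOT consistent"
    print(f"\ndirection of the mutant shift is {direction} across acceptors")


if __name__ == "__main__":
    main()
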