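#!/usr/bin/env python
"""Screen every docking pose for glucosyl-transfer reactive conformations.

Reads the PDBQT ensembles and receptor written by 01_generate_datasets.py,
computes (d1, d2, a1) per pose with the default criteria (d1 < 4 A,
d2 < 4 A, 80 deg < a1 < 140 deg) and writes one per-pose CSV per
ligand/variant under results/screen/.
"""

import argparse
from pathlib import Path

from asase.geometry import CatalyticSiteMap, ReactiveCriteria, classify_ensemble
from asase.structure_io import read_pdb, read_pdbqt_poses


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/screen"))
    args = parser.parse_args()
    criteria = ReactiveCriteria()
    args.out.mkdir(parents=True, exist_ok=True)

    for variant in ("wt", "mut"):
        pose_dir = args.data / "poses" / variant
        receptor = read_pdb(pose_dir / "receptor.pdb")
        site = CatalyticSiteMap.from_yaml(pose_dir / "site.yml")
        for pose_file in sorted(pose_dir.glob("*_poses.pdbqt")):
            ligand = pose_file.name.replace("_poses.pdbqt", "")
            poses = read_pdbqt_poses(pose_file)
            df = classify_ensemble(poses, receptor, site, criteria)
            dest = args.out / f"{ligand}_{variant}.csv"
            df.to_csv(dest, index=False, float_format="%.8g")
            print(f"{ligand:>10s}/{variant}: {len(df)} poses, "
                  f"{int(df['reactive'].sum())} reactive "
                  f"({df['reactive'].mean():.1%}) -> {dest}")


if __name__ == "__main__":
    main()
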