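#!/usr/bin/env python
"""Generate the synthetic study inputs: docking-pose ensembles for five
phenolic acceptors (WT and mutant), five replica trajectories per variant,
and the four initial-velocity assay datasets.

Writes everything under results/data/ in the on-disk formats the rest of
the analysis reads back (PDB receptor, multi-MODEL PDBQT poses, multi-frame
XYZ trajectories, kinetics CSVs).
"""

import argparse
import json
from pathlib import Path

import numpy as np

from asase.pipeline import DEFAULT_LIGANDS, _task_seed
from asase.synthetic import (
    MU_DESIGN_MM,
    SUCROSE_DESIGN_MM,
    KineticSimSpec,
    PoseEnsembleSpec,
    TrajectorySpec,
    generate_kinetic_data,
    generate_pose_ensemble,
    generate_trajectory,
)

REACTIVE_FRACTIONS = {"wt": 0.2, "mut": 0.3}
N_POSES = 1000
N_RESIDUES, N_FRAMES, N_REPLICAS = 50, 200, 5
SIGMA_WT, MUTATION_WINDOW, MUT_FACTOR = 0.5, (20, 30), 0.6

KINETIC_DESIGNS = {
    "wt_sucrose": dict(Km_true=36.174, Vmax_true=0.090, substrate_concs=SUCROSE_DESIGN_MM,
                       substrate="sucrose"),
    "mut_sucrose": dict(Km_true=44.570, Vmax_true=0.093, substrate_concs=SUCROSE_DESIGN_MM,
                        substrate="sucrose"),
    "mut_mu": dict(Km_true=2.718, Vmax_true=0.236, substrate_concs=MU_DESIGN_MM,
                   substrate="MU"),
    # WT with the MU acceptor never saturates over 0.1-1.0 mM: Km far above range
    "wt_mu": dict(Km_true=50.0, Vmax_true=3.625, substrate_concs=MU_DESIGN_MM,
                  substrate="MU"),
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/data"))
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    print(f"# pose ensembles: {len(DEFAULT_LIGANDS)} ligands x 2 variants x {N_POSES} poses")
    for ligand, n_oh in DEFAULT_LIGANDS.items():
        for variant, frac in REACTIVE_FRACTIONS.items():
            spec = PoseEnsembleSpec(
                n_conformations=N_POSES, ligand_name=ligand, n_hydroxyls=n_oh,
                fraction_reactive_target=frac,
                seed=_task_seed(args.seed, f"poses/{ligand}/{variant}"),
            )
            ens = generate_pose_ensemble(spec)
            paths = ens.write(out / "poses" / variant, prefix=ligand.lower())
            truth_frac = ens.ground_truth["reactive"].mean()
            print(f"  {ligand:>10s}/{variant}: {N_POSES} poses, {n_oh} OH, "
                  f"reactive fraction {truth_frac:.3f} -> {paths['poses'].name}")

    print(f"# trajectories: {N_REPLICAS} replicas x {N_FRAMES} frames, {N_RESIDUES} residues")
    sig_wt = np.full(N_RESIDUES, SIGMA_WT)
    sig_mut = sig_wt.copy()
    sig_mut[MUTATION_WINDOW[0]:MUTATION_WINDOW[1] + 1] *= MUT_FACTOR
    for variant, sig in (("wt", sig_wt), ("mut", sig_mut)):
        tset = generate_trajectory(
            TrajectorySpec(n_residues=N_RESIDUES, n_frames=N_FRAMES,
                           per_residue_sigma=tuple(sig), n_replicas=N_REPLICAS,
                           seed=_task_seed(args.seed, f"traj/{variant}"))
        )
        paths = tset.write(out / "trajectories" / variant)
        print(f"  {variant}: {len(paths)} replica XYZ files "
              f"(mutant window {MUTATION_WINDOW} stiffened x{MUT_FACTOR})"
              if variant == "mut" else f"  {variant}: {len(paths)} replica XYZ files")

    print("# kinetics: four assay designs, 5% CV multiplicative noise, triplicate")
    (out / "kinetics").mkdir(exist_ok=True)
    for name, design in KINETIC_DESIGNS.items():
        data = generate_kinetic_data(
            KineticSimSpec(noise_cv=0.05, replicates=3,
                           seed=_task_seed(args.seed, f"kin/{name}"), **design)
        )
        data.to_csv(out / "kinetics" / f"{name}.csv")
        print(f"  {name}: {data.velocity.size} points over "
              f"{data.n_distinct_concentrations} concentrations")

    with open(out / "conditions.json", "w") as fh:
        json.dump(
            {
                "seed": args.seed,
                "n_poses": N_POSES,
                "reactive_fractions": REACTIVE_FRACTIONS,
                "trajectory": {"n_residues": N_RESIDUES, "n_frames": N_FRAMES,
                               "n_replicas": N_REPLICAS, "sigma_wt": SIGMA_WT,
                               "mutation_window": MUTATION_WINDOW,
                               "mutant_sigma_factor": MUT_FACTOR},
                "kinetics": {k: {kk: vv for kk, vv in v.items()} for k, v in KINETIC_DESIGNS.items()},
            },
            fh, indent=2,
        )
    print(f"conditions recorded in {out / 'conditions.json'}")


if __name__ == "__main__":
    main()
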