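"""Structural comparison: regional RMSD and steric clash scanning.

By default runs on a synthetic Cα-trace pair emulating the mutant vs
wild-type comparison: a 167-residue bundle whose N-terminal helix and
following turn (residues 11-21, "αA") is rigidly displaced by 1.7 Å while
the rest carries only ~0.2 Å of coordinate noise. Reports the αA
global-frame RMSD, a core-region RMSD, and the overall Cα superposition.
A displacement-recovery check on a larger trace with small displaced
regions verifies the global-frame measurement quantitatively.

Given two real PDB files (``--ref wild_type.pdb --mob mutant.pdb``) it
runs the same comparison on them instead.

Also demonstrates the clash scan on a worked two-atom case: carbons 2.0 Å
apart overlap by 1.70 + 1.70 - 2.0 = 1.4 Å, well past the 0.4 Å
severe-clash threshold — the geometry behind a bulky H+4 side chain
occupying the space of the partner's catalytic lysine.

Writes results/structure_rmsd.tsv and results/clash_demo.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import hptkit as h
from hptkit.reference_data import ALPHA_A_RANGE

RESULTS = Path(__file__).resolve().parent.parent / "results"


def compare(mob: h.StructureModel, ref: h.StructureModel, label: str) -> list:
    P, Q, _ = h.match_atoms(mob, ref, "CA")
    sup = h.kabsch_superpose(P, Q)
    rows = [(label, "overall", "global_frame", sup.rmsd, sup.n_atoms)]
    regions = {
        "alphaA": h.RegionSpec("A", [ALPHA_A_RANGE]),
        "core_60_160": h.RegionSpec("A", [(60, 160)]),
    }
    for name, region in regions.items():
        for mode in ("global_frame", "local_fit"):
            try:
                r = h.region_rmsd(mob, ref, region, mode)
            except ValueError:
                continue
            rows.append((label, name, mode, r, None))
    return rows


def main(seed: int = 1, ref: str | None = None, mob: str | None = None) -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []

    if ref and mob:
        rows += compare(h.read_pdb(mob), h.read_pdb(ref), "user_pdb")
    else:
        base, partner, _ = h.generate_structure_pair(h.StructureDesign(seed=seed))
        rows += compare(partner, base, "synthetic_default")

        recovery = h.StructureDesign(
            n_residues=800,
            displacements={"regionA": ((101, 106), 1.7),
                           "regionB": ((501, 506), 0.8)},
            noise_sd=0.0, seed=seed,
        )
        b2, p2, truth = h.generate_structure_pair(recovery)
        for name, ((s, e), mag) in truth.displacements.items():
            got = h.region_rmsd(p2, b2, h.RegionSpec("A", [(s, e)]))
            rows.append(("recovery", name, "global_frame", got, None))
            print(f"{name}: planted {mag:.2f} Å, recovered {got:.3f} Å "
                  f"({100 * abs(got - mag) / mag:.1f}% off)")

    df = pd.DataFrame(rows, columns=["dataset", "region", "mode", "rmsd_A", "n_atoms"])
    df.to_csv(RESULTS / "structure_rmsd.tsv", sep="\t", index=False)
    print(df.to_string(index=False))

    # worked clash example: two carbons 2.0 Å apart
    a = h.StructureModel([h.Atom(serial=1, name="CD", altloc="", resname="GLN",
                                 chain="A", resseq=68, icode="",
                                 xyz=np.zeros(3), element="C")])
    b = h.StructureModel([h.Atom(serial=1, name="CE", altloc="", resname="LYS",
                                 chain="B", resseq=1195, icode="",
                                 xyz=np.array([2.0, 0.0, 0.0]), element="C")])
    pairs = h.clash_scan(a, h.RegionSpec("A", [(68, 68)], "heavy"),
                         b, h.RegionSpec("B", [(1195, 1195)], "heavy"), 0.4)
    pd.DataFrame(
        [(p.atom_a, p.atom_b, p.distance, p.overlap) for p in pairs],
        columns=["atom_a", "atom_b", "distance_A", "overlap_A"],
    ).to_csv(RESULTS / "clash_demo.tsv", sep="\t", index=False)
    print(f"\nclash demo: {pairs[0].atom_a} vs {pairs[0].atom_b} at "
          f"{pairs[0].distance:.1f} Å -> overlap {pairs[0].overlap:.2f} Å")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--ref", help="reference (wild-type) PDB file")
    ap.add_argument("--mob", help="mobile (mutant) PDB file")
    main(**vars(ap.parse_args()))
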