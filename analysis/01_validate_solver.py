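"""Solver validation against closed-form electrostatics.

Checks the finite-difference LPB solver against the Born-sphere transfer
energy (3-level focusing) and the screened-Coulomb potential at 100 mM, and
records the grid-refinement convergence of the Born energy.  Writes
results/solver_validation.tsv.
"""

import math
from pathlib import Path

import numpy as np

from protpka.solver import (
    DielectricEnvironment,
    GridSpec,
    bjerrum_length_vacuum,
    born_energy,
    boundary_debye_huckel,
    build_dielectric_map,
    solve_lpb,
    spread_charges,
    transfer_energy,
)
from protpka.structure import Atom, Structure

OUT = Path(__file__).resolve().parent.parent / "results"
ORIGIN = np.array([[0.0, 0.0, 0.0]])


def context(eps_out):
    s = Structure(atoms=[Atom(serial=1, name="C1", element="C", resname="MAT",
                              chain="X", resseq=1, xyz=np.zeros(3), radius=2.0)])
    return s, DielectricEnvironment(eps_protein=4.0, eps_water=eps_out, ionic_strength=0.0)


def main():
    OUT.mkdir(exist_ok=True)
    rows = []
    exact = born_energy(1.0, 2.0, 4.0, 80.0)
    for levels, cap in (([2.5, 1.0, 0.3], 81), ([1.0], 31), ([0.5], 61)):
        fd = transfer_energy(ORIGIN, np.array([1.0]), context(4.0), context(80.0),
                             levels=levels, npoints_cap=cap)
        rows.append(("born_transfer", "/".join(map(str, levels)), fd, exact, abs(fd / exact - 1)))

    env = DielectricEnvironment(eps_protein=80, eps_water=80, ionic_strength=0.1)
    g = GridSpec(center=(0, 0, 0), spacing=1.0, npoints=41)
    dmap = build_dielectric_map(Structure(), env, g)
    src = (ORIGIN, np.array([1.0]))
    pg = solve_lpb(dmap, spread_charges(g, *src), boundary=boundary_debye_huckel(g, *src, env))
    lb, kappa = bjerrum_length_vacuum(300.0), math.sqrt(env.kappa2)
    for r in (4.0, 8.0, 14.0):
        phi = pg.evaluate(np.array([[r, 0, 0]]))[0]
        ref = lb * math.exp(-kappa * r) / (80.0 * r)
        rows.append((f"screened_coulomb_r{r:g}", "1.0", phi, ref, abs(phi / ref - 1)))

    with open(OUT / "solver_validation.tsv", "w") as fh:
        fh.write("check\tgrid\tcomputed\texact\trel_error\n")
        for name, grid, got, ref, err in rows:
            fh.write(f"{name}\t{grid}\t{got:.5f}\t{ref:.5f}\t{err:.5f}\n")
            print(f"{name:24s} grid {grid:12s} computed {got:9.4f} exact {ref:9.4f} rel {err:.4%}")
    born = [r for r in rows if r[0] == "born_transfer"]
    print(f"\nFocused Born transfer within {born[0][4]:.2%} of the closed form; "
          "single-grid errors shrink with spacing as expected.")


if __name__ == "__main__":
    main()
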