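"""Synthetic desk-scale fixtures with known ground truth.

Everything here is generated geometry, not experimental data: capped
single-residue model compounds, linear multi-site toys with closed-form
coupling expectations, and a miniature membrane-protein-like bundle
(``make_mini_rc``) that emulates the structural motif of interest -- an
ionizable phenol wedged between a photo-oxidizable cofactor pair (whose +1
hole is split 2:1 over two rings), a hydroxyl H-bond partner, an imidazole,
a carboxylate and a crystal water, all buried in a low-dielectric ball of
uncharged dummy atoms.  The phenol side chain carries three alternate
conformers (A/B/C) whose hydroxyl oxygen sits at decreasing distances from
the partner hydroxyl, mimicking a dark / light / deprotonated-relaxed
geometry ladder.

All randomness flows from a single seed; regenerating with the same seed
yields a bit-identical PDB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .solver import bjerrum_length_vacuum, debye_kappa2
from .structure import Atom, Structure, place_internal, place_polar_hydrogens

LN10 = math.log(10.0)

__all__ = [
    "ToySpec",
    "ToyExpectation",
    "MiniRCExpectation",
    "build_residue",
    "make_model_compound",
    "make_toy_multisite",
    "make_mini_rc",
    "MODEL_COMPOUND_KINDS",
]

MODEL_COMPOUND_KINDS = ("ASP", "GLU", "LYS", "ARG", "CYS", "TYR", "HIS", "SER", "THR", "ASN")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# Residue geometry templates (idealized internal coordinates)
# ---------------------------------------------------------------------------

# (name, (a, b, parent), bond, angle, dihedral): heavy atoms only; polar
# hydrogens come from place_polar_hydrogens.
_SIDE_CHAINS: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.42, 111, 180)],
    "THR": [
        ("OG1", ("N", "CA", "CB"), 1.42, 109, 180),
        ("CG2", ("N", "CA", "CB"), 1.52, 110, -60),
    ],
    "CYS": [("SG", ("N", "CA", "CB"), 1.81, 112, 180)],
    "ASN": [
        ("CG", ("N", "CA", "CB"), 1.52, 112, 180),
        ("OD1", ("CA", "CB", "CG"), 1.23, 120, 0),
        ("ND2", ("CA", "CB", "CG"), 1.33, 116, 180),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.52, 112, 180),
        ("OD1", ("CA", "CB", "CG"), 1.25, 118, 0),
        ("OD2", ("CA", "CB", "CG"), 1.25, 118, 180),
    ],
    "GLU": [
        ("CG", ("N", "CA", "CB"), 1.52, 112, 180),
        ("CD", ("CA", "CB", "CG"), 1.52, 112, 180),
        ("OE1", ("CB", "CG", "CD"), 1.25, 118, 0),
        ("OE2", ("CB", "CG", "CD"), 1.25, 118, 180),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), 1.52, 112, 180),
        ("CD", ("CA", "CB", "CG"), 1.52, 112, 180),
        ("CE", ("CB", "CG", "CD"), 1.52, 112, 180),
        ("NZ", ("CG", "CD", "CE"), 1.49, 112, 180),
    ],
    "ARG": [
        ("CG", ("N", "CA", "CB"), 1.52, 112, 180),
        ("CD", ("CA", "CB", "CG"), 1.52, 112, 180),
        ("NE", ("CB", "CG", "CD"), 1.46, 112, 180),
        ("CZ", ("CG", "CD", "NE"), 1.33, 124, 180),
        ("NH1", ("CD", "NE", "CZ"), 1.33, 120, 0),
        ("NH2", ("CD", "NE", "CZ"), 1.33, 120, 180),
    ],
    "TYR": [("CG", ("N", "CA", "CB"), 1.51, 113, 180), ("RING6", None, 0, 0, 0)],
    "HIS": [("CG", ("N", "CA", "CB"), 1.50, 113, 180), ("RING5", None, 0, 0, 0)],
}

#: canonical heavy-atom order per residue (backbone first)
_ATOM_ORDER = {
    res: ["N", "CA", "C", "O"] + (["CB"] if res != "GLY" else []) + names
    for res, names in {
        "GLY": [],
        "ALA": [],
        "SER": ["OG"],
        "THR": ["OG1", "CG2"],
        "CYS": ["SG"],
        "ASN": ["CG", "OD1", "ND2"],
        "ASP": ["CG", "OD1", "OD2"],
        "GLU": ["CG", "CD", "OE1", "OE2"],
        "LYS": ["CG", "CD", "CE", "NZ"],
        "ARG": ["CG", "CD", "NE", "CZ", "NH1", "NH2"],
        "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
        "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
    }.items()
}


def _ring6(coords: dict[str, np.ndarray]) -> None:
    """Planar phenol ring grown from CB-CG, plus the hydroxyl oxygen."""
    cb, cg, ca = coords["CB"], coords["CG"], coords["CA"]
    u = _unit(cg - cb)
    n = _unit(np.cross(u, cb - ca))
    center = cg + 1.39 * u
    e1 = _unit(cg - center)
    e2 = np.cross(n, e1)
    for name, theta in (("CD1", 60), ("CE1", 120), ("CZ", 180), ("CE2", 240), ("CD2", 300)):
        th = math.radians(theta)
        coords[name] = center + 1.39 * (math.cos(th) * e1 + math.sin(th) * e2)
    coords["OH"] = center + (1.39 + 1.38) * (-e1)


def _ring5(coords: dict[str, np.ndarray]) -> None:
    """Planar imidazole grown from CB-CG."""
    cb, cg, ca = coords["CB"], coords["CG"], coords["CA"]
    u = _unit(cg - cb)
    n = _unit(np.cross(u, cb - ca))
    rad = 1.35 / (2 * math.sin(math.pi / 5))
    center = cg + rad * u
    e1 = _unit(cg - center)
    e2 = np.cross(n, e1)
    for name, theta in (("ND1", 72), ("CE1", 144), ("NE2", 216), ("CD2", 288)):
        th = math.radians(theta)
        coords[name] = center + rad * (math.cos(th) * e1 + math.sin(th) * e2)


def build_residue(resname: str) -> dict[str, np.ndarray]:
    """Heavy-atom coordinates of one idealized residue in a local frame."""
    if resname not in _SIDE_CHAINS:
        raise ValueError(f"unsupported residue type {resname!r}")
    c: dict[str, np.ndarray] = {
        "N": np.zeros(3),
        "CA": np.array([1.46, 0.0, 0.0]),
    }
    c["C"] = place_internal(np.array([0.0, 0.0, 1.0]), c["N"], c["CA"], 1.52, 111, 0)
    c["O"] = place_internal(c["N"], c["CA"], c["C"], 1.23, 120.5, 180)
    if resname != "GLY":
        c["CB"] = place_internal(c["C"], c["N"], c["CA"], 1.53, 110.5, 122)
    for row in _SIDE_CHAINS[resname]:
        name, refs, bond, angle, dih = row
        if name == "RING6":
            _ring6(c)
        elif name == "RING5":
            _ring5(c)
        else:
            a, b, p = refs
            c[name] = place_internal(c[a], c[b], c[p], bond, angle, dih)
    return c


def _element_of(name: str) -> str:
    if name == "FE":
        return "FE"
    if name == "MG":
        return "MG"
    return name[0]


def residue_atoms(
    resname: str,
    coords: dict[str, np.ndarray],
    chain: str,
    resseq: int,
    het: bool = False,
    altloc: dict[str, str] | None = None,
    order: list[str] | None = None,
) -> list[Atom]:
    names = order or _ATOM_ORDER.get(resname, sorted(coords))
    return [
        Atom(
            serial=0,
            name=n,
            element=_element_of(n),
            resname=resname,
            chain=chain,
            resseq=resseq,
            altloc=(altloc or {}).get(n, ""),
            xyz=np.round(coords[n], 3),
            hetatm=het,
        )
        for n in names
        if n in coords
    ]


def _frame(origin: np.ndarray, primary: np.ndarray, secondary: np.ndarray) -> np.ndarray:
    u = _unit(primary)
    w = _unit(np.cross(u, secondary))
    v = np.cross(w, u)
    return np.stack([u, v, w], axis=1)


def rigid_place(
    coords: dict[str, np.ndarray],
    anchor: str,
    target: np.ndarray,
    direction_atom: str,
    direction: np.ndarray,
    normal: np.ndarray = np.array([0.0, 0.0, 1.0]),
) -> dict[str, np.ndarray]:
    """Rigidly move a residue so ``anchor`` lands on ``target`` with the
    anchor-to-``direction_atom`` axis along ``direction``."""
    src = _frame(coords[anchor], coords[direction_atom] - coords[anchor], normal)
    dst = _frame(np.asarray(target, float), np.asarray(direction, float), normal)
    rot = dst @ src.T
    o = coords[anchor]
    return {k: rot @ (v - o) + np.asarray(target, float) for k, v in coords.items()}


# ---------------------------------------------------------------------------
# Model compounds
# ---------------------------------------------------------------------------


def make_model_compound(kind: str) -> Structure:
    """Capped single-residue structure whose two charge states both resolve.

    Run through the titration machinery in pure water it recovers its
    reference pKa exactly (the protein and model contexts coincide).
    """
    if kind not in MODEL_COMPOUND_KINDS:
        raise ValueError(f"unsupported model-compound kind {kind!r}; choose from {MODEL_COMPOUND_KINDS}")
    coords = build_residue(kind)
    s = Structure(atoms=residue_atoms(kind, coords, chain="A", resseq=1))
    return place_polar_hydrogens(s, mode="ideal")


# ---------------------------------------------------------------------------
# Multi-site toys
# ---------------------------------------------------------------------------


@dataclass
class ToySpec:
    n_sites: int
    site_kinds: list[str]  # acid | base | redox, one per site
    geometry: list[float] | float = 7.0  # consecutive inter-site gaps in A
    eps_context: str = "uniform"  # uniform | sphere
    seed: int = 0

    def gaps(self) -> list[float]:
        g = self.geometry
        gaps = [float(g)] * (self.n_sites - 1) if np.isscalar(g) else [float(x) for x in g]
        if len(gaps) != max(self.n_sites - 1, 0):
            raise ValueError("geometry must give n_sites - 1 gaps")
        if any(x < 3.0 for x in gaps):
            raise ValueError("inter-site distances must be at least 3 A")
        return gaps

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("toy spec requires an explicit seed")
        if len(self.site_kinds) != self.n_sites:
            raise ValueError("site_kinds must have one entry per site")
        if any(k not in ("acid", "base", "redox") for k in self.site_kinds):
            raise ValueError(f"unknown site kind in {self.site_kinds}")
        if self.eps_context not in ("uniform", "sphere"):
            raise ValueError(f"unknown eps context {self.eps_context!r}")
        self.gaps()


_TOY_RES = {"acid": ("TTA", "O1"), "base": ("TTB", "N1"), "redox": ("TTR", "FE")}
#: net charge of the charged-form deviation per kind (acid: anion, base:
#: cation, redox: oxidized hole)
_TOY_SIGN = {"acid": -1.0, "base": 1.0, "redox": 1.0}


@dataclass
class ToyExpectation:
    """Closed-form expectations bundled with a toy fixture."""

    positions: np.ndarray
    kinds: list[str]
    eps_w: float = 80.0
    ionic_strength: float = 0.1
    temperature: float = 300.0
    W_expected: np.ndarray = field(default=None)

    def compute_W(self) -> np.ndarray:
        """Screened-Coulomb couplings in pK units for the uniform context."""
        lb = bjerrum_length_vacuum(self.temperature)
        kappa = math.sqrt(debye_kappa2(self.ionic_strength, self.temperature, self.eps_w))
        n = len(self.positions)
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = float(np.linalg.norm(self.positions[i] - self.positions[j]))
                w = lb * math.exp(-kappa * d) / (self.eps_w * d * LN10)
                W[i, j] = W[j, i] = _TOY_SIGN[self.kinds[i]] * _TOY_SIGN[self.kinds[j]] * w
        return W

    def self_check(self, atol: float = 1e-9) -> bool:
        """Guard against fixture rot: stored values must match the closed
        forms recomputed from the stored geometry."""
        return bool(np.allclose(self.W_expected, self.compute_W(), atol=atol))


def make_toy_multisite(spec: ToySpec) -> tuple[Structure, ToyExpectation]:
    """Single-atom titratable sites along a line with perpendicular jitter.

    The jitter (seeded, < 0.5 A, perpendicular to the line) only increases
    pairwise distances, so the minimum-separation invariant is preserved.
    The bundled expectation record carries the closed-form screened-Coulomb
    coupling matrix for the uniform-dielectric context.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    gaps = spec.gaps()
    xs = np.concatenate([[0.0], np.cumsum(gaps)])
    atoms: list[Atom] = []
    positions = []
    for i, kind in enumerate(spec.site_kinds):
        resname, atom_name = _TOY_RES[kind]
        pos = np.round(
            np.array([xs[i], rng.uniform(-0.5, 0.5), rng.uniform(-0.5, 0.5)]), 3
        )
        positions.append(pos)
        atoms.append(
            Atom(
                serial=0,
                name=atom_name,
                element=_element_of(atom_name),
                resname=resname,
                chain="T",
                resseq=i + 1,
                xyz=pos,
                hetatm=True,
            )
        )
    s = Structure(atoms=atoms)
    if spec.eps_context == "sphere":
        center = np.mean(positions, axis=0)
        radius = float(np.max(np.linalg.norm(np.array(positions) - center, axis=1))) + 6.0
        s.atoms.extend(_matrix_ball(center, radius, rng, avoid=np.array(positions)))
    exp = ToyExpectation(positions=np.array(positions), kinds=list(spec.site_kinds))
    exp.W_expected = exp.compute_W()
    return s, exp


def _matrix_ball(
    center: np.ndarray,
    radius: float,
    rng: np.random.Generator,
    avoid: np.ndarray,
    spacing: float = 2.2,
    clearance: float = 2.7,
) -> list[Atom]:
    """Cubic lattice of uncharged carbon dummies filling a ball: a synthetic
    low-dielectric interior.  The lattice is tight enough (2.2 A for 1.7 A
    radii) that the van der Waals union has no solvent channels."""
    k = int(math.ceil(radius / spacing))
    pts = []
    for i in range(-k, k + 1):
        for j in range(-k, k + 1):
            for l in range(-k, k + 1):
                p = center + spacing * np.array([i, j, l]) + rng.uniform(-0.12, 0.12, 3)
                if np.linalg.norm(p - center) > radius:
                    continue
                if len(avoid) and np.min(np.linalg.norm(avoid - p, axis=1)) < clearance:
                    continue
                pts.append(np.round(p, 3))
    return [
        Atom(
            serial=0,
            name=f"C{i + 1}",
            element="C",
            resname="MAT",
            chain="Z",
            resseq=i + 1,
            xyz=p,
            hetatm=True,
        )
        for i, p in enumerate(pts)
    ]


def _cofactor_ring(
    resname: str, center: np.ndarray, normal: np.ndarray, chain: str, resseq: int, radius: float = 1.8
) -> list[Atom]:
    n = _unit(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, n)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(n, helper))
    e2 = np.cross(n, e1)
    coords = {}
    for k in range(12):
        th = 2 * math.pi * k / 12
        coords[f"C{k + 1}"] = np.round(center + radius * (math.cos(th) * e1 + math.sin(th) * e2), 3)
    return residue_atoms(resname, coords, chain=chain, resseq=resseq, het=True, order=sorted(coords, key=lambda x: int(x[1:])))


def _check_clearances(atoms: list[Atom], dmin: float = 2.55) -> None:
    """Guard against layout regressions: no two heavy atoms of different
    residues closer than ``dmin``, except intended H-bond partners."""
    allowed = {
        frozenset({("M", 185), ("L", 162)}),  # threonine-phenol H-bond ladder
        frozenset({("L", 162), ("M", 2001)}),  # phenol-water H-bond
    }
    groups: dict[tuple[str, int], list[Atom]] = {}
    for a in atoms:
        groups.setdefault((a.chain, a.resseq), []).append(a)
    keys = list(groups)
    for i, k1 in enumerate(keys):
        for k2 in keys[i + 1 :]:
            if frozenset({k1, k2}) in allowed:
                continue
            for x in groups[k1]:
                for y in groups[k2]:
                    d = float(np.linalg.norm(x.xyz - y.xyz))
                    if d < dmin:
                        raise AssertionError(
                            f"fixture layout clash: {k1}:{x.name} - {k2}:{y.name} at {d:.2f} A"
                        )


# ---------------------------------------------------------------------------
# Miniature reaction-center-like bundle
# ---------------------------------------------------------------------------


@dataclass
class MiniRCExpectation:
    """Construction record: key geometry and closed-form assertion bands."""

    oo_distances: dict[str, float]  # conformer label -> phenol O to hydroxyl O
    ring_centers: dict[str, np.ndarray]
    phenol_o: dict[str, np.ndarray]  # conformer label -> OH oxygen position
    hole_ratio: tuple[float, float] = (2.0, 1.0)
    eps_protein: float = 4.0
    eps_water: float = 80.0
    temperature: float = 300.0

    def hole_shift_bounds(self, conformer: str = "C") -> tuple[float, float]:
        """Bracket for the direct pKa shift of the phenol caused by switching
        the cofactor pair hole on: between the fully solvent-screened and the
        unscreened interior Coulomb estimate (both negative; returned as
        (lower, upper) bounds on the shift)."""
        lb = bjerrum_length_vacuum(self.temperature)
        wa, wb = self.hole_ratio
        qa, qb = wa / (wa + wb), wb / (wa + wb)
        o = self.phenol_o[conformer]
        da = float(np.linalg.norm(o - self.ring_centers["CFA"]))
        db = float(np.linalg.norm(o - self.ring_centers["CFB"]))
        coulomb = (qa / da + qb / db) * lb / LN10
        lo = -1.25 * coulomb / self.eps_protein  # unscreened interior estimate
        hi = -0.8 * coulomb / self.eps_water  # fully screened estimate
        return lo, hi

    def self_check(self) -> bool:
        for lab, o in self.phenol_o.items():
            if abs(self.oo_distances[lab] - float(np.linalg.norm(o))) > 1e-6:
                return False
        lo, hi = self.hole_shift_bounds()
        return lo < hi < 0


def make_mini_rc(seed: int = 0) -> tuple[Structure, MiniRCExpectation]:
    """A ~700-atom buried bundle emulating the phenol-deprotonation motif.

    Contents: a tyrosine whose side chain has three altloc conformers (A/B/C)
    with hydroxyl-O at 4.4 / 3.3 / 2.7 A from a threonine hydroxyl oxygen, a
    histidine near the threonine, an aspartate near the phenol (an acid that
    raises the phenol's pKa), a crystal water at H-bond distance from the
    dark-conformer hydroxyl, two neutral 12-carbon cofactor rings that accept
    a +1 hole at a 2:1 split, and a ball of uncharged dummy carbons providing
    the low-dielectric interior.  Switching the hole on must lower the phenol
    pKa, with the larger share of the effect from the nearer ring.
    """
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []

    # threonine: hydroxyl oxygen at the origin, body pointing away (-x)
    thr = build_residue("THR")
    thr = rigid_place(thr, "OG1", np.zeros(3), "CB", np.array([-1.0, -0.35, -0.2]), normal=np.array([0.0, 0.0, 1.0]))
    atoms += residue_atoms("THR", thr, chain="M", resseq=185)

    # tyrosine: backbone from the dark conformer; side chain in three altlocs.
    # The hydroxyl oxygens lie on the circle of radius |CB-OH| around the fixed
    # CB pivot, at exact target distances from the threonine oxygen, so the
    # three conformers are rigid side-chain rotations sharing CB.
    tyr_t = build_residue("TYR")
    L = float(np.linalg.norm(tyr_t["OH"] - tyr_t["CB"]))
    cb_pos = np.array([5.2, 0.6, 4.5])
    cbn = float(np.linalg.norm(cb_pos))
    oo_targets = {"A": 4.4, "B": 3.3, "C": 2.7}
    phenol_o: dict[str, np.ndarray] = {}
    conf_coords: dict[str, dict[str, np.ndarray]] = {}
    axis = _unit(np.cross(cb_pos, np.array([0.0, 1.0, 0.0])))  # rotation plane normal
    e_in = _unit(-cb_pos)  # from CB toward the threonine oxygen
    e_perp = np.cross(axis, e_in)
    for lab, d in oo_targets.items():
        cos_a = (cbn**2 + L**2 - d**2) / (2 * L * cbn)
        if not -1 < cos_a < 1:
            raise ValueError("infeasible phenol geometry")
        sin_a = math.sqrt(1 - cos_a**2)
        oh = cb_pos + L * (cos_a * e_in + sin_a * e_perp)
        phenol_o[lab] = np.round(oh, 3)
        conf_coords[lab] = rigid_place(tyr_t, "CB", cb_pos, "OH", oh - cb_pos, normal=axis)
    side_names = [n for n in _ATOM_ORDER["TYR"] if n not in ("N", "CA", "C", "O", "CB")]
    backbone = {n: conf_coords["A"][n] for n in ("N", "CA", "C", "O", "CB")}
    atoms += residue_atoms("TYR", backbone, chain="L", resseq=162, order=["N", "CA", "C", "O", "CB"])
    for lab in ("A", "B", "C"):
        side = {n: conf_coords[lab][n] for n in side_names}
        atoms += residue_atoms(
            "TYR", side, chain="L", resseq=162, altloc={n: lab for n in side_names}, order=side_names
        )

    # histidine: N-delta 4.2 A from the threonine hydroxyl, body on the +y side
    his = build_residue("HIS")
    his = rigid_place(
        his, "ND1", np.array([-1.5, 3.5, -1.7]), "CB", np.array([-0.2, 1.0, -0.55]),
        normal=np.array([1.0, 0.0, 0.2]),
    )
    atoms += residue_atoms("HIS", his, chain="L", resseq=168)

    # aspartate: carboxylate carbon 5.8 A from the dark-conformer phenol oxygen
    asp = build_residue("ASP")
    asp_dir = _unit(np.array([0.55, -0.6, 0.58]))
    asp = rigid_place(asp, "CG", phenol_o["A"] + 5.8 * asp_dir, "CB", asp_dir, normal=np.array([0.0, 0.0, 1.0]))
    atoms += residue_atoms("ASP", asp, chain="M", resseq=182)

    # crystal water at H-bond distance from the dark-conformer hydroxyl,
    # placed on the 109.5-degree cone its hydrogen can actually reach
    u_out = _unit(phenol_o["A"] - conf_coords["A"]["CZ"])
    p_hint = np.array([0.0, -0.8, -0.6])
    p_perp = _unit(p_hint - (p_hint @ u_out) * u_out)
    cone = math.radians(70.5)
    w_pos = np.round(phenol_o["A"] + 2.8 * (math.cos(cone) * u_out + math.sin(cone) * p_perp), 3)
    atoms.append(
        Atom(serial=0, name="O", element="O", resname="HOH", chain="M", resseq=2001, xyz=w_pos, hetatm=True)
    )

    # cofactor rings: the nearer ring (CFA) takes the 2/3 share of the hole
    ca_center = np.array([-3.5, -2.0, 6.5])
    cb_center = np.array([-8.0, -4.5, 10.5])
    atoms += _cofactor_ring("CFA", ca_center, np.array([0.3, 0.8, 0.5]), chain="P", resseq=1)
    atoms += _cofactor_ring("CFB", cb_center, np.array([0.4, 0.7, 0.6]), chain="P", resseq=2)

    _check_clearances(atoms)

    # low-dielectric ball around everything
    real = np.array([a.xyz for a in atoms])
    center = real.mean(axis=0)
    radius = float(np.max(np.linalg.norm(real - center, axis=1))) + 2.2
    atoms += _matrix_ball(center, radius, rng, avoid=real)

    s = Structure(atoms=atoms)
    exp = MiniRCExpectation(
        oo_distances={lab: float(np.linalg.norm(phenol_o[lab])) for lab in phenol_o},
        ring_centers={"CFA": ca_center, "CFB": cb_center},
        phenol_o=phenol_o,
    )
    return s, exp
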