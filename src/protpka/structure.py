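"""Protein structures with alternate conformers, water policy and geometry.

The in-memory model is deliberately flat: a :class:`Structure` is an ordered
list of :class:`Atom` records, mirroring the PDB file it came from.  Alternate
side-chain conformers (altloc A/B/...) are kept verbatim on reading and are
collapsed into a single named state with :func:`resolve_conformer`; crystal
waters are filtered with :func:`apply_water_policy`.  Polar hydrogens, which
crystal structures at ~3 A resolution do not resolve, are added at ideal
geometry and rotatable ones (hydroxyls, water) are oriented by a deterministic
dihedral grid search (:func:`place_polar_hydrogens`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import gemmi
import numpy as np

WATER_RESNAMES = {"HOH", "WAT", "H2O", "DOD"}

__all__ = [
    "Atom",
    "Structure",
    "read_structure",
    "write_pdb",
    "resolve_conformer",
    "apply_water_policy",
    "select_atom",
    "measure_distance",
    "place_polar_hydrogens",
    "place_internal",
]


@dataclass
class Atom:
    """One ATOM/HETATM record plus per-atom physics (radius, partial charge)."""

    serial: int
    name: str
    element: str
    resname: str
    chain: str
    resseq: int
    icode: str = ""
    altloc: str = ""
    xyz: np.ndarray = field(default_factory=lambda: np.zeros(3))
    occupancy: float = 1.0
    hetatm: bool = False
    radius: float = 0.0
    charge: float = 0.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if self.radius < 0.0:
            raise ValueError(f"atom {self.name}: negative radius")

    @property
    def reskey(self) -> tuple[str, int, str]:
        """Residue identity: (chain, resseq, insertion code)."""
        return (self.chain, self.resseq, self.icode)

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_RESNAMES

    def copy(self) -> "Atom":
        a = replace(self)
        a.xyz = self.xyz.copy()
        return a


@dataclass
class Structure:
    """Ordered atom collection with bookkeeping for resolved conformer state."""

    atoms: list[Atom] = field(default_factory=list)
    waters_kept: list[str] = field(default_factory=list)
    conformer_label: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def copy(self) -> "Structure":
        return Structure(
            atoms=[a.copy() for a in self.atoms],
            waters_kept=list(self.waters_kept),
            conformer_label=self.conformer_label,
        )

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms]) if self.atoms else np.zeros((0, 3))

    def residues(self) -> dict[tuple[str, int, str], list[Atom]]:
        """Atoms grouped by residue key, preserving file order."""
        out: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.reskey, []).append(a)
        return out

    def water_ids(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.is_water:
                wid = water_id(a)
                if wid not in seen:
                    seen.append(wid)
        return seen

    def find(self, chain: str, resseq: int, name: str, icode: str = "") -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.chain == chain and a.resseq == resseq and a.icode == icode and a.name == name
        ]


def water_id(atom: Atom) -> str:
    """Water identifier in the conventional 'HOH <chain> <resseq>' form."""
    return f"{atom.resname} {atom.chain} {atom.resseq}".strip()


# ---------------------------------------------------------------------------
# Reading / writing PDB
# ---------------------------------------------------------------------------


def _validate_pdb_text(text: str) -> None:
    """Light pre-scan so malformed coordinate records fail with a line number."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise ValueError(f"malformed PDB record at line {lineno}: truncated coordinates")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise ValueError(f"malformed PDB record at line {lineno}: {exc}") from None


def read_structure(pdb_source, model_index: int = 0) -> Structure:
    """Read a PDB file/stream/string into a :class:`Structure`.

    All alternate-location records are retained; HETATM groups (cofactors,
    waters) are kept and flagged.  ``model_index`` selects among NMR-style
    MODEL blocks (0-based).
    """
    if hasattr(pdb_source, "read"):
        text = pdb_source.read()
    else:
        text = str(pdb_source)
        if "\n" not in text:  # a path
            with open(text) as fh:
                text = fh.read()
    _validate_pdb_text(text)
    st = gemmi.read_pdb_string(text)
    if not 0 <= model_index < len(st):
        raise IndexError(f"model index {model_index} not in structure with {len(st)} model(s)")
    model = st[model_index]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            for at in res:
                altloc = at.altloc if at.altloc != "\x00" else ""
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name.upper(),
                        resname=res.name,
                        chain=chain.name,
                        resseq=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        altloc=altloc,
                        xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=min(1.0, round(float(at.occ), 4)),
                        hetatm=res.het_flag == "H",
                    )
                )
    s = Structure(atoms=atoms)
    s.waters_kept = s.water_ids()
    return s


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_pdb(s: Structure, target=None) -> str:
    """Write standard ATOM/HETATM/TER/END records; returns the text."""
    lines = []
    last_chain = None
    serial = 0
    for a in s.atoms:
        serial += 1
        if last_chain is not None and a.chain != last_chain:
            lines.append("TER")
        last_chain = a.chain
        rec = "HETATM" if a.hetatm else "ATOM  "
        lines.append(
            f"{rec}{serial:5d} {_format_atom_name(a.name, a.element)}{a.altloc or ' '}"
            f"{a.resname:>3s} {a.chain[:1]}{a.resseq:4d}{a.icode or ' '}   "
            f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if target is not None:
        if hasattr(target, "write"):
            target.write(text)
        else:
            with open(target, "w") as fh:
                fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Conformers and waters
# ---------------------------------------------------------------------------


def resolve_conformer(s: Structure, label: str, state_name: str = "") -> Structure:
    """Collapse alternate locations to the conformer ``label``.

    Atoms with a blank altloc are kept as-is.  For every group of records
    sharing (chain, resseq, icode, name) with non-blank altlocs, the record
    whose altloc equals ``label`` is kept.  A multi-conformer group lacking the
    requested label is an error (conformer choice is always explicit, never by
    occupancy).
    """
    groups: dict[tuple, list[Atom]] = {}
    order: list[tuple] = []
    for a in s.atoms:
        key = (a.chain, a.resseq, a.icode, a.name)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(a)
    atoms: list[Atom] = []
    missing: list[tuple] = []
    for key in order:
        grp = groups[key]
        blanks = [a for a in grp if a.altloc == ""]
        alts = [a for a in grp if a.altloc != ""]
        if blanks and not alts:
            if len(blanks) > 1:
                raise ValueError(f"duplicate atom records for {key}")
            atoms.append(blanks[0].copy())
            continue
        chosen = [a for a in alts if a.altloc == label]
        if not chosen:
            missing.append(key)
            continue
        a = chosen[0].copy()
        a.altloc = ""
        atoms.append(a)
    if missing:
        raise ValueError(
            f"altloc '{label}' missing for atom group(s): "
            + ", ".join(f"{c}:{r}{i}:{n}" for c, r, i, n in missing)
        )
    out = Structure(atoms=atoms, waters_kept=list(s.waters_kept), conformer_label=state_name or label)
    return out


def apply_water_policy(s: Structure, keep: Sequence[str]) -> Structure:
    """Retain only the listed crystal waters (e.g. ``["HOH M 2001"]``).

    All other waters are dropped; the cavities they leave are filled with
    solvent dielectric downstream (no cavity patching).
    """
    present = set(s.water_ids())
    keep = list(keep)
    unknown = [w for w in keep if w not in present]
    if unknown:
        raise ValueError(f"water id(s) not found: {unknown}; present: {sorted(present)}")
    keepset = set(keep)
    atoms = [a.copy() for a in s.atoms if not a.is_water or water_id(a) in keepset]
    return Structure(atoms=atoms, waters_kept=keep, conformer_label=s.conformer_label)


# ---------------------------------------------------------------------------
# Selection and geometry
# ---------------------------------------------------------------------------


def select_atom(s: Structure, selector: str) -> Atom:
    """Resolve a 'chain:resseq:atomname' selector to exactly one atom."""
    try:
        chain, resseq, name = selector.split(":")
        resseq_i = int(resseq)
    except ValueError:
        raise ValueError(f"bad selector {selector!r}; expected 'chain:resseq:atomname'") from None
    hits = [a for a in s.atoms if a.chain == chain and a.resseq == resseq_i and a.name == name]
    if not hits:
        raise ValueError(f"selector {selector!r} matches no atom")
    if len(hits) > 1:
        alts = [a.altloc or "-" for a in hits]
        raise ValueError(f"selector {selector!r} is ambiguous (altlocs {alts}); resolve conformers first")
    return hits[0]


def measure_distance(s: Structure, sel1: str, sel2: str) -> float:
    """Euclidean distance in A between two uniquely selected atoms."""
    a, b = select_atom(s, sel1), select_atom(s, sel2)
    return float(np.linalg.norm(a.xyz - b.xyz))


def place_internal(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom D from internal coordinates relative to chain A-B-C.

    ``bond`` = |C-D| in A, ``angle`` = B-C-D in degrees, ``dihedral`` =
    A-B-C-D in degrees (standard NeRF construction).
    """
    ang = math.radians(angle)
    dih = math.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:  # colinear frame: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, bc)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(dih),
            bond * math.sin(ang) * math.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# Polar-hydrogen placement
# ---------------------------------------------------------------------------

#: (resname, hname) -> (parent, ref1, ref2, bond, angle, dihedral, rotor)
#: ``rotor`` groups hydrogens that share a rotatable torsion about ref1-parent;
#: their dihedral column is the offset within the rotor.  The model is a
#: polar-hydrogen representation: apolar hydrogens are subsumed in heavy-atom
#: radii and never placed.
_H_TOPOLOGY: dict[tuple[str, str], tuple] = {}


def _load_h_topology() -> dict[tuple[str, str], tuple]:
    if _H_TOPOLOGY:
        return _H_TOPOLOGY
    text = resources.files("protpka.data").joinpath("hydrogens.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        resname, hname, parent, r1, r2, bond, angle, dihedral, rotor = line.split("\t")
        _H_TOPOLOGY[(resname, hname)] = (
            parent,
            r1,
            r2,
            float(bond),
            float(angle),
            float(dihedral),
            rotor,
        )
    return _H_TOPOLOGY


IDEAL_OH = 0.96  # A, hydroxyl / water
IDEAL_NH = 1.01  # A
WATER_HOH_ANGLE = 104.5  # deg
DIHEDRAL_STEP = 15.0  # deg, rotor grid


def _hbond_score(hpos: np.ndarray, hcharge: float, others: list[Atom], parent: Atom) -> float:
    """Orientation score for one hydrogen: electrostatics + H-bond well.

    Lower is better.  The electrostatic term is a bare Coulomb sum (in
    arbitrary but fixed units); the H-bond term is a distance-weighted well
    rewarding proximity of the H to any N/O/S acceptor.
    """
    score = 0.0
    for o in others:
        d = float(np.linalg.norm(hpos - o.xyz))
        if d < 1.15 and (o.element != "H" or abs(o.charge) >= 0.05):
            return 1e6  # steric clash; zero-charge ghost protons are transparent
        score += hcharge * o.charge / d
        if o.element in ("N", "O", "S") and o.charge < -0.05:
            score -= 0.25 / (1.0 + (d / 2.0) ** 6)
    return score


def place_polar_hydrogens(
    s: Structure,
    mode: str = "optimize",
    skip: Iterable[tuple[tuple[str, int, str], str]] = (),
) -> Structure:
    """Add polar hydrogens at ideal geometry; orient rotatable ones.

    ``mode='ideal'`` places every hydrogen at its template dihedral.
    ``mode='optimize'`` additionally scans rotatable torsions (Ser/Thr/Tyr/Cys
    hydroxyls and sulfhydryls, Lys ammonium, water) on a 15-degree grid and
    keeps the orientation with the best electrostatic + H-bond score; this
    requires partial charges to already be assigned.  ``skip`` lists
    (residue-key, hydrogen-name) pairs that must not be built, e.g. the
    hydroxyl proton of a deprotonated phenolate.

    Heavy-atom coordinates are never modified.  Hydrogens already present in
    the input are kept as-is.
    """
    if mode not in ("ideal", "optimize"):
        raise ValueError(f"unknown placement mode {mode!r}")
    topo = _load_h_topology()
    out = s.copy()
    skipset = set((tuple(k), h) for k, h in skip)
    residues = out.residues()

    def res_atom(atoms: list[Atom], name: str) -> Atom | None:
        for a in atoms:
            if a.name == name:
                return a
        return None

    # --- build missing hydrogens at template geometry -----------------------
    new_atoms: list[Atom] = []
    for key, atoms in residues.items():
        resname = atoms[0].resname
        if resname in WATER_RESNAMES:
            new_atoms.extend(_build_water_hydrogens(atoms, key, skipset))
            continue
        for (rn, hname), row in topo.items():
            if rn != resname or (key, hname) in skipset:
                continue
            if res_atom(atoms, hname) is not None:
                continue  # already present
            parent, r1, r2, bond, angle, dihedral, rotor = row
            pa, a1, a2 = res_atom(atoms, parent), res_atom(atoms, r1), res_atom(atoms, r2)
            if pa is None:
                continue
            if a1 is None or a2 is None:
                raise ValueError(
                    f"incomplete heavy-atom frame for hydrogen {hname} of {resname} {key}"
                )
            new_atoms.append(
                Atom(
                    serial=0,
                    name=hname,
                    element="H",
                    resname=resname,
                    chain=key[0],
                    resseq=key[1],
                    icode=key[2],
                    xyz=place_internal(a2.xyz, a1.xyz, pa.xyz, bond, angle, dihedral),
                    hetatm=atoms[0].hetatm,
                )
            )

    # splice hydrogens in residue order, after their residue's heavy atoms
    for h in new_atoms:
        idx = max(i for i, a in enumerate(out.atoms) if a.reskey == h.reskey)
        out.atoms.insert(idx + 1, h)

    if mode == "ideal":
        return out

    # --- orient every rotatable group deterministically (15-degree grid) ----
    rotors: dict[tuple, list[Atom]] = {}  # (reskey, parent name) -> hydrogens
    for key, atoms in out.residues().items():
        resname = atoms[0].resname
        if resname in WATER_RESNAMES:
            hs = [a for a in atoms if a.element == "H" and (key, a.name) not in skipset]
            if hs:
                rotors[(key, "O")] = hs
            continue
        for (rn, hname), row in topo.items():
            if rn != resname or row[6] == "-":
                continue
            h = res_atom(atoms, hname)
            if h is not None:
                rotors.setdefault((key, row[0]), []).append(h)

    for (key, parent_name), hs in sorted(rotors.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        atoms = out.residues()[key]
        pa = res_atom(atoms, parent_name)
        # competitors: everything nearby except atoms covalently tied to the
        # rotor (the parent and its bonded frame) and the rotor H's themselves
        others = [
            a
            for a in out.atoms
            if a is not pa
            and a not in hs
            and np.linalg.norm(a.xyz - pa.xyz) < 8.0
            and (a.reskey != key or np.linalg.norm(a.xyz - pa.xyz) > 2.2)
        ]
        if pa.resname in WATER_RESNAMES:
            _orient_water(pa, hs, others)
            continue
        hs = sorted(hs, key=lambda h: h.name)
        _, r1, r2, bond, angle, _, _ = topo[(pa.resname, hs[0].name)]
        a1, a2 = res_atom(atoms, r1), res_atom(atoms, r2)
        offsets = [topo[(pa.resname, h.name)][5] for h in hs]
        best, best_positions = None, None
        hq = [h.charge if h.charge != 0.0 else 0.4 for h in hs]
        for step in range(int(round(360.0 / DIHEDRAL_STEP))):
            dih0 = step * DIHEDRAL_STEP
            positions = [
                place_internal(a2.xyz, a1.xyz, pa.xyz, bond, angle, dih0 + off)
                for off in offsets
            ]
            sc = sum(_hbond_score(p, q, others, pa) for p, q in zip(positions, hq))
            if best is None or sc < best - 1e-12:
                best, best_positions = sc, positions
        for h, p in zip(hs, best_positions):
            h.xyz = p
    return out


def _build_water_hydrogens(atoms: list[Atom], key, skipset) -> list[Atom]:
    o = next((a for a in atoms if a.element == "O"), None)
    if o is None:
        raise ValueError(f"water {key} lacks an oxygen atom")
    have = {a.name for a in atoms}
    hs = []
    for hname, direction in (("H1", np.array([1.0, 0.0, 0.0])), ("H2", None)):
        if hname in have or (key, hname) in skipset:
            continue
        if direction is None:
            ang = math.radians(WATER_HOH_ANGLE)
            direction = np.array([math.cos(ang), math.sin(ang), 0.0])
        hs.append(
            Atom(
                serial=0,
                name=hname,
                element="H",
                resname=o.resname,
                chain=key[0],
                resseq=key[1],
                icode=key[2],
                xyz=o.xyz + IDEAL_OH * direction,
                hetatm=True,
            )
        )
    return hs


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0))
    y = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - y * y)
    return np.stack([np.cos(phi * i) * r, y, np.sin(phi * i) * r], axis=1)


def _orient_water(o: Atom, hs: list[Atom], others: list[Atom]) -> None:
    """Deterministic water orientation: H1 over a fixed direction grid, H2 on
    a dihedral grid at the ideal H-O-H angle; joint best score wins."""
    if not hs:
        return
    hq = [h.charge if h.charge != 0.0 else 0.417 for h in hs]
    dirs = _fibonacci_sphere(64)
    best, best_pos = None, None
    for d in dirs:
        p1 = o.xyz + IDEAL_OH * d
        if len(hs) == 1:
            sc = _hbond_score(p1, hq[0], others, o)
            if best is None or sc < best - 1e-12:
                best, best_pos = sc, [p1]
            continue
        sc1 = _hbond_score(p1, hq[0], others, o)
        aref = p1 + np.array([0.013, 1.0, 0.027])  # fixed off-axis frame helper
        for step in range(int(round(360.0 / DIHEDRAL_STEP))):
            p2 = place_internal(aref, p1, o.xyz, IDEAL_OH, WATER_HOH_ANGLE, step * DIHEDRAL_STEP)
            sc = sc1 + _hbond_score(p2, hq[1], others, o)
            if best is None or sc < best - 1e-12:
                best, best_pos = sc, [p1, p2]
    for h, p in zip(hs, best_pos):
        h.xyz = p
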