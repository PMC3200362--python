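"""Partial charges and radii for every protonation/redox form of a group.

Charge conventions for titration follow the smeared-proton bookkeeping that is
standard in continuum-electrostatics pKa work: protonating a carboxylate adds
+0.5 e to each of its two oxygens; deprotonating an ammonium or guanidinium
spreads the loss of one unit charge evenly over its protons; the photo-oxidized
special-pair hole is a +1 charge split over the two macrocycles at a fixed
ratio.  The shipped charge set is a compact CHARMM22-informed polar-hydrogen
set; radii are PARSE-style, element-keyed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

from .structure import Structure

CHARGE_SET_VERSION = "compact-1.0"

#: residues whose backbone atoms take the generic amino-acid backbone charges
AMINO_RESNAMES = {
    "GLY", "ALA", "SER", "THR", "ASN", "ASP", "GLU",
    "LYS", "ARG", "CYS", "TYR", "HIS",
}

__all__ = [
    "ChargeState",
    "SiteDef",
    "ChargeLibrary",
    "load_default_library",
    "protonate_acidic",
    "deprotonate_basic",
    "special_pair_cation",
    "assign_state_charges",
    "site_id_string",
]


@dataclass
class ChargeState:
    """Named per-atom partial charges of one protonation/redox form."""

    state_id: str
    atom_charges: dict[str, float]

    @property
    def net_charge(self) -> float:
        return sum(self.atom_charges.values())

    def copy(self) -> "ChargeState":
        return ChargeState(self.state_id, dict(self.atom_charges))


@dataclass(frozen=True)
class SiteDef:
    """Template of a titratable site type (one per residue type / subsite)."""

    resname: str
    subsite: str  # "" for whole-residue sites, "ND1"/"NE2" for His
    kind: str  # acid | base | redox
    ref_value: float  # reference pKa (pH units) or midpoint (mV) for redox
    prot_state: str
    deprot_state: str
    ref_is: str  # "prot" | "deprot": the neutral reference member
    proton_atoms: tuple[str, ...]  # hydrogens absent in the deprotonated form


@dataclass
class ChargeLibrary:
    states: dict[tuple[str, str], ChargeState]
    radii: dict[str, float]
    sites: dict[str, list[SiteDef]]
    backbone: dict[str, float]
    version: str = CHARGE_SET_VERSION

    def state(self, resname: str, state_id: str) -> ChargeState:
        try:
            return self.states[(resname, state_id)]
        except KeyError:
            raise KeyError(f"no charge state {state_id!r} for residue {resname!r}") from None

    def radius(self, element: str) -> float:
        try:
            return self.radii[element.upper()]
        except KeyError:
            raise KeyError(f"no radius for element {element!r}") from None

    def site_defs(self, resname: str) -> list[SiteDef]:
        return self.sites.get(resname, [])

    def validate(self) -> None:
        for r in self.radii.values():
            if r <= 0:
                raise ValueError("radii must be strictly positive")
        for defs in self.sites.values():
            for sd in defs:
                dq = self.state(sd.resname, sd.prot_state).net_charge - self.state(
                    sd.resname, sd.deprot_state
                ).net_charge
                expect = -1.0 if sd.kind == "redox" else 1.0  # electron vs proton binding
                if abs(dq - expect) > 1e-9:
                    raise ValueError(
                        f"{sd.resname}/{sd.subsite or '-'}: bound minus unbound "
                        f"net charge is {dq}, expected exactly {expect}"
                    )


def _read_tsv(name: str):
    text = resources.files("protpka.data").joinpath(name).read_text()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            yield line.split("\t")


@lru_cache(maxsize=1)
def load_default_library() -> ChargeLibrary:
    states: dict[tuple[str, str], ChargeState] = {}
    backbone: dict[str, float] = {}
    for resname, state, atom, charge in _read_tsv("charges.tsv"):
        q = float(charge)
        if resname == "*":
            backbone[atom] = q
            continue
        key = (resname, state)
        if key not in states:
            states[key] = ChargeState(state, {})
        states[key].atom_charges[atom] = q
    radii = {el.upper(): float(r) for el, r in _read_tsv("radii.tsv")}
    sites: dict[str, list[SiteDef]] = {}
    for resname, subsite, kind, ref, prot, deprot, ref_is, protons in _read_tsv("sites.tsv"):
        sd = SiteDef(
            resname=resname,
            subsite="" if subsite == "-" else subsite,
            kind=kind,
            ref_value=float(ref),
            prot_state=prot,
            deprot_state=deprot,
            ref_is=ref_is,
            proton_atoms=() if protons == "-" else tuple(protons.split(",")),
        )
        sites.setdefault(resname, []).append(sd)
    lib = ChargeLibrary(states=states, radii=radii, sites=sites, backbone=backbone)
    lib.validate()
    return lib


# ---------------------------------------------------------------------------
# Charge-convention operations
# ---------------------------------------------------------------------------


def protonate_acidic(base: ChargeState) -> ChargeState:
    """Protonate a carboxylate by adding +0.5 e to each of its two oxygens.

    The proton is represented implicitly; only the two carboxylate oxygen
    charges change, and the net charge rises by exactly 1.
    """
    oxygens = [n for n in base.atom_charges if n.upper().startswith("O")]
    if len(oxygens) != 2:
        raise ValueError(
            f"state {base.state_id!r}: expected exactly two carboxylate oxygens, "
            f"found {oxygens}"
        )
    out = base.copy()
    out.state_id = base.state_id + "+H"
    for n in oxygens:
        out.atom_charges[n] += 0.5
    return out


def deprotonate_basic(base: ChargeState, proton_names: Sequence[str] | None = None) -> ChargeState:
    """Deprotonate an ammonium/guanidinium by smearing -1 e over its protons.

    Each titratable proton loses 1/n of a unit charge; heavy-atom charges are
    untouched and the protons stay in place as partial charges.
    """
    if proton_names is None:
        proton_names = [n for n in base.atom_charges if n.upper().startswith("H")]
    protons = list(proton_names)
    if not protons:
        raise ValueError(f"state {base.state_id!r}: no titratable protons identified")
    missing = [p for p in protons if p not in base.atom_charges]
    if missing:
        raise ValueError(f"state {base.state_id!r}: protons {missing} not in state")
    out = base.copy()
    out.state_id = base.state_id + "-H"
    for n in protons:
        out.atom_charges[n] -= 1.0 / len(protons)
    return out


def special_pair_cation(
    pa: ChargeState,
    pb: ChargeState,
    ratio: tuple[float, float] = (2.0, 1.0),
    atom_weights: tuple[Mapping[str, float] | None, Mapping[str, float] | None] = (None, None),
) -> tuple[ChargeState, ChargeState]:
    """Distribute the +1 hole of the photo-oxidized pair over two macrocycles.

    ``ratio`` sets the inter-ring split (the ENDOR-derived default is 2:1 on
    ring A vs ring B); within each ring the charge is spread uniformly over its
    atoms unless explicit per-atom weights are given.
    """
    wa, wb = float(ratio[0]), float(ratio[1])
    if wa < 0 or wb < 0 or wa + wb <= 0:
        raise ValueError(f"ratio weights must be non-negative with a positive sum, got {ratio}")
    out = []
    for state, w, weights in ((pa, wa, atom_weights[0]), (pb, wb, atom_weights[1])):
        add = w / (wa + wb)
        new = state.copy()
        new.state_id = state.state_id + "_cation"
        if weights is None:
            weights = {n: 1.0 for n in state.atom_charges}
        total_w = sum(weights.values())
        for n, aw in weights.items():
            new.atom_charges[n] += add * aw / total_w
        out.append(new)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Whole-structure assignment
# ---------------------------------------------------------------------------


def site_id_string(reskey: tuple[str, int, str], subsite: str = "") -> str:
    chain, resseq, icode = reskey
    base = f"{chain}:{resseq}{icode}"
    return f"{base}:{subsite}" if subsite else base


def default_state(sd: SiteDef) -> str:
    """Standard-state initialization at pH 7: each site in the form its
    reference pKa favors (Asp/Glu deprotonated, Lys/Arg protonated, Tyr/Cys
    neutral); redox groups and His subsites in their declared reference
    member (hemes reduced, neutral His tautomer)."""
    if sd.subsite or sd.kind == "redox":
        return sd.prot_state if sd.ref_is == "prot" else sd.deprot_state
    return sd.prot_state if sd.ref_value > 7.0 else sd.deprot_state


def reference_state(sd: SiteDef) -> str:
    """The neutral reference member used for intrinsic-pKa backgrounds."""
    return sd.prot_state if sd.ref_is == "prot" else sd.deprot_state


def assign_state_charges(
    s: Structure,
    lib: ChargeLibrary | None = None,
    assignment: Mapping[str, str | ChargeState] | None = None,
    waivers: Sequence[str] = (),
    use_reference_states: bool = False,
) -> Structure:
    """Assign a charge and radius to every atom of the structure.

    ``assignment`` maps site-id strings (``"L:162"`` for whole-residue sites,
    ``"L:168:ND1"`` for subsites) to a state id from the library, or to an
    explicit :class:`ChargeState` (e.g. a runtime-built special-pair cation
    state).  Unassigned titratable sites get their standard state (or neutral
    reference states when ``use_reference_states`` is true).  Residue types
    with neither a library entry nor a ``waivers`` membership are an error.
    """
    lib = lib or load_default_library()
    assignment = dict(assignment or {})
    waiverset = set(waivers)
    out = s.copy()
    for reskey, atoms in out.residues().items():
        resname = atoms[0].resname
        charge_map: dict[str, float] = {}
        wildcard: float | None = None
        # residue background state
        bg = lib.states.get((resname, "bg"))
        if bg is not None:
            for n, q in bg.atom_charges.items():
                if n == "*":
                    wildcard = q
                else:
                    charge_map[n] = q
        # site states (assigned, else default)
        for sd in lib.site_defs(resname):
            sid = site_id_string(reskey, sd.subsite)
            chosen = assignment.pop(sid, None)
            if chosen is None:
                chosen = reference_state(sd) if use_reference_states else default_state(sd)
            state = chosen if isinstance(chosen, ChargeState) else lib.state(resname, chosen)
            charge_map.update(state.atom_charges)
        # whole-residue assignment for fixed-state groups (cofactors)
        sid = site_id_string(reskey)
        if sid in assignment:
            chosen = assignment.pop(sid)
            state = chosen if isinstance(chosen, ChargeState) else lib.state(resname, chosen)
            for n, q in state.atom_charges.items():
                if n == "*":
                    wildcard = q
                else:
                    charge_map[n] = q
        elif bg is None and not lib.site_defs(resname):
            # residue type with a single non-bg library state (e.g. CFA neutral)
            single = [st for (rn, sid_), st in lib.states.items() if rn == resname]
            if len(single) == 1:
                for n, q in single[0].atom_charges.items():
                    if n == "*":
                        wildcard = q
                    else:
                        charge_map[n] = q
        backbone = lib.backbone if resname in AMINO_RESNAMES else {}
        for a in atoms:
            if a.name in charge_map:
                a.charge = charge_map[a.name]
            elif a.name in backbone:
                a.charge = backbone[a.name]
            elif wildcard is not None:
                a.charge = wildcard
            elif resname in waiverset:
                a.charge = 0.0
            else:
                raise KeyError(
                    f"no charge entry for atom {a.name} of residue {resname} "
                    f"{site_id_string(reskey)} and no waiver"
                )
            a.radius = lib.radius(a.element)
    if assignment:
        raise KeyError(f"assignment refers to unknown site id(s): {sorted(assignment)}")
    return out
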