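"""Per-residue decomposition of pKa shifts and H-bond network analysis.

Within the linear-response continuum model the shift of a target site's pKa
decomposes exactly over the background charges: every group contributes
``-(1/ln10) sum_a qbar_a phi_dq(r_a)`` pK units, where ``phi_dq`` is the
potential of the target's binding charge difference in the protein and
``qbar_a`` are the group's equilibrium-averaged charges (fractional
protonation allowed).  Positive contributions stabilize the protonated target,
i.e. raise its pKa; that sign convention is stated in every output header.
Residue rows are split into side-chain and backbone parts (backbone = N, H,
CA, HA, C, O); cofactors and waters are reported as a total only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .charges import site_id_string
from .structure import Structure
from .titration import TitrationSystem

LN10 = math.log(10.0)
BACKBONE_ATOMS = {"N", "H", "CA", "HA", "C", "O"}

SIGN_CONVENTION = (
    "positive contribution = stabilizes the protonated target (raises its pKa)"
)

__all__ = [
    "ContributionRow",
    "ContributionTable",
    "equilibrium_charges",
    "residue_contribution",
    "contribution_table",
    "pka_from_components",
    "hbond_network",
    "compare_states",
    "StateComparison",
]


@dataclass
class ContributionRow:
    residue_id: str
    resname: str
    side_chain: float | None  # None for groups without a backbone partition
    backbone: float | None
    total: float


@dataclass
class ContributionTable:
    target: str
    state_label: str
    rows: list[ContributionRow]
    sign_convention: str = SIGN_CONVENTION

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "residue": r.residue_id,
                    "resname": r.resname,
                    "side_chain": r.side_chain,
                    "backbone": r.backbone,
                    "total": r.total,
                }
                for r in self.rows
            ]
        )

    def row(self, residue_id: str) -> ContributionRow:
        for r in self.rows:
            if r.residue_id == residue_id:
                return r
        raise KeyError(f"no contribution row for {residue_id}")


def equilibrium_charges(
    system: TitrationSystem, means: Mapping[str, float] | None = None
) -> dict[tuple[tuple[str, int, str], str], float]:
    """Per-atom charges with each titratable site at its equilibrium-averaged
    occupancy.  ``means`` maps site id to mean binding; omitted sites stay in
    their neutral reference state (mean charged indicator 0)."""
    means = dict(means or {})
    qbar = {(a.reskey, a.name): a.charge for a in system.structure.atoms}
    for site in system.sites:
        sid = site.site_id
        if sid not in means:
            continue
        x = means[sid]
        t = x if site.charged_sign == +1 else 1.0 - x
        for name, dq in zip(site.atom_names, site.dq_bind):
            qbar[(site.reskey, name)] += t * site.charged_sign * dq
    return qbar


def residue_contribution(
    system: TitrationSystem,
    target: int | str,
    group: tuple[str, int, str],
    means: Mapping[str, float] | None = None,
) -> ContributionRow:
    """Contribution of one residue/cofactor group to the target's pKa, split
    into side-chain and backbone parts (equilibrium-averaged charges).

    The group's atoms are evaluated in the potential of the target's binding
    charge difference; the target's own titrating atoms are always excluded.
    """
    if isinstance(target, str):
        target = [s.site_id for s in system.sites].index(target)
    tsite = system.sites[target]
    phi = system.site_potential(target)
    qbar = equilibrium_charges(system, means)
    atoms = [a for a in system.structure.atoms if a.reskey == group]
    if not atoms:
        raise KeyError(f"no atoms for group {group}")
    resname = atoms[0].resname
    target_atoms = {(tsite.reskey, n) for n in tsite.atom_names}
    positions, charges, is_back = [], [], []
    for a in atoms:
        if (a.reskey, a.name) in target_atoms:
            continue
        q = qbar[(a.reskey, a.name)]
        if q == 0.0:
            continue
        positions.append(a.xyz)
        charges.append(q)
        is_back.append(a.name in BACKBONE_ATOMS)
    if not positions:
        return ContributionRow(site_id_string(group), resname, 0.0, 0.0, 0.0)
    vals = -np.asarray(charges) * phi.evaluate(np.array(positions)) / LN10
    total = float(vals.sum())
    if atoms[0].hetatm:  # cofactor / water: no meaningful backbone partition
        return ContributionRow(site_id_string(group), resname, None, None, total)
    back = float(vals[np.array(is_back)].sum()) if any(is_back) else 0.0
    side = total - back
    return ContributionRow(site_id_string(group), resname, side, back, total)


def contribution_table(
    system: TitrationSystem,
    target: int | str,
    means: Mapping[str, float] | None = None,
    state_label: str = "",
    top_n: int | None = None,
    include_target_residue: bool = False,
) -> ContributionTable:
    """Per-residue contributions to the target's pKa, sorted by |total|.

    Groups whose equilibrium charges are identically zero are omitted.
    """
    if isinstance(target, str):
        target = [s.site_id for s in system.sites].index(target)
    tsite = system.sites[target]
    rows = []
    for group in system.structure.residues():
        if group == tsite.reskey and not include_target_residue:
            continue
        row = residue_contribution(system, target, group, means)
        if row.total == 0.0 and not row.side_chain and not row.backbone:
            continue
        rows.append(row)
    rows.sort(key=lambda r: abs(r.total), reverse=True)
    if top_n is not None:
        rows = rows[:top_n]
    return ContributionTable(target=tsite.site_id, state_label=state_label, rows=rows)


def pka_from_components(
    system: TitrationSystem,
    target: int | str,
    means: Mapping[str, float] | None = None,
) -> float:
    """Target pKa reconstructed as reference + desolvation/model term + the sum
    of all group contributions, with the protonation pattern frozen at
    ``means``.  In the linear-response model this is exact, so it must agree
    with a direct bias titration against the same frozen pattern."""
    if isinstance(target, str):
        target = [s.site_id for s in system.sites].index(target)
    site = system.sites[target]
    phi_p = system.site_potential(target)
    phi_m = system.model_potential(target)
    phis_p = phi_p.evaluate(site.positions)
    phis_m = phi_m.evaluate(site.positions)
    self_p = 0.5 * float(np.dot(site.dq_bind, phis_p)) - float(np.dot(site.q_bound, phis_p))
    self_m = 0.5 * float(np.dot(site.dq_bind, phis_m)) - float(np.dot(site.q_bound, phis_m))
    # model-compound background (the residue's own non-titrating atoms)
    site_atoms = {(site.reskey, n) for n in site.atom_names}
    bg = [
        (a.xyz, a.charge)
        for a in system.structure.atoms
        if a.reskey == site.reskey and (a.reskey, a.name) not in site_atoms and a.charge != 0.0
    ]
    if bg:
        pos = np.array([p for p, _ in bg])
        q = np.array([c for _, c in bg])
        self_m -= float(np.dot(q, phi_m.evaluate(pos)))
    pka = site.pk_ref + (self_p - self_m) / LN10
    table = contribution_table(system, target, means, include_target_residue=True)
    return pka + sum(r.total for r in table.rows)


# ---------------------------------------------------------------------------
# H-bond network
# ---------------------------------------------------------------------------


def hbond_network(
    s: Structure,
    dmax: float = 2.5,
    angle_min: float = 120.0,
    min_h_charge: float = 0.05,
) -> nx.DiGraph:
    """Directed donor-to-acceptor H-bond graph.

    An edge runs from a donor heavy atom to an acceptor N/O/S when the
    hydrogen-acceptor distance is at most ``dmax`` and the donor-H-acceptor
    angle at least ``angle_min`` degrees.  Hydrogens carrying less than
    ``min_h_charge`` are not donors: in the smeared-proton charge convention a
    vanished proton keeps its position but loses its charge.  Edges carry the
    H..A and heavy-heavy distances and the angle, the latter for direct
    comparison with crystallographic O..O / O..N separations.
    """
    hydrogens = [a for a in s.atoms if a.element == "H"]
    if not hydrogens:
        raise ValueError(
            "structure contains no hydrogens; run place_polar_hydrogens first"
        )
    heavies = [a for a in s.atoms if a.element != "H"]
    acceptors = [a for a in heavies if a.element in ("N", "O", "S")]
    g = nx.DiGraph()

    def label(a):
        return f"{a.chain}:{a.resseq}{a.icode}:{a.name}"

    for h in hydrogens:
        if abs(h.charge) < min_h_charge:
            continue
        # covalent parent: nearest heavy within 1.6 A
        cand = [(float(np.linalg.norm(h.xyz - a.xyz)), a) for a in heavies]
        d0, parent = min(cand, key=lambda t: t[0])
        if d0 > 1.6 or parent.element not in ("N", "O", "S"):
            continue
        for acc in acceptors:
            if acc is parent:
                continue
            if float(np.linalg.norm(acc.xyz - parent.xyz)) < 1.8:
                continue  # covalently bonded to the donor heavy
            d_ha = float(np.linalg.norm(acc.xyz - h.xyz))
            if d_ha > dmax:
                continue
            v1 = parent.xyz - h.xyz
            v2 = acc.xyz - h.xyz
            cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if angle < angle_min:
                continue
            g.add_edge(
                label(parent),
                label(acc),
                hydrogen=label(h),
                d_ha=round(d_ha, 3),
                d_heavy=round(float(np.linalg.norm(acc.xyz - parent.xyz)), 3),
                angle=round(angle, 1),
            )
    return g


# ---------------------------------------------------------------------------
# State comparison
# ---------------------------------------------------------------------------


@dataclass
class StateComparison:
    reference_state: str
    pka: pd.DataFrame  # sites x states
    dpka: pd.DataFrame  # sites x states, relative to the reference state
    contribution_changes: pd.DataFrame  # residues exceeding the threshold
    edges_gained: dict[str, list[tuple[str, str]]]
    edges_lost: dict[str, list[tuple[str, str]]]


def compare_states(
    results: Mapping[str, Mapping[str, float]],
    tables: Mapping[str, ContributionTable] | None = None,
    networks: Mapping[str, nx.DiGraph] | None = None,
    threshold: float = 0.5,
) -> StateComparison:
    """Cross-state report: per-site pKa differences, residues whose
    contribution moved by more than ``threshold`` pK, H-bond edges gained and
    lost relative to the first state."""
    labels = list(results)
    if len(labels) < 2:
        raise ValueError("need at least two computed states to compare")
    ref = labels[0]
    common = set(results[ref])
    for lab in labels[1:]:
        common &= set(results[lab])
    if not common:
        raise ValueError("state results share no common sites")
    sites = sorted(common)
    pka = pd.DataFrame({lab: [results[lab][s] for s in sites] for lab in labels}, index=sites)
    dpka = pka.sub(pka[ref], axis=0)

    changes = pd.DataFrame()
    if tables:
        per_res: dict[str, dict[str, float]] = {}
        for lab, tab in tables.items():
            for r in tab.rows:
                per_res.setdefault(r.residue_id, {})[lab] = r.total
        rows = []
        for rid, vals in per_res.items():
            base = vals.get(ref, 0.0)
            delta = max(abs(vals.get(lab, 0.0) - base) for lab in tables)
            if delta >= threshold:
                rows.append({"residue": rid, **{lab: vals.get(lab, 0.0) for lab in tables}})
        changes = pd.DataFrame(rows)

    gained: dict[str, list] = {}
    lost: dict[str, list] = {}
    if networks:
        ref_edges = set(networks[ref].edges())
        for lab, g in networks.items():
            if lab == ref:
                continue
            e = set(g.edges())
            gained[lab] = sorted(e - ref_edges)
            lost[lab] = sorted(ref_edges - e)
    return StateComparison(
        reference_state=ref,
        pka=pka,
        dpka=dpka,
        contribution_changes=changes,
        edges_gained=gained,
        edges_lost=lost,
    )
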