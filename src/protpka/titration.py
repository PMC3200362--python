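"""Protonation/redox equilibria of coupled titratable sites.

The statistical-mechanical model is the standard one for continuum
electrostatics pKa calculations.  Each site i carries a binding indicator
x_i (1 = proton bound; for redox groups 1 = electron bound, i.e. reduced) and
an intrinsic pK (the value the site would have with every other site in its
neutral reference state).  A microstate x has energy, in units of kT,

    E(x)/kT = ln10 [ sum_i x_i (driv_i - pK_intr,i - bias_i)
                     + 1/2 sum_{i != j} W_ij t_i t_j ]  + exclusion penalties

where driv_i is pH for proton sites and E_h expressed in pK units for redox
sites, t_i indicates whether site i is in its charged (non-reference) form,
and W_ij is the pairwise electrostatic coupling in pK units (positive for two
sites whose charged forms repel).  His is modelled as two coupled subsites
(N-delta, N-epsilon) whose measured reference pK values already encode the
intramolecular tautomer energetics, so intra-residue couplings are excluded
from W and the doubly-deprotonated imidazolate is suppressed by a +30 pK
penalty.

Ensembles are sampled either exactly (full enumeration, the oracle) or by
Metropolis Monte Carlo with single-site and strongly-coupled pair moves.  A
pKa is located by bias titration: a root search on a per-site bias potential
until both forms are equally populated; the reported pKa is pH - bias (a
positive bias favors the bound form, so a site with pKa above the working pH
needs a negative bias to reach half-titration).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .charges import ChargeLibrary, SiteDef, load_default_library, site_id_string
from .solver import (
    DEFAULT_LEVELS,
    DEFAULT_NPOINTS_CAP,
    DielectricEnvironment,
    FocusedPotential,
    FINE_MARGIN,
    focus_solve,
    pk_to_mv,
)
from .structure import Structure

LN10 = math.log(10.0)
HIS_EXCLUSION_PENALTY = 30.0  # pK units; suppresses the imidazolate microstate
STRONG_COUPLING = 2.0  # pK units; threshold for MC pair moves

__all__ = [
    "TitratableSite",
    "InteractionMatrix",
    "MicrostateModel",
    "TitrationResult",
    "TitrationSystem",
    "discover_sites",
    "microstate_energy",
    "exact_populations",
    "mc_sample",
    "titrate_pka",
    "titration_curve",
    "redox_midpoint",
]


@dataclass
class TitratableSite:
    """One titratable group instance in a structure."""

    reskey: tuple[str, int, str]
    definition: SiteDef
    atom_names: tuple[str, ...]
    positions: np.ndarray  # (m, 3)
    dq_bind: np.ndarray  # per-atom bound-minus-unbound charges (net +1 / -1 redox)
    q_bound: np.ndarray  # per-atom charges of the bound (protonated/reduced) form
    charged_sign: int  # +1 if the charged form is the bound form, else -1
    pk_ref: float  # reference value in pK units (redox midpoints converted)
    pka_intr: float | None = None

    @property
    def site_id(self) -> str:
        return site_id_string(self.reskey, self.definition.subsite)

    @property
    def kind(self) -> str:
        return self.definition.kind


@dataclass
class InteractionMatrix:
    site_ids: list[str]
    W: np.ndarray  # symmetric, pK units, zero diagonal
    max_asymmetry: float = 0.0


@dataclass
class TitrationResult:
    site_id: str
    pka: float  # pH units (or mV for redox, see redox_midpoint)
    protonation_curve: dict[float, float]  # bias -> mean binding
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Site discovery
# ---------------------------------------------------------------------------


def discover_sites(
    s: Structure,
    lib: ChargeLibrary | None = None,
    temperature: float = 300.0,
    include: Sequence[str] | None = None,
    exclude: Sequence[str] = (),
) -> list[TitratableSite]:
    """Instantiate titratable sites from the residues present in a structure.

    ``include``/``exclude`` filter by site-id string.  Site atoms must all be
    present (hydrogens placed) or the residue is an error.
    """
    lib = lib or load_default_library()
    nu = pk_to_mv(temperature)
    sites: list[TitratableSite] = []
    for reskey, atoms in s.residues().items():
        resname = atoms[0].resname
        for sd in lib.site_defs(resname):
            sid = site_id_string(reskey, sd.subsite)
            if include is not None and sid not in include:
                continue
            if sid in exclude:
                continue
            qp = lib.state(resname, sd.prot_state).atom_charges
            qd = lib.state(resname, sd.deprot_state).atom_charges
            names = tuple(sorted(set(qp) | set(qd)))
            by_name = {a.name: a for a in atoms}
            missing = [n for n in names if n not in by_name]
            if missing:
                raise ValueError(
                    f"site {sid} ({resname}): atoms {missing} absent from structure "
                    "(place polar hydrogens first)"
                )
            pos = np.array([by_name[n].xyz for n in names])
            dq = np.array([qp.get(n, 0.0) - qd.get(n, 0.0) for n in names])
            qb = np.array([qp.get(n, 0.0) for n in names])
            charged_sign = +1 if sd.ref_is == "deprot" else -1
            pk_ref = sd.ref_value / nu if sd.kind == "redox" else sd.ref_value
            sites.append(
                TitratableSite(
                    reskey=reskey,
                    definition=sd,
                    atom_names=names,
                    positions=pos,
                    dq_bind=dq,
                    q_bound=qb,
                    charged_sign=charged_sign,
                    pk_ref=pk_ref,
                )
            )
    return sites


def _his_pairs(sites: Sequence[TitratableSite]) -> list[tuple[int, int]]:
    by_res: dict[tuple, dict[str, int]] = {}
    for i, st in enumerate(sites):
        if st.definition.resname == "HIS" and st.definition.subsite:
            by_res.setdefault(st.reskey, {})[st.definition.subsite] = i
    return [
        (d["ND1"], d["NE2"]) for d in by_res.values() if "ND1" in d and "NE2" in d
    ]


# ---------------------------------------------------------------------------
# Microstate model
# ---------------------------------------------------------------------------


@dataclass
class MicrostateModel:
    """Intrinsic pKs + couplings, ready for sampling.

    ``driv`` holds the per-site thermodynamic driving variable (pH, or E_h in
    pK units for redox sites); ``charged_is_bound`` maps binding indicators to
    charged-form indicators; ``excluded_pairs`` lists (i, j) whose joint
    unbound state is penalized (His subsites).
    """

    site_ids: list[str]
    pk_intr: np.ndarray
    W: np.ndarray
    driv: np.ndarray
    charged_is_bound: np.ndarray  # bool per site
    excluded_pairs: list[tuple[int, int]] = field(default_factory=list)
    penalty: float = HIS_EXCLUSION_PENALTY
    temperature: float = 300.0
    is_redox: np.ndarray | None = None  # per-site; None = all proton sites

    @property
    def n(self) -> int:
        return len(self.site_ids)

    def charged_indicator(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        return np.where(self.charged_is_bound, x, 1 - x)

    def index(self, site_id: str) -> int:
        return self.site_ids.index(site_id)


def microstate_energy(model: MicrostateModel, x: np.ndarray, bias: np.ndarray | None = None) -> float:
    """Energy of one microstate in kT (total function of x)."""
    x = np.asarray(x, dtype=float)
    b = np.zeros(model.n) if bias is None else np.asarray(bias, dtype=float)
    t = model.charged_indicator(x)
    e = float(np.dot(x, model.driv - model.pk_intr - b))
    e += 0.5 * float(t @ model.W @ t)
    for i, j in model.excluded_pairs:
        e += model.penalty * (1 - x[i]) * (1 - x[j])
    return LN10 * e


def exact_populations(
    model: MicrostateModel,
    bias: np.ndarray | None = None,
    clamp: Mapping[int, int] | None = None,
    max_sites: int = 20,
) -> np.ndarray:
    """Boltzmann-exact mean binding per site by full enumeration (the oracle).

    ``clamp`` pins chosen sites to fixed indicators; only the rest are
    enumerated.  Limited to 2^``max_sites`` microstates.
    """
    n = model.n
    clamp = dict(clamp or {})
    free = [i for i in range(n) if i not in clamp]
    if len(free) > max_sites:
        raise ValueError(f"{len(free)} free sites exceed the enumeration limit of {max_sites}")
    b = np.zeros(n) if bias is None else np.asarray(bias, dtype=float)
    m = len(free)
    states = ((np.arange(2**m)[:, None] >> np.arange(m)[None, :]) & 1).astype(float)
    X = np.zeros((2**m, n))
    X[:, free] = states
    for i, v in clamp.items():
        X[:, i] = v
    T = np.where(model.charged_is_bound[None, :], X, 1 - X)
    h = model.driv - model.pk_intr - b
    E = X @ h + 0.5 * np.einsum("si,ij,sj->s", T, model.W, T)
    for i, j in model.excluded_pairs:
        E = E + model.penalty * (1 - X[:, i]) * (1 - X[:, j])
    E = LN10 * E
    w = np.exp(-(E - E.min()))
    w /= w.sum()
    return w @ X


def mc_sample(
    model: MicrostateModel,
    bias: np.ndarray | None = None,
    n_sweeps: int = 10000,
    seed: int | np.random.SeedSequence = 0,
    burn_in: int = 100,
    clamp: Mapping[int, int] | None = None,
) -> tuple[np.ndarray, dict]:
    """Metropolis sampling of binding microstates.

    One sweep attempts a flip of every free site plus a joint flip of every
    strongly coupled pair (|W| > 2 pK) and every His subsite pair.  Returns the
    per-site mean binding over the post-burn-in sweeps and diagnostics
    (acceptance rate, schedule, seed).  Fixed seed gives bit-identical means.
    """
    n = model.n
    clamp = dict(clamp or {})
    b = np.zeros(n) if bias is None else np.asarray(bias, dtype=float)
    rng = np.random.default_rng(seed)
    x = np.ones(n)  # start fully bound; burn-in relaxes
    for i, v in clamp.items():
        x[i] = v
    free = [i for i in range(n) if i not in clamp]
    pairs = [
        (i, j)
        for i in free
        for j in free
        if i < j and abs(model.W[i, j]) > STRONG_COUPLING
    ]
    for i, j in model.excluded_pairs:
        if i in free and j in free and (i, j) not in pairs:
            pairs.append((i, j))
    h = model.driv - model.pk_intr - b
    sgn = np.where(model.charged_is_bound, 1.0, -1.0)
    excl = model.excluded_pairs
    pen = model.penalty

    def delta_e(i: int) -> float:
        dx = 1.0 - 2.0 * x[i]
        t = np.where(model.charged_is_bound, x, 1 - x)
        dt = sgn[i] * dx
        de = dx * h[i] + dt * float(model.W[i] @ t)
        for a, c in excl:
            if a == i:
                de += pen * (-dx) * (1 - x[c])
            elif c == i:
                de += pen * (1 - x[a]) * (-dx)
        return LN10 * de

    accepted = attempts = 0
    means = np.zeros(n)
    kept = 0
    for sweep in range(n_sweeps + burn_in):
        u = rng.random(len(free) + 2 * len(pairs))
        ui = 0
        for i in free:
            de = delta_e(i)
            attempts += 1
            if de <= 0 or u[ui] < math.exp(-de):
                x[i] = 1 - x[i]
                accepted += 1
            ui += 1
        for i, j in pairs:
            de = delta_e(i)
            x[i] = 1 - x[i]
            de += delta_e(j)
            x[i] = 1 - x[i]  # restore; de now holds the joint move energy
            attempts += 1
            if de <= 0 or u[ui] < math.exp(-de):
                x[i] = 1 - x[i]
                x[j] = 1 - x[j]
                accepted += 1
            ui += 1
        if sweep >= burn_in:
            means += x
            kept += 1
    means /= kept
    diag = {
        "acceptance_rate": accepted / max(attempts, 1),
        "n_sweeps": n_sweeps,
        "burn_in": burn_in,
        "seed": seed if isinstance(seed, int) else "derived",
    }
    if diag["acceptance_rate"] == 0.0:
        warnings.warn("Monte Carlo acceptance rate was zero over the run")
    return means, diag


def _mean_binding(
    model: MicrostateModel,
    target: int,
    bias_target: float,
    engine: str,
    clamp: Mapping[int, int],
    n_sweeps: int,
    seed_seq: np.random.SeedSequence | None,
) -> float:
    bias = np.zeros(model.n)
    bias[target] = bias_target
    if engine == "exact":
        return float(exact_populations(model, bias, clamp=clamp)[target])
    means, _ = mc_sample(
        model, bias, n_sweeps=n_sweeps, seed=seed_seq, clamp=clamp
    )
    return float(means[target])


def titrate_pka(
    model: MicrostateModel,
    target: int | str,
    pH: float | None = None,
    engine: str = "auto",
    clamp: Mapping[int, int] | None = None,
    clamp_his_sibling: bool = True,
    bias_limit: float = 30.0,
    bias_tol: float = 0.01,
    n_sweeps: int = 10000,
    seed: int = 0,
) -> TitrationResult:
    """Bias-potential titration of one site with all others equilibrated.

    A per-site bias is root-found (bisection to ``bias_tol`` pK) until the two
    forms of the target are equally populated; the pKa is pH - bias.  When the
    target is a His subsite its sibling subsite is clamped protonated, so the
    reported value is the microscopic pK of the His+ deprotonation at that
    nitrogen (the convention under which the reference values are measured).
    Every bias evaluation uses a fresh deterministically derived MC seed.
    """
    if isinstance(target, str):
        target = model.index(target)
    clamp = dict(clamp or {})
    if clamp_his_sibling:
        for i, j in model.excluded_pairs:
            if target == i and j not in clamp:
                clamp[j] = 1
            elif target == j and i not in clamp:
                clamp[i] = 1
    n_free = sum(1 for i in range(model.n) if i not in clamp)
    if engine == "auto":
        engine = "exact" if n_free <= 14 else "mc"
    if pH is None:
        pH = float(model.driv[target])
    root_seq = np.random.SeedSequence([seed & 0x7FFFFFFF, target])
    curve: dict[float, float] = {}
    n_eval = 0

    def f(bias: float) -> float:
        nonlocal n_eval
        seq = np.random.SeedSequence([seed & 0x7FFFFFFF, target, n_eval])
        n_eval += 1
        mean = _mean_binding(model, target, bias, engine, clamp, n_sweeps, seq)
        curve[bias] = mean
        return mean - 0.5

    lo, hi = -bias_limit, bias_limit
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise ValueError(
            f"titration root not bracketed within bias +/- {bias_limit} pK "
            f"(mean at -{bias_limit}: {flo + 0.5:.3f}, at +{bias_limit}: {fhi + 0.5:.3f})"
        )
    while hi - lo > bias_tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    bias_root = 0.5 * (lo + hi)
    pka = pH - bias_root
    return TitrationResult(
        site_id=model.site_ids[target],
        pka=pka,
        protonation_curve=dict(sorted(curve.items())),
        diagnostics={
            "engine": engine,
            "bias_root": bias_root,
            "n_evaluations": n_eval,
            "n_sweeps": n_sweeps if engine == "mc" else None,
            "seed": seed,
            "clamped": {model.site_ids[i]: v for i, v in clamp.items()},
        },
    )


def titration_curve(
    model: MicrostateModel,
    target: int | str,
    pH_values: Sequence[float],
    engine: str = "exact",
) -> dict[float, float]:
    """Mean binding of one proton site over a pH grid (Henderson-Hasselbalch
    generalized to the coupled system); redox drivings stay fixed."""
    if isinstance(target, str):
        target = model.index(target)
    out: dict[float, float] = {}
    base = model.driv.copy()
    proton_mask = (
        np.ones(model.n, dtype=bool) if model.is_redox is None else ~model.is_redox
    )
    for ph in pH_values:
        model.driv = np.where(proton_mask, ph, base)
        if engine == "exact":
            out[float(ph)] = float(exact_populations(model)[target])
        else:
            means, _ = mc_sample(model, seed=0)
            out[float(ph)] = float(means[target])
    model.driv = base
    return out


def redox_midpoint(
    model: MicrostateModel,
    target: int | str,
    Eh: float = 0.0,
    temperature: float | None = None,
    **kwargs,
) -> TitrationResult:
    """Midpoint potential (mV) of a redox site by bias titration.

    The electron chemical potential E_h enters the model in pK units; the
    Nernst constant ln10 kT/e (about 59.6 mV per pK unit at 300 K) converts
    the resulting half-reduction bias into millivolt.
    """
    if isinstance(target, str):
        target = model.index(target)
    nu = pk_to_mv(temperature if temperature is not None else model.temperature)
    eh_pk = Eh / nu
    model.driv[target] = eh_pk
    res = titrate_pka(model, target, pH=eh_pk, **kwargs)
    res.pka = res.pka * nu  # back to mV
    res.diagnostics["units"] = "mV"
    return res


# ---------------------------------------------------------------------------
# From structure to model: intrinsic pKs and couplings
# ---------------------------------------------------------------------------


class TitrationSystem:
    """Electrostatics of one structure: per-site charging potentials, intrinsic
    pKs, interaction matrix, and the assembled :class:`MicrostateModel`.

    The structure must have hydrogens placed; charges/radii are assigned here
    with every titratable site in its neutral reference state (``assignment``
    supplies fixed cofactor states, e.g. the special-pair hole).
    """

    def __init__(
        self,
        structure: Structure,
        env: DielectricEnvironment | None = None,
        lib: ChargeLibrary | None = None,
        assignment: Mapping | None = None,
        waivers: Sequence[str] = (),
        levels: Sequence[float] = DEFAULT_LEVELS,
        npoints_cap: int = DEFAULT_NPOINTS_CAP,
        tol: float = 1e-6,
        include: Sequence[str] | None = None,
        exclude: Sequence[str] = (),
    ):
        from .charges import assign_state_charges

        self.lib = lib or load_default_library()
        self.env = env or DielectricEnvironment()
        self.levels = list(levels)
        self.npoints_cap = npoints_cap
        self.tol = tol
        self.structure = assign_state_charges(
            structure, self.lib, assignment=assignment, waivers=waivers,
            use_reference_states=True,
        )
        self.sites = discover_sites(
            self.structure, self.lib, temperature=self.env.temperature,
            include=include, exclude=exclude,
        )
        self._site_phi: dict[int, FocusedPotential] = {}
        self._model_phi: dict[int, FocusedPotential] = {}

    # -- potentials ---------------------------------------------------------

    def _focus_params(self, site: TitratableSite) -> tuple[np.ndarray, float]:
        center = site.positions.mean(axis=0)
        fine_half = float(np.max(np.linalg.norm(site.positions - center, axis=1))) + FINE_MARGIN
        return center, fine_half

    def site_potential(self, i: int) -> FocusedPotential:
        """Potential of the site's binding charge difference in the protein."""
        if i not in self._site_phi:
            site = self.sites[i]
            center, fine_half = self._focus_params(site)
            self._site_phi[i] = focus_solve(
                self.structure,
                self.env,
                center,
                levels=self.levels,
                source_positions=site.positions,
                source_charges=site.dq_bind,
                npoints_cap=self.npoints_cap,
                fine_half_extent=fine_half,
                tol=self.tol,
            )
        return self._site_phi[i]

    def model_potential(self, i: int) -> FocusedPotential:
        """Same charge difference in the isolated model compound (the site's
        residue alone in solvent), on identically placed fine grids."""
        if i not in self._model_phi:
            site = self.sites[i]
            center, fine_half = self._focus_params(site)
            residue = Structure(
                atoms=[a.copy() for a in self.structure.atoms if a.reskey == site.reskey]
            )
            self._model_phi[i] = focus_solve(
                residue,
                self.env,
                center,
                levels=self.levels,
                source_positions=site.positions,
                source_charges=site.dq_bind,
                npoints_cap=self.npoints_cap,
                fine_half_extent=fine_half,
                tol=self.tol,
            )
        return self._model_phi[i]

    # -- energies -----------------------------------------------------------

    def _release_energy(self, i: int, phi: FocusedPotential, s: Structure) -> float:
        """G(unbound) - G(bound) in kT for the given context."""
        site = self.sites[i]
        phi_site = phi.evaluate(site.positions)
        e = 0.5 * float(np.dot(site.dq_bind, phi_site)) - float(np.dot(site.q_bound, phi_site))
        bg_pos, bg_q = [], []
        site_atoms = {(site.reskey, n) for n in site.atom_names}
        for a in s.atoms:
            if a.charge == 0.0 or (a.reskey, a.name) in site_atoms:
                continue
            bg_pos.append(a.xyz)
            bg_q.append(a.charge)
        if bg_pos:
            e -= float(np.dot(bg_q, phi.evaluate(np.array(bg_pos))))
        return e

    def intrinsic_pka(self, i: int) -> float:
        """Reference pK plus the protein-vs-model shift of the release free
        energy, with all other sites in their neutral reference states."""
        site = self.sites[i]
        if site.pka_intr is None:
            residue = Structure(
                atoms=[a.copy() for a in self.structure.atoms if a.reskey == site.reskey]
            )
            dg_protein = self._release_energy(i, self.site_potential(i), self.structure)
            dg_model = self._release_energy(i, self.model_potential(i), residue)
            site.pka_intr = site.pk_ref + (dg_protein - dg_model) / LN10
        return site.pka_intr

    def interaction_matrix(self) -> InteractionMatrix:
        """Couplings between charged-form deviations of all site pairs, in pK
        units; symmetrized by averaging the two reciprocity estimates.
        Intra-residue subsite pairs (His tautomers) are excluded: their
        coupling is already encoded in the measured reference pK values."""
        n = len(self.sites)
        W = np.zeros((n, n))
        asym = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                si, sj = self.sites[i], self.sites[j]
                if si.reskey == sj.reskey:
                    continue
                phi_i = self.site_potential(i)
                phi_j = self.site_potential(j)
                before_i, before_j = phi_i.fallback_count, phi_j.fallback_count
                wij = si.charged_sign * sj.charged_sign * float(
                    np.dot(sj.dq_bind, phi_i.evaluate(sj.positions))
                ) / LN10
                wji = si.charged_sign * sj.charged_sign * float(
                    np.dot(si.dq_bind, phi_j.evaluate(si.positions))
                ) / LN10
                if phi_i.fallback_count > before_i or phi_j.fallback_count > before_j:
                    warnings.warn(
                        f"interaction {si.site_id}~{sj.site_id} evaluated on a "
                        "coarser focusing level (partner outside the finest grid)"
                    )
                asym = max(asym, abs(wij - wji))
                W[i, j] = W[j, i] = 0.5 * (wij + wji)
        return InteractionMatrix(site_ids=[s.site_id for s in self.sites], W=W, max_asymmetry=asym)

    def build_model(self, pH: float = 7.0, Eh: float = 0.0) -> MicrostateModel:
        """Assemble the sampling-ready model at the given pH and E_h."""
        nu = pk_to_mv(self.env.temperature)
        pk = np.array([self.intrinsic_pka(i) for i in range(len(self.sites))])
        im = self.interaction_matrix()
        driv = np.array(
            [Eh / nu if s.kind == "redox" else pH for s in self.sites]
        )
        return MicrostateModel(
            site_ids=[s.site_id for s in self.sites],
            pk_intr=pk,
            W=im.W,
            driv=driv,
            charged_is_bound=np.array([s.charged_sign == +1 for s in self.sites]),
            excluded_pairs=_his_pairs(self.sites),
            temperature=self.env.temperature,
            is_redox=np.array([s.kind == "redox" for s in self.sites]),
        )
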