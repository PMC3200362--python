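"""End-to-end orchestration: structure -> states -> pKa -> decomposition.

A run is described by a :class:`RunConfig` whose defaults are the standard
continuum-electrostatics conditions for this kind of calculation (eps_p = 4,
eps_w = 80, 100 mM ionic strength, 300 K, pH 7, focusing at 2.5/1.0/0.3 A);
the seed is mandatory.  A "state" is one combination of side-chain conformer,
cofactor charge state and site overrides -- e.g. the four-column battery
neutral-pair/dark, hole/dark, hole/light, hole/deprotonated -- and
:func:`run_battery` executes a list of them and writes a cross-state report.

Every output directory gets a ``manifest.json`` recording all parameters,
seeds and data versions; replaying a manifest reproduces all numeric outputs
bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from . import __version__
from .charges import (
    ChargeState,
    load_default_library,
    special_pair_cation,
)
from .decomposition import (
    ContributionTable,
    compare_states,
    contribution_table,
    hbond_network,
)
from .solver import DEFAULT_LEVELS, DEFAULT_NPOINTS_CAP, DielectricEnvironment
from .structure import (
    Structure,
    apply_water_policy,
    place_polar_hydrogens,
    read_structure,
    resolve_conformer,
    write_pdb,
)
from .synth import make_mini_rc, make_model_compound
from .titration import TitrationSystem, exact_populations, mc_sample, titrate_pka

logger = logging.getLogger("protpka")

__all__ = ["RunConfig", "StateSpec", "StateResult", "validate_config", "run_state", "run_battery"]


@dataclass
class StateSpec:
    """One computed state: conformer + cofactor charge + site overrides."""

    label: str
    conformer: str = ""
    hole: bool = False  # special-pair cation on?
    site_states: dict[str, str] = field(default_factory=dict)


@dataclass
class RunConfig:
    structure: str = "mini_rc"  # path to a PDB file or the fixture name
    seed: int | None = None
    water_keep: list[str] | str = "all"
    eps_protein: float = 4.0
    eps_water: float = 80.0
    ionic_strength: float = 0.1
    temperature: float = 300.0
    pH: float = 7.0
    levels: list[float] = field(default_factory=lambda: list(DEFAULT_LEVELS))
    npoints_cap: int = DEFAULT_NPOINTS_CAP
    solver_tol: float = 1e-6
    mc_sweeps: int = 10000
    mc_burn_in: int = 100
    special_pair: list[str] = field(default_factory=lambda: ["P:1", "P:2"])
    hole_ratio: list[float] = field(default_factory=lambda: [2.0, 1.0])
    titrate_sites: list[str] | None = None
    waivers: list[str] = field(default_factory=list)
    outdir: str = "results/run"

    def environment(self) -> DielectricEnvironment:
        return DielectricEnvironment(
            eps_protein=self.eps_protein,
            eps_water=self.eps_water,
            ionic_strength=self.ionic_strength,
            temperature=self.temperature,
        )


def validate_config(raw: Mapping[str, Any] | RunConfig) -> tuple[RunConfig | None, list[str]]:
    """Normalize a raw mapping into a RunConfig; returns the full error list
    (never first-error-only).  Defaults are filled and logged once each."""
    if isinstance(raw, RunConfig):
        raw = asdict(raw)
    raw = dict(raw)
    errors: list[str] = []
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
        for k in unknown:
            raw.pop(k)
    defaults = RunConfig(seed=0)
    for name, fld in RunConfig.__dataclass_fields__.items():
        if name not in raw and name != "seed":
            logger.info("config default: %s = %r", name, getattr(defaults, name))
    cfg = RunConfig(**{k: v for k, v in raw.items()})
    if cfg.seed is None:
        errors.append("seed is mandatory and missing")
    elif not isinstance(cfg.seed, (int, np.integer)):
        errors.append(f"seed must be an integer, got {cfg.seed!r}")
    if cfg.eps_protein < 1 or cfg.eps_water < 1:
        errors.append("dielectric constants must be >= 1")
    if cfg.ionic_strength < 0:
        errors.append(f"ionic strength must be non-negative, got {cfg.ionic_strength}")
    if cfg.temperature <= 0:
        errors.append(f"temperature must be positive, got {cfg.temperature}")
    if any(a <= b for a, b in zip(cfg.levels, cfg.levels[1:])):
        errors.append(f"focus levels must be strictly decreasing, got {cfg.levels}")
    if any(h <= 0 for h in cfg.levels):
        errors.append("focus levels must be positive spacings")
    if cfg.mc_sweeps < 1 or cfg.mc_burn_in < 0:
        errors.append("Monte Carlo schedule must have sweeps >= 1 and burn_in >= 0")
    if len(cfg.hole_ratio) != 2 or any(w < 0 for w in cfg.hole_ratio) or sum(cfg.hole_ratio) <= 0:
        errors.append(f"hole_ratio must be two non-negative weights, got {cfg.hole_ratio}")
    return (None, errors) if errors else (cfg, errors)


@dataclass
class StateResult:
    label: str
    pkas: dict[str, float]
    means: dict[str, float]
    table: ContributionTable
    hbonds: Any
    structure: Structure
    system: TitrationSystem
    manifest: dict


def _load_structure(cfg: RunConfig) -> Structure:
    if cfg.structure == "mini_rc":
        s, _ = make_mini_rc(seed=cfg.seed)
        return s
    if cfg.structure.startswith("model:"):
        return make_model_compound(cfg.structure.split(":", 1)[1])
    return read_structure(cfg.structure)


def _hole_states(cfg: RunConfig, s: Structure, on: bool) -> dict[str, ChargeState]:
    """Neutral or cation charge states for the two special-pair groups."""
    out: dict[str, ChargeState] = {}
    rings = []
    for sid in cfg.special_pair:
        chain, resseq = sid.split(":")
        names = [a.name for a in s.atoms if a.chain == chain and a.resseq == int(resseq)]
        if not names:
            return {}
        rings.append(ChargeState(f"{sid}_neutral", {n: 0.0 for n in names}))
    if on:
        rings = list(special_pair_cation(rings[0], rings[1], tuple(cfg.hole_ratio)))
    return dict(zip(cfg.special_pair, rings))


def prepare_state_structure(cfg: RunConfig, spec: StateSpec) -> tuple[Structure, dict]:
    """Resolve conformer, apply the water policy, place and orient hydrogens
    under the state's charge assignment.  Returns the charged structure and
    the assignment used (site overrides + cofactor states)."""
    s = _load_structure(cfg)
    if spec.conformer:
        s = resolve_conformer(s, spec.conformer, spec.label)
    if cfg.water_keep != "all":
        s = apply_water_policy(s, list(cfg.water_keep))
    s = place_polar_hydrogens(s, mode="ideal")
    assignment: dict[str, Any] = dict(spec.site_states)
    assignment.update(_hole_states(cfg, s, spec.hole))
    from .charges import assign_state_charges

    charged = assign_state_charges(s, assignment=dict(assignment), waivers=cfg.waivers)
    charged = place_polar_hydrogens(charged, mode="optimize")
    return charged, assignment


def run_state(cfg: RunConfig, spec: StateSpec, write: bool = True) -> StateResult:
    """Compute one state end to end: titration of every requested site,
    per-residue contribution table for the first target, H-bond graph,
    and a manifest sufficient for bit-reproduction."""
    env = cfg.environment()
    charged, assignment = prepare_state_structure(cfg, spec)
    hb = hbond_network(charged)
    cofactor_assignment = {
        k: v for k, v in assignment.items() if isinstance(v, ChargeState)
    }
    system = TitrationSystem(
        charged,
        env=env,
        assignment=cofactor_assignment,
        waivers=cfg.waivers,
        levels=cfg.levels,
        npoints_cap=cfg.npoints_cap,
        tol=cfg.solver_tol,
    )
    model = system.build_model(pH=cfg.pH)
    targets = cfg.titrate_sites or model.site_ids
    pkas: dict[str, float] = {}
    for t in targets:
        res = titrate_pka(
            model,
            t,
            pH=cfg.pH,
            n_sweeps=cfg.mc_sweeps,
            seed=(cfg.seed or 0) + 1,
        )
        pkas[t] = res.pka
    # equilibrium pattern at the working pH for the decomposition
    if model.n <= 14:
        mvec = exact_populations(model)
    else:
        mvec, _ = mc_sample(
            model, n_sweeps=cfg.mc_sweeps, seed=(cfg.seed or 0) + 2, burn_in=cfg.mc_burn_in
        )
    means = dict(zip(model.site_ids, (float(x) for x in mvec)))
    table = contribution_table(system, targets[0], means, state_label=spec.label)

    manifest = {
        "protpka_version": __version__,
        "charge_set": system.lib.version,
        "config": asdict(cfg),
        "state": asdict(spec),
        "site_ids": model.site_ids,
        "engine_seeds": {"titration": (cfg.seed or 0) + 1, "pattern": (cfg.seed or 0) + 2},
    }
    result = StateResult(
        label=spec.label,
        pkas=pkas,
        means=means,
        table=table,
        hbonds=hb,
        structure=charged,
        system=system,
        manifest=manifest,
    )
    if write:
        _write_state(cfg, spec, result)
    return result


def _write_state(cfg: RunConfig, spec: StateSpec, r: StateResult) -> None:
    out = Path(cfg.outdir) / spec.label
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "pkas.tsv", "w") as fh:
        fh.write("site\tpka\tmean_binding_at_pH\n")
        for sid, pk in r.pkas.items():
            fh.write(f"{sid}\t{pk:.3f}\t{r.means.get(sid, float('nan')):.4f}\n")
    with open(out / "contributions.tsv", "w") as fh:
        fh.write(f"# target {r.table.target}; {r.table.sign_convention}\n")
        fh.write("residue\tresname\tside_chain\tbackbone\ttotal\n")
        for row in r.table.rows:
            sc = "" if row.side_chain is None else f"{row.side_chain:.3f}"
            bb = "" if row.backbone is None else f"{row.backbone:.3f}"
            fh.write(f"{row.residue_id}\t{row.resname}\t{sc}\t{bb}\t{row.total:.3f}\n")
    with open(out / "hbonds.tsv", "w") as fh:
        fh.write("donor\tacceptor\thydrogen\td_ha\td_heavy\tangle\n")
        for u, v, d in sorted(r.hbonds.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['hydrogen']}\t{d['d_ha']}\t{d['d_heavy']}\t{d['angle']}\n")
    write_pdb(r.structure, out / "structure.pdb")
    with open(out / "manifest.json", "w") as fh:
        json.dump(r.manifest, fh, indent=2, sort_keys=True)


def run_battery(cfg: RunConfig, states: Sequence[StateSpec], write: bool = True):
    """Run a list of states and produce the cross-state comparison report."""
    results = {spec.label: run_state(cfg, spec, write=write) for spec in states}
    comparison = compare_states(
        {lab: r.pkas for lab, r in results.items()},
        {lab: r.table for lab, r in results.items()},
        {lab: r.hbonds for lab, r in results.items()},
    )
    if write:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "state_comparison.tsv", "w") as fh:
            fh.write("# pKa by state (columns) and site (rows)\n")
            fh.write(comparison.pka.to_csv(sep="\t"))
            fh.write("\n# change versus %s\n" % comparison.reference_state)
            fh.write(comparison.dpka.to_csv(sep="\t"))
    return results, comparison


def replay_manifest(path: str | Path) -> StateResult:
    """Re-run the state recorded in a manifest; outputs are bit-identical."""
    with open(path) as fh:
        m = json.load(fh)
    cfg, errors = validate_config(m["config"])
    if errors:
        raise ValueError(f"manifest config invalid: {errors}")
    return run_state(cfg, StateSpec(**m["state"]), write=False)
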