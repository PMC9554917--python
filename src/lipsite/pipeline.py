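"""Configuration-driven orchestration of the analysis stages.

A run is described by one YAML file: where the system comes from
(generated from a spec, or loaded from PDB/DCD + topology TSV), which
stages run, and every stage parameter.  All stage defaults mirror the
analysis conventions used throughout the package (H-bond cutoff 3.2 Å,
nonbonded cutoff 10 Å, residue shell 5 Å, lipid margin 6 Å, T = 310 K,
GFE cap 3 kcal/mol, isovalue −1.2 kcal/mol).  Outputs are TSV/JSON/DX;
floats are written at 6 significant digits so a fixed config + seed
reproduces every analysis output byte-for-byte.  The run manifest also
records wall-clock timings, which naturally vary between runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .cavity import cavity_volume, sasa
from .core import SegmentClass, Selection, Topology, Trajectory, select
from .energy import NBParams, lipid_contact_census, per_residue_decomposition
from .gfe import (
    GfeParams,
    average_replica_gfe,
    bulk_reference,
    gfe_from_occupancy,
    occupancy_grid,
    region_mean_gfe,
)
from .hbonds import HBondCriteria, hbond_occupancy, water_site_occupancy
from .metrics import fragment_rmsf, rmsd_series, rmsf
from .sapt import (
    efficiency_table,
    electrostatic_ratio,
    load_fragment_table,
    load_qct_table,
    qct_classify,
)
from .synth import (
    HBondProgram,
    LigandFragmentSpec,
    LipidEnrichment,
    ToySystem,
    ToySystemSpec,
    TrajectorySchedule,
    WaterSiteProgram,
    build_toy_system,
    export_system,
    simulate_trajectory,
)

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"

__all__ = ["ConfigError", "InputError", "StageError", "RunConfig", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (exit code 2)."""


class InputError(ValueError):
    """A referenced input file is missing or unreadable (exit code 3)."""


class StageError(RuntimeError):
    """An analysis stage failed (exit code 4)."""


class RunConfig:
    """Thin validated wrapper around the YAML mapping."""

    def __init__(self, data: dict, path: Path | None = None):
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping")
        self.data = data
        self.path = path
        if "generate" not in data and "inputs" not in data:
            raise ConfigError("config needs a 'generate' or 'inputs' section")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        try:
            data = yaml.safe_load(path.read_text())
        except yaml.YAMLError as e:
            raise ConfigError(f"cannot parse {path}: {e}") from e
        return cls(data, path)

    @property
    def seed(self) -> int:
        return int(self.data.get("seed", 0))

    def stage(self, name: str) -> dict:
        return dict(self.data.get("stages", {}).get(name) or {})

    def stage_enabled(self, name: str) -> bool:
        stages = self.data.get("stages", {})
        return name in stages


# ---------------------------------------------------------------------
# atom resolution helpers

def _resolve_atoms(topology: Topology, spec, what: str = "atom") -> list[int]:
    """Resolve a config atom spec (or list of specs) to atom ids.

    A spec is either an integer atom_id or a mapping with any of
    name / residue_id / chain / segment / element keys.
    """
    if isinstance(spec, dict) or isinstance(spec, int):
        spec = [spec]
    out: list[int] = []
    for item in spec:
        if isinstance(item, int):
            if not 0 <= item < topology.n_atoms:
                raise ConfigError(f"{what}: atom_id {item} out of range")
            out.append(item)
            continue
        if not isinstance(item, dict):
            raise ConfigError(f"{what}: expected atom_id or mapping, got {item!r}")
        sel = select(
            topology,
            segment=item.get("segment"),
            residue_ids=[item["residue_id"]] if "residue_id" in item else None,
            names=[item["name"]] if "name" in item else None,
            elements=[item["element"]] if "element" in item else None,
        )
        ids = list(sel.indices)
        if "chain" in item:
            ids = [i for i in ids if topology.atoms[i].chain == item["chain"]]
        if not ids:
            raise ConfigError(f"{what}: no atom matches {item!r}")
        out.extend(ids)
    return out


def _snap_region(lo, hi, origin, spacing, mode: str = "outer"):
    """Align a region box to the analysis grid.

    'outer' grows the box to whole cells (for excluding the site from
    the bulk reference); 'inner' shrinks it so only cells lying fully
    inside the region are kept (for unbiased region means).
    """
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    origin = np.asarray(origin, float)
    eps = 1e-9
    if mode == "outer":
        lo_s = origin + np.floor((lo - origin) / spacing + eps) * spacing
        hi_s = origin + np.ceil((hi - origin) / spacing - eps) * spacing
    else:
        lo_s = origin + np.ceil((lo - origin) / spacing - eps) * spacing
        hi_s = origin + np.floor((hi - origin) / spacing + eps) * spacing
    return lo_s, hi_s


# ---------------------------------------------------------------------
# system acquisition

def _build_schedule(topology: Topology, sched_cfg: dict, seed: int) -> TrajectorySchedule:
    hb = []
    for p in sched_cfg.get("hbond_programs", []) or []:
        donor = _resolve_atoms(topology, p["donor"], "hbond donor")[0]
        acceptor = _resolve_atoms(topology, p["acceptor"], "hbond acceptor")[0]
        hyds = topology.bonded_hydrogens(donor)
        if not hyds:
            raise ConfigError(f"hbond program donor atom {donor} has no bonded H")
        hb.append(HBondProgram(
            donor=donor,
            hydrogen=hyds[0],
            acceptor=acceptor,
            target_occupancy=float(p["target_occupancy"]),
            bound_distance=float(p.get("bound_distance", 2.8)),
            unbound_distance=float(p.get("unbound_distance", 5.0)),
        ))
    ws = []
    for p in sched_cfg.get("water_site_programs", []) or []:
        site = _resolve_atoms(topology, p["site_atoms"], "water site")
        ws.append(WaterSiteProgram(
            site_atoms=tuple(site),
            target_occupancy=float(p["target_occupancy"]),
            bound_distance=float(p.get("bound_distance", 2.8)),
            n_alternating_waters=int(p.get("n_alternating_waters", 1)),
        ))
    enr = None
    enr_cfg = sched_cfg.get("lipid_enrichment")
    if enr_cfg:
        enr = LipidEnrichment(
            region_lo=tuple(enr_cfg["region_lo"]),
            region_hi=tuple(enr_cfg["region_hi"]),
            ratio=float(enr_cfg["ratio"]),
        )
    return TrajectorySchedule(
        n_frames=int(sched_cfg.get("n_frames", 100)),
        hbond_programs=hb,
        water_site_programs=ws,
        lipid_enrichment=enr,
        noise_sigma=float(sched_cfg.get("noise_sigma", 0.0)),
        seed=int(sched_cfg.get("seed", seed)),
    )


def acquire_system(config: RunConfig):
    """Return (system-or-None, topology, trajectory, manifest_extras)."""
    if "generate" in config.data:
        gen = config.data["generate"] or {}
        sys_cfg = dict(gen.get("system") or {})
        if "box" in sys_cfg:
            sys_cfg["box"] = tuple(sys_cfg["box"])
        if "ligand" in sys_cfg:
            sys_cfg["ligand"] = [
                LigandFragmentSpec(
                    f["label"],
                    tuple((b[0], b[1], float(b[2]), tuple(b[3])) for b in f["beads"]),
                )
                for f in sys_cfg["ligand"]
            ]
        sys_cfg.setdefault("seed", config.seed)
        try:
            spec = ToySystemSpec(**sys_cfg)
        except TypeError as e:
            raise ConfigError(f"bad generate.system section: {e}") from e
        system = build_toy_system(spec)
        schedule = _build_schedule(system.topology, gen.get("schedule") or {},
                                   config.seed)
        traj = simulate_trajectory(system, schedule)
        return system, system.topology, traj, {"generated": True,
                                               "schedule_seed": schedule.seed}

    inputs = config.data["inputs"] or {}
    structure = inputs.get("structure")
    if not structure:
        raise ConfigError("inputs.structure (PDB) is required")
    if not Path(structure).exists():
        raise InputError(f"structure file not found: {structure}")
    topo_path = inputs.get("topology")
    traj_path = inputs.get("trajectory")
    if traj_path and not Path(traj_path).exists():
        raise InputError(f"trajectory file not found: {traj_path}")
    if traj_path and str(traj_path).endswith(".dcd"):
        topo, traj = lio.read_dcd(traj_path, structure)
    else:
        topo, traj = lio.read_structure(traj_path or structure)
    if topo_path:
        if not Path(topo_path).exists():
            raise InputError(f"topology table not found: {topo_path}")
        skeleton, _ = lio.read_structure(structure)
        bonds = inputs.get("bonds")
        topo = lio.read_topology_table(topo_path, structure=skeleton,
                                       bonds_path=bonds)
    return None, topo, traj, {"generated": False}


# ---------------------------------------------------------------------
# stages

def _default_site(system: ToySystem | None, topology: Topology) -> Selection:
    lig = select(topology, segment="ligand", heavy_only=True)
    if len(lig):
        return lig
    prot = select(topology, segment="protein", heavy_only=True)
    if not len(prot):
        raise StageError("cannot derive a site seed: no ligand or protein atoms")
    return prot


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _fmt(x: float) -> float:
    """Round to 6 significant digits for stable JSON output."""
    return float(FLOAT_FORMAT % x)


def stage_rmsd(topology, traj, outdir: Path, cfg: dict) -> dict:
    prot_ca = select(topology, segment="protein", names=["CA"])
    fit = prot_ca if len(prot_ca) >= 3 else select(topology, segment="protein")
    series = rmsd_series(traj, fit, reference_frame=int(cfg.get("reference_frame", 0)))
    out = {"protein": series.summary()}
    rows = {"frame": np.arange(traj.n_frames), "rmsd_protein": series.values}
    lig = select(topology, segment="ligand", heavy_only=True)
    if len(lig):
        lseries = rmsd_series(traj, fit, lig)
        out["ligand"] = lseries.summary()
        rows["rmsd_ligand"] = lseries.values
    _write_tsv(pd.DataFrame(rows), outdir / "rmsd.tsv")
    return {k: {kk: _fmt(vv) if isinstance(vv, float) else vv
                for kk, vv in v.items()} for k, v in out.items()}


def stage_rmsf(topology, traj, outdir: Path, cfg: dict,
               system: ToySystem | None) -> dict:
    prot_ca = select(topology, segment="protein", names=["CA"])
    fit = prot_ca if len(prot_ca) >= 3 else select(topology, segment="protein")
    measure = select(topology, segment="protein", heavy_only=True)
    series = rmsf(traj, fit, measure)
    df = pd.DataFrame({
        "atom_id": measure.as_array(),
        "name": [topology.atoms[i].name for i in measure],
        "residue_id": [topology.atoms[i].residue_id for i in measure],
        "rmsf": series.values,
    })
    _write_tsv(df, outdir / "rmsf.tsv")
    out = {"protein": series.summary()}
    # per-ligand-fragment RMSF: fragments grouped by config or, for
    # generated systems, by the generator's fragment labels
    frags = cfg.get("fragments")
    frag_values = {}
    if frags:
        for fr in frags:
            sel = Selection(tuple(_resolve_atoms(topology, fr["atoms"], "fragment")),
                            fr.get("label", "fragment"))
            frag_values[fr.get("label", "fragment")] = fragment_rmsf(traj, fit, sel)
    elif system is not None:
        lig = select(topology, segment="ligand", heavy_only=True)
        if len(lig):
            frag_values["ligand"] = fragment_rmsf(traj, fit, lig)
    if frag_values:
        out["fragments"] = {k: _fmt(v) for k, v in frag_values.items()}
        _write_tsv(
            pd.DataFrame(
                [{"fragment": k, "rmsf": v} for k, v in frag_values.items()]
            ),
            outdir / "rmsf_fragments.tsv",
        )
    out["protein"] = {k: _fmt(v) if isinstance(v, float) else v
                      for k, v in out["protein"].items()}
    return out


def stage_hbonds(topology, traj, outdir: Path, cfg: dict) -> dict:
    criteria = HBondCriteria(
        d_cut=float(cfg.get("d_cut", 3.2)),
        angle_cut=float(cfg.get("angle_cut", 150.0)),
        require_hydrogen=bool(cfg.get("require_hydrogen", True)),
    )
    rows = []
    for pair in cfg.get("pairs", []) or []:
        donors = Selection(tuple(_resolve_atoms(topology, pair["donors"], "donors")))
        acceptors = Selection(tuple(_resolve_atoms(topology, pair["acceptors"], "acceptors")))
        rep = hbond_occupancy(traj, topology, donors, acceptors, criteria,
                              label=pair.get("label", "pair"))
        rows.append(rep.as_dict())
    if rows:
        _write_tsv(pd.DataFrame(rows), outdir / "hbond_occupancy.tsv")
    return {
        "criteria": dataclasses.asdict(criteria),
        "pairs": {r["label"]: _fmt(r["occupancy"]) for r in rows},
    }


def stage_water(topology, traj, outdir: Path, cfg: dict) -> dict:
    criteria = HBondCriteria(
        d_cut=float(cfg.get("d_cut", 3.2)),
        angle_cut=float(cfg.get("angle_cut", 150.0)),
    )
    site = Selection(tuple(_resolve_atoms(topology, cfg["site_atoms"], "site_atoms")))
    rep = water_site_occupancy(traj, topology, site, criteria,
                               mode=cfg.get("mode", "any"))
    _write_tsv(pd.DataFrame([rep.as_dict()]), outdir / "water_occupancy.tsv")
    return {"occupancy": _fmt(rep.occupancy), "mode": cfg.get("mode", "any")}


def stage_energy(topology, traj, outdir: Path, cfg: dict) -> dict:
    params = NBParams(cutoff=float(cfg.get("cutoff", 10.0)))
    lig = select(topology, segment="ligand", heavy_only=False)
    if not len(lig):
        raise StageError("energy stage needs ligand atoms")
    table = per_residue_decomposition(
        traj, topology, lig,
        shell=float(cfg.get("shell", 5.0)),
        params=params,
        membership=cfg.get("membership", "first_frame"),
    )
    _write_tsv(table, outdir / "energy_residues.tsv")
    out = {
        "cutoff": params.cutoff,
        "n_shell_residues": int(len(table)),
        "total_mean_vdw": _fmt(float(table["mean_vdw"].sum())) if len(table) else 0.0,
        "total_mean_elec": _fmt(float(table["mean_elec"].sum())) if len(table) else 0.0,
    }
    if len(topology.segment_indices(SegmentClass.LIPID)):
        census = lipid_contact_census(
            traj, topology, lig, params,
            vdw_threshold=float(cfg.get("vdw_threshold", -1.0)),
            polar_threshold=float(cfg.get("polar_threshold", -1.0)),
        )
        _write_tsv(census["per_lipid"], outdir / "lipid_census.tsv")
        out["lipid_tail_contacts"] = census["tail_count"]
        out["lipid_head_contacts"] = census["head_count"]
    return out


def stage_gfe(system, topology, traj, outdir: Path, cfg: dict) -> dict:
    params = GfeParams(
        temperature=float(cfg.get("temperature", 310.0)),
        gfe_max=float(cfg.get("gfe_max", 3.0)),
        spacing=float(cfg.get("spacing", 1.0)),
        bulk_min_protein_distance=float(cfg.get("bulk_distance", 10.0)),
        iso_default=float(cfg.get("iso", -1.2)),
    )
    carbons = select(topology, segment="lipid", elements=["C"])
    if not len(carbons):
        raise StageError("gfe stage needs lipid carbon atoms")
    if system is not None:
        box = system.box
        z_lo, z_hi = system.manifest["membrane_slab_z"]
    else:
        if traj.box is None:
            raise StageError("gfe stage needs box dimensions")
        box = traj.box[0]
        zs = traj.coordinates[0, carbons.as_array(), 2]
        z_lo, z_hi = float(zs.min()), float(zs.max())
    lo = np.array([-box[0] / 2, -box[1] / 2, z_lo])
    hi = np.array([box[0] / 2, box[1] / 2, z_hi])
    occ = occupancy_grid(traj, carbons, lo, hi, params)
    prot_idx = topology.segment_indices(SegmentClass.PROTEIN)
    prot_coords = traj.frame(0)[prot_idx] if len(prot_idx) else None
    region = cfg.get("region")
    if region is None and system is not None:
        ps = system.manifest["pocket_seed"]
        c = np.asarray(ps["center"])
        he = np.asarray(ps["half_extent"])
        region = {"lo": (c - he).tolist(), "hi": (c + he).tolist()}
    exclude = None
    if region:
        exclude = _snap_region(region["lo"], region["hi"], lo, params.spacing,
                               mode="outer")
    ref = bulk_reference(occ, prot_coords, params, slab_z=(z_lo, z_hi),
                         exclude_region=exclude)
    grid = gfe_from_occupancy(occ, ref, params)
    lio.write_grid_dx(grid, outdir / "gfe.dx")
    out = {
        "temperature": params.temperature,
        "gfe_max": params.gfe_max,
        "spacing": params.spacing,
        "iso": params.iso_default,
        "bulk_reference": _fmt(ref),
    }
    if region:
        r_lo, r_hi = _snap_region(region["lo"], region["hi"], lo,
                                  params.spacing, mode="inner")
        mean = region_mean_gfe(grid, r_lo, r_hi)
        out["region_mean_gfe"] = _fmt(mean)
        out["region_rho_hat"] = _fmt(float(np.exp(-mean / params.rt)))
    _write_tsv(pd.DataFrame([out]), outdir / "gfe_summary.tsv")
    return out


def stage_cavity(system, topology, traj, outdir: Path, cfg: dict) -> dict:
    frame = traj.frame(int(cfg.get("frame", 0)))
    seed = (
        Selection(tuple(_resolve_atoms(topology, cfg["site_seed"], "site_seed")))
        if "site_seed" in cfg
        else _default_site(system, topology)
    )
    kwargs = dict(
        spacing=float(cfg.get("spacing", 0.8)),
        probe=float(cfg.get("probe", 1.4)),
        lipid_margin=float(cfg.get("lipid_margin", 6.0)),
    )
    r_only = cavity_volume(frame, topology, seed, "receptor_only", **kwargs)
    out = {
        "receptor_only": {"volume": _fmt(r_only.volume),
                          "enclosed": r_only.enclosed},
    }
    if len(topology.segment_indices(SegmentClass.LIPID)):
        r_lip = cavity_volume(frame, topology, seed, "receptor_plus_lipids", **kwargs)
        out["receptor_plus_lipids"] = {"volume": _fmt(r_lip.volume),
                                       "enclosed": r_lip.enclosed}
        if r_lip.volume > 0:
            out["percent_volume_lost_without_lipids"] = _fmt(
                r_lip.percent_change(r_only)
            )
        lio.write_grid_dx(r_lip.mask, outdir / "cavity_mask.dx")
    _write_tsv(pd.DataFrame([_flatten(out)]), outdir / "cavity.tsv")
    return out


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


def stage_sasa(system, topology, traj, outdir: Path, cfg: dict) -> dict:
    frame = traj.frame(int(cfg.get("frame", 0)))
    if "residues" in cfg:
        sel = select(topology, segment="protein",
                     residue_ids=[int(r) for r in cfg["residues"]])
    else:
        # default site residues: protein residues within 6 A of the ligand
        lig = select(topology, segment="ligand")
        if not len(lig):
            raise StageError("sasa stage needs site residues or a ligand")
        from .energy import shell_residues
        keys = shell_residues(traj, topology, lig, shell=float(cfg.get("shell", 6.0)))
        rids = sorted({k[1] for k in keys})
        if not rids:
            raise StageError("no site residues within the SASA shell")
        sel = select(topology, segment="protein", residue_ids=rids)
    rep = sasa(frame, topology, sel,
               probe=float(cfg.get("probe", 1.4)),
               n_sphere_points=int(cfg.get("n_sphere_points", 960)))
    df = pd.DataFrame({
        "atom_id": rep.indices,
        "sasa": rep.atom_sasa,
        "polar": rep.polar_mask,
    })
    _write_tsv(df, outdir / "sasa.tsv")
    return {
        "total_sasa": _fmt(rep.total),
        "polar_fraction": _fmt(rep.polar_fraction),
        "nonpolar_fraction": _fmt(rep.nonpolar_fraction),
        "n_atoms": int(len(rep.indices)),
    }


def stage_sapt(outdir: Path, cfg: dict, base_dir: Path | None = None) -> dict:
    def _resolve(p) -> Path:
        p = Path(p)
        if not p.is_absolute() and base_dir is not None and (base_dir / p).exists():
            return base_dir / p
        return p

    out: dict = {}
    if "fragments" in cfg:
        path = _resolve(cfg["fragments"])
        if not path.exists():
            raise InputError(f"fragment table not found: {path}")
        records = load_fragment_table(path)
        table = efficiency_table(records)
        _write_tsv(table, outdir / "sapt_efficiency.tsv")
        out["n_fragments"] = len(records)
        out["best_efficiency"] = _fmt(float(table["efficiency"].iloc[0]))
        ratios = {}
        by_key = {f"{r.label}:{r.part}": r for r in records}
        for rc in cfg.get("ratios", []) or []:
            group = [by_key[g] for g in rc["group"]]
            refr = by_key[rc["reference"]]
            pct, pct_int = electrostatic_ratio(group, refr)
            ratios[rc.get("label", rc["reference"])] = {
                "percent": _fmt(pct), "percent_rounded": pct_int,
            }
        if ratios:
            out["electrostatic_ratios"] = ratios
    if "qct" in cfg:
        path = _resolve(cfg["qct"])
        if not path.exists():
            raise InputError(f"Q_CT table not found: {path}")
        rows = []
        refs = cfg.get("qct_references") or None
        for rec in load_qct_table(path):
            ratio, strength = qct_classify(rec, refs)
            rows.append({"label": rec.label, "bond_class": rec.bond_class,
                         "q_ct": rec.q_ct, "ratio": ratio, "strength": strength})
        _write_tsv(pd.DataFrame(rows), outdir / "qct_classification.tsv")
        out["qct"] = {r["label"]: r["strength"] for r in rows}
    return out


# ---------------------------------------------------------------------

_ALL_STAGES = ("rmsd", "rmsf", "hbonds", "water", "energy", "gfe",
               "cavity", "sasa", "sapt")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    stages: tuple[str, ...] | None = None,
    seed: int | None = None,
) -> dict:
    """Run the requested stages and write a manifest; returns the report."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config.data["seed"] = int(seed)
    wanted = stages or tuple(s for s in _ALL_STAGES if config.stage_enabled(s))
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.data,
        "input_checksums": {},
        "stages": {},
        "status": "ok",
    }
    if config.path is not None:
        manifest["input_checksums"][str(config.path)] = _sha256(config.path)
    for p in (config.data.get("inputs") or {}).values():
        if isinstance(p, str) and Path(p).exists():
            manifest["input_checksums"][p] = _sha256(Path(p))

    try:
        system, topology, traj, extra = acquire_system(config)
        manifest["system"] = {"n_atoms": topology.n_atoms,
                              "n_frames": traj.n_frames, **extra}
        if system is not None and config.data.get("export_system", True):
            export_system(system, None, outdir, prefix="system")
    except (ConfigError, InputError):
        manifest["status"] = "failed: system acquisition"
        _write_manifest(outdir, manifest)
        raise

    for name in wanted:
        cfg = config.stage(name)
        t0 = time.perf_counter()
        try:
            if name == "rmsd":
                res = stage_rmsd(topology, traj, outdir, cfg)
            elif name == "rmsf":
                res = stage_rmsf(topology, traj, outdir, cfg, system)
            elif name == "hbonds":
                res = stage_hbonds(topology, traj, outdir, cfg)
            elif name == "water":
                res = stage_water(topology, traj, outdir, cfg)
            elif name == "energy":
                res = stage_energy(topology, traj, outdir, cfg)
            elif name == "gfe":
                res = stage_gfe(system, topology, traj, outdir, cfg)
            elif name == "cavity":
                res = stage_cavity(system, topology, traj, outdir, cfg)
            elif name == "sasa":
                res = stage_sasa(system, topology, traj, outdir, cfg)
            elif name == "sapt":
                base = config.path.parent if config.path else None
                res = stage_sapt(outdir, cfg, base_dir=base)
            else:
                raise ConfigError(f"unknown stage {name!r}")
        except (ConfigError, InputError):
            manifest["status"] = f"failed: stage {name}"
            manifest["stages"][name] = {"error": "input/config error"}
            _write_manifest(outdir, manifest)
            raise
        except Exception as e:
            manifest["status"] = f"failed: stage {name}"
            manifest["stages"][name] = {"error": str(e)}
            _write_manifest(outdir, manifest)
            raise StageError(f"stage {name} failed: {e}") from e
        dt = time.perf_counter() - t0
        logger.info("stage %s finished in %.2f s", name, dt)
        report["stages"][name] = res
        manifest["stages"][name] = {"seconds": dt, "params": cfg}

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_manifest(outdir, manifest)
    return report


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
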