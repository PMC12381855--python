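"""End-to-end calibration workflow over a work directory.

The workflow mirrors the calibration template for the CH/CH-d protocol:

1. ``synth``    — generate a synthetic benchmark dataset (optional; real
                  snapshots can be supplied instead).
2. ``carve``    — define the reaction kernel, cap severed bonds, select the
                  environment residues within the cutoff, write the pair-task
                  manifest.
3. ``prepare``  — write engine-facing embedding inputs (Gaussian dialect) for
                  every pair, scheme and damping range.
4. ``engine``   — run the surrogate reference engine over the manifest
                  (a real QM engine would be run externally on the prepared
                  inputs; its totals go into the same energy-table CSV).
5. ``collate``  — assemble reference and embedded interaction energies into
                  the interaction-record table.
6. ``calibrate``— scan the r0 grid per state, fit λ, write the report.

Work-directory layout::

    config.yaml            flat key-value configuration
    snapshots/{replica}_{state}.csv     full-precision snapshot tables
    kernel_selection.txt   0-based snapshot atom indices of the kernel
    severed_bonds.txt      optional "i j" index pairs (one endpoint inside)
    kernels/{replica}_{state}.csv       capped kernels
    manifest.csv           one row per kernel-residue pair task
    inputs/*.gjf           prepared engine inputs
    energies.csv           energy table (pair_id, component, r0, energy, unit)
    records.csv            interaction-record table
    report.txt, calibration_summary.csv
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import format_report, recommend_defaults, scan_r0
from .carving import ReactionKernel, cap_severed_bonds, select_environment
from .damping import DampingScheme, apply_damping
from .electrostatics import (
    assemble_ch_interaction,
    assemble_qm_interaction,
    ch_column,
    charge_self_energy,
    coulomb_cross_energy,
)
from .errors import DataError, InputError
from .io import (
    AtomRecord,
    Snapshot,
    read_energy_table,
    read_structure,
    write_embedding_input,
    write_energy_table,
    write_structure,
)
from .synthetic import (
    DEFAULT_R0_GRID,
    SurrogateParams,
    generate_snapshot_set,
    pair_noise,
    surrogate_self_energy,
)

log = logging.getLogger("chdamp")

__all__ = ["RunConfig", "load_config", "cmd_synth", "cmd_carve", "cmd_prepare",
           "cmd_engine", "cmd_collate", "cmd_calibrate", "config_hash"]


@dataclass
class RunConfig:
    """Flat run configuration; every key can be overridden from the CLI."""

    workdir: str = "."
    cutoff: float = 12.0
    r0_grid: tuple[float, ...] = DEFAULT_R0_GRID
    states: tuple[str, ...] = ("R", "TS")
    q_rk: int = 0
    multiplicity: int = 1
    kernel_atoms: int = 10
    n_residues: int = 40
    n_replicas: int = 5
    truncation_mode: str = "full"
    truncation_threshold: float | None = None
    exclude_residues: tuple[str, ...] = ()
    engine: str = "surrogate"
    route: str = "#p sp charge"
    seed: int = 0
    smear_sigma: float = 1.0
    rep_A: float = 500.0
    rep_rho: float = 0.3
    noise_sigma: float = 0.3
    allow_missing: bool = False

    def __post_init__(self) -> None:
        self.r0_grid = tuple(sorted(float(r) for r in self.r0_grid))
        if 0.0 not in self.r0_grid:
            raise InputError("r0_grid must contain 0 (plain CH)")
        if self.cutoff <= 0:
            raise InputError("cutoff must be > 0")
        self.states = tuple(self.states)

    @property
    def path(self) -> Path:
        return Path(self.workdir)

    def surrogate_params(self) -> SurrogateParams:
        return SurrogateParams(
            smear_sigma=self.smear_sigma,
            rep_A=self.rep_A,
            rep_rho=self.rep_rho,
            noise_sigma=self.noise_sigma,
            seed=self.seed,
        )


def config_hash(config: RunConfig) -> str:
    d = _config_dict(config)
    d.pop("workdir", None)  # identify the run parameters, not the location
    payload = yaml.safe_dump(d, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["r0_grid"] = list(config.r0_grid)
    d["states"] = list(config.states)
    d["exclude_residues"] = list(config.exclude_residues)
    return d


def load_config(path, **overrides) -> RunConfig:
    """Load a YAML config file; keyword overrides take precedence."""
    path = Path(path)
    data: dict = {}
    if path.is_dir():
        cfg_file = path / "config.yaml"
        data["workdir"] = str(path)
    else:
        cfg_file = path
        data["workdir"] = str(path.parent)
    if cfg_file.exists():
        loaded = yaml.safe_load(cfg_file.read_text()) or {}
        if not isinstance(loaded, dict):
            raise InputError(f"config {cfg_file} must be a flat key-value mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig) -> Path:
    out = config.path / "config.yaml"
    d = _config_dict(config)
    d.pop("workdir", None)
    out.write_text(yaml.safe_dump(d, sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _snapshot_files(config: RunConfig) -> list[Path]:
    snapdir = config.path / "snapshots"
    if not snapdir.is_dir():
        raise InputError(f"no snapshots directory in {config.path}")
    files = sorted(snapdir.glob("*.csv"))
    if not files:
        raise InputError(f"no snapshot CSV files in {snapdir}")
    return files


def _parse_snapshot_name(path: Path) -> tuple[str, str]:
    stem = path.stem
    replica, _, state = stem.rpartition("_")
    if state not in ("R", "TS") or not replica:
        raise InputError(
            f"snapshot file name {path.name!r} must follow {{replica}}_{{state}}.csv"
        )
    return replica, state


def _load_snapshots(config: RunConfig) -> dict[tuple[str, str], Snapshot]:
    out = {}
    for f in _snapshot_files(config):
        replica, state = _parse_snapshot_name(f)
        out[(replica, state)] = read_structure(
            f, fmt="csv", state_label=state, replica_id=replica, require_charges=True
        )
    return out


def _load_kernel_selection(config: RunConfig) -> list[int]:
    sel = config.path / "kernel_selection.txt"
    if not sel.exists():
        raise InputError(f"kernel selection file not found: {sel}")
    indices = []
    for i, line in enumerate(sel.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            indices.append(int(line))
        except ValueError:
            raise InputError(f"bad kernel selection entry {line!r} ({sel}, line {i})") from None
    if not indices:
        raise InputError(f"kernel selection file {sel} is empty")
    return indices


def _load_severed_bonds(config: RunConfig) -> list[tuple[int, int]]:
    path = config.path / "severed_bonds.txt"
    if not path.exists():
        return []
    bonds = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        toks = line.split()
        if len(toks) != 2:
            raise InputError(f"bad severed-bond entry {line!r} ({path}, line {i})")
        bonds.append((int(toks[0]), int(toks[1])))
    return bonds


_KERNEL_COLUMNS = ["element", "x", "y", "z", "charge", "residue_id", "atom_label", "is_cap"]


def _write_kernel_csv(kernel: ReactionKernel, path: Path) -> None:
    rows = []
    for a, cap in zip(kernel.atoms, kernel.cap_flags):
        rows.append(
            {
                "element": a.element,
                "x": a.position[0],
                "y": a.position[1],
                "z": a.position[2],
                "charge": a.partial_charge,
                "residue_id": a.residue_id,
                "atom_label": a.atom_label,
                "is_cap": bool(cap),
            }
        )
    pd.DataFrame(rows, columns=_KERNEL_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def _read_kernel_csv(path: Path, net_charge: int, multiplicity: int) -> ReactionKernel:
    df = pd.read_csv(path, float_precision="round_trip")
    atoms = [
        AtomRecord(
            element=str(r["element"]),
            position=(float(r["x"]), float(r["y"]), float(r["z"])),
            partial_charge=float(r["charge"]) if pd.notna(r["charge"]) else None,
            residue_id=str(r["residue_id"]),
            atom_label=str(r["atom_label"]),
        )
        for _, r in df.iterrows()
    ]
    caps = [bool(c) for c in df["is_cap"]] if "is_cap" in df.columns else None
    return ReactionKernel(atoms, net_charge, multiplicity, cap_flags=caps or [])


def _load_kernels(config: RunConfig) -> dict[tuple[str, str], ReactionKernel]:
    kdir = config.path / "kernels"
    if not kdir.is_dir():
        raise InputError(f"no kernels directory in {config.path}; run carve first")
    out = {}
    for f in sorted(kdir.glob("*.csv")):
        replica, state = _parse_snapshot_name(f)
        out[(replica, state)] = _read_kernel_csv(f, config.q_rk, config.multiplicity)
    return out


def _load_manifest(config: RunConfig) -> pd.DataFrame:
    path = config.path / "manifest.csv"
    if not path.exists():
        raise InputError(f"manifest not found: {path}; run carve first")
    return pd.read_csv(path, float_precision="round_trip")


def _residue_atoms(snapshot: Snapshot, residue_id: str) -> list[AtomRecord]:
    atoms = [a for a in snapshot.atoms if a.residue_id == residue_id]
    if not atoms:
        raise DataError(f"residue {residue_id!r} not found in snapshot {snapshot.replica_id}")
    return atoms


def _pair_id(replica: str, state: str, residue: str) -> str:
    return f"{replica}_{state}_{residue}"


def _r0_tag(r0: float) -> str:
    return str(int(round(r0 * 10)))


# ---------------------------------------------------------------------------
# commands
# ---------------------------------------------------------------------------

def cmd_synth(config: RunConfig) -> "pd.DataFrame":
    """Generate the synthetic benchmark dataset into the work directory.

    Writes full-precision snapshot CSVs (plus PQR interop copies), the kernel
    selection file, the saved configuration and the generator's own record
    table (``records_reference.csv``) for closed-loop comparison.
    """
    config.path.mkdir(parents=True, exist_ok=True)
    (config.path / "snapshots").mkdir(exist_ok=True)
    dataset = generate_snapshot_set(
        n_residues=config.n_residues,
        kernel_spec={"q_rk": config.q_rk, "n_atoms": config.kernel_atoms},
        n_replicas=config.n_replicas,
        states=config.states,
        params=config.surrogate_params(),
        r0_grid=config.r0_grid,
    )
    for snap in dataset.snapshots:
        base = config.path / "snapshots" / f"{snap.replica_id}_{snap.state_label}"
        write_structure(snap, base.with_suffix(".csv"), fmt="csv")
        write_structure(snap, base.with_suffix(".pqr"), fmt="pqr")
    n_kernel = len(next(iter(dataset.kernel_indices.values())))
    (config.path / "kernel_selection.txt").write_text(
        "\n".join(str(i) for i in range(n_kernel)) + "\n"
    )
    dataset.records.to_csv(
        config.path / "records_reference.csv", index=False, float_format="%.17g"
    )
    save_config(config)
    log.info(
        "synth: wrote %d snapshots (%d residues each), config %s",
        len(dataset.snapshots), config.n_residues, config_hash(config),
    )
    return dataset.records


def cmd_carve(config: RunConfig) -> pd.DataFrame:
    """Build (and cap) the kernel per snapshot, select environment residues,
    write the pair-task manifest and the capped-kernel files."""
    snapshots = _load_snapshots(config)
    selection = _load_kernel_selection(config)
    bonds = _load_severed_bonds(config)
    kdir = config.path / "kernels"
    kdir.mkdir(exist_ok=True)
    rows = []
    for (replica, state), snap in sorted(snapshots.items()):
        kernel = ReactionKernel.from_snapshot(
            snap, selection, net_charge=config.q_rk, multiplicity=config.multiplicity
        )
        if bonds:
            kernel = cap_severed_bonds(kernel, bonds, snap)
        _write_kernel_csv(kernel, kdir / f"{replica}_{state}.csv")
        tasks = select_environment(snap, kernel, cutoff=config.cutoff)
        for t in tasks:
            rows.append(
                {
                    "snapshot": replica,
                    "state": state,
                    "residue": t.residue_id,
                    "min_distance": t.min_distance,
                    "n_atoms": len(t.residue_atoms),
                }
            )
        log.info("carve: %s/%s -> %d residue tasks", replica, state, len(tasks))
    manifest = pd.DataFrame(rows, columns=["snapshot", "state", "residue", "min_distance", "n_atoms"])
    manifest.to_csv(config.path / "manifest.csv", index=False, float_format="%.17g")
    if manifest.empty:
        log.warning("carve: no residues within %.2f Å of any kernel", config.cutoff)
    return manifest


@dataclass
class _MolSpec:
    """Minimal molecule view for engine-input writing."""

    atoms: list
    net_charge: int
    multiplicity: int = 1


def _residue_net_charge(atoms: Sequence[AtomRecord]) -> int:
    total = sum(a.partial_charge or 0.0 for a in atoms)
    return int(round(total))


def cmd_prepare(config: RunConfig) -> list[Path]:
    """Write engine input files per (pair, scheme, r0).

    Per snapshot: one bare-kernel input (``..._RK_bare_0.gjf``).  Per pair:
    one embedded input per r0 (``..._{residue}_chd_{r0x10}.gjf``) with damped
    charges, plus the QM-branch dimer and monomer inputs (``pair``, ``monk``,
    ``monr``).  File contents are deterministic for a given dataset/config.
    """
    manifest = _load_manifest(config)
    snapshots = _load_snapshots(config)
    kernels = _load_kernels(config)
    indir = config.path / "inputs"
    indir.mkdir(exist_ok=True)
    written: list[Path] = []

    def _write(path: Path, mol: _MolSpec, charges, title: str) -> None:
        write_embedding_input(mol, charges, path, route=config.route, title=title)
        written.append(path)

    for (replica, state), kernel in sorted(kernels.items()):
        mol_kernel = _MolSpec(kernel.atoms, kernel.net_charge, kernel.multiplicity)
        _write(
            indir / f"{replica}_{state}_RK_bare_0.gjf",
            mol_kernel, [], f"bare kernel {replica}/{state}",
        )

    for _, row in manifest.iterrows():
        replica, state, residue = row["snapshot"], row["state"], row["residue"]
        snap = snapshots[(replica, state)]
        kernel = kernels[(replica, state)]
        mol_kernel = _MolSpec(kernel.atoms, kernel.net_charge, kernel.multiplicity)
        res_atoms = _residue_atoms(snap, residue)
        res_charges = [a.as_point_charge() for a in res_atoms]
        res_net = _residue_net_charge(res_atoms)
        stem = f"{replica}_{state}_{residue}"

        dimer = _MolSpec(kernel.atoms + res_atoms, kernel.net_charge + res_net,
                         kernel.multiplicity)
        _write(indir / f"{stem}_pair_0.gjf", dimer, [], f"dimer {stem}")
        _write(indir / f"{stem}_monk_0.gjf", mol_kernel, [], f"kernel monomer {stem}")
        _write(indir / f"{stem}_monr_0.gjf",
               _MolSpec(res_atoms, res_net, 1), [], f"residue monomer {stem}")

        for r0 in config.r0_grid:
            damped = apply_damping(res_charges, kernel.coords, DampingScheme(r0))
            _write(
                indir / f"{stem}_chd_{_r0_tag(r0)}.gjf",
                mol_kernel, damped, f"embedded {stem} r0={r0:g}",
            )
    log.info("prepare: wrote %d input files to %s", len(written), indir)
    return written


def cmd_engine(config: RunConfig) -> pd.DataFrame:
    """Run the surrogate reference engine over the manifest.

    Produces the energy table a real QM engine run would provide: dimer and
    counterpoise-style monomer totals for the QM branch, and embedded-kernel
    totals (including the charge-charge self energy, as Gaussian-style
    engines report) for the CH branch at every r0.  Totals are computed in
    full precision from the snapshot/kernel CSVs; reference noise is the same
    deterministic function of (seed, snapshot, state, residue) the synthetic
    generator uses.
    """
    if config.engine != "surrogate":
        raise InputError(
            f"engine {config.engine!r} is external: run it on the prepared inputs "
            "and provide energies.csv yourself"
        )
    manifest = _load_manifest(config)
    snapshots = _load_snapshots(config)
    kernels = _load_kernels(config)
    params = config.surrogate_params()
    rows = []

    def add(pair_id: str, component: str, r0: float | None, energy: float) -> None:
        rows.append(
            {"pair_id": pair_id, "component": component,
             "r0": np.nan if r0 is None else r0, "energy": energy, "unit": "kcal/mol"}
        )

    for _, mrow in manifest.iterrows():
        replica, state, residue = mrow["snapshot"], mrow["state"], mrow["residue"]
        snap = snapshots[(replica, state)]
        kernel = kernels[(replica, state)]
        kernel_pc = kernel.point_charges
        res_pc = [a.as_point_charge() for a in _residue_atoms(snap, residue)]
        pid = _pair_id(replica, state, residue)

        e_kern = surrogate_self_energy(kernel_pc, params)
        e_res = surrogate_self_energy(res_pc, params)
        e_pair = surrogate_self_energy(kernel_pc + res_pc, params)
        e_pair += pair_noise(params, replica, state, residue)
        add(pid, "pair", None, e_pair)
        add(pid, "kernel", None, e_kern)
        add(pid, "residue", None, e_res)
        add(pid, "kernel_alone", None, e_kern)
        for r0 in config.r0_grid:
            damped = apply_damping(res_pc, kernel.coords, DampingScheme(r0))
            e_emb = (
                e_kern
                + coulomb_cross_energy(kernel_pc, damped)
                + charge_self_energy(damped)
            )
            add(pid, "kernel_in_charges", r0, e_emb)

    table = pd.DataFrame(rows)
    write_energy_table(table, config.path / "energies.csv")
    log.info("engine: wrote %d energy rows for %d pairs", len(table), len(manifest))
    return table


def cmd_collate(config: RunConfig) -> pd.DataFrame:
    """Assemble E_QM and E_CH@r0 per pair into the interaction-record table."""
    manifest = _load_manifest(config)
    energies = read_energy_table(config.path / "energies.csv")
    snapshots = _load_snapshots(config)
    kernels = _load_kernels(config)

    dup = energies.duplicated(subset=["pair_id", "component", "r0"], keep=False)
    if dup.any():
        bad = energies.loc[dup, "pair_id"].unique()[:5]
        raise DataError(f"duplicate engine outputs for pairs {list(bad)}: ambiguous")

    by_pair = {pid: grp for pid, grp in energies.groupby("pair_id")}
    rows, missing = [], []
    for _, mrow in manifest.iterrows():
        replica, state, residue = mrow["snapshot"], mrow["state"], mrow["residue"]
        pid = _pair_id(replica, state, residue)
        grp = by_pair.get(pid)
        try:
            comp = _components(grp, pid, config.r0_grid)
        except DataError as exc:
            if config.allow_missing:
                missing.append(pid)
                continue
            raise
        snap = snapshots[(replica, state)]
        kernel = kernels[(replica, state)]
        res_pc = [a.as_point_charge() for a in _residue_atoms(snap, residue)]
        e_qm = assemble_qm_interaction(comp["pair"], comp["kernel"], comp["residue"])
        row = {
            "snapshot": replica,
            "state": state,
            "residue": residue,
            "distance": float(mrow["min_distance"]),
            "E_QM": e_qm,
        }
        for r0 in config.r0_grid:
            damped = apply_damping(res_pc, kernel.coords, DampingScheme(r0))
            row[ch_column(r0)] = assemble_ch_interaction(
                comp[("kernel_in_charges", r0)], comp["kernel_alone"], damped
            )
        rows.append(row)
    if missing:
        log.warning("collate: dropped %d pairs with missing energies", len(missing))
    records = pd.DataFrame(rows)
    records.to_csv(config.path / "records.csv", index=False, float_format="%.17g")
    log.info("collate: wrote %d records", len(records))
    return records


def _components(grp: pd.DataFrame | None, pid: str, r0_grid) -> dict:
    if grp is None:
        raise DataError(f"no engine energies for pair {pid}")
    out: dict = {}
    for comp in ("pair", "kernel", "residue", "kernel_alone"):
        sel = grp[grp["component"] == comp]
        if sel.empty:
            raise DataError(f"missing component {comp!r} for pair {pid}")
        out[comp] = float(sel["energy"].iloc[0])
    emb = grp[grp["component"] == "kernel_in_charges"]
    for r0 in r0_grid:
        sel = emb[np.isclose(emb["r0"].astype(float), r0)]
        if sel.empty:
            raise DataError(f"missing embedded total at r0={r0:g} for pair {pid}")
        out[("kernel_in_charges", float(r0))] = float(sel["energy"].iloc[0])
    return out


def cmd_calibrate(config: RunConfig) -> dict:
    """Scan r0 per state on the record table and write the calibration report."""
    rec_path = config.path / "records.csv"
    if not rec_path.exists():
        raise InputError(f"records table not found: {rec_path}; run collate first")
    records = pd.read_csv(rec_path, float_precision="round_trip")
    results = {}
    for state in config.states:
        if not (records["state"] == state).any():
            continue
        results[state] = scan_r0(
            records,
            state,
            dataset=config.path.name,
            truncation_mode=config.truncation_mode,
            threshold=config.truncation_threshold,
            exclude_residues=config.exclude_residues or None,
        )
    if not results:
        raise DataError("no records for any requested state")

    rec = recommend_defaults(config.q_rk)
    header = (
        f"chdamp {__version__} calibration report\n"
        f"config {config_hash(config)}  seed {config.seed}  Q_RK {config.q_rk:+d}\n"
        f"advisory defaults for Q_RK={config.q_rk:+d}: "
        f"r0 in [{rec.r0_range[0]:g}, {rec.r0_range[1]:g}] Å, "
        f"λ in [{rec.lambda_range[0]:g}, {rec.lambda_range[1]:g}] "
        f"({rec.note}; not applied automatically)\n\n"
    )
    report = header + format_report(results)
    (config.path / "report.txt").write_text(report)

    summary_rows = []
    for state, res in results.items():
        for s in res.summaries:
            summary_rows.append(
                {
                    "dataset": s.dataset, "state": s.state, "r0": s.r0,
                    "pearson_r": s.pearson_r, "rmse": s.rmse,
                    "sum_avg_E_qm": s.sum_avg_e_qm, "sum_avg_E_ch": s.sum_avg_e_ch,
                    "lambda": s.lam, "lambda_std": s.lam_std,
                    "n_pairs": s.n_pairs, "truncated": s.truncated,
                    "selected": s.r0 == res.optimal.r0,
                }
            )
    pd.DataFrame(summary_rows).to_csv(
        config.path / "calibration_summary.csv", index=False, float_format="%.17g"
    )
    log.info("calibrate: %s", {st: r.optimal.r0 for st, r in results.items()})
    return results
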