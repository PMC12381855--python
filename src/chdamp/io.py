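"""Structure and energy file I/O.

Reads macromolecular snapshots (PDB, PQR, XYZ with a companion charge table,
or the toolkit's own full-precision CSV dialect), writes engine-facing
embedding inputs in the Gaussian dialect (Cartesian block followed by a
trailing ``x y z q`` point-charge block), and parses engine energies from
Gaussian-style logs or CSV energy tables.

PDB/PQR/XYZ parsing is delegated to MDAnalysis; a light validation pass adds
file/line context to parse failures.  Coordinates are Å at every interface;
hartree totals are converted with 627.5095 kcal/mol per hartree.

The CSV snapshot dialect (columns ``element,x,y,z,charge,residue_id,
atom_label``, full double precision) is the pipeline's lossless machine
format; PDB/PQR round-trip at their own format precision (1e-3 Å).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .damping import PointCharge
from .errors import DataError, IncompleteCalculationError, InputError, ParseError

__all__ = [
    "HARTREE_TO_KCAL",
    "AtomRecord",
    "Snapshot",
    "read_structure",
    "write_structure",
    "write_embedding_input",
    "read_embedding_input",
    "read_point_charge_block",
    "read_total_energy",
    "read_energy_table",
    "write_energy_table",
    "ENERGY_TABLE_COLUMNS",
]

HARTREE_TO_KCAL = 627.5095

_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Mn", "Fe", "Co", "Ni", "Cu",
    "Zn", "Se", "Br", "I",
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom: element, position (Å), optional partial charge (e), labels."""

    element: str
    position: tuple[float, float, float]
    partial_charge: float | None = None
    residue_id: str = ""
    atom_label: str = ""

    def __post_init__(self) -> None:
        elem = str(self.element).strip()
        elem = elem[:1].upper() + elem[1:].lower()
        if elem not in _ELEMENTS:
            raise ValueError(f"unrecognized element symbol {self.element!r}")
        pos = tuple(float(x) for x in self.position)
        if len(pos) != 3 or not all(math.isfinite(x) for x in pos):
            raise ValueError(f"position must be a finite triple, got {self.position!r}")
        q = self.partial_charge
        if q is not None:
            q = float(q)
            if not math.isfinite(q):
                raise ValueError("partial charge must be finite")
        object.__setattr__(self, "element", elem)
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "partial_charge", q)

    def as_point_charge(self) -> PointCharge:
        if self.partial_charge is None:
            raise DataError(f"atom {self.atom_label!r} ({self.residue_id}) has no charge")
        return PointCharge(self.position, self.partial_charge, self.residue_id, self.atom_label)


@dataclass
class Snapshot:
    """A structure frame: atoms plus reaction-state and replica labels."""

    atoms: list[AtomRecord]
    state_label: str = "R"
    replica_id: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.state_label not in ("R", "TS"):
            raise ValueError(f"state_label must be 'R' or 'TS', got {self.state_label!r}")
        if not self.atoms:
            raise ValueError("a snapshot must contain at least one atom")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        if any(a.partial_charge is None for a in self.atoms):
            raise DataError(f"snapshot {self.source or self.replica_id!r} lacks partial charges")
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    @property
    def has_charges(self) -> bool:
        return all(a.partial_charge is not None for a in self.atoms)


# ---------------------------------------------------------------------------
# structure reading
# ---------------------------------------------------------------------------

def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("pdb", "pqr", "xyz", "csv"):
        return suffix
    raise InputError(f"cannot infer structure format from suffix {path.suffix!r}")


_PDB_FLOAT_SLICES = [slice(30, 38), slice(38, 46), slice(46, 54)]


def _validate_pdb_lines(path: Path) -> int:
    """Check fixed-width numeric fields of ATOM/HETATM records; return count."""
    n = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            n += 1
            if len(line.rstrip("\n")) < 54:
                raise ParseError("truncated ATOM/HETATM record", path, i)
            for sl in _PDB_FLOAT_SLICES:
                try:
                    float(line[sl])
                except ValueError:
                    raise ParseError(
                        f"malformed coordinate field {line[sl]!r}", path, i
                    ) from None
    return n


def _validate_pqr_lines(path: Path) -> int:
    n = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            n += 1
            fields = line.split()
            if len(fields) < 10:
                raise ParseError(
                    f"PQR record has {len(fields)} fields, expected >= 10", path, i
                )
            try:
                [float(x) for x in fields[-5:]]
            except ValueError:
                raise ParseError("malformed numeric field in PQR record", path, i) from None
    return n


def _load_charge_table(path) -> np.ndarray:
    """Two-column companion table (atom index, charge), joined by position order."""
    tbl = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    if tbl.shape[1] == 1:
        q = tbl.iloc[:, 0].to_numpy(dtype=float)
    else:
        tbl = tbl.sort_values(tbl.columns[0])
        q = tbl.iloc[:, 1].to_numpy(dtype=float)
    return q


def _mda_universe(path: Path, fmt: str):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return mda.Universe(str(path), format=fmt.upper())
        except ParseError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrap with file context
            raise ParseError(f"failed to parse {fmt.upper()} file: {exc}", path) from exc


_NON_ALPHA = re.compile(r"[^A-Za-z]")


def _element_from_mda(atom) -> str:
    try:
        elem = atom.element
        if elem:
            return elem
    except Exception:  # noqa: BLE001 - topology may lack elements
        pass
    name = _NON_ALPHA.sub("", atom.name)
    if len(name) >= 2 and name[:2].capitalize() in _ELEMENTS:
        # two-letter symbols only when unambiguous (Na, Cl, Fe ...), not e.g. HB2
        if name[:1].upper() not in _ELEMENTS or name[:2].capitalize() in ("Na", "Cl", "Mg", "Fe", "Zn", "Br"):
            return name[:2].capitalize()
    return name[:1].upper()


def read_structure(
    path,
    fmt: str | None = None,
    charge_table=None,
    require_charges: bool = False,
    state_label: str = "R",
    replica_id: str = "",
) -> Snapshot:
    """Read a snapshot from PDB, PQR, XYZ (+charge table) or CSV.

    ``charge_table`` is a two-column file (atom index, charge) joined by
    position order, for formats without a charge column.  With
    ``require_charges`` an input that yields chargeless atoms is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"structure file not found: {path}")
    fmt = (fmt or _guess_format(path)).lower()

    if fmt == "csv":
        snap = _read_structure_csv(path, state_label, replica_id)
    elif fmt in ("pdb", "pqr", "xyz"):
        n_expected = {"pdb": _validate_pdb_lines, "pqr": _validate_pqr_lines}.get(fmt)
        expected = n_expected(path) if n_expected else None
        u = _mda_universe(path, fmt)
        if expected is not None and len(u.atoms) != expected:
            raise ParseError(
                f"parser returned {len(u.atoms)} atoms for {expected} records", path
            )
        has_q = fmt == "pqr"
        charges = u.atoms.charges if has_q else [None] * len(u.atoms)
        atoms = []
        for atom, q in zip(u.atoms, charges):
            if fmt == "xyz":
                rid = "MOL:1"
                label = f"{atom.name}{atom.ix + 1}"
            else:
                res = atom.residue
                segid = getattr(atom, "chainID", "") or getattr(res, "segid", "").strip()
                icode = getattr(atom, "icode", "") if hasattr(atom, "icode") else ""
                rid = f"{segid}:{res.resname}{res.resid}{icode}".strip()
                label = atom.name
            atoms.append(
                AtomRecord(
                    element=_element_from_mda(atom),
                    position=tuple(float(x) for x in atom.position),
                    partial_charge=float(q) if q is not None else None,
                    residue_id=rid,
                    atom_label=label,
                )
            )
        snap = Snapshot(atoms, state_label, replica_id, str(path))
    else:
        raise InputError(f"unsupported structure format {fmt!r}")

    if charge_table is not None:
        q = _load_charge_table(charge_table)
        if len(q) != len(snap.atoms):
            raise DataError(
                f"charge table has {len(q)} entries for {len(snap.atoms)} atoms"
            )
        snap.atoms = [
            AtomRecord(a.element, a.position, float(qi), a.residue_id, a.atom_label)
            for a, qi in zip(snap.atoms, q)
        ]
    if require_charges and not snap.has_charges:
        raise DataError(
            f"{path} provides no partial charges; supply a PQR/CSV input or a charge table"
        )
    return snap


def _read_structure_csv(path: Path, state_label: str, replica_id: str) -> Snapshot:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"element", "x", "y", "z"}
    if not needed.issubset(df.columns):
        raise ParseError(f"CSV snapshot needs columns {sorted(needed)}", path)
    atoms = []
    for i, row in df.iterrows():
        try:
            q = row["charge"] if "charge" in df.columns and pd.notna(row["charge"]) else None
            atoms.append(
                AtomRecord(
                    element=str(row["element"]),
                    position=(float(row["x"]), float(row["y"]), float(row["z"])),
                    partial_charge=q,
                    residue_id=str(row.get("residue_id", "")),
                    atom_label=str(row.get("atom_label", f"A{i + 1}")),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"malformed atom row: {exc}", path, int(i) + 2) from exc
    return Snapshot(atoms, state_label, replica_id, str(path))


# ---------------------------------------------------------------------------
# structure writing
# ---------------------------------------------------------------------------

def write_structure(snapshot: Snapshot, path, fmt: str | None = None) -> None:
    """Write a snapshot as CSV (lossless), PQR or PDB."""
    path = Path(path)
    fmt = (fmt or _guess_format(path)).lower()
    if fmt == "csv":
        rows = [
            {
                "element": a.element,
                "x": a.position[0],
                "y": a.position[1],
                "z": a.position[2],
                "charge": a.partial_charge,
                "residue_id": a.residue_id,
                "atom_label": a.atom_label,
            }
            for a in snapshot.atoms
        ]
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    elif fmt == "pqr":
        _write_pqr(snapshot, path)
    elif fmt == "pdb":
        _write_pdb(snapshot, path)
    else:
        raise InputError(f"unsupported structure output format {fmt!r}")


def _split_residue_id(rid: str) -> tuple[str, str, int]:
    m = re.match(r"^(?:(\w*):)?([A-Za-z]+)(\d+)", rid or "")
    if m:
        return (m.group(1) or "A"), m.group(2)[:3], int(m.group(3))
    return "A", (rid or "UNK")[:3].upper() or "UNK", 1


def _write_pqr(snapshot: Snapshot, path: Path) -> None:
    # whitespace-delimited PQR; radius column filled with a nominal 1.5 Å
    with open(path, "w") as fh:
        fh.write("REMARK generated by chdamp\n")
        for i, a in enumerate(snapshot.atoms, start=1):
            _, resname, resid = _split_residue_id(a.residue_id)
            q = a.partial_charge if a.partial_charge is not None else 0.0
            fh.write(
                f"ATOM {i:6d} {a.atom_label or a.element:<4s} {resname:<4s} {resid:5d} "
                f"{a.position[0]:11.4f} {a.position[1]:11.4f} {a.position[2]:11.4f} "
                f"{q:9.4f} {1.5:7.4f}\n"
            )
        fh.write("END\n")


def _write_pdb(snapshot: Snapshot, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("REMARK   1 generated by chdamp\n")
        for i, a in enumerate(snapshot.atoms, start=1):
            chain, resname, resid = _split_residue_id(a.residue_id)
            name = (a.atom_label or a.element)[:4]
            fh.write(
                f"ATOM  {i:5d} {name:<4s}{resname:<4s}{(chain or 'A')[:1]}{resid:4d}    "
                f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# embedding inputs (Gaussian dialect)
# ---------------------------------------------------------------------------

def write_embedding_input(
    kernel,
    charges: Sequence[PointCharge],
    path,
    route: str = "#p sp charge",
    title: str = "chdamp embedding input",
) -> None:
    """Write a Gaussian-dialect input: route, title, charge/multiplicity,
    Cartesian block, then one ``x y z q`` record per point charge (6-decimal).

    ``kernel`` needs ``atoms`` (with element/position), ``net_charge`` and
    ``multiplicity`` attributes.  An empty charge list produces a bare-kernel
    input that is still syntactically valid.
    """
    if not kernel.atoms:
        raise DataError("kernel is empty: nothing to write")
    lines = [route.rstrip(), "", title.rstrip(), "", f"{kernel.net_charge} {kernel.multiplicity}"]
    for a in kernel.atoms:
        x, y, z = a.position
        lines.append(f" {a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    lines.append("")
    for c in charges:
        x, y, z = c.position
        lines.append(f" {x:14.6f} {y:14.6f} {z:14.6f} {c.charge:14.6f}")
    lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def read_embedding_input(path) -> dict:
    """Parse a Gaussian-dialect embedding input written by this toolkit.

    Returns a dict with keys ``route``, ``title``, ``net_charge``,
    ``multiplicity``, ``atoms`` (element, position tuples) and ``charges``
    (list of :class:`PointCharge`).
    """
    path = Path(path)
    text = path.read_text()
    blocks: list[list[str]] = [[]]
    for line in text.splitlines():
        if line.strip():
            blocks[-1].append(line)
        elif blocks[-1]:
            blocks.append([])
    blocks = [b for b in blocks if b]
    if len(blocks) < 3:
        raise ParseError("embedding input needs route, title and molecule blocks", path)
    route = "\n".join(blocks[0])
    title = "\n".join(blocks[1])
    mol = blocks[2]
    try:
        net_charge, multiplicity = (int(tok) for tok in mol[0].split())
    except ValueError as exc:
        raise ParseError(f"malformed charge/multiplicity line {mol[0]!r}", path) from exc
    atoms = []
    for line in mol[1:]:
        tok = line.split()
        if len(tok) != 4:
            raise ParseError(f"malformed Cartesian line {line!r}", path)
        atoms.append((tok[0], (float(tok[1]), float(tok[2]), float(tok[3]))))
    charges = read_point_charge_block(blocks[3]) if len(blocks) > 3 else []
    return {
        "route": route,
        "title": title,
        "net_charge": net_charge,
        "multiplicity": multiplicity,
        "atoms": atoms,
        "charges": charges,
    }


def read_point_charge_block(lines: Sequence[str]) -> list[PointCharge]:
    """Parse ``x y z q`` point-charge records (one per line)."""
    out = []
    for line in lines:
        tok = line.split()
        if len(tok) != 4:
            raise ParseError(f"point-charge record needs 4 fields, got {line!r}")
        x, y, z, q = (float(t) for t in tok)
        out.append(PointCharge((x, y, z), q))
    return out


# ---------------------------------------------------------------------------
# engine energies
# ---------------------------------------------------------------------------

_SCF_RE = re.compile(r"SCF Done:\s+E\([^)]*\)\s*=\s*([-+]?\d*\.?\d+(?:[DdEe][-+]?\d+)?)")


def read_total_energy(path, fmt: str | None = None) -> float:
    """Return the last converged total energy from an engine output, kcal/mol.

    ``fmt`` is ``"gaussian-log"`` or ``"csv-table"`` (inferred from the suffix
    when omitted: .log/.out -> log, .csv -> table).  Hartree values are
    converted with 627.5095 kcal/mol per hartree; the last record wins.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"energy file not found: {path}")
    if fmt is None:
        fmt = "csv-table" if path.suffix.lower() == ".csv" else "gaussian-log"
    if fmt == "gaussian-log":
        matches = _SCF_RE.findall(path.read_text())
        if not matches:
            raise IncompleteCalculationError(f"no final SCF energy found in {path}")
        hartree = float(matches[-1].replace("D", "E").replace("d", "e"))
        return hartree * HARTREE_TO_KCAL
    if fmt == "csv-table":
        df = read_energy_table(path)
        if df.empty:
            raise IncompleteCalculationError(f"no energy rows in {path}")
        row = df.iloc[-1]
        return _to_kcal(float(row["energy"]), str(row["unit"]))
    raise InputError(f"unknown energy format {fmt!r}")


def _to_kcal(value: float, unit: str) -> float:
    unit = unit.strip().lower()
    if unit in ("kcal/mol", "kcal_mol", "kcal"):
        return value
    if unit in ("hartree", "au", "a.u."):
        return value * HARTREE_TO_KCAL
    raise DataError(f"unknown energy unit {unit!r}")


ENERGY_TABLE_COLUMNS = ["pair_id", "component", "r0", "energy", "unit"]

_COMPONENTS = {"pair", "kernel", "residue", "kernel_in_charges", "kernel_alone"}


def read_energy_table(path) -> pd.DataFrame:
    """Read the CSV energy-table schema (pair_id, component, r0, energy, unit)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"energy"} - set(df.columns)
    if missing:
        raise ParseError(f"energy table lacks columns {sorted(missing)}", path)
    if "unit" not in df.columns:
        df["unit"] = "kcal/mol"
    if "component" in df.columns:
        bad = set(df["component"].dropna().unique()) - _COMPONENTS
        if bad:
            raise DataError(f"unknown energy components {sorted(bad)} in {path}")
    if "r0" not in df.columns:
        df["r0"] = np.nan
    return df


def write_energy_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in ENERGY_TABLE_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols, float_format="%.17g")
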