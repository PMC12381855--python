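"""Reaction-kernel definition, environment carving and bond capping.

The reaction kernel (RK) is the QM-treated reacting moiety with an integer
net charge Q_RK and a spin multiplicity.  Around it, every residue (waters
included) with any atom within a cutoff — 12 Å by default — of any kernel
atom is carved out of the scaffold and paired with the kernel, coordinates
untouched.  Bonds severed when truncating the kernel are saturated with
hydrogen caps placed along the original bond vector at a standard X-H length.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .damping import PointCharge
from .errors import DataError
from .io import AtomRecord, Snapshot

__all__ = [
    "ReactionKernel",
    "ResiduePairTask",
    "select_environment",
    "cap_severed_bonds",
    "residues_to_charges",
    "CAP_BOND_LENGTHS",
    "DEFAULT_CAP_LENGTH",
]

# standard X-H bond lengths (Å) for hydrogen caps on severed bonds
CAP_BOND_LENGTHS = {"C": 1.09, "N": 1.01, "O": 0.96}
DEFAULT_CAP_LENGTH = 1.00


@dataclass
class ReactionKernel:
    """The QM-treated reacting moiety.

    ``cap_flags[i]`` marks atom ``i`` as a hydrogen cap added on a severed
    bond; ``source_indices`` registers non-cap atoms against the snapshot
    they were selected from (caps carry index -1).
    """

    atoms: list[AtomRecord]
    net_charge: int
    multiplicity: int = 1
    cap_flags: list[bool] = field(default_factory=list)
    source_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a reaction kernel must contain at least one atom")
        if int(self.net_charge) != self.net_charge:
            raise ValueError(f"Q_RK must be an integer, got {self.net_charge!r}")
        self.net_charge = int(self.net_charge)
        if self.multiplicity < 1:
            raise ValueError(f"multiplicity must be >= 1, got {self.multiplicity!r}")
        if not self.cap_flags:
            self.cap_flags = [False] * len(self.atoms)
        if len(self.cap_flags) != len(self.atoms):
            raise ValueError("cap_flags length must match atoms")
        if not self.source_indices:
            self.source_indices = [-1] * len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) positions of every kernel atom, caps included — the nearest-
        atom distance convention uses all of them."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def point_charges(self) -> list[PointCharge]:
        return [a.as_point_charge() for a in self.atoms]

    @classmethod
    def from_snapshot(
        cls,
        snapshot: Snapshot,
        indices: Sequence[int],
        net_charge: int | None = None,
        multiplicity: int = 1,
    ) -> "ReactionKernel":
        """Build a kernel from snapshot atom indices (0-based).

        Without an explicit ``net_charge`` the summed partial charges are
        rounded to the nearest integer (and must be within 0.01 e of it).
        """
        indices = sorted(set(int(i) for i in indices))
        if not indices:
            raise DataError("empty kernel selection")
        n = len(snapshot.atoms)
        if indices[0] < 0 or indices[-1] >= n:
            raise DataError(f"kernel selection index out of range for {n} atoms")
        atoms = [snapshot.atoms[i] for i in indices]
        if net_charge is None:
            total = sum(a.partial_charge or 0.0 for a in atoms)
            net_charge = round(total)
            if abs(total - net_charge) > 0.01:
                raise DataError(
                    f"kernel charges sum to {total:.4f} e, not close to an integer; "
                    "pass net_charge explicitly"
                )
        return cls(atoms, net_charge, multiplicity, source_indices=list(indices))


@dataclass
class ResiduePairTask:
    """One kernel-residue doublet to be evaluated: the residue atoms and the
    nearest residue-atom-to-kernel-atom distance."""

    snapshot: str
    state: str
    kernel_label: str
    residue_id: str
    residue_atoms: list[AtomRecord]
    min_distance: float

    def __post_init__(self) -> None:
        if not self.residue_atoms:
            raise ValueError("a pair task needs at least one residue atom")
        if not (math.isfinite(self.min_distance) and self.min_distance >= 0):
            raise ValueError(f"invalid min_distance {self.min_distance!r}")


def select_environment(
    snapshot: Snapshot,
    kernel: ReactionKernel,
    cutoff: float = 12.0,
    kernel_label: str = "RK",
) -> list[ResiduePairTask]:
    """Select every residue with any atom within ``cutoff`` Å of any kernel atom.

    Kernel-member atoms (registered via ``source_indices``) are excluded from
    the environment; waters count as residues like any other.  Tasks are
    sorted by residue id.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff!r}")
    n = len(snapshot.atoms)
    member = set(i for i in kernel.source_indices if i >= 0)
    if any(i >= n for i in member):
        raise DataError("kernel is not registered against this snapshot (index mismatch)")
    kern_coords = kernel.coords

    by_residue: dict[str, list[int]] = {}
    for i, atom in enumerate(snapshot.atoms):
        if i in member:
            continue
        by_residue.setdefault(atom.residue_id, []).append(i)

    coords = snapshot.coords
    tasks = []
    for rid in sorted(by_residue):
        idx = by_residue[rid]
        d = cdist(coords[idx], kern_coords).min()
        if d <= cutoff:
            tasks.append(
                ResiduePairTask(
                    snapshot=snapshot.replica_id or snapshot.source,
                    state=snapshot.state_label,
                    kernel_label=kernel_label,
                    residue_id=rid,
                    residue_atoms=[snapshot.atoms[i] for i in idx],
                    min_distance=float(d),
                )
            )
    return tasks


def cap_severed_bonds(
    kernel: ReactionKernel,
    severed_bonds: Sequence[tuple[int, int]],
    snapshot: Snapshot,
) -> ReactionKernel:
    """Saturate severed bonds with hydrogen caps.

    Each bond is a pair of snapshot atom indices with exactly one endpoint
    inside the kernel.  The cap hydrogen sits on the inside->outside bond
    vector at a standard X-H length (C-H 1.09, N-H 1.01, O-H 0.96, else
    1.00 Å), carries zero partial charge, and is flagged; Q_RK and the
    multiplicity are preserved.
    """
    if not severed_bonds:
        return kernel
    inside = {idx: pos for pos, idx in enumerate(kernel.source_indices) if idx >= 0}
    new_atoms = list(kernel.atoms)
    new_flags = list(kernel.cap_flags)
    new_src = list(kernel.source_indices)
    for a, b in severed_bonds:
        a, b = int(a), int(b)
        in_a, in_b = a in inside, b in inside
        if in_a == in_b:
            side = "inside" if in_a else "outside"
            raise DataError(
                f"bond ({a}, {b}) has both endpoints {side} the kernel; nothing severed"
            )
        i_in, i_out = (a, b) if in_a else (b, a)
        atom_in = kernel.atoms[inside[i_in]]
        atom_out = snapshot.atoms[i_out]
        vec = np.asarray(atom_out.position, float) - np.asarray(atom_in.position, float)
        norm = float(np.linalg.norm(vec))
        if norm < 1e-9:
            raise DataError(f"severed bond ({a}, {b}) endpoints coincide")
        length = CAP_BOND_LENGTHS.get(atom_in.element, DEFAULT_CAP_LENGTH)
        pos = np.asarray(atom_in.position, float) + vec * (length / norm)
        new_atoms.append(
            AtomRecord(
                element="H",
                position=tuple(pos),
                partial_charge=0.0,
                residue_id=atom_in.residue_id,
                atom_label=f"HCAP{len(new_atoms) + 1}",
            )
        )
        new_flags.append(True)
        new_src.append(-1)
    return ReactionKernel(
        new_atoms, kernel.net_charge, kernel.multiplicity, new_flags, new_src
    )


def residues_to_charges(
    task: ResiduePairTask,
    charge_source: Mapping[str, float] | Sequence[float] | None = None,
) -> list[PointCharge]:
    """Replace a residue by its point-charge representation, order preserved.

    Charges come from the atoms' own ``partial_charge`` fields, or from
    ``charge_source`` — either a sequence aligned with the residue atoms or a
    mapping keyed by atom label.  Any atom lacking a charge is an error.
    """
    atoms = task.residue_atoms
    if charge_source is None:
        return [a.as_point_charge() for a in atoms]
    if isinstance(charge_source, Mapping):
        out = []
        for a in atoms:
            if a.atom_label not in charge_source:
                raise DataError(f"no charge for atom {a.atom_label!r} in {task.residue_id}")
            out.append(PointCharge(a.position, float(charge_source[a.atom_label]),
                                   a.residue_id, a.atom_label))
        return out
    charge_source = list(charge_source)
    if len(charge_source) != len(atoms):
        raise DataError(
            f"charge source has {len(charge_source)} values for {len(atoms)} atoms"
        )
    return [
        PointCharge(a.position, float(q), a.residue_id, a.atom_label)
        for a, q in zip(atoms, charge_source)
    ]
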