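"""Classical Coulomb energies and interaction-energy assembly.

The toolkit compares three treatments of a kernel-residue pair:

* QM reference: ``E_int = E_pair - E_A(cp) - E_B(cp)`` where the monomer
  totals are counterpoise (BSSE) corrected by the external engine.
* CH / CH-d embedding: ``E_int = E(kernel in charges) - E(kernel alone)
  - E_self(charges)``, subtracting the Coulomb energy of the self-interacting
  point-charge set that most engines fold into the embedded total.

Energies are kcal/mol throughout; the Coulomb constant is
k = 332.0637 kcal Å mol^-1 e^-2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .damping import PointCharge, charge_coords, charge_values
from .errors import DataError

__all__ = [
    "COULOMB_K",
    "MIN_DISTANCE",
    "InteractionRecord",
    "coulomb_cross_energy",
    "charge_self_energy",
    "assemble_qm_interaction",
    "assemble_ch_interaction",
    "records_to_frame",
    "frame_to_records",
    "ch_column",
    "ch_columns",
]

COULOMB_K = 332.0637  # kcal * Å / (mol * e^2)

# distances below this are treated as coincident charges (data error, not inf)
MIN_DISTANCE = 1e-6


@dataclass
class InteractionRecord:
    """One kernel-residue pair's reference and approximate interaction energies.

    ``e_ch`` maps the damping range r0 (Å) to the embedded interaction energy;
    the ``r0 = 0`` entry is the plain-CH value and must be present whenever
    the map is non-empty.
    """

    snapshot: str
    state: str
    residue_id: str
    e_qm: float
    e_ch: dict[float, float] = field(default_factory=dict)
    min_distance: float = float("nan")

    def __post_init__(self) -> None:
        if self.state not in ("R", "TS"):
            raise ValueError(f"state must be 'R' or 'TS', got {self.state!r}")
        if not math.isfinite(self.e_qm):
            raise ValueError("E_QM must be finite")
        if self.e_ch and 0.0 not in self.e_ch:
            raise ValueError("the r0 = 0 (plain CH) entry is required in e_ch")
        for r0, e in self.e_ch.items():
            if not math.isfinite(e):
                raise ValueError(f"E_CH@{r0:g} must be finite")


def _check_separations(d: np.ndarray) -> None:
    if d.size and float(d.min()) < MIN_DISTANCE:
        raise DataError(
            f"coincident charges (separation {float(d.min()):.3e} Å < {MIN_DISTANCE} Å); "
            "Coulomb term is singular"
        )


def coulomb_cross_energy(
    set_a: Sequence[PointCharge], set_b: Sequence[PointCharge]
) -> float:
    """Coulomb interaction between two disjoint point-charge sets (kcal/mol)."""
    if len(set_a) == 0 or len(set_b) == 0:
        return 0.0
    d = cdist(charge_coords(set_a), charge_coords(set_b))
    _check_separations(d)
    qq = np.outer(charge_values(set_a), charge_values(set_b))
    return float(COULOMB_K * np.sum(qq / d))


def charge_self_energy(charges: Sequence[PointCharge]) -> float:
    """Coulomb energy of a point-charge set with itself (sum over i < j)."""
    n = len(charges)
    if n < 2:
        return 0.0
    d = pdist(charge_coords(charges))
    _check_separations(d)
    q = charge_values(charges)
    iu, ju = np.triu_indices(n, k=1)
    return float(COULOMB_K * np.sum(q[iu] * q[ju] / d))


def _finite(*values: float) -> None:
    for v in values:
        if not math.isfinite(float(v)):
            raise DataError(f"non-finite energy in assembly: {values!r}")


def assemble_qm_interaction(e_pair: float, e_a_cp: float, e_b_cp: float) -> float:
    """Reference interaction energy from dimer and counterpoise-corrected monomer totals."""
    _finite(e_pair, e_a_cp, e_b_cp)
    return float(e_pair) - float(e_a_cp) - float(e_b_cp)


def assemble_ch_interaction(
    e_kernel_in_charges: float,
    e_kernel_alone: float,
    charges: Sequence[PointCharge],
    subtract_self_energy: bool = True,
) -> float:
    """Embedded interaction energy from kernel totals with/without the charges.

    ``charges`` must be the exact (already damped, if CH-d) set used in the
    embedded run.  Engines differ in whether the reported total includes the
    charge-charge self energy; ``subtract_self_energy`` (default True) controls
    the correction.
    """
    _finite(e_kernel_in_charges, e_kernel_alone)
    e = float(e_kernel_in_charges) - float(e_kernel_alone)
    if subtract_self_energy:
        e -= charge_self_energy(charges)
    return e


# ---------------------------------------------------------------------------
# tabular form: one row per kernel-residue pair, one column per scheme
# ---------------------------------------------------------------------------

_BASE_COLUMNS = ["snapshot", "state", "residue", "distance", "E_QM"]


def ch_column(r0: float) -> str:
    """Column name for the embedded energy at damping range ``r0``."""
    return f"E_CH@{float(r0):g}"


def ch_columns(frame: pd.DataFrame) -> dict[float, str]:
    """Map r0 -> column name for every embedded-energy column, sorted by r0."""
    out: dict[float, str] = {}
    for col in frame.columns:
        if isinstance(col, str) and col.startswith("E_CH@"):
            out[float(col.split("@", 1)[1])] = col
    return dict(sorted(out.items()))


def records_to_frame(records: Sequence[InteractionRecord]) -> pd.DataFrame:
    """Serialize records to the tabular schema (snapshot, state, residue,
    distance, E_QM, E_CH@r0...)."""
    if not records:
        return pd.DataFrame(columns=_BASE_COLUMNS)
    grids = {tuple(sorted(r.e_ch)) for r in records}
    if len(grids) > 1:
        raise DataError(f"inconsistent r0 grids across records: {sorted(grids)}")
    rows = []
    for r in records:
        row = {
            "snapshot": r.snapshot,
            "state": r.state,
            "residue": r.residue_id,
            "distance": r.min_distance,
            "E_QM": r.e_qm,
        }
        for r0 in sorted(r.e_ch):
            row[ch_column(r0)] = r.e_ch[r0]
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[InteractionRecord]:
    cols = ch_columns(frame)
    out = []
    for _, row in frame.iterrows():
        out.append(
            InteractionRecord(
                snapshot=str(row["snapshot"]),
                state=str(row["state"]),
                residue_id=str(row["residue"]),
                e_qm=float(row["E_QM"]),
                e_ch={r0: float(row[col]) for r0, col in cols.items()},
                min_distance=float(row.get("distance", float("nan"))),
            )
        )
    return out
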