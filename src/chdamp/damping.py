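"""Sigmoidal charge damping for electrostatic embedding (the CH-d scheme).

Electrostatic embedding represents the environment of a quantum-mechanically
treated reaction kernel as fixed point charges.  Because the embedding carries
no Pauli repulsion, positive charges close to the kernel over-polarize its
electron density ("electron spill-out"), and the resulting interaction
energies are overestimated at short range.  The CH-d remedy attenuates each
point charge according to its distance ``r`` from the nearest kernel atom with
a sigmoidal ramp

    d(r) = 1 / (1 + exp((r - d_c) / d_w)),

where the center ``d_c = r0/2`` and the width ``d_w = d_c / ln(100)`` both
derive from a single tunable parameter, the damping range ``r0``.  A charge is
scaled multiplicatively by ``1 - d(r)``: at ``r = 0`` it is reduced to
~1/101 of its value, at ``r = d_c`` it is halved, and at ``r = r0`` it is
restored to 100/101 of its value — beyond the damping range charges are
effectively unscaled.  ``r0 = 0`` encodes "damping disabled" (plain CH).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DataError

__all__ = [
    "LN100",
    "DampingScheme",
    "PointCharge",
    "damping_value",
    "scale_factor",
    "apply_damping",
    "nearest_kernel_distance",
    "charge_coords",
    "charge_values",
    "point_charges_from_arrays",
]

LN100 = math.log(100.0)

# beyond this argument exp() is effectively infinite in double precision;
# clamping avoids overflow warnings while leaving d(r) exactly 0.0/1.0
_EXP_CLAMP = 700.0


@dataclass(frozen=True)
class DampingScheme:
    """The r0-parameterized sigmoidal damping scheme.

    Parameters
    ----------
    r0 : float
        Damping range in Å.  Must be >= 0; ``r0 = 0`` disables damping
        (plain point-charge embedding, CH).
    """

    r0: float = 0.0

    def __post_init__(self) -> None:
        r0 = float(self.r0)
        if not math.isfinite(r0) or r0 < 0.0:
            raise ValueError(f"damping range r0 must be finite and >= 0, got {self.r0!r}")
        object.__setattr__(self, "r0", r0)

    @property
    def enabled(self) -> bool:
        return self.r0 > 0.0

    @property
    def d_c(self) -> float:
        """Ramp center in Å (r0/2).  Undefined for a disabled scheme."""
        self._require_enabled()
        return 0.5 * self.r0

    @property
    def d_w(self) -> float:
        """Ramp width in Å (d_c / ln 100).  Undefined for a disabled scheme."""
        return self.d_c / LN100

    def _require_enabled(self) -> None:
        if not self.enabled:
            raise ValueError(
                "damping is disabled (r0 = 0); the sigmoid parameters are not defined"
            )


@dataclass(frozen=True)
class PointCharge:
    """A fixed partial charge at a Cartesian position (the MM embedding unit).

    Positions are in Å, charges in elementary-charge units.  ``residue_id``
    and ``atom_label`` are opaque grouping labels.
    """

    position: tuple[float, float, float]
    charge: float
    residue_id: str = ""
    atom_label: str = ""

    def __post_init__(self) -> None:
        pos = tuple(float(x) for x in self.position)
        if len(pos) != 3 or not all(math.isfinite(x) for x in pos):
            raise ValueError(f"position must be a finite Cartesian triple, got {self.position!r}")
        q = float(self.charge)
        if not math.isfinite(q):
            raise ValueError(f"charge must be finite, got {self.charge!r}")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "charge", q)

    def scaled(self, factor: float) -> "PointCharge":
        return PointCharge(self.position, self.charge * factor, self.residue_id, self.atom_label)


def charge_coords(charges: Sequence[PointCharge]) -> np.ndarray:
    """(n, 3) float64 coordinate array for a charge list."""
    if len(charges) == 0:
        return np.empty((0, 3), dtype=float)
    return np.array([c.position for c in charges], dtype=float)


def charge_values(charges: Sequence[PointCharge]) -> np.ndarray:
    return np.array([c.charge for c in charges], dtype=float)


def point_charges_from_arrays(
    coords: np.ndarray,
    charges: np.ndarray,
    residue_ids: Sequence[str] | None = None,
    atom_labels: Sequence[str] | None = None,
) -> list[PointCharge]:
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    charges = np.asarray(charges, dtype=float).ravel()
    if coords.shape[0] != charges.shape[0]:
        raise ValueError("coords and charges must have matching lengths")
    n = coords.shape[0]
    rid = residue_ids if residue_ids is not None else [""] * n
    lab = atom_labels if atom_labels is not None else [""] * n
    return [
        PointCharge(tuple(coords[i]), float(charges[i]), str(rid[i]), str(lab[i]))
        for i in range(n)
    ]


def _validated_distances(r) -> tuple[np.ndarray, bool]:
    arr = np.asarray(r, dtype=float)
    scalar = arr.ndim == 0
    if np.any(~np.isfinite(arr)) or np.any(arr < 0.0):
        raise ValueError("distances must be finite and >= 0")
    return np.atleast_1d(arr), scalar


def damping_value(r, scheme: DampingScheme):
    """Evaluate the sigmoidal damping function d(r) for an enabled scheme.

    Strictly decreasing in ``r``: d(0) = 100/101, d(d_c) = 1/2, d(r0) = 1/101.
    Accepts a scalar or array of distances (Å); returns the matching shape.
    """
    scheme._require_enabled()
    arr, scalar = _validated_distances(r)
    x = np.clip((arr - scheme.d_c) / scheme.d_w, -_EXP_CLAMP, _EXP_CLAMP)
    d = 1.0 / (1.0 + np.exp(x))
    return float(d[0]) if scalar else d.reshape(np.shape(r))


def scale_factor(r, scheme: DampingScheme):
    """Multiplicative charge attenuation factor, ``1 - d(r)``.

    Returns 1.0 for a disabled scheme (plain CH).  Strictly increasing in
    ``r`` and -> 1 as r -> infinity: charges beyond r0 are effectively
    unscaled (1 - d(r0) = 100/101).
    """
    arr, scalar = _validated_distances(r)
    if not scheme.enabled:
        ones = np.ones_like(arr)
        return 1.0 if scalar else ones.reshape(np.shape(r))
    s = 1.0 - damping_value(arr, scheme)
    return float(s[0]) if scalar else s.reshape(np.shape(r))


def nearest_kernel_distance(position, kernel_atoms) -> float:
    """Minimum Euclidean distance (Å) from ``position`` to any kernel atom."""
    kern = np.asarray(kernel_atoms, dtype=float).reshape(-1, 3)
    if kern.shape[0] == 0:
        raise DataError("reaction kernel is empty: cannot compute nearest-atom distance")
    pos = np.asarray(position, dtype=float).reshape(3)
    return float(np.min(np.linalg.norm(kern - pos, axis=1)))


def apply_damping(
    charges: Iterable[PointCharge],
    kernel_atoms,
    scheme: DampingScheme,
) -> list[PointCharge]:
    """Attenuate each point charge by its distance to the nearest kernel atom.

    Each output charge is ``q * scale_factor(min_a |x - x_a|)``; positions and
    labels are untouched and the input order is preserved.  With a disabled
    scheme the charges are returned unscaled.
    """
    charges = list(charges)
    kern = np.asarray(kernel_atoms, dtype=float).reshape(-1, 3)
    if kern.shape[0] == 0:
        raise DataError("reaction kernel is empty: unusable selection")
    if not charges:
        return []
    if not scheme.enabled:
        return [c.scaled(1.0) for c in charges]
    dists = cdist(charge_coords(charges), kern).min(axis=1)
    factors = scale_factor(dists, scheme)
    return [c.scaled(float(f)) for c, f in zip(charges, factors)]
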