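"""Unit cells, space-group symmetry and Miller-index arithmetic.

This module is the substrate for every pipeline stage: d-spacing from the
reciprocal metric tensor, mapping of Miller indices to a canonical
asymmetric-unit (ASU) representative under the Laue group, systematic-absence
tests derived from the operator table, and generation of the complete unique
reflection set to a resolution limit.

Space groups are represented by explicit operator tables (rotation matrix +
translation vector in fractional coordinates).  Only the groups the merging
pipeline needs are tabulated (P1, P212121, C2221); the downstream code depends
only on the Laue operations and the absence rule, both of which are derived
from the table rather than hard-coded per group.

Conventions
-----------
* Miller indices are plain integer triples; ``(0, 0, 0)`` is never a valid
  observation index.
* The canonical ASU representative is the lexicographically greatest tuple
  among all symmetry equivalents (Friedel mate included when merging is
  requested).  For an mmm Laue group this yields ``h >= 0, k >= 0, l >= 0``.
* d-spacings are in Angstrom throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "UnitCell",
    "SpaceGroupInfo",
    "space_group",
    "d_spacing",
    "d_spacing_array",
    "map_to_asu",
    "map_to_asu_array",
    "is_absent",
    "is_absent_array",
    "generate_complete_set",
]


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell (lengths in Angstrom, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError(f"cell lengths must be positive: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angles must lie in (0, 180): {self}")
        # positive-definiteness of the metric tensor rejects impossible
        # angle combinations (e.g. alpha + beta + gamma too close to 360)
        if np.linalg.det(self.metric_tensor()) <= 0:
            raise ValueError(f"cell metric is not positive definite: {self}")

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric tensor G (3x3, Angstrom^2)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in self.angles)
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def reciprocal_metric_tensor(self) -> np.ndarray:
        """Reciprocal metric tensor G* = G^-1 (Angstrom^-2)."""
        return np.linalg.inv(self.metric_tensor())

    def volume(self) -> float:
        return float(math.sqrt(np.linalg.det(self.metric_tensor())))

    def to_tuple(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


# ---------------------------------------------------------------------------
# Space groups
# ---------------------------------------------------------------------------

def _op(rot: Sequence[Sequence[int]], trans: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    return np.asarray(rot, dtype=int), np.asarray(trans, dtype=float)


_I3 = ((1, 0, 0), (0, 1, 0), (0, 0, 1))

# International Tables operator lists.  C-centred groups carry the centring
# translation explicitly so that the table alone defines the absences.
_SG_TABLE: dict[str, dict] = {
    "P1": {
        "ops": [_op(_I3, (0, 0, 0))],
        "centering": "P",
    },
    "P212121": {
        "ops": [
            _op(_I3, (0, 0, 0)),
            _op(((-1, 0, 0), (0, -1, 0), (0, 0, 1)), (0.5, 0, 0.5)),
            _op(((-1, 0, 0), (0, 1, 0), (0, 0, -1)), (0, 0.5, 0.5)),
            _op(((1, 0, 0), (0, -1, 0), (0, 0, -1)), (0.5, 0.5, 0)),
        ],
        "centering": "P",
    },
    "C2221": {
        "ops": [
            _op(_I3, (0, 0, 0)),
            _op(((-1, 0, 0), (0, -1, 0), (0, 0, 1)), (0, 0, 0.5)),
            _op(((-1, 0, 0), (0, 1, 0), (0, 0, -1)), (0, 0, 0.5)),
            _op(((1, 0, 0), (0, -1, 0), (0, 0, -1)), (0, 0, 0)),
        ],
        "centering": "C",
    },
}

_ALIASES = {
    "P 1": "P1",
    "P 21 21 21": "P212121",
    "C 2 2 21": "C2221",
    "C 2 2 2 1": "C2221",
    "C2 2 21": "C2221",
}


def _expand_centering(ops, centering):
    if centering == "P":
        return list(ops)
    if centering == "C":
        shift = np.array([0.5, 0.5, 0.0])
        out = list(ops)
        for rot, trans in ops:
            out.append((rot, (trans + shift) % 1.0))
        return out
    raise ValueError(f"unsupported centering {centering!r}")


@dataclass(frozen=True)
class SpaceGroupInfo:
    """Space-group operator table plus derived Laue operations.

    ``symmetry_ops`` is the full list of (rotation, translation) pairs,
    centring included.  ``laue_ops`` are the unique rotation parts closed
    under inversion (the Laue group); ``point_ops`` are the rotation parts
    without the added inversion, used when Friedel mates are kept separate.
    """

    symbol: str
    symmetry_ops: tuple = field(repr=False)
    centering: str = "P"

    @property
    def n_ops(self) -> int:
        return len(self.symmetry_ops)

    def _unique_rotations(self, with_inversion: bool) -> tuple[np.ndarray, ...]:
        seen: dict[bytes, np.ndarray] = {}
        rots = [rot for rot, _ in self.symmetry_ops]
        if with_inversion:
            rots = rots + [-rot for rot in rots]
        for rot in rots:
            seen.setdefault(rot.tobytes(), rot)
        return tuple(seen.values())

    @property
    def point_ops(self) -> tuple[np.ndarray, ...]:
        return self._unique_rotations(with_inversion=False)

    @property
    def laue_ops(self) -> tuple[np.ndarray, ...]:
        return self._unique_rotations(with_inversion=True)


def space_group(symbol: str) -> SpaceGroupInfo:
    """Look up a supported space group by Hermann-Mauguin symbol."""
    key = symbol.strip()
    key = _ALIASES.get(key, key.replace(" ", ""))
    key = _ALIASES.get(key, key)
    if key not in _SG_TABLE:
        raise ValueError(
            f"unsupported space group {symbol!r}; supported: {sorted(_SG_TABLE)}"
        )
    entry = _SG_TABLE[key]
    ops = _expand_centering(entry["ops"], entry["centering"])
    return SpaceGroupInfo(
        symbol=key,
        symmetry_ops=tuple((rot, trans) for rot, trans in ops),
        centering=entry["centering"],
    )


# ---------------------------------------------------------------------------
# d-spacing
# ---------------------------------------------------------------------------

def d_spacing(cell: UnitCell, hkl: Sequence[int]) -> float:
    """Resolution d (Angstrom) of one reflection: 1/d^2 = h G* h^T."""
    h = np.asarray(hkl, dtype=float)
    if not np.any(h):
        raise ValueError("d-spacing undefined for hkl = (0, 0, 0)")
    inv_d2 = float(h @ cell.reciprocal_metric_tensor() @ h)
    return 1.0 / math.sqrt(inv_d2)


def d_spacing_array(cell: UnitCell, hkl: np.ndarray) -> np.ndarray:
    """Vectorised d-spacing for an (N, 3) integer index array."""
    hkl = np.asarray(hkl, dtype=float)
    if hkl.ndim != 2 or hkl.shape[1] != 3:
        raise ValueError("hkl must be an (N, 3) array")
    if np.any(~hkl.any(axis=1)):
        raise ValueError("d-spacing undefined for hkl = (0, 0, 0)")
    gstar = cell.reciprocal_metric_tensor()
    inv_d2 = np.einsum("ni,ij,nj->n", hkl, gstar, hkl)
    return 1.0 / np.sqrt(inv_d2)


# ---------------------------------------------------------------------------
# ASU mapping
# ---------------------------------------------------------------------------

def _equivalents_ops(sg: SpaceGroupInfo, merge_friedel: bool):
    return sg.laue_ops if merge_friedel else sg.point_ops


def map_to_asu_array(
    hkl: np.ndarray, sg: SpaceGroupInfo, merge_friedel: bool = True
) -> np.ndarray:
    """Canonical ASU representative for each row of an (N, 3) index array.

    Indices transform as row vectors: ``h' = h R``.  The representative is
    the lexicographically greatest equivalent, which for mmm gives the
    all-non-negative octant.
    """
    hkl = np.asarray(hkl, dtype=int)
    single = hkl.ndim == 1
    hkl = np.atleast_2d(hkl)
    if np.any(~hkl.any(axis=1)):
        raise ValueError("cannot map hkl = (0, 0, 0)")
    best = None
    for rot in _equivalents_ops(sg, merge_friedel):
        cand = hkl @ rot
        if best is None:
            best = cand.copy()
            continue
        c0, c1, c2 = cand[:, 0], cand[:, 1], cand[:, 2]
        b0, b1, b2 = best[:, 0], best[:, 1], best[:, 2]
        better = (c0 > b0) | (
            (c0 == b0) & ((c1 > b1) | ((c1 == b1) & (c2 > b2)))
        )
        best[better] = cand[better]
    return best[0] if single else best


def map_to_asu(
    hkl: Sequence[int], sg: SpaceGroupInfo, merge_friedel: bool = True
) -> tuple[int, int, int]:
    """Canonical ASU representative of a single Miller index."""
    out = map_to_asu_array(np.asarray(hkl, dtype=int), sg, merge_friedel)
    return (int(out[0]), int(out[1]), int(out[2]))


# ---------------------------------------------------------------------------
# Systematic absences
# ---------------------------------------------------------------------------

def is_absent_array(hkl: np.ndarray, sg: SpaceGroupInfo) -> np.ndarray:
    """Systematic-absence mask derived from the operator table.

    A reflection is absent iff some operator (R, t) leaves the index fixed
    (h R = h) while h . t is non-integral.  This reproduces both centring
    conditions (C: h + k odd) and screw-axis conditions (21 along c: 00l
    with l odd) without per-group special cases.
    """
    hkl = np.asarray(hkl, dtype=int)
    single = hkl.ndim == 1
    hkl = np.atleast_2d(hkl)
    absent = np.zeros(len(hkl), dtype=bool)
    for rot, trans in sg.symmetry_ops:
        fixed = np.all(hkl @ rot == hkl, axis=1)
        if not fixed.any():
            continue
        phase = hkl[fixed].astype(float) @ trans
        absent[np.flatnonzero(fixed)] |= ~np.isclose(
            phase - np.round(phase), 0.0, atol=1e-9
        )
    return absent[0] if single else absent


def is_absent(hkl: Sequence[int], sg: SpaceGroupInfo) -> bool:
    return bool(is_absent_array(np.asarray(hkl, dtype=int), sg))


# ---------------------------------------------------------------------------
# Complete unique set
# ---------------------------------------------------------------------------

def generate_complete_set(
    cell: UnitCell,
    sg: SpaceGroupInfo,
    d_min: float,
    merge_friedel: bool = True,
) -> np.ndarray:
    """All unique, non-absent ASU indices with d >= d_min, as an (N, 3) array.

    The enumeration bound per index i is |h_i| <= a_i / d_min (from
    h_i = s . a_i with |s| = 1/d), so no reflection inside the resolution
    sphere is missed for any cell geometry.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    hmax = [int(math.floor(length / d_min)) for length in cell.lengths]
    if min(hmax) < 0:  # pragma: no cover - defensive
        return np.empty((0, 3), dtype=int)
    axes = [np.arange(-m, m + 1) for m in hmax]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid[grid.any(axis=1)]
    if len(grid) == 0:
        return np.empty((0, 3), dtype=int)
    d = d_spacing_array(cell, grid)
    grid = grid[d >= d_min - 1e-9]
    if len(grid) == 0:
        return np.empty((0, 3), dtype=int)
    asu = map_to_asu_array(grid, sg, merge_friedel)
    uniq = np.unique(asu, axis=0)
    uniq = uniq[~is_absent_array(uniq, sg)]
    # stable, documented ordering: descending d (ascending 1/d), then lex
    d_u = d_spacing_array(cell, uniq)
    order = np.lexsort((uniq[:, 2], uniq[:, 1], uniq[:, 0], -d_u))
    return uniq[order]
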