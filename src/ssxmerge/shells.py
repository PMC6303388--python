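"""Resolution-shell construction and assignment.

Shells partition an observed d-spacing range (d_min, d_max] with no gaps or
overlap.  Two schemes are provided: ``equal_volume`` (edges equally spaced in
1/d^3, so each shell covers the same reciprocal-space volume) and
``equal_count`` (quantile edges; shell populations differ by at most one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ResolutionShell", "bin_by_resolution", "assign_to_shells"]


@dataclass(frozen=True)
class ResolutionShell:
    """Half-open resolution interval (d_min, d_max], Angstrom."""

    d_max: float
    d_min: float

    def __post_init__(self) -> None:
        if not self.d_max > self.d_min > 0:
            raise ValueError(f"require d_max > d_min > 0, got {self}")

    def __str__(self) -> str:
        return f"{self.d_max:.2f}-{self.d_min:.2f}"


def bin_by_resolution(
    d_values: np.ndarray,
    n_shells: int,
    scheme: str = "equal_volume",
) -> tuple[list[ResolutionShell], np.ndarray]:
    """Partition d-spacings into shells; return shells plus assignment.

    The assignment array gives, for every input d, the index of its shell
    (0 = lowest resolution / largest d).  The lowest-resolution shell is
    closed at both ends so the maximum d is not orphaned.
    """
    d = np.asarray(d_values, dtype=float)
    if d.size == 0:
        raise ValueError("empty d-value list")
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    if n_shells > np.unique(d).size:
        warnings.warn(
            f"{n_shells} shells requested for only {np.unique(d).size} "
            "distinct d values; shells will be degenerate",
            stacklevel=2,
        )
    lo, hi = float(d.min()), float(d.max())
    if hi - lo < 1e-9 * n_shells * max(lo, 1.0):
        # (near-)degenerate range: widen so every shell has positive width
        hi = lo + 1e-9 * n_shells * max(lo, 1.0) + 1e-12
    if scheme == "equal_volume":
        s_edges = np.linspace(hi ** -3, lo ** -3, n_shells + 1)
        edges = s_edges ** (-1 / 3)  # descending d
    elif scheme == "equal_count":
        q = np.linspace(0, 1, n_shells + 1)
        edges = np.quantile(d, 1 - q)  # descending d
        edges[0], edges[-1] = hi, lo
        if np.any(np.diff(edges) >= 0):
            # duplicate quantiles (heavily tied data): fall back to a
            # linear partition of the (widened) range
            edges = np.linspace(hi, lo, n_shells + 1)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    edges[0] = hi
    edges[-1] = lo
    shells = [
        ResolutionShell(d_max=float(edges[i]), d_min=float(edges[i + 1]))
        for i in range(n_shells)
    ]
    assignment = assign_to_shells(d, shells)
    return shells, assignment


def assign_to_shells(d_values: np.ndarray, shells: list[ResolutionShell]) -> np.ndarray:
    """Shell index for each d; -1 where d falls outside every shell."""
    d = np.asarray(d_values, dtype=float)
    edges = np.array([shells[0].d_max] + [s.d_min for s in shells])
    # shells are (d_min, d_max]; searchsorted on descending edges
    idx = np.searchsorted(-edges, -d, side="right") - 1
    idx[np.isclose(d, edges[0])] = 0
    out = np.where((idx >= 0) & (idx < len(shells)), idx, -1)
    # guard the last closed edge
    out[np.isclose(d, edges[-1])] = len(shells) - 1
    return out
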