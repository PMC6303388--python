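"""Containers for unmerged per-wedge reflection observations.

An :class:`ObservationSet` holds one wedge's observations as flat numpy
arrays (index triples, intensities, raw sigmas) together with the wedge's
refined unit cell.  Intensities may be negative — weak reflections are kept
with their measured values rather than truncated — but raw sigmas are
strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .symmetry import UnitCell

__all__ = ["Observation", "ObservationSet"]


class Observation(NamedTuple):
    hkl: tuple[int, int, int]
    intensity: float
    sigma_raw: float
    dataset_id: str


@dataclass
class ObservationSet:
    """One wedge/dataset of unmerged observations plus its unit cell."""

    dataset_id: str
    cell: UnitCell
    hkl: np.ndarray          # (N, 3) int
    intensity: np.ndarray    # (N,)
    sigma_raw: np.ndarray    # (N,)
    wedge_width_deg: float = 10.0

    def __post_init__(self) -> None:
        self.hkl = np.ascontiguousarray(np.asarray(self.hkl, dtype=int))
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma_raw = np.asarray(self.sigma_raw, dtype=float)
        n = len(self.hkl)
        if n == 0:
            raise ValueError(f"dataset {self.dataset_id!r} has no observations")
        if self.hkl.shape != (n, 3):
            raise ValueError("hkl must be an (N, 3) array")
        if len(self.intensity) != n or len(self.sigma_raw) != n:
            raise ValueError("intensity/sigma arrays must match hkl length")
        if np.any(self.sigma_raw <= 0):
            raise ValueError("raw sigmas must be strictly positive")
        if np.any(~self.hkl.any(axis=1)):
            raise ValueError("observation index (0, 0, 0) is invalid")

    def __len__(self) -> int:
        return len(self.hkl)

    def __iter__(self) -> Iterator[Observation]:
        for i in range(len(self)):
            yield Observation(
                tuple(int(x) for x in self.hkl[i]),
                float(self.intensity[i]),
                float(self.sigma_raw[i]),
                self.dataset_id,
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "h": self.hkl[:, 0],
                "k": self.hkl[:, 1],
                "l": self.hkl[:, 2],
                "intensity": self.intensity,
                "sigma_raw": self.sigma_raw,
                "dataset_id": self.dataset_id,
            }
        )
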