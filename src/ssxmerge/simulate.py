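"""Synthetic multi-crystal wedge collections with known ground truth.

The generator emulates what a serial-synchrotron experiment hands the
merging pipeline: many partial, low-multiplicity wedge datasets of one
crystal form, each with its own multiplicative scale K, relative B factor,
and a two-parameter (a, b) intensity error model whose asymptotic
signal-to-noise ISa = (a*b)^(-1/2) is known exactly.  Mis-indexed outliers
are planted as unit-cell distortions.  Because every planted parameter is
recorded, each pipeline stage has a parameter-recovery test surface.

Model
-----
* True merged intensities follow acentric Wilson statistics: I_true ~
  Exponential with mean C * exp(-B_wilson / (2 d^2)).  Centric zones are not
  treated specially — a documented simplification that does not affect the
  scaling/merging machinery under test.
* A dataset observes a uniformly chosen fraction ``coverage`` of the unique
  set; each covered reflection is measured ~``multiplicity`` times, each
  observation assigned a random symmetry equivalent of the ASU index.
* Observed intensity: I_obs = g(d) * I_true + e, with g(d) =
  K * exp(-B_rel/(2 d^2)) and Gaussian e of variance
  a * (sigma_raw^2 + b * I_expected^2); the file's reported sigma is
  sigma_raw = sqrt(max(I_expected, floor^2)) + floor (Poisson-like, with a
  small floor keeping sigmas positive).
* One collection seed expands into per-dataset seeds through
  ``numpy.random.SeedSequence(seed).spawn`` in dataset order, so every
  output is a pure, bit-reproducible function of (inputs, seed).

Ideal metal-site polyhedra (tetrahedron, octahedron, pentagonal bipyramid)
with optional coordinate jitter and dropped vertices provide fixtures for
the coordination-geometry classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import ObservationSet
from .symmetry import (
    SpaceGroupInfo,
    UnitCell,
    d_spacing_array,
    generate_complete_set,
)

__all__ = [
    "GroundTruth",
    "DatasetSpec",
    "SimulatedCollection",
    "IdealSite",
    "make_ground_truth",
    "simulate_dataset",
    "make_benchmark_collection",
    "make_ideal_site",
    "POLYHEDRA",
]

SIGMA_FLOOR = 0.5  # intensity units; keeps reported sigmas positive


@dataclass(frozen=True)
class GroundTruth:
    """True merged intensities on the unique set, plus the Wilson model."""

    cell: UnitCell
    sg: SpaceGroupInfo
    d_min: float
    scale_C: float
    wilson_B: float
    hkl: np.ndarray            # (N, 3) unique ASU indices
    intensity: np.ndarray      # (N,) true intensities
    seed: int

    @property
    def n_unique(self) -> int:
        return len(self.hkl)

    @property
    def d(self) -> np.ndarray:
        return d_spacing_array(self.cell, self.hkl)

    def as_dict(self) -> dict[tuple[int, int, int], float]:
        return {
            (int(h), int(k), int(l)): float(i)
            for (h, k, l), i in zip(self.hkl, self.intensity)
        }


@dataclass(frozen=True)
class DatasetSpec:
    """Planted per-dataset parameters; ``true_isa`` is implied by (a, b)."""

    dataset_id: str
    K: float = 1.0
    B_rel: float = 0.0               # Angstrom^2, relative to the truth
    err_a: float = 1.0
    err_b: float = 0.0
    coverage: float = 1.0            # fraction of unique set observed
    multiplicity: float = 1.0        # mean observations per covered reflection
    cell_perturbation: tuple[float, float, float, float, float, float] = (
        0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
    )                                # fractional length offsets + degree offsets
    seed: int = 0
    role: str = "good"               # bookkeeping label for benchmarks

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.err_a <= 0 or self.err_b < 0:
            raise ValueError("require err_a > 0 and err_b >= 0")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must lie in (0, 1]")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")

    @property
    def true_isa(self) -> float:
        if self.err_b == 0:
            return math.inf
        return (self.err_a * self.err_b) ** -0.5


@dataclass(frozen=True)
class SimulatedCollection:
    ground_truth: GroundTruth
    specs: tuple[DatasetSpec, ...]
    datasets: tuple[ObservationSet, ...]

    def ids_with_role(self, role: str) -> list[str]:
        return [s.dataset_id for s in self.specs if s.role == role]


def make_ground_truth(
    cell: UnitCell,
    sg: SpaceGroupInfo,
    d_min: float,
    scale_C: float = 2000.0,
    wilson_B: float = 73.6,
    seed: int = 0,
) -> GroundTruth:
    """Draw Wilson-distributed true intensities for the complete unique set."""
    if scale_C <= 0:
        raise ValueError("scale_C must be positive")
    if wilson_B < 0:
        raise ValueError("wilson_B must be non-negative")
    hkl = generate_complete_set(cell, sg, d_min)
    if len(hkl) == 0:
        raise ValueError(f"no reflections to d_min = {d_min} for cell {cell}")
    d = d_spacing_array(cell, hkl)
    mean = scale_C * np.exp(-wilson_B / (2.0 * d * d))
    rng = np.random.default_rng(seed)
    intensity = rng.exponential(mean)
    return GroundTruth(
        cell=cell, sg=sg, d_min=d_min, scale_C=scale_C, wilson_B=wilson_B,
        hkl=hkl, intensity=intensity, seed=seed,
    )


def _perturbed_cell(cell: UnitCell, pert) -> UnitCell:
    da, db, dc, dal, dbe, dga = pert
    return UnitCell(
        cell.a * (1 + da), cell.b * (1 + db), cell.c * (1 + dc),
        cell.alpha + dal, cell.beta + dbe, cell.gamma + dga,
    )


def simulate_dataset(truth: GroundTruth, spec: DatasetSpec) -> ObservationSet:
    """Emit one wedge dataset according to its planted parameters."""
    rng = np.random.default_rng(spec.seed)
    n = truth.n_unique
    n_cov = max(1, int(round(spec.coverage * n)))
    covered = rng.choice(n, size=n_cov, replace=False)

    if spec.multiplicity > 1:
        n_obs = 1 + rng.poisson(spec.multiplicity - 1.0, size=n_cov)
    else:
        n_obs = np.ones(n_cov, dtype=int)
    ref_idx = np.repeat(covered, n_obs)

    d = truth.d[ref_idx]
    g = spec.K * np.exp(-spec.B_rel / (2.0 * d * d))
    i_expected = g * truth.intensity[ref_idx]
    sigma_raw = np.sqrt(np.maximum(i_expected, SIGMA_FLOOR ** 2)) + SIGMA_FLOOR
    noise_var = spec.err_a * (sigma_raw ** 2 + spec.err_b * i_expected ** 2)
    i_obs = i_expected + rng.normal(0.0, np.sqrt(noise_var))

    # scatter each observation over a random symmetry equivalent so the
    # pipeline genuinely exercises ASU reduction
    ops = truth.sg.laue_ops
    op_idx = rng.integers(0, len(ops), size=len(ref_idx))
    hkl = truth.hkl[ref_idx].copy()
    for j, rot in enumerate(ops):
        sel = op_idx == j
        if sel.any():
            hkl[sel] = hkl[sel] @ rot

    return ObservationSet(
        dataset_id=spec.dataset_id,
        cell=_perturbed_cell(truth.cell, spec.cell_perturbation),
        hkl=hkl,
        intensity=i_obs,
        sigma_raw=sigma_raw,
        wedge_width_deg=10.0,
    )


def _spec_from_isa(
    dataset_id: str,
    isa: float,
    rng: np.random.Generator,
    seed: int,
    role: str,
    cell_perturbation=(0, 0, 0, 0, 0, 0),
) -> DatasetSpec:
    err_a = float(rng.uniform(1.0, 2.0))
    err_b = 1.0 / (err_a * isa * isa)
    return DatasetSpec(
        dataset_id=dataset_id,
        K=float(rng.uniform(0.5, 2.0)),
        B_rel=float(rng.uniform(0.0, 30.0)),
        err_a=err_a,
        err_b=err_b,
        coverage=float(rng.uniform(0.25, 0.45)),
        multiplicity=float(rng.uniform(2.5, 4.0)),
        cell_perturbation=tuple(cell_perturbation),
        seed=seed,
        role=role,
    )


def make_benchmark_collection(
    truth: GroundTruth,
    n_good: int = 20,
    n_low_isa: int = 5,
    n_misindexed: int = 3,
    seed: int = 0,
) -> SimulatedCollection:
    """Selection benchmark: good wedges plus planted low-ISa and mis-indexed outliers.

    Good datasets carry ISa in [10, 40]; low-ISa datasets ISa in [0.5, 2.0];
    mis-indexed datasets have a good error model but >= 4% deviation on one
    cell axis, so only the indexing-consistency filter can catch them.
    """
    if min(n_good, n_low_isa, n_misindexed) < 0 or n_good + n_low_isa + n_misindexed < 2:
        raise ValueError("need non-negative counts totalling >= 2")
    root = np.random.SeedSequence(seed)
    n_total = n_good + n_low_isa + n_misindexed
    children = root.spawn(n_total + 1)
    rng = np.random.default_rng(children[0])

    specs: list[DatasetSpec] = []
    k = 1
    for i in range(n_good):
        spec = _spec_from_isa(
            f"good_{i:03d}", float(rng.uniform(10, 40)),
            rng, int(children[k].generate_state(1)[0] % (2 ** 31)), "good")
        if i == 0:
            # the first dataset is the reference crystal: relative scales
            # are only defined up to a gauge, and the pipeline fixes its
            # gauge on the first retained dataset, so the truth frame and
            # the scaling frame coincide by construction
            spec = replace(spec, K=1.0, B_rel=0.0)
        specs.append(spec)
        k += 1
    for i in range(n_low_isa):
        specs.append(_spec_from_isa(
            f"lowisa_{i:03d}", float(rng.uniform(0.5, 2.0)),
            rng, int(children[k].generate_state(1)[0] % (2 ** 31)), "low_isa"))
        k += 1
    for i in range(n_misindexed):
        axis = int(rng.integers(0, 3))
        pert = [0.0] * 6
        pert[axis] = float(rng.uniform(0.04, 0.08)) * float(rng.choice([-1, 1]))
        specs.append(_spec_from_isa(
            f"misidx_{i:03d}", float(rng.uniform(10, 40)),
            rng, int(children[k].generate_state(1)[0] % (2 ** 31)),
            "misindexed", cell_perturbation=pert))
        k += 1

    datasets = tuple(simulate_dataset(truth, s) for s in specs)
    return SimulatedCollection(ground_truth=truth, specs=tuple(specs), datasets=datasets)


# ---------------------------------------------------------------------------
# Ideal coordination polyhedra
# ---------------------------------------------------------------------------

def _tetrahedron() -> np.ndarray:
    v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    return v / np.linalg.norm(v[0])


def _octahedron() -> np.ndarray:
    return np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )


def _pentagonal_bipyramid() -> np.ndarray:
    # two axial vertices first, then five equatorial at 72 degree spacing;
    # dropped vertices are removed from the end, i.e. equatorial first
    ang = np.deg2rad(72.0) * np.arange(5)
    eq = np.stack([np.cos(ang), np.sin(ang), np.zeros(5)], axis=1)
    ax = np.array([[0, 0, 1], [0, 0, -1]], dtype=float)
    return np.vstack([ax, eq])


POLYHEDRA: dict[str, np.ndarray] = {
    "tetrahedral": _tetrahedron(),
    "octahedral": _octahedron(),
    "pentagonal_bipyramid": _pentagonal_bipyramid(),
}


@dataclass(frozen=True)
class IdealSite:
    geometry_label: str
    center: np.ndarray
    ligands: np.ndarray       # (n, 3) Angstrom
    bond_length: float
    jitter_sd: float


def make_ideal_site(
    geometry_label: str,
    bond_length: float = 2.4,
    jitter_sd: float = 0.0,
    drop_vertices: int = 0,
    seed: int = 0,
    center=(0.0, 0.0, 0.0),
) -> IdealSite:
    """Canonical polyhedron scaled to ``bond_length``, optionally jittered.

    ``drop_vertices`` removes vertices from the end of the canonical list
    (for the pentagonal bipyramid that means equatorial positions first),
    producing "incomplete" variants such as the six-ligand incomplete
    pentagonal bipyramid seen at partially occupied Ca sites.
    """
    if geometry_label not in POLYHEDRA:
        raise ValueError(
            f"unknown geometry {geometry_label!r}; known: {sorted(POLYHEDRA)}"
        )
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    verts = POLYHEDRA[geometry_label]
    if not 0 <= drop_vertices < len(verts):
        raise ValueError("drop_vertices must be < vertex count")
    kept = verts[: len(verts) - drop_vertices] * bond_length
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        kept = kept + rng.normal(0.0, jitter_sd, size=kept.shape)
    center = np.asarray(center, dtype=float)
    return IdealSite(
        geometry_label=geometry_label,
        center=center,
        ligands=kept + center,
        bond_length=bond_length,
        jitter_sd=jitter_sd,
    )
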