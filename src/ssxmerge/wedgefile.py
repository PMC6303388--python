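"""The wedge-file dialect: one unmerged mini-dataset per plain-text file.

Format (whitespace separated)::

    !CELL 60.88 68.83 257.52 90 90 90
    !SPACE_GROUP C2221
    !DATASET xtal_0001
    !WEDGE_WIDTH 10.0          (optional)
    h k l I sigI
    ...

Header lines start with '!' and precede all records; sigI must be positive.
A best-effort converter from genuine XDS_ASCII unmerged files is included
(``convert_xds_ascii``); it maps the H K L IOBS SIGMA(IOBS) columns and the
standard header keys, with no guarantee across XDS versions.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .datasets import ObservationSet
from .simulate import DatasetSpec, GroundTruth, SimulatedCollection
from .symmetry import UnitCell

__all__ = ["read_wedge", "write_wedge", "write_collection", "read_collection_dir",
           "convert_xds_ascii"]


class WedgeFormatError(ValueError):
    pass


def write_wedge(path: str | Path, obs: ObservationSet) -> None:
    path = Path(path)
    c = obs.cell
    lines = [
        f"!CELL {c.a:.4f} {c.b:.4f} {c.c:.4f} {c.alpha:.3f} {c.beta:.3f} {c.gamma:.3f}",
        "!SPACE_GROUP unknown",
        f"!DATASET {obs.dataset_id}",
        f"!WEDGE_WIDTH {obs.wedge_width_deg:.2f}",
    ]
    for (h, k, l), i, s in zip(obs.hkl, obs.intensity, obs.sigma_raw):
        lines.append(f"{h} {k} {l} {i:.4f} {s:.4f}")
    path.write_text("\n".join(lines) + "\n")


def read_wedge(path: str | Path) -> ObservationSet:
    path = Path(path)
    cell = None
    dataset_id = None
    wedge_width = 10.0
    hkl, ii, ss = [], [], []
    in_records = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("!"):
            if in_records:
                raise WedgeFormatError(
                    f"{path}:{lineno}: header line after data records"
                )
            key, _, val = line[1:].partition(" ")
            if key == "CELL":
                parts = val.split()
                if len(parts) != 6:
                    raise WedgeFormatError(f"{path}:{lineno}: !CELL needs 6 values")
                cell = UnitCell(*(float(x) for x in parts))
            elif key == "DATASET":
                dataset_id = val.strip()
            elif key == "WEDGE_WIDTH":
                wedge_width = float(val)
            # unknown header keys (incl. SPACE_GROUP) are carried as metadata
            continue
        in_records = True
        parts = line.split()
        if len(parts) != 5:
            raise WedgeFormatError(
                f"{path}:{lineno}: expected 'h k l I sigI', got {len(parts)} fields"
            )
        try:
            h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
            i, s = float(parts[3]), float(parts[4])
        except ValueError as exc:
            raise WedgeFormatError(f"{path}:{lineno}: non-numeric field: {exc}")
        if s <= 0:
            raise WedgeFormatError(f"{path}:{lineno}: sigI must be > 0, got {s}")
        hkl.append((h, k, l))
        ii.append(i)
        ss.append(s)
    if cell is None:
        raise WedgeFormatError(f"{path}: missing !CELL header")
    if dataset_id is None:
        raise WedgeFormatError(f"{path}: missing !DATASET header")
    if not hkl:
        raise WedgeFormatError(f"{path}: no observation records")
    return ObservationSet(
        dataset_id=dataset_id,
        cell=cell,
        hkl=np.array(hkl, dtype=int),
        intensity=np.array(ii),
        sigma_raw=np.array(ss),
        wedge_width_deg=wedge_width,
    )


# ---------------------------------------------------------------------------
# Simulated collections on disk
# ---------------------------------------------------------------------------

def write_collection(out_dir: str | Path, coll: SimulatedCollection) -> None:
    """One wedge file per dataset plus a truth.json sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for obs in coll.datasets:
        write_wedge(out_dir / f"{obs.dataset_id}.hkl", obs)
    truth = {
        "cell": coll.ground_truth.cell.to_tuple(),
        "space_group": coll.ground_truth.sg.symbol,
        "d_min": coll.ground_truth.d_min,
        "scale_C": coll.ground_truth.scale_C,
        "wilson_B": coll.ground_truth.wilson_B,
        "seed": coll.ground_truth.seed,
        "datasets": [
            {
                "dataset_id": s.dataset_id,
                "K": s.K,
                "B_rel": s.B_rel,
                "err_a": s.err_a,
                "err_b": s.err_b,
                "true_isa": None if s.err_b == 0 else s.true_isa,
                "coverage": s.coverage,
                "multiplicity": s.multiplicity,
                "cell_perturbation": list(s.cell_perturbation),
                "seed": s.seed,
                "role": s.role,
            }
            for s in coll.specs
        ],
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))


def read_collection_dir(wedge_dir: str | Path) -> list[ObservationSet]:
    wedge_dir = Path(wedge_dir)
    paths = sorted(p for p in wedge_dir.glob("*.hkl"))
    if not paths:
        raise WedgeFormatError(f"no .hkl wedge files in {wedge_dir}")
    return [read_wedge(p) for p in paths]


# ---------------------------------------------------------------------------
# XDS_ASCII import shim
# ---------------------------------------------------------------------------

def convert_xds_ascii(path: str | Path, dataset_id: str | None = None) -> ObservationSet:
    """Best-effort conversion of an unmerged XDS_ASCII.HKL file."""
    path = Path(path)
    cell = None
    wedge = 10.0
    cols: dict[str, int] = {}
    n_items = None
    hkl, ii, ss = [], [], []
    for raw in path.read_text().splitlines():
        if raw.startswith("!"):
            m = re.match(r"!UNIT_CELL_CONSTANTS=\s*(.*)", raw)
            if m:
                cell = UnitCell(*(float(x) for x in m.group(1).split()[:6]))
            m = re.match(r"!NUMBER_OF_ITEMS_IN_EACH_DATA_RECORD=\s*(\d+)", raw)
            if m:
                n_items = int(m.group(1))
            m = re.match(r"!ITEM_(\S+)=\s*(\d+)", raw)
            if m:
                cols[m.group(1)] = int(m.group(2)) - 1
            if raw.startswith("!END_OF_DATA"):
                break
            continue
        parts = raw.split()
        if n_items and len(parts) != n_items:
            continue
        try:
            h = int(float(parts[cols.get("H", 0)]))
            k = int(float(parts[cols.get("K", 1)]))
            l = int(float(parts[cols.get("L", 2)]))
            i = float(parts[cols.get("IOBS", 3)])
            s = float(parts[cols.get("SIGMA(IOBS)", 4)])
        except (IndexError, ValueError):
            continue
        if s <= 0 or (h, k, l) == (0, 0, 0):
            continue
        hkl.append((h, k, l))
        ii.append(i)
        ss.append(s)
    if cell is None:
        raise WedgeFormatError(f"{path}: no !UNIT_CELL_CONSTANTS header")
    if not hkl:
        raise WedgeFormatError(f"{path}: no usable records")
    return ObservationSet(
        dataset_id=dataset_id or path.stem,
        cell=cell,
        hkl=np.array(hkl, dtype=int),
        intensity=np.array(ii),
        sigma_raw=np.array(ss),
        wedge_width_deg=wedge,
    )
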