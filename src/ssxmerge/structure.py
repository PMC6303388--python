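"""Structure-model metrics: metal coordination spheres, polyhedral geometry
classification, disulfide detection, atom census, and deposited
structure-factor counting.

Models are read with gemmi (PDB or mmCIF) into a flat atom table.  The
geometry classifier compares a metal site's ligand directions with ideal
polyhedra (tetrahedron, octahedron, pentagonal bipyramid) by exhaustive
assignment search with an optimal superposition rotation per assignment,
reporting the template and the angular RMSD of the best fit; templates with
dropped vertices cover "incomplete" coordination such as a six-ligand
pentagonal bipyramid.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

from .simulate import POLYHEDRA
from .symmetry import SpaceGroupInfo, UnitCell, d_spacing_array, generate_complete_set

__all__ = [
    "StructureModel",
    "CoordinationSite",
    "AtomCensus",
    "read_structure",
    "find_coordination",
    "classify_geometry",
    "find_disulfides",
    "atom_census",
    "count_deposited_reflections",
]

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",
}
WATER_NAMES = {"HOH", "WAT", "DOD"}
METAL_ELEMENTS = {"ZN", "CA", "MG", "NA", "K", "MN", "FE", "CO", "NI", "CU", "CD"}

# conventional first-coordination-sphere cutoffs (Angstrom) per metal
DEFAULT_CUTOFFS: dict[str, float] = {"ZN": 2.6, "CA": 3.0, "MG": 2.6, "NA": 3.0}
COORDINATING_ELEMENTS = {"N", "O", "S"}


@dataclass
class StructureModel:
    """Flat atom table plus cell and space-group symbol."""

    atoms: pd.DataFrame       # element, name, res_name, res_seq, chain, x, y, z, occ, altloc
    cell: UnitCell | None = None
    sg_symbol: str | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self, mask=None) -> np.ndarray:
        t = self.atoms if mask is None else self.atoms[mask]
        return t[["x", "y", "z"]].to_numpy()


def read_structure(path: str) -> StructureModel:
    """Read a PDB or mmCIF model into a :class:`StructureModel`.

    Alternate locations are resolved by keeping, per atom site, the altloc
    with the highest occupancy (ties broken by altloc letter order), so
    every downstream count is deterministic.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    rows = []
    model = st[0]
    for chain in model:
        for res in chain:
            for atom in res:
                rows.append(
                    {
                        "element": atom.element.name.upper(),
                        "name": atom.name,
                        "res_name": res.name.strip(),
                        "res_seq": res.seqid.num,
                        "chain": chain.name,
                        "x": atom.pos.x,
                        "y": atom.pos.y,
                        "z": atom.pos.z,
                        "occ": atom.occ,
                        "altloc": atom.altloc if atom.altloc != "\x00" else "",
                    }
                )
    if not rows:
        raise ValueError(f"no atoms read from {path}")
    atoms = pd.DataFrame(rows)
    # altloc resolution: highest occupancy wins, then altloc letter;
    # file order is preserved afterwards
    atoms = atoms.sort_values(
        ["occ", "altloc"], ascending=[False, True], kind="stable",
    ).drop_duplicates(subset=["chain", "res_seq", "res_name", "name"], keep="first")
    atoms = atoms.sort_index().reset_index(drop=True)
    cell = None
    if st.cell and st.cell.a > 1.0:
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                        st.cell.alpha, st.cell.beta, st.cell.gamma)
    sg = st.spacegroup_hm or None
    return StructureModel(atoms=atoms, cell=cell, sg_symbol=sg)


# ---------------------------------------------------------------------------
# Coordination spheres
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ligand:
    element: str
    name: str
    res_name: str
    res_seq: int
    chain: str
    distance: float
    coords: tuple[float, float, float]


@dataclass(frozen=True)
class CoordinationSite:
    center_element: str
    center_res_seq: int
    center_chain: str
    center_coords: tuple[float, float, float]
    ligands: tuple[Ligand, ...]
    geometry_label: str | None = None
    angular_rmsd: float | None = None

    @property
    def n_ligands(self) -> int:
        return len(self.ligands)

    def multidentate_residues(self) -> list[tuple[str, int, int]]:
        """(res_name, res_seq, n_atoms) for residues contributing >= 2 ligands."""
        counts: dict[tuple[str, int, str], int] = {}
        for lig in self.ligands:
            key = (lig.res_name, lig.res_seq, lig.chain)
            counts[key] = counts.get(key, 0) + 1
        return [(rn, rs, n) for (rn, rs, _), n in counts.items() if n >= 2]


def find_coordination(
    model: StructureModel,
    center_element: str,
    center_res_seq: int | None = None,
    center_chain: str | None = None,
    cutoffs: dict[str, float] | None = None,
    coordinating: set[str] = COORDINATING_ELEMENTS,
) -> CoordinationSite:
    """First coordination sphere of one metal atom, sorted by distance.

    The centre is selected by element and optionally residue number/chain;
    an ambiguous or missing selection raises.  All atoms of coordinating
    element types within the element-specific cutoff count as ligands,
    excluding atoms of the metal's own residue.
    """
    a = model.atoms
    sel = a["element"] == center_element.upper()
    if center_res_seq is not None:
        sel &= a["res_seq"] == center_res_seq
    if center_chain is not None:
        sel &= a["chain"] == center_chain
    centers = a[sel]
    if len(centers) == 0:
        raise ValueError(f"no {center_element} centre matches the selection")
    if len(centers) > 1:
        raise ValueError(
            f"{len(centers)} {center_element} atoms match; narrow the "
            "selection with residue number/chain"
        )
    c = centers.iloc[0]
    table = dict(DEFAULT_CUTOFFS)
    if cutoffs:
        table.update({k.upper(): v for k, v in cutoffs.items()})
    cutoff = table.get(center_element.upper(), 2.6)
    cand = a[
        a["element"].isin(coordinating)
        & ~((a["res_seq"] == c["res_seq"]) & (a["chain"] == c["chain"])
            & (a["res_name"] == c["res_name"]))
    ]
    pos = cand[["x", "y", "z"]].to_numpy()
    center = np.array([c["x"], c["y"], c["z"]])
    dist = np.linalg.norm(pos - center, axis=1)
    within = dist <= cutoff
    order = np.argsort(dist[within], kind="stable")
    ligands = []
    hits = cand[within].iloc[order]
    for (_, row), dd in zip(hits.iterrows(), np.sort(dist[within])):
        ligands.append(
            Ligand(
                element=row["element"], name=row["name"],
                res_name=row["res_name"], res_seq=int(row["res_seq"]),
                chain=row["chain"], distance=float(dd),
                coords=(row["x"], row["y"], row["z"]),
            )
        )
    return CoordinationSite(
        center_element=center_element.upper(),
        center_res_seq=int(c["res_seq"]),
        center_chain=c["chain"],
        center_coords=(float(c["x"]), float(c["y"]), float(c["z"])),
        ligands=tuple(ligands),
    )


# ---------------------------------------------------------------------------
# Geometry classification
# ---------------------------------------------------------------------------

def _batched_kabsch_angular_rmsd(obs: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Angular RMSD (degrees) of obs unit vectors vs each template assignment
    after an optimal rotation (batched Kabsch over the assignment axis)."""
    # cross-covariance per assignment: (M, 3, 3)
    H = np.einsum("ni,mnj->mij", obs, templates)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("mij,mjk->mik", U, Vt))
    D = np.repeat(np.eye(3)[None], len(H), axis=0)
    D[:, 2, 2] = det
    R = np.einsum("mij,mjk,mkl->mil", U, D, Vt)
    rotated = np.einsum("mij,mnj->mni", np.transpose(R, (0, 2, 1)), np.repeat(obs[None], len(H), axis=0))
    # angle between rotated obs and template vectors
    dots = np.clip(np.einsum("mni,mni->mn", rotated, templates), -1.0, 1.0)
    ang = np.degrees(np.arccos(dots))
    return np.sqrt((ang ** 2).mean(axis=1))


def _best_fit_to_template(obs_unit: np.ndarray, template: np.ndarray) -> float:
    """Minimum angular RMSD over all injective assignments of observed
    ligand directions to template vertices (exhaustive)."""
    n, m = len(obs_unit), len(template)
    perms = np.array(list(itertools.permutations(range(m), n)), dtype=int)
    templates = template[perms]          # (M, n, 3)
    return float(_batched_kabsch_angular_rmsd(obs_unit, templates).min())


def classify_geometry(
    site: CoordinationSite | np.ndarray,
    center: np.ndarray | None = None,
    incomplete_margin: float = 5.0,
) -> tuple[str, float]:
    """Best-matching coordination polyhedron and its angular RMSD (degrees).

    Accepts a :class:`CoordinationSite` or a raw (n, 3) ligand coordinate
    array plus centre.  Every template with at least as many vertices as
    ligands is tried; a template larger than the ligand count implies
    dropped vertices and its label gains an "incomplete " prefix — but only
    if it beats the best complete (equal-vertex-count) template by more
    than ``incomplete_margin`` degrees, so noisy complete polyhedra are not
    over-labelled.
    """
    if isinstance(site, CoordinationSite):
        lig = np.array([l.coords for l in site.ligands], dtype=float)
        center = np.asarray(site.center_coords, dtype=float)
    else:
        lig = np.asarray(site, dtype=float)
        if center is None:
            raise ValueError("center required with raw ligand coordinates")
        center = np.asarray(center, dtype=float)
    n = len(lig)
    if n < 3:
        raise ValueError(f"geometry undefined for {n} ligands (need >= 3)")
    if n > 8:
        raise ValueError("exhaustive search supports at most 8 ligands")
    vec = lig - center
    norms = np.linalg.norm(vec, axis=1)
    if np.any(norms <= 0):
        raise ValueError("ligand coincides with the centre")
    unit = vec / norms[:, None]

    complete_best: tuple[str, float] | None = None
    incomplete_best: tuple[str, float] | None = None
    for label, tmpl in POLYHEDRA.items():
        m = len(tmpl)
        if m < n:
            continue
        rmsd = _best_fit_to_template(unit, tmpl)
        if m == n:
            if complete_best is None or rmsd < complete_best[1]:
                complete_best = (label, rmsd)
        else:
            if incomplete_best is None or rmsd < incomplete_best[1]:
                incomplete_best = (f"incomplete {label}", rmsd)
    if complete_best is None and incomplete_best is None:
        raise ValueError(f"no template accommodates {n} ligands")
    if complete_best is None:
        return incomplete_best
    if incomplete_best is None:
        return complete_best
    if incomplete_best[1] < complete_best[1] - incomplete_margin:
        return incomplete_best
    return complete_best


# ---------------------------------------------------------------------------
# Disulfides
# ---------------------------------------------------------------------------

def find_disulfides(
    model: StructureModel, s_s_cutoff: float = 2.5
) -> list[tuple[tuple[str, int], tuple[str, int], float]]:
    """All SG-SG pairs from distinct Cys residues within the cutoff.

    Returns ((chain, res_seq), (chain, res_seq), distance) triples, each
    pair reported once, sorted by residue number.
    """
    sg_atoms = model.atoms[
        (model.atoms["res_name"] == "CYS") & (model.atoms["name"] == "SG")
    ]
    pos = sg_atoms[["x", "y", "z"]].to_numpy()
    out = []
    recs = sg_atoms.to_dict("records")
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            if (recs[i]["chain"], recs[i]["res_seq"]) == (
                recs[j]["chain"], recs[j]["res_seq"]
            ):
                continue
            dist = float(np.linalg.norm(pos[i] - pos[j]))
            if dist <= s_s_cutoff:
                out.append(
                    (
                        (recs[i]["chain"], int(recs[i]["res_seq"])),
                        (recs[j]["chain"], int(recs[j]["res_seq"])),
                        dist,
                    )
                )
    return sorted(out, key=lambda t: (t[0], t[1]))


# ---------------------------------------------------------------------------
# Atom census
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomCensus:
    protein: int
    water: int
    metals: dict[str, int]
    other: dict[str, int]

    @property
    def total(self) -> int:
        return self.protein + self.water + sum(self.metals.values()) + sum(
            self.other.values()
        )

    def as_dict(self) -> dict:
        return {
            "protein": self.protein,
            "water": self.water,
            "metals": dict(self.metals),
            "other": dict(self.other),
            "total": self.total,
        }


def atom_census(model: StructureModel) -> AtomCensus:
    """Classify every atom: standard amino acids -> protein; HOH -> water;
    single-atom metal residues -> metals by element; anything else -> an
    other-ligand bucket keyed by residue name."""
    a = model.atoms
    protein = int(a["res_name"].isin(STANDARD_AA).sum())
    water = int(a["res_name"].isin(WATER_NAMES).sum())
    metals: dict[str, int] = {}
    other: dict[str, int] = {}
    rest = a[~a["res_name"].isin(STANDARD_AA | WATER_NAMES)]
    for (_, _, res_name), group in rest.groupby(["chain", "res_seq", "res_name"]):
        elem = group.iloc[0]["element"]
        if len(group) == 1 and elem in METAL_ELEMENTS:
            metals[elem] = metals.get(elem, 0) + 1
        else:
            other[res_name] = other.get(res_name, 0) + len(group)
    return AtomCensus(protein=protein, water=water, metals=metals, other=other)


# ---------------------------------------------------------------------------
# Deposited structure factors
# ---------------------------------------------------------------------------

def count_deposited_reflections(
    path: str,
    status_filter: set[str] | None = frozenset({"o"}),
    d_min: float | None = None,
) -> dict:
    """Count unique reflections in an mmCIF structure-factor file.

    Returns a dict with the reflection count, the file's cell/space group,
    the data's d_min, and completeness against the complete unique set to
    that resolution (supported space groups only; None otherwise).
    """
    doc = gemmi.cif.read(str(path))
    block = None
    for b in doc:
        if b.find_loop("_refln.index_h"):
            block = b
            break
    if block is None:
        raise ValueError(
            f"{path}: no _refln loop found; blocks: {[b.name for b in doc]}"
        )
    h = [int(x) for x in block.find_loop("_refln.index_h")]
    k = [int(x) for x in block.find_loop("_refln.index_k")]
    l = [int(x) for x in block.find_loop("_refln.index_l")]
    status = list(block.find_loop("_refln.status"))
    has_data = any(
        block.find_loop(tag)
        for tag in (
            "_refln.intensity_meas",
            "_refln.F_meas_au",
            "_refln.F_meas",
        )
    )
    if not has_data:
        tags = [t for t in block.get_mmcif_category_names()]
        raise ValueError(f"{path}: no intensity/amplitude column; found {tags}")
    hkl = np.array([h, k, l]).T
    if status and status_filter is not None:
        keep = np.array([s in status_filter for s in status])
        hkl = hkl[keep]
    uniq = np.unique(hkl, axis=0)
    n = len(uniq)

    def _cif_float(tag):
        v = block.find_loop(tag)
        vals = list(v)
        if vals:
            return float(vals[0])
        p = block.find_pair(tag)
        return float(p[1]) if p else None

    out = {"n_reflections": n, "completeness": None, "d_min": None}
    try:
        cell = UnitCell(
            _cif_float("_cell.length_a"), _cif_float("_cell.length_b"),
            _cif_float("_cell.length_c"), _cif_float("_cell.angle_alpha"),
            _cif_float("_cell.angle_beta"), _cif_float("_cell.angle_gamma"),
        )
    except (TypeError, ValueError):
        return out
    sym_pair = block.find_pair("_symmetry.space_group_name_H-M")
    sg_name = sym_pair[1].strip("'\"") if sym_pair else None
    d = d_spacing_array(cell, uniq)
    lim = d_min if d_min is not None else float(d.min())
    out["d_min"] = lim
    if sg_name:
        from .symmetry import space_group

        try:
            sg = space_group(sg_name)
        except ValueError:
            return out
        full = generate_complete_set(cell, sg, lim)
        out["completeness"] = float(
            len(np.intersect1d(
                _pack(uniq), _pack(full)
            )) / max(len(full), 1)
        )
    return out


def _pack(hkl: np.ndarray) -> np.ndarray:
    from .selection import encode_hkl
    return encode_hkl(hkl)
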