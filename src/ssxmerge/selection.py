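"""Dataset selection: indexing-consistency filter, multi-crystal scaling,
per-dataset error-model (ISa) fitting, and the two-round rejection loop.

The selection procedure mirrors standard serial-crystallography practice:

1. every wedge's refined cell is checked against a user-provided reference
   cell (mis-indexed wedges show multi-percent axis deviations);
2. the survivors are scaled together with a per-dataset model
   g_i(d) = K_i * exp(-B_i / (2 d^2)) refined against an iteratively
   re-merged reference, and a two-parameter error model
   sigma_adj^2(I) = a * (sigma_raw^2 + b * I^2) is fitted per dataset,
   whose asymptotic signal-to-noise ISa = (a * b)^(-1/2) flags wedges with
   dominant systematic error;
3. datasets with ISa strictly below the cutoff (default 3.0) are rejected
   and the survivors are re-scaled and re-fitted in a second round.

Scaling works on a flat observation table (pandas) keyed by the canonical
ASU index, so symmetry mates from different wedges meet in the same group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ObservationSet
from .symmetry import (
    SpaceGroupInfo,
    UnitCell,
    d_spacing_array,
    map_to_asu_array,
)

__all__ = [
    "CellCheck",
    "CellFilterReport",
    "ScaleFactors",
    "ScalingModel",
    "ErrorModelFit",
    "SelectionRound",
    "SelectionResult",
    "build_observation_table",
    "check_cell_consistency",
    "scale_datasets",
    "fit_error_model",
    "apply_error_model",
    "run_selection",
]

ISA_CAP_B = 1e-12        # below this b the ISa is reported as infinity
_KEY_OFF = 1024          # index packing offset; supports |h|,|k|,|l| < 1024
_KEY_BASE = 2048


def encode_hkl(hkl: np.ndarray) -> np.ndarray:
    """Pack (N, 3) integer indices into a single int64 key."""
    h = np.asarray(hkl, dtype=np.int64)
    if np.any(np.abs(h) >= _KEY_OFF):
        raise ValueError("index magnitude exceeds packing capacity (1023)")
    return ((h[:, 0] + _KEY_OFF) * _KEY_BASE + (h[:, 1] + _KEY_OFF)) * _KEY_BASE + (
        h[:, 2] + _KEY_OFF
    )


def decode_key(key: np.ndarray) -> np.ndarray:
    k = np.asarray(key, dtype=np.int64)
    l = k % _KEY_BASE - _KEY_OFF
    k2 = k // _KEY_BASE
    kk = k2 % _KEY_BASE - _KEY_OFF
    hh = k2 // _KEY_BASE - _KEY_OFF
    return np.stack([hh, kk, l], axis=1).astype(int)


# ---------------------------------------------------------------------------
# Indexing-consistency (unit cell) filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellCheck:
    dataset_id: str
    accepted: bool
    max_length_dev: float      # fraction of reference length
    max_angle_dev: float       # degrees
    reason: str


@dataclass(frozen=True)
class CellFilterReport:
    checks: tuple[CellCheck, ...]
    length_tol: float
    angle_tol: float

    @property
    def accepted_ids(self) -> list[str]:
        return [c.dataset_id for c in self.checks if c.accepted]

    @property
    def rejected(self) -> dict[str, str]:
        return {c.dataset_id: c.reason for c in self.checks if not c.accepted}


def check_cell_consistency(
    datasets: list[ObservationSet],
    ref_cell: UnitCell,
    length_tol: float = 0.02,
    angle_tol: float = 2.0,
) -> CellFilterReport:
    """Accept a dataset iff every cell length is within ``length_tol``
    (fractional) and every angle within ``angle_tol`` degrees of the
    reference."""
    if not datasets:
        raise ValueError("no datasets to check")
    if length_tol <= 0 or angle_tol <= 0:
        raise ValueError("tolerances must be positive")
    checks = []
    axis_names = ("a", "b", "c")
    angle_names = ("alpha", "beta", "gamma")
    for ds in datasets:
        len_dev = [
            abs(x - r) / r for x, r in zip(ds.cell.lengths, ref_cell.lengths)
        ]
        ang_dev = [abs(x - r) for x, r in zip(ds.cell.angles, ref_cell.angles)]
        bad = []
        for name, dev in zip(axis_names, len_dev):
            if dev > length_tol:
                bad.append(f"axis {name} deviates {dev * 100:.1f}%")
        for name, dev in zip(angle_names, ang_dev):
            if dev > angle_tol:
                bad.append(f"angle {name} deviates {dev:.2f} deg")
        accepted = not bad
        checks.append(
            CellCheck(
                dataset_id=ds.dataset_id,
                accepted=accepted,
                max_length_dev=max(len_dev),
                max_angle_dev=max(ang_dev),
                reason="" if accepted else "; ".join(bad),
            )
        )
    return CellFilterReport(tuple(checks), length_tol, angle_tol)


# ---------------------------------------------------------------------------
# Observation table
# ---------------------------------------------------------------------------

def build_observation_table(
    datasets: list[ObservationSet],
    sg: SpaceGroupInfo,
    cell: UnitCell | None = None,
    merge_friedel: bool = True,
) -> pd.DataFrame:
    """Flat table of all observations with canonical ASU keys and d-spacings.

    d is computed with one common cell (the first dataset's unless given) so
    that symmetry-equivalent observations from different wedges share one d.
    """
    if not datasets:
        raise ValueError("no datasets")
    cell = cell or datasets[0].cell
    frames = []
    for ds in datasets:
        asu = map_to_asu_array(ds.hkl, sg, merge_friedel)
        frames.append(
            pd.DataFrame(
                {
                    "dataset_id": ds.dataset_id,
                    "key": encode_hkl(asu),
                    "h": asu[:, 0],
                    "k": asu[:, 1],
                    "l": asu[:, 2],
                    "d": d_spacing_array(cell, asu),
                    "i_obs": ds.intensity,
                    "sigma_raw": ds.sigma_raw,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _connected_components(table: pd.DataFrame) -> list[set[str]]:
    """Connected components of the dataset graph (edge = shared ASU key)."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for ds in table["dataset_id"].unique():
        parent[ds] = ds
    first_seen: dict[int, str] = {}
    pairs = table[["key", "dataset_id"]].drop_duplicates()
    for key, ds in zip(pairs["key"].to_numpy(), pairs["dataset_id"].to_numpy()):
        if key in first_seen:
            union(first_seen[key], ds)
        else:
            first_seen[key] = ds
    comps: dict[str, set[str]] = {}
    for ds in parent:
        comps.setdefault(find(ds), set()).add(ds)
    return list(comps.values())


# ---------------------------------------------------------------------------
# Multi-crystal scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaleFactors:
    K: float
    B: float     # Angstrom^2


@dataclass(frozen=True)
class ScalingModel:
    factors: dict[str, ScaleFactors]
    gauge_id: str
    n_iterations: int
    converged: bool

    def K(self, dataset_id: str) -> float:
        return self.factors[dataset_id].K

    def B(self, dataset_id: str) -> float:
        return self.factors[dataset_id].B


def scale_datasets(
    datasets: list[ObservationSet] | pd.DataFrame,
    sg: SpaceGroupInfo,
    cell: UnitCell | None = None,
    positivity_threshold: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[ScalingModel, pd.DataFrame]:
    """Refine per-dataset (K, B) against an iteratively re-merged reference.

    Alternates (i) inverse-variance merge of currently scaled observations
    per ASU key with (ii) per-dataset weighted linear least squares of
    log(I_obs / I_ref) on (1, -1/(2 d^2)), until the RMS change in log K
    falls below ``tol``.  The gauge is fixed by the first dataset
    (K = 1, B = 0).  Only observations with I_obs above
    ``positivity_threshold`` * sigma and a positive reference enter the
    log-linear step; all observations enter the merged reference.

    Returns the scaling model and the observation table extended with
    ``g`` (the scale), ``i_scaled`` and ``sigma_scaled`` columns.
    """
    if isinstance(datasets, pd.DataFrame):
        table = datasets.copy()
    else:
        if len(datasets) < 2:
            raise ValueError("scaling needs at least two datasets")
        table = build_observation_table(datasets, sg, cell)

    comps = _connected_components(table)
    if len(comps) > 1:
        comps.sort(key=len, reverse=True)
        raise ValueError(
            "dataset graph is disconnected; smallest component: "
            f"{sorted(comps[-1])}"
        )

    ids = list(dict.fromkeys(table["dataset_id"]))
    gauge = ids[0]
    ds_codes, _ = pd.factorize(table["dataset_id"])
    id_to_code = {d: i for i, d in enumerate(dict.fromkeys(table["dataset_id"]))}
    n_ds = len(ids)

    s = 1.0 / (2.0 * table["d"].to_numpy() ** 2)
    i_obs = table["i_obs"].to_numpy()
    sigma = table["sigma_raw"].to_numpy()
    keys, key_codes = np.unique(table["key"].to_numpy(), return_inverse=True)

    log_k = np.zeros(n_ds)
    b_fac = np.zeros(n_ds)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = np.exp(log_k[ds_codes] - b_fac[ds_codes] * s)
        i_sc = i_obs / g
        w = (g / sigma) ** 2
        sw = np.bincount(key_codes, weights=w, minlength=len(keys))
        swi = np.bincount(key_codes, weights=w * i_sc, minlength=len(keys))
        ref = swi / sw
        ref_per_obs = ref[key_codes]

        usable = (i_obs > positivity_threshold * sigma) & (ref_per_obs > 0)
        new_log_k = log_k.copy()
        new_b = b_fac.copy()
        for code in range(n_ds):
            sel = usable & (ds_codes == code)
            if sel.sum() < 3:
                continue
            y = np.log(i_obs[sel] / ref_per_obs[sel])
            x = s[sel]
            # weight by predicted signal-to-noise so weak, noisy ratios
            # cannot bias the log fit
            wt = (ref_per_obs[sel] * g[sel] / sigma[sel]) ** 2
            sw_ = wt.sum()
            mx = (wt * x).sum() / sw_
            my = (wt * y).sum() / sw_
            vxx = (wt * (x - mx) ** 2).sum() / sw_
            if vxx <= 0:
                continue
            vxy = (wt * (x - mx) * (y - my)).sum() / sw_
            slope = vxy / vxx
            new_b[code] = -slope
            new_log_k[code] = my - slope * mx
        # re-gauge
        gcode = id_to_code[gauge]
        new_log_k -= new_log_k[gcode]
        new_b -= new_b[gcode]
        delta = float(np.sqrt(np.mean((new_log_k - log_k) ** 2)))
        log_k, b_fac = new_log_k, new_b
        if delta < tol:
            converged = True
            break

    g = np.exp(log_k[ds_codes] - b_fac[ds_codes] * s)
    out = table.copy()
    out["g"] = g
    out["i_scaled"] = i_obs / g
    out["sigma_scaled"] = sigma / g
    model = ScalingModel(
        factors={
            d: ScaleFactors(K=float(np.exp(log_k[c])), B=float(b_fac[c]))
            for d, c in id_to_code.items()
        },
        gauge_id=gauge,
        n_iterations=it,
        converged=converged,
    )
    return model, out


# ---------------------------------------------------------------------------
# Error-model / ISa fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorModelFit:
    dataset_id: str
    a: float
    b: float
    isa: float                # math.inf when b below the cap
    n_pairs: int
    converged: bool
    method: str = "binned"    # "binned" or "overall" fallback

    def as_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "a": self.a,
            "b": self.b,
            "isa": "inf" if math.isinf(self.isa) else self.isa,
            "n_pairs": self.n_pairs,
            "converged": self.converged,
            "method": self.method,
        }


def _loo_reference(
    table: pd.DataFrame, weight_var: np.ndarray | None = None
) -> pd.DataFrame:
    """Leave-one-out merged reference per observation, in the scaled frame.

    Adds columns ``loo_ref`` (merged intensity of all *other* observations
    of the same ASU reflection), ``loo_var`` (its variance under the
    per-observation variances ``weight_var``, raw sigmas squared by
    default) and ``n_group`` (group multiplicity).  Rows of singleton
    groups get NaN.
    """
    t = table
    var = (
        t["sigma_scaled"].to_numpy() ** 2
        if weight_var is None
        else np.asarray(weight_var, dtype=float)
    )
    w = 1.0 / var
    i_sc = t["i_scaled"].to_numpy()
    keys, codes = np.unique(t["key"].to_numpy(), return_inverse=True)
    sw = np.bincount(codes, weights=w, minlength=len(keys))
    swi = np.bincount(codes, weights=w * i_sc, minlength=len(keys))
    cnt = np.bincount(codes, minlength=len(keys))
    sw_o = sw[codes] - w
    swi_o = swi[codes] - w * i_sc
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = np.where(sw_o > 0, swi_o / sw_o, np.nan)
        loo_var = np.where(sw_o > 0, 1.0 / sw_o, np.nan)
    out = t.copy()
    out["loo_ref"] = loo
    out["loo_var"] = loo_var
    out["n_group"] = cnt[codes]
    return out


def _fit_one(
    resid: np.ndarray,
    s2: np.ndarray,
    iref: np.ndarray,
    vref: np.ndarray,
    n_bins: int,
) -> tuple[float, float, str]:
    """Moment-matching (a, b) fit from one dataset's leave-one-out residuals.

    Residuals are binned by reference intensity; (a, a*b) solve the
    count-weighted least-squares match of empirical bin variance (reference
    variance subtracted) to a*(sigma^2 + b*I^2), which is exactly the
    condition that the normalised residuals have unit variance per bin.
    If the unconstrained solution drives a non-physical (a <= 0), a is
    pinned to 1 and b refitted alone; if binning degenerates (near-constant
    intensities), a single overall-variance fit with b = 0 is used.
    """
    n_pairs = len(resid)
    n_bins_eff = max(3, min(n_bins, n_pairs // 20))
    q = np.unique(np.quantile(iref, np.linspace(0, 1, n_bins_eff + 1)))
    if len(q) < 4:
        v = float(np.mean(resid ** 2) - np.mean(vref))
        return max(v / float(np.mean(s2)), 1e-6), 0.0, "overall"
    bins = np.clip(np.searchsorted(q, iref, side="right") - 1, 0, len(q) - 2)
    nb = len(q) - 1
    n_j = np.maximum(np.bincount(bins, minlength=nb), 1).astype(float)
    v_j = np.bincount(bins, weights=resid ** 2, minlength=nb) / n_j
    v_j -= np.bincount(bins, weights=vref, minlength=nb) / n_j
    s_j = np.bincount(bins, weights=s2, minlength=nb) / n_j
    m_j = np.bincount(bins, weights=iref ** 2, minlength=nb) / n_j
    X = np.stack([s_j, m_j], axis=1)
    W = np.sqrt(n_j)
    coef, *_ = np.linalg.lstsq(X * W[:, None], v_j * W, rcond=None)
    a, c = float(coef[0]), float(coef[1])
    method = "binned"
    if a <= 0:
        # all variance attributed to the I^2 term; pin a and refit b
        a = 1.0
        c = float((n_j * (v_j - a * s_j) * m_j).sum() / (n_j * m_j ** 2).sum())
        method = "pinned_a"
    b = max(c / a, 0.0)
    return a, b, method


def fit_error_model(
    table: pd.DataFrame,
    dataset_id: str,
    n_bins: int = 5,
    min_pairs: int = 50,
) -> ErrorModelFit:
    """Fit sigma_adj^2 = a (sigma_raw^2 + b I^2) for one dataset.

    ``table`` must carry ``i_scaled``/``sigma_scaled`` columns for the whole
    collection (the leave-one-out merged reference uses every dataset) —
    see :func:`scale_datasets`.  ISa = (a b)^(-1/2), reported as infinity
    when b falls below 1e-12.

    This is a single-pass fit whose reference variance comes from the raw
    sigmas; when several datasets of unequal quality are fitted together,
    prefer :func:`fit_error_models`, which iterates the fits to
    self-consistency so that noisy datasets do not contaminate the
    reference variance of clean ones.
    """
    if "loo_ref" not in table.columns:
        table = _loo_reference(table)
    rows = table[(table["dataset_id"] == dataset_id) & (table["n_group"] >= 2)]
    rows = rows.dropna(subset=["loo_ref"])
    n_pairs = len(rows)
    if n_pairs < min_pairs:
        raise ValueError(
            f"dataset {dataset_id!r}: only {n_pairs} multiply-measured "
            f"observations (< {min_pairs}) — cannot fit error model"
        )
    a, b, method = _fit_one(
        rows["i_scaled"].to_numpy() - rows["loo_ref"].to_numpy(),
        rows["sigma_scaled"].to_numpy() ** 2,
        rows["loo_ref"].to_numpy(),
        rows["loo_var"].to_numpy(),
        n_bins,
    )
    isa = math.inf if b < ISA_CAP_B else (a * b) ** -0.5
    return ErrorModelFit(
        dataset_id=dataset_id, a=a, b=b, isa=isa,
        n_pairs=n_pairs, converged=True, method=method,
    )


def fit_error_models(
    table: pd.DataFrame,
    n_bins: int = 5,
    min_pairs: int = 50,
    n_iter: int = 4,
) -> tuple[dict[str, ErrorModelFit], dict[str, str]]:
    """Self-consistent error-model fit for every dataset in the table.

    The leave-one-out reference and its variance are recomputed each
    iteration from the current adjusted sigmas, so a dataset with large
    systematic error stops being treated as precise when the reference
    for the other datasets is formed.  Returns (fits, failures), failures
    mapping dataset id to the reason no model could be fitted.
    """
    ids = list(dict.fromkeys(table["dataset_id"]))
    sigma2 = table["sigma_scaled"].to_numpy() ** 2
    a_row = np.ones(len(table))
    b_row = np.zeros(len(table))
    ref_sq = np.zeros(len(table))
    fits: dict[str, ErrorModelFit] = {}
    failures: dict[str, str] = {}
    ds_col = table["dataset_id"].to_numpy()
    for it in range(n_iter):
        eff_var = a_row * (sigma2 + b_row * ref_sq)
        t = _loo_reference(table, weight_var=eff_var)
        loo = t["loo_ref"].to_numpy()
        ref_sq = np.where(np.isnan(loo), 0.0, loo) ** 2
        fits, failures = {}, {}
        for ds_id in ids:
            try:
                fit = fit_error_model(t, ds_id, n_bins=n_bins, min_pairs=min_pairs)
            except ValueError as exc:
                failures[ds_id] = str(exc)
                continue
            fits[ds_id] = fit
            sel = ds_col == ds_id
            a_row[sel] = fit.a
            b_row[sel] = fit.b
    return fits, failures


def apply_error_model(
    table: pd.DataFrame, fits: dict[str, ErrorModelFit]
) -> pd.DataFrame:
    """Add the error-model-adjusted sigma column used for merging.

    The I^2 term uses the reflection's group-mean intensity rather than the
    observation's own value: weighting each observation by a function of
    its own noise would anti-correlate weight and error and bias the
    merged means low for strong reflections.
    """
    out = table.copy()
    a = out["dataset_id"].map(lambda d: fits[d].a if d in fits else 1.0).to_numpy()
    b = out["dataset_id"].map(lambda d: fits[d].b if d in fits else 0.0).to_numpy()
    keys, codes = np.unique(out["key"].to_numpy(), return_inverse=True)
    i_sc = out["i_scaled"].to_numpy()
    grp_mean = (
        np.bincount(codes, weights=i_sc, minlength=len(keys))
        / np.bincount(codes, minlength=len(keys))
    )[codes]
    out["sigma_adj"] = np.sqrt(
        a * (out["sigma_scaled"].to_numpy() ** 2 + b * grp_mean ** 2)
    )
    return out


# ---------------------------------------------------------------------------
# Two-round selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionRound:
    retained: tuple[str, ...]
    rejected: dict[str, str]
    fits: dict[str, ErrorModelFit]
    scaling: ScalingModel


@dataclass(frozen=True)
class SelectionResult:
    cell_filter: CellFilterReport
    rounds: tuple[SelectionRound, ...]
    final_retained: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "cell_filter": {
                "length_tol": self.cell_filter.length_tol,
                "angle_tol": self.cell_filter.angle_tol,
                "accepted": self.cell_filter.accepted_ids,
                "rejected": self.cell_filter.rejected,
            },
            "rounds": [
                {
                    "retained": list(r.retained),
                    "rejected": r.rejected,
                    "fits": {d: f.as_dict() for d, f in r.fits.items()},
                    "scales": {
                        d: {"K": sf.K, "B": sf.B}
                        for d, sf in r.scaling.factors.items()
                    },
                    "gauge": r.scaling.gauge_id,
                    "n_iterations": r.scaling.n_iterations,
                    "converged": r.scaling.converged,
                }
                for r in self.rounds
            ],
            "final_retained": list(self.final_retained),
        }


def run_selection(
    datasets: list[ObservationSet],
    ref_cell: UnitCell,
    sg: SpaceGroupInfo,
    isa_cutoff: float = 3.0,
    length_tol: float = 0.02,
    angle_tol: float = 2.0,
    min_pairs: int = 50,
    iterate: bool = False,
    merge_friedel: bool = True,
) -> SelectionResult:
    """Full selection: cell filter, then scale/fit/reject in two rounds.

    Rejection is strict (``isa < isa_cutoff``): a dataset sitting exactly on
    the cutoff is retained.  ``isa_cutoff = 0`` disables ISa rejection.  With
    ``iterate=True`` rejection rounds repeat until no dataset falls below
    the cutoff; the default performs exactly one rejection round followed by
    one re-scaling round.
    """
    if isa_cutoff < 0:
        raise ValueError("isa_cutoff must be >= 0")
    cell_report = check_cell_consistency(datasets, ref_cell, length_tol, angle_tol)
    current = [d for d in datasets if d.dataset_id in set(cell_report.accepted_ids)]
    if len(current) < 2:
        raise ValueError(
            "fewer than two datasets survive the indexing-consistency filter "
            f"({len(current)} of {len(datasets)})"
        )

    def _scale_and_fit(
        members: list[ObservationSet], reject: bool
    ) -> tuple[SelectionRound, list[ObservationSet]]:
        model, table = scale_datasets(members, sg, cell=ref_cell)
        fits, failures = fit_error_models(table, min_pairs=min_pairs)
        rejected: dict[str, str] = dict(failures)
        retained: list[str] = []
        for ds in members:
            fit = fits.get(ds.dataset_id)
            if fit is None:
                continue
            if reject and fit.isa < isa_cutoff:
                rejected[ds.dataset_id] = (
                    f"ISa {fit.isa:.2f} < cutoff {isa_cutoff:.2f}"
                )
            else:
                retained.append(ds.dataset_id)
        rnd = SelectionRound(tuple(retained), rejected, fits, model)
        survivors = [d for d in members if d.dataset_id in set(retained)]
        return rnd, survivors

    rounds: list[SelectionRound] = []
    # rejection round(s): one by default, to a fixpoint with iterate=True
    while True:
        rnd, current = _scale_and_fit(current, reject=True)
        rounds.append(rnd)
        if len(current) < 2:
            attrition = "; ".join(
                f"round {i + 1}: {len(r.retained)} retained"
                for i, r in enumerate(rounds)
            )
            raise ValueError(
                f"ISa rejection left {len(current)} dataset(s); {attrition}"
            )
        if not iterate or not rnd.rejected:
            break
    # final round: re-scale and re-fit the survivors without rejecting
    rnd, current = _scale_and_fit(current, reject=False)
    rounds.append(rnd)

    return SelectionResult(
        cell_filter=cell_report,
        rounds=tuple(rounds),
        final_retained=rounds[-1].retained,
    )
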