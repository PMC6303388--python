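"""Merging in the Laue group and the data-quality statistics block.

Computes everything a crystallographic "Table 1" reports for merged data:
multiplicity-weighted agreement factors (Rmerge, Rmeas, Rpim), half-dataset
correlation CC1/2, mean I/sigma(I), completeness against the complete unique
set, redundancy, the Wilson B factor from the resolution falloff of mean
intensities, and the CC1/2-threshold resolution cutoff.

Conventions
-----------
* Merged intensity per ASU reflection is the inverse-variance-weighted mean
  using the error-model-adjusted sigmas; the propagated sigma is
  (sum of weights)^(-1/2).
* R factors use the unweighted group mean (the convention under which
  Rmeas = sqrt(n/(n-1)) and Rpim = sqrt(1/(n-1)) rescale each group's
  deviations), summed over multiply-observed reflections only.
* A statistic that is undefined on its input (e.g. an R factor with no
  multiply-observed reflection, CC1/2 in a near-empty shell) is reported as
  None / NaN, never silently as zero.
* Negative merged intensities are retained; the Wilson fit skips shells
  with non-positive mean intensity.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .selection import SelectionResult, decode_key, encode_hkl
from .shells import ResolutionShell, assign_to_shells, bin_by_resolution
from .symmetry import (
    SpaceGroupInfo,
    UnitCell,
    d_spacing_array,
    generate_complete_set,
)

__all__ = [
    "MergedReflection",
    "ShellStatistics",
    "MergeReport",
    "merge_intensities",
    "r_factors",
    "cc_half",
    "completeness",
    "wilson_b",
    "resolution_cutoff",
    "compute_report",
]


@dataclass(frozen=True)
class MergedReflection:
    asu_hkl: tuple[int, int, int]
    n_obs: int
    i_mean: float
    sigma_mean: float
    d: float


def merge_intensities(
    table: pd.DataFrame, sigma_col: str = "sigma_adj"
) -> pd.DataFrame:
    """Inverse-variance merge per ASU key.

    ``table`` is a scaled observation table (see ``selection``) carrying
    ``i_scaled`` and an adjusted-sigma column.  Returns one row per unique
    reflection: h, k, l, key, d, n_obs, i_mean, sigma_mean.
    """
    if sigma_col not in table.columns:
        raise KeyError(
            f"table lacks {sigma_col!r}; run the error model first or pass "
            "sigma_col='sigma_scaled'"
        )
    w = 1.0 / table[sigma_col].to_numpy() ** 2
    i_sc = table["i_scaled"].to_numpy()
    keys, codes = np.unique(table["key"].to_numpy(), return_inverse=True)
    sw = np.bincount(codes, weights=w, minlength=len(keys))
    swi = np.bincount(codes, weights=w * i_sc, minlength=len(keys))
    cnt = np.bincount(codes, minlength=len(keys))
    d_first = np.zeros(len(keys))
    d_first[codes[::-1]] = table["d"].to_numpy()[::-1]
    hkl = decode_key(keys)
    return pd.DataFrame(
        {
            "h": hkl[:, 0],
            "k": hkl[:, 1],
            "l": hkl[:, 2],
            "key": keys,
            "d": d_first,
            "n_obs": cnt,
            "i_mean": swi / sw,
            "sigma_mean": 1.0 / np.sqrt(sw),
        }
    )


def merged_records(merged: pd.DataFrame) -> list[MergedReflection]:
    return [
        MergedReflection(
            (int(r.h), int(r.k), int(r.l)), int(r.n_obs), float(r.i_mean),
            float(r.sigma_mean), float(r.d),
        )
        for r in merged.itertuples()
    ]


# ---------------------------------------------------------------------------
# R factors
# ---------------------------------------------------------------------------

def _group_stats(table: pd.DataFrame):
    keys, codes = np.unique(table["key"].to_numpy(), return_inverse=True)
    i = table["i_scaled"].to_numpy()
    cnt = np.bincount(codes, minlength=len(keys))
    mean = np.bincount(codes, weights=i, minlength=len(keys)) / cnt
    dev = np.abs(i - mean[codes])
    return keys, codes, cnt, mean, dev


def r_factors(
    table: pd.DataFrame, assignment: np.ndarray | None = None, n_shells: int = 0
):
    """(r_merge, r_meas, r_pim), overall or per shell.

    With ``assignment`` (per-row shell index, -1 = unassigned) the return is
    a DataFrame with one row per shell; otherwise a single tuple.  Sums run
    over multiply-observed reflections only; an empty sum yields None/NaN.
    """
    keys, codes, cnt, mean, dev = _group_stats(table)
    multi = cnt[codes] >= 2
    n = cnt[codes].astype(float)
    i = table["i_scaled"].to_numpy()
    nm1 = np.maximum(n - 1.0, 1.0)
    num_merge = np.where(multi, dev, 0.0)
    num_meas = np.where(multi, dev * np.sqrt(n / nm1), 0.0)
    num_pim = np.where(multi, dev * np.sqrt(1.0 / nm1), 0.0)
    den = np.where(multi, i, 0.0)

    def _ratios(sel: np.ndarray):
        dd = den[sel].sum()
        if not multi[sel].any() or dd == 0:
            return (None, None, None)
        return (
            float(num_merge[sel].sum() / dd),
            float(num_meas[sel].sum() / dd),
            float(num_pim[sel].sum() / dd),
        )

    if assignment is None:
        return _ratios(np.ones(len(table), dtype=bool))
    rows = []
    for sh in range(int(assignment.max()) + 1 if len(assignment) else 0):
        rows.append(_ratios(assignment == sh))
    return pd.DataFrame(rows, columns=["r_merge", "r_meas", "r_pim"])


# ---------------------------------------------------------------------------
# CC1/2
# ---------------------------------------------------------------------------

def cc_half(
    table: pd.DataFrame,
    assignment: np.ndarray | None = None,
    seed: int = 0,
    n_splits: int = 10,
    min_groups: int = 3,
):
    """Half-dataset correlation by repeated random splits of observations.

    Observations of every multiply-observed reflection are randomly divided
    into two halves; the Pearson correlation of the two half-merged
    (unweighted mean) intensity vectors is computed per shell and averaged
    over ``n_splits`` splits.  Shells with fewer than ``min_groups`` usable
    reflections report NaN.
    """
    rng = np.random.default_rng(seed)
    keys, codes = np.unique(table["key"].to_numpy(), return_inverse=True)
    i = table["i_scaled"].to_numpy()
    cnt = np.bincount(codes, minlength=len(keys))
    usable_group = cnt >= 2
    rows_usable = usable_group[codes]
    if assignment is None:
        assignment = np.zeros(len(table), dtype=int)
    n_shell = int(assignment.max()) + 1 if len(assignment) else 0
    # shell of each group = shell of its rows (constant within group)
    group_shell = np.full(len(keys), -1)
    group_shell[codes] = assignment

    acc = np.zeros(n_shell)
    n_ok = np.zeros(n_shell, dtype=int)
    for _ in range(n_splits):
        u = rng.random(len(table))
        order = np.lexsort((u, codes))
        rank = np.empty(len(table), dtype=int)
        starts = np.zeros(len(keys), dtype=int)
        np.cumsum(cnt[:-1], out=starts[1:])
        rank[order] = np.arange(len(table)) - starts[codes[order]]
        half_a = rank < np.ceil(cnt[codes] / 2)
        sum_a = np.bincount(codes[half_a], weights=i[half_a], minlength=len(keys))
        n_a = np.bincount(codes[half_a], minlength=len(keys))
        sum_b = np.bincount(codes[~half_a], weights=i[~half_a], minlength=len(keys))
        n_b = np.bincount(codes[~half_a], minlength=len(keys))
        ok = usable_group & (n_a > 0) & (n_b > 0)
        with np.errstate(invalid="ignore"):
            ia = np.where(ok, sum_a / np.maximum(n_a, 1), np.nan)
            ib = np.where(ok, sum_b / np.maximum(n_b, 1), np.nan)
        for sh in range(n_shell):
            sel = ok & (group_shell == sh)
            if sel.sum() < min_groups:
                continue
            va, vb = ia[sel], ib[sel]
            if np.std(va) == 0 and np.std(vb) == 0 and np.allclose(va, vb):
                r = 1.0
            elif np.std(va) == 0 or np.std(vb) == 0:
                continue
            else:
                r = float(np.corrcoef(va, vb)[0, 1])
            acc[sh] += r
            n_ok[sh] += 1
    out = np.where(n_ok > 0, acc / np.maximum(n_ok, 1), np.nan)
    return float(out[0]) if n_shell == 1 else out


# ---------------------------------------------------------------------------
# Completeness, Wilson B, resolution cutoff
# ---------------------------------------------------------------------------

def completeness(
    merged: pd.DataFrame,
    cell: UnitCell,
    sg: SpaceGroupInfo,
    shells: list[ResolutionShell],
    merge_friedel: bool = True,
) -> tuple[np.ndarray, float]:
    """Per-shell and overall fraction of the complete unique set observed.

    The complete set is generated to the innermost shell's d_min; entries
    at lower resolution than the outermost shell edge (e.g. the few very
    low-resolution reflections outside the observed range) are counted in
    the first shell, mirroring how a Table 1 resolution range is quoted
    from the lowest observed d.
    """
    full = generate_complete_set(cell, sg, shells[-1].d_min, merge_friedel)
    d_full = d_spacing_array(cell, full)
    assign = assign_to_shells(d_full, shells)
    assign[d_full > shells[0].d_max] = 0
    have = np.isin(encode_hkl(full), merged["key"].to_numpy())
    per_shell = np.empty(len(shells))
    for sh in range(len(shells)):
        sel = assign == sh
        per_shell[sh] = have[sel].mean() if sel.any() else np.nan
    overall = float(have.mean())
    return per_shell, overall


def wilson_b(
    merged: pd.DataFrame,
    cell: UnitCell | None = None,
    d_max_include: float = 4.5,
    n_shells: int = 15,
) -> float:
    """Wilson B from the falloff of shell-mean intensity.

    Fits ln <I> against s = 1/(2 d^2) over equal-count shells restricted to
    d <= ``d_max_include`` (the low-resolution region, where the Wilson
    approximation fails for real macromolecules, is excluded) and returns
    minus the slope.  Requires at least three usable shells.
    """
    d = merged["d"].to_numpy()
    i = merged["i_mean"].to_numpy()
    sel = d <= d_max_include
    if sel.sum() < 3 * n_shells and sel.sum() >= 30:
        n_shells = max(3, sel.sum() // 10)
    if sel.sum() < 9:
        raise ValueError(
            f"only {int(sel.sum())} reflections beyond {d_max_include} A — "
            "cannot fit a Wilson plot"
        )
    shells, assign = bin_by_resolution(d[sel], n_shells, scheme="equal_count")
    s_vals, y_vals = [], []
    for sh in range(len(shells)):
        m = assign == sh
        if not m.any():
            continue
        mean_i = i[sel][m].mean()
        if mean_i <= 0:
            warnings.warn(
                f"Wilson fit: shell {shells[sh]} has non-positive mean "
                "intensity; skipped", stacklevel=2,
            )
            continue
        s_vals.append((1.0 / (2.0 * d[sel][m] ** 2)).mean())
        y_vals.append(math.log(mean_i))
    if len(s_vals) < 3:
        raise ValueError("fewer than 3 usable Wilson shells")
    slope = np.polyfit(np.array(s_vals), np.array(y_vals), 1)[0]
    return float(-slope)


def resolution_cutoff(
    shells: list[ResolutionShell],
    cc_values: np.ndarray,
    threshold: float = 0.3,
) -> float:
    """d_min of the last shell in the initial contiguous run with
    CC1/2 >= threshold, walking from low to high resolution."""
    cc = np.asarray(cc_values, dtype=float)
    if len(cc) != len(shells):
        raise ValueError("cc_values and shells length mismatch")
    if not (cc[0] >= threshold):
        raise ValueError(
            f"lowest-resolution shell already below the CC1/2 threshold "
            f"({cc[0]:.3f} < {threshold}); inspect the data before cutting"
        )
    last = 0
    for sh in range(len(shells)):
        if np.isnan(cc[sh]) or cc[sh] < threshold:
            break
        last = sh
    return shells[last].d_min


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShellStatistics:
    shell: ResolutionShell
    r_merge: float | None
    r_meas: float | None
    r_pim: float | None
    cc_half: float | None
    mean_i_over_sigma: float | None
    completeness: float | None
    redundancy: float | None
    n_unique: int
    n_obs: int

    def as_dict(self) -> dict:
        def _clean(x):
            if x is None:
                return None
            return None if isinstance(x, float) and math.isnan(x) else float(x)

        return {
            "d_max": self.shell.d_max,
            "d_min": self.shell.d_min,
            "r_merge": _clean(self.r_merge),
            "r_meas": _clean(self.r_meas),
            "r_pim": _clean(self.r_pim),
            "cc_half": _clean(self.cc_half),
            "mean_i_over_sigma": _clean(self.mean_i_over_sigma),
            "completeness": _clean(self.completeness),
            "redundancy": _clean(self.redundancy),
            "n_unique": self.n_unique,
            "n_obs": self.n_obs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShellStatistics":
        return cls(
            shell=ResolutionShell(d["d_max"], d["d_min"]),
            r_merge=d["r_merge"], r_meas=d["r_meas"], r_pim=d["r_pim"],
            cc_half=d["cc_half"], mean_i_over_sigma=d["mean_i_over_sigma"],
            completeness=d["completeness"], redundancy=d["redundancy"],
            n_unique=d["n_unique"], n_obs=d["n_obs"],
        )


@dataclass(frozen=True)
class MergeReport:
    overall: ShellStatistics
    shells: tuple[ShellStatistics, ...]
    wilson_b: float | None
    resolution_cutoff: float | None
    dataset_counts: dict[str, int]
    config: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "overall": self.overall.as_dict(),
            "shells": [s.as_dict() for s in self.shells],
            "wilson_b": self.wilson_b,
            "resolution_cutoff": self.resolution_cutoff,
            "dataset_counts": self.dataset_counts,
            "config": self.config,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.as_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MergeReport":
        d = json.loads(text)
        return cls(
            overall=ShellStatistics.from_dict(d["overall"]),
            shells=tuple(ShellStatistics.from_dict(s) for s in d["shells"]),
            wilson_b=d["wilson_b"],
            resolution_cutoff=d["resolution_cutoff"],
            dataset_counts=d["dataset_counts"],
            config=d.get("config", {}),
        )

    def to_text(self) -> str:
        """Table-1-style rendering: overall value (highest shell)."""
        o, hi = self.overall, self.shells[-1]

        def fmt(v, nd=3, pct=False):
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return "NA"
            return f"{v * 100:.1f}" if pct else f"{v:.{nd}f}"

        def pair(label, a, b, nd=3, pct=False):
            return f"{label:<22}{fmt(a, nd, pct)} ({fmt(b, nd, pct)})"

        lines = [
            "Merging statistics (values in parentheses: highest-resolution shell)",
            f"{'Resolution (A)':<22}{o.shell.d_max:.2f}-{o.shell.d_min:.2f} "
            f"({hi.shell.d_max:.2f}-{hi.shell.d_min:.2f})",
            pair("Rmerge", o.r_merge, hi.r_merge),
            pair("Rmeas", o.r_meas, hi.r_meas),
            pair("Rpim", o.r_pim, hi.r_pim),
            pair("CC1/2", o.cc_half, hi.cc_half),
            pair("I/sigI", o.mean_i_over_sigma, hi.mean_i_over_sigma, nd=1),
            pair("Completeness (%)", o.completeness, hi.completeness, pct=True),
            pair("Redundancy", o.redundancy, hi.redundancy, nd=1),
            f"{'Wilson B (A^2)':<22}"
            + ("NA" if self.wilson_b is None else f"{self.wilson_b:.1f}"),
            f"{'Resolution cutoff (A)':<22}"
            + ("NA" if self.resolution_cutoff is None else f"{self.resolution_cutoff:.2f}"),
            f"{'Unique reflections':<22}{o.n_unique}",
            f"{'Observations':<22}{o.n_obs}",
        ]
        for label, count in self.dataset_counts.items():
            lines.append(f"{label:<30}{count}")
        return "\n".join(lines)


def compute_report(
    table: pd.DataFrame,
    cell: UnitCell,
    sg: SpaceGroupInfo,
    n_shells: int = 10,
    scheme: str = "equal_volume",
    seed: int = 0,
    n_splits: int = 10,
    cc_threshold: float = 0.3,
    selection: SelectionResult | None = None,
    merge_friedel: bool = True,
    config: dict | None = None,
    fit_wilson: bool = True,
) -> MergeReport:
    """Assemble the full statistics block from a scaled observation table.

    ``table`` must carry ``sigma_adj`` (error-model-adjusted sigmas); the
    shell layout is derived from the merged reflections' d range.
    """
    merged = merge_intensities(table)
    shells, m_assign = bin_by_resolution(merged["d"].to_numpy(), n_shells, scheme)
    key_shell = dict(zip(merged["key"].to_numpy(), m_assign))
    o_assign = table["key"].map(key_shell).to_numpy()

    rf_shell = r_factors(table, o_assign)
    rf_all = r_factors(table)
    cc_shell = cc_half(table, o_assign, seed=seed, n_splits=n_splits)
    cc_all = cc_half(table, None, seed=seed, n_splits=n_splits)
    comp_shell, comp_all = completeness(merged, cell, sg, shells, merge_friedel)
    try:
        wb = wilson_b(merged)
    except ValueError:
        wb = None
    if not fit_wilson:
        wb = None
    try:
        cut = resolution_cutoff(shells, np.atleast_1d(cc_shell), cc_threshold)
    except ValueError:
        cut = None

    ios = merged["i_mean"].to_numpy() / merged["sigma_mean"].to_numpy()

    def shell_stats(sh: int) -> ShellStatistics:
        g_sel = m_assign == sh
        o_sel = o_assign == sh
        return ShellStatistics(
            shell=shells[sh],
            r_merge=rf_shell.iloc[sh]["r_merge"],
            r_meas=rf_shell.iloc[sh]["r_meas"],
            r_pim=rf_shell.iloc[sh]["r_pim"],
            cc_half=float(np.atleast_1d(cc_shell)[sh]),
            mean_i_over_sigma=float(ios[g_sel].mean()) if g_sel.any() else None,
            completeness=float(comp_shell[sh]),
            redundancy=float(o_sel.sum() / max(g_sel.sum(), 1)),
            n_unique=int(g_sel.sum()),
            n_obs=int(o_sel.sum()),
        )

    shell_list = tuple(shell_stats(sh) for sh in range(len(shells)))
    overall = ShellStatistics(
        shell=ResolutionShell(shells[0].d_max, shells[-1].d_min),
        r_merge=rf_all[0], r_meas=rf_all[1], r_pim=rf_all[2],
        cc_half=float(cc_all) if not np.isnan(cc_all) else None,
        mean_i_over_sigma=float(ios.mean()),
        completeness=comp_all,
        redundancy=float(len(table) / len(merged)),
        n_unique=len(merged),
        n_obs=len(table),
    )

    counts: dict[str, int] = {"datasets_merged": table["dataset_id"].nunique()}
    if selection is not None:
        counts["datasets_input"] = len(selection.cell_filter.checks)
        counts["datasets_after_cell_filter"] = len(selection.cell_filter.accepted_ids)
        for i, rnd in enumerate(selection.rounds):
            counts[f"datasets_retained_round_{i + 1}"] = len(rnd.retained)
    return MergeReport(
        overall=overall,
        shells=shell_list,
        wilson_b=wb,
        resolution_cutoff=cut,
        dataset_counts=counts,
        config=config or {},
    )
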