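"""End-to-end orchestration: cell filter -> round-1 scale/ISa -> rejection
-> round-2 scale -> merge -> statistics -> resolution cutoff.

Every artifact written (selection.json, merged.hkl, report.json, report.txt)
is a pure function of the input wedge files, the configuration and its
seeds; partial artifacts are removed if a stage fails.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .config import PipelineConfig
from .datasets import ObservationSet
from .merging import MergeReport, compute_report, merge_intensities
from .selection import (
    SelectionResult,
    apply_error_model,
    run_selection,
    scale_datasets,
)
from .symmetry import space_group

__all__ = ["run_pipeline", "write_merged_hkl"]

log = logging.getLogger("ssxmerge")


def write_merged_hkl(path: Path, merged) -> None:
    lines = ["! H K L IMEAN SIGIMEAN NOBS"]
    for r in merged.itertuples():
        lines.append(
            f"{int(r.h)} {int(r.k)} {int(r.l)} {r.i_mean:.4f} "
            f"{r.sigma_mean:.4f} {int(r.n_obs)}"
        )
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(
    datasets: list[ObservationSet],
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> tuple[SelectionResult, MergeReport]:
    """Run selection and merging; optionally write artifacts to ``out_dir``."""
    sg = space_group(config.space_group)
    ref_cell = config.cell()

    log.info("pipeline start: %d datasets", len(datasets))
    selection = run_selection(
        datasets,
        ref_cell,
        sg,
        isa_cutoff=config.isa_cutoff,
        length_tol=config.length_tol,
        angle_tol=config.angle_tol,
        min_pairs=config.min_pairs,
        iterate=config.iterate_rejection,
        merge_friedel=config.merge_friedel,
    )
    n_in = len(datasets)
    for ds_id, reason in selection.cell_filter.rejected.items():
        log.info("rejected (indexing): %s — %s", ds_id, reason)
    for i, rnd in enumerate(selection.rounds):
        for ds_id, reason in rnd.rejected.items():
            log.info("rejected (round %d): %s — %s", i + 1, ds_id, reason)
        log.info("round %d: %d retained", i + 1, len(rnd.retained))
    log.info(
        "%d datasets were selected out of %d datasets",
        len(selection.final_retained), n_in,
    )

    retained = [d for d in datasets if d.dataset_id in set(selection.final_retained)]
    _, table = scale_datasets(retained, sg, cell=ref_cell)
    table = apply_error_model(table, selection.rounds[-1].fits)
    report = compute_report(
        table,
        ref_cell,
        sg,
        n_shells=config.n_shells,
        scheme=config.shell_scheme,
        seed=config.seed,
        n_splits=config.n_splits,
        cc_threshold=config.cc_threshold,
        selection=selection,
        merge_friedel=config.merge_friedel,
        config=config.echo(),
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        try:
            p = out_dir / "selection.json"
            p.write_text(json.dumps(selection.as_dict(), indent=2, sort_keys=True))
            written.append(p)
            p = out_dir / "merged.hkl"
            write_merged_hkl(p, merge_intensities(table))
            written.append(p)
            p = out_dir / "report.json"
            p.write_text(report.to_json())
            written.append(p)
            p = out_dir / "report.txt"
            p.write_text(report.to_text() + "\n")
            written.append(p)
        except Exception:
            for p in written:
                p.unlink(missing_ok=True)
            raise
    return selection, report
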