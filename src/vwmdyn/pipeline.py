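"""End-to-end demo pipeline: simulate -> measure -> fit -> dissociate.

Produces the tabular and graphical summaries of the full analysis on
synthetic data: binned placement-performance curves over viewing time
and delay, the fitted placement regression with its interaction test,
the rigid-task precision model, and the free-vs-forced dissociation
summary.  All acceptance-relevant outputs are tabular; figures are
advisory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, io, measures, mom, synthetic

__all__ = ["run_demo"]

log = logging.getLogger("vwmdyn")


def _tertile_edges(x: pd.Series) -> list:
    qs = np.quantile(x.to_numpy(float), [0.0, 1 / 3, 2 / 3, 1.0])
    qs[0] -= 1e-9
    qs[-1] += 1e-9
    out = list(map(float, qs))
    if any(b <= a for a, b in zip(out, out[1:])):  # degenerate spread
        lo, hi = out[0], out[-1]
        out = [lo, lo + (hi - lo) / 3, lo + 2 * (hi - lo) / 3, hi]
    return out


def _plot_curves(binned_v, binned_d, grid, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for ax, table, key, label in (
        (axes[0], binned_v, "viewing_bin", "viewing time bin (s)"),
        (axes[1], binned_d, "delay_bin", "delay bin (s)"),
    ):
        ax.plot(range(len(table)), table["proportion"], "o-")
        ax.set_xticks(range(len(table)))
        ax.set_xticklabels([str(b) for b in table[key]], rotation=30, ha="right")
        ax.set_xlabel(label)
        ax.set_ylabel("proportion placed")
        ax.set_ylim(0, 1)
    ax = axes[2]
    for vb, sub in grid.groupby("viewing_bin", observed=False):
        ax.plot(
            range(len(sub)),
            sub["proportion"].to_numpy(),
            "o-",
            label=f"viewing {vb}",
        )
    ax.set_xticks(range(grid["delay_bin"].nunique()))
    ax.set_xticklabels(
        [str(b) for b in grid["delay_bin"].unique()], rotation=30, ha="right"
    )
    ax.set_xlabel("delay bin (s)")
    ax.set_ylabel("proportion placed")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "performance_curves.png", dpi=120)
    plt.close(fig)


def run_demo(config: io.RunConfig) -> dict:
    """Run the full synthetic analysis and write a report bundle.

    Writes, under ``config.output_dir``: the event logs and measured
    table, the binned performance tables, placement-fit and
    precision-fit summaries, the dissociation summary, a figure, and
    ``results.json`` stamped with the seed and config hash.  Returns
    the results dictionary.
    """
    config = config.resolved()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:  # fail before any compute
        raise OSError(f"output directory {outdir} is not writable: {exc}")

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    log.info("simulating copying-task cohort (%d participants)", config.cohort.n_participants)
    logs = synthetic.generate_copy_task_logs(config.cohort)
    io.write_event_log(logs, outdir / "copy_task_events.tsv")

    rows = measures.measured_items_frame(logs)
    io.write_measured_items(rows, outdir / "measured_items.tsv")

    v_edges = _tertile_edges(rows["viewing_time_s"])
    d_edges = _tertile_edges(rows["delay_s"])
    binned_v = measures.bin_performance(rows, viewing_edges=v_edges)
    binned_d = measures.bin_performance(rows, delay_edges=d_edges)
    grid = measures.bin_performance(rows, viewing_edges=v_edges, delay_edges=d_edges)
    binned_v.to_csv(outdir / "binned_by_viewing.tsv", sep="\t", index=False)
    binned_d.to_csv(outdir / "binned_by_delay.tsv", sep="\t", index=False)
    grid.to_csv(outdir / "binned_grid.tsv", sep="\t", index=False)

    log.info("fitting placement regression")
    full = inference.fit_logistic(rows, include_interaction=True)
    reduced = inference.fit_logistic(rows, include_interaction=False)
    lrt_stat, lrt_df, lrt_p, delta_bic = inference.likelihood_ratio_compare(full, reduced)
    full.summary_frame().to_csv(outdir / "placement_fit.tsv", sep="\t", index=False)

    log.info("simulating rigid-task experiment and fitting precision model")
    records = synthetic.generate_rigid_task_data(config.rigid)
    io.write_report_records(records, outdir / "rigid_task_records.tsv")
    precision_fit = inference.fit_precision_model(records)
    precision_fit.summary_frame().to_csv(outdir / "precision_fit.tsv", sep="\t", index=False)

    log.info("running free-vs-forced dissociation experiment")
    summary = mom.run_dissociation_experiment(
        config.mom,
        n_per_cell=config.dissociation_n_per_cell,
        seed=config.seed + 2,
        n_boot=config.n_boot,
    )
    summary.cell_table.to_csv(outdir / "dissociation_cells.tsv", sep="\t", index=False)

    try:
        _plot_curves(binned_v, binned_d, grid, outdir)
    except Exception as exc:  # pragma: no cover - figures are advisory
        log.warning("figure rendering failed: %s", exc)

    results = {
        "seed": config.seed,
        "config_hash": io.config_hash(config),
        "n_trials": int(rows[["participant_id", "trial_index"]].drop_duplicates().shape[0]),
        "n_measured_rows": int(len(rows)),
        "placement_fit": {
            "coefficients": full.coefficients,
            "standard_errors": full.standard_errors,
            "log_likelihood": full.log_likelihood,
        },
        "interaction_test": {
            "lrt_statistic": lrt_stat,
            "df": lrt_df,
            "p": lrt_p,
            "delta_bic": delta_bic,
        },
        "precision_fit": {
            "coefficients": precision_fit.coefficients,
            "standard_errors": precision_fit.standard_errors,
            "n_cells": precision_fit.n_cells,
        },
        "dissociation": {
            "free_coefficients": summary.free_coefficients,
            "free_interaction_ci": list(summary.free_interaction_ci),
            "forced_coefficients": summary.forced_coefficients,
            "forced_interaction_ci": list(summary.forced_interaction_ci),
            "n_per_cell": summary.n_per_cell,
        },
    }
    with (outdir / "results.json").open("w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return results
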