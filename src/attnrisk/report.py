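"""Serialize an evaluation report bundle to disk (TSV/CSV/JSON + figures)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import report_to_frame


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return x


def save_report(report: dict, outdir, figures: bool = False) -> dict:
    """Write the per-model metric table, curve coordinates and a JSON
    summary under ``outdir``; optionally render SVG figures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = report_to_frame(report)
    summary.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    js = {}
    for name, r in report.items():
        cal = r["calibration"]
        pd.DataFrame({"predicted": cal.grid, "observed": cal.observed,
                      "lower": cal.lower, "upper": cal.upper}).to_csv(
            outdir / f"calibration_{name}.csv", index=False)
        r["decision_curve"].to_frame().to_csv(
            outdir / f"decision_curve_{name}.csv", index=False)
        js[name] = {
            "auc": {"estimate": r["auc"].estimate, "lower": r["auc"].lower,
                    "upper": r["auc"].upper},
            "auprc": {"estimate": r["auprc"].estimate, "lower": r["auprc"].lower,
                      "upper": r["auprc"].upper},
            "recalibration": {k: _jsonable(v)
                              for k, v in r["recalibration"].items()},
        }
    (outdir / "report.json").write_text(json.dumps(js, indent=2, sort_keys=True))
    if figures:
        _render_figures(report, outdir)
    return js


def _render_figures(report: dict, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, r in report.items():
        cal = r["calibration"]
        ax.plot(cal.grid, cal.observed, label=name)
    lim = max(c["calibration"].grid.max() for c in report.values())
    ax.plot([0, lim], [0, lim], "k--", lw=0.8, label="ideal")
    ax.set_xlabel("predicted risk")
    ax.set_ylabel("observed risk")
    ax.legend(fontsize=8)
    fig.savefig(outdir / "calibration.svg", bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    first = next(iter(report.values()))["decision_curve"]
    ax.plot(first.thresholds, first.nb_treat_all, color="gray", lw=0.8,
            label="treat all")
    ax.axhline(0.0, color="black", lw=0.8, label="treat none")
    for name, r in report.items():
        dc = r["decision_curve"]
        ax.plot(dc.thresholds, dc.nb_model, label=name)
    ax.set_ylim(bottom=-0.05)
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.legend(fontsize=8)
    fig.savefig(outdir / "decision_curves.svg", bbox_inches="tight")
    plt.close(fig)


def save_hyperparam_importance(result: dict, outdir, figures: bool = False) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result["summary"].to_csv(outdir / "hyperparam_importance.tsv", sep="\t",
                             index=False)
    result["attributions"].to_csv(outdir / "hyperparam_attributions.csv",
                                  index=False)
    if figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        attr = result["attributions"]
        order = result["summary"]["hyperparameter"].tolist()
        fig, ax = plt.subplots(figsize=(6, 0.5 * len(order) + 1))
        rng = np.random.default_rng(0)
        for i, hp in enumerate(order):
            sub = attr[attr["hyperparameter"] == hp]
            jitter = rng.uniform(-0.15, 0.15, len(sub))
            vals = sub["value"].to_numpy()
            vr = vals.max() - vals.min()
            colors = (vals - vals.min()) / vr if vr > 0 else np.full(len(vals), 0.5)
            ax.scatter(sub["attribution"], np.full(len(sub), i) + jitter,
                       c=colors, cmap="coolwarm", s=12)
        ax.set_yticks(range(len(order)), order)
        ax.invert_yaxis()
        ax.axvline(0.0, color="gray", lw=0.6)
        ax.set_xlabel("attribution to validation AUC")
        fig.savefig(outdir / "hyperparam_importance.svg", bbox_inches="tight")
        plt.close(fig)
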