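"""Accuracy quantification for the inverse model.

Per-sample accuracy is the (unsigned, linear-scale) percent standard error
``E = 100 * |truth - predicted| / truth``; a parameter's headline figure is
its 95% confidence level, defined as the error value below which 95% of
the test records fall (95th percentile with linear interpolation between
order statistics). Reports carry per-record prediction-versus-truth and
error-versus-truth tables for the three recovered parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import Dataset
from .inversion import MomentInversionResults, TARGET_LABELS
from .montecarlo import InvalidParameterError

__all__ = [
    "standard_error",
    "confidence_level",
    "EvaluationReport",
    "evaluate_model",
    "plot_prediction_vs_truth",
    "plot_error_vs_truth",
]


def standard_error(truth, predicted):
    """Percent standard error 100 * |truth - predicted| / truth.

    Always evaluated on the linear parameter scale, regardless of the log
    transforms used during training.
    """
    truth = np.asarray(truth, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if np.any(truth == 0.0):
        raise InvalidParameterError("standard error is undefined for zero truth")
    out = 100.0 * np.abs(truth - predicted) / np.abs(truth)
    return float(out) if out.ndim == 0 else out


def confidence_level(errors, q: float = 95.0) -> float:
    """Error value below which ``q`` percent of the records fall.

    Linear interpolation between order statistics (the numpy default), so
    the value is pinned reproducibly even at small sample sizes.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise InvalidParameterError("confidence_level requires a non-empty error sequence")
    if not 0.0 <= q <= 100.0:
        raise InvalidParameterError("q must lie in [0, 100]")
    return float(np.percentile(errors, q, method="linear"))


@dataclass
class EvaluationReport:
    """Per-record predictions and per-parameter error summaries.

    ``records`` columns: truth_*, pred_* and err_* (percent) for each of
    n, mu_s_prime and mu_a. ``summary`` is indexed by parameter with
    columns median_error_pct, mean_error_pct and cl95_pct.
    """

    records: pd.DataFrame
    summary: pd.DataFrame
    n_test: int

    def __str__(self) -> str:
        lines = [
            f"Inverse-model evaluation on {self.n_test} held-out records",
            "=" * 58,
            self.summary.to_string(float_format=lambda v: f"{v:10.3f}"),
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def summary_to_csv(self, path) -> None:
        self.summary.to_csv(path)


def evaluate_model(
    results: MomentInversionResults,
    dataset: Dataset,
    split: Optional[str] = "test",
) -> EvaluationReport:
    """Predict every record of a split and summarize the percent errors.

    The default split is the held-out test set; pass ``split='train'`` for
    consistency checks (an overfit model should score near zero there).
    """
    frame = dataset._subset(split)
    if len(frame) == 0:
        raise InvalidParameterError(f"no records in split {split!r}")
    features = frame[dataset.feature_columns].to_numpy(dtype=float)
    truth = frame[["n", "mu_s_prime", "mu_a"]].to_numpy(dtype=float)
    pred = results.predict(features)

    cols = {}
    for j, name in enumerate(TARGET_LABELS):
        cols[f"truth_{name}"] = truth[:, j]
        cols[f"pred_{name}"] = pred[:, j]
        cols[f"err_{name}"] = standard_error(truth[:, j], pred[:, j])
    records = pd.DataFrame(cols)
    records.insert(0, "run_id", frame["run_id"].to_numpy())

    summary = pd.DataFrame(
        {
            "median_error_pct": [float(np.median(records[f"err_{p}"])) for p in TARGET_LABELS],
            "mean_error_pct": [float(np.mean(records[f"err_{p}"])) for p in TARGET_LABELS],
            "cl95_pct": [confidence_level(records[f"err_{p}"]) for p in TARGET_LABELS],
        },
        index=list(TARGET_LABELS),
    )
    return EvaluationReport(records=records, summary=summary, n_test=len(records))


_SCALES = {"n": "linear", "mu_s_prime": "log", "mu_a": "log"}
_TEX = {"n": "n", "mu_s_prime": r"$\mu_s'$ (mm$^{-1}$)", "mu_a": r"$\mu_a$ (mm$^{-1}$)"}


def plot_prediction_vs_truth(report: EvaluationReport, path=None):
    """Three-panel prediction-vs-truth scatter with the y = x reference."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, name in zip(axes, TARGET_LABELS):
        t = report.records[f"truth_{name}"]
        p = report.records[f"pred_{name}"]
        ax.plot(t, p, ".", ms=2, alpha=0.4)
        lo, hi = float(t.min()), float(t.max())
        ax.plot([lo, hi], [lo, hi], "r--", lw=1)
        if _SCALES[name] == "log":
            ax.set_xscale("log")
            ax.set_yscale("log")
        ax.set_xlabel(f"truth {_TEX[name]}")
        ax.set_ylabel(f"predicted {_TEX[name]}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_error_vs_truth(report: EvaluationReport, path=None):
    """Error-vs-truth scatter per parameter with the 95% level line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, name in zip(axes, TARGET_LABELS):
        t = report.records[f"truth_{name}"]
        e = report.records[f"err_{name}"]
        ax.plot(t, e, ".", ms=2, alpha=0.4)
        ax.axhline(report.summary.loc[name, "cl95_pct"], color="r", lw=1, label="95% level")
        if _SCALES[name] == "log":
            ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel(f"truth {_TEX[name]}")
        ax.set_ylabel("standard error (%)")
        ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
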