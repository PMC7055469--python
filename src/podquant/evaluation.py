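"""Classification and counting metrics.

Confusion matrices are oriented rows = Predicted, columns = Actual, class
order (base, body, stem, tip).  Under this orientation the reported
"precision" of a class is diagonal / column sum and "recall" is
diagonal / row sum — the reverse of the textbook row/column mapping, but
the operational definition that reproduces the published per-class tables
this layout comes from; totals are unweighted macro averages of the four
per-class values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

CLASS_NAMES = ("base", "body", "stem", "tip")
N = 4


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (4, 4) ints, rows=Predicted, cols=Actual

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (N, N) or np.any(c < 0):
            raise ValueError("confusion matrix must be 4x4 nonnegative")

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())


@dataclass(frozen=True)
class MetricsReport:
    per_class_precision: dict[str, float]  # percent
    per_class_recall: dict[str, float]     # percent
    total_precision: float                 # percent, macro
    total_recall: float                    # percent, macro


@dataclass(frozen=True)
class CountAgreement:
    correlation_coefficient: float  # Pearson r
    r_squared: float
    rmse: float
    errors: np.ndarray              # per-image (actual - predicted)


def confusion_from_pairs(predicted, actual) -> ConfusionMatrix:
    predicted = np.asarray(predicted, dtype=int)
    actual = np.asarray(actual, dtype=int)
    if predicted.shape != actual.shape:
        raise ValueError("label sequences must have equal length")
    if predicted.size and (predicted.min() < 0 or predicted.max() >= N
                           or actual.min() < 0 or actual.max() >= N):
        raise ValueError("labels must lie in {0, 1, 2, 3}")
    counts = np.zeros((N, N), dtype=int)
    np.add.at(counts, (predicted, actual), 1)
    return ConfusionMatrix(counts)


def metrics_from_confusion(m: ConfusionMatrix) -> MetricsReport:
    """Per-class and macro precision/recall in percent.

    A class with an empty row or column yields an undefined metric, which
    is excluded from the macro average with a warning.
    """
    c = np.asarray(m.counts, dtype=float)
    diag = np.diag(c)
    col = c.sum(axis=0)
    row = c.sum(axis=1)
    precision, recall = {}, {}
    for i, name in enumerate(CLASS_NAMES):
        precision[name] = 100.0 * diag[i] / col[i] if col[i] > 0 else np.nan
        recall[name] = 100.0 * diag[i] / row[i] if row[i] > 0 else np.nan
    if any(np.isnan(v) for v in (*precision.values(), *recall.values())):
        warnings.warn("class with zero denominator excluded from macro "
                      "averages", UserWarning)
    return MetricsReport(
        per_class_precision=precision,
        per_class_recall=recall,
        total_precision=float(np.nanmean(list(precision.values()))),
        total_recall=float(np.nanmean(list(recall.values()))),
    )


def count_agreement(predicted, manual) -> CountAgreement:
    """Pearson correlation, its square, RMSE and the signed error vector."""
    predicted = np.asarray(predicted, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if predicted.shape != manual.shape or predicted.ndim != 1:
        raise ValueError("need paired 1-d count vectors")
    if predicted.size < 3:
        raise ValueError("need at least 3 paired counts")
    if predicted.std() == 0 or manual.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    r = float(sps.pearsonr(predicted, manual).statistic)
    errors = manual - predicted
    return CountAgreement(
        correlation_coefficient=r,
        r_squared=r * r,
        rmse=float(np.sqrt(np.mean(errors ** 2))),
        errors=errors,
    )


def error_histogram(errors, bin_width: float = 1.0):
    """Bin signed counting errors (actual - predicted).

    Returns ``(bin_edges, counts)`` with integer-aligned bins; the counts
    sum to the number of errors.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        return np.array([0.0, bin_width]), np.array([0])
    lo = np.floor(errors.min() / bin_width) * bin_width
    hi = np.ceil(errors.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo - bin_width / 2, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(errors, bins=edges)
    return edges, counts


# ---------------------------------------------------------------------------
# plots (saved as PNG; used by the CLI evaluate subcommand)
# ---------------------------------------------------------------------------

def scatter_plot(path, predicted, manual, title="Predicted vs manual counts"):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agreement = count_agreement(predicted, manual)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(manual, predicted, s=12, alpha=0.7)
    lim = [0, max(np.max(manual), np.max(predicted)) * 1.05]
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel("manual count")
    ax.set_ylabel("predicted count")
    ax.set_title(f"{title} (R$^2$={agreement.r_squared:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def histogram_plot(path, errors, bin_width: float = 1.0,
                   title="Count error (actual - predicted)"):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges, counts = error_histogram(errors, bin_width)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(edges[:-1] + bin_width / 2, counts, width=bin_width * 0.9)
    ax.set_xlabel("error")
    ax.set_ylabel("images")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
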