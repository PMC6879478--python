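"""Quality-control summaries: per-sample Ct distributions and the
per-feature CV comparison before/after normalization.

CV is computed on the Ct scale (sd with n-1 denominator over the absolute
mean); features whose mean is within epsilon of zero after normalization are
dropped from the CV vector and logged.  The pre/post CV distributions are
compared with a two-sample two-sided Kolmogorov-Smirnov test (asymptotic
p-value) and rendered as ECDF curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .qpcr_io import CtDataset

__all__ = [
    "QCReport",
    "cv_per_feature",
    "ecdf_compare",
    "ecdf_points",
    "build_qc_report",
    "boxplot_figure",
    "ecdf_figure",
    "render_boxplots",
    "render_ecdf",
    "five_number_summaries",
]

log = logging.getLogger(__name__)

MEAN_EPS = 1e-8


def cv_per_feature(m: np.ndarray, eps: float = MEAN_EPS) -> np.ndarray:
    """Coefficient of variation per feature row over non-missing samples.

    Rows with fewer than two observations or |mean| < eps are dropped
    (logged); the returned vector holds only finite values.
    """
    m = np.asarray(m, dtype=float)
    cvs = []
    n_dropped = 0
    for row in m:
        vals = row[~np.isnan(row)]
        if len(vals) < 2:
            n_dropped += 1
            continue
        mean = vals.mean()
        if abs(mean) < eps:
            n_dropped += 1
            continue
        cvs.append(vals.std(ddof=1) / abs(mean))
    if n_dropped:
        log.info("CV: dropped %d features (too few observations or ~zero mean)",
                 n_dropped)
    return np.array(cvs)


def ecdf_points(values) -> tuple[np.ndarray, np.ndarray]:
    """ECDF as (sorted values, cumulative fractions), a step from 0 to 1."""
    x = np.sort(np.asarray(values, dtype=float))
    y = np.arange(1, len(x) + 1) / len(x)
    return x, y


def ecdf_compare(cv_pre, cv_post):
    """Two-sample two-sided KS comparison of the two CV distributions."""
    cv_pre = np.asarray(cv_pre, dtype=float)
    cv_post = np.asarray(cv_post, dtype=float)
    if cv_pre.size == 0 or cv_post.size == 0:
        raise ValueError("both CV vectors must be nonempty")
    res = stats.ks_2samp(cv_pre, cv_post, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue), (
        ecdf_points(cv_pre), ecdf_points(cv_post))


def five_number_summaries(ds: CtDataset) -> pd.DataFrame:
    """Min/Q1/median/Q3/max per sample over non-missing Ct values."""
    rows = []
    for j, name in enumerate(ds.sample_names):
        vals = ds.ct[~np.isnan(ds.ct[:, j]), j]
        if len(vals) == 0:
            rows.append({"sample": name, "min": np.nan, "q1": np.nan,
                         "median": np.nan, "q3": np.nan, "max": np.nan})
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"sample": name, "min": vals.min(), "q1": q1,
                     "median": med, "q3": q3, "max": vals.max()})
    return pd.DataFrame(rows)


@dataclass
class QCReport:
    summaries_pre: pd.DataFrame
    summaries_post: pd.DataFrame
    cv_pre: np.ndarray
    cv_post: np.ndarray
    ks_D: float
    ks_p: float


def build_qc_report(masked: CtDataset, normalized: CtDataset) -> QCReport:
    """Assemble the QC report from the post-categorization (masked) and
    normalized datasets."""
    cv_pre = cv_per_feature(masked.ct)
    cv_post = cv_per_feature(normalized.ct)
    ks_d, ks_p, _ = ecdf_compare(cv_pre, cv_post)
    return QCReport(
        summaries_pre=five_number_summaries(masked),
        summaries_post=five_number_summaries(normalized),
        cv_pre=cv_pre,
        cv_post=cv_post,
        ks_D=ks_d,
        ks_p=ks_p,
    )


def boxplot_figure(ds: CtDataset, title: str = "Ct distribution"):
    """One box per sample, in treatment-file order; missing values skipped."""
    data = [ds.ct[~np.isnan(ds.ct[:, j]), j] for j in range(ds.n_samples)]
    data = [d if len(d) else np.array([np.nan]) for d in data]
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * ds.n_samples + 2), 4.5))
    ax.boxplot(data, tick_labels=ds.sample_names)
    ax.set_title(title)
    ax.set_ylabel("Ct")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    return fig


def ecdf_figure(report: QCReport):
    """Pre/post CV ECDF curves with the KS p-value in the title."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for values, label, color in ((report.cv_pre, "after categorization", "tab:blue"),
                                 (report.cv_post, "after normalization", "tab:green")):
        x, y = ecdf_points(values)
        ax.step(x, y, where="post", label=label, color=color)
    ax.set_xlabel("coefficient of variation")
    ax.set_ylabel("ECDF")
    ax.set_title(f"KS p = {report.ks_p:.4g}")
    ax.legend()
    fig.tight_layout()
    return fig


def render_boxplots(ds: CtDataset, path, title: str = "Ct distribution") -> None:
    fig = boxplot_figure(ds, title)
    fig.savefig(path, format="png", dpi=100)
    plt.close(fig)


def render_ecdf(report: QCReport, path) -> None:
    fig = ecdf_figure(report)
    fig.savefig(path, format="png", dpi=100)
    plt.close(fig)
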