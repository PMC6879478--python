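"""Ct normalization methods and reference-gene stability estimation.

Six normalization options are provided: global mean, modified global mean
(common-detected feature set, the geometric-mean equivalent on the linear
scale), deltaCt against housekeeping features (given explicitly or selected
by geNorm / NormFinder stability), quantile, and the two rank-invariant
procedures (norm / scale).  The rank-invariant procedures require complete
data, so a cubic-spline pre-fill over sample index is applied internally;
original missing positions are restored in the output.

All methods preserve missingness exactly: no method invents or destroys a
missing value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.stats import rankdata
import statsmodels.api as sm

from .qpcr_io import CtDataset, TreatmentMap

__all__ = [
    "NormalizationSpec",
    "StabilityReport",
    "NormalizationError",
    "spline_fill",
    "normalize_global_mean",
    "normalize_modified_global_mean",
    "normalize_deltact",
    "normalize_quantile",
    "normalize_rank_invariant",
    "genorm_stability",
    "normfinder_stability",
    "apply_normalization",
    "METHODS",
]

log = logging.getLogger(__name__)

METHODS = (
    "global_mean",
    "modified_global_mean",
    "deltact",
    "quantile",
    "norm_rank_invariant",
    "scale_rank_invariant",
)


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizationSpec:
    """Which method to run and, for deltaCt, how to pick housekeepers.

    ``genorm_direction`` selects which side of the cutoff counts as stable:
    "below" (low M = stable, the convention of the original stability
    measure, the default) or "above".
    """

    method: str = "global_mean"
    housekeepers: tuple[str, ...] | None = None
    hk_selector: str = "explicit"
    genorm_cutoff: float = 1.5
    genorm_direction: str = "below"
    hk_count: int = 1
    rank_invariant_min_set: int = 5

    def __post_init__(self):
        if self.method not in METHODS:
            raise NormalizationError(f"unknown method {self.method!r}; one of {METHODS}")
        if self.hk_selector not in ("explicit", "genorm", "normfinder"):
            raise NormalizationError(f"unknown hk_selector {self.hk_selector!r}")
        if self.method == "deltact" and self.hk_selector == "explicit" and not self.housekeepers:
            raise NormalizationError(
                "deltact requires housekeepers or hk_selector in {genorm, normfinder}"
            )
        if self.genorm_direction not in ("below", "above"):
            raise NormalizationError("genorm_direction must be 'below' or 'above'")


@dataclass
class StabilityReport:
    """Per-feature stability scores and the selected housekeeper set."""

    method: str
    scores: dict[str, float]
    selected: list[str]
    excluded_features: list[str] = field(default_factory=list)

    def __post_init__(self):
        missing = set(self.selected) - set(self.scores)
        if missing:
            raise NormalizationError(f"selected features missing scores: {sorted(missing)}")
        bad = [g for g, v in self.scores.items() if not np.isfinite(v)]
        if bad:
            raise NormalizationError(f"non-finite stability scores for {bad}")


# ---------------------------------------------------------------------------
# spline pre-fill


def spline_fill(m: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Fill missing entries row-wise with a natural cubic spline over sample
    index (treatment-file order).

    Interior gaps are interpolated; leading/trailing gaps are extrapolated.
    Rows with fewer than two observed values are left untouched and their
    indices returned as flagged.
    """
    m = np.asarray(m, dtype=float)
    out = m.copy()
    flagged: list[int] = []
    x = np.arange(m.shape[1], dtype=float)
    for i in range(m.shape[0]):
        row = m[i]
        obs = ~np.isnan(row)
        if obs.all():
            continue
        if obs.sum() < 2:
            flagged.append(i)
            continue
        spline = CubicSpline(x[obs], row[obs], bc_type="natural", extrapolate=True)
        out[i, ~obs] = spline(x[~obs])
    return out, flagged


# ---------------------------------------------------------------------------
# mean-based methods


def normalize_global_mean(ds: CtDataset) -> CtDataset:
    """Subtract each sample's mean of non-missing Ct values from that sample."""
    out = ds.copy()
    empty = np.isnan(out.ct).all(axis=0)
    if empty.any():
        bad = [s for s, e in zip(out.sample_names, empty) if e]
        raise NormalizationError(f"samples with no observed Ct values: {bad}")
    col_means = np.nanmean(out.ct, axis=0)
    out.ct = out.ct - col_means
    return out


def normalize_modified_global_mean(ds: CtDataset) -> CtDataset:
    """Subtract the per-sample mean over the common-detected feature set.

    The reference set S holds the features observed in every sample;
    subtracting its arithmetic mean on the Ct scale equals dividing by its
    geometric mean on the linear 2^-Ct scale.
    """
    out = ds.copy()
    common = ~np.isnan(out.ct).any(axis=1)
    if not common.any():
        raise NormalizationError("no feature is observed in every sample")
    col_means = out.ct[common].mean(axis=0)
    out.ct = out.ct - col_means
    return out


def normalize_deltact(ds: CtDataset, spec: NormalizationSpec,
                      treatment: TreatmentMap | None = None
                      ) -> tuple[CtDataset, StabilityReport]:
    """DeltaCt: subtract the mean housekeeper Ct of each sample.

    Housekeepers are either the explicit ``spec.housekeepers`` or selected by
    the configured stability method.  Housekeepers missing in a sample are
    dropped from that sample's reference mean.
    """
    if spec.hk_selector == "explicit":
        hk = list(spec.housekeepers or ())
        absent = [g for g in hk if g not in ds.feature_names]
        if absent:
            raise NormalizationError(f"housekeepers not in dataset: {absent}")
        report = StabilityReport("explicit", {g: 0.0 for g in hk}, hk)
    elif spec.hk_selector == "genorm":
        report = genorm_stability(ds.ct, ds.feature_names,
                                  cutoff=spec.genorm_cutoff,
                                  direction=spec.genorm_direction)
        hk = report.selected
    else:
        if treatment is None:
            raise NormalizationError("normfinder selection requires a treatment map")
        report = normfinder_stability(ds.ct, ds.feature_names, ds.sample_names,
                                      treatment, n_select=spec.hk_count)
        hk = report.selected
    if not hk:
        raise NormalizationError(f"housekeeper selection ({spec.hk_selector}) is empty")

    rows = [i for i, g in enumerate(ds.feature_names) if g in set(hk)]
    out = ds.copy()
    hk_ct = out.ct[rows]
    n_obs = (~np.isnan(hk_ct)).sum(axis=0)
    if (n_obs == 0).any():
        bad = [s for s, n in zip(out.sample_names, n_obs) if n == 0]
        raise NormalizationError(f"all housekeepers missing in samples: {bad}")
    ref = np.nanmean(hk_ct, axis=0)
    out.ct = out.ct - ref
    return out, report


# ---------------------------------------------------------------------------
# quantile


def normalize_quantile(ds: CtDataset) -> CtDataset:
    """Classical quantile normalization, missing-aware.

    The reference distribution is the mean across samples of each sample's
    sorted non-missing values interpolated onto a common quantile grid; every
    value is then replaced by the reference value at its own within-sample
    quantile.  Missing cells stay missing.
    """
    if ds.n_samples < 2:
        raise NormalizationError("quantile normalization needs >= 2 samples")
    out = ds.copy()
    counts = (~np.isnan(out.ct)).sum(axis=0)
    if (counts == 0).any():
        bad = [s for s, n in zip(out.sample_names, counts) if n == 0]
        raise NormalizationError(f"samples with no observed Ct values: {bad}")

    n_ref = int(counts.max())
    grid = np.linspace(0.0, 1.0, n_ref) if n_ref > 1 else np.array([0.5])
    curves = np.empty((out.n_samples, len(grid)))
    for j in range(out.n_samples):
        vals = np.sort(out.ct[~np.isnan(out.ct[:, j]), j])
        if len(vals) == 1:
            curves[j] = vals[0]
        else:
            p = np.linspace(0.0, 1.0, len(vals))
            curves[j] = np.interp(grid, p, vals)
    reference = curves.mean(axis=0)

    for j in range(out.n_samples):
        col = out.ct[:, j]
        obs = ~np.isnan(col)
        n = obs.sum()
        if n == 1:
            out.ct[obs, j] = reference.mean() if n_ref == 1 else np.interp(
                0.5, grid, reference)
            continue
        ranks = rankdata(col[obs], method="average") - 1.0
        out.ct[obs, j] = np.interp(ranks / (n - 1), grid, reference)
    return out


# ---------------------------------------------------------------------------
# rank-invariant


def _invariant_set(sample: np.ndarray, reference: np.ndarray,
                   low: float = 0.003, high: float = 0.007,
                   max_iter: int = 10) -> np.ndarray:
    """Approximately-rank-invariant feature set of one sample vs reference.

    Iterative trimmed-rank selection: points whose normalized rank difference
    exceeds a threshold (interpolated between ``low`` and ``high`` by average
    rank) are dropped until a fixed point or ``max_iter``.
    """
    n = len(sample)
    keep = np.ones(n, dtype=bool)
    for _ in range(max_iter):
        m = keep.sum()
        if m == 0:
            break
        rs = rankdata(sample[keep]) / m
        rr = rankdata(reference[keep]) / m
        avg = (rs + rr) / 2.0
        thr = low + (high - low) * avg
        new_local = np.abs(rs - rr) < thr
        new_keep = np.zeros(n, dtype=bool)
        new_keep[np.flatnonzero(keep)[new_local]] = True
        if (new_keep == keep).all():
            break
        keep = new_keep
    return keep


def _monotone_curve_offset(ref: np.ndarray, samp: np.ndarray, values: np.ndarray,
                           span: float = 0.3) -> np.ndarray:
    """Map sample values back to the reference scale through the inverse of a
    monotone lowess fit of sample vs reference over the invariant pairs."""
    order = np.argsort(ref)
    x = ref[order]
    fitted = sm.nonparametric.lowess(samp[order], x, frac=span, return_sorted=False)
    fitted = np.maximum.accumulate(fitted)  # enforce monotone non-decreasing
    out = np.empty_like(values)
    lo_f, hi_f = fitted[0], fitted[-1]
    inside = (values >= lo_f) & (values <= hi_f)
    out[inside] = np.interp(values[inside], fitted, x)
    out[values < lo_f] = values[values < lo_f] - (lo_f - x[0])
    out[values > hi_f] = values[values > hi_f] - (hi_f - x[-1])
    return out


def normalize_rank_invariant(ds: CtDataset, mode: str = "norm",
                             min_set: int = 5) -> CtDataset:
    """Rank-invariant normalization against the per-feature mean reference.

    A spline-filled complete copy is used for selection and fitting only; the
    original missing positions are restored in the output.  ``mode="norm"``
    fits a monotone smooth curve per sample through its invariant pairs and
    transforms the sample through the curve's inverse; ``mode="scale"``
    subtracts a per-sample shift computed on features invariant in every
    sample-vs-reference comparison.
    """
    if mode not in ("norm", "scale"):
        raise NormalizationError("mode must be 'norm' or 'scale'")
    if ds.n_samples < 2:
        raise NormalizationError("rank-invariant normalization needs >= 2 samples")
    out = ds.copy()
    missing = np.isnan(out.ct)
    work, flagged = spline_fill(out.ct)
    usable = np.ones(out.n_features, dtype=bool)
    usable[flagged] = False
    if flagged:
        log.warning("rank-invariant: %d all-or-nearly-missing features ignored "
                    "for fitting", len(flagged))
    filled = work[usable]
    reference = filled.mean(axis=1)

    keeps = np.column_stack([
        _invariant_set(filled[:, j], reference) for j in range(out.n_samples)
    ])

    if mode == "scale":
        invariant = keeps.all(axis=1)
        if invariant.sum() < min_set:
            raise NormalizationError(
                f"rank-invariant set has {int(invariant.sum())} features "
                f"(< {min_set}); consider quantile normalization")
        grand = filled[invariant].mean()
        shifts = filled[invariant].mean(axis=0) - grand
        out.ct = out.ct - shifts
    else:
        new = work.copy()
        rows = np.flatnonzero(usable)
        for j in range(out.n_samples):
            keep = keeps[:, j]
            if keep.sum() < min_set:
                raise NormalizationError(
                    f"rank-invariant set for sample {out.sample_names[j]!r} has "
                    f"{int(keep.sum())} features (< {min_set}); consider "
                    f"quantile normalization")
            new[rows, j] = _monotone_curve_offset(
                reference[keep], filled[keep, j], work[rows, j])
        out.ct = new
    out.ct[missing] = np.nan
    return out


# ---------------------------------------------------------------------------
# stability measures


def genorm_stability(m: np.ndarray, feature_names: list[str],
                     cutoff: float = 1.5, direction: str = "below") -> StabilityReport:
    """Pairwise-variation gene stability.

    For features j,k: V_jk = sd across samples of (Ct_j - Ct_k) (n-1
    denominator); M_j = mean of V_jk over k != j.  Features with any missing
    value are excluded from scoring and reported.  Low M = stable; selection
    keeps M strictly on the configured side of the cutoff.
    """
    m = np.asarray(m, dtype=float)
    complete = ~np.isnan(m).any(axis=1)
    excluded = [g for g, c in zip(feature_names, complete) if not c]
    rows = m[complete]
    names = [g for g, c in zip(feature_names, complete) if c]
    n = rows.shape[0]
    if n < 3:
        raise NormalizationError(
            f"geNorm needs >= 3 complete features, found {n} "
            f"(excluded: {excluded[:10]}{'...' if len(excluded) > 10 else ''})")
    if rows.shape[1] < 2:
        raise NormalizationError("geNorm needs >= 2 samples")
    # sd of pairwise differences; vectorized via the variance identity would
    # lose the explicit pairing, keep the double loop readable (n is small).
    M = np.zeros(n)
    for j in range(n):
        diffs = rows - rows[j]
        v = np.delete(diffs, j, axis=0).std(axis=1, ddof=1)
        M[j] = v.mean()
    scores = dict(zip(names, M))
    if direction == "below":
        selected = [g for g, s in zip(names, M) if s < cutoff]
    else:
        selected = [g for g, s in zip(names, M) if s > cutoff]
    return StabilityReport("genorm", scores, selected, excluded)


def normfinder_stability(m: np.ndarray, feature_names: list[str],
                         sample_names: list[str], treatment: TreatmentMap,
                         n_select: int = 1) -> StabilityReport:
    """Model-based stability combining intra- and inter-group variation.

    Operates on the Ct (log) scale.  Per group, gene-specific variances are
    estimated from two-way centered residuals with the small-gene-count bias
    correction; the inter-group deviation of each gene's group means is
    shrunk toward zero by its sampling variance.  The stability value is the
    group-averaged sum of the absolute shrunk deviation and the standard
    error of the gene in that group; the smallest value is the most stable.
    """
    m = np.asarray(m, dtype=float)
    complete = ~np.isnan(m).any(axis=1)
    excluded = [g for g, c in zip(feature_names, complete) if not c]
    rows = m[complete]
    names = [g for g, c in zip(feature_names, complete) if c]
    G = rows.shape[0]
    if G < 3:
        raise NormalizationError(f"NormFinder needs >= 3 complete features, found {G}")

    col_of = {s: j for j, s in enumerate(sample_names)}
    group_cols = []
    for grp in (treatment.calibrator_group, treatment.target_group):
        cols = [col_of[s] for s in treatment.samples_in(grp) if s in col_of]
        if len(cols) < 2:
            raise NormalizationError(f"group {grp!r} has < 2 samples in the dataset")
        group_cols.append(np.array(cols))

    n_groups = len(group_cols)
    var = np.zeros((G, n_groups))      # intra-group gene variances
    ns = np.zeros(n_groups)
    group_gene_means = np.zeros((G, n_groups))
    for gidx, cols in enumerate(group_cols):
        sub = rows[:, cols]
        ns[gidx] = sub.shape[1]
        gene_mean = sub.mean(axis=1, keepdims=True)
        sample_mean = sub.mean(axis=0, keepdims=True)
        total = sub.mean()
        z = sub - gene_mean - sample_mean + total
        u = (z ** 2).sum(axis=1) / (sub.shape[1] - 1)
        # bias-corrected gene variance (residuals from gene centering shrink
        # the raw sums of squares by a factor depending on the gene count)
        sig2 = u * G / (G - 2) - u.mean() * G / ((G - 1) * (G - 2))
        var[:, gidx] = np.maximum(sig2, 0.0)
        group_gene_means[:, gidx] = gene_mean.ravel()

    d = group_gene_means - group_gene_means.mean(axis=1, keepdims=True)
    # inter-group variance of the deviations, shrinkage toward 0
    se2 = var / ns
    gamma2 = max((d ** 2).sum() / ((G - 1) * (n_groups - 1)) - se2.mean(), 0.0)
    d_tilde = d * gamma2 / (gamma2 + se2) if gamma2 > 0 else np.zeros_like(d)
    rho = (np.abs(d_tilde) + np.sqrt(se2 * gamma2 / (gamma2 + se2))
           if gamma2 > 0 else np.sqrt(se2))
    stability = rho.mean(axis=1)

    scores = dict(zip(names, stability))
    order = np.argsort(stability, kind="stable")
    selected = [names[i] for i in order[:max(1, n_select)]]
    return StabilityReport("normfinder", scores, selected, excluded)


# ---------------------------------------------------------------------------
# dispatcher


def apply_normalization(ds: CtDataset, spec: NormalizationSpec,
                        treatment: TreatmentMap | None = None
                        ) -> tuple[CtDataset, StabilityReport | None]:
    """Run the configured normalization; returns (dataset, stability report
    or None for methods without housekeeper selection)."""
    if spec.method == "global_mean":
        return normalize_global_mean(ds), None
    if spec.method == "modified_global_mean":
        return normalize_modified_global_mean(ds), None
    if spec.method == "deltact":
        return normalize_deltact(ds, spec, treatment)
    if spec.method == "quantile":
        return normalize_quantile(ds), None
    if spec.method == "norm_rank_invariant":
        return normalize_rank_invariant(ds, "norm", spec.rank_invariant_min_set), None
    if spec.method == "scale_rank_invariant":
        return normalize_rank_invariant(ds, "scale", spec.rank_invariant_min_set), None
    raise NormalizationError(f"unknown method {spec.method!r}")
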