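"""Feature filtering by missingness / name list, and missing-Ct imputation.

Three imputation methods: KNN (Troyanskaya-style feature neighbours on
overlap-scaled Euclidean distance), Mestdagh (per-feature observed maximum
plus one cycle, the low-abundance assumption) and Cubic (natural cubic
spline over sample index, falling back to the Mestdagh rule for features
with fewer than two observations).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .normalize import spline_fill
from .qpcr_io import CtDataset

__all__ = [
    "FilterSpec",
    "ImputeSpec",
    "ImputationError",
    "filter_features",
    "impute_mestdagh",
    "impute_knn",
    "impute_cubic",
    "apply_imputation",
]

log = logging.getLogger(__name__)


class ImputationError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    """Maximum admissible missing-value percentage and explicit removals."""

    max_missing_pct: float = 100.0
    remove_names: tuple[str, ...] = ()

    def __post_init__(self):
        if not 0.0 <= self.max_missing_pct <= 100.0:
            raise ValueError("max_missing_pct must be in [0, 100]")


@dataclass(frozen=True)
class ImputeSpec:
    method: str = "knn"
    k: int = 10

    def __post_init__(self):
        if self.method not in ("knn", "mestdagh", "cubic"):
            raise ValueError(f"unknown imputation method {self.method!r}")
        if self.k <= 0:
            raise ValueError("k must be positive")


def filter_features(ds: CtDataset, spec: FilterSpec) -> tuple[CtDataset, list[str]]:
    """Drop features whose missing percentage strictly exceeds the threshold
    or whose name is listed for removal; order preserved among survivors.

    Returns the filtered dataset and the list of removed feature names.
    """
    miss_pct = np.isnan(ds.ct).sum(axis=1) / ds.n_samples * 100.0
    removal = set(spec.remove_names)
    keep = np.array([
        miss_pct[i] <= spec.max_missing_pct and name not in removal
        for i, name in enumerate(ds.feature_names)
    ])
    removed = [n for n, k in zip(ds.feature_names, keep) if not k]
    if removed:
        log.info("filtered out %d features: %s", len(removed), removed[:20])
    if not keep.any():
        log.warning("all features removed by filtering")
    out = CtDataset(
        [n for n, k in zip(ds.feature_names, keep) if k],
        list(ds.sample_names),
        ds.ct[keep].copy(),
        ds.flags[keep].copy(),
        ds.categories[keep].copy(),
    )
    return out, removed


def impute_mestdagh(ds: CtDataset) -> CtDataset:
    """Replace each missing Ct with its feature's observed maximum + 1 cycle.

    Features with no observation at all fall back to the dataset-wide
    maximum + 1.
    """
    out = ds.copy()
    if np.isnan(out.ct).all():
        raise ImputationError("entire dataset is missing; nothing to impute from")
    global_max = np.nanmax(out.ct)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        row_max = np.nanmax(out.ct, axis=1)
    row_max = np.where(np.isnan(row_max), global_max, row_max)
    fill = row_max + 1.0
    miss = np.isnan(out.ct)
    out.ct[miss] = np.broadcast_to(fill[:, None], out.ct.shape)[miss]
    return out


def impute_knn(ds: CtDataset, spec: ImputeSpec | None = None) -> CtDataset:
    """Nearest-neighbour imputation over features.

    For feature g missing at sample s, candidate neighbours are features
    observed at s.  The distance to a candidate is the Euclidean distance
    over the samples where both are observed, divided by sqrt(overlap size)
    so distances are comparable across overlap sizes.  The fill is the
    1/distance-weighted mean of the k nearest neighbours' values at s (equal
    weights among exact-zero-distance neighbours); a feature with no usable
    neighbour falls back to its own mean.
    """
    spec = spec or ImputeSpec(method="knn")
    if ds.n_features < spec.k + 1:
        raise ImputationError(
            f"KNN with k={spec.k} requires at least {spec.k + 1} features, "
            f"found {ds.n_features}")
    out = ds.copy()
    m = out.ct
    obs = ~np.isnan(m)
    if (~obs.any(axis=0)).any():
        bad = [s for s, o in zip(out.sample_names, obs.any(axis=0)) if not o]
        raise ImputationError(f"no feature observed in samples: {bad}")

    filled = m.copy()
    for i in np.flatnonzero(~obs.all(axis=1)):
        gi_obs = obs[i]
        dists = np.full(m.shape[0], np.inf)
        for g in range(m.shape[0]):
            if g == i:
                continue
            shared = gi_obs & obs[g]
            n_shared = shared.sum()
            if n_shared == 0:
                continue
            diff = m[i, shared] - m[g, shared]
            dists[g] = np.sqrt((diff ** 2).sum()) / np.sqrt(n_shared)
        for s in np.flatnonzero(~gi_obs):
            cand = np.flatnonzero(obs[:, s] & np.isfinite(dists))
            if cand.size == 0:
                filled[i, s] = np.nanmean(m[i]) if gi_obs.any() else np.nan
                continue
            nearest = cand[np.argsort(dists[cand], kind="stable")[:spec.k]]
            d = dists[nearest]
            if (d == 0).any():
                vals = m[nearest[d == 0], s]
                filled[i, s] = vals.mean()
            else:
                w = 1.0 / d
                filled[i, s] = np.average(m[nearest, s], weights=w)
    out.ct = filled
    return out


def impute_cubic(ds: CtDataset) -> CtDataset:
    """Cubic-spline imputation over sample index; features with < 2 observed
    values fall back to the Mestdagh rule (logged)."""
    out = ds.copy()
    filled, flagged = spline_fill(out.ct)
    out.ct = filled
    if flagged:
        log.info("cubic imputation: %d features with <2 observations fall "
                 "back to max+1 fill", len(flagged))
        if np.isnan(out.ct).any():
            out = impute_mestdagh(out)
    return out


def apply_imputation(ds: CtDataset, spec: ImputeSpec) -> CtDataset:
    if spec.method == "mestdagh":
        return impute_mestdagh(ds)
    if spec.method == "cubic":
        return impute_cubic(ds)
    return impute_knn(ds, spec)
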