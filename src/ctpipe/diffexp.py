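"""Two-group differential expression on Ct data.

Three tests are available: Welch/pooled or paired t-test, Wilcoxon
(Mann-Whitney unpaired / signed-rank paired) and the rank product
permutation test.  Every result table carries, per feature, the statistic,
raw and adjusted p-values, ddCt (target mean minus calibrator mean),
FC = 2^-ddCt, the two group means and the aggregated per-group reliability
category; rows are sorted by ascending p-value.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .qpcr_io import OK, UNDETERMINED, CtDataset, TreatmentMap

__all__ = [
    "DESpec",
    "DEError",
    "group_summary",
    "ttest_de",
    "wilcoxon_de",
    "rankprod_de",
    "rank_products",
    "rankprod_pfp",
    "adjust_pvalues",
    "aggregate_category",
    "run_diffexp",
    "RESULT_COLUMNS",
]

log = logging.getLogger(__name__)

ADJUST_METHODS = {
    "BH": "fdr_bh",
    "BY": "fdr_by",
    "bonferroni": "bonferroni",
    "holm": "holm",
    "hochberg": "simes-hochberg",
    "hommel": "hommel",
}

#: Output column order; the statistic column is named after the test
#: ("t.test", "W" or "RP").
RESULT_COLUMNS = ("genes", "{stat}", "p.value", "adj.p.value", "ddCt", "FC",
                  "meanCalibrator", "meanTarget",
                  "categoryCalibrator", "categoryTarget")


class DEError(ValueError):
    pass


@dataclass(frozen=True)
class DESpec:
    """Test choice and its six parameters."""

    method: str = "ttest"
    alternative: str = "two_sided"
    paired: bool = False
    replicates: bool = False
    stringent: bool = True
    adjust: str = "BH"
    equal_var: bool = False
    permutations: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if self.method not in ("ttest", "wilcoxon", "rankprod", "none"):
            raise DEError(f"unknown DE method {self.method!r}")
        if self.alternative not in ("two_sided", "less", "greater"):
            raise DEError(f"unknown alternative {self.alternative!r}")
        if self.adjust != "none" and self.adjust not in ADJUST_METHODS:
            raise DEError(f"unknown adjustment {self.adjust!r}")
        if self.method == "rankprod" and self.permutations < 1:
            raise DEError("permutations must be >= 1")


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment; 'none' is the identity."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise DEError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method not in ADJUST_METHODS:
        raise DEError(f"unknown adjustment {method!r}")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method=ADJUST_METHODS[method])[1]


def aggregate_category(categories, stringent: bool = True) -> str:
    """Collapse per-sample categories of one gene in one group to OK or
    Undetermined: all-OK when stringent, strict majority OK when lenient."""
    cats = list(categories)
    if not cats:
        raise DEError("empty category list")
    n_ok = sum(1 for c in cats if c == OK)
    if stringent:
        return OK if n_ok == len(cats) else UNDETERMINED
    return OK if n_ok * 2 > len(cats) else UNDETERMINED


def group_summary(values_cal, values_tgt):
    """Group means, ddCt = mean_target - mean_calibrator, FC = 2^-ddCt."""
    cal = np.asarray(values_cal, dtype=float)
    tgt = np.asarray(values_tgt, dtype=float)
    cal = cal[~np.isnan(cal)]
    tgt = tgt[~np.isnan(tgt)]
    if cal.size == 0 or tgt.size == 0:
        raise DEError("a group has no observed values for this gene")
    mean_cal = cal.mean()
    mean_tgt = tgt.mean()
    ddct = mean_tgt - mean_cal
    return mean_cal, mean_tgt, ddct, 2.0 ** -ddct


def _collapse_replicates(ds: CtDataset) -> CtDataset:
    """Average equal-named features per sample (missing-aware)."""
    seen: dict[str, list[int]] = {}
    order: list[str] = []
    for i, name in enumerate(ds.feature_names):
        if name not in seen:
            seen[name] = []
            order.append(name)
        seen[name].append(i)
    ct = np.vstack([np.nanmean(ds.ct[seen[n]], axis=0) for n in order])
    flags = np.vstack([ds.flags[seen[n][0]] for n in order])
    cats = np.empty((len(order), ds.n_samples), dtype=object)
    for r, n in enumerate(order):
        for j in range(ds.n_samples):
            col = ds.categories[seen[n], j]
            cats[r, j] = OK if (col == OK).all() else UNDETERMINED
    return CtDataset(order, list(ds.sample_names), ct, flags, cats)


def _group_columns(ds: CtDataset, tm: TreatmentMap):
    col = {s: j for j, s in enumerate(ds.sample_names)}
    cal = [col[s] for s in tm.calibrator_samples if s in col]
    tgt = [col[s] for s in tm.target_samples if s in col]
    if not cal or not tgt:
        raise DEError("both treatment groups must be present in the dataset")
    return np.array(cal), np.array(tgt)


_SCIPY_ALT = {"two_sided": "two-sided", "less": "less", "greater": "greater"}


def _build_table(ds, tm, spec, stat_name, stats_arr, pvals):
    cal_cols, tgt_cols = _group_columns(ds, tm)
    rows = []
    adj = adjust_pvalues(np.nan_to_num(pvals, nan=1.0), spec.adjust)
    for i, gene in enumerate(ds.feature_names):
        mean_cal, mean_tgt, ddct, fc = group_summary(
            ds.ct[i, cal_cols], ds.ct[i, tgt_cols])
        rows.append({
            "genes": gene,
            stat_name: stats_arr[i],
            "p.value": pvals[i],
            "adj.p.value": adj[i],
            "ddCt": ddct,
            "FC": fc,
            "meanCalibrator": mean_cal,
            "meanTarget": mean_tgt,
            "categoryCalibrator": aggregate_category(
                ds.categories[i, cal_cols], spec.stringent),
            "categoryTarget": aggregate_category(
                ds.categories[i, tgt_cols], spec.stringent),
        })
    table = pd.DataFrame(rows, columns=[c.format(stat=stat_name) for c in RESULT_COLUMNS])
    table = table.sort_values("p.value", kind="stable").reset_index(drop=True)
    return table


def ttest_de(ds: CtDataset, tm: TreatmentMap, spec: DESpec) -> pd.DataFrame:
    """Per-gene two-sample t-test (Welch by default, pooled with
    ``equal_var``, or paired)."""
    if spec.replicates:
        ds = _collapse_replicates(ds)
    cal_cols, tgt_cols = _group_columns(ds, tm)
    if spec.paired and len(cal_cols) != len(tgt_cols):
        raise DEError("paired analysis requires equal group sizes")
    alt = _SCIPY_ALT[spec.alternative]
    t_arr = np.empty(ds.n_features)
    p_arr = np.empty(ds.n_features)
    for i in range(ds.n_features):
        cal = ds.ct[i, cal_cols]
        tgt = ds.ct[i, tgt_cols]
        if spec.paired:
            ok = ~np.isnan(cal) & ~np.isnan(tgt)
            cal, tgt = cal[ok], tgt[ok]
            degenerate = len(cal) < 2 or np.std(tgt - cal) == 0
        else:
            cal, tgt = cal[~np.isnan(cal)], tgt[~np.isnan(tgt)]
            degenerate = (len(cal) < 2 or len(tgt) < 2 or
                          (np.std(cal) == 0 and np.std(tgt) == 0))
        if degenerate:
            if (len(cal) and len(tgt) and np.std(cal) == 0 and np.std(tgt) == 0
                    and cal.mean() != tgt.mean()):
                # zero variance but distinct means: infinitely significant in
                # the limit; report the sign and p=0, logged
                t_arr[i] = np.sign(np.mean(tgt) - np.mean(cal)) * np.inf
                p_arr[i] = 0.0
            else:
                t_arr[i], p_arr[i] = 0.0, 1.0
            log.info("degenerate t-test for %s (zero variance)", ds.feature_names[i])
            continue
        if spec.paired:
            res = stats.ttest_rel(tgt, cal, alternative=alt)
        else:
            res = stats.ttest_ind(tgt, cal, equal_var=spec.equal_var, alternative=alt)
        t_arr[i], p_arr[i] = res.statistic, res.pvalue
    return _build_table(ds, tm, spec, "t.test", t_arr, p_arr)


def wilcoxon_de(ds: CtDataset, tm: TreatmentMap, spec: DESpec) -> pd.DataFrame:
    """Per-gene Mann-Whitney (unpaired) or Wilcoxon signed-rank (paired).

    Exact p-values for combined n <= 12 without ties, otherwise the normal
    approximation with tie and continuity correction.
    """
    if spec.replicates:
        ds = _collapse_replicates(ds)
    cal_cols, tgt_cols = _group_columns(ds, tm)
    if spec.paired and len(cal_cols) != len(tgt_cols):
        raise DEError("paired analysis requires equal group sizes")
    alt = _SCIPY_ALT[spec.alternative]
    w_arr = np.empty(ds.n_features)
    p_arr = np.empty(ds.n_features)
    for i in range(ds.n_features):
        cal = ds.ct[i, cal_cols]
        tgt = ds.ct[i, tgt_cols]
        if spec.paired:
            ok = ~np.isnan(cal) & ~np.isnan(tgt)
            cal, tgt = cal[ok], tgt[ok]
            diffs = tgt - cal
            if len(diffs) == 0 or (diffs == 0).all():
                w_arr[i], p_arr[i] = 0.0, 1.0
                log.info("degenerate signed-rank for %s", ds.feature_names[i])
                continue
            res = stats.wilcoxon(tgt, cal, alternative=alt,
                                 zero_method="wilcox", correction=True)
            w_arr[i], p_arr[i] = res.statistic, res.pvalue
        else:
            cal, tgt = cal[~np.isnan(cal)], tgt[~np.isnan(tgt)]
            if len(cal) == 0 or len(tgt) == 0:
                w_arr[i], p_arr[i] = 0.0, 1.0
                continue
            pooled = np.concatenate([cal, tgt])
            has_ties = len(np.unique(pooled)) < len(pooled)
            method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
            res = stats.mannwhitneyu(tgt, cal, alternative=alt, method=method,
                                     use_continuity=True)
            w_arr[i], p_arr[i] = res.statistic, res.pvalue
    return _build_table(ds, tm, spec, "W", w_arr, p_arr)


# ---------------------------------------------------------------------------
# rank product


def rank_products(m: np.ndarray, cal_cols, tgt_cols):
    """RP_up and RP_down: geometric mean over all cross-group sample pairs of
    each gene's rank of the pairwise expression difference.

    For pair (i, j) the difference is value_target_j - value_calibrator_i;
    rank 1 of the ascending difference = most down in target, rank 1 of the
    descending difference = most up in target.
    """
    m = np.asarray(m, dtype=float)
    pairs = list(itertools.product(cal_cols, tgt_cols))
    log_down = np.zeros(m.shape[0])
    log_up = np.zeros(m.shape[0])
    for ci, tj in pairs:
        diff = m[:, tj] - m[:, ci]
        r_down = rankdata(diff, method="average")
        r_up = rankdata(-diff, method="average")
        log_down += np.log(r_down)
        log_up += np.log(r_up)
    n = len(pairs)
    return np.exp(log_up / n), np.exp(log_down / n)


def _exhaustive_null(m, cal_cols, tgt_cols):
    """Null RP distribution over every combination of per-column permutations.

    Feasible only for tiny instances: the joint space has (n_genes!)^n_samples
    points.  Log-ranks of each cross-group pair depend only on that pair's two
    column permutations, so the total log-RP factorizes into broadcast sums
    over a (P, ..., P, genes) grid.
    """
    n_genes, n_cols = m.shape
    perm_mat = np.array(list(itertools.permutations(range(n_genes))))
    P = len(perm_mat)
    if P ** n_cols * n_genes > 5e7:
        raise DEError("instance too large for exhaustive enumeration")
    total_down = np.zeros((P,) * n_cols + (n_genes,))
    total_up = np.zeros_like(total_down)
    n_pairs = 0
    for ci in cal_cols:
        for tj in tgt_cols:
            x = m[perm_mat, ci]          # (P, genes): permuted calibrator col
            y = m[perm_mat, tj]
            diff = y[None, :, :] - x[:, None, :]        # (P_cal, P_tgt, genes)
            r_down = rankdata(diff, method="average", axis=-1)
            r_up = rankdata(-diff, method="average", axis=-1)
            shape = [1] * n_cols + [n_genes]
            shape[ci], shape[tj] = P, P
            if ci > tj:  # reshape keeps order: first varying axis = lower col
                r_down = np.swapaxes(r_down, 0, 1)
                r_up = np.swapaxes(r_up, 0, 1)
            total_down += np.log(r_down).reshape(shape)
            total_up += np.log(r_up).reshape(shape)
            n_pairs += 1
    null_down = np.exp(total_down / n_pairs).ravel()
    null_up = np.exp(total_up / n_pairs).ravel()
    return null_up, null_down, P ** n_cols


def _column_shuffled(m, rng):
    out = np.empty_like(m)
    for j in range(m.shape[1]):
        out[:, j] = m[rng.permutation(m.shape[0]), j]
    return out


def rankprod_pfp(m: np.ndarray, cal_cols, tgt_cols, permutations=1000,
                 seed: int | None = None, exhaustive: bool = False):
    """Observed RPs and their permutation pfp (percentage of false prediction).

    The null is generated by shuffling values within each sample column
    across genes.  ``exhaustive=True`` enumerates every combination of
    per-column permutations (tiny inputs only); otherwise ``permutations``
    Monte Carlo draws seeded by ``seed``.

    pfp(g) = E(g) / rank(g) where E(g) is the expected number of genes with a
    permuted RP <= the observed RP of g, and rank(g) is g's ascending
    observed-RP rank.
    """
    m = np.asarray(m, dtype=float)
    n_genes = m.shape[0]
    rp_up, rp_down = rank_products(m, cal_cols, tgt_cols)

    if exhaustive:
        null_up, null_down, n_perm = _exhaustive_null(m, cal_cols, tgt_cols)
    else:
        rng = np.random.default_rng(seed)
        null_up = np.empty(permutations * n_genes)
        null_down = np.empty(permutations * n_genes)
        for b in range(permutations):
            u, d = rank_products(_column_shuffled(m, rng), cal_cols, tgt_cols)
            null_up[b * n_genes:(b + 1) * n_genes] = u
            null_down[b * n_genes:(b + 1) * n_genes] = d
        n_perm = permutations

    def pfp_of(rp, null):
        null = np.sort(null)
        count = np.searchsorted(null, rp, side="right")
        expected = count / n_perm
        rank = rankdata(rp, method="average")
        return expected / rank

    return rp_up, rp_down, pfp_of(rp_up, null_up), pfp_of(rp_down, null_down)


def rankprod_de(ds: CtDataset, tm: TreatmentMap, spec: DESpec) -> pd.DataFrame:
    """Rank product test; per gene the better-direction RP is the statistic
    and its pfp the p-value."""
    if spec.replicates:
        ds = _collapse_replicates(ds)
    if spec.paired:
        raise DEError("rank product is an unpaired two-class method")
    cal_cols, tgt_cols = _group_columns(ds, tm)
    if np.isnan(ds.ct).any():
        raise DEError("rank product requires complete data; impute first")
    rp_up, rp_down, pfp_up, pfp_down = rankprod_pfp(
        ds.ct, cal_cols, tgt_cols, permutations=spec.permutations, seed=spec.seed)
    take_up = pfp_up <= pfp_down
    stat = np.where(take_up, rp_up, rp_down)
    pfp = np.where(take_up, pfp_up, pfp_down)
    return _build_table(ds, tm, spec, "RP", stat, np.clip(pfp, 0.0, 1.0))


def run_diffexp(ds: CtDataset, tm: TreatmentMap, spec: DESpec) -> pd.DataFrame | None:
    """Dispatch on the configured method; ``none`` returns None."""
    if spec.method == "none":
        return None
    if spec.method == "ttest":
        return ttest_de(ds, tm, spec)
    if spec.method == "wilcoxon":
        return wilcoxon_de(ds, tm, spec)
    return rankprod_de(ds, tm, spec)
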