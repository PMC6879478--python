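"""Synthetic Ct dataset generation and embedded published result tables.

The generator produces per-sample Plain-dialect report files with a known
additive structure (feature baseline + per-sample technical shift + group
effect on a spiked subset + Gaussian noise), missing-not-at-random dropout
at high Ct, and optional Failed quality flags, together with a truth record
for parameter-recovery tests.

Two published differential-expression result tables (a metastatic-cancer
cohort, 23 rows, and a non-small-cell lung cancer cohort, 16 rows) are
embedded verbatim as regression fixtures; no network access is needed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .qpcr_io import CtDataset

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_synthetic",
    "generate_dataset",
    "dataset_to_plain_files",
    "load_printed_de_table",
    "significant_counts",
    "PRINTED_TABLE_COLUMNS",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the additive Ct model and its dropout/flag process."""

    n_features: int = 384
    n_samples_per_group: tuple[int, int] = (8, 8)
    group_labels: tuple[str, str] = ("CTRL", "CASE")
    baseline_mean: float = 25.0
    feature_sd: float = 3.0
    sample_shift_sd: float = 1.0
    noise_sd: float = 0.5
    n_spiked: int = 0
    spike_ddct: float = 2.0
    missing_threshold: float | None = 35.0
    fail_flag_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_spiked > self.n_features:
            raise ValueError("n_spiked must be <= n_features")
        for sd in (self.feature_sd, self.sample_shift_sd, self.noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")


@dataclass
class SyntheticTruth:
    """Generating parameters retained for parameter-recovery assertions."""

    baselines: np.ndarray
    sample_shifts: np.ndarray
    spiked: list[str]
    spike_signs: np.ndarray
    clean_ct: np.ndarray  # pre-missingness matrix
    groups: list[str]


def generate_dataset(cfg: SyntheticConfig) -> tuple[CtDataset, "SyntheticTruth",
                                                    list[tuple[str, str]]]:
    """Build the synthetic dataset in memory.

    Ct_gs = baseline_g + shift_s + sign_g * spike_ddct * [s in target] + noise.
    Values above ``missing_threshold`` are dropped with probability rising
    linearly from 0 at the threshold to 1 at threshold + 5.
    Returns (dataset, truth record, treatment entries).
    """
    rng = np.random.default_rng(cfg.seed)
    n_cal, n_tgt = cfg.n_samples_per_group
    n_samples = n_cal + n_tgt
    cal_label, tgt_label = cfg.group_labels

    features = [f"miR-{i + 1:03d}" for i in range(cfg.n_features)]
    samples = [f"sample{j + 1:02d}.txt" for j in range(n_samples)]
    groups = [cal_label] * n_cal + [tgt_label] * n_tgt

    baselines = rng.normal(cfg.baseline_mean, cfg.feature_sd, cfg.n_features)
    shifts = rng.normal(0.0, cfg.sample_shift_sd, n_samples)
    spiked_idx = rng.choice(cfg.n_features, size=cfg.n_spiked, replace=False)
    signs = np.zeros(cfg.n_features)
    if cfg.n_spiked:
        signs[spiked_idx] = np.where(np.arange(cfg.n_spiked) % 2 == 0, 1.0, -1.0)
    in_target = np.array([g == tgt_label for g in groups], dtype=float)

    clean = (baselines[:, None] + shifts[None, :]
             + signs[:, None] * cfg.spike_ddct * in_target[None, :])
    ct = clean + rng.normal(0.0, cfg.noise_sd, clean.shape)

    flags = np.full(ct.shape, "Passed", dtype=object)
    if cfg.fail_flag_rate > 0:
        flags[rng.random(ct.shape) < cfg.fail_flag_rate] = "Failed"

    observed = ct.copy()
    if cfg.missing_threshold is not None:
        p_miss = np.clip((ct - cfg.missing_threshold) / 5.0, 0.0, 1.0)
        observed[rng.random(ct.shape) < p_miss] = np.nan

    categories = np.where(np.isnan(observed), "Undetermined", "OK").astype(object)
    ds = CtDataset(features, samples, observed, flags, categories)
    truth = SyntheticTruth(
        baselines=baselines,
        sample_shifts=shifts,
        spiked=[features[i] for i in sorted(spiked_idx)],
        spike_signs=signs,
        clean_ct=clean,
        groups=groups,
    )
    return ds, truth, list(zip(samples, groups))


def dataset_to_plain_files(ds: CtDataset, out_dir,
                           undetermined: str = "Undetermined") -> list[Path]:
    """Write one Plain-dialect report per sample (feature, Ct, flag)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for j, sample in enumerate(ds.sample_names):
        path = out_dir / sample
        with open(path, "w", encoding="utf-8") as fh:
            for i, feat in enumerate(ds.feature_names):
                v = ds.ct[i, j]
                token = undetermined if np.isnan(v) else repr(float(v))
                fh.write(f"{feat}\t{token}\t{ds.flags[i, j]}\n")
        paths.append(path)
    return paths


def generate_synthetic(cfg: SyntheticConfig, out_dir) -> dict:
    """Generate Plain-dialect files + treatment file + truth JSON on disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds, truth, entries = generate_dataset(cfg)
    sample_paths = dataset_to_plain_files(ds, out_dir)
    treatment_path = out_dir / "treatment.tsv"
    with open(treatment_path, "w", encoding="utf-8") as fh:
        fh.write("SampleName\tTreatment\n")
        for s, g in entries:
            fh.write(f"{s}\t{g}\n")
    truth_path = out_dir / "truth.json"
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump({
            "config": asdict(cfg),
            "spiked": truth.spiked,
            "sample_shifts": truth.sample_shifts.tolist(),
            "groups": truth.groups,
        }, fh, indent=1)
    return {
        "samples": [str(p) for p in sample_paths],
        "treatment": str(treatment_path),
        "truth": str(truth_path),
    }


# ---------------------------------------------------------------------------
# Embedded published DE tables (verbatim transcriptions).

PRINTED_TABLE_COLUMNS = ("genes", "t.test", "p.value", "adj.p.value", "ddCt",
                         "FC", "meanCalibrator", "meanTarget",
                         "categoryCalibrator", "categoryTarget")

_METASTATIC_ROWS = [
    ("hsa-miR-200c-4395411", 3.110, 0.011, 0.449, -4.414, 21.324, 25.793, 21.378, "OK", "OK"),
    ("hsa-miR-375-4373027", 2.558, 0.026, 0.560, -3.943, 15.381, 27.514, 23.570, "OK", "OK"),
    ("hsa-miR-141-4373137", 2.288, 0.043, 0.563, -3.640, 12.467, 28.392, 24.751, "OK", "OK"),
    ("hsa-miR-654-3p-4395350", 2.810, 0.019, 0.488, -3.008, 8.045, 34.747, 31.739, "Undetermined", "Undetermined"),
    ("hsa-miR-135b-4395372", 2.937, 0.013, 0.449, -2.916, 7.546, 28.848, 25.932, "OK", "OK"),
    ("hsa-miR-200b-4395362", 2.912, 0.014, 0.449, -2.516, 5.722, 24.808, 22.291, "OK", "OK"),
    ("hsa-miR-410-4378093", 2.299, 0.047, 0.563, -2.285, 4.873, 31.701, 29.417, "OK", "OK"),
    ("hsa-miR-323-3p-4395338", 2.209, 0.049, 0.563, -1.988, 3.966, 30.228, 28.240, "OK", "OK"),
    ("hsa-miR-370-4395386", 2.604, 0.021, 0.488, -1.686, 3.218, 27.286, 25.600, "OK", "OK"),
    ("hsa-miR-642-4380995", 2.807, 0.015, 0.449, -1.673, 3.188, 31.283, 29.610, "OK", "OK"),
    ("hsa-miR-127-3p-4373147", 2.338, 0.035, 0.563, -1.512, 2.853, 26.167, 24.655, "OK", "OK"),
    ("hsa-miR-212-4373087", 4.008, 0.001, 0.449, -1.422, 2.680, 27.481, 26.059, "OK", "OK"),
    ("hsa-miR-628-5p-4395544", -2.530, 0.032, 0.563, 1.097, 0.467, 29.281, 30.378, "OK", "Undetermined"),
    ("hsa-miR-125a-3p-4395310", -2.790, 0.017, 0.474, 1.191, 0.438, 29.835, 31.026, "OK", "OK"),
    ("hsa-miR-328-4373049", -2.592, 0.028, 0.563, 1.215, 0.431, 27.772, 28.987, "OK", "OK"),
    ("hsa-miR-886-3p-4395305", -2.311, 0.042, 0.563, 1.225, 0.428, 24.007, 25.232, "OK", "OK"),
    ("hsa-miR-140-5p-4373374", -2.880, 0.012, 0.449, 1.245, 0.422, 23.457, 24.702, "OK", "OK"),
    ("hsa-miR-29c-4395171", -2.926, 0.015, 0.449, 1.339, 0.395, 23.351, 24.691, "OK", "OK"),
    ("hsa-miR-140-3p-4395345", -3.118, 0.008, 0.449, 1.410, 0.376, 26.526, 27.935, "OK", "OK"),
    ("hsa-miR-570-4395458", -2.305, 0.038, 0.563, 1.460, 0.363, 34.499, 35.959, "Undetermined", "Undetermined"),
    ("hsa-miR-489-4395469", -3.029, 0.009, 0.449, 1.522, 0.348, 26.810, 28.332, "OK", "OK"),
    ("hsa-miR-545-4395378", -3.097, 0.008, 0.449, 2.067, 0.239, 31.847, 33.914, "Undetermined", "Undetermined"),
    ("hsa-miR-502-5p-4373227", -3.107, 0.009, 0.449, 3.300, 0.102, 29.814, 33.113, "Undetermined", "Undetermined"),
]

_NSLC_ROWS = [
    ("hsa-miR-205-4373093", 5.190, 0.000, 0.001, -4.411, 21.272, 8.013, 3.602, "Undetermined", "Undetermined"),
    ("hsa-miR-375-4373027", -4.079, 0.000, 0.038, 2.065, 0.239, 3.354, 5.418, "OK", "OK"),
    ("hsa-miR-422a-4395408", 3.854, 0.000, 0.069, -1.418, 2.673, 8.215, 6.796, "OK", "OK"),
    ("hsa-miR-149-4395366", 3.758, 0.001, 0.094, -2.322, 5.000, 7.393, 5.071, "OK", "Undetermined"),
    ("hsa-miR-708-4395452", 3.634, 0.001, 0.135, -2.044, 4.123, 5.995, 3.952, "OK", "OK"),
    ("hsa-miR-204-4373094", 3.440, 0.001, 0.232, -1.587, 3.004, 9.177, 7.590, "Undetermined", "Undetermined"),
    ("hsa-miR-483-5p-4395449", 3.376, 0.002, 0.285, -1.397, 2.634, 10.019, 8.622, "Undetermined", "Undetermined"),
    ("hsa-miR-127-3p-4373147", 2.984, 0.005, 0.918, -1.166, 2.245, 6.256, 5.090, "OK", "OK"),
    ("hsa-miR-196b-4395326", 2.915, 0.006, 1.000, -1.933, 3.818, 9.416, 7.483, "Undetermined", "Undetermined"),
    ("hsa-miR-202-4395474", 2.922, 0.006, 1.000, -1.061, 2.087, 10.305, 9.244, "Undetermined", "Undetermined"),
    ("hsa-miR-494-4395476", 2.669, 0.011, 1.000, -1.165, 2.242, 3.657, 2.492, "OK", "OK"),
    ("hsa-miR-376a-4373026", 2.628, 0.012, 1.000, -1.093, 2.133, 10.615, 9.522, "Undetermined", "Undetermined"),
    ("hsa-miR-376c-4395233", 2.624, 0.013, 1.000, -1.299, 2.460, 9.324, 8.025, "OK", "Undetermined"),
    ("hsa-miR-130b-4373144", 2.575, 0.014, 1.000, -1.071, 2.100, 8.247, 7.176, "Undetermined", "Undetermined"),
    ("hsa-miR-203-4373095", 2.131, 0.039, 1.000, -1.098, 2.140, 4.716, 3.618, "Undetermined", "OK"),
    ("hsa-miR-194-4373106", -2.089, 0.046, 1.000, 1.182, 0.441, 8.508, 9.690, "OK", "Undetermined"),
]

_PRINTED = {"metastatic": _METASTATIC_ROWS, "nslc": _NSLC_ROWS}

#: Rows whose printed FC differs from round(2^-ddCt, 3) by one or two ulps at
#: 3 decimals because the published FC was computed from the unrounded ddCt.
FC_ROUNDING_EXCEPTIONS = {
    "metastatic": (
        "hsa-miR-200c-4395411", "hsa-miR-375-4373027", "hsa-miR-654-3p-4395350",
        "hsa-miR-135b-4395372", "hsa-miR-200b-4395362", "hsa-miR-410-4378093",
        "hsa-miR-323-3p-4395338", "hsa-miR-642-4380995", "hsa-miR-127-3p-4373147",
    ),
    "nslc": (
        "hsa-miR-205-4373093", "hsa-miR-422a-4395408", "hsa-miR-708-4395452",
        "hsa-miR-127-3p-4373147", "hsa-miR-202-4395474", "hsa-miR-376c-4395233",
        "hsa-miR-130b-4373144", "hsa-miR-203-4373095",
    ),
}


def load_printed_de_table(study: str) -> pd.DataFrame:
    """Return one of the embedded published DE tables ("metastatic", 23 rows,
    calibrator OLIGO; or "nslc", 16 rows, calibrator LA)."""
    try:
        rows = _PRINTED[study]
    except KeyError:
        raise KeyError(f"unknown study {study!r}; known: {sorted(_PRINTED)}") from None
    return pd.DataFrame(rows, columns=PRINTED_TABLE_COLUMNS)


def significant_counts(table: pd.DataFrame, p_cutoff: float = 0.05,
                       fc_up: float = 2.0, fc_down: float = 0.5) -> dict[str, int]:
    """Significance-filter counts used in the published results sections."""
    sig = table["p.value"] < p_cutoff
    up = int((sig & (table["FC"] > fc_up)).sum())
    down = int((sig & (table["FC"] < fc_down)).sum())
    return {"up": up, "down": down, "modulated": up + down}
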