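import numpy as np
import pytest

from ctpipe.qpcr_io import OK, UNDETERMINED, CtDataset, TreatmentMap


def make_dataset(ct, feature_names=None, sample_names=None, flags=None,
                 categories=None):
    """Build a CtDataset from a (nested) list/array with NaN as missing."""
    ct = np.asarray(ct, dtype=float)
    n_feat, n_samp = ct.shape
    feature_names = feature_names or [f"g{i}" for i in range(n_feat)]
    sample_names = sample_names or [f"s{j}" for j in range(n_samp)]
    if flags is None:
        flags = np.full(ct.shape, "Passed", dtype=object)
    if categories is None:
        categories = np.where(np.isnan(ct), UNDETERMINED, OK).astype(object)
    return CtDataset(list(feature_names), list(sample_names), ct.copy(),
                     np.asarray(flags, dtype=object),
                     np.asarray(categories, dtype=object))


def make_treatment(n_cal, n_tgt, cal="CTRL", tgt="CASE", sample_names=None):
    if sample_names is None:
        sample_names = [f"s{j}" for j in range(n_cal + n_tgt)]
    groups = [cal] * n_cal + [tgt] * n_tgt
    return TreatmentMap(tuple(zip(sample_names, groups)))


@pytest.fixture
def treatment_4v4():
    return make_treatment(4, 4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
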