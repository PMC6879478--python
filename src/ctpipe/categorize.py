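"""Reliability categorization of Ct values and masking of non-OK cells.

Each cell gets one of three labels: OK, Unreliable (numeric Ct outside the
user range) or Undetermined (missing sentinel on input, or failed quality
flag when flag checking is on).  The flag rule is applied after the range
rule and overrides it.  Masking replaces every non-OK Ct with NaN while
keeping the labels for downstream group-category reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .qpcr_io import MISSING, OK, UNDETERMINED, UNRELIABLE, CtDataset

__all__ = ["CategorySettings", "assign_categories", "mask_unreliable"]


@dataclass(frozen=True)
class CategorySettings:
    """User range and flag rule for category assignment.

    The default range is permissive ([0, inf): no range filtering).
    """

    ct_min: float = 0.0
    ct_max: float = float("inf")
    use_flags: bool = True
    fail_flag_values: tuple[str, ...] = ("Failed",)

    def __post_init__(self):
        if not self.ct_min < self.ct_max:
            raise ValueError(f"ct_min ({self.ct_min}) must be < ct_max ({self.ct_max})")


def assign_categories(ds: CtDataset, settings: CategorySettings) -> CtDataset:
    """Assign a category to every cell from its Ct value and flag.

    Missing (sentinel) cells are Undetermined; numeric cells outside
    [ct_min, ct_max] are Unreliable; failed-flag cells are Undetermined
    regardless of the range rule; everything else is OK.  Idempotent for
    fixed settings.
    """
    out = ds.copy()
    cat = np.full(out.ct.shape, OK, dtype=object)
    cat[np.isnan(out.ct)] = UNDETERMINED
    with np.errstate(invalid="ignore"):
        out_of_range = (~np.isnan(out.ct)) & (
            (out.ct < settings.ct_min) | (out.ct > settings.ct_max)
        )
    cat[out_of_range] = UNRELIABLE
    if settings.use_flags:
        failed = np.isin(out.flags, settings.fail_flag_values)
        cat[failed] = UNDETERMINED
    out.categories = cat
    return out


def mask_unreliable(ds: CtDataset) -> CtDataset:
    """Replace the Ct of every non-OK cell with NaN; categories retained."""
    out = ds.copy()
    out.ct[out.categories != OK] = MISSING
    return out
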