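"""Vectorized treatment + aggregation kernels on (n_subjects, 2, n_obs) arrays.

The Monte-Carlo engines apply every treatment thousands of times; doing that
through the DataFrame path would dominate the run time.  These kernels
operate on the balanced 3-D array produced by ``datagen.sample_trial_arrays``
and mark removed trials as NaN.  Their results are asserted equal to the
DataFrame implementation in the test suite.
"""

from __future__ import annotations

import warnings

import numpy as np

from .treatments import TreatmentSpec


def apply_treatment_masked(rt: np.ndarray, spec: TreatmentSpec) -> np.ndarray:
    """Return a copy of ``rt`` with removed trials set to NaN (or transformed).

    ``rt`` may already contain NaN (previously removed trials); those stay NaN
    and never enter threshold computations.
    """
    if spec.family in ("ignore", "median"):
        return rt
    if spec.family == "transform":
        return np.log(rt) if spec.transform_fn == "log" else 1.0 / rt
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if spec.sd_multiplier is None:
            keep = (rt >= spec.low_cutoff) & (rt <= spec.high_cutoff)
        else:
            k = spec.sd_multiplier
            if spec.scope == "experiment":
                center = np.nanmean(rt)
                spread = np.nanstd(rt, ddof=1)
            elif spec.scope == "subject":
                center = np.nanmean(rt, axis=(1, 2), keepdims=True)
                spread = np.nanstd(rt, axis=(1, 2), ddof=1, keepdims=True)
            elif spec.scope == "condition":
                center = np.nanmean(rt, axis=2, keepdims=True)
                spread = np.nanstd(rt, axis=2, ddof=1, keepdims=True)
            else:  # condition_pooled
                center = np.nanmean(rt, axis=(0, 2), keepdims=True)
                spread = np.nanstd(rt, axis=(0, 2), ddof=1, keepdims=True)
            keep = (rt >= center - k * spread) & (rt <= center + k * spread)
    return np.where(keep, rt, np.nan)


def subject_values(rt: np.ndarray, aggregation: str) -> np.ndarray:
    """Aggregate retained trials per subject and condition.

    Returns an (n_subjects, 2) array; a subject with an empty cell yields NaN
    in that cell and is dropped by the downstream test.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if aggregation == "median":
            return np.nanmedian(rt, axis=2)
        return np.nanmean(rt, axis=2)
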