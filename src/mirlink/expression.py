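"""Comparative-Ct arithmetic and per-feature group statistics.

TaqMan-style arrays report threshold cycles (Ct): the PCR cycle at which a
probe's fluorescence crosses a fixed threshold. One cycle corresponds to a
doubling, so Ct is a (negated) log2 abundance. Normalizing each assay to a
stable reference assay (RNU6 for miRNAs) gives ``-dCt = -(Ct_assay -
Ct_reference)``, a log2-scale abundance relative to the reference that is
directly comparable across samples. Microarray log2 intensities live on the
same scale, which is why one set of fold-change/t-test routines serves both.

Fold changes between sample groups are computed from group means on the log2
scale and exponentiated, and reported both as a linear ratio and in the signed
convention common in array studies: ratios below 1 are flipped to the negative
reciprocal (a ratio of 0.68 is printed as -1.47).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "neg_delta_ct",
    "handle_undetermined",
    "detect_expressed",
    "student_t_test",
    "group_fold_change",
    "signed_fold_change",
    "ddct_relative_expression",
]


def neg_delta_ct(ct: pd.DataFrame, reference_assay: str) -> pd.DataFrame:
    """Normalize a Ct matrix (assays x samples) to a reference assay.

    Returns ``-(Ct_assay - Ct_reference)`` per sample; the reference row maps
    to 0 everywhere. Raises ``ValueError`` if the reference assay is absent or
    undetected (missing) in any sample.
    """
    if reference_assay not in ct.index:
        raise ValueError(f"reference assay {reference_assay!r} not in matrix")
    ref = ct.loc[reference_assay]
    missing = ref.index[ref.isna()].tolist()
    if missing:
        raise ValueError(
            f"reference assay {reference_assay!r} undetected in sample(s): {missing}"
        )
    return -(ct.sub(ref, axis=1))


def handle_undetermined(
    ct: pd.DataFrame, policy: str = "ct", undetermined_ct: float = 40.0
) -> pd.DataFrame:
    """Resolve undetermined wells (missing Ct) before normalization.

    policy="ct" assigns them the maximal cycle number (default 40);
    policy="missing" leaves them missing so they propagate as undetected.
    """
    if policy == "ct":
        return ct.fillna(undetermined_ct)
    if policy == "missing":
        return ct.copy()
    raise ValueError(f"unknown undetermined-well policy {policy!r}")


def detect_expressed(
    ct: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    max_detect_ct: float = 35.0,
    min_samples_per_group: int | None = None,
) -> list[str]:
    """Return assay ids detected in at least one sample group.

    An assay counts as detected in a sample when its Ct is at most
    ``max_detect_ct`` (missing wells are undetected). It is kept when detected
    in at least ``min_samples_per_group`` samples of some group; the default
    threshold is ceil(group size / 2) per group.
    """
    for name, samples in groups.items():
        if len(samples) == 0:
            raise ValueError(f"empty sample group {name!r}")
    keep = pd.Series(False, index=ct.index)
    for name, samples in groups.items():
        need = min_samples_per_group
        if need is None:
            need = math.ceil(len(samples) / 2)
        detected = (ct[list(samples)] <= max_detect_ct).sum(axis=1)
        keep |= detected >= need
    return list(ct.index[keep])


def student_t_test(
    a: Sequence[float], b: Sequence[float], paired: bool = False
) -> float:
    """Two-sided Student t-test p-value with explicit degenerate conventions.

    Equal-variance (classic Student) by default; ``paired=True`` runs the
    paired test on aligned values. Missing values are dropped (pairwise for
    the paired test). Conventions for zero pooled variance: p = 1 when the
    means are equal, p = 0 when they differ. Fewer than 2 usable values in
    either group gives nan.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test requires equal-length groups")
        ok = ~(np.isnan(a) | np.isnan(b))
        d = a[ok] - b[ok]
        if d.size < 2:
            return float("nan")
        if np.var(d, ddof=1) == 0.0:
            return 1.0 if d.mean() == 0.0 else 0.0
        return float(sps.ttest_rel(a[ok], b[ok]).pvalue)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return float("nan")
    sp2 = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)) / (
        a.size + b.size - 2
    )
    if sp2 == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=True).pvalue)


def signed_fold_change(fc_linear):
    """Signed convention: ratios >= 1 unchanged, ratios < 1 become -1/ratio."""
    fc = np.asarray(fc_linear, dtype=float)
    out = np.where(fc >= 1.0, fc, -1.0 / fc)
    if np.isscalar(fc_linear) or np.ndim(fc_linear) == 0:
        return float(out)
    return out


def group_fold_change(
    x: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    paired: bool = False,
) -> pd.DataFrame:
    """Per-feature group means, fold change A vs B, and t-test p-value.

    ``x`` holds log2-scale values (-dCt or log2 intensity), features in rows.
    fc_linear = 2**(mean_A - mean_B) from the group means; fc_signed follows
    the negative-reciprocal convention. The p-value is the two-sided Student
    t-test (see :func:`student_t_test`); groups with fewer than 2 observed
    values yield a missing p-value while the fold change is still computed.
    """
    samples_a = list(samples_a)
    samples_b = list(samples_b)
    if not samples_a or not samples_b:
        raise ValueError("both sample groups must be non-empty")
    A = x[samples_a].to_numpy(dtype=float)
    B = x[samples_b].to_numpy(dtype=float)
    with np.errstate(all="ignore"):
        mean_a = np.nanmean(A, axis=1)
        mean_b = np.nanmean(B, axis=1)
    fc_linear = np.power(2.0, mean_a - mean_b)
    p = np.array(
        [
            student_t_test(A[i], B[i], paired=paired)
            for i in range(x.shape[0])
        ]
    )
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fc_linear": fc_linear,
            "fc_signed": signed_fold_change(fc_linear),
            "p_value": p,
        },
        index=x.index,
    )


def ddct_relative_expression(dct_sample, dct_calibrator):
    """Comparative-Ct relative expression, 2**-(dCt_sample - dCt_calibrator).

    Inputs are dCt values (assay Ct minus reference Ct). A sample compared
    with itself gives 1; each unit of ddCt halves the relative expression.
    """
    dct_sample = np.asarray(dct_sample, dtype=float)
    dct_calibrator = np.asarray(dct_calibrator, dtype=float)
    out = np.power(2.0, -(dct_sample - dct_calibrator))
    if out.ndim == 0:
        return float(out)
    return out
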