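"""Numeric post-processing for wet-lab validation assays.

Comparative-Ct (2^-ddCt) relative quantification for qPCR, dual-luciferase
normalization (firefly over Renilla, scaled to the control-group mean), and
Welch two-group significance with the conventional star annotation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .models import ValidationError

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def delta_delta_ct(
    records: pd.DataFrame,
    calibrator_group: str = "control",
) -> pd.DataFrame:
    """Per-sample relative quantity by the comparative-Ct method.

    ``records`` needs columns sample_id, group, ct_target, ct_reference.
    dCt = ct_target - ct_reference; ddCt subtracts the calibrator-group mean
    dCt; RQ = 2^-ddCt.
    """
    required = {"sample_id", "group", "ct_target", "ct_reference"}
    if not required.issubset(records.columns):
        raise ValidationError(f"qPCR table needs columns {sorted(required)}")
    ct = records[["ct_target", "ct_reference"]].to_numpy(dtype=float)
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise ValidationError("Ct values must be finite and positive")
    cal = records["group"] == calibrator_group
    if not cal.any():
        raise ValidationError(f"no records in calibrator group {calibrator_group!r}")
    out = records.copy()
    out["delta_ct"] = out["ct_target"] - out["ct_reference"]
    calibrator_mean = out.loc[cal, "delta_ct"].mean()
    out["delta_delta_ct"] = out["delta_ct"] - calibrator_mean
    out["rq"] = 2.0 ** (-out["delta_delta_ct"])
    return out


def luciferase_relative_activity(
    records: pd.DataFrame,
    control_group: str = "control",
) -> pd.DataFrame:
    """Firefly/Renilla ratio per well, scaled by the control-group mean ratio.

    ``records`` needs columns well_id, group, firefly, renilla.
    """
    required = {"well_id", "group", "firefly", "renilla"}
    if not required.issubset(records.columns):
        raise ValidationError(f"luciferase table needs columns {sorted(required)}")
    if (records["renilla"] <= 0).any():
        raise ValidationError("Renilla luminescence must be positive")
    if (records["firefly"] <= 0).any():
        raise ValidationError("firefly luminescence must be positive")
    ctrl = records["group"] == control_group
    if not ctrl.any():
        raise ValidationError(f"no wells in control group {control_group!r}")
    out = records.copy()
    out["ratio"] = out["firefly"] / out["renilla"]
    out["relative_activity"] = out["ratio"] / out.loc[ctrl, "ratio"].mean()
    return out


def stars(p: float) -> str:
    for threshold, label in STAR_THRESHOLDS:
        if p < threshold:
            return label
    return "ns"


def two_group_test(a, b) -> tuple[float, str]:
    """Welch two-sided t-test with star annotation.

    Degenerate inputs (zero variance in both groups with equal means) return
    p = 1, "ns" by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        if not np.isfinite(p):
            p = 1.0
    return p, stars(p)


def group_summary(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Mean +/- SD per group, the usual figure-panel summary."""
    df = pd.DataFrame({"value": values, "group": groups})
    return df.groupby("group")["value"].agg(["mean", "std", "count"]).reset_index()
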