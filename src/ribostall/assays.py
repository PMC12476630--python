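"""Polysome-profile processing and qPCR analytics (spike-normalized tRNA
charging, delta-delta-Ct expression)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError, logger


@dataclass
class PolysomeProfile:
    """Smoothed, baseline-shifted, anchor-aligned, AUC-normalized trace."""

    positions: np.ndarray  # aligned (reference) axis
    absorbance: np.ndarray  # min-zeroed, AUC-normalized
    anchors: np.ndarray  # anchor positions on the reference axis


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    # centered window, truncated at the edges
    if window <= 1:
        return y.astype(float)
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y, dtype=float), kernel, mode="same")
    return num / den


def _warp(x: np.ndarray, anchors: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Piecewise-linear map sending each anchor exactly onto its reference;
    segments beyond the outer anchors extend with the edge slopes."""
    out = np.interp(x, anchors, ref)
    if anchors.size >= 2:
        s0 = (ref[1] - ref[0]) / (anchors[1] - anchors[0])
        s1 = (ref[-1] - ref[-2]) / (anchors[-1] - anchors[-2])
        left = x < anchors[0]
        right = x > anchors[-1]
        out[left] = ref[0] + s0 * (x[left] - anchors[0])
        out[right] = ref[-1] + s1 * (x[right] - anchors[-1])
    return out


def process_polysome_profile(
    positions: np.ndarray,
    absorbance: np.ndarray,
    anchors: np.ndarray,
    ref_anchors: np.ndarray,
    smooth_window: int = 5,
) -> PolysomeProfile:
    """Smooth, baseline-shift, align anchors onto references, normalize AUC.

    Anchors must be strictly increasing (in both frames) and at least two.
    A constant trace baseline-shifts to all-zero and is fatal (zero AUC).
    """
    positions = np.asarray(positions, dtype=float)
    absorbance = np.asarray(absorbance, dtype=float)
    anchors = np.asarray(anchors, dtype=float)
    ref_anchors = np.asarray(ref_anchors, dtype=float)
    if anchors.size < 2 or anchors.size != ref_anchors.size:
        raise ValidationError("need >= 2 matched anchors")
    if (np.diff(anchors) <= 0).any() or (np.diff(ref_anchors) <= 0).any():
        raise ValidationError("anchors must be strictly increasing")
    if anchors.min() < positions.min() or anchors.max() > positions.max():
        raise ValidationError("anchors outside trace range")
    y = _moving_average(absorbance, smooth_window)
    y = y - y.min()
    x = _warp(positions, anchors, ref_anchors)
    auc = np.trapezoid(y, x)
    if auc <= 0:
        raise ValidationError("degenerate trace: zero area under the curve")
    return PolysomeProfile(positions=x, absorbance=y / auc, anchors=ref_anchors.copy())


def _window_auc(x: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal AUC over [lo, hi], interpolating the window edges."""
    if lo >= hi:
        raise ValidationError("empty integration window")
    inside = (x > lo) & (x < hi)
    xs = np.concatenate([[lo], x[inside], [hi]])
    ys = np.concatenate([[np.interp(lo, x, y)], y[inside], [np.interp(hi, x, y)]])
    return float(np.trapezoid(ys, xs))


def pm_ratio(
    profile: PolysomeProfile,
    monosome_window: tuple[float, float],
    polysome_window: tuple[float, float],
    control_ratio: float | None = None,
) -> dict:
    """Polysome/monosome AUC ratio, optionally normalized to control."""
    if not (monosome_window[1] <= polysome_window[0] or polysome_window[1] <= monosome_window[0]):
        raise ValidationError("monosome and polysome windows overlap")
    m = _window_auc(profile.positions, profile.absorbance, *monosome_window)
    p = _window_auc(profile.positions, profile.absorbance, *polysome_window)
    if m <= 0:
        raise ValidationError("zero monosome AUC")
    ratio = p / m
    out = {"monosome_auc": m, "polysome_auc": p, "pm_ratio": ratio}
    if control_ratio is not None:
        out["pm_ratio_normalized"] = ratio / control_ratio
    return out


def trna_charging_relative(
    measurements: pd.DataFrame, control: str
) -> pd.DataFrame:
    """Spike-normalized relative tRNA charging per (isoacceptor, condition).

    delta-Ct = Ct_target - Ct_spike per sample; ddCt subtracts the control
    mean per isoacceptor; relative charging = 2^(-ddCt).  One-sample t-test
    on the log2 scale against 0, significance at p < 0.05.  Rows lacking a
    spike Ct are dropped with a warning.
    """
    df = measurements.copy()
    missing = df["ct_spike"].isna() | df["ct_target"].isna()
    if missing.any():
        logger.warning("dropping %d measurements without spike/target Ct", int(missing.sum()))
        df = df[~missing]
    df["dct"] = df["ct_target"] - df["ct_spike"]
    rows = []
    for iso, grp in df.groupby("isoacceptor", sort=True):
        ctrl = grp.loc[grp["condition"] == control, "dct"]
        if ctrl.empty:
            raise ValidationError(f"{iso}: no control measurements")
        base = ctrl.mean()
        for cond, sub in grp.groupby("condition", sort=True):
            ddct = sub["dct"].to_numpy() - base
            rel = 2.0 ** (-ddct)
            mean = float(rel.mean())
            if ddct.size >= 2 and ddct.std(ddof=1) > 0:
                p = float(stats.ttest_1samp(-ddct, 0.0).pvalue)
            else:
                p = np.nan
            sem = float(rel.std(ddof=1) / np.sqrt(rel.size)) if rel.size > 1 else np.nan
            rows.append((iso, cond, mean, sem, rel.size, p, bool(p < 0.05) if np.isfinite(p) else False))
    return pd.DataFrame(
        rows,
        columns=["isoacceptor", "condition", "relative_charging", "sem", "n", "p", "significant"],
    )


def ddct_fold_change(
    ct_table: pd.DataFrame,
    target: str,
    housekeeping: str,
    control: str,
) -> pd.DataFrame:
    """Fold change of a target gene vs control by the ddCt method.

    ``ct_table`` columns: sample_id, condition, gene, ct.  Samples missing
    the housekeeping Ct are dropped.  Returns mean fold change +/- SEM per
    condition (fold change = 2^(-ddCt), ddCt vs the housekeeping gene and
    the control-condition mean).
    """
    wide = ct_table.pivot_table(
        index=["sample_id", "condition"], columns="gene", values="ct", aggfunc="mean"
    ).reset_index()
    if housekeeping not in wide.columns or target not in wide.columns:
        raise ValidationError("target or housekeeping gene absent from Ct table")
    bad = wide[housekeeping].isna() | wide[target].isna()
    if bad.any():
        logger.warning("dropping %d samples without matched Cts", int(bad.sum()))
        wide = wide[~bad]
    wide["dct"] = wide[target] - wide[housekeeping]
    ctrl = wide.loc[wide["condition"] == control, "dct"]
    if ctrl.empty:
        raise ValidationError(f"no control samples for {target}")
    base = ctrl.mean()
    wide["fold_change"] = 2.0 ** (-(wide["dct"] - base))
    rows = []
    for cond, grp in wide.groupby("condition", sort=True):
        fc = grp["fold_change"].to_numpy()
        sem = float(fc.std(ddof=1) / np.sqrt(fc.size)) if fc.size > 1 else np.nan
        rows.append((cond, float(fc.mean()), sem, fc.size))
    return pd.DataFrame(rows, columns=["condition", "fold_change", "sem", "n"])
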