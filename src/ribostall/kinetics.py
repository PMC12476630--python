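"""Protein-abundance kinetics under reduced synthesis, classification, and
half-life stratified comparisons.

Model: first-order decay with rate k = ln2 / t_half from pre-perturbation
steady state; at t = 0 synthesis is scaled by the retention fraction s with
k unchanged.  The abundance ratio at time t is then

    P(t) / P(0) = s + (1 - s) * 2^(-t / t_half)

which interpolates between full block (s = 0, pure decay) and no change
(s = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError, logger


@dataclass(frozen=True)
class KineticScenario:
    t: float  # hours since onset
    t_half: float  # protein half-life, hours
    s: float  # synthesis retention fraction in [0, 1]

    def __post_init__(self) -> None:
        if self.t_half <= 0:
            raise ValidationError("t_half must be > 0")
        if self.t < 0:
            raise ValidationError("t must be >= 0")
        if not (0.0 <= self.s <= 1.0):
            raise ValidationError("s must be in [0, 1]")

    @property
    def k(self) -> float:
        return float(np.log(2.0) / self.t_half)


def predict_log2fc(sc: KineticScenario) -> float:
    """log2 abundance fold change at time t under the scenario."""
    ratio = sc.s + (1.0 - sc.s) * 2.0 ** (-sc.t / sc.t_half)
    return float(np.log2(ratio))


def predict_log2fc_grid(
    t_half: np.ndarray | Sequence[float], t: float, s: float
) -> np.ndarray:
    th = np.asarray(t_half, dtype=float)
    if (th <= 0).any():
        raise ValidationError("t_half must be > 0")
    return np.log2(s + (1.0 - s) * 2.0 ** (-t / th))


def classify_proteins(
    records: pd.DataFrame, p_cut: float = 0.01, fc_cut: float = 0.26
) -> pd.DataFrame:
    """Label proteins up/down/unchanged by strict thresholds.

    down: p_adj < p_cut and log2fc < -fc_cut; up symmetric.  Records with
    missing adjusted p are labeled unchanged with a warning.
    """
    df = records.copy()
    p = df["p_adj"]
    n_missing = int(p.isna().sum())
    if n_missing:
        logger.warning("%d records lack adjusted p; labeled unchanged", n_missing)
    sig = p.notna() & (p < p_cut)
    cls = np.where(
        sig & (df["log2fc"] < -fc_cut),
        "down",
        np.where(sig & (df["log2fc"] > fc_cut), "up", "unchanged"),
    )
    df["class"] = cls
    return df


def class_counts(records: pd.DataFrame) -> dict[str, int]:
    return {k: int(v) for k, v in records["class"].value_counts().items()}


def halflife_group_comparison(
    records: pd.DataFrame, log_scale: bool = True
) -> dict:
    """One-way ANOVA + Tukey HSD on half-lives across protein classes.

    Half-lives are log-transformed by default (heavy right tail).  Classes
    with fewer than 2 members are dropped with a warning.
    """
    groups = {}
    for name, grp in records.groupby("class"):
        vals = grp["half_life"].dropna().to_numpy(dtype=float)
        if log_scale:
            vals = np.log(vals[vals > 0])
        if vals.size < 2:
            logger.warning("class %s has < 2 members; dropped", name)
            continue
        groups[name] = vals
    if len(groups) < 2:
        raise ValidationError("need at least 2 non-empty classes")
    names = sorted(groups)
    f, p = stats.f_oneway(*(groups[n] for n in names))
    res = stats.tukey_hsd(*(groups[n] for n in names))
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairs.append((names[i], names[j], float(res.pvalue[i, j])))
    tukey = pd.DataFrame(pairs, columns=["class_a", "class_b", "tukey_p"])
    return {"F": float(f), "p": float(p), "tukey": tukey, "classes": names}


def expected_vs_observed_curve(
    records: pd.DataFrame,
    s_values: Sequence[float] = (0.0, 0.5),
    t: float = 6.0,
    grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Theoretical log2FC-vs-half-life guide curves plus observed values."""
    if grid is None:
        hi = float(records["half_life"].max()) if len(records) else 100.0
        grid = np.geomspace(0.5, max(hi, 1.0), 200)
    curves = pd.DataFrame({"half_life": grid})
    for s in s_values:
        curves[f"pred_log2fc_s{s:g}"] = predict_log2fc_grid(grid, t=t, s=s)
    observed = records[["protein_id", "half_life", "log2fc"]].copy()
    return curves, observed
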