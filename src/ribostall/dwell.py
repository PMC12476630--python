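"""Per-codon, per-site dwell factor estimation and condition testing.

The estimator fits, independently per sample, the Poisson log-linear model

    E[count(g, i)] = exp( log alpha_g + sum_{o=-3..+3} log delta_o(c_{i+o}) )

by cyclic closed-form multiplicative updates.  Identifiability: log delta
has zero mean over the 61 sense codons at every site, enforced each cycle
(the compensation is folded into alpha, so the likelihood is unchanged).
Only positions whose full +/-3 window lies inside the CDS and contains no
stop codon enter the fit.

Site labels follow the ribosome convention: offsets (-3..+3) relative to
the P-site are written ("-2", "-1", "E", "P", "A", "3", "4").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    SENSE_CODONS,
    PositionalCounts,
    TranscriptModel,
    ValidationError,
    logger,
)

OFFSETS = tuple(range(-3, 4))
SITE_LABELS = {-3: "-2", -2: "-1", -1: "E", 0: "P", 1: "A", 2: "3", 3: "4"}
LABEL_TO_OFFSET = {v: k for k, v in SITE_LABELS.items()}
LOG2E = np.log2(np.e)


@dataclass
class DwellTimeTable:
    """Per-sample log2 dwell estimates and gene levels."""

    values: pd.DataFrame  # sample_id, offset, site, codon, log2_dt
    gene_levels: pd.DataFrame  # sample_id, gene_id, log2_alpha
    converged: dict[str, bool] = field(default_factory=dict)
    ll_trace: dict[str, np.ndarray] = field(default_factory=dict)

    def matrix(self, sample_id: str) -> pd.DataFrame:
        """(offset x codon) pivot of log2 dwell for one sample."""
        sub = self.values[self.values["sample_id"] == sample_id]
        return sub.pivot(index="offset", columns="codon", values="log2_dt")


def _valid_positions(codon_ids: np.ndarray) -> np.ndarray:
    """Positions whose +/-3 window is in range and all-sense."""
    n = codon_ids.size
    if n < 7:
        return np.empty(0, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    ok[:3] = False
    ok[n - 3 :] = False
    sense = codon_ids >= 0
    for o in OFFSETS:
        shifted = np.ones(n, dtype=bool)
        lo = max(0, -o)
        hi = min(n, n - o)
        shifted[lo:hi] = sense[lo + o : hi + o]
        ok &= shifted
    return np.nonzero(ok)[0]


def _fit_sample(
    y: np.ndarray,
    gene_idx: np.ndarray,
    n_genes: int,
    C: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, bool, np.ndarray]:
    """Cyclic multiplicative Poisson fit for one sample.

    y: counts per retained position; gene_idx: gene of each position;
    C: (7, n_pos) sense-codon ids at each window slot.
    Returns (delta (7,61), alpha (n_genes,), converged, ll trace).
    """
    n_codons = len(SENSE_CODONS)
    delta = np.ones((len(OFFSETS), n_codons))
    gene_y = np.bincount(gene_idx, weights=y, minlength=n_genes)
    gene_n = np.bincount(gene_idx, minlength=n_genes).astype(float)
    alpha = gene_y / np.maximum(gene_n, 1.0)
    alpha = np.maximum(alpha, 1e-300)

    mu = alpha[gene_idx]
    for k in range(len(OFFSETS)):
        mu = mu * delta[k, C[k]]

    ll_prev = -np.inf
    trace = []
    converged = False
    for _ in range(max_iter):
        for k in range(len(OFFSETS)):
            s_y = np.bincount(C[k], weights=y, minlength=n_codons)
            s_mu = np.bincount(C[k], weights=mu, minlength=n_codons)
            fac = np.where(s_mu > 0, s_y / np.maximum(s_mu, 1e-300), 1.0)
            fac = np.maximum(fac, 1e-12)
            delta[k] *= fac
            mu = mu * fac[C[k]]
        g_mu = np.bincount(gene_idx, weights=mu, minlength=n_genes)
        a_fac = np.where(g_mu > 0, gene_y / np.maximum(g_mu, 1e-300), 1.0)
        a_fac = np.maximum(a_fac, 1e-300)
        alpha *= a_fac
        mu = mu * a_fac[gene_idx]

        # zero-mean log delta per site; compensation goes into alpha so mu
        # (hence the likelihood) is untouched -- exact because every
        # retained window slot is a sense codon
        logd = np.log(delta)
        means = logd.mean(axis=1)
        delta = np.exp(logd - means[:, None])
        alpha *= np.exp(means.sum())

        ll = float(np.sum(y * np.log(np.maximum(mu, 1e-300)) - mu))
        trace.append(ll)
        if ll + 1e-9 * max(1.0, abs(ll)) < ll_prev:
            raise AssertionError("likelihood decreased during cyclic updates")
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * max(1.0, abs(ll_prev)):
            converged = True
            break
        ll_prev = ll
    return delta, alpha, converged, np.asarray(trace)


def estimate_dwell_times(
    counts: PositionalCounts,
    transcripts: Mapping[str, TranscriptModel],
    min_reads_per_gene: float = 10,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> DwellTimeTable:
    """Fit the 7-site dwell model per sample.

    Genes with fewer than ``min_reads_per_gene`` total counts in a sample
    are excluded from that sample's fit.  Non-convergence at ``max_iter``
    is reported via the converged flag (with a warning), not an error.
    """
    tx_ids = [t for t in sorted(counts.counts) if t in transcripts]
    if not tx_ids:
        raise ValidationError("no transcripts shared between counts and CDS set")
    prepped = []
    for tx in tx_ids:
        ids = transcripts[tx].codon_ids()
        pos = _valid_positions(ids)
        if pos.size == 0:
            continue
        win = np.stack([ids[pos + o] for o in OFFSETS])  # all sense by construction
        prepped.append((tx, pos, win))

    value_rows = []
    gene_rows = []
    dt = DwellTimeTable(values=pd.DataFrame(), gene_levels=pd.DataFrame())
    for j, meta in enumerate(counts.samples):
        ys, gidx, wins = [], [], []
        gene_index: dict[str, int] = {}
        for tx, pos, win in prepped:
            yv = counts.counts[tx][pos, j]
            if counts.counts[tx][:, j].sum() < min_reads_per_gene:
                continue
            g = transcripts[tx].gene_id
            gi = gene_index.setdefault(g, len(gene_index))
            ys.append(yv)
            gidx.append(np.full(yv.size, gi))
            wins.append(win)
        genes = list(gene_index)
        if len(genes) < 2:
            raise ValidationError(
                f"sample {meta.sample_id}: fewer than 2 genes pass the read filter"
            )
        y = np.concatenate(ys)
        gene_idx = np.concatenate(gidx)
        C = np.concatenate(wins, axis=1)
        delta, alpha, conv, trace = _fit_sample(y, gene_idx, len(genes), C, tol, max_iter)
        if not conv:
            logger.warning("sample %s: dwell fit did not converge in %d iterations", meta.sample_id, max_iter)
        dt.converged[meta.sample_id] = conv
        dt.ll_trace[meta.sample_id] = trace
        log2d = np.log2(delta)
        for k, o in enumerate(OFFSETS):
            for i, c in enumerate(SENSE_CODONS):
                value_rows.append((meta.sample_id, o, SITE_LABELS[o], c, log2d[k, i]))
        for g, a in zip(genes, alpha):
            gene_rows.append((meta.sample_id, g, float(np.log2(a))))

    dt.values = pd.DataFrame(value_rows, columns=["sample_id", "offset", "site", "codon", "log2_dt"])
    dt.gene_levels = pd.DataFrame(gene_rows, columns=["sample_id", "gene_id", "log2_alpha"])
    return dt


def summarize_window_dt(dt: DwellTimeTable) -> pd.DataFrame:
    """Mean log2 dwell over the seven sites, per (sample, codon)."""
    got = set(dt.values["site"].unique())
    missing = set(SITE_LABELS.values()) - got
    if missing:
        raise ValidationError(f"missing sites in dwell table: {sorted(missing)}")
    out = (
        dt.values.groupby(["sample_id", "codon"], sort=True)["log2_dt"]
        .mean()
        .reset_index()
        .rename(columns={"log2_dt": "window_log2_dt"})
    )
    return out


def dt_anova_tukey(
    window_dt: pd.DataFrame,
    control: str,
    flag_p: float = 0.01,
) -> pd.DataFrame:
    """Per-codon one-way ANOVA across conditions + Tukey HSD vs control.

    ``window_dt`` columns: codon, condition, replicate, window_log2_dt.
    Returns one row per (codon, non-control condition) with the ANOVA F/p,
    the Tukey-adjusted p of the condition-vs-control contrast, the mean
    difference delta_dt, and a flag at ``flag_p``.
    """
    conditions = sorted(window_dt["condition"].unique())
    if control not in conditions:
        raise ValidationError(f"control condition {control!r} absent")
    if len(conditions) < 2:
        raise ValidationError("need at least 2 conditions")
    if len(conditions) == 2:
        out = _anova_tukey_two_groups(window_dt, control, conditions, flag_p)
    else:
        out = _anova_tukey_general(window_dt, control, conditions, flag_p)
    return out


def _anova_tukey_two_groups(
    window_dt: pd.DataFrame, control: str, conditions: list[str], flag_p: float
) -> pd.DataFrame:
    # vectorized fast path: for k = 2 the studentized range reduces exactly
    # to the pooled-variance t distribution (q = sqrt(2)|t|)
    other = next(c for c in conditions if c != control)
    piv = {
        c: window_dt[window_dt["condition"] == c]
        .pivot(index="codon", columns="replicate", values="window_log2_dt")
        .sort_index()
        for c in conditions
    }
    a, b = piv[other], piv[control]
    if a.isna().any().any() or b.isna().any().any() or a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("fewer than 2 replicates in a condition (or ragged design)")
    codons = a.index
    av, bv = a.to_numpy(), b.to_numpy()
    na, nb = av.shape[1], bv.shape[1]
    diff = av.mean(axis=1) - bv.mean(axis=1)
    ssw = ((av - av.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (bv - bv.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = na + nb - 2
    mse = ssw / df
    degen = mse == 0
    if degen.any():
        logger.warning("%d codons with zero within-group variance; p set to 1", int(degen.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / np.sqrt(mse * (1.0 / na + 1.0 / nb))
        F = t ** 2
    p = np.where(degen, 1.0, 2.0 * stats.t.sf(np.abs(np.where(degen, 0.0, t)), df))
    out = pd.DataFrame(
        {
            "codon": codons,
            "condition": other,
            "delta_dt": diff,
            "anova_F": np.where(degen, np.nan, F),
            "anova_p": p,
            "tukey_p": p,  # identical for two groups
            "flagged": p < flag_p,
        }
    )
    return out.reset_index(drop=True)


def _anova_tukey_general(
    window_dt: pd.DataFrame, control: str, conditions: list[str], flag_p: float
) -> pd.DataFrame:
    rows = []
    for codon, grp in window_dt.groupby("codon", sort=True):
        groups = [grp.loc[grp["condition"] == c, "window_log2_dt"].to_numpy() for c in conditions]
        if any(g.size < 2 for g in groups):
            raise ValidationError(f"codon {codon}: fewer than 2 replicates in a condition")
        pooled_var = np.concatenate([g - g.mean() for g in groups]).var()
        if pooled_var == 0.0:
            logger.warning("codon %s: zero within-group variance; p set to 1", codon)
            for c in conditions:
                if c == control:
                    continue
                d = groups[conditions.index(c)].mean() - groups[conditions.index(control)].mean()
                rows.append((codon, c, float(d), np.nan, 1.0, 1.0, False))
            continue
        F, p = stats.f_oneway(*groups)
        res = stats.tukey_hsd(*groups)
        ci = conditions.index(control)
        for k, c in enumerate(conditions):
            if c == control:
                continue
            d = float(groups[k].mean() - groups[ci].mean())
            tp = float(res.pvalue[k, ci])
            rows.append((codon, c, d, float(F), float(p), tp, tp < flag_p))
    return pd.DataFrame(
        rows,
        columns=["codon", "condition", "delta_dt", "anova_F", "anova_p", "tukey_p", "flagged"],
    )


def tukey_two_group_p(a: np.ndarray, b: np.ndarray) -> float:
    """Direct studentized-range p for the two-group case (test oracle)."""
    na, nb = a.size, b.size
    df = na + nb - 2
    mse = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / df
    se = np.sqrt(mse / 2.0 * (1.0 / na + 1.0 / nb))
    q = abs(a.mean() - b.mean()) / se
    return float(stats.studentized_range.sf(q, 2, df))


def dt_frequency_relation(
    window_dt_mean: pd.DataFrame, freq: pd.Series
) -> dict:
    """Correlate per-codon log2 DT with codon frequency (%).

    ``window_dt_mean``: columns codon, window_log2_dt (already averaged over
    replicates).  Returns Pearson/Spearman correlations and the OLS trend.
    Constant DTs yield missing correlations and slope 0.
    """
    merged = window_dt_mean.set_index("codon")["window_log2_dt"].reindex(freq.index)
    if merged.isna().any():
        raise ValidationError("codons missing from dwell summary")
    x = freq.to_numpy(dtype=float)
    y = merged.to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        return {
            "pearson_r": np.nan, "pearson_p": np.nan,
            "spearman_r": np.nan, "spearman_p": np.nan,
            "slope": 0.0, "intercept": float(y[0]),
        }
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return {
        "pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
        "spearman_r": float(sr.statistic), "spearman_p": float(sr.pvalue),
        "slope": float(slope), "intercept": float(intercept),
    }
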