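"""Normalization, transcript filtering, metagene profiles, ramp indices,
polarity scores, codon-window density enrichment and region codon-frequency
shifts.

All "unpaired t-tests" here are Welch's (unequal variance).  Density log2
fold changes use a pseudocount of half the smallest nonzero Norm_RPM of the
transcript.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import (
    SENSE_CODONS,
    PositionalCounts,
    TranscriptModel,
    ValidationError,
    logger,
)


def normalize_counts(counts: PositionalCounts) -> PositionalCounts:
    """Populate the RPM and Norm_RPM layers in place (and return counts).

    RPM = count * 1e6 / library size.  Norm_RPM divides each position's RPM
    by the transcript's total RPM in that sample; transcripts with zero
    total carry NaN Norm_RPM for that sample.
    """
    lib = counts.library_sizes()
    if (lib <= 0).any():
        raise ValidationError("zero library size")
    rpm: dict[str, np.ndarray] = {}
    norm: dict[str, np.ndarray] = {}
    for tx, arr in counts.counts.items():
        r = arr * (1e6 / lib)
        tot = r.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            n = np.where(tot > 0, r / np.where(tot > 0, tot, 1.0), np.nan)
        rpm[tx] = r
        norm[tx] = n
    counts.rpm = rpm
    counts.norm_rpm = norm
    return counts


def filter_transcripts(
    counts: PositionalCounts,
    min_mean_total: float = 50.0,
    min_coverage: float = 0.30,
) -> list[str]:
    """Transcripts with cross-sample mean total count >= min_mean_total and
    mean fraction of nonzero positions >= min_coverage."""
    keep = []
    for tx in sorted(counts.counts):
        arr = counts.counts[tx]
        if arr.sum(axis=0).mean() < min_mean_total:
            continue
        if (arr > 0).mean(axis=0).mean() < min_coverage:
            continue
        keep.append(tx)
    if not keep:
        raise ValidationError(
            f"no transcripts pass filtering (of {len(counts.counts)}; "
            f"min_mean_total={min_mean_total}, min_coverage={min_coverage})"
        )
    return keep


def _half_min_nonzero(arr: np.ndarray) -> float:
    nz = arr[np.isfinite(arr) & (arr > 0)]
    return float(nz.min()) / 2.0 if nz.size else 0.0


def _binned_profile(density: np.ndarray, n_bins: int) -> np.ndarray:
    """Distribute a per-position density over percent-rank bins by interval
    overlap (position i of L covers [i, i+1)/L), so uniform density maps to
    an exactly flat profile."""
    L = density.size
    cum = np.concatenate([[0.0], np.cumsum(density)])
    pos_edges = np.arange(L + 1) / L
    bin_edges = np.arange(n_bins + 1) / n_bins
    F = np.interp(bin_edges, pos_edges, cum)
    return np.diff(F)


def metagene_profile(
    counts: PositionalCounts,
    transcripts: Mapping[str, TranscriptModel],
    retained: Sequence[str],
    exclude_nt: int = 15,
    n_bins: int = 100,
) -> pd.DataFrame:
    """Mean Norm_RPM by normalized CDS position, per condition, with SEM.

    The first/last ``exclude_nt`` nucleotides (5 codons for the default) are
    dropped and the remaining density renormalized per transcript before
    percent-rank binning.  Each (transcript, replicate) profile contributes
    once; SEM is across those profiles.
    """
    if counts.norm_rpm is None:
        normalize_counts(counts)
    k = exclude_nt // 3
    per_cond: dict[str, list[np.ndarray]] = {}
    for tx in retained:
        n = transcripts[tx].n_codons
        if n < 2 * k + 1:
            logger.warning("metagene: %s too short after edge exclusion; skipped", tx)
            continue
        norm = counts.norm_rpm[tx]
        trimmed = norm[k : n - k, :]
        for j, s in enumerate(counts.samples):
            d = trimmed[:, j]
            tot = np.nansum(d)
            if not np.isfinite(tot) or tot <= 0:
                continue
            prof = _binned_profile(np.nan_to_num(d) / tot, n_bins)
            per_cond.setdefault(s.condition, []).append(prof)
    rows = []
    for cond in sorted(per_cond):
        mat = np.vstack(per_cond[cond])
        mean = mat.mean(axis=0)
        sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 else np.zeros(n_bins)
        for b in range(n_bins):
            rows.append((cond, b + 1, mean[b], sem[b], mat.shape[0]))
    return pd.DataFrame(rows, columns=["condition", "bin", "mean_norm_rpm", "sem", "n"])


def region_sums(
    norm: np.ndarray, region_fraction: float = 0.20
) -> tuple[np.ndarray, np.ndarray]:
    """(5' sum, 3' sum) of per-sample Norm_RPM over the first/last region."""
    L = norm.shape[0]
    k = max(1, int(np.floor(region_fraction * L)))
    return np.nansum(norm[:k, :], axis=0), np.nansum(norm[L - k :, :], axis=0)


def ramp_index(
    counts: PositionalCounts,
    transcripts: Mapping[str, TranscriptModel],
    retained: Sequence[str],
    control: str,
    region_fraction: float = 0.20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """5'/3' region Norm_RPM sums and their log2 ratios vs the control mean.

    Returns (per-transcript table, per-condition summary).  The summary
    holds mean +/- SEM of the log2 ratios and a Welch t-test vs the control
    replicates' own ratios, Bonferroni-corrected across non-control
    conditions.
    """
    if counts.norm_rpm is None:
        normalize_counts(counts)
    ctrl_cols = counts.columns(control)
    if not ctrl_cols:
        raise ValidationError(f"control condition {control!r} absent")
    rows = []
    for tx in retained:
        norm = counts.norm_rpm[tx]
        s5, s3 = region_sums(norm, region_fraction)
        c5 = np.nanmean(s5[ctrl_cols])
        c3 = np.nanmean(s3[ctrl_cols])
        if not (c5 > 0) or not (c3 > 0):
            continue
        for j, s in enumerate(counts.samples):
            if not np.isfinite(s5[j]):
                continue
            rows.append(
                (
                    tx, s.sample_id, s.condition, s.replicate,
                    s5[j], s3[j],
                    np.log2(s5[j] / c5) if s5[j] > 0 else np.nan,
                    np.log2(s3[j] / c3) if s3[j] > 0 else np.nan,
                )
            )
    per_tx = pd.DataFrame(
        rows,
        columns=["transcript_id", "sample_id", "condition", "replicate",
                 "sum5", "sum3", "log2_ratio5", "log2_ratio3"],
    )
    conditions = sorted(per_tx["condition"].unique())
    n_tests = max(1, len(conditions) - 1)
    srows = []
    for cond in conditions:
        sub = per_tx[per_tx["condition"] == cond]
        ctrl = per_tx[per_tx["condition"] == control]
        for region in ("5", "3"):
            v = sub[f"log2_ratio{region}"].dropna().to_numpy()
            cv = ctrl[f"log2_ratio{region}"].dropna().to_numpy()
            if cond == control or v.size < 2 or cv.size < 2:
                p = np.nan
            else:
                p = min(1.0, float(stats.ttest_ind(v, cv, equal_var=False).pvalue) * n_tests)
            sem = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan
            srows.append((cond, region, float(v.mean()) if v.size else np.nan, sem, p))
    summary = pd.DataFrame(srows, columns=["condition", "region", "mean_log2_ratio", "sem", "p_bonferroni"])
    return per_tx, summary


def polarity_weights(L: int) -> np.ndarray:
    """w_i = (2i - (L+1)) / (L-1) for 1-based i; w_1 = -1, w_L = +1."""
    if L < 2:
        raise ValidationError("polarity needs at least 2 positions")
    i = np.arange(1, L + 1)
    return (2 * i - (L + 1)) / (L - 1)


def polarity_score(
    counts: PositionalCounts, retained: Sequence[str]
) -> pd.DataFrame:
    """Polarity pi per (transcript, sample): density-weighted mean of the
    position weights; -1 means all density at the first codon."""
    rows = []
    for tx in retained:
        arr = counts.counts[tx]
        L = arr.shape[0]
        if L < 2:
            continue
        w = polarity_weights(L)
        tot = arr.sum(axis=0)
        for j, s in enumerate(counts.samples):
            if tot[j] <= 0:
                continue
            pi = float(w @ (arr[:, j] / tot[j]))
            rows.append((tx, s.sample_id, s.condition, s.replicate, pi))
    return pd.DataFrame(rows, columns=["transcript_id", "sample_id", "condition", "replicate", "polarity"])


def delta_polarity_test(
    records: pd.DataFrame,
    control: str,
    cut: float = -0.15,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-transcript Welch t-test of replicate polarity vs control.

    Returns one row per (transcript, non-control condition) with delta_pi,
    p, and the significance flag (delta_pi < cut AND p < alpha).
    """
    rows = []
    for (tx, cond), grp in records.groupby(["transcript_id", "condition"], sort=True):
        if cond == control:
            continue
        ctrl = records[(records["transcript_id"] == tx) & (records["condition"] == control)]
        a = grp["polarity"].to_numpy()
        b = ctrl["polarity"].to_numpy()
        if a.size < 2 or b.size < 2:
            raise ValidationError(f"{tx}/{cond}: need >= 2 replicates per condition")
        delta = float(a.mean() - b.mean())
        if np.allclose(a, a.mean()) and np.allclose(b, b.mean()) and np.isclose(a.mean(), b.mean()):
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append((tx, cond, delta, p, (delta < cut) and (p < alpha)))
    return pd.DataFrame(rows, columns=["transcript_id", "condition", "delta_polarity", "p", "significant"])


def codon_window_enrichment(
    counts: PositionalCounts,
    transcripts: Mapping[str, TranscriptModel],
    retained: Sequence[str],
    codon: str,
    condition: str,
    control: str,
    halfwidth_nt: int = 50,
) -> pd.DataFrame:
    """Mean relative density (condition / control baseline) around each
    occurrence of ``codon``, by codon-unit offset, reported as log2.

    Occurrences closer than the halfwidth to a CDS edge are skipped.
    """
    if counts.norm_rpm is None:
        normalize_counts(counts)
    hw = halfwidth_nt // 3
    cond_cols = counts.columns(condition)
    ctrl_cols = counts.columns(control)
    if not cond_cols or not ctrl_cols:
        raise ValidationError("condition or control absent from samples")
    acc = np.zeros(2 * hw + 1)
    n_occ = np.zeros(2 * hw + 1, dtype=int)
    found = 0
    for tx in retained:
        m = transcripts[tx]
        positions = [i for i, c in enumerate(m.codons) if c == codon]
        if not positions:
            continue
        norm = counts.norm_rpm[tx]
        pc = _half_min_nonzero(norm)
        if pc == 0.0:
            continue
        base = np.nanmean(norm[:, ctrl_cols], axis=1) + pc
        rel = (np.nan_to_num(norm[:, cond_cols]) + pc) / base[:, None]
        L = m.n_codons
        for p in positions:
            if p - hw < 0 or p + hw > L - 1:
                continue
            found += 1
            window = rel[p - hw : p + hw + 1, :]
            acc += window.sum(axis=1)
            n_occ += window.shape[1]
    if found == 0:
        logger.warning("codon %s absent from retained transcripts (or all near edges)", codon)
        return pd.DataFrame(columns=["offset", "log2_relative", "n_occurrences"])
    with np.errstate(divide="ignore"):
        log2rel = np.log2(acc / n_occ)
    return pd.DataFrame(
        {"offset": np.arange(-hw, hw + 1), "log2_relative": log2rel, "n_occurrences": found}
    )


def region_codon_fractions(
    transcripts: Mapping[str, TranscriptModel],
    tx_ids: Sequence[str],
    region_fraction: float = 0.20,
) -> pd.DataFrame:
    """Per-transcript sense-codon fractions within the first region."""
    rows = []
    for tx in tx_ids:
        m = transcripts[tx]
        k = max(1, int(np.floor(region_fraction * m.n_codons)))
        region = [c for c in m.codons[:k] if c in set(SENSE_CODONS)]
        if not region:
            continue
        counts = pd.Series(region).value_counts()
        frac = counts.reindex(SENSE_CODONS, fill_value=0) / len(region)
        rows.append(pd.Series(frac.to_numpy(), index=SENSE_CODONS, name=tx))
    return pd.DataFrame(rows)


def region_codon_frequency_shift(
    selected: Sequence[str],
    background: Sequence[str],
    transcripts: Mapping[str, TranscriptModel],
    region_fraction: float = 0.20,
) -> pd.DataFrame:
    """Compare first-region codon fractions of selected vs background
    transcripts: per-codon log2FC of means, Welch t, BH across codons."""
    if not len(selected) or not len(background):
        raise ValidationError("selected and background sets must be non-empty")
    sel = region_codon_fractions(transcripts, selected, region_fraction)
    bg = region_codon_fractions(transcripts, background, region_fraction)
    rows = []
    for codon in SENSE_CODONS:
        a = sel[codon].to_numpy()
        b = bg[codon].to_numpy()
        mb = b.mean()
        fc = np.log2(a.mean() / mb) if mb > 0 and a.mean() > 0 else np.nan
        if a.size >= 2 and b.size >= 2 and (a.std() > 0 or b.std() > 0):
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            p = np.nan
        rows.append((codon, fc, p))
    df = pd.DataFrame(rows, columns=["codon", "log2fc", "p"])
    mask = df["p"].notna()
    df["p_adj"] = np.nan
    if mask.any():
        df.loc[mask, "p_adj"] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
    return df
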