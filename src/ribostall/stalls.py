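"""Per-position stall-site calling versus control, codon-context profiles,
overlap statistics, positional distributions and proteome enrichment.

A position passes when log2FC(RPM) > 2, log2FC(Norm_RPM) > 2,
FC_relative_to_gene_mean > 1 and the Welch p across replicates is < 0.05
(all thresholds configurable).  "Position" is a codon position; the
replicate test runs on log(Norm_RPM + pseudocount).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    AnalysisConfig,
    PositionalCounts,
    StallSite,
    TranscriptModel,
    ValidationError,
    logger,
)
from .metrics import _half_min_nonzero, normalize_counts


def _welch_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-test p-values; both-groups-zero-variance rows get 1."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    denom = va / na + vb / nb
    p = np.ones(a.shape[0])
    ok = denom > 0
    t = np.zeros(a.shape[0])
    t[ok] = (ma[ok] - mb[ok]) / np.sqrt(denom[ok])
    df = np.ones(a.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        df[ok] = denom[ok] ** 2 / (
            (va[ok] / na) ** 2 / (na - 1) + (vb[ok] / nb) ** 2 / (nb - 1)
        )
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    n_degen = int((~ok).sum())
    if n_degen:
        logger.debug("%d positions with zero variance in both groups; p=1", n_degen)
    return p


def call_stall_sites(
    counts: PositionalCounts,
    transcripts: Mapping[str, TranscriptModel],
    retained: Sequence[str],
    condition: str,
    control: str,
    cfg: AnalysisConfig | None = None,
    full_table: bool = False,
) -> pd.DataFrame:
    """Call per-position stalling sites of ``condition`` versus ``control``.

    Returns passing sites by default; ``full_table=True`` returns every
    tested position with its criteria.
    """
    cfg = cfg or AnalysisConfig()
    if counts.norm_rpm is None:
        normalize_counts(counts)
    cond_cols = counts.columns(condition)
    ctrl_cols = counts.columns(control)
    if len(cond_cols) < 2 or len(ctrl_cols) < 2:
        raise ValidationError("need >= 2 replicates in condition and control")
    frames = []
    for tx in retained:
        rpm = counts.rpm[tx]
        norm = np.nan_to_num(counts.norm_rpm[tx])
        mean_rpm_c = rpm[:, cond_cols].mean(axis=1)
        mean_rpm_k = rpm[:, ctrl_cols].mean(axis=1)
        pc = cfg.pseudocount
        l2_rpm = np.log2((mean_rpm_c + pc) / (mean_rpm_k + pc))
        pcn = _half_min_nonzero(norm)
        if pcn == 0.0:
            continue
        mean_n_c = norm[:, cond_cols].mean(axis=1)
        mean_n_k = norm[:, ctrl_cols].mean(axis=1)
        l2_norm = np.log2((mean_n_c + pcn) / (mean_n_k + pcn))
        gene_mean = mean_rpm_c.mean()
        fc_gene = mean_rpm_c / gene_mean if gene_mean > 0 else np.zeros_like(mean_rpm_c)
        p = _welch_rows(
            np.log(norm[:, cond_cols] + pcn), np.log(norm[:, ctrl_cols] + pcn)
        )
        passes = (
            (l2_rpm > cfg.peak_log2fc_rpm)
            & (l2_norm > cfg.peak_log2fc_norm)
            & (fc_gene > cfg.peak_fc_gene_mean)
            & (p < cfg.peak_p)
        )
        df = pd.DataFrame(
            {
                "transcript_id": tx,
                "codon_position": np.arange(rpm.shape[0]),
                "condition": condition,
                "log2fc_rpm": l2_rpm,
                "log2fc_norm": l2_norm,
                "fc_gene_mean": fc_gene,
                "p": p,
                "passes": passes,
            }
        )
        frames.append(df if full_table else df[df["passes"]])
    cols = ["transcript_id", "codon_position", "condition", "log2fc_rpm",
            "log2fc_norm", "fc_gene_mean", "p", "passes"]
    if not frames:
        return pd.DataFrame(columns=cols)
    out = pd.concat(frames, ignore_index=True)
    return out[cols]


def sites_to_records(sites: pd.DataFrame) -> list[StallSite]:
    return [
        StallSite(
            transcript_id=r.transcript_id,
            codon_position=int(r.codon_position),
            condition=r.condition,
            log2fc_rpm=float(r.log2fc_rpm),
            log2fc_norm=float(r.log2fc_norm),
            fc_gene_mean=float(r.fc_gene_mean),
            p=float(r.p),
            passes=bool(r.passes),
        )
        for r in sites.itertuples()
    ]


def stall_codon_context(
    sites: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    codons: Sequence[str],
    halfwidth_nt: int = 50,
) -> tuple[pd.DataFrame, float]:
    """Count queried codons by offset around each called site.

    Offset 0 is the called codon itself; windows truncate at CDS edges with
    no padding.  Returns (per-offset counts per queried codon, proportion of
    windows containing at least one queried codon).
    """
    hw = halfwidth_nt // 3
    offsets = np.arange(-hw, hw + 1)
    table = pd.DataFrame(0, index=offsets, columns=list(codons))
    table.index.name = "offset"
    if sites.empty:
        return table, float("nan")
    qset = set(codons)
    n_windows = 0
    n_containing = 0
    for r in sites.itertuples():
        m = transcripts[r.transcript_id]
        p = int(r.codon_position)
        lo = max(0, p - hw)
        hi = min(m.n_codons - 1, p + hw)
        window = m.codons[lo : hi + 1]
        n_windows += 1
        if qset & set(window):
            n_containing += 1
        for i, c in enumerate(window, start=lo):
            if c in qset:
                table.loc[i - p, c] += 1
    return table, n_containing / n_windows


def stall_overlap(
    sites_a: Iterable[tuple], sites_b: Iterable[tuple], universe_size: int
) -> dict:
    """Overlap of two site (or transcript) sets + upper-tail hypergeometric p.

    p = P(X >= k) with X ~ Hypergeom(N=universe, K=|A|, n=|B|).
    """
    a, b = set(sites_a), set(sites_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValidationError("set larger than universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return {"overlap": k, "n_a": len(a), "n_b": len(b), "universe": universe_size, "p": p}


def stall_site_metagene(
    sites: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    n_bins: int = 50,
) -> pd.DataFrame:
    """Distribution of called sites over relative CDS position, per condition."""
    if sites.empty:
        return pd.DataFrame(columns=["condition", "bin", "count", "density"])
    rows = []
    for cond, grp in sites.groupby("condition", sort=True):
        rel = np.array(
            [
                r.codon_position / transcripts[r.transcript_id].n_codons
                for r in grp.itertuples()
            ]
        )
        idx = np.minimum((rel * n_bins).astype(int), n_bins - 1)
        hist = np.bincount(idx, minlength=n_bins)
        dens = hist / hist.sum()
        for b in range(n_bins):
            rows.append((cond, b + 1, int(hist[b]), dens[b]))
    return pd.DataFrame(rows, columns=["condition", "bin", "count", "density"])


def first_site_distance(
    sites_cond1: pd.DataFrame, sites_cond2: pd.DataFrame
) -> pd.DataFrame:
    """Signed distance (codons) between the first (most 5') sites of two
    conditions, per transcript.  Positive means condition 2's first site is
    upstream of condition 1's.  Transcripts lacking sites in either
    condition are excluded."""
    f1 = sites_cond1.groupby("transcript_id")["codon_position"].min()
    f2 = sites_cond2.groupby("transcript_id")["codon_position"].min()
    shared = f1.index.intersection(f2.index)
    return pd.DataFrame(
        {
            "transcript_id": shared,
            "first_cond1": f1[shared].to_numpy(),
            "first_cond2": f2[shared].to_numpy(),
            "distance": (f1[shared] - f2[shared]).to_numpy(),
        }
    )


def stall_proteome_enrichment(
    sites: pd.DataFrame,
    downregulated: Iterable[str],
    universe: Iterable[str],
    tx_to_protein: Mapping[str, str] | None = None,
    k_max: int = 5,
) -> pd.DataFrame:
    """Overlap of downregulated proteins with transcripts carrying >= k
    stall sites, with the hypergeometric -log10 p per stratum.

    k = 0 is the whole universe (overlap = |downregulated| by definition).
    ``tx_to_protein`` maps transcript ids into the protein namespace;
    identity by default.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    down = set(downregulated) & uni
    mapper = tx_to_protein or {}
    per_tx = sites.groupby("transcript_id").size()
    n_sites: dict[str, int] = {}
    for tx, n in per_tx.items():
        n_sites[mapper.get(tx, tx)] = int(n)
    rows = []
    for k in range(0, k_max + 1):
        stratum = uni if k == 0 else {p for p in uni if n_sites.get(p, 0) >= k}
        overlap = len(down & stratum)
        p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(stratum), len(down)))
        rows.append((k, len(stratum), overlap, p, -np.log10(p) if p > 0 else np.inf))
    df = pd.DataFrame(rows, columns=["k", "n_transcripts", "overlap", "p", "neglog10_p"])
    df.attrs["reference_line"] = -np.log10(0.05)
    return df
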