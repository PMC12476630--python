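"""Genome-wide codon count table and positional codon-bias profiling."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import SENSE_CODONS, TranscriptModel, ValidationError, logger

_SENSE_SET = set(SENSE_CODONS)


@dataclass
class CodonTable:
    counts: pd.DataFrame  # gene x codon mean counts (isoform-averaged)
    fractions: pd.DataFrame  # gene x codon fractions (rows sum to 1)

    def mean_frequency_percent(self) -> pd.Series:
        """Transcriptome mean codon frequency (%) over genes."""
        return self.fractions.mean(axis=0) * 100.0


def build_codon_table(
    transcripts: Mapping[str, TranscriptModel]
) -> CodonTable:
    """Per-gene codon counts and fractions over the 61 sense codons.

    Isoforms (transcripts sharing a gene_id) have their counts averaged
    first, then normalized — averaging fractions directly would weight
    isoforms by length and give different numbers.  Stop codons are
    excluded; the start codon is retained.
    """
    if not transcripts:
        raise ValidationError("empty CDS set")
    per_gene: dict[str, list[np.ndarray]] = {}
    idx = {c: i for i, c in enumerate(SENSE_CODONS)}
    for tx_id in sorted(transcripts):
        m = transcripts[tx_id]
        vec = np.zeros(len(SENSE_CODONS))
        for c in m.codons:
            if c in _SENSE_SET:
                vec[idx[c]] += 1
        per_gene.setdefault(m.gene_id, []).append(vec)
    genes = sorted(per_gene)
    mat = np.vstack([np.mean(per_gene[g], axis=0) for g in genes])
    counts = pd.DataFrame(mat, index=genes, columns=SENSE_CODONS)
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValidationError(f"gene {bad} has no sense codons")
    fractions = counts.div(totals, axis=0)
    return CodonTable(counts=counts, fractions=fractions)


def positional_codon_bias(
    transcripts: Mapping[str, TranscriptModel],
    n_bins: int = 20,
    region_fraction: float = 0.20,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Codon frequency by normalized CDS position.

    Returns (codon x bin frequency matrix, per-codon first-region/rest
    frequency ratio with a bootstrap CI over genes).  Frequencies within a
    bin sum to 1 across codons.
    """
    if not transcripts:
        raise ValidationError("empty CDS set")
    tx_ids = sorted(transcripts)
    idx = {c: i for i, c in enumerate(SENSE_CODONS)}
    # per-gene (bin x codon) and (2 x codon: first region / rest) count blocks
    bin_blocks = []
    region_blocks = []
    for tx in tx_ids:
        m = transcripts[tx]
        ids = [idx[c] for c in m.codons if c in _SENSE_SET]
        n = len(ids)
        if n == 0:
            continue
        rel = np.arange(n) / n
        bins = np.minimum((rel * n_bins).astype(int), n_bins - 1)
        bb = np.zeros((n_bins, len(SENSE_CODONS)))
        np.add.at(bb, (bins, ids), 1.0)
        bin_blocks.append(bb)
        rb = np.zeros((2, len(SENSE_CODONS)))
        first = rel < region_fraction
        np.add.at(rb, (np.where(first, 0, 1), ids), 1.0)
        region_blocks.append(rb)
    bin_counts = np.sum(bin_blocks, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        bin_freq = bin_counts / bin_counts.sum(axis=1, keepdims=True)
    freq_df = pd.DataFrame(
        bin_freq.T, index=SENSE_CODONS, columns=np.arange(1, n_bins + 1)
    )

    region = np.stack(region_blocks)  # (genes, 2, codons)

    def _ratio(block_sum: np.ndarray) -> np.ndarray:
        first_f = block_sum[0] / max(block_sum[0].sum(), 1.0)
        rest_f = block_sum[1] / max(block_sum[1].sum(), 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(rest_f > 0, first_f / rest_f, np.nan)

    point = _ratio(region.sum(axis=0))
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, len(SENSE_CODONS)))
    ng = region.shape[0]
    for b in range(n_boot):
        pick = rng.integers(0, ng, ng)
        boot[b] = _ratio(region[pick].sum(axis=0))
    lo = np.nanpercentile(boot, 2.5, axis=0)
    hi = np.nanpercentile(boot, 97.5, axis=0)
    ratio_df = pd.DataFrame(
        {"codon": SENSE_CODONS, "ratio_first_vs_rest": point, "ci_low": lo, "ci_high": hi}
    )
    return freq_df, ratio_df
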