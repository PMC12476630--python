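"""Shared domain types, file formats, configuration and logging.

Counts are codon-resolution and already P-site assigned; the long-format
TSV count table, the CDS FASTA and the BED6 stall-site output are the
interchange formats for every other module.

Coordinate conventions: codon positions are 0-based throughout; BED output
uses 0-based half-open nucleotide coordinates on the transcript.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("ribostall")

STOP_CODONS = ("TAA", "TAG", "TGA")
ALL_CODONS = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
#: sense codons get ids 0..60; stop codons map to -1 in codon-id arrays
CODON_TO_ID = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_TO_ID.update({c: -1 for c in STOP_CODONS})

VAL_CODONS = ("GTT", "GTC", "GTA", "GTG")
ILE_CODONS = ("ATT", "ATC", "ATA")
LEU_CODONS = ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG")


class ValidationError(ValueError):
    """Fatal input-validation failure."""


@dataclass(frozen=True)
class TranscriptModel:
    """One CDS as an ordered codon sequence (the coordinate frame downstream)."""

    gene_id: str
    transcript_id: str
    cds_nt: str

    def __post_init__(self) -> None:
        nt = self.cds_nt.upper().replace("U", "T")
        if len(nt) == 0 or len(nt) % 3 != 0:
            raise ValidationError(
                f"{self.transcript_id}: CDS length {len(nt)} is not a positive multiple of 3"
            )
        if set(nt) - set("ACGT"):
            raise ValidationError(
                f"{self.transcript_id}: CDS contains non-ACGT(U) characters"
            )
        object.__setattr__(self, "cds_nt", nt)

    @property
    def n_codons(self) -> int:
        return len(self.cds_nt) // 3

    @property
    def codons(self) -> tuple[str, ...]:
        nt = self.cds_nt
        return tuple(nt[i : i + 3] for i in range(0, len(nt), 3))

    def codon_ids(self) -> np.ndarray:
        """Sense-codon ids per position; stop codons are -1."""
        return np.array([CODON_TO_ID[c] for c in self.codons], dtype=np.int64)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    condition: str
    replicate: int
    library_size: float | None = None

    def __post_init__(self) -> None:
        if self.library_size is not None and self.library_size < 0:
            raise ValidationError(f"{self.sample_id}: negative library size")


@dataclass
class PositionalCounts:
    """Transcript x codon-position x sample footprint counts.

    ``counts[t]`` is an (n_positions, n_samples) array in sample order.
    ``rpm`` / ``norm_rpm`` are derived layers filled by
    :func:`ribostall.metrics.normalize_counts`.
    """

    samples: list[SampleMeta]
    counts: dict[str, np.ndarray]
    rpm: dict[str, np.ndarray] | None = None
    norm_rpm: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        seen = set()
        for s in self.samples:
            key = (s.condition, s.replicate)
            if key in seen:
                raise ValidationError(f"duplicate (condition, replicate) {key}")
            seen.add(key)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def sample_index(self) -> dict[str, int]:
        return {s.sample_id: j for j, s in enumerate(self.samples)}

    def columns(self, condition: str) -> list[int]:
        return [j for j, s in enumerate(self.samples) if s.condition == condition]

    def library_sizes(self) -> np.ndarray:
        """Declared library sizes, falling back to observed per-sample totals."""
        totals = self.totals()
        out = np.empty(len(self.samples))
        for j, s in enumerate(self.samples):
            out[j] = s.library_size if s.library_size else totals[j]
        return out

    def totals(self) -> np.ndarray:
        tot = np.zeros(len(self.samples))
        for arr in self.counts.values():
            tot += arr.sum(axis=0)
        return tot

    def to_frame(self) -> pd.DataFrame:
        rows = []
        ids = self.sample_ids
        for tx in sorted(self.counts):
            arr = self.counts[tx]
            pos, col = np.nonzero(arr)
            for p, j in zip(pos, col):
                rows.append((tx, int(p), ids[j], arr[p, j]))
        df = pd.DataFrame(rows, columns=["transcript_id", "codon_position", "sample_id", "count"])
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class StallSite:
    """A called peak: position plus the three fold-change criteria and p."""

    transcript_id: str
    codon_position: int
    condition: str
    log2fc_rpm: float
    log2fc_norm: float
    fc_gene_mean: float
    p: float
    passes: bool = True


# Default analysis thresholds; every field may be overridden from the
# YAML config consumed by load_config.
_CONFIG_DEFAULTS: dict[str, float | int] = {
    "min_mean_total": 50.0,
    "min_coverage_fraction": 0.30,
    "edge_exclusion_nt": 15,
    "region_fraction": 0.20,
    "delta_polarity_cut": -0.15,
    "delta_polarity_alpha": 0.05,
    "peak_log2fc_rpm": 2.0,
    "peak_log2fc_norm": 2.0,
    "peak_fc_gene_mean": 1.0,
    "peak_p": 0.05,
    "protein_p": 0.01,
    "protein_log2fc": 0.26,
    "pseudocount": 0.5,
    "context_halfwidth_nt": 50,
    "metagene_bins": 100,
    "stall_metagene_bins": 50,
    "min_reads_per_gene": 10,
    "seed": 0,
}


@dataclass(frozen=True)
class AnalysisConfig:
    min_mean_total: float = 50.0
    min_coverage_fraction: float = 0.30
    edge_exclusion_nt: int = 15
    region_fraction: float = 0.20
    delta_polarity_cut: float = -0.15
    delta_polarity_alpha: float = 0.05
    peak_log2fc_rpm: float = 2.0
    peak_log2fc_norm: float = 2.0
    peak_fc_gene_mean: float = 1.0
    peak_p: float = 0.05
    protein_p: float = 0.01
    protein_log2fc: float = 0.26
    pseudocount: float = 0.5
    context_halfwidth_nt: int = 50
    metagene_bins: int = 100
    stall_metagene_bins: int = 50
    min_reads_per_gene: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValidationError(f"config value {f.name} is not finite")


def load_config(path: str | Path | None = None, **overrides) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML; unset keys take defaults.

    Unknown keys are fatal.  The fully resolved configuration is echoed to
    the package log.
    """
    values: dict = dict(_CONFIG_DEFAULTS)
    loaded: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"{path}: config must be a mapping")
    loaded.update(overrides)
    for key, val in loaded.items():
        if key not in _CONFIG_DEFAULTS:
            raise ValidationError(f"unknown configuration key: {key!r}")
        values[key] = val
    cfg = AnalysisConfig(**values)
    logger.info("resolved config: %s", dataclasses.asdict(cfg))
    return cfg


def read_cds_fasta(path: str | Path) -> dict[str, TranscriptModel]:
    """Read CDS records into TranscriptModels keyed by transcript id.

    Records whose length is not a multiple of 3, or containing characters
    outside A/C/G/T/U, are skipped with a warning.  ``gene=<id>`` in the
    description assigns the gene; otherwise gene_id = transcript_id.
    """
    models: dict[str, TranscriptModel] = {}
    n_skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        gene = rec.id
        for tok in rec.description.split():
            if tok.startswith("gene="):
                gene = tok[5:]
        if len(seq) == 0 or len(seq) % 3 != 0 or set(seq) - set("ACGT"):
            logger.warning("skipping %s: invalid CDS (length %d)", rec.id, len(seq))
            n_skipped += 1
            continue
        if rec.id in models:
            raise ValidationError(f"duplicate FASTA identifier {rec.id}")
        models[rec.id] = TranscriptModel(gene_id=gene, transcript_id=rec.id, cds_nt=seq)
    if not models:
        raise ValidationError(f"{path}: no valid CDS records")
    if n_skipped:
        logger.warning("skipped %d invalid CDS records", n_skipped)
    return models


def write_cds_fasta(transcripts: Mapping[str, TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tx_id in sorted(transcripts):
            t = transcripts[tx_id]
            fh.write(f">{t.transcript_id} gene={t.gene_id}\n{t.cds_nt}\n")


def read_position_counts(
    path: str | Path,
    samples: Sequence[SampleMeta],
    transcripts: Mapping[str, TranscriptModel] | None = None,
) -> PositionalCounts:
    """Read the long-format TSV count table.

    Duplicate (transcript, position, sample) rows are summed with a warning;
    negative counts or out-of-range positions are fatal.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "codon_position", "sample_id", "count"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: missing columns {required - set(df.columns)}")
    if (df["count"] < 0).any():
        bad = df.index[df["count"] < 0][0]
        raise ValidationError(f"{path}: negative count at row {bad}")
    if (df["codon_position"] < 0).any():
        bad = df.index[df["codon_position"] < 0][0]
        raise ValidationError(f"{path}: negative position at row {bad}")

    sindex = {s.sample_id: j for j, s in enumerate(samples)}
    unknown = set(df["sample_id"]) - set(sindex)
    if unknown:
        raise ValidationError(f"{path}: unknown sample ids {sorted(unknown)}")

    dup = df.duplicated(subset=["transcript_id", "codon_position", "sample_id"]).sum()
    if dup:
        logger.warning("%s: %d duplicate rows summed", path, dup)

    counts: dict[str, np.ndarray] = {}
    for tx, grp in df.groupby("transcript_id", sort=True):
        pos = grp["codon_position"].to_numpy()
        if transcripts is not None:
            if tx not in transcripts:
                raise ValidationError(f"{path}: transcript {tx} not in CDS set")
            n = transcripts[tx].n_codons
            if pos.max() >= n:
                bad = grp.index[pos >= n][0]
                raise ValidationError(
                    f"{path}: row {bad}: position >= n_codons ({n}) for {tx}"
                )
        else:
            n = int(pos.max()) + 1
        arr = np.zeros((n, len(samples)))
        cols = grp["sample_id"].map(sindex).to_numpy()
        np.add.at(arr, (pos, cols), grp["count"].to_numpy(dtype=float))
        counts[str(tx)] = arr

    # fill declared library sizes where missing
    pc = PositionalCounts(samples=list(samples), counts=counts)
    totals = pc.totals()
    filled = [
        dataclasses.replace(s, library_size=float(totals[j]))
        if s.library_size is None
        else s
        for j, s in enumerate(samples)
    ]
    pc.samples = filled
    return pc


def write_stall_sites_bed(sites: Iterable[StallSite], path: str | Path) -> None:
    """Write called sites as BED6 in transcript nt coordinates.

    score = min(1000, round(-10*log10 p)); p of zero caps at 1000.
    """
    with open(path, "w") as fh:
        for s in sites:
            start = 3 * s.codon_position
            if s.p <= 0:
                score = 1000
            else:
                score = min(1000, int(round(-10.0 * np.log10(s.p))))
            fh.write(f"{s.transcript_id}\t{start}\t{start + 3}\t{s.condition}\t{score}\t+\n")


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """TSV with columns sample_id, condition, replicate[, library_size]."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        lib = float(r["library_size"]) if "library_size" in df.columns and pd.notna(r.get("library_size")) else None
        out.append(SampleMeta(str(r["sample_id"]), str(r["condition"]), int(r["replicate"]), lib))
    return out
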