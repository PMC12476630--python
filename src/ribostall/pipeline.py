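"""End-to-end driver: simulate -> filter -> dwell times -> positional
metrics -> stall calling -> context -> enrichment, writing deterministic
TSV outputs from a single seeded configuration."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import codons, dwell, metrics, simulate, stalls
from .core import (
    VAL_CODONS,
    AnalysisConfig,
    write_cds_fasta,
    write_stall_sites_bed,
)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_end_to_end(
    sim_cfg: simulate.SimulationConfig,
    cfg: AnalysisConfig,
    outdir: str | Path,
    stall_condition: str | None = None,
    context_codons=VAL_CODONS,
) -> dict[str, Path]:
    """Run the full synthetic analysis; returns the map of written files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    transcripts, _ = simulate.make_transcriptome(sim_cfg)
    fasta = outdir / "transcriptome.fa"
    write_cds_fasta(transcripts, fasta)
    written["fasta"] = fasta

    counts, truth = simulate.simulate_footprints(transcripts, sim_cfg)
    counts_path = outdir / "counts.tsv"
    counts.write_tsv(counts_path)
    written["counts"] = counts_path
    if truth.stalls is not None and len(truth.stalls):
        _write(truth.stalls, outdir / "truth_stalls.tsv")
        written["truth_stalls"] = outdir / "truth_stalls.tsv"

    metrics.normalize_counts(counts)
    retained = metrics.filter_transcripts(
        counts, cfg.min_mean_total, cfg.min_coverage_fraction
    )
    pd.DataFrame({"transcript_id": retained}).to_csv(
        outdir / "retained.tsv", sep="\t", index=False
    )
    written["retained"] = outdir / "retained.tsv"

    dt = dwell.estimate_dwell_times(
        counts, transcripts, min_reads_per_gene=cfg.min_reads_per_gene
    )
    _write(dt.values, outdir / "dwell_times.tsv")
    written["dwell_times"] = outdir / "dwell_times.tsv"
    window = dwell.summarize_window_dt(dt)
    _write(window, outdir / "dwell_window.tsv")
    written["dwell_window"] = outdir / "dwell_window.tsv"

    meta_df = metrics.metagene_profile(
        counts, transcripts, retained, cfg.edge_exclusion_nt, cfg.metagene_bins
    )
    _write(meta_df, outdir / "metagene.tsv")
    written["metagene"] = outdir / "metagene.tsv"

    control = sim_cfg.control
    pol = metrics.polarity_score(counts, retained)
    _write(pol, outdir / "polarity.tsv")
    written["polarity"] = outdir / "polarity.tsv"
    dpol = metrics.delta_polarity_test(
        pol, control, cfg.delta_polarity_cut, cfg.delta_polarity_alpha
    )
    _write(dpol, outdir / "delta_polarity.tsv")
    written["delta_polarity"] = outdir / "delta_polarity.tsv"

    ramp_tx, ramp_summary = metrics.ramp_index(
        counts, transcripts, retained, control, cfg.region_fraction
    )
    _write(ramp_summary, outdir / "ramp_summary.tsv")
    written["ramp_summary"] = outdir / "ramp_summary.tsv"

    table = codons.build_codon_table(transcripts)
    table.fractions.to_csv(outdir / "codon_fractions.tsv", sep="\t", float_format="%.10g")
    written["codon_fractions"] = outdir / "codon_fractions.tsv"

    cond = stall_condition or next(
        (c for c in sim_cfg.conditions if c != control), None
    )
    if cond is not None:
        sites = stalls.call_stall_sites(
            counts, transcripts, retained, cond, control, cfg
        )
        _write(sites, outdir / "stall_sites.tsv")
        written["stall_sites"] = outdir / "stall_sites.tsv"
        write_stall_sites_bed(stalls.sites_to_records(sites), outdir / "stall_sites.bed")
        written["stall_sites_bed"] = outdir / "stall_sites.bed"

        ctx, prop = stalls.stall_codon_context(
            sites, transcripts, list(context_codons), cfg.context_halfwidth_nt
        )
        ctx_out = ctx.reset_index()
        ctx_out["containing_proportion"] = prop
        _write(ctx_out, outdir / "stall_context.tsv")
        written["stall_context"] = outdir / "stall_context.tsv"

        site_meta = stalls.stall_site_metagene(
            sites, transcripts, cfg.stall_metagene_bins
        )
        _write(site_meta, outdir / "stall_metagene.tsv")
        written["stall_metagene"] = outdir / "stall_metagene.tsv"

        # proteome-style enrichment against a deterministic pseudo set:
        # transcripts ranked by stall burden
        per_tx = sites.groupby("transcript_id").size().sort_values(ascending=False)
        down = list(per_tx.index[: max(1, len(per_tx) // 2)])
        enr = stalls.stall_proteome_enrichment(sites, down, retained)
        _write(enr, outdir / "stall_enrichment.tsv")
        written["stall_enrichment"] = outdir / "stall_enrichment.tsv"

    return written
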