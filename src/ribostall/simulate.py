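"""Synthetic transcriptomes, footprint counts, proteome fold changes and
qPCR Ct tables with planted ground truth.

The footprint generator uses the same multiplicative 7-site window model as
the dwell-time estimator, so noiseless recovery is an exact identity test:

    mu(g, i, s) = alpha_g * prod_{o=-3..+3} delta_o(codon at i+o)
                  * spike(g, i, cond) * beta^(#planted stalls upstream of i)

Out-of-range offsets and stop codons contribute factor 1.  Planted stall
spikes multiply the expected count at the stall position itself (condition
samples only) and attenuate all strictly-downstream flux by ``beta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    SENSE_CODONS,
    STOP_CODONS,
    PositionalCounts,
    SampleMeta,
    TranscriptModel,
    ValidationError,
    logger,
)
from .kinetics import KineticScenario, predict_log2fc

OFFSETS = tuple(range(-3, 4))


@dataclass
class SimulationConfig:
    n_genes: int = 200
    length_range: tuple[int, int] = (120, 320)  # sense codons incl. start
    codon_weights: dict[str, float] | None = None  # global draw weights, sense codons
    positional_enrichment: dict[str, float] = field(default_factory=dict)
    region_fraction: float = 0.20
    expression_log_mean: float = 1.0  # lognormal parameters of alpha_g
    expression_log_sd: float = 0.75
    dwell_truth: dict[tuple[int, str], float] = field(default_factory=dict)
    condition_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    a_site_offset: int = 1  # condition effects act on this window offset
    conditions: tuple[str, ...] = ("Ctrl",)
    control: str = "Ctrl"
    n_replicates: int = 3
    attenuation_beta: float = 1.0
    stall_fraction: float = 0.0  # fraction of eligible positions spiked
    stall_fold: float = 8.0
    stall_conditions: tuple[str, ...] = ()
    stall_region: tuple[float, float] = (0.0, 1.0)  # relative CDS interval
    noise: str = "poisson"  # "poisson" | "nb" | "none"
    nb_dispersion: float = 0.1
    library_size: float = 2e6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.attenuation_beta <= 1.0):
            raise ValidationError("attenuation beta must be in (0, 1]")
        if self.noise not in ("poisson", "nb", "none"):
            raise ValidationError(f"unknown noise law {self.noise!r}")
        for (o, c), v in self.dwell_truth.items():
            if o not in OFFSETS or c not in SENSE_CODONS or v <= 0:
                raise ValidationError(f"bad dwell_truth entry ({o}, {c}) -> {v}")


@dataclass
class GroundTruth:
    """Planted parameters, stored on the scale the estimator reports."""

    dwell_log2: pd.DataFrame | None = None  # condition, offset, codon, log2_dt (zero-mean per offset)
    stalls: pd.DataFrame | None = None  # transcript_id, codon_position, condition, fold
    alpha: dict[str, float] = field(default_factory=dict)
    proteome: pd.DataFrame | None = None
    charging: pd.DataFrame | None = None


def _codon_probs(cfg: SimulationConfig) -> np.ndarray:
    w = np.ones(len(SENSE_CODONS))
    if cfg.codon_weights:
        for i, c in enumerate(SENSE_CODONS):
            w[i] = cfg.codon_weights.get(c, 1.0)
    if (w < 0).any() or w.sum() <= 0:
        raise ValidationError("codon weights must be non-negative and normalizable")
    return w / w.sum()


def make_transcriptome(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, TranscriptModel], GroundTruth]:
    """Draw CDS sequences with optional positional codon enrichment.

    Codons are drawn per position from global weights; within the first
    ``region_fraction`` of the CDS, designated codons have their weight
    multiplied by the enrichment factor (then renormalized).  Every CDS
    starts with ATG and ends with a stop codon.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    base = _codon_probs(cfg)
    enriched = base.copy()
    for c, f in cfg.positional_enrichment.items():
        if c not in SENSE_CODONS:
            raise ValidationError(f"cannot enrich stop/unknown codon {c}")
        if f < 0:
            raise ValidationError("enrichment factors must be >= 0")
        enriched[SENSE_CODONS.index(c)] *= f
    if enriched.sum() <= 0:
        raise ValidationError("positional enrichment makes distribution non-normalizable")
    enriched = enriched / enriched.sum()

    lo, hi = cfg.length_range
    transcripts: dict[str, TranscriptModel] = {}
    width = max(4, len(str(cfg.n_genes)))
    for g in range(cfg.n_genes):
        n_sense = int(rng.integers(lo, hi + 1))
        n_early = int(np.floor(cfg.region_fraction * n_sense))
        ids_early = rng.choice(len(SENSE_CODONS), size=max(0, n_early - 1), p=enriched)
        ids_late = rng.choice(len(SENSE_CODONS), size=n_sense - max(1, n_early), p=base)
        codons = ["ATG"] + [SENSE_CODONS[i] for i in ids_early] + [SENSE_CODONS[i] for i in ids_late]
        codons.append("TAA")
        name = f"g{g:0{width}d}"
        transcripts[f"tx{g:0{width}d}"] = TranscriptModel(
            gene_id=name, transcript_id=f"tx{g:0{width}d}", cds_nt="".join(codons)
        )
    return transcripts, GroundTruth()


def _delta_matrix(cfg: SimulationConfig, condition: str) -> np.ndarray:
    """(7, 61) multiplicative dwell factors for one condition."""
    d = np.ones((len(OFFSETS), len(SENSE_CODONS)))
    for (o, c), v in cfg.dwell_truth.items():
        d[o + 3, SENSE_CODONS.index(c)] = v
    eff = cfg.condition_effects.get(condition, {})
    for c, fold in eff.items():
        if fold <= 0:
            raise ValidationError("condition effect folds must be > 0")
        d[cfg.a_site_offset + 3, SENSE_CODONS.index(c)] *= fold
    return d


def _zero_mean_log2(delta: np.ndarray) -> np.ndarray:
    log2d = np.log2(delta)
    return log2d - log2d.mean(axis=1, keepdims=True)


def _window_mu(codon_ids: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Per-position window product of dwell factors; stops/out-of-range = 1."""
    n = codon_ids.size
    mu = np.ones(n)
    for k, o in enumerate(OFFSETS):
        lo = max(0, -o)
        hi = min(n, n - o)
        ids = codon_ids[lo + o : hi + o]
        fac = np.where(ids >= 0, delta[k, np.clip(ids, 0, None)], 1.0)
        mu[lo:hi] *= fac
    return mu


def simulate_footprints(
    transcripts: Mapping[str, TranscriptModel], cfg: SimulationConfig
) -> tuple[PositionalCounts, GroundTruth]:
    """Generate a PositionalCounts table from the window dwell model."""
    rng = np.random.default_rng(cfg.seed + 1)
    tx_ids = sorted(transcripts)
    usable = []
    for tx in tx_ids:
        if transcripts[tx].n_codons < 7:
            logger.warning("skipping %s: shorter than 7 codons", tx)
            continue
        usable.append(tx)
    if not usable:
        raise ValidationError("no transcripts of usable length")

    alpha = {
        transcripts[tx].gene_id: float(v)
        for tx, v in zip(
            usable,
            rng.lognormal(cfg.expression_log_mean, cfg.expression_log_sd, len(usable)),
        )
    }

    samples = [
        SampleMeta(f"{cond}_r{r + 1}", cond, r + 1)
        for cond in cfg.conditions
        for r in range(cfg.n_replicates)
    ]

    # plant stall spikes per condition
    stall_rows = []
    stall_pos: dict[str, dict[str, np.ndarray]] = {cond: {} for cond in cfg.stall_conditions}
    if cfg.stall_fraction > 0:
        for cond in cfg.stall_conditions:
            for tx in usable:
                n = transcripts[tx].n_codons
                lo = max(3, int(np.floor(cfg.stall_region[0] * n)))
                hi = min(n - 4, int(np.ceil(cfg.stall_region[1] * n)))
                eligible = np.arange(lo, hi)
                if eligible.size == 0:
                    continue
                k = rng.binomial(eligible.size, cfg.stall_fraction)
                if k == 0:
                    continue
                pos = np.sort(rng.choice(eligible, size=k, replace=False))
                stall_pos[cond][tx] = pos
                for p in pos:
                    stall_rows.append((tx, int(p), cond, cfg.stall_fold))

    # expected counts, per condition (shared by its replicates)
    mu_cond: dict[str, dict[str, np.ndarray]] = {}
    truth_rows = []
    for cond in cfg.conditions:
        delta = _delta_matrix(cfg, cond)
        log2z = _zero_mean_log2(delta)
        for k, o in enumerate(OFFSETS):
            for i, c in enumerate(SENSE_CODONS):
                truth_rows.append((cond, o, c, log2z[k, i]))
        mu_cond[cond] = {}
        for tx in usable:
            m = transcripts[tx]
            mu = alpha[m.gene_id] * _window_mu(m.codon_ids(), delta)
            pos = stall_pos.get(cond, {}).get(tx)
            if pos is not None and pos.size:
                mu[pos] *= cfg.stall_fold
                if cfg.attenuation_beta < 1.0:
                    n_up = np.searchsorted(pos, np.arange(m.n_codons), side="left")
                    mu *= cfg.attenuation_beta ** n_up
            mu_cond[cond][tx] = mu

    counts: dict[str, np.ndarray] = {tx: np.zeros((transcripts[tx].n_codons, len(samples))) for tx in usable}
    for j, s in enumerate(samples):
        mus = mu_cond[s.condition]
        total = sum(m.sum() for m in mus.values())
        scale = cfg.library_size / total
        for tx in usable:
            mu = mus[tx] * scale
            if cfg.noise == "none":
                counts[tx][:, j] = mu
            elif cfg.noise == "poisson":
                counts[tx][:, j] = rng.poisson(mu)
            else:  # negative binomial with Var = mu + disp*mu^2
                disp = cfg.nb_dispersion
                shape = 1.0 / disp
                lam = rng.gamma(shape, mu * disp)
                counts[tx][:, j] = rng.poisson(lam)

    gt = GroundTruth(
        dwell_log2=pd.DataFrame(truth_rows, columns=["condition", "offset", "codon", "log2_dt"]),
        stalls=pd.DataFrame(stall_rows, columns=["transcript_id", "codon_position", "condition", "fold"]),
        alpha=alpha,
    )
    return PositionalCounts(samples=samples, counts=counts), gt


def random_dwell_truth(
    rng: np.random.Generator,
    log2_sd: float = 0.3,
    offsets: Sequence[int] = (1,),
) -> dict[tuple[int, str], float]:
    """Random multiplicative dwell factors, lognormal on the log2 scale."""
    truth = {}
    for o in offsets:
        vals = rng.normal(0.0, log2_sd, len(SENSE_CODONS))
        for c, v in zip(SENSE_CODONS, vals):
            truth[(o, c)] = float(2.0 ** v)
    return truth


def simulate_proteome(
    scenarios: Sequence[KineticScenario],
    noise_sd: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Protein log2FC tables consistent with first-order turnover.

    Each protein's replicate log2 ratios are Gaussian around the kinetic
    prediction; observed log2fc is the replicate mean and p comes from a
    one-sample t-test (BH-adjusted across proteins).
    """
    from scipy import stats
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(seed)
    rows = []
    width = max(4, len(str(len(scenarios))))
    for i, sc in enumerate(scenarios):
        truth = predict_log2fc(sc)
        reps = truth + rng.normal(0.0, noise_sd, n_replicates)
        obs = float(reps.mean())
        if noise_sd > 0 and n_replicates > 1:
            p = float(stats.ttest_1samp(reps, 0.0).pvalue)
        else:
            p = 0.0 if obs != 0 else 1.0
        rows.append(
            (f"prot{i:0{width}d}", obs, p, sc.t_half, sc.s, truth)
            + tuple(reps)
        )
    cols = ["protein_id", "log2fc", "p", "half_life", "s", "true_log2fc"] + [
        f"rep{r + 1}" for r in range(n_replicates)
    ]
    df = pd.DataFrame(rows, columns=cols)
    if len(df) and noise_sd > 0:
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["p_adj"] = df["p"]
    truth_df = df[["protein_id", "half_life", "s", "true_log2fc"]].copy()
    return df, GroundTruth(proteome=truth_df)


def simulate_charging_cts(
    isoacceptors: Sequence[str],
    charged_fraction: Mapping[str, Mapping[str, float]],
    control: str = "Ctrl",
    ct_ref: float = 20.0,
    spike_ct: float = 15.0,
    noise_sd: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Ct tables for the spike-normalized charging assay.

    Ct(target) = ct_ref - log2(charged fraction) + noise: halving the
    charged pool costs one extra amplification cycle.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth_rows = []
    for cond, fracs in charged_fraction.items():
        for r in range(n_replicates):
            sample = f"{cond}_r{r + 1}"
            for iso in isoacceptors:
                frac = fracs[iso]
                if frac <= 0:
                    raise ValidationError(f"charged fraction must be > 0 ({cond}, {iso})")
                ct_t = ct_ref - np.log2(frac) + rng.normal(0.0, noise_sd)
                ct_s = spike_ct + rng.normal(0.0, noise_sd)
                rows.append((sample, cond, iso, float(ct_t), float(ct_s)))
        for iso in isoacceptors:
            truth_rows.append((cond, iso, fracs[iso]))
    df = pd.DataFrame(rows, columns=["sample_id", "condition", "isoacceptor", "ct_target", "ct_spike"])
    gt = GroundTruth(charging=pd.DataFrame(truth_rows, columns=["condition", "isoacceptor", "charged_fraction"]))
    return df, gt
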