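import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribostall.core import SampleMeta, TranscriptModel, ValidationError
from ribostall.metrics import (
    codon_window_enrichment,
    delta_polarity_test,
    filter_transcripts,
    metagene_profile,
    normalize_counts,
    polarity_score,
    polarity_weights,
    ramp_index,
    region_codon_frequency_shift,
)
from ribostall.simulate import SimulationConfig, make_transcriptome, simulate_footprints
from tests.conftest import make_counts


def _tx(n_sense, tx_id="t1", gene="g1", body="GCA"):
    return TranscriptModel(gene, tx_id, "ATG" + body * (n_sense - 1) + "TAA")


class TestNormalize:
    def test_norm_rpm_fractions(self):
        samples = [SampleMeta("s1", "Ctrl", 1, library_size=1e6)]
        pc = make_counts({"t": np.array([[2.0], [3.0], [5.0]])}, samples)
        normalize_counts(pc)
        np.testing.assert_allclose(pc.norm_rpm["t"][:, 0], [0.2, 0.3, 0.5])

    def test_scale_invariance_of_norm(self):
        samples = [SampleMeta("s1", "Ctrl", 1)]
        pc1 = make_counts({"t": np.array([[2.0], [3.0], [5.0]])}, samples)
        pc2 = make_counts({"t": np.array([[4.0], [6.0], [10.0]])}, samples)
        normalize_counts(pc1)
        normalize_counts(pc2)
        np.testing.assert_allclose(pc1.norm_rpm["t"], pc2.norm_rpm["t"])

    def test_zero_transcript_nan_only_that_sample(self):
        samples = [SampleMeta("s1", "Ctrl", 1), SampleMeta("s2", "Val", 1)]
        pc = make_counts({"a": np.array([[0.0, 1.0], [0.0, 3.0]]),
                          "b": np.array([[2.0, 2.0], [2.0, 2.0]])}, samples)
        normalize_counts(pc)
        assert np.isnan(pc.norm_rpm["a"][:, 0]).all()
        assert np.isfinite(pc.norm_rpm["a"][:, 1]).all()

    def test_zero_library_fatal(self):
        samples = [SampleMeta("s1", "Ctrl", 1)]
        pc = make_counts({"t": np.zeros((3, 1))}, samples)
        with pytest.raises(ValidationError):
            normalize_counts(pc)


class TestFilter:
    def _pc(self, total, coverage, n=100):
        samples = [SampleMeta("s1", "Ctrl", 1)]
        arr = np.zeros((n, 1))
        k = int(round(coverage * n))
        arr[:k, 0] = total / k
        return make_counts({"t": arr, "keepme": np.full((n, 1), 10.0)}, samples)

    def test_mean_total_just_below_50_excluded(self):
        pc = self._pc(49.9, 0.5)
        assert "t" not in filter_transcripts(pc)

    def test_coverage_threshold(self):
        assert "t" not in filter_transcripts(self._pc(100, 0.25))
        assert "t" in filter_transcripts(self._pc(100, 0.35))

    def test_all_zero_excluded(self):
        samples = [SampleMeta("s1", "Ctrl", 1)]
        pc = make_counts({"t": np.zeros((50, 1)), "keepme": np.full((50, 1), 10.0)}, samples)
        assert filter_transcripts(pc) == ["keepme"]

    def test_empty_retained_fatal(self):
        samples = [SampleMeta("s1", "Ctrl", 1)]
        pc = make_counts({"t": np.zeros((50, 1))}, samples)
        with pytest.raises(ValidationError):
            filter_transcripts(pc)


class TestMetagene:
    def test_uniform_density_flat_profile(self):
        samples = [SampleMeta("s1", "Ctrl", 1)]
        tx = {"t1": _tx(97)}
        pc = make_counts({"t1": np.full((98, 1), 4.0)}, samples)
        prof = metagene_profile(pc, tx, ["t1"])
        vals = prof["mean_norm_rpm"].to_numpy()
        assert np.abs(vals - vals[0]).max() < 1e-12

    def test_attenuation_monotone_nonincreasing(self):
        cfg = SimulationConfig(
            n_genes=20,
            length_range=(150, 250),
            conditions=("Ctrl", "Val"),
            n_replicates=1,
            noise="none",
            attenuation_beta=0.8,
            stall_fraction=0.02,
            stall_fold=1.0,
            stall_conditions=("Val",),
            stall_region=(0.0, 0.5),
            seed=1,
        )
        tx, _ = make_transcriptome(cfg)
        counts, _ = simulate_footprints(tx, cfg)
        prof = metagene_profile(counts, tx, sorted(counts.counts))
        val = prof[prof.condition == "Val"].sort_values("bin")["mean_norm_rpm"].to_numpy()
        assert (np.diff(val) <= 1e-12).all()

    def test_short_transcript_skipped(self, caplog):
        samples = [SampleMeta("s1", "Ctrl", 1)]
        tx = {"t1": _tx(5)}  # 6 codons < 2*5+1
        pc = make_counts({"t1": np.full((6, 1), 1.0)}, samples)
        prof = metagene_profile(pc, tx, ["t1"])
        assert prof.empty
        assert "too short" in caplog.text


class TestRampIndex:
    def test_identical_condition_and_control_zero(self):
        samples = [SampleMeta("c1", "Ctrl", 1), SampleMeta("c2", "Ctrl", 2),
                   SampleMeta("v1", "Val", 1), SampleMeta("v2", "Val", 2)]
        arr = np.tile(np.linspace(1, 3, 50)[:, None], (1, 4))
        pc = make_counts({"t": arr}, samples)
        tx = {"t": _tx(49)}
        per_tx, _ = ramp_index(pc, tx, ["t"], control="Ctrl")
        assert np.allclose(per_tx["log2_ratio5"], 0.0, atol=1e-12)
        assert np.allclose(per_tx["log2_ratio3"], 0.0, atol=1e-12)

    def test_hand_worked_example(self):
        # control uniform over 100 positions; condition 2x on first 20
        samples = [SampleMeta("c1", "Ctrl", 1), SampleMeta("v1", "Val", 1)]
        cond = np.ones(100)
        cond[:20] = 2.0
        pc = make_counts({"t": np.column_stack([np.ones(100), cond])}, samples)
        tx = {"t": _tx(99)}
        per_tx, _ = ramp_index(pc, tx, ["t"], control="Ctrl")
        val = per_tx[per_tx.condition == "Val"].iloc[0]
        assert val["log2_ratio5"] == pytest.approx(np.log2((40 / 120) / 0.2), abs=5e-4)
        assert val["log2_ratio3"] == pytest.approx(np.log2((20 / 120) / 0.2), abs=5e-4)
        assert round(val["log2_ratio5"], 3) == 0.737
        assert round(val["log2_ratio3"], 3) == -0.263

    def test_half_regions_mirror_symmetry(self):
        samples = [SampleMeta("c1", "Ctrl", 1), SampleMeta("v1", "Val", 1)]
        prof = np.linspace(1, 2, 40)
        pc = make_counts({"t": np.column_stack([np.ones(40), prof]),
                          "u": np.column_stack([np.ones(40), prof[::-1]])}, samples)
        tx = {"t": _tx(39, "t"), "u": _tx(39, "u", "g2")}
        per_tx, _ = ramp_index(pc, tx, ["t", "u"], control="Ctrl", region_fraction=0.5)
        t = per_tx[(per_tx.transcript_id == "t") & (per_tx.condition == "Val")].iloc[0]
        u = per_tx[(per_tx.transcript_id == "u") & (per_tx.condition == "Val")].iloc[0]
        assert t["log2_ratio5"] == pytest.approx(u["log2_ratio3"])
        assert t["log2_ratio3"] == pytest.approx(u["log2_ratio5"])


class TestPolarity:
    def _pc(self, dens, n_samples=1):
        samples = [SampleMeta(f"s{i}", "Ctrl", i + 1) for i in range(n_samples)]
        arr = np.tile(np.asarray(dens, dtype=float)[:, None], (1, n_samples))
        return make_counts({"t": arr}, samples)

    def test_all_mass_first_position(self):
        pc = self._pc([1, 0, 0, 0, 0])
        pol = polarity_score(pc, ["t"])
        assert pol["polarity"].iloc[0] == pytest.approx(-1.0)

    def test_uniform_density_zero(self):
        pc = self._pc(np.ones(37))
        pol = polarity_score(pc, ["t"])
        assert abs(pol["polarity"].iloc[0]) < 1e-12

    def test_worked_l4_example(self):
        pc = self._pc([0.75, 0, 0, 0.25])
        pol = polarity_score(pc, ["t"])
        assert pol["polarity"].iloc[0] == pytest.approx(-0.5)

    def test_weights_endpoints(self):
        w = polarity_weights(10)
        assert w[0] == -1.0 and w[-1] == 1.0
        assert abs(w.sum()) < 1e-12

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 100.0), min_size=2, max_size=60).filter(lambda v: sum(v) > 0))
    def test_bounds_and_antisymmetry(self, dens):
        d = np.asarray(dens)
        w = polarity_weights(d.size)
        pi = float(w @ (d / d.sum()))
        pi_rev = float(w @ (d[::-1] / d.sum()))
        assert -1.0 <= pi <= 1.0
        assert pi == pytest.approx(-pi_rev, abs=1e-9)


class TestDeltaPolarity:
    def _records(self, ctrl_pis, cond_pis):
        rows = []
        for i, v in enumerate(ctrl_pis):
            rows.append(("t", f"c{i}", "Ctrl", i + 1, v))
        for i, v in enumerate(cond_pis):
            rows.append(("t", f"v{i}", "Val", i + 1, v))
        return pd.DataFrame(rows, columns=["transcript_id", "sample_id", "condition", "replicate", "polarity"])

    def test_identical_nothing_selected(self):
        res = delta_polarity_test(self._records([0.1, 0.1, 0.1], [0.1, 0.1, 0.1]), "Ctrl")
        assert not res["significant"].any()

    def test_planted_shift_selected(self):
        rng = np.random.default_rng(2)
        ctrl = 0.0 + rng.normal(0, 0.02, 3)
        cond = -0.3 + rng.normal(0, 0.02, 3)
        res = delta_polarity_test(self._records(ctrl, cond), "Ctrl")
        assert bool(res["significant"].iloc[0])

    def test_above_cut_not_selected_regardless_of_p(self):
        rng = np.random.default_rng(3)
        ctrl = 0.0 + rng.normal(0, 0.001, 5)
        cond = -0.10 + rng.normal(0, 0.001, 5)
        res = delta_polarity_test(self._records(ctrl, cond), "Ctrl")
        assert res["p"].iloc[0] < 0.05
        assert not bool(res["significant"].iloc[0])

    def test_single_replicate_fatal(self):
        with pytest.raises(ValidationError):
            delta_polarity_test(self._records([0.1], [0.2]), "Ctrl")


class TestCodonWindowEnrichment:
    def test_condition_equals_control_zero_profile(self):
        samples = [SampleMeta("c1", "Ctrl", 1), SampleMeta("v1", "Val", 1)]
        tx = {"t": TranscriptModel("g", "t", "ATG" + "GCA" * 20 + "GTT" + "GCA" * 20 + "TAA")}
        arr = np.tile(np.linspace(1, 2, 43)[:, None], (1, 2))
        pc = make_counts({"t": arr}, samples)
        prof = codon_window_enrichment(pc, tx, ["t"], "GTT", "Val", "Ctrl", halfwidth_nt=30)
        assert np.allclose(prof["log2_relative"], 0.0, atol=1e-12)

    def test_planted_spike_at_codon(self):
        samples = [SampleMeta("c1", "Ctrl", 1), SampleMeta("v1", "Val", 1)]
        tx = {"t": TranscriptModel("g", "t", "ATG" + "GCA" * 20 + "GTT" + "GCA" * 20 + "TAA")}
        ctrl = np.ones(43)
        cond = np.ones(43)
        cond[21] = 4.0  # the GTT position
        pc = make_counts({"t": np.column_stack([ctrl, cond])}, samples)
        prof = codon_window_enrichment(pc, tx, ["t"], "GTT", "Val", "Ctrl", halfwidth_nt=30)
        prof = prof.set_index("offset")["log2_relative"]
        # closed-form oracle: Norm_RPM are 4/46 at the spike and 1/46 off it
        # (vs 1/43 in control); pseudocount = half the min nonzero Norm_RPM
        pcnt = 0.5 / 46
        peak = np.log2((4 / 46 + pcnt) / (1 / 43 + pcnt))
        shoulder = np.log2((1 / 46 + pcnt) / (1 / 43 + pcnt))
        assert prof[0] == pytest.approx(peak, abs=1e-9)
        assert prof[5] == pytest.approx(shoulder, abs=1e-9)
        assert prof[0] > 1.0 > 0 > prof[5]

    def test_absent_codon_empty_with_warning(self, caplog):
        samples = [SampleMeta("c1", "Ctrl", 1), SampleMeta("v1", "Val", 1)]
        tx = {"t": _tx(30)}
        pc = make_counts({"t": np.ones((31, 2))}, samples)
        prof = codon_window_enrichment(pc, tx, ["t"], "TGG", "Val", "Ctrl")
        assert prof.empty
        assert "absent" in caplog.text


class TestRegionCodonShift:
    def _transcriptome(self, n, seed, enrich=None):
        cfg = SimulationConfig(
            n_genes=n, length_range=(100, 200), seed=seed,
            positional_enrichment=enrich or {},
        )
        return make_transcriptome(cfg)[0]

    def test_doubled_gtt_fraction_log2fc_near_one(self):
        bg = self._transcriptome(150, 4)
        sel_all = self._transcriptome(150, 5, enrich={"GTT": 2.3})
        sel = {f"s_{k}": TranscriptModel(f"sg_{k}", f"s_{k}", v.cds_nt) for k, v in sel_all.items()}
        tx = {**bg, **sel}
        res = region_codon_frequency_shift(sorted(sel), sorted(bg), tx)
        gtt = res[res.codon == "GTT"].iloc[0]
        assert gtt["log2fc"] == pytest.approx(1.0, abs=0.25)
        assert gtt["p_adj"] < 0.05

    def test_null_calibration(self):
        tx = self._transcriptome(200, 6)
        ids = sorted(tx)
        rng = np.random.default_rng(7)
        sel = list(rng.choice(ids, 100, replace=False))
        res = region_codon_frequency_shift(sel, ids, tx)
        frac_sig = (res["p"].dropna() < 0.05).mean()
        assert frac_sig < 0.2

    def test_identical_single_transcript_zero_fc_missing_p(self):
        tx = self._transcriptome(1, 8)
        tid = sorted(tx)[0]
        res = region_codon_frequency_shift([tid], [tid], tx)
        present = res.dropna(subset=["log2fc"])
        assert np.allclose(present["log2fc"], 0.0)
        assert res["p"].isna().all()

    def test_empty_sets_fatal(self):
        tx = self._transcriptome(2, 9)
        with pytest.raises(ValidationError):
            region_codon_frequency_shift([], sorted(tx), tx)
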