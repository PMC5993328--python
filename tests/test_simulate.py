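import itertools

import numpy as np
import pandas as pd
import pytest

from dmsenv import simulate as sim
from dmsenv.calling import CallingConfig, call_fastq
from dmsenv.genetic_code import NNK_CODONS


class TestLibrary:
    def test_nnk_enumeration_single_codon(self):
        df = sim.enumerate_nnk("ATG")
        assert len(df) == 32  # 4 x 4 x 2
        assert set(df["mut_codon"]) == set(NNK_CODONS)
        met = df[df["mut_aa"] == "M"]
        assert met["synonymous"].all() and len(met) == 1  # only ATG encodes Met

    def test_catalogue_excludes_wildtype_codon(self, small_dataset):
        cat = small_dataset["catalogue"]
        assert (cat["mut_codon"] != cat["wt_codon"]).all()

    def test_determinism_seed_7(self):
        cfg = sim.SimulationConfig(gene_length_codons=10, seed=7)
        ref = sim.random_reference(cfg)
        a = sim.generate_library(ref, cfg)
        b = sim.generate_library(sim.random_reference(cfg), cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_full_gene_counts_match_enumeration_oracle(self):
        # brute-force oracle: every (position, NNK codon) pair
        cfg = sim.SimulationConfig(gene_length_codons=177, seed=3)
        ref = sim.random_reference(cfg)
        expected_pre_dedup = sum(
            1 for _pos in range(177) for _codon in itertools.product("ACGT", "ACGT", "GT")
        )
        assert expected_pre_dedup == 177 * 32
        assert len(sim.enumerate_nnk(ref)) == expected_pre_dedup
        n_wt_nnk = sum(
            1 for i in range(177) if ref[3 * i + 2] in "GT"
        )  # wt codons that are themselves NNK
        assert len(sim.generate_library(ref, cfg)) == expected_pre_dedup - n_wt_nnk

    def test_non_acgt_reference_rejected(self, small_config):
        with pytest.raises(ValueError, match="non-ACGT"):
            sim.generate_library("ATGNNN", small_config)

    def test_random_subset_size(self):
        cfg = sim.SimulationConfig(
            gene_length_codons=20, seed=1, library_spec="random_subset", subset_size=100
        )
        ref = sim.random_reference(cfg)
        assert len(sim.generate_library(ref, cfg)) == 100


class TestTrueFeatures:
    def test_synonymous_ddg_zero(self, small_dataset):
        truth = small_dataset["truth"]
        syn = truth[truth["synonymous"]]
        assert (syn["ddG"] == 0).all()
        assert (syn["F_true_reference"] == 0).all()

    def test_distance_identical_within_position(self, small_dataset):
        truth = small_dataset["truth"]
        assert (truth.groupby("position")["dist_active"].nunique() == 1).all()

    def test_ddg_sampling_mean(self):
        cfg = sim.SimulationConfig(gene_length_codons=70, seed=5)
        ref = sim.random_reference(cfg)
        truth = sim.assign_true_features(sim.generate_library(ref, cfg), cfg)
        ddg = truth.loc[~truth["synonymous"], "ddG"]
        mean = sim.ddg_mean(cfg)
        sd = np.sqrt(cfg.ddg_shape) * cfg.ddg_scale
        se = sd / np.sqrt(len(ddg))
        assert abs(ddg.mean() - mean) < 3 * se
        assert len(ddg) >= 2000

    def test_empty_catalogue_rejected(self, small_config):
        with pytest.raises(ValueError, match="empty"):
            sim.assign_true_features(pd.DataFrame(), small_config)


class TestTrueFitness:
    def test_half_cliff_midpoint(self):
        env = sim.EnvironmentSpec("e", folding_shift=0.5)
        model = sim.FitnessModel()
        f = sim.true_fitness(model.folding_cliff - 0.5, 1e6, env, model)
        assert f == pytest.approx(model.f_min + (0 - model.f_min) * 0.5, rel=1e-6)

    def test_limits(self):
        env = sim.EnvironmentSpec("e")
        model = sim.FitnessModel()
        assert sim.true_fitness(-100.0, 1e6, env, model) == pytest.approx(0.0, abs=1e-9)
        assert sim.true_fitness(100.0, 1e6, env, model) == pytest.approx(model.f_min, abs=1e-9)

    def test_monotone_grid_sweep(self):
        # pointwise grid oracle: F non-increasing in ddG, non-decreasing in distance
        env = sim.EnvironmentSpec("e", folding_shift=0.3)
        model = sim.FitnessModel()
        ddg_grid = np.linspace(-1, 6, 40)
        dist_grid = np.linspace(3, 40, 40)
        for dist in (5.0, 15.0, 30.0):
            f = np.asarray(sim.true_fitness(ddg_grid, dist, env, model))
            assert (np.diff(f) <= 1e-12).all()
        for ddg in (-0.5, 1.5, 3.0):
            f = np.asarray(sim.true_fitness(ddg, dist_grid, env, model))
            assert (np.diff(f) >= -1e-12).all()

    def test_wildtype_near_zero(self):
        f = sim.true_fitness(0.0, 1e6, sim.EnvironmentSpec("e"), sim.FitnessModel())
        assert abs(f) < 0.2


def _truth_frame(f_values, survives=None):
    n = len(f_values)
    survives = survives if survives is not None else [np.isfinite(f) for f in f_values]
    return pd.DataFrame(
        {
            "position": np.arange(1, n + 1),
            "wt_codon": ["AAA"] * n,
            "mut_codon": ["CCC"] * n,
            "mut_aa": ["P"] * n,
            "synonymous": [False] * n,
            "F_true_env": f_values,
            "survives_env": survives,
        }
    )


class TestSimulateCounts:
    def _config(self, **kw):
        defaults = dict(
            gene_length_codons=10,
            seed=2,
            depth_per_sample=100_000,
            environments=(sim.EnvironmentSpec("env"),),
        )
        defaults.update(kw)
        return sim.SimulationConfig(**defaults)

    def test_null_selection_mean_enrichment(self):
        # all F_true = 0: mean per-mutant enrichment over 50 replicates ~ 0
        cfg = self._config(n_replicates=50, depth_per_sample=100_000)
        truth = _truth_frame([0.0] * 50)
        counts = sim.simulate_counts(truth, cfg)
        enrich = []
        for rep in range(1, 51):
            sel = counts[("env", "selected", rep)].counts["count"].to_numpy()
            unsel = counts[("env", "unselected", rep)].counts["count"].to_numpy()
            enrich.append(np.log2(sel / unsel))
        assert abs(np.mean(enrich)) < 0.1

    def test_eliminated_mutant_zero_selected_counts(self):
        cfg = self._config(n_replicates=5)
        truth = _truth_frame([0.0, 0.0, sim.ELIMINATED], survives=[True, True, False])
        counts = sim.simulate_counts(truth, cfg)
        for rep in range(1, 6):
            sel = counts[("env", "selected", rep)].counts
            assert sel.loc[sel["position"] == 3, "count"].item() == 0

    def test_enrichment_ratio_of_two_mutants(self):
        # F difference of 2 -> selected/unselected count-ratio ratio ~ 4
        cfg = self._config(n_replicates=10)
        truth = _truth_frame([0.0, 2.0] + [0.0] * 18)
        counts = sim.simulate_counts(truth, cfg)
        ratios = []
        for rep in range(1, 11):
            sel = counts[("env", "selected", rep)].counts["count"].to_numpy()
            unsel = counts[("env", "unselected", rep)].counts["count"].to_numpy()
            ratios.append((sel[1] / unsel[1]) / (sel[0] / unsel[0]))
        assert np.mean(ratios) == pytest.approx(4.0, rel=0.05)

    def test_all_eliminated_is_error(self):
        cfg = self._config()
        truth = _truth_frame([sim.ELIMINATED, sim.ELIMINATED], survives=[False, False])
        with pytest.raises(ValueError, match="eliminated"):
            sim.simulate_counts(truth, cfg)


class TestEmitReads:
    def test_error_free_round_trip(self, small_dataset, tmp_path):
        cfg = small_dataset["config"]
        ref = small_dataset["reference"]
        matrix = small_dataset["counts"][("reference", "unselected", 1)]
        fq = sim.emit_reads(matrix, ref, cfg, tmp_path / "s.fastq")
        called = call_fastq(fq, ref, CallingConfig(min_reads_per_variant=1, anchor_length=12))
        key = ["position", "wt", "mut"]
        merged = (
            matrix.counts[matrix.counts["count"] > 0][key + ["count"]]
            .merge(called.counts[called.counts["count"] > 0], on=key, how="outer",
                   suffixes=("_in", "_out"))
            .fillna(0)
        )
        assert (merged["count_in"] == merged["count_out"]).all()

    def test_low_quality_reads_are_filtered(self, tmp_path):
        # 10% of one mutant's reads at mean Q20 -> caller keeps ~90%
        cfg = sim.SimulationConfig(
            gene_length_codons=10, seed=9, depth_per_sample=2000, low_q_fraction=0.1,
            environments=(sim.EnvironmentSpec("env"),),
        )
        ref = sim.random_reference(cfg)
        cat = sim.generate_library(ref, cfg)
        truth = sim.ground_truth(sim.assign_true_features(cat, cfg), cfg)
        matrix = sim.simulate_counts(truth, cfg)[("env", "unselected", 1)]
        fq = sim.emit_reads(matrix, ref, cfg, tmp_path / "s.fastq")
        called = call_fastq(fq, ref, CallingConfig(min_reads_per_variant=1, anchor_length=12))
        total_in = matrix.counts["count"].sum()
        total_out = called.counts["count"].sum() + called.n_wt_reads
        assert total_out / total_in == pytest.approx(0.9, abs=0.03)
        assert called.n_rejected == total_in - total_out

    def test_empty_matrix_yields_valid_empty_fastq(self, small_dataset, tmp_path):
        cfg = small_dataset["config"]
        ref = small_dataset["reference"]
        matrix = small_dataset["counts"][("reference", "unselected", 1)]
        empty = matrix.counts.iloc[0:0]
        from dmsenv.calling import MutantCountMatrix

        m = MutantCountMatrix(level="codon", counts=empty, depth=matrix.depth, sample=matrix.sample)
        fq = sim.emit_reads(m, ref, cfg, tmp_path / "empty.fastq")
        assert fq.read_text() == ""
        from dmsenv.calling import iter_fastq

        assert list(iter_fastq(fq)) == []

    def test_fastq_bytes_deterministic(self, small_dataset, tmp_path):
        cfg = small_dataset["config"]
        ref = small_dataset["reference"]
        matrix = small_dataset["counts"][("reference", "selected", 1)]
        a = sim.emit_reads(matrix, ref, cfg, tmp_path / "a.fastq")
        b = sim.emit_reads(matrix, ref, cfg, tmp_path / "b.fastq")
        assert a.read_bytes() == b.read_bytes()


def test_write_dataset_manifest(tmp_path):
    cfg = sim.SimulationConfig(
        gene_length_codons=10, seed=4, depth_per_sample=1000,
        environments=(sim.EnvironmentSpec("reference"),), n_replicates=2,
    )
    manifest = sim.write_dataset(cfg, tmp_path / "ds")
    assert (tmp_path / "ds" / "reference.fasta").exists()
    assert len(manifest["samples"]) == 4  # 2 pools x 2 replicates
    for s in manifest["samples"]:
        assert (tmp_path / "ds" / s["counts"]).exists()
        assert (tmp_path / "ds" / s["fastq"]).exists()


def test_seed_change_same_catalogue_different_counts(tmp_path):
    base = dict(gene_length_codons=10, depth_per_sample=1000,
                environments=(sim.EnvironmentSpec("reference"),))
    cfg_a = sim.SimulationConfig(seed=1, **base)
    cfg_b = sim.SimulationConfig(seed=2, **base)
    ref = sim.random_reference(cfg_a)
    cat_a = sim.generate_library(ref, cfg_a)
    cat_b = sim.generate_library(ref, cfg_b)
    pd.testing.assert_frame_equal(cat_a, cat_b)
    t_a = sim.ground_truth(sim.assign_true_features(cat_a, cfg_a), cfg_a)
    t_b = sim.ground_truth(sim.assign_true_features(cat_b, cfg_b), cfg_b)
    c_a = sim.simulate_counts(t_a, cfg_a)[("reference", "unselected", 1)]
    c_b = sim.simulate_counts(t_b, cfg_b)[("reference", "unselected", 1)]
    assert not c_a.counts["count"].equals(c_b.counts["count"])
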