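"""The generative model of the nested-fragment experiment."""

import numpy as np
import pandas as pd
import pytest

from posrnaseq import (
    SimulationConfig,
    build_truth,
    classify_all,
    default_lignano_design,
    default_mass_weights,
    fragment_mixture,
    read_truth_tsv,
    simulate_counts,
    write_truth_tsv,
)
from posrnaseq.simulate import load_simulation_config


def balanced_noiseless_config(n=400, enrichment=64.0):
    """Equal planting in all regions with deterministic baselines, so every
    region contributes the same total abundance and mixture ratios are exact."""
    return SimulationConfig(
        n_transcripts=n,
        noiseless=True,
        seed=5,
        spec_fractions={"head": 0.05, "testis": 0.05, "ovary": 0.05, "tail": 0.05},
        base_abundance_logsd=0.0,
        leakage=0.0,
        enrichment=enrichment,
    )


class TestBuildTruth:
    def test_no_fractions_means_all_uniform(self):
        config = SimulationConfig(n_transcripts=50, spec_fractions={}, seed=0)
        truth = build_truth(config)
        assert (truth.labels == "uniform").all()

    def test_exact_product_gives_exact_count(self):
        config = SimulationConfig(
            n_transcripts=100, spec_fractions={"testis": 0.1}, seed=0
        )
        truth = build_truth(config)
        assert (truth.labels == "testis").sum() == 10
        assert (truth.labels == "uniform").sum() == 90

    def test_largest_remainder_conserves_n(self):
        config = SimulationConfig(
            n_transcripts=101,
            spec_fractions={"testis": 1 / 3, "ovary": 1 / 3, "tail": 1 / 3},
            seed=0,
        )
        truth = build_truth(config)
        assert len(truth.labels) == 101
        assert (truth.labels != "uniform").sum() == 101

    def test_same_seed_same_truth(self):
        config = SimulationConfig(n_transcripts=80, seed=42)
        t1, t2 = build_truth(config), build_truth(config)
        pd.testing.assert_series_equal(t1.labels, t2.labels)
        pd.testing.assert_frame_equal(t1.abundance, t2.abundance)

    def test_uniform_rows_constant_specific_rows_peaked(self):
        config = SimulationConfig(n_transcripts=200, seed=1, enrichment=8.0)
        truth = build_truth(config)
        uni = truth.abundance[truth.labels == "uniform"]
        assert (uni.nunique(axis=1) == 1).all()
        tes = truth.abundance[truth.labels == "testis"]
        assert (tes["testis"] > 0).all()
        assert (tes[["head", "ovary", "tail"]] == 0).all().all()


class TestFragmentMixture:
    def test_single_region_fragment(self, design):
        assert fragment_mixture(design, {}, "A") == {
            "head": 1.0, "testis": 0.0, "ovary": 0.0, "tail": 0.0,
        }

    def test_contaminated_fragment_shares(self):
        design = default_lignano_design(mass_weights=default_mass_weights())
        mix = fragment_mixture(design, {("B", "ovary"): 0.02}, "B")
        total = 0.35 + 0.25 + 0.02
        assert mix["head"] == pytest.approx(0.35 / total)
        assert mix["testis"] == pytest.approx(0.25 / total)
        assert mix["ovary"] == pytest.approx(0.02 / total)
        assert mix["tail"] == 0.0

    def test_whole_worm_equals_mass_weights(self):
        design = default_lignano_design(mass_weights=default_mass_weights())
        assert fragment_mixture(design, {}, "D") == pytest.approx(
            default_mass_weights()
        )

    def test_contaminating_a_present_region_is_an_error(self, design):
        with pytest.raises(ValueError, match="already part"):
            fragment_mixture(design, {("B", "testis"): 0.01}, "B")


class TestSimulateCounts:
    def test_noiseless_uniform_only_is_flat(self):
        config = SimulationConfig(
            n_transcripts=50, spec_fractions={}, noiseless=True, seed=0
        )
        counts, _ = simulate_counts(config)
        values = counts.values()
        fractions = values / values.sum(axis=0)
        np.testing.assert_allclose(fractions, fractions[:, [0]] @ np.ones((1, 4)),
                                   rtol=1e-12)
        table = classify_all(counts, config.design)
        assert (table["region_call"] == "non-differential").all()

    def test_multinomial_column_sums_equal_library_sizes(self):
        config = SimulationConfig(n_transcripts=500, seed=7,
                                  library_sizes={"A": 10_000, "B": 20_000,
                                                 "C": 30_000, "D": 40_000})
        counts, _ = simulate_counts(config)
        assert counts.totals.tolist() == [10_000.0, 20_000.0, 30_000.0, 40_000.0]

    def test_same_seed_reproduces_counts_exactly(self):
        config = SimulationConfig(n_transcripts=300, seed=123)
        c1, _ = simulate_counts(config)
        c2, _ = simulate_counts(config)
        assert c1 == c2

    def test_planted_codes_in_balanced_noiseless_data(self):
        config = balanced_noiseless_config()
        counts, truth = simulate_counts(config)
        table = classify_all(counts, config.design)
        for region, code in [("testis", "[+,0,0]"), ("ovary", "[0,+,0]"),
                             ("tail", "[0,0,+]")]:
            planted = truth.labels == region
            assert (table.loc[planted.values, "profile_code"] == code).all()
        # head is never an added region: its planted transcripts only dilute
        head = truth.labels == "head"
        assert (table.loc[head.values, "profile_code"] == "[0,0,0]").all()
        head_diffs = table.loc[head.values, ["B-A", "C-B", "D-C"]].to_numpy()
        assert (head_diffs <= 0).all()

    def test_contamination_migrates_ovary_codes_within_the_identifiable_range(self):
        # below the cap ε* = w_o(w_h+w_t)/(4(w_h+w_t+w_o) − w_o) ≈ 0.0316 the
        # [+,+,0] fraction can only grow with ε
        fractions = []
        for eps in [0.0, 0.005, 0.01, 0.02]:
            config = SimulationConfig(
                n_transcripts=2000, seed=11,
                contamination={("B", "ovary"): eps},
                library_sizes=1_000_000,
            )
            counts, truth = simulate_counts(config)
            table = classify_all(counts, config.design)
            ovary = truth.labels == "ovary"
            fractions.append(
                float((table.loc[ovary.values, "profile_code"] == "[+,+,0]").mean())
            )
        assert fractions == sorted(fractions)
        assert fractions[0] == 0.0 and fractions[-1] > 0.5

    def test_overdispersion_runs_and_keeps_library_size(self):
        config = SimulationConfig(n_transcripts=200, seed=3, overdispersion=5.0,
                                  library_sizes=100_000)
        counts, _ = simulate_counts(config)
        assert counts.totals.tolist() == [100_000.0] * 4


class TestConfigAndIo:
    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="at most 1"):
            SimulationConfig(spec_fractions={"testis": 0.7, "ovary": 0.5})

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="unknown region"):
            SimulationConfig(spec_fractions={"gills": 0.1})

    def test_truth_round_trip(self, tmp_path):
        config = SimulationConfig(n_transcripts=40, seed=9)
        _, truth = simulate_counts(config)
        path = tmp_path / "truth.tsv"
        write_truth_tsv(truth, path)
        back = read_truth_tsv(path)
        pd.testing.assert_series_equal(back.labels, truth.labels)
        pd.testing.assert_frame_equal(back.abundance, truth.abundance)

    def test_yaml_config_strict_keys(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text("n_transcripts: 10\nbogus_knob: 3\n")
        with pytest.raises(ValueError, match="bogus_knob"):
            load_simulation_config(path)

    def test_yaml_config_round_trip(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text(
            "n_transcripts: 25\nseed: 4\nnoiseless: true\n"
            "spec_fractions: {testis: 0.2}\ncontamination: {'B:ovary': 0.01}\n"
        )
        config = load_simulation_config(path)
        assert config.n_transcripts == 25
        assert config.contamination == {("B", "ovary"): 0.01}
        counts, truth = simulate_counts(config)
        assert counts.shape == (25, 4)
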