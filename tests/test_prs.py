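"""PRS engine: harmonization, clumping, scoring, threshold sweep."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_panel, make_sumstats
from pfactor.prs import (
    EmptyScoreError,
    HarmonizationError,
    PrsConfig,
    compute_prs,
    harmonize_alleles,
    ld_clump,
    score_trait,
    threshold_sweep,
)
from pfactor.simulate import SimulationConfig, simulate_genotypes, true_polygenic_values


class TestHarmonize:
    def test_orientation_match_and_flip(self):
        panel = make_panel(np.ones((4, 2)), refs=["A", "C"], alts=["G", "T"])
        ss = make_sumstats(panel, beta=[0.2, 0.2], p=[0.01, 0.01],
                           a1=["G", "C"], a2=["A", "T"])  # first matches, second flipped
        eff = harmonize_alleles(ss, panel)
        assert eff["BETA"].tolist() == [0.2, -0.2]
        assert eff.attrs["harmonization_counts"]["flipped"] == 1

    def test_ambiguous_dropped_and_counted(self):
        panel = make_panel(np.ones((4, 2)), refs=["A", "C"], alts=["T", "A"])
        ss = make_sumstats(panel, beta=[0.1, 0.1], p=[0.5, 0.5])
        eff = harmonize_alleles(ss, panel)
        assert eff["SNP"].tolist() == ["s1"]
        assert eff.attrs["harmonization_counts"]["ambiguous"] == 1
        both = harmonize_alleles(ss, panel, drop_ambiguous=False)
        assert len(both) == 2

    def test_mismatch_dropped_and_zero_survivors_fails(self):
        panel = make_panel(np.ones((4, 1)), refs=["A"], alts=["G"])
        ss = make_sumstats(panel, beta=[0.1], p=[0.5], a1=["C"], a2=["A"])
        with pytest.raises(HarmonizationError, match="mismatch"):
            harmonize_alleles(ss, panel)


class TestClump:
    def test_toy_example_retains_index_and_independent(self, toy_ld_panel):
        eff = pd.DataFrame(
            {
                "SNP": ["s0", "s1", "s2"],
                "CHR": [1, 1, 1],
                "BP": [100_000, 110_000, 120_000],
                "BETA": [0.3, 0.2, 0.1],
                "SE": [0.01] * 3,
                "P": [1e-8, 1e-4, 1e-3],
                "col": [0, 1, 2],
            }
        )
        assert ld_clump(eff, toy_ld_panel, PrsConfig()) == ["s0", "s2"]

    def test_no_ld_keeps_all(self):
        rng = np.random.default_rng(0)
        panel = make_panel(rng.integers(0, 3, size=(500, 4)).astype(float))
        eff = harmonize_alleles(
            make_sumstats(panel, beta=[0.1] * 4, p=[0.1, 0.2, 0.3, 0.4]), panel
        )
        assert len(ld_clump(eff, panel, PrsConfig())) == 4

    def test_perfect_ld_equal_p_keeps_smaller_position(self):
        col = np.array([0.0, 1, 2, 1, 0, 2, 1, 1])
        panel = make_panel(np.column_stack([col, col]), bps=[5_000, 6_000])
        eff = harmonize_alleles(
            make_sumstats(panel, beta=[0.1, 0.1], p=[0.5, 0.5]), panel
        )
        assert ld_clump(eff, panel, PrsConfig()) == ["s0"]

    def test_row_order_invariance(self, toy_ld_panel):
        eff = harmonize_alleles(
            make_sumstats(toy_ld_panel, beta=[0.3, 0.2, 0.1], p=[1e-8, 1e-4, 1e-3]),
            toy_ld_panel,
        )
        shuffled = eff.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert ld_clump(eff, toy_ld_panel, PrsConfig()) == ld_clump(
            shuffled, toy_ld_panel, PrsConfig()
        )

    def test_empty_input(self, toy_ld_panel):
        empty = pd.DataFrame(columns=["SNP", "CHR", "BP", "BETA", "SE", "P", "col"])
        assert ld_clump(empty, toy_ld_panel, PrsConfig()) == []


class TestScore:
    def test_threshold_is_strict(self):
        panel = make_panel(np.array([[2.0, 1.0], [0.0, 1.0]]))
        eff = harmonize_alleles(
            make_sumstats(panel, beta=[0.1, 0.2], p=[0.04, 0.06]), panel
        )
        vec = compute_prs(panel, eff, ["s0", "s1"], PrsConfig())
        assert int(vec["n_snps"].iloc[0]) == 1

    def test_worked_example_with_negative_weight(self):
        panel = make_panel(np.array([[2.0, 1.0, 0.0], [0.0, 2.0, 2.0]]))
        eff = harmonize_alleles(
            make_sumstats(panel, beta=[0.1, 0.2, -0.3], p=[0.01] * 3), panel
        )
        vec = compute_prs(panel, eff, ["s0", "s1", "s2"], PrsConfig(), p_threshold=1.0)
        assert vec["raw"].iloc[0] == pytest.approx(1.0 / 6.0, abs=1e-12)

    def test_standardized_scores(self):
        rng = np.random.default_rng(7)
        panel = make_panel(rng.integers(0, 3, size=(200, 5)).astype(float))
        eff = harmonize_alleles(
            make_sumstats(panel, beta=rng.normal(size=5), p=rng.uniform(size=5)), panel
        )
        vec = compute_prs(panel, eff, list(eff["SNP"]), PrsConfig(), p_threshold=1.0)
        assert abs(vec["z"].mean()) < 1e-10
        assert abs(np.std(vec["z"]) - 1.0) < 1e-10

    def test_missing_dosage_denominator(self):
        dos = np.array([[2.0, np.nan], [1.0, 1.0], [0.0, 2.0]])
        panel = make_panel(dos)
        eff = harmonize_alleles(
            make_sumstats(panel, beta=[0.1, 0.3], p=[0.01, 0.01]), panel
        )
        vec = compute_prs(panel, eff, ["s0", "s1"], PrsConfig(), p_threshold=1.0)
        # person 0 scored over the single non-missing SNP
        assert vec["raw"].iloc[0] == pytest.approx(0.1 * 2 / 2.0)
        assert vec["raw"].iloc[1] == pytest.approx((0.1 + 0.3) / 4.0)

    def test_empty_threshold_fails_with_threshold_named(self):
        panel = make_panel(np.ones((3, 1)))
        eff = harmonize_alleles(make_sumstats(panel, beta=[0.1], p=[0.5]), panel)
        with pytest.raises(EmptyScoreError, match="0.001"):
            compute_prs(panel, eff, ["s0"], PrsConfig(), p_threshold=0.001)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(11)
        dos = rng.integers(0, 3, size=(100, 3)).astype(float)
        panel = make_panel(dos, refs=["A", "C", "G"], alts=["G", "T", "C"])
        ss = make_sumstats(panel, beta=[0.2, -0.1, 0.3], p=[0.01, 0.02, 0.03])
        base = score_trait(panel, ss, PrsConfig(clump_r2=1.0), p_threshold=1.0)

        # relabel SNP 1: swap REF/ALT and dosage -> 2 - dosage
        dos2 = dos.copy()
        dos2[:, 1] = 2.0 - dos2[:, 1]
        panel2 = make_panel(dos2, refs=["A", "T", "G"], alts=["G", "C", "C"])
        flipped = score_trait(panel2, ss, PrsConfig(clump_r2=1.0), p_threshold=1.0)
        np.testing.assert_allclose(base["z"], flipped["z"], atol=1e-12)


class TestSweep:
    def test_counts_monotone_and_exact(self, toy_ld_panel):
        eff = harmonize_alleles(
            make_sumstats(toy_ld_panel, beta=[0.1, 0.2, 0.3], p=[0.01, 0.04, 0.2]),
            toy_ld_panel,
        )
        retained = list(eff["SNP"])
        sweep = threshold_sweep(
            toy_ld_panel, eff, retained, PrsConfig(threshold_sweep=(0.05, 1.0))
        )
        counts = {t: int(v["n_snps"].iloc[0]) for t, v in sweep.items()}
        assert counts == {0.05: 2, 1.0: 3}

    def test_full_sweep_monotone(self, toy_ld_panel):
        eff = harmonize_alleles(
            make_sumstats(toy_ld_panel, beta=[0.1, 0.2, 0.3], p=[0.0005, 0.04, 0.6]),
            toy_ld_panel,
        )
        sweep = threshold_sweep(toy_ld_panel, eff, list(eff["SNP"]), PrsConfig())
        ns = [int(v["n_snps"].iloc[0]) for _, v in sorted(sweep.items())]
        assert ns == sorted(ns)


class TestTruthRecovery:
    def test_noiseless_prs_tracks_true_polygenic_value(self):
        # default SNP panel (causal variants spread one per LD block)
        cfg = SimulationConfig(n_individuals=2000, gwas_n=np.inf, seed=3)
        panel, sumstats = simulate_genotypes(cfg)
        truth = true_polygenic_values(panel, sumstats)
        vec = score_trait(panel, sumstats[0])
        r = np.corrcoef(vec["z"], truth[:, 0])[0, 1]
        assert r >= 0.95
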