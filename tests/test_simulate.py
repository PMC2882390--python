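"""Synthetic-data generator: reproducibility, planted structure, prevalence
control and file round-trips."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from pogo import (
    SimulationConfig,
    chi_square_scores,
    load_bundle,
    simulate_bundle,
    simulate_disjoint_source_signal,
    write_bundle,
)


class TestReproducibility:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(n_proteins=60, n_terms=4, seed=5)
        a, truth_a = simulate_bundle(cfg)
        b, truth_b = simulate_bundle(cfg)
        assert a.proteins.sequences == b.proteins.sequences
        assert a.annotations.records == b.annotations.records
        for sa, sb in zip(a.sources, b.sources):
            da = sa.matrix.toarray() if hasattr(sa.matrix, "toarray") else sa.matrix
            db = sb.matrix.toarray() if hasattr(sb.matrix, "toarray") else sb.matrix
            np.testing.assert_array_equal(da, db)
        assert truth_a["terms"].keys() == truth_b["terms"].keys()

    def test_different_seed_differs(self):
        a, _ = simulate_bundle(SimulationConfig(n_proteins=60, n_terms=4, seed=1))
        b, _ = simulate_bundle(SimulationConfig(n_proteins=60, n_terms=4, seed=2))
        assert a.annotations.records != b.annotations.records


class TestPlantedStructure:
    def test_prevalence_matches_configuration(self, fixture_bundle, fixture_truth):
        n = len(fixture_bundle.proteins)
        for term, info in fixture_truth["terms"].items():
            observed = len(fixture_bundle.annotations.proteins_for(term))
            assert observed == info["n_positives"]
            assert observed == pytest.approx(info["prevalence"] * n, abs=0.51)

    def test_planted_features_dominate_background_chi2(
        self, fixture_bundle, fixture_truth
    ):
        """Rank-sum check: planted-feature chi-square scores stochastically
        dominate background scores."""
        src = fixture_bundle.source("interpro")
        term = next(iter(fixture_truth["terms"]))
        positives = fixture_bundle.annotations.proteins_for(term)
        y = np.array(
            [1 if p in positives else 0 for p in fixture_bundle.proteins.ids]
        )
        scores = chi_square_scores(src.matrix, y, src.vocabulary)
        planted = set(fixture_truth["terms"][term]["planted"]["interpro"])
        planted_scores = [
            s for name, s in zip(scores.feature_names, scores.scores)
            if name in planted
        ]
        background = [
            s for name, s in zip(scores.feature_names, scores.scores)
            if name not in planted
        ]
        stat = mannwhitneyu(planted_scores, background, alternative="greater")
        # 3 planted vs ~200 background features: the tie-corrected normal
        # approximation bottoms out near 1.5e-3 even at perfect separation
        assert stat.pvalue < 0.01
        assert min(planted_scores) > np.quantile(background, 0.99)

    def test_noiseless_limit_single_feature_rule_is_perfect(self):
        cfg = SimulationConfig(
            n_proteins=80, n_terms=4, p_signal=1.0, background_density=0.0,
            composition_shift=0.0, seed=3,
        )
        bundle, truth = simulate_bundle(cfg)
        for term, info in truth["terms"].items():
            feature = info["planted"]["interpro"][0]
            src = bundle.source("interpro")
            col = src.vocabulary.index(feature)
            predicted = set(
                np.array(bundle.proteins.ids)[
                    src.matrix.toarray()[:, col] == 1
                ]
            )
            assert predicted == bundle.annotations.proteins_for(term)

    def test_disjoint_quarters_recorded_and_disjoint(self):
        bundle, truth = simulate_disjoint_source_signal(
            SimulationConfig(n_proteins=60, n_terms=8, seed=2)
        )
        quarters = truth["informative"]
        assert sorted(quarters) == ["biochem", "blast", "interpro", "structure"]
        all_terms = [t for ts in quarters.values() for t in ts]
        assert len(all_terms) == len(set(all_terms)) == 8
        for name in ("blast", "structure"):
            for term in quarters[name]:
                assert "interpro" not in truth["terms"][term]["planted"]

    def test_null_config_plants_nothing_distinguishable(self):
        cfg = SimulationConfig(
            n_proteins=100, n_terms=4, p_signal=0.02, background_density=0.02,
            composition_shift=0.0, seed=9,
        )
        bundle, truth = simulate_bundle(cfg)
        src = bundle.source("interpro")
        term = next(iter(truth["terms"]))
        positives = bundle.annotations.proteins_for(term)
        y = np.array(
            [1 if p in positives else 0 for p in bundle.proteins.ids]
        )
        scores = chi_square_scores(src.matrix, y, src.vocabulary)
        planted = set(truth["terms"][term]["planted"]["interpro"])
        planted_scores = [
            s for name, s in zip(scores.feature_names, scores.scores)
            if name in planted
        ]
        # under the null the planted columns are ordinary background
        assert max(planted_scores) < np.quantile(scores.scores, 0.999) + 1e-9


class TestFileRoundTrip:
    def test_write_then_load_preserves_labels_and_binary_sources(
        self, tmp_path
    ):
        cfg = SimulationConfig(n_proteins=40, n_terms=4, seed=11)
        bundle, truth = simulate_bundle(cfg)
        write_bundle(bundle, truth, str(tmp_path))
        back = load_bundle(str(tmp_path))
        assert back.annotations.records == bundle.annotations.records
        assert back.proteins.sequences == bundle.proteins.sequences
        for name in ("interpro", "blast"):
            orig = bundle.source(name)
            re = back.source(name)
            orig_pairs = {
                (pid, orig.vocabulary[j])
                for i, pid in enumerate(bundle.proteins.ids)
                for j in orig.matrix[i].indices
            }
            re_pairs = {
                (pid, re.vocabulary[j])
                for i, pid in enumerate(back.proteins.ids)
                for j in re.matrix[i].indices
            }
            assert orig_pairs == re_pairs

    def test_decoy_blast_hits_filtered_on_read(self, tmp_path):
        cfg = SimulationConfig(n_proteins=20, n_terms=4, seed=12)
        bundle, truth = simulate_bundle(cfg)
        write_bundle(bundle, truth, str(tmp_path))
        back = load_bundle(str(tmp_path))
        assert "DECOY00001" not in back.source("blast").vocabulary

    def test_structure_read_respects_top_ten(self, tmp_path):
        cfg = SimulationConfig(n_proteins=40, n_terms=4, seed=13)
        bundle, truth = simulate_bundle(cfg)
        write_bundle(bundle, truth, str(tmp_path))
        back = load_bundle(str(tmp_path))
        row_sums = np.asarray(
            back.source("structure").matrix.sum(axis=1)
        ).ravel()
        assert row_sums.max() <= 10
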