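"""Synthetic-study generator: distributions, planted truth, determinism."""

import numpy as np
import pytest

from twaskit.engine import twas_zscore
from twaskit.enrichment import enrich
from twaskit.errors import DomainError
from twaskit.integrate import filter_de
from twaskit.simulate import (
    SimConfig,
    generate_study,
    make_ld,
    plant_causal,
    read_truth,
    simulate_de_table,
    simulate_go,
    simulate_gwas_z,
    simulate_weights,
    write_study,
)
from twaskit.sumstats import read_sumstats
from twaskit.weights import FeatureWeights, load_weights


class TestMakeLd:
    def test_rho_zero_identity(self):
        np.testing.assert_array_equal(make_ld(4, 0.0).D, np.eye(4))

    def test_ar1_closed_form(self):
        D = make_ld(3, 0.5).D
        np.testing.assert_allclose(D[0], [1.0, 0.5, 0.25])
        np.testing.assert_allclose(D[1], [0.5, 1.0, 0.5])

    @pytest.mark.parametrize("size,rho", [(2, 0.9), (10, -0.7), (25, 0.99)])
    def test_always_positive_definite(self, size, rho):
        assert np.linalg.eigvalsh(make_ld(size, rho).D).min() > 0

    def test_invalid_rho(self):
        with pytest.raises(DomainError):
            make_ld(3, 1.0)


class TestSimulateWeights:
    def test_full_sparsity_all_nonzero(self, rng):
        assert np.all(simulate_weights(10, 1.0, rng) != 0)

    def test_minimal_sparsity_exactly_one_nonzero(self, rng):
        w = simulate_weights(10, 0.1, rng)
        assert np.count_nonzero(w) == 1

    def test_ceiling_rule(self, rng):
        assert np.count_nonzero(simulate_weights(10, 0.25, rng)) == 3

    def test_deterministic_given_seed(self):
        a = simulate_weights(8, 0.5, np.random.default_rng(3))
        b = simulate_weights(8, 0.5, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)


class TestSimulateGwasZ:
    def test_null_identity_moments(self, rng):
        z = simulate_gwas_z(np.eye(4), np.zeros(4), 1000, rng, size=10_000)
        assert np.all(np.abs(z.mean(axis=0)) < 0.05)
        assert np.all(np.abs(z.var(axis=0) - 1.0) < 0.05)

    def test_null_correlation_matches_ld(self, rng):
        ld = make_ld(5, 0.6)
        z = simulate_gwas_z(ld, np.zeros(5), 1000, rng, size=10_000)
        emp = np.corrcoef(z.T)
        assert np.max(np.abs(emp - ld.D)) < 0.05

    def test_deterministic_given_seed(self):
        ld = make_ld(4, 0.3)
        a = simulate_gwas_z(ld, np.zeros(4), 100, np.random.default_rng(5))
        b = simulate_gwas_z(ld, np.zeros(4), 100, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestPlantCausal:
    def test_zero_effect_zero_beta(self):
        ld = make_ld(4, 0.5)
        fw = FeatureWeights("G", "NTR", ld.snp_ids, [1.0, 0, 0, 2.0])
        np.testing.assert_array_equal(plant_causal(fw, ld, 0.0), np.zeros(4))

    def test_single_snp_closed_form(self, rng):
        """E[z_twas] = sqrt(n) * effect for a single-SNP feature."""
        ld = make_ld(1, 0.0)
        fw = FeatureWeights("G", "NTR", ld.snp_ids, [0.7])
        beta = plant_causal(fw, ld, 0.02)
        n = 10_000
        z = simulate_gwas_z(ld, beta, n, rng, size=20_000)
        zt = z[:, 0] * np.sign(fw.w[0])
        expected = np.sqrt(n) * 0.02
        assert zt.mean() == pytest.approx(expected, abs=3 * zt.std() / np.sqrt(len(zt)))

    def test_general_case_monte_carlo_mean(self, rng):
        ld = make_ld(8, 0.6)
        w = simulate_weights(8, 0.5, rng)
        fw = FeatureWeights("G", "NTR", ld.snp_ids, w)
        effect, n = 0.01, 50_000
        beta = plant_causal(fw, ld, effect)
        draws = simulate_gwas_z(ld, beta, n, rng, size=5000)
        zt = np.array([twas_zscore(w, z, ld.D) for z in draws])
        expected = np.sqrt(n) * effect
        assert zt.mean() == pytest.approx(expected, abs=3 * zt.std() / np.sqrt(len(zt)))


class TestSimulateDeTable:
    def test_null_calibration(self, rng):
        genes = [f"G{i}" for i in range(800)]
        de = simulate_de_table(genes, set(), n_cases=20, n_controls=20, rng=rng)
        frac = (de.df["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.03)

    def test_planted_genes_recovered_with_high_sensitivity(self, rng):
        genes = [f"G{i}" for i in range(300)]
        planted = set(genes[:100])
        de = simulate_de_table(genes, planted, log2_shift=1.0, noise_sd=0.5, rng=rng)
        hits = filter_de(de)
        sensitivity = len(hits & planted) / len(planted)
        assert sensitivity > 0.9

    def test_deterministic(self):
        genes = ["A", "B", "C"]
        a = simulate_de_table(genes, {"A"}, rng=np.random.default_rng(9))
        b = simulate_de_table(genes, {"A"}, rng=np.random.default_rng(9))
        assert a.df.equals(b.df)


class TestSimulateGo:
    def test_planted_term_present_verbatim_and_ranks_first(self, rng):
        genes = [f"G{i}" for i in range(60)]
        planted = set(genes[:8])
        coll = simulate_go(genes, 30, planted, rng)
        by_id = {t.term_id: t for t in coll.terms}
        assert by_id["TERM_PLANTED"].members == frozenset(planted)
        assert coll.universe == frozenset(genes)
        results = enrich(planted, coll)
        assert results[0].term_id == "TERM_PLANTED"


class TestGenerateStudy:
    def test_round_trip_through_readers(self, synthetic_study):
        study, out = synthetic_study
        ss = read_sumstats(out / "sumstats.tsv")
        assert len(ss) == len(study.sumstats)
        feats = load_weights(out / "weights.tsv")
        assert len(feats) == len(study.features)
        truth = read_truth(out / "truth.tsv")
        assert truth.causal_genes == study.truth.causal_genes
        assert truth.de_genes == study.truth.de_genes

    def test_causal_subset_of_de_and_covered(self, synthetic_study):
        study, _ = synthetic_study
        covered = {fw.gene for fw in study.features}
        assert study.truth.causal_genes <= covered
        assert study.truth.causal_genes <= study.truth.de_genes

    def test_byte_identical_determinism(self, tmp_path):
        cfg = SimConfig(n_loci=6, snps_per_locus=5, genes_per_panel=4, seed=11)
        a, b = tmp_path / "a", tmp_path / "b"
        write_study(generate_study(cfg), a)
        write_study(generate_study(cfg), b)
        for fa in sorted(p for p in a.rglob("*") if p.is_file()):
            fb = b / fa.relative_to(a)
            assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_generated_artifacts_satisfy_consumer_invariants(self, synthetic_study):
        study, _ = synthetic_study
        for ld in study.ld:
            assert np.linalg.eigvalsh(ld.D).min() > 0
        for fw in study.features:
            assert np.any(fw.w != 0)
        assert study.gene_sets.universe >= study.truth.causal_genes
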