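"""Feature weights, LD matrices, PSD regularization and alignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from twaskit.errors import DomainError, FeatureSkipped, FormatError
from twaskit.sumstats import GwasSumstats
from twaskit.weights import (
    FeatureWeights,
    LdMatrix,
    LdStore,
    align_feature,
    load_ld_matrix,
    load_weights,
    regularize_psd,
    write_ld_matrix,
)


def _sumstats(snp_z: dict[str, float]) -> GwasSumstats:
    rows = [(s, "1", i, "A", "G", z) for i, (s, z) in enumerate(snp_z.items())]
    return GwasSumstats(
        df=pd.DataFrame(rows, columns=["snp", "chrom", "pos", "a1", "a2", "z"])
    )


class TestFeatureWeights:
    def test_all_zero_rejected(self):
        with pytest.raises(DomainError, match="zero"):
            FeatureWeights("G1", "NTR", ["rs1", "rs2"], [0.0, 0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            FeatureWeights("G1", "NTR", ["rs1"], [1.0, 2.0])

    def test_load_long_format(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text(
            "GENE\tPANEL\tSNP\tWEIGHT\n"
            "G1\tNTR\trs1\t0.5\nG1\tNTR\trs2\t-0.5\n"
            "G2\tNTR\trs3\t1.0\n"
            "G1\tYFS\trs1\t0.3\n"
        )
        feats = load_weights(path)
        assert [(f.gene, f.panel) for f in feats] == [("G1", "NTR"), ("G2", "NTR"), ("G1", "YFS")]

    def test_same_gene_two_panels_are_distinct_features(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text("GENE\tPANEL\tSNP\tWEIGHT\nG1\tNTR\trs1\t1.0\nG1\tYFS\trs1\t0.5\n")
        assert len(load_weights(path)) == 2

    def test_all_zero_row_in_file_rejected(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text("GENE\tPANEL\tSNP\tWEIGHT\nG1\tNTR\trs1\t0.0\n")
        with pytest.raises(FormatError):
            load_weights(path)


class TestRegularizePsd:
    def test_identity_unchanged(self):
        np.testing.assert_allclose(regularize_psd(np.eye(3), eps=0.0), np.eye(3))

    def test_indefinite_matrix_clipped_to_psd_unit_diagonal(self):
        D = np.array([[1.0, 1.2], [1.2, 1.0]])
        # independent eigendecomposition oracle: eigenvalues -0.2 and 2.2
        np.testing.assert_allclose(np.linalg.eigvalsh(D), [-0.2, 2.2])
        M = regularize_psd(D, eps=0.0)
        vals = np.linalg.eigvalsh(M)
        assert vals.min() >= -1e-12
        np.testing.assert_allclose(np.diag(M), 1.0)
        np.testing.assert_allclose(M, M.T)

    def test_valid_correlation_matrix_unchanged(self, rng):
        A = rng.standard_normal((6, 40))
        C = np.corrcoef(A)
        assert np.linalg.eigvalsh(C).min() > 1e-8
        np.testing.assert_allclose(regularize_psd(C), C, atol=1e-10)

    def test_nonsquare_rejected(self):
        with pytest.raises(DomainError):
            regularize_psd(np.ones((2, 3)))

    @given(rho=st.floats(min_value=-0.95, max_value=0.95), n=st.integers(2, 8))
    def test_output_always_psd_unit_diagonal(self, rho, n):
        idx = np.arange(n)
        D = rho ** np.abs(idx[:, None] - idx[None, :])
        D[0, -1] = D[-1, 0] = 0.99  # may break PSD-ness
        M = regularize_psd(D)
        assert np.linalg.eigvalsh(M).min() >= -1e-8
        np.testing.assert_allclose(np.diag(M), 1.0)


class TestLdMatrix:
    def test_symmetry_enforced(self):
        with pytest.raises(DomainError):
            LdMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]))

    def test_unit_diagonal_enforced(self):
        with pytest.raises(DomainError):
            LdMatrix(["a", "b"], np.array([[2.0, 0.0], [0.0, 1.0]]))

    def test_round_trip(self, tmp_path):
        ld = LdMatrix(["rs1", "rs2"], np.array([[1.0, 0.3], [0.3, 1.0]]))
        write_ld_matrix(ld, tmp_path / "ld.tsv")
        back = load_ld_matrix(tmp_path / "ld.tsv")
        assert back.snp_ids == ld.snp_ids
        np.testing.assert_allclose(back.D, ld.D)

    def test_store_lookup_and_duplicate_rejection(self):
        m1 = LdMatrix(["rs1", "rs2"], np.eye(2))
        m2 = LdMatrix(["rs3"], np.eye(1))
        store = LdStore([m1, m2])
        assert store.locus_for(["rs2"]).snp_ids == ["rs1", "rs2"]
        with pytest.raises(FeatureSkipped):
            store.locus_for(["rsX"])
        with pytest.raises(FeatureSkipped):
            store.locus_for(["rs1", "rs3"])
        with pytest.raises(FormatError):
            LdStore([m1, LdMatrix(["rs2"], np.eye(1))])


class TestAlignFeature:
    def test_identical_sets_full_overlap(self):
        fw = FeatureWeights("G1", "NTR", ["rs1", "rs2"], [1.0, -1.0])
        ld = LdMatrix(["rs1", "rs2"], np.eye(2))
        af = align_feature(fw, _sumstats({"rs1": 1.0, "rs2": 2.0}), ld)
        assert af.n_overlap == 2 and af.overlap_fraction == 1.0

    def test_partial_overlap_above_threshold(self):
        fw = FeatureWeights("G1", "NTR", ["rs1", "rs2", "rs3", "rs4"], [1, 1, 1, 1])
        ld = LdMatrix(["rs1", "rs2", "rs3", "rs4"], np.eye(4))
        af = align_feature(fw, _sumstats({"rs1": 1.0, "rs2": 2.0}), ld, 0.5)
        assert af.n_overlap == 2
        np.testing.assert_allclose(af.z, [1.0, 2.0])

    def test_below_threshold_skipped(self):
        fw = FeatureWeights("G1", "NTR", ["rs1", "rs2", "rs3", "rs4"], [1, 1, 1, 1])
        ld = LdMatrix(["rs1", "rs2", "rs3", "rs4"], np.eye(4))
        with pytest.raises(FeatureSkipped, match="overlap"):
            align_feature(fw, _sumstats({"rs1": 1.0}), ld, 0.5)

    def test_order_follows_ld_matrix(self, rng):
        """Statistic order source: permuting input SNP order changes nothing."""
        from twaskit.engine import twas_zscore

        snps = [f"rs{i}" for i in range(5)]
        idx = np.arange(5)
        D = 0.5 ** np.abs(idx[:, None] - idx[None, :])
        w = rng.standard_normal(5)
        zmap = {s: float(rng.standard_normal()) for s in snps}
        ld = LdMatrix(snps, D)

        perm = rng.permutation(5)
        fw_perm = FeatureWeights("G1", "NTR", [snps[i] for i in perm], w[perm])
        fw_orig = FeatureWeights("G1", "NTR", snps, w)
        af1 = align_feature(fw_orig, _sumstats(zmap), ld)
        af2 = align_feature(fw_perm, _sumstats(zmap), ld)
        assert af1.snp_ids == af2.snp_ids == snps
        assert twas_zscore(af1.w, af1.z, af1.D) == pytest.approx(
            twas_zscore(af2.w, af2.z, af2.D), rel=1e-12
        )
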