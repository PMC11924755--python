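import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddr_wescore.panel import DDRPanel, PanelEntry
from ddr_wescore.scoring import (
    ExpressionMatrix,
    SignatureDefinition,
    ZMatrix,
    raw_we_scores,
    scale_we_scores,
    signature_score,
    to_log_scale,
    zscore_genes,
)


def _expr(values, genes, samples, units="TPM"):
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), units=units
    )


def _zmat(values, genes, samples):
    return ZMatrix(values=pd.DataFrame(values, index=genes, columns=samples))


class TestLogScale:
    @pytest.mark.parametrize("tpm,expected", [(0, 0), (1, 1), (7, 3)])
    def test_log2_plus_one(self, tpm, expected):
        e = _expr([[float(tpm), float(tpm)]], ["G"], ["a", "b"])
        out = to_log_scale(e)
        assert out.units == "log2TPM"
        assert out.values.iloc[0, 0] == pytest.approx(expected)

    def test_idempotent_on_logged_input(self):
        e = _expr([[1.0, 2.0]], ["G"], ["a", "b"], units="log2TPM")
        with pytest.warns(UserWarning, match="no-op"):
            out = to_log_scale(e)
        pd.testing.assert_frame_equal(out.values, e.values)

    def test_negative_tpm_rejected_at_construction(self):
        with pytest.raises(ValueError, match="negative"):
            _expr([[-1.0, 2.0]], ["G"], ["a", "b"])


class TestZScore:
    def test_simple_row(self):
        z = zscore_genes(_expr([[1, 2, 3]], ["G"], list("abc"), units="log2TPM"))
        assert z.values.iloc[0].tolist() == pytest.approx([-1, 0, 1])

    def test_constant_row_zeroed_and_flagged(self):
        z = zscore_genes(_expr([[5, 5, 5], [1, 2, 3]], ["C", "G"], list("abc"),
                               units="log2TPM"))
        assert (z.values.loc["C"] == 0).all()
        assert z.degenerate_genes == ("C",)

    def test_zscore_units_pass_through(self, small_zscore_expr):
        z = zscore_genes(small_zscore_expr)
        pd.testing.assert_frame_equal(z.values, small_zscore_expr.values)
        assert z.provenance["transform"] == "passthrough"

    def test_rows_standardized(self):
        rng = np.random.default_rng(0)
        e = _expr(rng.gamma(2, 50, size=(10, 8)), [f"g{i}" for i in range(10)],
                  [f"s{j}" for j in range(8)])
        z = zscore_genes(e)  # TPM input auto-logged
        np.testing.assert_allclose(z.values.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1, atol=1e-9)
        assert z.provenance["transform"] == "log2(TPM+1)"

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            zscore_genes(_expr([[1.0]], ["G"], ["a"]))

    def test_nan_named(self):
        e = _expr([[1.0, np.nan]], ["GX"], ["a", "b"], units="log2TPM")
        with pytest.raises(ValueError, match="GX"):
            zscore_genes(e)

    def test_shift_invariance(self):
        """Adding a constant to one gene leaves its z-scores unchanged."""
        rng = np.random.default_rng(3)
        base = rng.normal(size=(3, 6))
        shifted = base.copy()
        shifted[1] += 7.5
        z1 = zscore_genes(_expr(base, list("xyz"), list("abcdef"), units="log2TPM"))
        z2 = zscore_genes(_expr(shifted, list("xyz"), list("abcdef"), units="log2TPM"))
        pd.testing.assert_frame_equal(z1.values, z2.values)


class TestRawWEScores:
    def test_two_gene_pathway_formula(self):
        panel = DDRPanel(entries=(PanelEntry("G1", "HR", 2.0),
                                  PanelEntry("G2", "HR", 1.0)))
        z = _zmat([[1.0, -1.0], [-1.0, 1.0]], ["G1", "G2"], ["a", "b"])
        we = raw_we_scores(z, panel)
        # (1*2 + (-1)*1)/2 = 0.5 for sample a, mirrored for b
        assert we.raw.loc["HR"].tolist() == pytest.approx([0.5, -0.5])

    def test_single_gene_pathway(self):
        panel = DDRPanel(entries=(PanelEntry("G1", "HR", 1.0),))
        z = _zmat([[1.5, 0.0]], ["G1"], ["a", "b"])
        assert raw_we_scores(z, panel).raw.loc["HR", "a"] == pytest.approx(1.5)

    def test_zero_z_gives_zero_scores(self, toy_panel):
        z = _zmat(np.zeros((3, 4)), ["BRCA1", "XRCC1", "POLH"], list("abcd"))
        assert (raw_we_scores(z, toy_panel).raw.to_numpy() == 0).all()

    def test_unmatched_pathway_dropped_with_warning(self, toy_panel):
        z = _zmat([[1.0, -1.0]], ["BRCA1"], ["a", "b"])
        with pytest.warns(UserWarning, match="BER"):
            we = raw_we_scores(z, toy_panel)
        assert list(we.raw.index) == ["HR"]
        assert set(we.unmatched_genes) == {"XRCC1", "POLH"}

    def test_no_overlap_errors(self, toy_panel):
        z = _zmat([[1.0, -1.0]], ["OTHER"], ["a", "b"])
        with pytest.raises(ValueError, match="no panel genes"):
            raw_we_scores(z, toy_panel)

    def test_strict_denominator_uses_full_pathway_size(self):
        panel = DDRPanel(entries=(PanelEntry("G1", "HR", 1.0),
                                  PanelEntry("G2", "HR", 1.0)))
        z = _zmat([[2.0, -2.0]], ["G1"], ["a", "b"])
        lenient = raw_we_scores(z, panel).raw.loc["HR", "a"]
        strict = raw_we_scores(z, panel, strict_denominator=True).raw.loc["HR", "a"]
        assert lenient == pytest.approx(2.0)
        assert strict == pytest.approx(1.0)

    def test_esf_neutrality_equals_pathway_mean(self, default_panel):
        """With all ESF = 1 the raw WE score is the per-pathway mean z."""
        rng = np.random.default_rng(5)
        genes = list(default_panel.genes)
        z = _zmat(rng.normal(size=(len(genes), 6)), genes,
                  [f"s{j}" for j in range(6)])
        we = raw_we_scores(z, default_panel)  # packaged panel has esf=1
        for pathway in default_panel.pathways:
            expected = z.values.loc[list(default_panel.genes_in(pathway))].mean(axis=0)
            np.testing.assert_allclose(we.raw.loc[pathway], expected, atol=1e-12)

    def test_linearity(self, toy_panel):
        rng = np.random.default_rng(8)
        genes = ["BRCA1", "XRCC1", "POLH"]
        a, b = rng.normal(size=(3, 5)), rng.normal(size=(3, 5))
        cols = list("vwxyz")
        r = lambda m: raw_we_scores(_zmat(m, genes, cols), toy_panel).raw
        np.testing.assert_allclose(r(a + b), r(a) + r(b), atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_sample_permutation_equivariance(self, seed):
        toy_panel = DDRPanel(entries=(PanelEntry("BRCA1", "HR", 2.0),
                                      PanelEntry("XRCC1", "BER", 1.0),
                                      PanelEntry("POLH", "TLS", 1.0)))
        rng = np.random.default_rng(seed)
        genes = ["BRCA1", "XRCC1", "POLH"]
        cols = [f"s{j}" for j in range(6)]
        m = rng.normal(size=(3, 6))
        perm = rng.permutation(6)
        we = raw_we_scores(_zmat(m, genes, cols), toy_panel).raw
        we_p = raw_we_scores(_zmat(m[:, perm], genes, [cols[i] for i in perm]),
                             toy_panel).raw
        pd.testing.assert_frame_equal(we_p, we[we_p.columns])


class TestScaleWEScores:
    def test_two_point_standardization(self):
        panel = DDRPanel(entries=(PanelEntry("G1", "HR", 1.0),))
        z = _zmat([[0.5, -0.5]], ["G1"], ["a", "b"])
        we = scale_we_scores(raw_we_scores(z, panel))
        assert we.scaled.loc["HR"].tolist() == pytest.approx(
            [0.7071067811865475, -0.7071067811865475])

    def test_constant_row_zeroed_with_warning(self):
        panel = DDRPanel(entries=(PanelEntry("G1", "HR", 1.0),))
        z = _zmat([[1.0, 1.0, 1.0]], ["G1"], list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            we = scale_we_scores(raw_we_scores(z, panel))
        assert (we.scaled.loc["HR"] == 0).all()

    def test_rows_have_zero_mean_unit_sd(self, default_panel):
        rng = np.random.default_rng(1)
        genes = list(default_panel.genes)
        z = _zmat(rng.normal(size=(len(genes), 9)), genes,
                  [f"s{j}" for j in range(9)])
        we = scale_we_scores(raw_we_scores(z, default_panel))
        np.testing.assert_allclose(we.scaled.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(we.scaled.std(axis=1, ddof=1), 1, atol=1e-9)


class TestSignatureScore:
    def test_opposed_weights(self):
        sig = SignatureDefinition("toy", {"G1": 1.0, "G2": -1.0})
        z = _zmat([[1.0, 0.0], [-1.0, 0.0]], ["G1", "G2"], ["a", "b"])
        assert signature_score(z, sig)["a"] == pytest.approx(1.0)

    def test_positive_weights_mean(self):
        sig = SignatureDefinition("toy", {"G1": 1.0, "G2": 1.0})
        z = _zmat([[2.0, 0.0], [0.0, 0.0]], ["G1", "G2"], ["a", "b"])
        assert signature_score(z, sig)["a"] == pytest.approx(1.0)

    def test_missing_genes_warned_disjoint_errors(self):
        z = _zmat([[1.0, 0.0]], ["G1"], ["a", "b"])
        with pytest.warns(UserWarning, match="missing"):
            signature_score(z, SignatureDefinition("s", {"G1": 1.0, "GX": 1.0}))
        with pytest.raises(ValueError, match="no genes overlap"):
            signature_score(z, SignatureDefinition("s", {"GX": 1.0}))

    def test_invalid_signatures_rejected(self):
        with pytest.raises(ValueError):
            SignatureDefinition("empty", {})
        with pytest.raises(ValueError):
            SignatureDefinition("zero", {"G1": 0.0})


class TestBruteForceOracle:
    def test_vectorized_matches_triple_loop(self, default_panel):
        """Naive per-(pathway, sample, gene) loop agrees with the vectorized path."""
        rng = np.random.default_rng(99)
        genes = list(default_panel.genes)[:20]
        samples = [f"s{j}" for j in range(8)]
        z = _zmat(rng.normal(size=(20, 8)), genes, samples)
        with pytest.warns(UserWarning):  # pathways absent from the 20-gene slice
            we = raw_we_scores(z, default_panel)
        esf = default_panel.esf_map()
        for pathway in we.raw.index:
            in_data = [g for g in default_panel.genes_in(pathway) if g in genes]
            for s in samples:
                total = 0.0
                for g in in_data:
                    total += esf[g] * z.values.loc[g, s]
                assert we.raw.loc[pathway, s] == pytest.approx(
                    total / len(in_data), abs=1e-10)
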