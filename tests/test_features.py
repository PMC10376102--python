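"""Feature profiles, assembly and sliding windows."""

import numpy as np
import pandas as pd
import pytest

from torsionflux import (
    assemble,
    bigram,
    default_feature_matrix,
    flexibility_profile,
    load_pssm,
    monogram,
    physiochemical_profile,
    residue_profile,
    structural_profile,
    window,
)
from torsionflux.features import (
    AA_ALPHABET,
    GROUP_WIDTHS,
    PSIBLAST_ORDER,
    load_factor_table,
    normalize_pssm,
)
from torsionflux.synthetic import _write_pssm_ascii


class TestResidueProfile:
    def test_single_residue_one_hot(self):
        row = residue_profile("A")
        assert row.shape == (1, 20)
        assert row[0, AA_ALPHABET.index("A")] == 1 and row.sum() == 1

    def test_rows_sum_to_one(self):
        assert np.allclose(residue_profile("ACDEFGHIKLMNPQRSTVWY").sum(axis=1), 1)

    def test_acd_identity_pattern(self):
        block = residue_profile("ACD")
        assert np.array_equal(block[:3, :3], np.eye(3))

    def test_nonstandard_letter_raises(self):
        with pytest.raises(ValueError):
            residue_profile("AXA")


class TestPhysiochemicalProfile:
    def test_identical_residues_identical_rows(self):
        block = physiochemical_profile("LL")
        assert np.array_equal(block[0], block[1])

    def test_permuting_sequence_permutes_rows(self):
        a = physiochemical_profile("ACD")
        b = physiochemical_profile("DCA")
        assert np.array_equal(a[::-1], b)

    def test_toy_table_direct_lookup(self):
        table = pd.DataFrame(
            np.eye(5), index=list("ACDEF"), columns=[f"f{i}" for i in range(5)]
        )
        table.index.name = "aa"
        block = physiochemical_profile("EA", factor_table=table)
        assert np.array_equal(block, np.eye(5)[[3, 0]])

    def test_shipped_table_covers_all_residues(self):
        table = load_factor_table()
        assert set(table.index) == set(AA_ALPHABET)
        assert table.shape == (20, 5)

    def test_missing_residue_in_table_raises(self):
        table = load_factor_table().drop("W")
        with pytest.raises(ValueError):
            physiochemical_profile("W", factor_table=table)


class TestPssm:
    def test_zero_score_maps_to_half(self):
        assert normalize_pssm(np.zeros((1, 20)))[0, 0] == 0.5

    def test_saturation_limits(self):
        assert normalize_pssm(np.array([[500.0]]))[0, 0] == pytest.approx(1.0)
        assert normalize_pssm(np.array([[-500.0]]))[0, 0] == pytest.approx(0.0)

    def test_ascii_fixture_all_scores_two(self, tmp_path):
        seq = "ACD"
        _write_pssm_ascii(tmp_path / "x.pssm", seq, np.full((3, 20), 2))
        block = load_pssm(tmp_path / "x.pssm", sequence=seq)
        assert block.shape == (3, 20)
        assert np.allclose(block, 1 / (1 + np.exp(-2)))
        assert np.allclose(block, 0.8808, atol=1e-4)

    def test_ascii_columns_reordered_to_alphabet(self, tmp_path):
        # score i in PSI-BLAST column order must land on the right letter
        scores = np.arange(20)[None, :]
        _write_pssm_ascii(tmp_path / "o.pssm", "A", scores)
        block = load_pssm(tmp_path / "o.pssm")
        for j, aa in enumerate(AA_ALPHABET):
            expected = 1 / (1 + np.exp(-float(PSIBLAST_ORDER.index(aa))))
            assert block[0, j] == pytest.approx(expected)

    def test_tsv_fallback(self, tmp_path):
        df = pd.DataFrame(np.zeros((2, 20)), columns=list(AA_ALPHABET))
        df.to_csv(tmp_path / "p.tsv", sep="\t", index=False)
        block = load_pssm(tmp_path / "p.tsv")
        assert np.allclose(block, 0.5)

    def test_row_count_mismatch_raises(self, tmp_path):
        _write_pssm_ascii(tmp_path / "m.pssm", "AC", np.zeros((2, 20)))
        with pytest.raises(ValueError):
            load_pssm(tmp_path / "m.pssm", sequence="ACD")


class TestMonogramBigram:
    def test_monogram_of_uniform_rows(self):
        assert np.allclose(monogram(np.full((4, 20), 0.5)), 0.5)

    def test_monogram_column_permutation_invariant(self):
        rng = np.random.default_rng(0)
        p = rng.random((5, 20))
        perm = rng.permutation(20)
        assert np.allclose(monogram(p), monogram(p[:, perm]))

    def test_monogram_single_hot_row(self):
        row = np.zeros((1, 20))
        row[0, 0] = 1.0
        assert monogram(row)[0, 0] == pytest.approx(0.05)

    def test_bigram_uniform_half(self):
        assert np.allclose(bigram(np.full((3, 20), 0.5)), 0.25)

    def test_bigram_zero_matrix(self):
        assert np.allclose(bigram(np.zeros((3, 20))), 0.0)

    def test_bigram_last_row_self_transition(self):
        rng = np.random.default_rng(1)
        p = rng.random((4, 20))
        bg = bigram(p)
        assert np.allclose(bg[-1], p[-1].mean() * p[-1])
        assert np.allclose(bg[0], p[0].mean() * p[1])

    def test_bigram_single_row(self):
        p = np.random.default_rng(2).random((1, 20))
        assert np.allclose(bigram(p)[0], p[0].mean() * p[0])


class TestStructuralFlexibility:
    def test_structural_width_and_order(self):
        rng = np.random.default_rng(0)
        ss = rng.dirichlet(np.ones(3), 5)
        ssb = rng.dirichlet(np.ones(3), 5)
        asa = rng.random(5)
        block = structural_profile(asa, ss, ssb)
        assert block.shape == (5, 7)
        assert np.allclose(block[:, 0], asa)
        assert np.allclose(block[:, 1:4], ss)  # preserved verbatim

    def test_out_of_range_probability_clipped_with_warning(self):
        ss = np.array([[-0.01, 0.5, 0.51]])
        with pytest.warns(UserWarning, match="clip"):
            block = structural_profile([0.5], ss, np.array([[0.3, 0.3, 0.4]]))
        assert block[0, 1] == 0.0

    def test_structural_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            structural_profile([0.5, 0.5], np.zeros((1, 3)), np.zeros((1, 3)))

    def test_flexibility_width(self):
        block = flexibility_profile([0.1, 0.2], [0.3, 0.4], [0.5, 0.6], [1.0, 2.0])
        assert block.shape == (2, 4)

    def test_missing_psee_imputed_per_chain(self):
        block = flexibility_profile([0.2, 0.4], [0.1, 0.1], [0.1, 0.1], None)
        assert np.allclose(block[:, 3], 0.3)

    def test_disorder_clipped(self):
        with pytest.warns(UserWarning):
            block = flexibility_profile([1.2], [0.1], [0.1], [0.0])
        assert block[0, 0] == 1.0


class TestAssembleAndWindow:
    def make_default(self, L=6, seed=0):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(AA_ALPHABET), L))
        pssm = rng.random((L, 20))
        return default_feature_matrix(
            seq,
            pssm,
            rng.random(L),
            rng.dirichlet(np.ones(3), L),
            rng.dirichlet(np.ones(3), L),
            rng.random(L),
            rng.random(L),
            rng.random(L),
            rng.normal(size=L),
        )

    def test_default_layout_is_77_columns(self):
        fm = self.make_default()
        assert fm.width == sum(GROUP_WIDTHS.values()) == 77
        assert len(fm.columns) == 77

    def test_disabling_bigram_drops_twenty(self):
        rng = np.random.default_rng(1)
        L = 5
        fm = default_feature_matrix(
            "ACDEF",
            rng.random((L, 20)),
            rng.random(L),
            rng.dirichlet(np.ones(3), L),
            rng.dirichlet(np.ones(3), L),
            rng.random(L),
            rng.random(L),
            rng.random(L),
            groups=[g for g in GROUP_WIDTHS if g != "bigram"],
        )
        assert fm.width == 57

    def test_inconsistent_lengths_raise(self):
        with pytest.raises(ValueError):
            assemble([("a", np.zeros((3, 2))), ("b", np.zeros((4, 2)))])

    def test_window_ws1_is_identity(self):
        fm = self.make_default()
        wm = window(fm, 1)
        assert np.array_equal(wm.values, fm.values)

    def test_window_zero_padding_at_termini(self):
        m = np.arange(6, dtype=float).reshape(3, 2)
        wm = window(m, 3)
        assert wm.values.shape == (3, 6)
        assert np.array_equal(wm.values[0, :2], [0, 0])  # left pad
        assert np.array_equal(wm.values[-1, -2:], [0, 0])  # right pad

    def test_interior_row_matches_manual_concatenation(self):
        m = np.random.default_rng(3).random((5, 4))
        wm = window(m, 3)
        assert np.allclose(wm.values[2], np.concatenate([m[1], m[2], m[3]]))

    def test_edge_padding_replicates_terminal_rows(self):
        m = np.arange(6, dtype=float).reshape(3, 2)
        wm = window(m, 3, pad="edge")
        assert np.array_equal(wm.values[0, :2], m[0])

    def test_even_window_raises(self):
        with pytest.raises(ValueError):
            window(np.zeros((3, 2)), 4)
        with pytest.raises(ValueError):
            window(np.zeros((3, 2)), -1)

    def test_locality_of_window_influence(self):
        rng = np.random.default_rng(4)
        m = rng.random((9, 3))
        m2 = m.copy()
        m2[4] += 1.0
        w1, w2 = window(m, 5).values, window(m2, 5).values
        changed = np.where(np.any(w1 != w2, axis=1))[0]
        assert set(changed) <= {2, 3, 4, 5, 6}

    def test_width_is_d_times_ws(self):
        fm = self.make_default()
        for ws in (1, 3, 5):
            assert window(fm, ws).width == fm.width * ws
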