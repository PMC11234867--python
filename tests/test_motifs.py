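import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tpsmine import motifs as mo
from tpsmine import structure
from tpsmine import fixtures as fx
from tpsmine.structure import Superposition


def identity_sup(n_pairs=0):
    return Superposition(np.eye(3), np.zeros(3), [], 0.0, 1.0, max(n_pairs, 1))


def catref_of(model, positions):
    return mo.CatalyticReference(model.model_id,
                                 [(int(p), model.aa[list(model.res_index).index(p)], "catalytic")
                                  for p in positions])


class TestProximalResidues:
    def test_self_superposition_returns_catalytic_set(self):
        m = fx.make_helical_bundle(4, 25, seed=1)
        cat = catref_of(m, [30, 70])
        out = mo.map_proximal_residues(m, m, identity_sup(), cat, cutoff=0.5)
        got = {p for p, _, _ in out}
        assert {30, 70} <= got
        assert all(d == pytest.approx(0.0) for p, _, d in out if p in (30, 70))

    def test_transform_invariance(self):
        """Translating the candidate and encoding that shift in the
        superposition changes nothing."""
        m = fx.make_helical_bundle(4, 25, seed=2)
        cat = catref_of(m, [30, 70, 100])
        base = mo.map_proximal_residues(m, m, identity_sup(), cat, cutoff=5.0)
        shifted = structure.StructureModel(m.model_id, m.res_index, m.aa, m.coords + 100.0, m.confidence)
        sup = Superposition(np.eye(3), np.array([-100.0, -100.0, -100.0]), [], 0.0, 1.0, 1)
        moved = mo.map_proximal_residues(shifted, m, sup, cat, cutoff=5.0)
        assert [(p, aa) for p, aa, _ in base] == [(p, aa) for p, aa, _ in moved]
        np.testing.assert_allclose([d for _, _, d in base], [d for _, _, d in moved], atol=1e-9)

    def test_closed_cutoff_boundary(self):
        coords = np.array([[0, 0, 0], [4.9, 0, 0], [0, 5.1, 0], [50, 50, 50]], dtype=float)
        cand = structure.StructureModel("cand", [1, 2, 3, 4], "DAAA", coords)
        ref = structure.StructureModel("ref", [1], "D", np.zeros((1, 3)))
        cat = mo.CatalyticReference("ref", [(1, "D", "catalytic")])
        out = mo.map_proximal_residues(cand, ref, identity_sup(), cat, cutoff=5.0)
        assert [p for p, _, _ in out] == [1, 2]  # 4.9 in, 5.1 out

    def test_missing_catalytic_residue_error(self):
        m = fx.make_helical_bundle(2, 12, seed=3)
        cat = mo.CatalyticReference(m.model_id, [(9999, "D", "catalytic")])
        with pytest.raises(ValueError, match="9999"):
            mo.map_proximal_residues(m, m, identity_sup(), cat, cutoff=5.0)


class TestExtractMotifs:
    def test_discontinuous_run_renders_x(self):
        out = mo.extract_motifs([(338, "R"), (341, "K"), (342, "D")])
        assert [m.pattern for m in out] == ["RXXKD"]
        assert out[0].positions == [338, 341, 342]

    def test_adjacent_pairs(self):
        out = mo.extract_motifs([(95, "D"), (96, "N"), (289, "N"), (290, "D")])
        assert [m.pattern for m in out] == ["DN", "ND"]

    def test_gap_exceeding_merge_rule_splits(self):
        out = mo.extract_motifs([(10, "D"), (20, "D")], max_gap=3)
        assert [m.pattern for m in out] == ["D", "D"]

    def test_empty_input(self):
        assert mo.extract_motifs([]) == []

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.sets(st.integers(1, 80), min_size=1, max_size=12))
    def test_roundtrip_property(self, positions):
        """Rendering the motif over a sequence reproduces the listed residues
        at the listed positions."""
        seq = "ACDEFGHIKLMNPQRSTVWY" * 4
        proximal = [(p, seq[p - 1]) for p in sorted(positions)]
        motifs = mo.extract_motifs(proximal, max_gap=3)
        recovered = []
        for m in motifs:
            start = m.positions[0]
            for k, ch in enumerate(m.pattern):
                if ch != "X" or (start + k) in m.positions:
                    if (start + k) in m.positions:
                        recovered.append((start + k, ch))
        assert recovered == proximal
        for m in motifs:
            assert len(m.pattern) == m.positions[-1] - m.positions[0] + 1


class TestStarMsa:
    def test_identical_homologs(self, scheme):
        anchor = "MKLVDEHRAGWSTYF" * 3
        msa = mo.star_msa(anchor, [("h1", anchor), ("h2", anchor)], scheme)
        assert msa.shape == (2, len(anchor))
        assert (msa.values != "-").all()
        assert "".join(msa.loc["h1"]) == anchor

    def test_deletion_leaves_gap_at_deleted_column(self, scheme):
        anchor = "MKLVDEHRAGWSTYFCQNIP" * 3
        drop = 25
        homolog = anchor[:drop] + anchor[drop + 1:]
        msa = mo.star_msa(anchor, [("h1", homolog)], scheme)
        row = msa.loc["h1"]
        assert (row == "-").sum() == 1
        assert row.iloc[drop] == "-"

    def test_insertion_is_projected_out(self, scheme):
        anchor = "MKLVDEHRAGWSTYFCQNIP" * 3
        homolog = anchor[:30] + "WWWW" + anchor[30:]
        msa = mo.star_msa(anchor, [("h1", homolog)], scheme)
        assert msa.shape[1] == len(anchor)
        assert "".join(msa.loc["h1"]) == anchor  # flanks aligned, insert invisible


class TestConservation:
    def test_invariant_column(self):
        msa = pd.DataFrame([["D"], ["D"], ["D"]], columns=[0])
        ic, heights = mo.column_conservation(msa)
        assert ic[0] == pytest.approx(math.log2(20))
        assert heights.loc[0, "D"] == pytest.approx(math.log2(20))

    def test_uniform_column_zero_bits(self):
        msa = pd.DataFrame([[a] for a in "ACDEFGHIKLMNPQRSTVWY"], columns=[0])
        ic, _ = mo.column_conservation(msa)
        assert ic[0] == pytest.approx(0.0, abs=1e-12)

    def test_mixed_column_entropy(self):
        msa = pd.DataFrame([["D"]] * 18 + [["N"]] * 2, columns=[0])
        ic, heights = mo.column_conservation(msa)
        h = -(0.9 * math.log2(0.9) + 0.1 * math.log2(0.1))
        assert ic[0] == pytest.approx(math.log2(20) - h)
        assert heights.loc[0].sum() == pytest.approx(ic[0])

    def test_all_gap_column(self):
        msa = pd.DataFrame([["-"], ["-"]], columns=[0])
        ic, heights = mo.column_conservation(msa)
        assert ic[0] == 0.0 and heights.loc[0].sum() == 0.0

    def test_bounds_on_random_msas(self, rng):
        letters = list("ACDEFGHIKLMNPQRSTVWY-")
        for _ in range(10):
            data = rng.choice(letters, size=(8, 15))
            ic, heights = mo.column_conservation(pd.DataFrame(data, columns=range(15)))
            assert ((ic >= 0) & (ic <= math.log2(20) + 1e-12)).all()
            np.testing.assert_allclose(heights.sum(axis=1), ic, atol=1e-12)


class TestAlternation:
    def test_split_column_gets_group(self):
        motif = mo.MotifString("DN", [95, 96])
        rows = [["D", "N"]] * 10 + [["D", "D"]] * 10
        msa = pd.DataFrame(rows, columns=[0, 1])
        pattern = mo.motif_with_alternation(motif, msa, {95: 0, 96: 1})
        assert pattern == "D(N/D)"

    def test_dominant_column_stays_single(self):
        motif = mo.MotifString("DN", [95, 96])
        msa = pd.DataFrame([["D", "N"]] * 10, columns=[0, 1])
        assert mo.motif_with_alternation(motif, msa, {95: 0, 96: 1}) == "DN"


def test_logo_matrix_export(tmp_path, scheme):
    anchor = "MKLVDEHRAGWSTYFCQNIP"
    msa = mo.star_msa(anchor, [("h1", anchor), ("h2", anchor)], scheme)
    mo.logo_matrix_tsv(msa, tmp_path / "logo.tsv")
    df = pd.read_csv(tmp_path / "logo.tsv", sep="\t", index_col=0)
    assert df.shape == (len(anchor), 21)
    assert df["information_content"].max() == pytest.approx(math.log2(20))
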