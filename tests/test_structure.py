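import numpy as np
import pytest
from scipy import integrate

from tpsmine import structure as st
from tpsmine import fixtures as fx

MINIMAL_PDB = """\
ATOM      1  CA  MET A   1       0.000   0.000   0.000  1.00 90.10           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00 55.20           C
ATOM      3  CA  GLY A   3       7.600   0.000   0.000  1.00 70.00           C
END
"""


def rand_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


class TestParse:
    def test_minimal_pdb(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(MINIMAL_PDB)
        m = st.parse_structure(p)
        assert len(m) == 3
        assert m.aa == "MAG"
        assert list(m.res_index) == [1, 2, 3]
        np.testing.assert_allclose(m.confidence, [90.1, 55.2, 70.0])

    def test_missing_chain_error(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(MINIMAL_PDB)
        with pytest.raises(ValueError, match="available"):
            st.parse_structure(p, chain="Z")

    def test_no_ca_error(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text("ATOM      1  N   MET A   1       0.000   0.000   0.000  1.00  0.00           N\nEND\n")
        with pytest.raises(ValueError):
            st.parse_structure(p)

    def test_pdb_writer_roundtrip(self, tmp_path):
        m = fx.make_helical_bundle(2, 12, seed=5)
        st.write_pdb(m, tmp_path / "b.pdb")
        back = st.parse_structure(tmp_path / "b.pdb")
        np.testing.assert_allclose(back.coords, m.coords, atol=1e-3)
        assert back.aa == m.aa


class TestTrim:
    def test_all_confident_unchanged(self):
        m = fx.make_helical_bundle(2, 12, seed=0)
        assert len(st.trim_low_confidence(m, 70)) == len(m)

    def test_mixed_keeps_high_half(self):
        m = fx.make_helical_bundle(2, 12, seed=0)
        m.confidence = np.where(np.arange(len(m)) % 2 == 0, 90.0, 50.0)
        trimmed = st.trim_low_confidence(m, 70)
        assert len(trimmed) == (len(m) + 1) // 2
        assert list(trimmed.res_index) == list(m.res_index[::2])  # numbering preserved

    def test_all_low_gives_empty(self):
        m = fx.make_helical_bundle(2, 12, seed=0)
        m.confidence = np.full(len(m), 30.0)
        assert len(st.trim_low_confidence(m, 70)) == 0

    def test_no_confidence_warns_and_passes_through(self):
        m = fx.make_helical_bundle(2, 12, seed=0)
        m.confidence = None
        assert st.trim_low_confidence(m, 70) is m


class TestKabsch:
    def test_pure_translation(self, rng):
        P = rng.normal(size=(10, 3))
        R, t, rmsd = st.kabsch(P, P + np.array([1.0, 2.0, 3.0]))
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t, [1, 2, 3], atol=1e-10)

    def test_rotation_recovered(self, rng):
        P = rng.normal(size=(20, 3))
        Rtrue = rand_rotation(rng)
        R, t, rmsd = st.kabsch(P, P @ Rtrue.T)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(R, Rtrue, atol=1e-8)

    def test_beats_random_transforms(self):
        """Least-squares optimality: no random proper rigid transform does
        better (Monte-Carlo lower-bound oracle, small version)."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            P, Q = rng.normal(size=(12, 3)), rng.normal(size=(12, 3))
            _, _, rmsd = st.kabsch(P, Q)
            for _ in range(500):
                R = rand_rotation(rng)
                moved = P @ R.T
                moved += Q.mean(axis=0) - moved.mean(axis=0) + rng.normal(scale=0.5, size=3)
                trial = np.sqrt(((moved - Q) ** 2).sum() / len(P))
                assert trial >= rmsd - 1e-9

    def test_mirror_image_not_matched(self):
        """det(R)=+1 is enforced, so a chiral set's mirror image has rmsd > 0
        even though a reflection would superpose it exactly."""
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        Q = P * np.array([1, 1, -1])
        R, t, rmsd = st.kabsch(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-8)
        assert rmsd > 0.1
        # reflection-allowed optimum is exactly zero
        H = (P - P.mean(0)).T @ (Q - Q.mean(0))
        U, S, Vt = np.linalg.svd(H)
        refl = Vt.T @ U.T
        moved = P @ refl.T + (Q.mean(0) - P.mean(0) @ refl.T)
        assert np.sqrt(((moved - Q) ** 2).sum() / 4) == pytest.approx(0.0, abs=1e-10)

    def test_invariance_under_rigid_pretransform(self, rng):
        P, Q = rng.normal(size=(15, 3)), rng.normal(size=(15, 3))
        _, _, rmsd0 = st.kabsch(P, Q)
        R = rand_rotation(rng)
        _, _, rmsd1 = st.kabsch(P @ R.T + rng.normal(size=3), Q)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)

    def test_size_mismatch_error(self, rng):
        with pytest.raises(ValueError):
            st.kabsch(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestTmScore:
    def test_d0_values(self):
        assert st.tm_d0(120) == pytest.approx(1.24 * 105 ** (1 / 3) - 1.8, abs=1e-9)
        assert st.tm_d0(21) == 0.5
        d0s = [st.tm_d0(L) for L in range(22, 400)]
        assert all(b > a for a, b in zip(d0s, d0s[1:]))

    def test_self_is_exactly_one(self):
        m = fx.make_helical_bundle(4, 25, seed=1)
        pairs = [(i, i) for i in range(len(m))]
        assert st.tm_score(pairs, m.coords, m.coords, len(m)) == 1.0

    def test_in_unit_interval(self, rng):
        for _ in range(5):
            A, B = rng.normal(size=(30, 3)) * 10, rng.normal(size=(30, 3)) * 10
            s = st.tm_score([(i, i) for i in range(30)], A, B, 30)
            assert 0 < s <= 1

    def test_noise_matches_analytic_expectation(self):
        """TM of a noised copy approximates E[1/(1+(d/d0)^2)] under the
        chi(3)-distributed displacement d (numerical-integration oracle)."""
        m = fx.make_helical_bundle(8, 22, seed=2)  # 204 residues
        n = len(m)
        sigma = 0.5
        rng = np.random.default_rng(9)
        noisy = m.coords + rng.normal(scale=sigma, size=m.coords.shape)
        s = st.tm_score([(i, i) for i in range(n)], noisy, m.coords, n)
        d0 = st.tm_d0(n)
        pdf = lambda d: np.sqrt(2 / np.pi) * (d ** 2 / sigma ** 3) * np.exp(-d ** 2 / (2 * sigma ** 2))
        expected, _ = integrate.quad(lambda d: pdf(d) / (1 + (d / d0) ** 2), 0, 20 * sigma)
        assert s == pytest.approx(expected, abs=0.03)


class TestStructureAlign:
    def test_self_alignment(self):
        m = fx.make_helical_bundle(4, 25, seed=3)
        sup = st.structure_align(m, m)
        assert sup.tm_score == pytest.approx(1.0, abs=1e-9)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-8)
        assert sup.pairs == [(i, i) for i in range(len(m))]

    def test_nterminal_deletion_recovers_offset(self):
        m = fx.make_helical_bundle(4, 25, seed=4)
        truncated = m.subset(np.arange(len(m)) >= 10, model_id="trunc")
        sup = st.structure_align(truncated, m)
        offsets = {j - i for i, j in sup.pairs}
        assert offsets == {10}
        assert len(sup.pairs) == len(m) - 10

    def test_fold_mismatch_scores_low(self):
        bundle = fx.make_helical_bundle(4, 25, seed=5)
        chain = fx.make_extended_chain(len(bundle), seed=5)
        assert st.structure_align(chain, bundle).tm_score < 0.3

    def test_deterministic(self):
        a = fx.perturb_structure(fx.make_helical_bundle(4, 25, seed=6), 1.0, seed=7)
        b = fx.make_helical_bundle(4, 25, seed=6)
        s1, s2 = st.structure_align(a, b), st.structure_align(a, b)
        assert s1.pairs == s2.pairs and s1.tm_score == s2.tm_score

    def test_rotation_is_proper_orthonormal(self):
        a = fx.perturb_structure(fx.make_helical_bundle(4, 25, seed=8), 2.0, seed=9)
        b = fx.make_helical_bundle(4, 25, seed=8)
        sup = st.structure_align(a, b)
        np.testing.assert_allclose(sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_too_short_error(self):
        tiny = fx.make_extended_chain(10, seed=0)
        with pytest.raises(ValueError):
            st.structure_align(tiny, fx.make_helical_bundle(4, 25, seed=0))

    def test_noise_monotonicity(self):
        """TM-score decreases as planted coordinate noise grows."""
        base = fx.make_helical_bundle(4, 25, seed=10)
        scores = []
        for sigma in (0.25, 0.5, 1.0, 2.0, 4.0):
            noisy = fx.perturb_structure(base, sigma, seed=11)
            scores.append(st.structure_align(noisy, base).tm_score)
        assert all(b < a for a, b in zip(scores, scores[1:]))


class TestScreen:
    def test_verbatim_reference_passes(self, kit):
        ref = kit.ref_models["classI_ref"]
        results = st.screen_by_structure(ref, list(kit.ref_models.values()))
        assert st.passes_screen(results)
        assert results[0][0] == "classI_ref"
        assert results[0][1].tm_score == pytest.approx(1.0, abs=1e-9)

    def test_noisy_copy_passes_and_decoy_fails(self, kit):
        refs = list(kit.ref_models.values())
        noisy = fx.perturb_structure(kit.ref_models["classI_ref"], 1.0, seed=13)
        assert st.passes_screen(st.screen_by_structure(noisy, refs))
        decoy = fx.make_extended_chain(150, seed=13)
        assert not st.passes_screen(st.screen_by_structure(decoy, refs))

    def test_results_sorted_by_tm(self, kit):
        noisy = fx.perturb_structure(kit.ref_models["classIB_ref"], 0.5, seed=14)
        results = st.screen_by_structure(noisy, list(kit.ref_models.values()))
        tms = [sup.tm_score for _, sup in results]
        assert tms == sorted(tms, reverse=True)
        assert results[0][0] == "classIB_ref"


def test_superposition_json_roundtrip(tmp_path):
    m = fx.make_helical_bundle(2, 15, seed=1)
    sup = st.structure_align(m, m)
    text = st.superposition_to_json(sup, tmp_path / "sup.json")
    import json

    data = json.loads(text)
    assert data["tm_score"] == pytest.approx(1.0)
    assert len(data["pairs"]) == len(m)
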