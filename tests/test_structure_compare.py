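import copy

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from glycodelta.structure_compare import (
    cumulative_histogram,
    extract_local_shell,
    global_rmsd,
    kabsch_superpose,
    local_rmsd,
    map_equivalent_residues,
    tm_d0,
    tm_score,
)
from glycodelta.synthetic_data import (
    DomainRotation,
    LoopShift,
    SiteSpec,
    SyntheticSpec,
    attach_mock_glycan,
    generate_toy_protein,
)
from .conftest import make_pair
from .oracles import grid_superpose_rmsd


def _random_points(rng, n):
    return rng.uniform(-10, 10, (n, 3))


class TestKabsch:
    def test_identical_sets(self):
        pts = _random_points(np.random.default_rng(0), 10)
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_transform_recovered(self):
        rng = np.random.default_rng(1)
        pts = _random_points(rng, 12)
        rot = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([5.0, -2.0, 1.0])
        res = kabsch_superpose(pts, moved)
        assert res.rmsd <= 1e-6
        np.testing.assert_allclose(res.transform(moved), pts, atol=1e-6)

    def test_rotation_is_proper(self):
        # mirrored point set must not be matched by a reflection
        rng = np.random.default_rng(2)
        pts = _random_points(rng, 8)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        res = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd > 0.1

    def test_displaced_vertex_matches_grid_oracle(self):
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        displaced = square.copy()
        displaced[2, 2] = 1.0
        res = kabsch_superpose(square, displaced)
        oracle = grid_superpose_rmsd(square, displaced, polish=True)
        assert res.rmsd == pytest.approx(oracle, abs=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_flagged_not_failed(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        res = kabsch_superpose(line, line + np.array([1.0, 2.0, 3.0]))
        assert res.degenerate
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)


class TestResidueMapping:
    def _chains(self, n=5, drop_b=()):
        spec = SyntheticSpec(n_residues=max(n, 5), seed=9)
        a = generate_toy_protein(spec).chains[0]
        b = copy.deepcopy(a)
        b.residues = [r for r in b.residues if r.number not in drop_b]
        return a, b

    def test_identical_chains_full_map(self):
        a, b = self._chains(5)
        mapping = map_equivalent_residues(a, b)
        assert mapping == [(r.id, r.id) for r in a.residues]

    def test_missing_first_residue(self):
        a, b = self._chains(5, drop_b=(1,))
        mapping = map_equivalent_residues(a, b)
        assert len(mapping) == 4
        assert mapping[0] == ((2, ""), (2, ""))

    def test_missing_internal_loop(self):
        spec = SyntheticSpec(n_residues=20, seed=9)
        a = generate_toy_protein(spec).chains[0]
        b = copy.deepcopy(a)
        b.residues = [r for r in b.residues if r.number not in (8, 9, 10)]
        mapping = map_equivalent_residues(a, b)
        assert len(mapping) == 17
        mapped_a = [m[0][0] for m in mapping]
        assert 8 not in mapped_a and 10 not in mapped_a

    def test_empty_chain_rejected(self):
        a, _ = self._chains(5)
        from glycodelta.structure_io import ChainModel
        with pytest.raises(ValueError):
            map_equivalent_residues(a, ChainModel(chain_id="B"))


class TestGlobalScores:
    def test_identical_pair_scores(self, toy_glycoprotein):
        pair, _ = make_pair(toy_glycoprotein)
        assert global_rmsd(pair) == pytest.approx(0.0, abs=1e-9)
        assert tm_score(pair).score == pytest.approx(1.0, abs=1e-9)

    def test_noise_pair_matches_oracle(self, gp_p_pair):
        pair, _ = gp_p_pair
        from glycodelta.structure_compare import _mapped_ca
        xa, xb = _mapped_ca(pair)
        oracle = grid_superpose_rmsd(xa, xb, polish=True)
        assert global_rmsd(pair) == pytest.approx(oracle, abs=1e-3)

    def test_domain_rotation_exceeds_noise(self, toy_glycoprotein):
        noisy, _ = make_pair(toy_glycoprotein, noise_sigma=0.2, seed=3)
        spec = SyntheticSpec(n_residues=60, geometry="two_domain",
                             sites=[SiteSpec(residue=10, n_sugars=1)], seed=4)
        two_dom = generate_toy_protein(spec)
        attach_mock_glycan(two_dom, 10, 1)
        rotated, _ = make_pair(two_dom, perturbation=DomainRotation(30, 20.0))
        assert global_rmsd(rotated) > global_rmsd(noisy)

    def test_d0_formula(self):
        assert tm_d0(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8, abs=1e-9)
        assert tm_d0(100) == pytest.approx(3.652, abs=1e-3)
        assert tm_d0(20) == 0.5  # floored

    def test_short_target_rejected(self, toy_glycoprotein):
        pair, _ = make_pair(toy_glycoprotein)
        pair.record_b.sequence = pair.record_b.sequence[:19]
        pair.record_a.sequence = pair.record_a.sequence[:19]
        with pytest.raises(ValueError):
            tm_score(pair)

    def test_refinement_dominates_single_superposition(self, toy_glycoprotein):
        from glycodelta.structure_compare import _mapped_ca, _tm_sum
        for seed in (1, 2, 3):
            pair, _ = make_pair(toy_glycoprotein, noise_sigma=0.5, seed=seed)
            xa, xb = _mapped_ca(pair)
            sup = kabsch_superpose(xa, xb)
            d2 = np.sum((sup.transform(xb) - xa) ** 2, axis=1)
            result = tm_score(pair)
            single = _tm_sum(d2, result.d0) / result.l_target
            assert result.score >= single - 1e-12


class TestLocalShell:
    def test_boundary_inclusive(self):
        spec = SyntheticSpec(n_residues=10, geometry="extended",
                             sites=[SiteSpec(residue=1)], seed=0)
        model = generate_toy_protein(spec)
        chain = model.chains[0]
        # extended chain: residue i at x ~ 3.8 (i-1); place three probes
        for num, x in ((2, 10.0), (3, 14.9), (4, 15.1)):
            chain.residue(num).atom("CA").xyz = np.array([x, 0.0, 0.0])
        chain.residue(1).atom("CA").xyz = np.zeros(3)
        from glycodelta.glycan_annotation import GlycosylationSite
        site = GlycosylationSite(chain_id="A", residue_number=1,
                                 root_saccharide=("A", 99, ""))
        shell = extract_local_shell(chain, site, radius=15.0)
        members = [m[0] for m in shell.member_ids]
        assert 2 in members and 3 in members and 4 not in members
        assert 1 in members  # the site itself

    def test_radius_zero_is_site_only(self, toy_glycoprotein):
        from glycodelta.glycan_annotation import detect_sites
        site = detect_sites(toy_glycoprotein)[0]
        shell = extract_local_shell(toy_glycoprotein.chains[0], site, radius=0.0)
        assert shell.member_ids == [(site.residue_number, "")]

    def test_large_radius_is_whole_chain(self, toy_glycoprotein):
        from glycodelta.glycan_annotation import detect_sites
        site = detect_sites(toy_glycoprotein)[0]
        chain = toy_glycoprotein.chains[0]
        shell = extract_local_shell(chain, site, radius=1e6)
        assert len(shell.member_ids) == len(chain.amino_acid_residues())


class TestLocalRMSD:
    def test_identical_pair_zero_everywhere(self, toy_glycoprotein):
        pair, sites = make_pair(toy_glycoprotein)
        for site in sites:
            assert local_rmsd(pair, site) == pytest.approx(0.0, abs=1e-9)

    def test_perturbation_outside_shell_invisible(self, toy_glycoprotein):
        # helix: residues 50..60 are > 15 A along the axis from Asn-20's Ca
        pair, sites = make_pair(toy_glycoprotein,
                                perturbation=LoopShift(52, 60, 5.0))
        site = sites[0]
        assert local_rmsd(pair, site, radius=15.0) < 1e-6
        assert global_rmsd(pair) > 0.5

    def test_shell_subset_matches_oracle(self, toy_glycoprotein):
        pair, sites = make_pair(toy_glycoprotein, noise_sigma=0.4, seed=11)
        site = sites[0]
        shell = extract_local_shell(pair.record_a.chain, site, radius=15.0)
        from glycodelta.structure_compare import _mapped_ca
        xa, xb = _mapped_ca(pair, subset_a=set(shell.member_ids))
        oracle = grid_superpose_rmsd(xa, xb, polish=True)
        assert local_rmsd(pair, site) == pytest.approx(oracle, abs=1e-3)

    def test_infinite_radius_converges_to_global(self, gp_p_pair):
        pair, sites = gp_p_pair
        assert local_rmsd(pair, sites[0], radius=1e9) == \
            pytest.approx(global_rmsd(pair), abs=1e-9)


class TestCumulativeHistogram:
    def test_counting(self):
        assert cumulative_histogram([1, 1, 3], [1.5])[0] == pytest.approx(2 / 3)

    def test_extremes(self):
        fr = cumulative_histogram([1.0, 2.0], [0.5, 5.0])
        assert fr[0] == 0.0 and fr[1] == 1.0

    def test_tm_direction(self):
        fr = cumulative_histogram([0.95, 0.90], [0.94], direction="ge")
        assert fr[0] == pytest.approx(0.5)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        means = rng.uniform(0, 5, 50)
        grid = np.linspace(0, 6, 25)
        fr = cumulative_histogram(means, grid)
        assert np.all(fr >= 0) and np.all(fr <= 1)
        assert np.all(np.diff(fr) >= 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cumulative_histogram([], [1.0])


class TestRigidInvariance:
    def test_scores_invariant_under_rigid_transform(self, gp_p_pair):
        from .conftest import apply_rigid_to_model, random_rigid_transform
        pair, sites = gp_p_pair
        rmsd0 = global_rmsd(pair)
        tm0 = tm_score(pair).score
        loc0 = local_rmsd(pair, sites[0])
        rng = np.random.default_rng(17)
        for _ in range(3):
            rot, trans = random_rigid_transform(rng)
            import glycodelta.structure_io as sio
            moved = apply_rigid_to_model(
                sio.StructureModel(id="m", chains=[pair.record_b.chain]),
                rot, trans)
            pair2 = copy.deepcopy(pair)
            pair2.record_b.chain = moved.chains[0]
            pair2.correspondence = None
            assert abs(global_rmsd(pair2) - rmsd0) < 1e-6
            assert abs(tm_score(pair2).score - tm0) < 1e-6
            assert abs(local_rmsd(pair2, sites[0]) - loc0) < 1e-6
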