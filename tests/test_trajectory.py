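"""Contact counting, residue distances, WHAM reweighting, block errors, I/O."""

import numpy as np
import pytest

from memfret.synthetic import (
    LandscapeSpec,
    default_protein_bead_spec,
    make_cg_frame,
    simulate_langevin_cv,
)
from memfret.trajectory import (
    ATP_SITE_RESIDUES,
    BlockEstimate,
    TrajectoryFrame,
    UmbrellaWindow,
    block_stats,
    count_atp_site_contacts,
    read_gro,
    read_xyz_table,
    residue_distance,
    wham_reweight,
    write_gro,
    write_xyz_table,
)


def _frame(lipids, protein, box=None, periodic=False):
    lipids = np.atleast_2d(lipids) if len(lipids) else np.zeros((0, 3))
    protein_coords = np.atleast_2d([p[1] for p in protein])
    coords = np.vstack([lipids, protein_coords])
    kinds = np.array(["lipid"] * len(lipids) + ["protein"] * len(protein), dtype=object)
    resids = np.array([0] * len(lipids) + [p[0] for p in protein])
    return TrajectoryFrame(coords, kinds, resids, box=box, periodic=periodic)


def _brute_force_contacts(frame, cutoff=16.0):
    lipids = frame.beads_of_kind("lipid")
    site = frame.protein_coords(ATP_SITE_RESIDUES)
    count = 0
    for s in site:
        for l in lipids:
            d = s - l
            if frame.periodic:
                d = d - frame.box * np.round(d / frame.box)
            if np.sqrt((d**2).sum()) < cutoff:
                count += 1
    return count


class TestContacts:
    def test_strict_cutoff_boundary(self):
        f1 = _frame([[15.9, 0, 0]], [(719, (0.0, 0.0, 0.0))])
        f2 = _frame([[16.1, 0, 0]], [(719, (0.0, 0.0, 0.0))])
        assert count_atp_site_contacts(f1) == 1
        assert count_atp_site_contacts(f2) == 0

    def test_minimum_image_wraps(self):
        f = _frame(
            [[90.0, 0.0, 0.0]],
            [(719, (0.0, 0.0, 0.0))],
            box=np.array([100.0, 100.0, 100.0]),
            periodic=True,
        )
        assert count_atp_site_contacts(f) == 1  # image distance 10 A

    @pytest.mark.parametrize("periodic", [False, True])
    def test_equals_brute_force(self, periodic):
        rng = np.random.default_rng(0)
        box = np.array([60.0, 60.0, 60.0])
        for trial in range(10):
            spec = {r: rng.uniform(0, 60, size=(1, 3)) for r in sorted(ATP_SITE_RESIDUES)}
            f = make_cg_frame(500, spec, box=box, seed=trial)
            f.periodic = periodic
            assert count_atp_site_contacts(f) == _brute_force_contacts(f)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        box = np.array([50.0, 50.0, 50.0])
        spec = {r: rng.uniform(10, 40, size=(1, 3)) for r in sorted(ATP_SITE_RESIDUES)}
        f = make_cg_frame(300, spec, box=box, seed=5)
        n0 = count_atp_site_contacts(f)
        shifted = TrajectoryFrame(
            f.coordinates + box * np.array([1.0, -2.0, 3.0]),
            f.bead_kind,
            f.residue_id,
            box=box,
            periodic=True,
        )
        assert count_atp_site_contacts(shifted) == n0

    def test_missing_beads_rejected(self):
        f = _frame([[1, 1, 1]], [(999, (0.0, 0.0, 0.0))])
        with pytest.raises(ValueError):
            count_atp_site_contacts(f)


class TestResidueDistance:
    def test_three_four_five(self):
        f = _frame([], [(721, (0.0, 0.0, 0.0)), (1186, (30.0, 40.0, 0.0))])
        assert residue_distance(f) == pytest.approx(5.0)

    def test_coincident_zero(self):
        f = _frame([], [(721, (5.0, 5.0, 5.0)), (1186, (5.0, 5.0, 5.0))])
        assert residue_distance(f) == 0.0

    def test_matches_image_enumeration(self):
        box = np.array([30.0, 25.0, 20.0])
        a, b = np.array([2.0, 3.0, 1.0]), np.array([28.0, 23.0, 19.0])
        f = _frame([], [(721, a), (1186, b)], box=box, periodic=True)
        images = []
        for i in (-1, 0, 1):
            for j in (-1, 0, 1):
                for k in (-1, 0, 1):
                    images.append(np.linalg.norm(a - (b + box * [i, j, k])))
        assert residue_distance(f) == pytest.approx(min(images) / 10.0)

    def test_centroid_of_multibead_residue(self):
        f = _frame(
            [],
            [(721, (0.0, 0.0, 0.0)), (721, (2.0, 0.0, 0.0)), (1186, (1.0, 40.0, 0.0))],
        )
        assert residue_distance(f) == pytest.approx(4.0)

    def test_missing_residue(self):
        f = _frame([], [(721, (0.0, 0.0, 0.0))])
        with pytest.raises(ValueError, match="1186"):
            residue_distance(f)


class TestWham:
    def test_single_unbiased_window_identities(self):
        """With one unbiased window WHAM reduces to plain histogramming:
        the reweighted mean is the sample mean and the PMF is -ln(hist)."""
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 20_000)
        w = UmbrellaWindow(0.0, 0.0, x)
        res = wham_reweight([w], bins=40, observable=lambda v: v)
        assert res.reweighted_mean == pytest.approx(x.mean(), abs=1e-12)
        hist = np.histogram(x, bins=40)[0]
        p = hist / hist.sum()
        with np.errstate(divide="ignore"):
            pmf = -np.log(p)
        pmf -= pmf.min()
        assert np.allclose(res.pmf, pmf, atol=1e-9)

    def test_constant_observable_reweights_to_itself(self):
        spec = LandscapeSpec(lambda x: 0.5 * x**2, [(-1.0, 5.0), (0.0, 5.0), (1.0, 5.0)],
                             n_steps=20_000, seed=1)
        wins = simulate_langevin_cv(spec)
        res = wham_reweight(wins, bins=50, observable=lambda v: np.full_like(v, 3.25))
        assert res.reweighted_mean == pytest.approx(3.25, abs=1e-9)

    def test_harmonic_well_pmf(self):
        """Five umbrella windows on U = x^2/2 kT recover the quadratic PMF
        to within 0.2 kT over the sampled range."""
        spec = LandscapeSpec(
            lambda x: 0.5 * x**2,
            [(c, 10.0) for c in (-2.0, -1.0, 0.0, 1.0, 2.0)],
            n_steps=60_000,
            seed=2,
        )
        wins = simulate_langevin_cv(spec)
        res = wham_reweight(wins, bins=60)
        sel = np.abs(res.bin_centers) < 1.8
        ref = 0.5 * res.bin_centers**2
        ref = ref - ref[sel].min()
        assert np.max(np.abs(res.pmf[sel] - ref[sel])) < 0.2

    def test_duplicating_samples_leaves_profile_unchanged(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 0.5, 5000)
        w1 = UmbrellaWindow(0.0, 2.0, x)
        w2 = UmbrellaWindow(0.0, 2.0, np.concatenate([x, x]))
        edges = np.linspace(-2, 2, 41)
        r1 = wham_reweight([w1], bins=edges)
        r2 = wham_reweight([w2], bins=edges)
        assert np.allclose(r1.pmf, r2.pmf, atol=1e-9)

    def test_non_overlapping_windows_diagnosed(self):
        w1 = UmbrellaWindow(0.0, 50.0, np.random.default_rng(4).normal(0, 0.05, 500))
        w2 = UmbrellaWindow(10.0, 50.0, np.random.default_rng(5).normal(10, 0.05, 500))
        with pytest.raises(ValueError, match="do not overlap"):
            wham_reweight([w1, w2], bins=100)


class TestBlockStats:
    def test_three_block_example(self):
        est = block_stats([1, 2, 3, 4, 5, 6], n_blocks=3, reducer="mean")
        assert est.block_values.tolist() == [1.5, 3.5, 5.5]
        assert (est.low, est.high) == (1.5, 5.5)
        assert est.value == 3.5

    def test_constant_series_zero_width(self):
        est = block_stats([2.0] * 9, n_blocks=3)
        assert est.low == est.value == est.high == 2.0

    def test_matches_explicit_slicing(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=101)  # remainder goes to the last block
        est = block_stats(x, n_blocks=3, reducer="median")
        manual = [np.median(x[:33]), np.median(x[33:66]), np.median(x[66:])]
        assert np.allclose(est.block_values, manual)
        assert est.low <= est.value <= est.high

    def test_too_short_series(self):
        with pytest.raises(ValueError):
            block_stats([1.0, 2.0], n_blocks=3)


class TestFrameIO:
    def _example(self):
        spec = default_protein_bead_spec([40, 40, 40], seed=1)
        return make_cg_frame(50, spec, box=[40, 40, 40], seed=1)

    def test_gro_round_trip(self, tmp_path):
        f = self._example()
        path = tmp_path / "frame.gro"
        write_gro(f, path)
        g = read_gro(path)
        assert np.allclose(g.coordinates, f.coordinates, atol=0.06)  # 0.001 nm grid
        assert np.array_equal(g.bead_kind, f.bead_kind)
        assert np.array_equal(g.residue_id, f.residue_id)
        assert np.allclose(g.box, f.box)

    def test_gro_readable_by_mdanalysis(self, tmp_path):
        MDAnalysis = pytest.importorskip("MDAnalysis")
        f = self._example()
        path = tmp_path / "frame.gro"
        write_gro(f, path)
        u = MDAnalysis.Universe(str(path))
        assert len(u.atoms) == f.n_beads
        assert np.allclose(u.atoms.positions, f.coordinates, atol=0.06)

    def test_xyz_table_round_trip(self, tmp_path):
        f = self._example()
        path = tmp_path / "frame.tsv"
        write_xyz_table(f, path)
        g = read_xyz_table(path, box=f.box, periodic=True)
        assert np.allclose(g.coordinates, f.coordinates)
        assert count_atp_site_contacts(g) == count_atp_site_contacts(f)
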