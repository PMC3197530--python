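"""Hex lattice: neighbourhoods, boundaries, movement bias, diffusion, placement."""

import numpy as np
import pytest

from melimm.lattice import (
    ChemotaxisParams,
    HexLattice,
    choose_move,
    diffuse_field,
    move_weights,
    neighbors,
    placement_iv,
    placement_tumor_seed,
)


class TestNeighbors:
    def test_interior_site_has_six(self, small_lattice):
        assert len(neighbors((5, 5), small_lattice)) == 6

    def test_top_row_has_four(self, small_lattice):
        assert len(neighbors((0, 5), small_lattice)) == 4
        assert len(neighbors((small_lattice.L - 1, 5), small_lattice)) == 4

    def test_columns_wrap(self, small_lattice):
        L = small_lattice.L
        assert (5, L - 1) in neighbors((5, 0), small_lattice)

    def test_no_vertical_wrap(self, small_lattice):
        L = small_lattice.L
        rows = {r for r, _ in neighbors((0, 3), small_lattice)}
        assert L - 1 not in rows

    def test_symmetry_exhaustive(self):
        lat = HexLattice(8)
        for r in range(8):
            for c in range(8):
                for nb in neighbors((r, c), lat):
                    assert (r, c) in neighbors(nb, lat)

    def test_out_of_lattice_rejected(self, small_lattice):
        with pytest.raises(IndexError):
            neighbors((small_lattice.L, 0), small_lattice)


class TestChooseMove:
    def test_flat_field_is_uniform(self, small_lattice, rng):
        ca = small_lattice.new_field()
        site = small_lattice.flat((5, 5))
        draws = np.array([choose_move(site, small_lattice, ca, 1.0, rng) for _ in range(7000)])
        counts = np.bincount(draws, minlength=small_lattice.n_sites)
        cand = [site] + [int(j) for j in small_lattice.neighbor_table[site]]
        assert counts.sum() == 7000
        for s in cand:
            assert abs(counts[s] - 1000) < 4 * np.sqrt(7000 * (1 / 7) * (6 / 7))

    def test_chemoattractant_neighbour_is_strictly_preferred(self, small_lattice):
        ca = small_lattice.new_field()
        site = small_lattice.flat((5, 5))
        target = int(small_lattice.neighbor_table[site][2])
        ca[target] = 10
        cand, probs = move_weights(site, small_lattice, ca, 1.0)
        assert probs[cand.index(target)] == max(probs)
        assert probs[cand.index(target)] > probs[0]

    def test_probabilities_normalised(self, small_lattice, rng):
        ca = small_lattice.new_field()
        ca[:] = rng.integers(0, 5, size=small_lattice.n_sites)
        _, probs = move_weights(small_lattice.flat((3, 4)), small_lattice, ca, 2.0)
        assert probs.sum() == pytest.approx(1.0)

    def test_gradient_drift_positive_and_boosted_faster(self, rng):
        # fixed CA gradient increasing with row: mean displacement toward the
        # source is positive, and larger for a CD137-boosted sensitivity
        lat = HexLattice(30)
        ca = (np.arange(lat.n_sites) // lat.L).astype(np.int64)  # CA = row index
        chem = ChemotaxisParams()
        start = lat.flat((15, 15))

        def mean_drift(sens, n=10_000):
            drows = np.empty(n)
            for i in range(n):
                dest = choose_move(start, lat, ca, sens, rng)
                drows[i] = dest // lat.L - 15
            return drows.mean()

        base = mean_drift(chem.base_sensitivity)
        boosted = mean_drift(chem.base_sensitivity * chem.cd137_sensitivity_boost)
        assert base > 0
        assert boosted > base


class TestDiffusion:
    def test_zero_fraction_is_identity(self, small_lattice, rng):
        f = small_lattice.new_field()
        f[10] = 50
        assert (diffuse_field(f, small_lattice, 0.0, rng) == f).all()

    def test_total_quanta_conserved(self, rng):
        lat = HexLattice(15)
        f = rng.integers(0, 20, size=lat.n_sites)
        for _ in range(5):
            f = diffuse_field(f, lat, 0.4, rng)
        assert f.sum() == f.sum()  # integer field
        total0 = rng.integers(0, 20, size=lat.n_sites)
        out = diffuse_field(total0.copy(), lat, 0.7, rng)
        assert out.sum() == total0.sum()
        assert (out >= 0).all()

    def test_point_mass_variance_grows_linearly(self, rng):
        lat = HexLattice(61)
        f = lat.new_field()
        center = lat.flat((30, 30))
        f[center] = 200_000
        variances = []
        for t in range(1, 31):
            f = diffuse_field(f, lat, 0.5, rng)
            if t in (10, 20, 30):
                rows = np.arange(lat.n_sites) // lat.L
                p = f / f.sum()
                mu = (p * rows).sum()
                variances.append(((rows - mu) ** 2 * p).sum())
        v10, v20, v30 = variances
        assert v20 / v10 == pytest.approx(2.0, rel=0.15)
        assert v30 / v10 == pytest.approx(3.0, rel=0.15)


class TestPlacement:
    def test_tumor_seed_center_first_connected_and_large_enough(self):
        lat = HexLattice(51)
        sites = placement_tumor_seed(lat, n_cells=1000, site_capacity=8)
        assert sites[0] == lat.flat(lat.center)
        assert len(sites) >= -(-1000 // 8)
        # connectivity: every site after the first touches an earlier one
        placed = {sites[0]}
        for s in sites[1:]:
            assert any(int(j) in placed for j in lat.neighbor_table[s] if j >= 0)
            placed.add(s)

    def test_iv_sites_on_walls_and_balanced(self, rng):
        lat = HexLattice(40)
        sites = placement_iv(lat, 4000, rng)
        rows = np.array(sites) // lat.L
        assert set(np.unique(rows)) <= {0, lat.L - 1}
        n_top = (rows == 0).sum()
        assert abs(n_top - 2000) < 3 * np.sqrt(4000 * 0.25)

    def test_iv_empty(self, rng):
        assert placement_iv(HexLattice(10), 0, rng) == []
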