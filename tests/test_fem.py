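"""Free-energy-map toolkit: I/O, minima, classification, transforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycanmc import (
    BasinSpec,
    FreeEnergyMap,
    area_fraction_below,
    boltzmann_weights,
    circular_distance,
    classify_conformers,
    find_minima,
    fit_axis_shift,
    make_gaussian_fem,
    read_fem,
    transform_map,
    write_fem,
)
from glycanmc.constants import K_B
from glycanmc.fem import MinimumRecord, wrap_angle


def grid_4x4(tmp_path, energies, order=None):
    angles = [-180.0, -90.0, 0.0, 90.0]
    rows = [(a1, a2, energies[i * 4 + j])
            for i, a1 in enumerate(angles) for j, a2 in enumerate(angles)]
    if order is not None:
        rows = [rows[k] for k in order]
    path = tmp_path / "fem.dat"
    path.write_text("# test grid\n" + "\n".join(
        f"{a1} {a2} {e}" for a1, a2, e in rows) + "\n")
    return path


class TestReadWrite:
    def test_enumerated_grid(self, tmp_path):
        path = grid_4x4(tmp_path, list(range(16)))
        fem = read_fem(path)
        assert fem.shape == (4, 4)
        assert fem.step1 == fem.step2 == 90.0
        assert fem.unmasked_energies().min() == 0.0
        assert fem.energy[3, 3] == 15.0

    def test_row_order_irrelevant(self, tmp_path):
        rng = np.random.default_rng(0)
        order = rng.permutation(16)
        a = read_fem(grid_4x4(tmp_path, list(range(16))))
        b = read_fem(grid_4x4(tmp_path, list(range(16)), order=order))
        np.testing.assert_array_equal(a.energy, b.energy)

    def test_zero_to_360_convention_canonicalized(self, tmp_path):
        path = tmp_path / "f.dat"
        rows = [(a1, a2, a1 + a2 / 1000)
                for a1 in (0.0, 90.0, 180.0, 270.0)
                for a2 in (0.0, 90.0, 180.0, 270.0)]
        path.write_text("\n".join(f"{r[0]} {r[1]} {r[2]}" for r in rows))
        fem = read_fem(path)
        assert fem.axis1[0] == -180.0
        assert fem.axis1[-1] == 90.0

    def test_nonfinite_energy_masked(self, tmp_path):
        e = [float(x) for x in range(16)]
        e[5] = float("nan")
        fem = read_fem(grid_4x4(tmp_path, e))
        assert fem.mask.sum() == 1
        assert fem.mask[1, 1]
        # normalization over the remaining bins
        assert fem.unmasked_energies().min() == 0.0

    def test_round_trip(self, tmp_path):
        fem = make_gaussian_fem([BasinSpec((-74, 117), 20, 40)], grid_step=30.0)
        out = tmp_path / "rt.dat"
        write_fem(fem, out)
        back = read_fem(out)
        np.testing.assert_allclose(back.energy[~back.mask],
                                   fem.energy[~fem.mask], atol=1e-9)
        np.testing.assert_array_equal(back.mask, fem.mask)

    def test_irregular_grid_rejected(self, tmp_path):
        path = tmp_path / "bad.dat"
        path.write_text("0 0 1\n10 0 1\n25 0 1\n0 10 1\n10 10 1\n25 10 1\n")
        with pytest.raises(ValueError, match="irregular|period"):
            read_fem(path)

    def test_missing_bins_become_masked(self, tmp_path):
        rows = [f"{a1} {a2} 1.0" for a1 in (-180, -90, 0, 90)
                for a2 in (-180, -90, 0, 90) if not (a1 == 0 and a2 == 0)]
        path = tmp_path / "m.dat"
        path.write_text("\n".join(rows))
        fem = read_fem(path)
        assert fem.mask.sum() == 1


class TestMinima:
    def test_single_well(self):
        fem = make_gaussian_fem([BasinSpec((-74, 117), 20, 20)], grid_step=2.0)
        recs = find_minima(fem)
        assert len(recs) == 1
        assert recs[0].energy == 0.0
        assert circular_distance(recs[0].angle1, -74) <= 1.0
        assert circular_distance(recs[0].angle2, 117) <= 1.0

    def test_three_wells_known_depths(self):
        # wells at the tabulated relative energies 0 / 11.5 / 7.4 kJ/mol
        plateau = 45.0
        fem = make_gaussian_fem(
            [BasinSpec((-74, 117), plateau - 0.0, 18.0),
             BasinSpec((50, 123), plateau - 11.5, 18.0),
             BasinSpec((-59, -36), plateau - 7.4, 18.0)],
            grid_step=2.0, plateau=plateau)
        recs = find_minima(fem)
        assert len(recs) == 3
        got = sorted(r.energy for r in recs)
        # brute-force oracle: depths are analytic up to overlap of the
        # Gaussian tails and half-bin discretization
        assert got[0] == 0.0
        assert got[1] == pytest.approx(7.4, abs=0.5)
        assert got[2] == pytest.approx(11.5, abs=0.5)

    def test_brute_force_neighbourhood_oracle(self):
        fem = make_gaussian_fem(
            [BasinSpec((-100, 40), 25, 22), BasinSpec((80, -120), 18, 22)],
            grid_step=10.0)
        recs = find_minima(fem)
        e = np.where(fem.mask, np.inf, fem.energy)
        n1, n2 = e.shape
        brute = []
        for i in range(n1):
            for j in range(n2):
                neigh = [e[(i + di) % n1, (j + dj) % n2]
                         for di in (-1, 0, 1) for dj in (-1, 0, 1)
                         if (di, dj) != (0, 0)]
                if np.isfinite(e[i, j]) and all(e[i, j] < v for v in neigh):
                    brute.append((fem.axis1[i], fem.axis2[j], e[i, j]))
        assert len(recs) == len(brute) == 2
        for r, (a1, a2, en) in zip(recs, sorted(brute, key=lambda t: t[2])):
            assert (r.angle1, r.angle2, r.energy) == (a1, a2, en)

    def test_flat_map_has_no_strict_minima(self):
        from glycanmc import make_flat_fem
        assert find_minima(make_flat_fem(30.0)) == []

    def test_seam_basin(self):
        fem = make_gaussian_fem([BasinSpec((180, 180), 20, 20)], grid_step=2.0)
        recs = find_minima(fem)
        assert len(recs) == 1
        assert circular_distance(recs[0].angle1, 180) <= 1.0


class TestClassify:
    @pytest.mark.parametrize("minima,expected", [
        # three-state row: main at (-74,117), anti-phi at (50,123), anti-psi at (-59,-36)
        ([(-74, 117, 0.0), (-59, -36, 7.4), (50, 123, 11.5)],
         ["exo-syn", "anti-psi", "anti-phi"]),
        # two-conformer row: main (97,99) and anti-psi (87,-49)
        ([(97, 99, 0.0), (87, -49, 6.3)], ["exo-syn", "anti-psi"]),
        ([(12, 34, 0.0)], ["exo-syn"]),
    ])
    def test_label_assignment(self, minima, expected):
        recs = [MinimumRecord(*m) for m in minima]
        labels = [r.label for r in classify_conformers(recs)]
        assert labels == expected

    def test_all_tabulated_rows(self):
        from glycanmc import table1_fixture
        for fx in table1_fixture():
            recs = [MinimumRecord(m.angle1, m.angle2, m.energy)
                    for m in sorted(fx.minima, key=lambda m: m.energy)
                    if m.is_minimum]
            labels = {(r.angle1, r.angle2): r.label
                      for r in classify_conformers(recs)}
            for m in fx.minima:
                if m.is_minimum:
                    assert labels[(m.angle1, m.angle2)] == m.label, \
                        (fx.force_field, fx.linkage)


class TestAreaFraction:
    def test_two_level_map(self):
        fem = FreeEnergyMap([-180.0, 0.0], [-180.0], [[0.0], [10.0]])
        assert area_fraction_below(fem, 5.0) == 0.5
        assert area_fraction_below(fem, -1.0) == 0.0

    def test_flat_map(self):
        from glycanmc import make_flat_fem
        fem = make_flat_fem(30.0)
        assert area_fraction_below(fem, 0.0) == 1.0

    def test_gaussian_well_vs_ellipse_area(self):
        depth, sigma = 30.0, 30.0
        fem = make_gaussian_fem([BasinSpec((0, 0), depth, sigma)],
                                grid_step=1.0, plateau=depth)
        t = 10.0
        # region with E <= t is the disc d^2 <= 2 sigma^2 ln(depth/(depth-t))
        r2 = 2 * sigma ** 2 * np.log(depth / (depth - t))
        expected = np.pi * r2 / 360.0 ** 2
        assert area_fraction_below(fem, t) == pytest.approx(expected, rel=0.02)

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(0, 40), min_size=2, max_size=6).map(sorted))
    def test_monotone_in_threshold(self, thresholds):
        fem = make_gaussian_fem([BasinSpec((0, 0), 20, 30)], grid_step=15.0)
        fractions = [area_fraction_below(fem, t) for t in thresholds]
        assert fractions == sorted(fractions)
        assert area_fraction_below(fem, 1e9) == 1.0


class TestAxisShift:
    def test_exact_shift(self):
        src = np.linspace(-170, 170, 30)
        assert fit_axis_shift(src, wrap_angle(src + 120)) == pytest.approx(120, abs=1e-6)

    def test_noisy_shift_near_seam(self):
        rng = np.random.default_rng(42)
        src = rng.uniform(-180, 180, 500)
        tgt = wrap_angle(src - 170 + rng.normal(0, 5, src.size))
        # oracle: circular mean of the wrapped pairwise differences
        d = np.radians(wrap_angle(tgt - src))
        oracle = np.degrees(np.arctan2(np.sin(d).mean(), np.cos(d).mean()))
        s = fit_axis_shift(src, tgt)
        assert s == pytest.approx(-170, abs=1.0)
        assert s == pytest.approx(oracle, abs=0.5)

    def test_wraparound_exact(self):
        src = np.linspace(100, 250, 40)  # straddles the +180 seam after shift
        tgt = wrap_angle(src + 175)
        assert fit_axis_shift(src, tgt) == pytest.approx(175, abs=1e-6)


class TestTransform:
    def test_identity_and_full_period(self, three_basin_map):
        fem = three_basin_map
        for s1, s2 in [(0.0, 0.0), (360.0, 360.0), (360.0, 0.0)]:
            out = transform_map(fem, s1, s2)
            np.testing.assert_array_equal(out.energy, fem.energy)

    def test_quarter_turn_on_4x4(self):
        energy = np.arange(16, dtype=float).reshape(4, 4)
        axes = np.array([-180.0, -90.0, 0.0, 90.0])
        fem = FreeEnergyMap(axes, axes.copy(), energy)
        out = transform_map(fem, 90.0, 0.0)
        # brute-force index arithmetic: E'(i) = E(i-1 mod 4)
        for i in range(4):
            for j in range(4):
                assert out.energy[i, j] == energy[(i - 1) % 4, j]

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(-5, 5), st.integers(-5, 5))
    def test_energy_multiset_preserved(self, k1, k2):
        fem = make_gaussian_fem([BasinSpec((10, -40), 20, 35)], grid_step=24.0)
        out = transform_map(fem, k1 * 24.0, k2 * 24.0)
        np.testing.assert_allclose(np.sort(out.energy.ravel()),
                                   np.sort(fem.energy.ravel()))


class TestBoltzmann:
    def test_closed_forms(self):
        T = 298.0
        fem = FreeEnergyMap([-180.0, 0.0], [-180.0],
                            [[0.0], [K_B * T * np.log(2.0)]])
        w = boltzmann_weights(fem, T)
        np.testing.assert_allclose(w.ravel(), [2 / 3, 1 / 3], atol=1e-12)

    def test_flat_uniform(self):
        from glycanmc import make_flat_fem
        fem = make_flat_fem(45.0)
        w = boltzmann_weights(fem)
        np.testing.assert_allclose(w, 1.0 / fem.n_bins)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_three_level_ground_population(self):
        fem = FreeEnergyMap([-180.0, -60.0, 60.0], [-180.0],
                            [[0.0], [7.4], [11.5]])
        w = boltzmann_weights(fem, 298.0)
        assert w.ravel()[0] == pytest.approx(0.943, abs=0.001)
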