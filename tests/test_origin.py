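import numpy as np
import pytest

from rangexp.genotypes import SampleInfo
from rangexp.origin import (Grid, geodesic_distance, make_grid, origin_scan,
                            tdoa_fit_at)
from rangexp.origin import test_expansion_vs_ibd as expansion_vs_ibd
from rangexp.selection import ConfigurationError
from rangexp.simulate import plant_linear_psi

# scattered, non-collinear populations around central Australia
POP_COORDS = {
    "p0": (-24.0, 127.0), "p1": (-23.2, 128.1), "p2": (-25.1, 128.7),
    "p3": (-22.6, 126.2), "p4": (-25.8, 126.5), "p5": (-23.9, 129.6),
    "p6": (-22.1, 129.0), "p7": (-26.0, 130.1), "p8": (-24.6, 125.4),
    "p9": (-21.9, 127.6),
}


def info_from_coords(coords):
    return [SampleInfo(f"{p}_s0", p, lat, lon, "diploid", "ingroup")
            for p, (lat, lon) in coords.items()]


class TestGeodesic:
    def test_quarter_great_circle(self):
        assert geodesic_distance((0, 0), (0, 90)) == pytest.approx(10007.543, abs=0.1)

    def test_identity(self):
        assert geodesic_distance((-24.3, 131.2), (-24.3, 131.2)) == 0.0

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(-80, 80, 3000),
                               rng.uniform(-180, 180, 3000)]).reshape(1000, 3, 2)
        for a, b, c in pts:
            dab = geodesic_distance(a, b)
            assert dab == pytest.approx(geodesic_distance(b, a), abs=1e-9)
            assert dab <= geodesic_distance(a, c) + geodesic_distance(c, b) + 1e-6

    def test_invalid_latitude(self):
        with pytest.raises(ValueError):
            geodesic_distance((95, 0), (0, 0))


class TestMakeGrid:
    def _info(self, lat_span=10.0, lon_span=20.0):
        coords = {"a": (-30.0, 120.0), "b": (-30.0 + lat_span, 120.0 + lon_span)}
        return info_from_coords(coords)

    def test_padding_half_doubles_box(self):
        g = make_grid(self._info(), spacing_deg=0.5, padding_fraction=0.5)
        lat_min, lat_max, lon_min, lon_max = g.bbox
        assert (lat_max - lat_min) == pytest.approx(20.0)
        assert (lon_max - lon_min) == pytest.approx(40.0)
        # centered on the original box
        assert (lat_min + lat_max) / 2 == pytest.approx(-25.0)
        assert (lon_min + lon_max) / 2 == pytest.approx(130.0)

    def test_padding_zero_is_sample_bbox(self):
        g = make_grid(self._info(), spacing_deg=0.5, padding_fraction=0.0)
        assert g.bbox == (-30.0, -20.0, 120.0, 140.0)

    def test_spacing_larger_than_span(self):
        g = make_grid(self._info(lat_span=0.5, lon_span=0.5), spacing_deg=5.0,
                      padding_fraction=0.0)
        assert g.shape == (1, 1)

    def test_degenerate_extent(self):
        info = info_from_coords({"a": (-30.0, 120.0), "b": (-30.0, 120.0)})
        with pytest.raises(ConfigurationError, match="degenerate"):
            make_grid(info)

    def test_clipped_to_valid_coordinates(self):
        info = info_from_coords({"a": (-89.0, 0.0), "b": (-80.0, 10.0)})
        g = make_grid(info, spacing_deg=1.0, padding_fraction=1.0)
        assert g.bbox[0] >= -90.0


class TestTdoaFit:
    def test_planted_linear_exact(self):
        origin = (-24.1, 127.3)
        psi = plant_linear_psi(POP_COORDS, origin, slope=1e-3, noise_sd=0.0)
        info = info_from_coords(POP_COORDS)
        slope, rss, r2 = tdoa_fit_at(origin, psi, info)
        assert slope == pytest.approx(1e-3, rel=1e-9)
        assert rss == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_zero_psi_flat_surface(self):
        psi = plant_linear_psi(POP_COORDS, (-24, 127), slope=0.0, noise_sd=0.0)
        info = info_from_coords(POP_COORDS)
        slope, rss, r2 = tdoa_fit_at((-23.0, 126.0), psi, info)
        assert slope == 0.0 and rss == 0.0

    def test_closed_form_three_pair_slope(self):
        # DERIVED: slope = sum(psi * dd) / sum(dd^2) by hand
        coords = {"a": (0.0, 0.0), "b": (0.0, 1.0), "c": (1.0, 0.5)}
        info = info_from_coords(coords)
        origin = (0.0, -1.0)
        from rangexp.directionality import PsiMatrix
        psi_vals = {("a", "b"): 0.2, ("a", "c"): 0.1, ("b", "c"): -0.05}
        pops = list(coords)
        mat = np.zeros((3, 3))
        for (x, y), v in psi_vals.items():
            i, j = pops.index(x), pops.index(y)
            mat[i, j], mat[j, i] = v, -v
        psi = PsiMatrix(pops, mat, np.zeros((3, 3)), np.full((3, 3), 10), m=2)
        d = {p: geodesic_distance(origin, coords[p]) for p in pops}
        dd = np.array([d["b"] - d["a"], d["c"] - d["a"], d["c"] - d["b"]])
        pv = np.array([0.2, 0.1, -0.05])
        expected = float(pv @ dd / (dd @ dd))
        slope, rss, r2 = tdoa_fit_at(origin, psi, info)
        assert slope == pytest.approx(expected, rel=1e-12)

    def test_too_few_pairs(self):
        coords = {k: POP_COORDS[k] for k in ("p0", "p1")}
        psi = plant_linear_psi(coords, (-24, 127), slope=1e-3)
        with pytest.raises(ConfigurationError):
            tdoa_fit_at((-24, 127), psi, info_from_coords(coords))


class TestOriginScan:
    def test_planted_origin_recovered(self):
        # DERIVED: exhaustive scan on a coarse grid finds the planted cell
        origin = (-24.0, 127.5)
        psi = plant_linear_psi(POP_COORDS, origin, slope=1e-3, noise_sd=0.0)
        info = info_from_coords(POP_COORDS)
        grid = make_grid(info, spacing_deg=0.25, padding_fraction=0.5)
        surf = origin_scan(psi, info, grid)
        assert abs(surf.best_cell[0] - origin[0]) <= grid.spacing_deg / 2 + 1e-9
        assert abs(surf.best_cell[1] - origin[1]) <= grid.spacing_deg / 2 + 1e-9
        assert surf.slope > 0
        assert not surf.boundary_flag

    def test_origin_outside_padded_box_flags_boundary(self):
        origin = (-40.0, 110.0)  # far outside the padded area
        psi = plant_linear_psi(POP_COORDS, origin, slope=1e-3, noise_sd=0.0)
        info = info_from_coords(POP_COORDS)
        grid = make_grid(info, spacing_deg=0.25, padding_fraction=0.2)
        surf = origin_scan(psi, info, grid)
        assert surf.boundary_flag

    def test_symmetric_zero_psi_ties(self):
        coords = {"a": (0.0, -1.0), "b": (0.0, 1.0), "c": (1.0, 0.0), "d": (-1.0, 0.0)}
        psi = plant_linear_psi(coords, (0.0, 0.0), slope=0.0, noise_sd=0.0)
        info = info_from_coords(coords)
        grid = make_grid(info, spacing_deg=1.0, padding_fraction=0.0)
        surf = origin_scan(psi, info, grid)
        assert surf.tie_flag

    def test_best_cell_attains_min_rss_among_positive_slopes(self):
        psi = plant_linear_psi(POP_COORDS, (-24.0, 127.5), slope=1e-3,
                               noise_sd=0.02, seed=5)
        info = info_from_coords(POP_COORDS)
        grid = make_grid(info, spacing_deg=0.5, padding_fraction=0.5)
        surf = origin_scan(psi, info, grid)
        pos = surf.slopes > 0
        assert surf.rss[surf.best_index] == surf.rss[pos].min()

    def test_surface_export_shape(self):
        psi = plant_linear_psi(POP_COORDS, (-24.0, 127.5), slope=1e-3)
        info = info_from_coords(POP_COORDS)
        grid = make_grid(info, spacing_deg=0.5, padding_fraction=0.5)
        surf = origin_scan(psi, info, grid)
        df = surf.to_frame()
        assert len(df) == grid.n_cells
        assert list(df.columns) == ["lat", "lon", "rss", "r2", "slope"]


class TestExpansionVsIbd:
    def test_planted_linear_significant(self):
        psi = plant_linear_psi(POP_COORDS, (-24.0, 127.5), slope=1e-3, noise_sd=0.0)
        info = info_from_coords(POP_COORDS)
        grid = make_grid(info, spacing_deg=0.5, padding_fraction=0.5)
        p = expansion_vs_ibd(psi, info, grid, n_perm=999, seed=1)
        assert p <= 0.01

    def test_zero_psi_not_significant(self):
        psi = plant_linear_psi(POP_COORDS, (-24.0, 127.5), slope=0.0, noise_sd=0.0)
        info = info_from_coords(POP_COORDS)
        grid = make_grid(info, spacing_deg=0.5, padding_fraction=0.5)
        p = expansion_vs_ibd(psi, info, grid, n_perm=99, seed=1)
        assert p > 0.5

    def test_relabeling_invariance(self):
        info = info_from_coords(POP_COORDS)
        psi = plant_linear_psi(POP_COORDS, (-24.0, 127.5), slope=5e-4,
                               noise_sd=0.05, seed=2)
        grid = make_grid(info, spacing_deg=0.5, padding_fraction=0.5)
        p1 = expansion_vs_ibd(psi, info, grid, n_perm=199, seed=3)

        perm = np.random.default_rng(0).permutation(len(psi.populations))
        from rangexp.directionality import PsiMatrix
        psi2 = PsiMatrix([psi.populations[i] for i in perm],
                         psi.psi[np.ix_(perm, perm)], psi.se[np.ix_(perm, perm)],
                         psi.n_informative[np.ix_(perm, perm)], m=psi.m)
        info2 = [info[i] for i in perm]
        p2 = expansion_vs_ibd(psi2, info2, grid, n_perm=199, seed=3)
        assert p1 == p2

    def test_n_perm_minimum(self):
        psi = plant_linear_psi(POP_COORDS, (-24.0, 127.5), slope=1e-3)
        info = info_from_coords(POP_COORDS)
        grid = make_grid(info, spacing_deg=0.5, padding_fraction=0.5)
        with pytest.raises(ConfigurationError):
            expansion_vs_ibd(psi, info, grid, n_perm=50, seed=0)

    def test_underpowered_warning(self, caplog):
        coords = {k: POP_COORDS[k] for k in ("p0", "p1", "p2")}
        psi = plant_linear_psi(coords, (-24.0, 127.5), slope=1e-3)
        info = info_from_coords(coords)
        grid = make_grid(info, spacing_deg=0.5, padding_fraction=0.5)
        import logging
        with caplog.at_level(logging.WARNING, logger="rangexp"):
            expansion_vs_ibd(psi, info, grid, n_perm=99, seed=0)
        assert any("underpowered" in r.message for r in caplog.records)
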