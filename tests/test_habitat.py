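"""Raster I/O and circular-buffer composition extraction."""

import numpy as np
import pandas as pd
import pytest

from stopover_rsf.geo import haversine_km
from stopover_rsf.habitat import (
    EmptyCompositionError,
    GLOBCOVER_LEGEND,
    LandCoverRaster,
    buffer_sweep_radii,
    composition_table,
    extract_composition,
)


def uniform_raster(code=14, n=40, cellsize=0.01, xll=0.0, yll=45.0):
    return LandCoverRaster(np.full((n, n), code, dtype=np.int16), xll, yll, cellsize)


class TestRasterBasics:
    def test_ascii_round_trip(self, tmp_path, rng):
        codes = np.array(sorted(GLOBCOVER_LEGEND))
        data = rng.choice(codes, size=(30, 20)).astype(np.int16)
        r = LandCoverRaster(data, xll=3.5, yll=47.25, cellsize=0.02)
        r.write_ascii(tmp_path / "r.asc", tmp_path / "legend.json")
        back = LandCoverRaster.read_ascii(tmp_path / "r.asc", tmp_path / "legend.json")
        assert np.array_equal(back.data, r.data)
        assert back.xll == r.xll and back.yll == r.yll and back.cellsize == r.cellsize
        assert back.legend == r.legend

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            LandCoverRaster(np.array([[1, 2]]), 0.0, 0.0, 0.1)


class TestExtractComposition:
    def test_uniform_raster_is_all_one_class(self):
        comp = extract_composition(uniform_raster(code=14), 0.2, 45.2, 0.1)
        assert comp.percentages[14] == pytest.approx(100.0)
        assert sum(comp.percentages.values()) == pytest.approx(100.0)
        assert all(v == 0.0 for c, v in comp.percentages.items() if c != 14)

    def test_half_plane_split_is_fifty_fifty(self):
        n = 200
        data = np.full((n, n), 14, dtype=np.int16)
        data[:, n // 2:] = 50  # east half forest
        r = LandCoverRaster(data, 0.0, 45.0, 0.01)
        comp = extract_composition(r, 1.0, 46.0, 0.5)  # centred on the split
        quantum = 100.0 / comp.n_valid * (2 * 0.5 / 0.01)  # one cell column
        assert comp.percentages[14] == pytest.approx(50.0, abs=quantum)
        assert comp.percentages[50] == pytest.approx(50.0, abs=quantum)

    @pytest.mark.parametrize("unit,radius", [("deg", 0.07), ("m", 7000.0)])
    def test_matches_exhaustive_cell_loop(self, rng, unit, radius):
        codes = np.array(sorted(GLOBCOVER_LEGEND))
        data = rng.choice(codes, size=(60, 60)).astype(np.int16)
        r = LandCoverRaster(data, xll=10.0, yll=50.0, cellsize=0.01)
        lon, lat = 10.31, 50.29
        comp = extract_composition(r, lon, lat, radius, unit=unit)
        # independent oracle: loop over every cell centre
        counts = {int(c): 0 for c in codes}
        n_inside = 0
        for row in range(60):
            for col in range(60):
                clon = 10.0 + (col + 0.5) * 0.01
                clat = 50.0 + (60 - 1 - row + 0.5) * 0.01
                if unit == "deg":
                    inside = (clon - lon) ** 2 + (clat - lat) ** 2 <= radius**2
                else:
                    inside = haversine_km(clon, clat, lon, lat) * 1000.0 <= radius
                if inside:
                    counts[int(data[row, col])] += 1
                    n_inside += 1
        assert comp.n_valid == n_inside
        for c in codes:
            assert comp.percentages[int(c)] == pytest.approx(100.0 * counts[int(c)] / n_inside, abs=1e-9)

    def test_nodata_cells_excluded(self):
        data = np.full((40, 40), 14, dtype=np.int16)
        data[:20] = 255
        r = LandCoverRaster(data, 0.0, 45.0, 0.01, nodata=255)
        comp = extract_composition(r, 0.2, 45.2, 0.15)
        assert comp.n_nodata > 0
        assert comp.percentages[14] == pytest.approx(100.0)

    def test_buffer_outside_raster_raises(self):
        with pytest.raises(EmptyCompositionError):
            extract_composition(uniform_raster(), 30.0, 45.2, 0.1)

    def test_all_nodata_raises(self):
        data = np.full((40, 40), 255, dtype=np.int16)
        r = LandCoverRaster(data, 0.0, 45.0, 0.01, nodata=255)
        with pytest.raises(EmptyCompositionError):
            extract_composition(r, 0.2, 45.2, 0.1)

    def test_large_buffers_converge_to_regional_mixture(self, rng):
        # closure/nesting: as the radius grows the composition approaches
        # the raster-wide mixture (L1 distance shrinks)
        codes = np.array([14, 50])
        data = rng.choice(codes, size=(400, 400)).astype(np.int16)
        r = LandCoverRaster(data, 0.0, 40.0, 0.01)
        target = {c: 100.0 * np.mean(data == c) for c in codes}
        l1 = []
        for radius in (0.2, 0.8, 1.9):
            comp = extract_composition(r, 2.0, 42.0, radius)
            l1.append(sum(abs(comp.percentages[int(c)] - target[int(c)]) for c in codes))
        assert l1[0] > l1[-1]


class TestBufferSweepRadii:
    def test_default_ladder_has_fourteen_radii(self):
        radii = buffer_sweep_radii(1500, 1500, 21000)
        assert len(radii) == 14
        assert radii[0] == 1500 and radii[-1] == 21000

    def test_degenerate_and_coarse_ladders(self):
        assert buffer_sweep_radii(1500, 1500, 1500) == [1500]
        assert buffer_sweep_radii(1000, 2000, 9000) == [1000, 3000, 5000, 7000, 9000]

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValueError):
            buffer_sweep_radii(0, 1500, 21000)


class TestCompositionTable:
    def _points(self):
        pts = [{"point_id": "use-0", "bird_id": "B01", "label": "use", "replicate": 0, "lon": 0.2, "lat": 45.2}]
        pts += [
            {"point_id": f"av-{i}", "bird_id": "B01", "label": "available", "replicate": 1 + i // 2,
             "lon": 0.15 + 0.01 * i, "lat": 45.15 + 0.01 * i}
            for i in range(8)
        ]
        return pts

    def test_rows_and_closure(self):
        df = composition_table(self._points(), uniform_raster(), 0.1)
        assert len(df) == 9
        class_cols = [c for c in df.columns if c in set(GLOBCOVER_LEGEND.values())]
        assert np.allclose(df[class_cols].sum(axis=1), 100.0)

    def test_two_radii_share_row_keys(self):
        r = uniform_raster()
        a = composition_table(self._points(), r, 0.05)
        b = composition_table(self._points(), r, 0.1)
        assert list(a["point_id"]) == list(b["point_id"])

    def test_error_names_offending_point(self):
        pts = self._points()
        pts.append({"point_id": "av-bad", "bird_id": "B01", "label": "available", "replicate": 4,
                    "lon": 50.0, "lat": 45.0})
        with pytest.raises(EmptyCompositionError, match="av-bad"):
            composition_table(pts, uniform_raster(), 0.1)

    def test_cropland_declines_eastwards_in_synthetic_world(self, demo_world):
        # the generated west-east gradient must show up in buffer compositions
        cfg, raster, fixes, truths = demo_world
        lons = np.linspace(0.0, 95.0, 24)
        crop = []
        for lon in lons:
            # buffers wide enough to average over several intensity regions
            comp = extract_composition(raster, lon, 51.0, 1.5)
            crop.append(comp.percentages[14] + comp.percentages[11])
        rho = pd.Series(crop).corr(pd.Series(lons), method="spearman")
        assert rho < -0.5
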