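import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diskfret.geometry import (
    ChromophoreSet,
    CoupledDiskGeometry,
    GeometryError,
    PathwayTable,
    RingArraySpec,
    build_disk,
    couple_disks,
    modified_monomer_count,
    pathway_table,
    rate_fold_change,
    ring_radius,
)


class TestRingRadius:
    @pytest.mark.parametrize(
        "n, s, expected",
        [
            (17, 1.95, 5.306),  # chord inversion of the intra-disk spacing
            (6, 1.3, 1.3),      # regular hexagon: radius equals side
            (4, 2.0, 2.0 / math.sqrt(2)),
        ],
    )
    def test_closed_form(self, n, s, expected):
        assert ring_radius(n, s) == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize("n, s", [(1, 1.0), (0, 1.0), (5, 0.0), (5, -2.0)])
    def test_invalid_spec(self, n, s):
        with pytest.raises(GeometryError):
            ring_radius(n, s)

    @pytest.mark.parametrize("n", [2, 3, 7, 17, 40])
    def test_generated_points_realize_spacing(self, n):
        # oracle: place points at the computed radius and measure the
        # adjacent-site chords directly
        spec = RingArraySpec(n, 1.95, 1, 0.0)
        disk = build_disk(spec)
        pts = disk.coordinates
        chords = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
        assert np.allclose(chords, 1.95, atol=1e-6)


class TestBuildDisk:
    def test_double_disk_site_count(self):
        disk = build_disk(RingArraySpec(17, 1.95, 2, 2.5))
        assert len(disk) == 34

    def test_single_ring_equidistant_from_center(self):
        spec = RingArraySpec(11, 1.4, 1, 0.0)
        disk = build_disk(spec, center=(0.0, 0.0, 0.0))
        r = np.linalg.norm(disk.coordinates, axis=1)
        assert np.allclose(r, spec.radius, atol=1e-9)

    def test_layers_equidistant_from_axis(self):
        spec = RingArraySpec(17, 1.95, 2, 2.5)
        disk = build_disk(spec)
        axial_r = np.linalg.norm(disk.coordinates[:, :2], axis=1)
        assert np.allclose(axial_r, spec.radius, atol=1e-9)

    def test_degenerate_layer_separation_collapses_layers(self):
        disk = build_disk(RingArraySpec(17, 1.95, 2, 0.0, azimuthal_offset=0.0))
        assert np.allclose(disk.coordinates[:17], disk.coordinates[17:])

    def test_reference_azimuth_aligns_first_site(self):
        disk = build_disk(RingArraySpec(9, 1.0, 1, 0.0), reference_azimuth=0.0)
        first = disk.coordinates[0]
        assert first[1] == pytest.approx(0.0, abs=1e-12)
        assert first[0] == pytest.approx(ring_radius(9, 1.0))


class TestCoupleDisks:
    def test_default_model_center_separation(self):
        spec = RingArraySpec(17, 1.95, 2, 2.5)
        geom = couple_disks(spec, spec, closest_pair=7.5)
        assert geom.center_separation == pytest.approx(7.5 + 2 * spec.radius, abs=1e-3)
        assert geom.center_separation == pytest.approx(18.11, abs=0.01)

    def test_minimum_distance_is_calibrated(self):
        spec = RingArraySpec(17, 1.95, 2, 2.5)
        geom = couple_disks(spec, spec, closest_pair=7.5)
        # brute force over all pairs
        assert geom.min_distance == pytest.approx(7.5, abs=1e-6)
        assert (geom.distances() >= 7.5 - 1e-6).all()

    def test_furthest_pair_rounds_to_29_nm(self):
        spec = RingArraySpec(17, 1.95, 2, 2.5)
        geom = couple_disks(spec, spec, closest_pair=7.5)
        assert round(geom.max_distance) == 29

    def test_two_site_disks_calibrate_exactly(self):
        spec = RingArraySpec(2, 1.0, 1, 0.0)
        geom = couple_disks(spec, spec, closest_pair=7.5)
        assert geom.min_distance == pytest.approx(7.5, abs=1e-9)

    def test_invalid_closest_pair(self):
        spec = RingArraySpec(17, 1.95, 2, 2.5)
        with pytest.raises(GeometryError):
            couple_disks(spec, spec, closest_pair=-1.0)

    @settings(deadline=None, max_examples=30)
    @given(
        n=st.integers(2, 25),
        s=st.floats(0.5, 5.0),
        layers=st.integers(1, 2),
        sep=st.floats(0.0, 5.0),
        closest=st.floats(1.0, 20.0),
    )
    def test_calibration_property(self, n, s, layers, sep, closest):
        spec = RingArraySpec(n, s, layers, sep)
        geom = couple_disks(spec, spec, closest_pair=closest)
        assert geom.min_distance == pytest.approx(closest, abs=1e-6)

    def test_export_roundtrip(self, tmp_path):
        import pandas as pd

        spec = RingArraySpec(5, 1.0, 2, 1.0)
        geom = couple_disks(spec, spec, closest_pair=3.0)
        path = tmp_path / "coords.tsv"
        geom.export(path)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 20
        assert set(df["disk_label"]) == {"donor", "acceptor"}


def _fake_geometry(donor_pts, acceptor_pts):
    def mk(pts, label):
        pts = np.asarray(pts, dtype=float)
        return ChromophoreSet(
            coordinates=pts,
            disk_label=label,
            layer_index=np.zeros(len(pts), dtype=int),
            site_index=np.arange(len(pts)),
        )

    d, a = mk(donor_pts, "donor"), mk(acceptor_pts, "acceptor")
    return CoupledDiskGeometry(d, a, center_separation=0.0, closest_pair=0.0)


class TestPathwayTable:
    def test_equal_distances_give_uniform_weights(self):
        # one donor site, acceptors on a sphere of radius 5
        ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        acc = np.column_stack([5 * np.cos(ang), 5 * np.sin(ang), np.zeros(8)])
        geom = _fake_geometry([[0, 0, 0]], acc)
        table = pathway_table(geom)
        assert np.allclose(table.weights, 1 / 8, atol=1e-12)

    def test_two_pair_analytic_ratio(self):
        geom = _fake_geometry([[0, 0, 0]], [[2.0, 0, 0], [4.0, 0, 0]])
        table = pathway_table(geom)
        assert table.weights[0] == pytest.approx(64 / 65, rel=1e-12)
        assert table.weights[1] == pytest.approx(1 / 65, rel=1e-12)

    def test_full_coupled_model_max_weight_below_12_pct(self):
        spec = RingArraySpec(17, 1.95, 2, 2.5)
        geom = couple_disks(spec, spec, closest_pair=7.5)
        table = pathway_table(geom)
        assert len(table) == 34 * 34
        assert table.max_weight <= 0.12

    def test_top_k_renormalizes(self):
        spec = RingArraySpec(17, 1.95, 2, 2.5)
        geom = couple_disks(spec, spec, closest_pair=7.5)
        table = pathway_table(geom, top_k=25)
        assert len(table) == 25
        assert table.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert table.max_weight <= 0.12

    def test_top_k_out_of_range(self):
        spec = RingArraySpec(3, 1.0, 1, 0.0)
        geom = couple_disks(spec, spec, closest_pair=2.0)
        with pytest.raises(GeometryError):
            pathway_table(geom, top_k=10)

    @settings(deadline=None, max_examples=30)
    @given(
        n=st.integers(2, 20),
        s=st.floats(0.5, 4.0),
        layers=st.integers(1, 2),
        closest=st.floats(1.0, 15.0),
    )
    def test_weights_normalized_and_monotone(self, n, s, layers, closest):
        spec = RingArraySpec(n, s, layers, 2.0)
        geom = couple_disks(spec, spec, closest_pair=closest)
        table = pathway_table(geom)
        w, r = table.weights, table.distances
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert (w >= 0).all()
        assert (np.diff(r) >= -1e-12).all()  # sorted ascending by distance
        assert (np.diff(w) <= 1e-15).all()   # weights non-increasing
        # strictly decreasing wherever the distance strictly increases
        strict = np.diff(r) > 1e-9
        assert (np.diff(w)[strict] < 0).all()

    def test_export(self, tmp_path):
        import pandas as pd

        geom = _fake_geometry([[0, 0, 0]], [[2.0, 0, 0], [4.0, 0, 0]])
        path = tmp_path / "pathways.tsv"
        pathway_table(geom).export(path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["donor_idx", "acceptor_idx", "R_nm", "weight"]
        assert (df["R_nm"].diff().dropna() >= 0).all()

    def test_invalid_table_rejected(self):
        import pandas as pd

        with pytest.raises(GeometryError):
            PathwayTable(pd.DataFrame({"R_nm": [1.0]}))


class TestRateFoldChange:
    def test_printed_bound(self):
        fold = rate_fold_change(7.5, 3.0)
        assert fold == pytest.approx(244.1, abs=0.1)
        assert fold > 200

    @pytest.mark.parametrize("a, b, expected", [(3.0, 3.0, 1.0), (2.0, 1.0, 64.0)])
    def test_simple_cases(self, a, b, expected):
        assert rate_fold_change(a, b) == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        a=st.floats(0.5, 30.0),
        b=st.floats(0.5, 30.0),
        c=st.floats(0.5, 30.0),
    )
    def test_multiplicative_chain(self, a, b, c):
        lhs = rate_fold_change(a, b) * rate_fold_change(b, c)
        assert lhs == pytest.approx(rate_fold_change(a, c), rel=1e-9)

    def test_nonpositive_distance(self):
        with pytest.raises(GeometryError):
            rate_fold_change(0.0, 1.0)


class TestModifiedMonomerCount:
    def test_31_pct_of_34(self):
        exact, nearest = modified_monomer_count(0.31, 34)
        assert exact == pytest.approx(10.54, abs=1e-9)
        assert round(exact, 1) == 10.5

    def test_91_pct_of_34(self):
        exact, nearest = modified_monomer_count(0.91, 34)
        assert nearest == 31

    def test_zero_fraction(self):
        assert modified_monomer_count(0.0, 34) == (0.0, 0)

    @pytest.mark.parametrize("frac", [-0.1, 1.5])
    def test_out_of_range(self, frac):
        with pytest.raises(GeometryError):
            modified_monomer_count(frac, 34)
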