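"""Container invariants and file round-trips for every supported format."""

import numpy as np
import pandas as pd
import pytest

import railphen as rp
from railphen.cloudio import CloudIOError

from conftest import random_cloud


class TestPointCloud:
    def test_rejects_non_finite_coordinates(self):
        with pytest.raises(ValueError, match="non-finite"):
            rp.PointCloud([[0, 0, np.nan]])

    def test_rejects_out_of_range_intensity(self):
        with pytest.raises(ValueError, match="intensity"):
            rp.PointCloud([[0, 0, 0]], intensity=[1.5])

    def test_subset_and_concat_preserve_aux(self, rng):
        c = random_cloud(rng, 10)
        c.aux["frame"] = np.arange(10)
        sub = c.subset(np.array([3, 1, 7]))
        assert list(sub.aux["frame"]) == [3, 1, 7]
        cat = rp.PointCloud.concat([sub, sub])
        assert len(cat) == 6 and list(cat.aux["frame"]) == [3, 1, 7, 3, 1, 7]


class TestReadWriteCloud:
    def test_xyz_literal_three_points(self, tmp_path):
        p = tmp_path / "tri.xyz"
        p.write_text("0 0 0\n1 0 0\n0 1 0\n")
        cloud = rp.read_cloud(p)
        assert np.array_equal(cloud.xyz, [[0, 0, 0], [1, 0, 0], [0, 1, 0]])

    @pytest.mark.parametrize("fmt,tol", [("ply", 1e-6), ("ply_binary", 0.0),
                                         ("xyz", 1e-6), ("csv", 1e-6)])
    def test_round_trip_random_clouds(self, tmp_path, rng, fmt, tol):
        # order, coordinates and intensity survive 100 random clouds
        ext = {"ply": ".ply", "ply_binary": ".ply", "xyz": ".xyz", "csv": ".csv"}[fmt]
        for i in range(100):
            cloud = random_cloud(rng, int(rng.integers(1, 40)))
            p = tmp_path / f"c{i}{ext}"
            rp.write_cloud(cloud, p, fmt)
            back = rp.read_cloud(p)
            if tol == 0.0:
                assert np.array_equal(back.xyz, cloud.xyz)
                assert np.array_equal(back.intensity, cloud.intensity)
            else:
                assert np.allclose(back.xyz, cloud.xyz, atol=tol)
                assert np.allclose(back.intensity, cloud.intensity, atol=1e-6)

    def test_ascii_and_binary_ply_agree(self, tmp_path, rng):
        cloud = random_cloud(rng, 25)
        rp.write_cloud(cloud, tmp_path / "a.ply", "ply")
        rp.write_cloud(cloud, tmp_path / "b.ply", "ply_binary")
        a = rp.read_cloud(tmp_path / "a.ply")
        b = rp.read_cloud(tmp_path / "b.ply")
        assert np.allclose(a.xyz, b.xyz, atol=1e-6)

    def test_binary_ply_is_byte_stable(self, tmp_path, rng):
        cloud = random_cloud(rng, 17)
        rp.write_cloud(cloud, tmp_path / "a.ply", "ply_binary")
        rp.write_cloud(cloud, tmp_path / "b.ply", "ply_binary")
        assert (tmp_path / "a.ply").read_bytes() == (tmp_path / "b.ply").read_bytes()

    def test_empty_cloud_round_trip(self, tmp_path):
        empty = rp.PointCloud(np.empty((0, 3)))
        p = tmp_path / "e.ply"
        rp.write_cloud(empty, p)
        assert len(rp.read_cloud(p)) == 0

    def test_single_point_survives(self, tmp_path):
        p = tmp_path / "one.ply"
        rp.write_cloud(rp.PointCloud([[1.5, 2.5, 3.5]]), p)
        assert np.allclose(rp.read_cloud(p).xyz, [[1.5, 2.5, 3.5]])

    def test_nan_vertex_reports_offending_line(self, tmp_path):
        p = tmp_path / "bad.ply"
        p.write_text("ply\nformat ascii 1.0\nelement vertex 2\n"
                     "property double x\nproperty double y\nproperty double z\n"
                     "end_header\n0 0 0\n1 nan 0\n")
        with pytest.raises(CloudIOError, match="vertex 1"):
            rp.read_cloud(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("0 0 0\n1 oops 0\n")
        with pytest.raises(CloudIOError, match="line 2"):
            rp.read_cloud(p)

    def test_unknown_ply_properties_ignored(self, tmp_path):
        p = tmp_path / "extra.ply"
        p.write_text("ply\nformat ascii 1.0\nelement vertex 1\n"
                     "property float x\nproperty float y\nproperty float z\n"
                     "property float weird\nend_header\n1 2 3 9\n")
        cloud = rp.read_cloud(p)
        assert np.allclose(cloud.xyz, [[1, 2, 3]])

    def test_cross_check_against_scipy_loadtxt(self, tmp_path, rng):
        # independent reader for the ASCII body of our own PLY output
        cloud = random_cloud(rng, 30)
        p = tmp_path / "x.ply"
        rp.write_cloud(cloud, p, "ply")
        body = p.read_text().split("end_header\n")[1]
        arr = np.loadtxt(body.strip().splitlines())
        assert np.allclose(arr[:, :3], cloud.xyz, atol=1e-6)


class TestFrameStream:
    def test_frame_indices_must_increase(self):
        f = lambda k: rp.Frame(k, rp.PointCloud([[0, 0, 0]]))
        with pytest.raises(ValueError, match="strictly increasing"):
            rp.FrameStream([f(1), f(1)])

    def test_csv_stream_grouping(self, tmp_path):
        rows = [{"x": i * 0.1, "y": 0, "z": 0, "frame": k}
                for k in (0, 1, 2) for i in range(10)]
        p = tmp_path / "frames.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        stream = rp.read_frames(p)
        assert len(stream) == 3 and stream.n_points == 30

    def test_duplicate_rows_kept(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("x,y,z,frame\n1,2,3,0\n1,2,3,0\n")
        stream = rp.read_frames(p)
        assert len(stream.frames[0].points) == 2

    def test_directory_sorted_by_index(self, tmp_path):
        for k in (2, 0):
            rp.write_cloud(rp.PointCloud([[k, 0, 0]]), tmp_path / f"frame_{k:04d}.xyz")
        stream = rp.read_frames(tmp_path)
        assert [f.index for f in stream.frames] == [0, 2]

    def test_duplicate_frame_index_rejected(self, tmp_path):
        rp.write_cloud(rp.PointCloud([[0, 0, 0]]), tmp_path / "frame_1.xyz")
        rp.write_cloud(rp.PointCloud([[0, 0, 0]]), tmp_path / "sweep_0001.xyz")
        with pytest.raises(CloudIOError, match="duplicate frame index"):
            rp.read_frames(tmp_path)

    def test_missing_frame_column_rejected(self, tmp_path):
        p = tmp_path / "noframe.csv"
        p.write_text("x,y,z\n0,0,0\n")
        with pytest.raises(CloudIOError, match="frame"):
            rp.read_frames(p)

    def test_write_read_round_trip(self, tmp_path, rng):
        frames = [rp.Frame(k, random_cloud(rng, 5)) for k in (0, 2, 5)]
        stream = rp.FrameStream(frames)
        p = tmp_path / "s.csv"
        rp.write_frames(stream, p)
        back = rp.read_frames(p)
        assert [f.index for f in back.frames] == [0, 2, 5]
        for a, b in zip(stream.frames, back.frames):
            assert np.allclose(a.points.xyz, b.points.xyz, atol=1e-8)


class TestTraitTable:
    def test_duplicate_plant_id_rejected(self):
        rows = [dict(plant_id="p1", height_m=0.4, crown_width_m=0.3,
                     n_points=10, cx=0.0, cy=0.0)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            rp.TraitTable.from_rows(rows)

    def test_written_format_and_round_trip(self, tmp_path):
        table = rp.TraitTable.from_rows([dict(plant_id="p1", height_m=0.40,
                                              crown_width_m=0.30, n_points=12,
                                              cx=1.0, cy=-2.0)])
        p = tmp_path / "t.csv"
        rp.write_traits(table, p)
        text = p.read_text().splitlines()
        assert text[0] == "plant_id,height_m,crown_width_m,n_points,cx,cy"
        assert text[1].startswith("p1,0.400000,0.300000,12,")
        back = rp.read_traits(p)
        assert np.isclose(back.df.loc[0, "height_m"], 0.40)

    def test_empty_table_is_header_only(self, tmp_path):
        table = rp.TraitTable.from_rows([])
        p = tmp_path / "t.csv"
        rp.write_traits(table, p)
        assert p.read_text().strip() == "plant_id,height_m,crown_width_m,n_points,cx,cy"
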