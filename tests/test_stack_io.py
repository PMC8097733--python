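"""Tests for lazy stack access, the parallel pipeline and exports."""

import threading

import numpy as np
import pytest
import tifffile

from devils import (
    DevilsParams,
    FormatError,
    LazyStack,
    ProcessJob,
    convert_bit_depth,
    devils_transform,
    export_hdf5,
    open_devils_folder,
    open_stack,
    plane_stats,
    preview_plane,
    process_stack,
    write_plane_stats,
)

from conftest import bell_stack, write_stack_tiff


def small_job(stack, out_dir, workers=1, **params_kw):
    params_kw.setdefault("division_scale", 100.0)
    return ProcessJob(
        input=stack,
        params_per_channel=[DevilsParams(p=3, **params_kw)],
        output_dir=out_dir,
        workers=workers,
    )


class TestOpenStack:
    def test_roundtrip_3_planes(self, tmp_path, rng):
        data = (rng.random((3, 10, 12)) * 255).astype(np.uint8)
        path = write_stack_tiff(tmp_path / "s.tif", data, axes="ZYX")
        stack = open_stack(path)
        assert (stack.n_t, stack.n_c, stack.n_z) == (1, 1, 3)
        assert (stack.height, stack.width) == (10, 12)
        for z in range(3):
            np.testing.assert_array_equal(stack.get_plane(0, 0, z), data[z])

    def test_axis_metadata_parsed(self, tmp_path, rng):
        data = (rng.random((2, 4, 8, 8)) * 1000).astype(np.uint16)
        path = write_stack_tiff(tmp_path / "cz.tif", data, axes="CZYX")
        stack = open_stack(path)
        assert (stack.n_t, stack.n_c, stack.n_z) == (1, 2, 4)
        np.testing.assert_array_equal(stack.get_plane(0, 1, 3), data[1, 3])

    def test_axes_override(self, tmp_path, rng):
        data = (rng.random((2, 4, 8, 8)) * 1000).astype(np.uint16)
        tifffile.imwrite(tmp_path / "raw.tif", data, photometric="minisblack")  # no axis tags
        stack = open_stack(tmp_path / "raw.tif", axes="CZYX")
        assert (stack.n_c, stack.n_z) == (2, 4)

    def test_plane_reads_are_repeatable(self, tmp_path, rng):
        data = (rng.random((3, 6, 6)) * 255).astype(np.uint8)
        path = write_stack_tiff(tmp_path / "r.tif", data, axes="ZYX")
        stack = open_stack(path)
        np.testing.assert_array_equal(stack.get_plane(0, 0, 1), stack.get_plane(0, 0, 1))

    def test_truncated_file_is_format_error(self, tmp_path, rng):
        data = (rng.random((4, 32, 32)) * 65535).astype(np.uint16)
        path = write_stack_tiff(tmp_path / "t.tif", data, axes="ZYX")
        raw = path.read_bytes()
        path.write_bytes(raw[: len(raw) // 3])
        with pytest.raises(FormatError):
            stack = open_stack(path)
            stack.get_plane(0, 0, 3)

    def test_rgb_rejected(self, tmp_path, rng):
        rgb = (rng.random((8, 8, 3)) * 255).astype(np.uint8)
        tifffile.imwrite(tmp_path / "rgb.tif", rgb, photometric="rgb")
        with pytest.raises(FormatError):
            open_stack(tmp_path / "rgb.tif")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FormatError):
            open_stack(tmp_path / "nope.tif")


class TestProcessStack:
    def test_worker_count_does_not_change_bytes(self, tmp_path, memory_stack):
        stack, _ = memory_stack
        outs = {}
        for workers in (1, 4):
            out = tmp_path / f"w{workers}"
            process_stack(small_job(stack, out, workers=workers))
            outs[workers] = {f.name: f.read_bytes() for f in sorted(out.glob("*.tif"))}
        assert outs[1].keys() == outs[4].keys()
        assert all(outs[1][k] == outs[4][k] for k in outs[1])

    def test_all_planes_written_with_convention(self, tmp_path, memory_stack):
        stack, _ = memory_stack
        stats = process_stack(small_job(stack, tmp_path / "o"))
        files = sorted((tmp_path / "o").glob("*.tif"))
        assert len(files) == stack.n_planes == len(stats)
        assert files[0].name == "stack_t000_c00_z0000.tif"

    def test_constant_stack_maps_to_known_constant(self, tmp_path):
        """A constant plane tone-maps to 0, and the default conversion
        window (-100, 10000) then puts 0 at round(100/10100 * 65535)."""
        stack = LazyStack.from_array(np.full((2, 16, 16), 50.0, dtype=np.float32), axes="ZYX")
        job = ProcessJob(
            input=stack,
            params_per_channel=[DevilsParams(p=3, division_scale=100.0)],
            output_dir=tmp_path / "c",
        )
        process_stack(job)
        expected = round(100 / 10100 * 65535)
        for f in (tmp_path / "c").glob("*.tif"):
            np.testing.assert_array_equal(tifffile.imread(f), expected)

    def test_per_channel_params(self, tmp_path, memory_stack):
        stack, data = memory_stack
        job = ProcessJob(
            input=stack,
            params_per_channel=[
                DevilsParams(p=3, division_scale=100.0),
                DevilsParams(p=5, division_scale=100.0),
            ],
            output_dir=tmp_path / "pc",
        )
        process_stack(job)
        for c, p in enumerate((3, 5)):
            params = job.channel_params(c)
            assert params.resolved_sigma == 2 * p and params.resolved_ball_radius == p
            got = tifffile.imread(tmp_path / "pc" / f"stack_t000_c{c:02d}_z0000.tif")
            want = convert_bit_depth(
                devils_transform(data[c, 0].astype(float), params),
                params.conv_min, params.conv_max, params.out_depth,
            )
            np.testing.assert_array_equal(got, want)

    def test_broadcast_length_validated(self, memory_stack, tmp_path):
        stack, _ = memory_stack
        with pytest.raises(ValueError):
            ProcessJob(
                input=stack,
                params_per_channel=[DevilsParams(p=3)] * 3,
                output_dir=tmp_path,
            )

    def test_failure_names_the_plane(self, tmp_path):
        def bad_accessor(t, c, z):
            if z == 2:
                raise OSError("disk on fire")
            return np.ones((8, 8))

        stack = LazyStack(bad_accessor, 1, 1, 4, 8, 8, pixel_depth=16)
        with pytest.raises(RuntimeError, match=r"z=2"):
            process_stack(small_job(stack, tmp_path / "f"))

    def test_bounded_concurrent_planes(self, tmp_path, rng):
        """The pipeline holds at most `workers` planes at once: plane loads
        minus completions never exceed the worker count."""
        data = (rng.random((12, 16, 16)) * 255).astype(np.uint8)
        in_flight = []
        lock = threading.Lock()
        counter = {"n": 0, "peak": 0}

        def accessor(t, c, z):
            with lock:
                counter["n"] += 1
                counter["peak"] = max(counter["peak"], counter["n"])
            return data[z]

        def done(_):
            with lock:
                counter["n"] -= 1

        stack = LazyStack(accessor, 1, 1, 12, 16, 16, pixel_depth=8)
        process_stack(small_job(stack, tmp_path / "m", workers=2), on_plane_done=done)
        assert counter["peak"] <= 2


class TestDevilsFolder:
    def test_roundtrip(self, tmp_path, memory_stack):
        stack, _ = memory_stack
        process_stack(small_job(stack, tmp_path / "out"))
        reopened = open_devils_folder(tmp_path / "out")
        assert reopened.shape == stack.shape
        for t, c, z in reopened.iter_indices():
            np.testing.assert_array_equal(
                reopened.get_plane(t, c, z),
                tifffile.imread(tmp_path / "out" / f"stack_t{t:03d}_c{c:02d}_z{z:04d}.tif"),
            )

    def test_empty_folder_rejected(self, tmp_path):
        (tmp_path / "e").mkdir()
        with pytest.raises(FormatError):
            open_devils_folder(tmp_path / "e")

    def test_gap_is_reported(self, tmp_path, memory_stack):
        stack, _ = memory_stack
        process_stack(small_job(stack, tmp_path / "g"))
        (tmp_path / "g" / "stack_t000_c00_z0001.tif").unlink()
        with pytest.raises(FormatError, match=r"\(0, 0, 1\)"):
            open_devils_folder(tmp_path / "g")


class TestExportHdf5:
    def test_layout_and_roundtrip(self, tmp_path, rng):
        import h5py

        data = (rng.random((8, 16, 16)) * 65535).astype(np.uint16)
        stack = LazyStack.from_array(data, axes="ZYX")
        path = export_hdf5(stack, tmp_path / "bdv.h5")
        with h5py.File(path) as h5:
            assert h5["s00/resolutions"].shape == (1, 3)
            assert h5["s00/subdivisions"].shape == (1, 3)
            cells = h5["t00000/s00/0/cells"]
            assert cells.shape == (8, 16, 16)
            np.testing.assert_array_equal(cells[...], data)

    def test_two_channels_two_setups_and_xml(self, tmp_path, rng):
        import h5py
        import xml.etree.ElementTree as ET

        data = (rng.random((2, 3, 8, 8)) * 1000).astype(np.uint16)
        stack = LazyStack.from_array(data, axes="CZYX")
        path = export_hdf5(stack, tmp_path / "two.h5")
        with h5py.File(path) as h5:
            assert "s00" in h5 and "s01" in h5
            assert "t00000/s01/0/cells" in h5
        xml = ET.parse(tmp_path / "two.xml")
        assert len(xml.findall(".//ViewSetup")) == 2
        assert xml.find(".//ImageLoader").get("format") == "bdv.hdf5"


class TestPreviewAndStats:
    def test_middle_selection_and_consistency(self, memory_stack):
        stack, data = memory_stack
        params = DevilsParams(p=3, division_scale=100.0)
        original, processed = preview_plane(stack, "middle", 0, "middle", params)
        np.testing.assert_array_equal(original, data[0, stack.n_z // 2])
        np.testing.assert_allclose(processed, devils_transform(original, params), rtol=1e-12)

    def test_out_of_range_index(self, memory_stack):
        stack, _ = memory_stack
        with pytest.raises(IndexError):
            preview_plane(stack, 0, 0, 99, DevilsParams(p=3))

    def test_constant_stack_stats(self):
        stack = LazyStack.from_array(np.full((3, 8, 8), 5.0, dtype=np.float32), axes="ZYX")
        stats = plane_stats(stack)
        assert len(stats) == 3
        assert (stats["mean"] == 5.0).all() and (stats["max"] == 5.0).all()

    def test_single_bright_pixel(self):
        data = np.zeros((2, 10, 10), dtype=np.float32)
        data[1, 3, 4] = 100.0
        stats = plane_stats(LazyStack.from_array(data, axes="ZYX"))
        row = stats[stats.z == 1].iloc[0]
        assert row["max"] == 100.0
        assert row["mean"] == pytest.approx(100.0 / 100)
        assert (stats["mean"] <= stats["max"]).all()

    def test_stats_tsv_header(self, tmp_path):
        stack = LazyStack.from_array(np.zeros((2, 4, 4), dtype=np.float32), axes="ZYX")
        write_plane_stats(plane_stats(stack), tmp_path / "s.tsv")
        header = (tmp_path / "s.tsv").read_text().splitlines()[0]
        assert header == "t\tc\tz\tmean\tmax"


class TestFlattening:
    def test_devils_reduces_z_profile_cv(self, tmp_path):
        """On a stack whose per-plane mean follows a bell along z, the
        operator flattens the profile: the coefficient of variation of the
        per-plane means strictly drops."""
        data = bell_stack(n_z=9, size=48, seed=0)
        stack = LazyStack.from_array(data.astype(np.float32), axes="ZYX")
        before = plane_stats(stack)["mean"]
        job = ProcessJob(
            input=stack,
            params_per_channel=[DevilsParams(p=4, division_scale=100.0, out_depth=32)],
            output_dir=tmp_path / "flat",
        )
        after = process_stack(job)["mean"]
        cv = lambda x: np.std(x) / np.mean(x)
        assert cv(after) < cv(before)
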