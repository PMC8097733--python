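"""Lazy stack access, the parallel per-plane pipeline, and exports.

Volumetric light-sheet acquisitions do not fit in memory, so the pipeline
never holds a stack: a :class:`LazyStack` is a plane-addressable view
(time, channel, z) that loads a single 2-D plane on demand, and
:func:`process_stack` maps the tone-mapping operator over planes with a
thread pool.  Planes are mutually independent, which makes the parallel
output bitwise identical for any worker count.

Outputs follow the per-plane TIFF folder convention
``<stem>_t{TTT}_c{CC}_z{ZZZZ}.tif`` (zero-padded, 0-based), which
:func:`open_devils_folder` can reopen as a stack, plus an optional
BigDataViewer-compatible HDF5/XML export for interactive browsing.
"""

from __future__ import annotations

import logging
import re
import threading
import xml.etree.ElementTree as ET
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .tone_ops import DevilsParams, convert_bit_depth, devils_transform, resolve_division_scale

logger = logging.getLogger(__name__)

PLANE_NAME_TEMPLATE = "{stem}_t{t:03d}_c{c:02d}_z{z:04d}.tif"
PLANE_NAME_RE = re.compile(r"^(?P<stem>.*)_t(?P<t>\d{3})_c(?P<c>\d{2})_z(?P<z>\d{4})\.tiff?$")

#: dtype → bit depth for the formats the reader accepts
_DEPTHS = {np.dtype("uint8"): 8, np.dtype("uint16"): 16, np.dtype("float32"): 32}


class FormatError(ValueError):
    """Raised for unreadable or inconsistent stack inputs."""


class LazyStack:
    """A plane-addressable (t, c, z) stack loaded on demand.

    ``accessor(t, c, z)`` returns the raw 2-D array for one plane; nothing
    is cached here, so peak memory is bounded by whoever holds planes.
    """

    def __init__(
        self,
        accessor: Callable[[int, int, int], np.ndarray],
        n_t: int,
        n_c: int,
        n_z: int,
        height: int,
        width: int,
        pixel_depth: int,
        voxel_size: tuple[float, float, float] | None = None,
        source: str | Path | None = None,
    ):
        if min(n_t, n_c, n_z, height, width) < 1:
            raise FormatError("all stack dimensions must be >= 1")
        if pixel_depth not in (8, 16, 32):
            raise FormatError(f"pixel_depth must be 8, 16 or 32, got {pixel_depth}")
        self._accessor = accessor
        self.n_t, self.n_c, self.n_z = n_t, n_c, n_z
        self.height, self.width = height, width
        self.pixel_depth = pixel_depth
        self.voxel_size = voxel_size
        self.source = source

    @property
    def shape(self) -> tuple[int, int, int, int, int]:
        return (self.n_t, self.n_c, self.n_z, self.height, self.width)

    @property
    def n_planes(self) -> int:
        return self.n_t * self.n_c * self.n_z

    def _check_index(self, t: int, c: int, z: int) -> None:
        if not (0 <= t < self.n_t and 0 <= c < self.n_c and 0 <= z < self.n_z):
            raise IndexError(
                f"plane index (t={t}, c={c}, z={z}) out of range "
                f"(n_t={self.n_t}, n_c={self.n_c}, n_z={self.n_z})"
            )

    def get_plane(self, t: int, c: int, z: int) -> np.ndarray:
        """Load one plane as float64 of shape (height, width)."""
        self._check_index(t, c, z)
        arr = np.asarray(self._accessor(t, c, z))
        if arr.shape != (self.height, self.width):
            raise FormatError(
                f"plane (t={t}, c={c}, z={z}) has shape {arr.shape}, "
                f"expected {(self.height, self.width)}"
            )
        return arr.astype(np.float64)

    def iter_indices(self):
        """All (t, c, z) indices in deterministic C order."""
        for t in range(self.n_t):
            for c in range(self.n_c):
                for z in range(self.n_z):
                    yield t, c, z

    @classmethod
    def from_array(cls, data, axes: str = "ZYX", **kwargs) -> "LazyStack":
        """Wrap an in-memory array whose axis string is a subset of TCZYX."""
        arr = np.asarray(data)
        return _stack_from_indexable(lambda key: arr[key], arr.shape, arr.dtype, axes, **kwargs)


def _depth_of(dtype) -> int:
    dt = np.dtype(dtype)
    if dt not in _DEPTHS:
        raise FormatError(f"unsupported pixel type {dt} (need uint8, uint16 or float32)")
    return _DEPTHS[dt]


def _stack_from_indexable(getter, shape, dtype, axes: str, **kwargs) -> LazyStack:
    """Build a LazyStack over any array-like indexable with numpy basic slicing."""
    axes = axes.upper()
    if len(axes) != len(shape):
        raise FormatError(f"axes {axes!r} do not match array of rank {len(shape)}")
    if not axes.endswith("YX"):
        raise FormatError(f"axes must end in YX, got {axes!r}")
    extra = axes[:-2]
    if any(a not in "TCZ" for a in extra) or len(set(extra)) != len(extra):
        raise FormatError(f"unsupported axes {axes!r}; leading axes must be unique among T, C, Z")
    dims = dict(zip(extra, shape[: len(extra)]))
    n_t, n_c, n_z = dims.get("T", 1), dims.get("C", 1), dims.get("Z", 1)
    height, width = shape[-2], shape[-1]

    def accessor(t: int, c: int, z: int) -> np.ndarray:
        key = tuple({"T": t, "C": c, "Z": z}[a] for a in extra)
        return getter(key + (slice(None), slice(None)))

    return LazyStack(
        accessor, n_t, n_c, n_z, height, width, pixel_depth=_depth_of(dtype), **kwargs
    )


def open_stack(path, axes: str | None = None) -> LazyStack:
    """Open a multi-page grayscale TIFF as a lazily-read stack.

    Z/C/T axes are taken from the TIFF series metadata; ``axes`` overrides
    them (e.g. ``"CZYX"`` for a file written without axis tags).  Unknown
    singleton axes (S, Q, I) of length 1 are dropped; an ``I`` page axis of
    length > 1 is treated as Z.
    """
    path = Path(path)
    try:
        tif = tifffile.TiffFile(path)
    except (OSError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    series = tif.series[0]
    raw_axes = series.axes.upper() if axes is None else axes.upper()
    raw_shape = list(series.shape)
    if len(raw_axes) != len(raw_shape):
        raise FormatError(f"{path}: axes {raw_axes!r} do not match data of rank {len(raw_shape)}")
    # normalize: generic page axes (I/Q) of length > 1 act as Z, singleton
    # unknown axes are dropped; a multi-sample axis means RGB, which is out
    kept: list[int] = []
    file_axes = ""
    for i, a in enumerate(raw_axes):
        if a in "IQ":
            a = "Z" if raw_shape[i] > 1 else ""
        elif a == "S" and raw_shape[i] > 1:
            raise FormatError(f"{path}: RGB/multi-sample TIFF is not supported")
        elif a not in "TCZYX":
            if raw_shape[i] > 1:
                raise FormatError(f"{path}: cannot interpret axes {raw_axes!r} as grayscale TCZYX")
            a = ""
        if a:
            kept.append(i)
            file_axes += a
    shape = [raw_shape[i] for i in kept]
    _depth_of(series.dtype)  # reject unsupported pixel types early
    lock = threading.Lock()
    # uncompressed series are memory-mapped so plane reads stay lazy (the OS
    # pages in only the slices touched); compressed data falls back to a
    # one-time decode guarded for thread safety
    state: dict = {}

    def backing():
        with lock:
            if "data" not in state:
                try:
                    state["data"] = series.asarray(out="memmap")
                except (ValueError, OSError):
                    logger.warning("%s: not memory-mappable, decoding in memory", path)
                    state["data"] = series.asarray()
                except Exception as exc:
                    raise FormatError(f"{path}: cannot read image data: {exc}") from exc
            return state["data"]

    def getter(key):
        # reinsert zeros for the singleton axes dropped above
        full = [0] * len(raw_shape)
        for pos, value in zip(kept, key):
            full[pos] = value
        try:
            plane = np.asarray(backing()[tuple(full)])
        except FormatError:
            raise
        except Exception as exc:  # truncated/corrupt data surfaces here
            raise FormatError(f"{path}: cannot read plane {key[:-2]}: {exc}") from exc
        if plane.ndim != 2:
            raise FormatError(f"{path}: plane {key[:-2]} is not 2-D grayscale")
        return plane

    return _stack_from_indexable(getter, tuple(shape), series.dtype, file_axes, source=path)


@dataclass
class ProcessJob:
    """One stack-processing run.

    ``params_per_channel`` holds one :class:`DevilsParams` per channel; a
    single entry broadcasts to all channels.
    """

    input: LazyStack
    params_per_channel: Sequence[DevilsParams]
    output_dir: Path
    workers: int = 1
    export_hdf5: bool = False
    stem: str | None = None

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        n = len(self.params_per_channel)
        if n not in (1, self.input.n_c):
            raise ValueError(
                f"params_per_channel must have length 1 or n_c={self.input.n_c}, got {n}"
            )
        if self.workers < 1:
            raise ValueError(f"workers must be >= 1, got {self.workers}")
        if self.stem is None:
            src = self.input.source
            self.stem = Path(src).stem if src is not None else "stack"

    def channel_params(self, c: int) -> DevilsParams:
        if len(self.params_per_channel) == 1:
            return self.params_per_channel[0]
        return self.params_per_channel[c]


def process_stack(
    job: ProcessJob,
    on_plane_done: Callable[[tuple[int, int, int]], None] | None = None,
) -> pd.DataFrame:
    """Apply the tone-mapping operator to every plane and write the folder.

    Each plane is transformed with its channel's parameters, converted to the
    requested bit depth, and written as one TIFF under the folder naming
    convention.  The result is bitwise identical for any ``workers`` >= 1.
    Returns the per-plane statistics table of the converted output.
    """
    stack = job.input
    job.output_dir.mkdir(parents=True, exist_ok=True)
    # resolve any "auto" division scale once per channel up front, so worker
    # threads never race on the calibration cache
    scales = {
        c: resolve_division_scale(job.channel_params(c)) for c in range(stack.n_c)
    }

    def run_one(tcz: tuple[int, int, int]) -> dict:
        t, c, z = tcz
        params = job.channel_params(c)
        try:
            plane = stack.get_plane(t, c, z)
            processed = devils_transform(plane, replace(params, division_scale=scales[c]))
            converted = convert_bit_depth(processed, params.conv_min, params.conv_max, params.out_depth)
            name = PLANE_NAME_TEMPLATE.format(stem=job.stem, t=t, c=c, z=z)
            tifffile.imwrite(job.output_dir / name, converted)
        except Exception as exc:
            raise RuntimeError(f"failed while processing plane (t={t}, c={c}, z={z}): {exc}") from exc
        logger.info("processed plane t=%d c=%d z=%d", t, c, z)
        row = {
            "t": t,
            "c": c,
            "z": z,
            "mean": float(np.mean(converted)),
            "max": float(np.max(converted)),
        }
        if on_plane_done is not None:
            on_plane_done(tcz)
        return row

    indices = list(stack.iter_indices())
    if job.workers == 1:
        rows = [run_one(tcz) for tcz in indices]
    else:
        with ThreadPoolExecutor(max_workers=job.workers) as pool:
            rows = list(pool.map(run_one, indices))
    stats = pd.DataFrame(rows, columns=["t", "c", "z", "mean", "max"])
    if job.export_hdf5:
        out = open_devils_folder(job.output_dir)
        export_hdf5(out, job.output_dir / f"{job.stem}_devils.h5")
    return stats


def open_devils_folder(path) -> LazyStack:
    """Reopen a per-plane TIFF folder written by :func:`process_stack`.

    (t, c, z) indices are recovered from the filenames; the full cartesian
    grid must be present — missing planes raise with the list of gaps.
    """
    path = Path(path)
    files: dict[tuple[int, int, int], Path] = {}
    for f in sorted(path.iterdir()) if path.is_dir() else []:
        m = PLANE_NAME_RE.match(f.name)
        if m:
            files[(int(m["t"]), int(m["c"]), int(m["z"]))] = f
    if not files:
        raise FormatError(f"{path}: no files matching the plane naming convention")
    n_t = max(t for t, _, _ in files) + 1
    n_c = max(c for _, c, _ in files) + 1
    n_z = max(z for _, _, z in files) + 1
    gaps = [
        (t, c, z)
        for t in range(n_t)
        for c in range(n_c)
        for z in range(n_z)
        if (t, c, z) not in files
    ]
    if gaps:
        raise FormatError(f"{path}: missing planes in the folder grid: {gaps}")
    first = tifffile.imread(files[(0, 0, 0)])
    if first.ndim != 2:
        raise FormatError(f"{path}: plane files must be single 2-D images")

    def accessor(t: int, c: int, z: int) -> np.ndarray:
        return tifffile.imread(files[(t, c, z)])

    return LazyStack(
        accessor,
        n_t,
        n_c,
        n_z,
        height=first.shape[0],
        width=first.shape[1],
        pixel_depth=_depth_of(first.dtype),
        source=path,
    )


def export_hdf5(stack: LazyStack, path) -> Path:
    """Write a BigDataViewer-compatible HDF5 dataset plus its XML sidecar.

    One setup per channel, one timepoint group per t, a single resolution
    level, chunked 3-D cell datasets in 16-bit.  Values are written as they
    come from the stack (the pipeline converts before export), so a raw read
    of ``t{ttttt}/s{ss}/0/cells`` round-trips the planes exactly.
    """
    import h5py

    path = Path(path)
    chunks = tuple(min(64, n) for n in (stack.n_z, stack.height, stack.width))
    with h5py.File(path, "w") as h5:
        for c in range(stack.n_c):
            grp = h5.create_group(f"s{c:02d}")
            grp.create_dataset("resolutions", data=np.array([[1.0, 1.0, 1.0]]))
            grp.create_dataset("subdivisions", data=np.array([chunks[::-1]], dtype=np.int32))
        for t in range(stack.n_t):
            for c in range(stack.n_c):
                cells = h5.create_dataset(
                    f"t{t:05d}/s{c:02d}/0/cells",
                    shape=(stack.n_z, stack.height, stack.width),
                    dtype=np.uint16,
                    chunks=chunks,
                )
                for z in range(stack.n_z):
                    cells[z] = np.clip(stack.get_plane(t, c, z), 0, 65535).astype(np.uint16)
    _write_bdv_xml(stack, path.with_suffix(".xml"), path.name)
    return path


def _write_bdv_xml(stack: LazyStack, xml_path: Path, h5_name: str) -> None:
    vx, vy, vz = stack.voxel_size if stack.voxel_size else (1.0, 1.0, 1.0)
    root = ET.Element("SpimData", version="0.2")
    ET.SubElement(root, "BasePath", type="relative").text = "."
    seq = ET.SubElement(root, "SequenceDescription")
    loader = ET.SubElement(seq, "ImageLoader", format="bdv.hdf5")
    ET.SubElement(loader, "hdf5", type="relative").text = h5_name
    setups = ET.SubElement(seq, "ViewSetups")
    for c in range(stack.n_c):
        vs = ET.SubElement(setups, "ViewSetup")
        ET.SubElement(vs, "id").text = str(c)
        ET.SubElement(vs, "name").text = f"channel {c}"
        ET.SubElement(vs, "size").text = f"{stack.width} {stack.height} {stack.n_z}"
        vox = ET.SubElement(vs, "voxelSize")
        ET.SubElement(vox, "unit").text = "micrometer"
        ET.SubElement(vox, "size").text = f"{vx} {vy} {vz}"
    tp = ET.SubElement(seq, "Timepoints", type="range")
    ET.SubElement(tp, "first").text = "0"
    ET.SubElement(tp, "last").text = str(stack.n_t - 1)
    regs = ET.SubElement(root, "ViewRegistrations")
    for t in range(stack.n_t):
        for c in range(stack.n_c):
            vr = ET.SubElement(regs, "ViewRegistration", timepoint=str(t), setup=str(c))
            vt = ET.SubElement(vr, "ViewTransform", type="affine")
            ET.SubElement(vt, "affine").text = (
                f"{vx} 0.0 0.0 0.0 0.0 {vy} 0.0 0.0 0.0 0.0 {vz} 0.0"
            )
    ET.indent(root)
    ET.ElementTree(root).write(xml_path, xml_declaration=True, encoding="unicode")


def _resolve_middle(idx, n: int, what: str) -> int:
    if idx == "middle" or idx is None:
        return n // 2
    idx = int(idx)
    if not (0 <= idx < n):
        raise IndexError(f"{what} index {idx} out of range [0, {n})")
    return idx


def preview_plane(stack: LazyStack, t, c, z, params: DevilsParams) -> tuple[np.ndarray, np.ndarray]:
    """Process a single plane for parameter tuning; writes nothing.

    Any of t/c/z may be ``"middle"`` (or None) to select the central index.
    Returns ``(original, processed)`` with the processed plane unconverted.
    """
    t = _resolve_middle(t, stack.n_t, "t")
    c = _resolve_middle(c, stack.n_c, "c")
    z = _resolve_middle(z, stack.n_z, "z")
    original = stack.get_plane(t, c, z)
    return original, devils_transform(original, params)


def plane_stats(stack: LazyStack) -> pd.DataFrame:
    """Mean and max intensity of every plane (columns t, c, z, mean, max)."""
    rows = []
    for t, c, z in stack.iter_indices():
        plane = stack.get_plane(t, c, z)
        rows.append({"t": t, "c": c, "z": z, "mean": float(plane.mean()), "max": float(plane.max())})
    return pd.DataFrame(rows, columns=["t", "c", "z", "mean", "max"])


def write_plane_stats(stats: pd.DataFrame, path) -> None:
    """Write a stats table as tab-separated text with header t/c/z/mean/max."""
    stats.to_csv(path, sep="\t", index=False)
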