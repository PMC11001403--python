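"""Synthetic multi-event frame stores with ground-truth labels.

Emulates the ingredients of a serial-crystallography detector frame that
matter for triage: a diffuse water-ring background centred on the beam, a
handful of Bragg-like Gaussian spots, additive Gaussian noise, and — on
the "bad" fraction of frames — a per-panel miscalibration artefact
confined to a band of slow-scan rows, the signature a gain-switching
fault leaves when the water ring crosses a critical intensity range.

The generator is the package's test bed: it writes multi-event HDF5
files, the matching CrystFEL-style geometry text, truth label lists and a
parameter dump, all byte-reproducible under a seed.  It makes no claim to
physical accuracy (no photon statistics, no detector electronics, no real
diffraction physics); see docs/methods.md for what that does and does not
validate.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .frame_store import FrameRef
from .geometry import DetectorGeometry, GeometryError, PanelDef, parse_geometry, serialize_geometry
from .labels import LabelSet, save_label_set

__all__ = ["SynthConfig", "SynthResult", "make_geometry", "generate_stack"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a 600-frame, 30%-bad run on a two-panel 32x64
    detector whose water ring crosses both panels, with an additive
    miscalibration offset of 5 noise sigma on a 12-row band of the second
    panel — strong enough that a trained sorter should recover the truth,
    weak enough that single pixels stay noise-dominated.
    """

    n_frames: int = 600
    frac_bad: float = 0.3
    n_files: int = 1

    # panel layout: n_panels slabs stacked along ss in data space,
    # side by side along x in the lab frame
    n_panels: int = 2
    panel_rows: int = 32
    panel_cols: int = 64
    panel_gap: int = 2
    panel_y: float = 8.0

    # diffuse water-ring background (lab-frame, beam centre at origin)
    ring_center: tuple[float, float] = (0.0, 0.0)
    ring_radius: float = 40.0
    ring_width: float = 6.0
    ring_amplitude: float = 10.0

    # Bragg-like spots
    n_spots: int = 15
    spot_amplitude: float = 50.0
    spot_sigma: float = 1.5

    noise_sigma: float = 1.0

    # miscalibration artefact on bad frames
    artefact_panel: str = "p1"
    artefact_rows: tuple[int, int] = (10, 22)   # half-open, panel-local ss
    artefact_offset: float = 5.0                # additive, "offset" mode
    artefact_mode: str = "offset"               # "offset" | "clip"
    artefact_clip_level: float = 12.0

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_bad <= 1.0:
            raise ValueError("frac_bad must be in [0, 1]")
        if self.n_frames < 1 or self.n_files < 1 or self.n_files > self.n_frames:
            raise ValueError("need 1 <= n_files <= n_frames")
        if self.artefact_mode not in ("offset", "clip"):
            raise ValueError("artefact_mode must be 'offset' or 'clip'")
        if min(self.ring_amplitude, self.spot_amplitude, self.noise_sigma,
               self.artefact_offset) < 0:
            raise ValueError("amplitudes must be >= 0")

    @property
    def n_bad(self) -> int:
        return int(math.ceil(self.frac_bad * self.n_frames))

    @property
    def data_shape(self) -> tuple[int, int]:
        return (self.n_panels * self.panel_rows, self.panel_cols)


@dataclass(frozen=True)
class SynthResult:
    """Everything one generation run produced, for tests and pipelines."""

    file_paths: tuple[Path, ...]
    truth: LabelSet
    geometry: DetectorGeometry
    geometry_text: str
    geometry_path: Path
    dump: dict
    dump_path: Path
    truth_dir: Path


def make_geometry(config: SynthConfig) -> tuple[str, DetectorGeometry, dict]:
    """Geometry text + parsed DetectorGeometry + parameter dump.

    Panels are stacked along ss in the raw slab and placed side by side in
    the lab frame, centred on x = 0, with ``panel_gap`` empty lab pixels
    between neighbours.  The text round-trips through
    :func:`sfxtriage.geometry.parse_geometry`.
    """
    total_width = config.n_panels * config.panel_cols \
        + (config.n_panels - 1) * config.panel_gap
    start_x = -total_width / 2.0
    panels = []
    for i in range(config.n_panels):
        panels.append(PanelDef(
            name=f"p{i}",
            min_fs=0, max_fs=config.panel_cols - 1,
            min_ss=i * config.panel_rows,
            max_ss=(i + 1) * config.panel_rows - 1,
            fs_vec=(1.0, 0.0), ss_vec=(0.0, 1.0),
            corner=(start_x + i * (config.panel_cols + config.panel_gap),
                    config.panel_y),
        ))
    geom = DetectorGeometry(panels=tuple(panels), data_shape=config.data_shape)
    text = serialize_geometry(geom)
    # parse round trip guards the serializer against drift
    parse_geometry(text)
    dump = {
        "data_shape": list(config.data_shape),
        "panels": [
            {"name": p.name, "min_fs": p.min_fs, "max_fs": p.max_fs,
             "min_ss": p.min_ss, "max_ss": p.max_ss,
             "fs_vec": list(p.fs_vec), "ss_vec": list(p.ss_vec),
             "corner": list(p.corner)}
            for p in geom.panels
        ],
    }
    return text, geom, dump


def _lab_coordinates(geom: DetectorGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Lab (x, y) of every raw-data pixel; NaN where no panel sits."""
    rows, cols = geom.data_shape
    xx = np.full((rows, cols), np.nan)
    yy = np.full((rows, cols), np.nan)
    for p in geom.panels:
        i_ss, i_fs = np.meshgrid(np.arange(p.n_ss), np.arange(p.n_fs), indexing="ij")
        (ss0, ss1), (fs0, fs1) = p.slab
        xx[ss0:ss1, fs0:fs1] = p.corner[0] + i_fs * p.fs_vec[0] + i_ss * p.ss_vec[0]
        yy[ss0:ss1, fs0:fs1] = p.corner[1] + i_fs * p.fs_vec[1] + i_ss * p.ss_vec[1]
    return xx, yy


def _artefact_band(config: SynthConfig, geom: DetectorGeometry) -> tuple[int, int]:
    """Data-space ss row range (half-open) carrying the artefact."""
    p = geom.panel(config.artefact_panel)
    r0, r1 = config.artefact_rows
    if not 0 <= r0 < r1 <= p.n_ss:
        raise ValueError(
            f"artefact_rows {config.artefact_rows} outside panel "
            f"{p.name!r} with {p.n_ss} rows")
    return (p.min_ss + r0, p.min_ss + r1)


def generate_stack(config: SynthConfig, out_dir: str | Path) -> SynthResult:
    """Write the synthetic HDF5 files, geometry, truth lists and dump.

    Bad frames are the first ceil(frac_bad * n_frames) indices of a
    seeded permutation, so class counts are exact and runs reproducible;
    datasets are written with HDF5 timestamps disabled so identical seeds
    give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    text, geom, geo_dump = make_geometry(config)
    xx, yy = _lab_coordinates(geom)
    r = np.hypot(xx - config.ring_center[0], yy - config.ring_center[1])
    ring = config.ring_amplitude * np.exp(
        -((r - config.ring_radius) ** 2) / (2.0 * config.ring_width ** 2))
    ring = np.nan_to_num(ring, nan=0.0)
    band = _artefact_band(config, geom)

    # dedicated stream tag: keeps the class shuffle independent of other
    # components (e.g. the train/test split) seeded with the same integer
    rng = np.random.default_rng([config.seed, 0x53594E])
    perm = rng.permutation(config.n_frames)
    bad_indices = set(int(i) for i in perm[: config.n_bad])

    rows, cols = config.data_shape
    ss_grid, fs_grid = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")

    frames = np.empty((config.n_frames, rows, cols), dtype=np.float32)
    for i in range(config.n_frames):
        frame = ring.copy()
        for _ in range(config.n_spots):
            c_ss = rng.uniform(0, rows)
            c_fs = rng.uniform(0, cols)
            amp = config.spot_amplitude * rng.uniform(0.5, 1.5)
            frame += amp * np.exp(
                -((ss_grid - c_ss) ** 2 + (fs_grid - c_fs) ** 2)
                / (2.0 * config.spot_sigma ** 2))
        frame += rng.normal(0.0, config.noise_sigma, size=frame.shape)
        if i in bad_indices:
            if config.artefact_mode == "offset":
                frame[band[0]:band[1], :] += config.artefact_offset
            else:
                frame[band[0]:band[1], :] = np.minimum(
                    frame[band[0]:band[1], :], config.artefact_clip_level)
        frames[i] = frame.astype(np.float32)

    # contiguous event chunks per file
    chunks = np.array_split(np.arange(config.n_frames), config.n_files)
    file_paths: list[Path] = []
    mapping: dict[FrameRef, str] = {}
    events_per_file: list[int] = []
    for f_idx, chunk in enumerate(chunks):
        path = out_dir / f"synth_{f_idx:03d}.h5"
        with h5py.File(path, "w") as h5:
            h5.create_dataset("/data/data", data=frames[chunk],
                              track_times=False)
        file_paths.append(path)
        events_per_file.append(len(chunk))
        for local_ev, global_idx in enumerate(chunk):
            label = "bad" if int(global_idx) in bad_indices else "good"
            mapping[FrameRef(str(path), local_ev)] = label
    truth = LabelSet(mapping)

    geometry_path = out_dir / "synth.geom"
    geometry_path.write_text(text)
    truth_dir = out_dir / "truth"
    save_label_set(truth, truth_dir)

    dump = {
        "config": asdict(config),
        "geometry": geo_dump,
        "files": [str(p) for p in file_paths],
        "events_per_file": events_per_file,
        "n_bad": config.n_bad,
        "artefact_band_ss": list(band),
        "bad_global_indices": sorted(bad_indices),
    }
    dump_path = out_dir / "synth_params.json"
    dump_path.write_text(json.dumps(dump, indent=2))

    return SynthResult(
        file_paths=tuple(file_paths), truth=truth, geometry=geom,
        geometry_text=text, geometry_path=geometry_path,
        dump=dump, dump_path=dump_path, truth_dir=truth_dir,
    )
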