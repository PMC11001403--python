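"""CrystFEL-style detector geometry: panel slabs and lab-frame assembly.

Segmented XFEL detectors store each event as a single 2D "slab" array in
which every panel occupies a rectangle addressed by fast-scan (fs, column)
and slow-scan (ss, row) index ranges.  A geometry description places each
panel in the laboratory frame through two direction vectors (one pixel step
along fs and along ss) and the lab position of the panel's first pixel.

Only the key subset needed for frame triage is supported: the panel
rectangle (``min_fs``/``max_fs``/``min_ss``/``max_ss``), the ``fs``/``ss``
axis vectors and ``corner_x``/``corner_y``.  Everything else a real
geometry file carries (``res``, ``clen``, ``adu_per_photon``, masks, ...)
is ignored with a logged notice — the triage task needs panel *location*,
not photon-unit conversion or 3D ray tracing.

Conventions
-----------
* Raw data space is 0-based ``(row=ss, col=fs)``.
* CrystFEL's inclusive ``max_fs``/``max_ss`` are converted to half-open
  ranges internally.
* Lab frame: x grows with assembled-canvas columns, y with rows; positions
  are in pixel units relative to the beam centre.
* Assembly rounds each pixel's lab position to the nearest canvas cell;
  two pixels landing on one cell is a validation error.  Unpopulated cells
  hold NaN and are excluded from all downstream statistics.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PanelDef",
    "DetectorGeometry",
    "GeometryError",
    "GeometryParseError",
    "parse_geometry",
    "serialize_geometry",
    "assemble_image",
    "locate_source_panel",
    "panel_slice",
]


class GeometryError(ValueError):
    """Invalid geometry (overlapping panels, shape mismatch, unknown panel)."""


class GeometryParseError(GeometryError):
    """Geometry text could not be parsed."""


@dataclass(frozen=True)
class PanelDef:
    """One detector panel: its raw-data rectangle and lab-frame placement.

    ``min_fs``..``max_ss`` are 0-based *inclusive* pixel indices into the
    raw slab, as written in geometry files.  ``fs_vec``/``ss_vec`` are the
    lab-frame (x, y) displacements of one pixel step along the fast- and
    slow-scan axes; ``corner`` is the lab position of pixel (ss=0, fs=0).
    """

    name: str
    min_fs: int
    max_fs: int
    min_ss: int
    max_ss: int
    fs_vec: tuple[float, float]
    ss_vec: tuple[float, float]
    corner: tuple[float, float]

    def __post_init__(self) -> None:
        if self.max_fs < self.min_fs or self.max_ss < self.min_ss:
            raise GeometryError(
                f"panel {self.name!r}: max_fs/max_ss must be >= min_fs/min_ss"
            )
        det = (self.fs_vec[0] * self.ss_vec[1]
               - self.fs_vec[1] * self.ss_vec[0])
        if abs(det) < 1e-12:
            raise GeometryError(
                f"panel {self.name!r}: fs and ss vectors are linearly dependent"
            )

    @property
    def n_fs(self) -> int:
        return self.max_fs - self.min_fs + 1

    @property
    def n_ss(self) -> int:
        return self.max_ss - self.min_ss + 1

    @property
    def slab(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """Half-open ((ss0, ss1), (fs0, fs1)) rectangle in raw data space."""
        return ((self.min_ss, self.max_ss + 1), (self.min_fs, self.max_fs + 1))


@dataclass(frozen=True)
class DetectorGeometry:
    """Ordered panel collection plus the raw per-event array shape."""

    panels: tuple[PanelDef, ...]
    data_shape: tuple[int, int]

    def __post_init__(self) -> None:
        rows, cols = self.data_shape
        seen: list[PanelDef] = []
        for p in self.panels:
            if p.max_ss >= rows or p.max_fs >= cols:
                raise GeometryError(
                    f"panel {p.name!r} rectangle exceeds data_shape {self.data_shape}"
                )
            for q in seen:
                if (p.min_fs <= q.max_fs and q.min_fs <= p.max_fs
                        and p.min_ss <= q.max_ss and q.min_ss <= p.max_ss):
                    raise GeometryError(
                        f"panels {q.name!r} and {p.name!r} overlap in data space"
                    )
            seen.append(p)

    @property
    def panel_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.panels)

    def panel(self, name: str) -> PanelDef:
        for p in self.panels:
            if p.name == name:
                return p
        raise GeometryError(
            f"unknown panel {name!r}; valid panels: {list(self.panel_names)}"
        )


_MANDATORY_KEYS = ("min_fs", "max_fs", "min_ss", "max_ss",
                   "fs", "ss", "corner_x", "corner_y")

_AXIS_TOKEN = re.compile(r"([+-]?[0-9]*\.?[0-9]*)([xy])")


def _parse_axis_vector(value: str, panel: str, key: str) -> tuple[float, float]:
    """Parse a CrystFEL axis expression such as ``+1.0x -0.002y`` or ``-y``."""
    x = y = 0.0
    matched_any = False
    for token in value.split():
        m = _AXIS_TOKEN.fullmatch(token)
        if m is None:
            raise GeometryParseError(
                f"panel {panel!r}: cannot parse {key} component {token!r}"
            )
        coeff_s, axis = m.groups()
        coeff = 1.0 if coeff_s in ("", "+") else -1.0 if coeff_s == "-" else float(coeff_s)
        if axis == "x":
            x += coeff
        else:
            y += coeff
        matched_any = True
    if not matched_any:
        raise GeometryParseError(f"panel {panel!r}: empty {key} expression")
    return (x, y)


def parse_geometry(text: str, data_shape: tuple[int, int] | None = None) -> DetectorGeometry:
    """Parse CrystFEL-format geometry text into a :class:`DetectorGeometry`.

    Lines have the form ``panel/key = value``; global (slash-free) lines
    and unrecognized panel keys are ignored with a debug-level notice.
    ``data_shape`` defaults to the tightest slab containing every panel,
    ``(max(max_ss)+1, max(max_fs)+1)``.
    """
    raw: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split(";", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise GeometryParseError(f"line {lineno}: expected 'key = value': {line!r}")
        lhs, value = (s.strip() for s in line.split("=", 1))
        if "/" not in lhs:
            logger.debug("ignoring global geometry key %r", lhs)
            continue
        panel, key = (s.strip() for s in lhs.split("/", 1))
        if key not in _MANDATORY_KEYS:
            logger.debug("panel %r: ignoring unsupported key %r", panel, key)
            continue
        if panel not in raw:
            raw[panel] = {}
            order.append(panel)
        raw[panel][key] = value

    if not order:
        raise GeometryParseError("no panel blocks found in geometry text")

    panels = []
    for name in order:
        block = raw[name]
        for key in _MANDATORY_KEYS:
            if key not in block:
                raise GeometryParseError(f"panel {name!r}: missing mandatory key {key!r}")
        try:
            panels.append(PanelDef(
                name=name,
                min_fs=int(block["min_fs"]),
                max_fs=int(block["max_fs"]),
                min_ss=int(block["min_ss"]),
                max_ss=int(block["max_ss"]),
                fs_vec=_parse_axis_vector(block["fs"], name, "fs"),
                ss_vec=_parse_axis_vector(block["ss"], name, "ss"),
                corner=(float(block["corner_x"]), float(block["corner_y"])),
            ))
        except ValueError as exc:
            if isinstance(exc, GeometryError):
                raise
            raise GeometryParseError(f"panel {name!r}: {exc}") from exc

    if data_shape is None:
        data_shape = (max(p.max_ss for p in panels) + 1,
                      max(p.max_fs for p in panels) + 1)
    return DetectorGeometry(panels=tuple(panels), data_shape=data_shape)


def serialize_geometry(geom: DetectorGeometry) -> str:
    """Write the supported key subset back out as CrystFEL-style text."""
    lines = []
    for p in geom.panels:
        lines.append(f"{p.name}/min_fs = {p.min_fs}")
        lines.append(f"{p.name}/max_fs = {p.max_fs}")
        lines.append(f"{p.name}/min_ss = {p.min_ss}")
        lines.append(f"{p.name}/max_ss = {p.max_ss}")
        lines.append(f"{p.name}/fs = {p.fs_vec[0]:+g}x {p.fs_vec[1]:+g}y")
        lines.append(f"{p.name}/ss = {p.ss_vec[0]:+g}x {p.ss_vec[1]:+g}y")
        lines.append(f"{p.name}/corner_x = {p.corner[0]:g}")
        lines.append(f"{p.name}/corner_y = {p.corner[1]:g}")
        lines.append("")
    return "\n".join(lines)


def _panel_lab_indices(p: PanelDef) -> tuple[np.ndarray, np.ndarray]:
    """Integer lab-frame (x, y) cell for every pixel of a panel (ss, fs grid)."""
    i_ss, i_fs = np.meshgrid(np.arange(p.n_ss), np.arange(p.n_fs), indexing="ij")
    x = p.corner[0] + i_fs * p.fs_vec[0] + i_ss * p.ss_vec[0]
    y = p.corner[1] + i_fs * p.fs_vec[1] + i_ss * p.ss_vec[1]
    return np.rint(x).astype(np.int64), np.rint(y).astype(np.int64)


def assemble_image(frame: np.ndarray, geom: DetectorGeometry,
                   fill: float = np.nan) -> np.ndarray:
    """Place every panel of a raw frame at its lab-frame position.

    Returns a canvas sized to the bounding box of all rounded pixel
    positions; cells not covered by any panel hold ``fill`` (NaN by
    default, so gaps never bias statistics).  Two panels claiming one cell
    raise :class:`GeometryError`.
    """
    frame = np.asarray(frame)
    if frame.shape != geom.data_shape:
        raise GeometryError(
            f"frame shape {frame.shape} does not match geometry "
            f"data_shape {geom.data_shape}"
        )
    placements = []
    for p in geom.panels:
        x, y = _panel_lab_indices(p)
        placements.append((p, x, y))
    x_min = min(int(x.min()) for _, x, _ in placements)
    x_max = max(int(x.max()) for _, x, _ in placements)
    y_min = min(int(y.min()) for _, _, y in placements)
    y_max = max(int(y.max()) for _, _, y in placements)

    canvas = np.full((y_max - y_min + 1, x_max - x_min + 1), fill, dtype=float)
    claimed = np.zeros(canvas.shape, dtype=bool)
    for p, x, y in placements:
        rows = y - y_min
        cols = x - x_min
        if claimed[rows, cols].any():
            raise GeometryError(
                f"panel {p.name!r} collides with an already-placed panel "
                "after rounding to integer lab cells"
            )
        claimed[rows, cols] = True
        (ss0, ss1), (fs0, fs1) = p.slab
        canvas[rows, cols] = frame[ss0:ss1, fs0:fs1]
    return canvas


def locate_source_panel(geom: DetectorGeometry, canvas_row: int, canvas_col: int) -> str | None:
    """Inverse of :func:`assemble_image` addressing: which panel covers a cell.

    Returns the panel name, or None for a gap cell.  Canvas indices use the
    same bounding box as :func:`assemble_image`.
    """
    placements = [(p, *_panel_lab_indices(p)) for p in geom.panels]
    x_min = min(int(x.min()) for _, x, _ in placements)
    y_min = min(int(y.min()) for _, _, y in placements)
    for p, x, y in placements:
        hit = (y - y_min == canvas_row) & (x - x_min == canvas_col)
        if hit.any():
            return p.name
    return None


def panel_slice(geom: DetectorGeometry, panel_name: str) -> tuple[tuple[int, int], tuple[int, int]]:
    """Half-open ((ss0, ss1), (fs0, fs1)) raw-data rectangle of a panel.

    This rectangle is the default region of interest: in the interactive
    workflow the user picks a panel and its whole slab becomes the ROI.
    """
    return geom.panel(panel_name).slab
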