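"""Multi-event HDF5 frame stacks and plain-text event lists.

An *event* is one detector frame inside a multi-event HDF5 file, addressed
by file path plus 0-based event index.  Sorted output and resume state are
plain-text event lists with one ``<path> //<event>`` line per event — the
dialect downstream serial-crystallography indexing tools consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FrameRef",
    "FrameStack",
    "EventList",
    "FrameStoreError",
    "DEFAULT_DATA_PATHS",
    "open_stack",
    "read_frame",
    "write_event_lists",
    "read_event_list",
]

#: Dataset locations tried, in order, when no data path is given.
DEFAULT_DATA_PATHS = ("/entry_1/data_1/data", "/data/data")


class FrameStoreError(ValueError):
    """Frame-store contract violation (missing dataset, bad list line, ...)."""


@dataclass(frozen=True)
class FrameRef:
    """One event: file path + 0-based event index.

    ``event=None`` denotes a whole-file reference (a list line without the
    ``//event`` suffix); it expands to all events once the file is opened.
    """

    path: str
    event: int | None = None

    def __post_init__(self) -> None:
        if self.event is not None and self.event < 0:
            raise FrameStoreError(f"event index must be >= 0, got {self.event}")

    # None sorts before concrete events for a given path
    def __lt__(self, other: "FrameRef") -> bool:
        return self.sort_key() < other.sort_key()

    def sort_key(self) -> tuple[str, int]:
        return (self.path, -1 if self.event is None else self.event)

    def __str__(self) -> str:
        if self.event is None:
            return self.path
        return f"{self.path} //{self.event}"


@dataclass(frozen=True)
class FrameStack:
    """Handle on one multi-event HDF5 file's frame dataset."""

    path: str
    data_path: str
    n_events: int
    frame_shape: tuple[int, int]

    def refs(self) -> list[FrameRef]:
        return [FrameRef(self.path, e) for e in range(self.n_events)]


@dataclass(frozen=True)
class EventList:
    """Ordered, duplicate-free collection of FrameRefs under one label tag."""

    refs: tuple[FrameRef, ...]
    tag: str = "good"

    def __post_init__(self) -> None:
        if len(set(self.refs)) != len(self.refs):
            dupes = [r for r in self.refs if list(self.refs).count(r) > 1]
            raise FrameStoreError(f"duplicate FrameRef in event list: {dupes[0]}")

    def __len__(self) -> int:
        return len(self.refs)

    def __iter__(self):
        return iter(self.refs)


def _dataset_candidates(h5: h5py.File, limit: int = 20) -> list[str]:
    """Names of datasets in the file, for error messages."""
    found: list[str] = []

    def visit(name: str, obj) -> None:
        if isinstance(obj, h5py.Dataset) and len(found) < limit:
            found.append("/" + name)

    h5.visititems(visit)
    return found


def open_stack(path: str | Path, data_path: str | None = None) -> FrameStack:
    """Open a multi-event (events x rows x cols) or single-frame 2D dataset.

    With ``data_path=None`` the candidates in :data:`DEFAULT_DATA_PATHS`
    are tried in order.
    """
    path = str(path)
    with h5py.File(path, "r") as h5:
        if data_path is None:
            for cand in DEFAULT_DATA_PATHS:
                if cand in h5:
                    data_path = cand
                    break
            else:
                raise FrameStoreError(
                    f"{path}: no dataset at any default location "
                    f"{list(DEFAULT_DATA_PATHS)}; datasets present: "
                    f"{_dataset_candidates(h5)}"
                )
        if data_path not in h5:
            raise FrameStoreError(
                f"{path}: no dataset at {data_path!r}; datasets present: "
                f"{_dataset_candidates(h5)}"
            )
        dset = h5[data_path]
        if dset.ndim == 2:
            n_events, frame_shape = 1, dset.shape
        elif dset.ndim == 3:
            n_events, frame_shape = dset.shape[0], dset.shape[1:]
        else:
            raise FrameStoreError(
                f"{path}:{data_path} has rank {dset.ndim}; expected 2 or 3"
            )
    return FrameStack(path=path, data_path=data_path,
                      n_events=int(n_events),
                      frame_shape=(int(frame_shape[0]), int(frame_shape[1])))


def read_frame(stack: FrameStack, event: int) -> np.ndarray:
    """Read one event's frame as float64, non-finite pixels replaced by 0.

    Classifier features must be finite; the replacement count is logged so
    silently dead panels remain visible in the run log.
    """
    if not 0 <= event < stack.n_events:
        raise FrameStoreError(
            f"event {event} out of range [0, {stack.n_events}) for {stack.path}"
        )
    with h5py.File(stack.path, "r") as h5:
        dset = h5[stack.data_path]
        frame = np.asarray(dset[event] if dset.ndim == 3 else dset[()], dtype=float)
    bad = ~np.isfinite(frame)
    n_bad = int(bad.sum())
    if n_bad:
        logger.info("%s //%d: replaced %d non-finite pixels with 0",
                    stack.path, event, n_bad)
        frame[bad] = 0.0
    return frame


def _write_list(refs, out_path: Path) -> None:
    with open(out_path, "w") as fh:
        for ref in sorted(refs, key=FrameRef.sort_key):
            fh.write(f"{ref}\n")


def write_event_lists(good: EventList, bad: EventList,
                      out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``good.lst`` and ``bad.lst``, one ``path //event`` line each.

    Lines are ordered by (path, event) so output is deterministic; the two
    lists must be disjoint.
    """
    overlap = set(good.refs) & set(bad.refs)
    if overlap:
        first = min(overlap, key=FrameRef.sort_key)
        raise FrameStoreError(f"event in both good and bad lists: {first}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    good_path, bad_path = out_dir / "good.lst", out_dir / "bad.lst"
    _write_list(good.refs, good_path)
    _write_list(bad.refs, bad_path)
    return good_path, bad_path


def read_event_list(path: str | Path, tag: str = "good") -> EventList:
    """Parse an event-list file back into an :class:`EventList`.

    Lines without ``//`` are whole-file references (``event=None``); blank
    lines are ignored; anything else malformed is an error with its line
    number, so a half-written resume file fails loudly.
    """
    refs: list[FrameRef] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if "//" in line:
                file_part, _, ev_part = line.rpartition("//")
                file_part = file_part.strip()
                ev_part = ev_part.strip()
                if not file_part or not ev_part.isdigit():
                    raise FrameStoreError(
                        f"{path}:{lineno}: malformed event-list line {line!r}"
                    )
                refs.append(FrameRef(file_part, int(ev_part)))
            else:
                refs.append(FrameRef(line, None))
    return EventList(refs=tuple(refs), tag=tag)
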