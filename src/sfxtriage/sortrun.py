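"""Batch sorting: apply a trained model to folders of multi-event files.

The sorter walks every matching file, classifies every event exactly
once, and writes good/bad event lists plus a per-file summary.  Work is
partitioned into contiguous per-file event ranges and merged back in
canonical (path, event) order, so the output is byte-identical whatever
the worker count — parallelism only changes wall time, never results.

Execution tiers: a process pool when more than one worker is requested,
otherwise serial in-process; the chosen tier is logged.  Unreadable files
are skipped with a logged error and marked failed in the summary rather
than aborting a long overnight run.
"""

from __future__ import annotations

import glob as globlib
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .classify import FeatureMatrix, TrainedModel
from .frame_store import EventList, FrameRef, FrameStoreError, open_stack
from .geometry import DetectorGeometry
from .labels import GOOD
from .profiling import ROI

logger = logging.getLogger(__name__)

__all__ = ["SortSummary", "FileSummary", "SortRunError", "sort_dataset"]


class SortRunError(ValueError):
    """Sorting-run contract violation (no input files, ROI mismatch)."""


@dataclass(frozen=True)
class FileSummary:
    path: str
    n_events: int
    n_good: int
    n_bad: int
    failed: bool = False
    error: str | None = None


@dataclass(frozen=True)
class SortSummary:
    """Per-file counts plus totals; good + bad = events classified."""

    files: tuple[FileSummary, ...]
    workers: int
    tier: str

    @property
    def n_events(self) -> int:
        return sum(f.n_events for f in self.files if not f.failed)

    @property
    def n_good(self) -> int:
        return sum(f.n_good for f in self.files)

    @property
    def n_bad(self) -> int:
        return sum(f.n_bad for f in self.files)

    @property
    def n_failed_files(self) -> int:
        return sum(1 for f in self.files if f.failed)

    def to_text(self) -> str:
        lines = [f"{'file':<40}{'events':>8}{'good':>8}{'bad':>8}"]
        for f in self.files:
            if f.failed:
                lines.append(f"{f.path:<40}  FAILED: {f.error}")
            else:
                lines.append(f"{f.path:<40}{f.n_events:>8}{f.n_good:>8}{f.n_bad:>8}")
        lines.append(f"{'TOTAL':<40}{self.n_events:>8}{self.n_good:>8}{self.n_bad:>8}")
        lines.append(f"tier: {self.tier} ({self.workers} worker(s))")
        return "\n".join(lines)


def _classify_chunk(path: str, data_path: str, start: int, stop: int,
                    rect: tuple[tuple[int, int], tuple[int, int]],
                    model: TrainedModel) -> tuple[str, int, tuple[str, ...]]:
    """Classify events [start, stop) of one file; picklable work unit."""
    (ss0, ss1), (fs0, fs1) = rect
    with h5py.File(path, "r") as h5:
        dset = h5[data_path]
        if dset.ndim == 3:
            slab = np.asarray(dset[start:stop, ss0:ss1, fs0:fs1], dtype=float)
        else:
            slab = np.asarray(dset[ss0:ss1, fs0:fs1], dtype=float)[None]
    slab[~np.isfinite(slab)] = 0.0
    X = slab.reshape(slab.shape[0], -1)
    refs = tuple(FrameRef(path, e) for e in range(start, stop))
    features = FeatureMatrix(X, refs, model.roi_fingerprint)
    return path, start, model.predict(features)


def sort_dataset(folder: str | Path, glob: str, model: TrainedModel,
                 roi: ROI, geom: DetectorGeometry | None = None,
                 workers: int = 1, data_path: str | None = None,
                 out_dir: str | Path | None = None,
                 chunk_size: int = 64,
                 ) -> tuple[EventList, EventList, SortSummary]:
    """Classify every event of every matching file into good/bad lists.

    ``roi`` must match the model's training ROI (fingerprint check).
    When ``out_dir`` is given, ``good.lst``/``bad.lst`` are written there
    via the frame store.  Returns the two lists and a :class:`SortSummary`.
    """
    folder = Path(folder)
    paths = sorted(str(p) for p in folder.glob(glob))
    if not paths:
        raise SortRunError(f"no files matching {glob!r} in {folder}")

    rect = roi.resolve(geom)
    if roi.fingerprint() != model.roi_fingerprint:
        raise SortRunError(
            f"ROI {roi.fingerprint()!r} does not match the model's training "
            f"ROI {model.roi_fingerprint!r}")
    n_px = (rect[0][1] - rect[0][0]) * (rect[1][1] - rect[1][0])
    if n_px != model.n_features:
        raise SortRunError(
            f"ROI covers {n_px} pixels but model expects {model.n_features}")

    chunks: list[tuple[str, str, int, int]] = []
    open_ok: dict[str, int] = {}
    failures: dict[str, str] = {}
    for path in paths:
        try:
            stack = open_stack(path, data_path)
        except (OSError, FrameStoreError) as exc:
            logger.error("skipping unreadable file %s: %s", path, exc)
            failures[path] = str(exc)
            continue
        open_ok[path] = stack.n_events
        for start in range(0, stack.n_events, chunk_size):
            chunks.append((path, stack.data_path, start,
                           min(start + chunk_size, stack.n_events)))
    if not open_ok:
        raise SortRunError(f"every matching file in {folder} failed to open")

    tier = "process-pool" if workers > 1 else "serial"
    logger.info("sorting %d files in %d chunks via %s tier (%d workers)",
                len(open_ok), len(chunks), tier, workers)

    results: dict[tuple[str, int], tuple[str, ...]] = {}
    if workers > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            futures = [pool.submit(_classify_chunk, p, dp, s0, s1, rect, model)
                       for p, dp, s0, s1 in chunks]
            for fut in futures:
                path, start, labels = fut.result()
                results[(path, start)] = labels
    else:
        for p, dp, s0, s1 in chunks:
            path, start, labels = _classify_chunk(p, dp, s0, s1, rect, model)
            results[(path, start)] = labels

    good_refs: list[FrameRef] = []
    bad_refs: list[FrameRef] = []
    file_summaries: list[FileSummary] = []
    for path in paths:
        if path in failures:
            file_summaries.append(FileSummary(path, 0, 0, 0, failed=True,
                                              error=failures[path]))
            continue
        n_good = n_bad = 0
        for (p, start), labels in sorted(results.items()):
            if p != path:
                continue
            for offset, lab in enumerate(labels):
                ref = FrameRef(path, start + offset)
                if lab == GOOD:
                    good_refs.append(ref)
                    n_good += 1
                else:
                    bad_refs.append(ref)
                    n_bad += 1
        file_summaries.append(FileSummary(path, open_ok[path], n_good, n_bad))

    good = EventList(tuple(sorted(good_refs, key=FrameRef.sort_key)), tag="good")
    bad = EventList(tuple(sorted(bad_refs, key=FrameRef.sort_key)), tag="bad")
    summary = SortSummary(tuple(file_summaries), workers=workers, tier=tier)
    logger.info("sorted %d events: %d good, %d bad (%d failed files)",
                summary.n_events, summary.n_good, summary.n_bad,
                summary.n_failed_files)

    if out_dir is not None:
        from .frame_store import write_event_lists
        write_event_lists(good, bad, out_dir)
    return good, bad, summary
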