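"""Good/bad/skip frame annotations with resume and merge semantics.

Annotation of thousands of frames rarely happens in one sitting, and may
be split across people.  A :class:`LabelSet` persists to three event-list
files (``good.lst``, ``bad.lst``, ``skip.lst``) so an interrupted session
resumes losslessly, and independent sessions merge — with conflicting
labels treated as hard errors rather than votes, because silent label
corruption poisons every model trained afterwards.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .frame_store import EventList, FrameRef, _write_list, read_event_list, write_event_lists

__all__ = ["GOOD", "BAD", "SKIP", "LABELS", "LabelSet", "LabelConflictError",
           "merge_label_sets", "save_label_set", "load_label_set"]

GOOD = "good"
BAD = "bad"
SKIP = "skip"
LABELS = (GOOD, BAD, SKIP)


class LabelConflictError(ValueError):
    """The same frame carries two different labels."""


@dataclass(frozen=True)
class LabelSet:
    """Immutable mapping FrameRef -> label in {good, bad, skip}."""

    labels: Mapping[FrameRef, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ref, lab in self.labels.items():
            if lab not in LABELS:
                raise ValueError(f"invalid label {lab!r} for {ref} (expected one of {LABELS})")

    @classmethod
    def from_refs(cls, good: Iterable[FrameRef] = (), bad: Iterable[FrameRef] = (),
                  skip: Iterable[FrameRef] = ()) -> "LabelSet":
        mapping: dict[FrameRef, str] = {}
        for refs, lab in ((good, GOOD), (bad, BAD), (skip, SKIP)):
            for ref in refs:
                if mapping.get(ref, lab) != lab:
                    raise LabelConflictError(
                        f"{ref} labelled both {mapping[ref]!r} and {lab!r}")
                mapping[ref] = lab
        return cls(mapping)

    def with_label(self, ref: FrameRef, label: str) -> "LabelSet":
        """New LabelSet with one annotation added or overwritten."""
        if label not in LABELS:
            raise ValueError(f"invalid label {label!r}")
        new = dict(self.labels)
        new[ref] = label
        return LabelSet(new)

    def refs_with(self, label: str) -> tuple[FrameRef, ...]:
        return tuple(sorted((r for r, l in self.labels.items() if l == label),
                            key=FrameRef.sort_key))

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(self.labels.values())
        return {lab: c.get(lab, 0) for lab in LABELS}

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, ref: FrameRef) -> bool:
        return ref in self.labels

    def __getitem__(self, ref: FrameRef) -> str:
        return self.labels[ref]


def merge_label_sets(sets: Iterable[LabelSet]) -> LabelSet:
    """Union of several label sets; identical duplicates collapse.

    A frame labelled differently in two sets raises
    :class:`LabelConflictError` naming the frame and both labels.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("merge_label_sets requires at least one LabelSet")
    merged: dict[FrameRef, str] = {}
    for s in sets:
        for ref, lab in s.labels.items():
            if merged.get(ref, lab) != lab:
                raise LabelConflictError(
                    f"conflicting labels for {ref}: {merged[ref]!r} vs {lab!r}")
            merged[ref] = lab
    return LabelSet(merged)


def save_label_set(labelset: LabelSet, out_dir: str | Path) -> dict[str, Path]:
    """Persist to good.lst / bad.lst / skip.lst under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    good = EventList(labelset.refs_with(GOOD), tag=GOOD)
    bad = EventList(labelset.refs_with(BAD), tag=BAD)
    good_path, bad_path = write_event_lists(good, bad, out_dir)
    skip_path = out_dir / "skip.lst"
    _write_list(labelset.refs_with(SKIP), skip_path)
    return {GOOD: good_path, BAD: bad_path, SKIP: skip_path}


def load_label_set(in_dir: str | Path) -> LabelSet:
    """Rebuild a LabelSet from list files; missing files are empty.

    Requires at least one of the three files to exist; a frame present in
    two files is a conflict error.
    """
    in_dir = Path(in_dir)
    found = False
    by_label: dict[str, tuple[FrameRef, ...]] = {}
    for lab in LABELS:
        path = in_dir / f"{lab}.lst"
        if path.exists():
            found = True
            by_label[lab] = read_event_list(path, tag=lab).refs
        else:
            by_label[lab] = ()
    if not found:
        raise FileNotFoundError(
            f"{in_dir}: none of good.lst / bad.lst / skip.lst present")
    return LabelSet.from_refs(good=by_label[GOOD], bad=by_label[BAD],
                              skip=by_label[SKIP])
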