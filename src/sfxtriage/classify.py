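"""ROI-pixel feature extraction, train/test splitting, and the four
supported classifier families.

The feature vector of a frame is simply the flattened pixel intensities of
the region of interest — no engineered descriptors — so the classifier
learns whatever intensity structure separates the annotated good and bad
frames (a miscalibrated band, a shadow, parasitic scattering).  Four
classical families are supported: logistic regression, K-nearest
neighbours, decision tree and random forest; which performs best depends
on the artefact, so all are first-class.

The module is surfaced statsmodels-style: build a :class:`FrameClassifier`
from a :class:`FeatureMatrix` plus labels, call :meth:`~FrameClassifier.fit`
and receive :class:`FrameClassifierResults` carrying the fitted state, a
``predict``/``evaluate``/``summary`` interface and ``save``/``load``
persistence.  Thin functional wrappers (:func:`train_model`,
:func:`predict`, :func:`persist_model`, :func:`restore_model`) expose the
same operations for pipeline code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .frame_store import FrameRef, FrameStack, open_stack, read_frame
from .geometry import DetectorGeometry
from .labels import BAD, GOOD, LabelSet
from .metrics import ClassificationReport, classification_report
from .profiling import ROI

__all__ = [
    "ALGORITHMS",
    "SplitSpec",
    "FeatureMatrix",
    "FrameClassifier",
    "FrameClassifierResults",
    "TrainedModel",
    "ClassifyError",
    "build_features",
    "split_dataset",
    "train_model",
    "predict",
    "persist_model",
    "restore_model",
]

#: Supported classifier families and their default hyperparameters.
ALGORITHMS: dict[str, dict] = {
    "logreg": {},                      # L2 logistic regression, lbfgs
    "knn": {"n_neighbors": 5},         # odd K avoids binary-vote ties
    "dtree": {},                       # unlimited depth
    "rforest": {"n_estimators": 100},
}

_MODEL_FORMAT = "sfxtriage-model/1"

#: Seed-stream tag so split permutations are independent of any other
#: seeded component fed the same user seed.
_SPLIT_STREAM = 0x5350


class ClassifyError(ValueError):
    """Classifier contract violation (bad split, fingerprint mismatch, ...)."""


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test split: fractions must sum to 1 (the 100% rule).

    The default 70/30 split mirrors the tool's standard workflow; a pair
    of fractions not summing to 1 is rejected outright rather than
    renormalized, to avoid unintentional model bias from a typo.
    """

    train_frac: float = 0.7
    test_frac: float = 0.3
    seed: int = 0
    stratify: bool = False

    def __post_init__(self) -> None:
        if self.train_frac <= 0 or self.test_frac <= 0:
            raise ClassifyError("train_frac and test_frac must both be > 0")
        total = self.train_frac + self.test_frac
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ClassifyError(
                f"split fractions must sum to 100%: got train={self.train_frac} "
                f"+ test={self.test_frac} = {total}")


@dataclass(frozen=True)
class FeatureMatrix:
    """n_frames x n_features ROI pixel intensities, rows bound to refs."""

    X: np.ndarray
    refs: tuple[FrameRef, ...]
    roi_fingerprint: str

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ClassifyError(f"feature matrix must be 2D, got shape {X.shape}")
        if X.shape[0] != len(self.refs):
            raise ClassifyError(
                f"{X.shape[0]} feature rows but {len(self.refs)} refs")
        if not np.all(np.isfinite(X)):
            raise ClassifyError("feature matrix contains non-finite values")
        object.__setattr__(self, "X", X)

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, refs: Sequence[FrameRef]) -> "FeatureMatrix":
        index = {r: i for i, r in enumerate(self.refs)}
        rows = [index[r] for r in refs]
        return FeatureMatrix(self.X[rows], tuple(refs), self.roi_fingerprint)


def build_features(refs: Sequence[FrameRef], roi: ROI,
                   geom: DetectorGeometry | None = None,
                   stacks: Mapping[str, FrameStack] | None = None,
                   data_path: str | None = None) -> FeatureMatrix:
    """Extract each frame's ROI slab as a row-major flattened feature row.

    ``stacks`` maps file path -> opened FrameStack; missing entries are
    opened on demand (at ``data_path`` or the default candidates).
    """
    if not refs:
        raise ClassifyError("build_features needs at least one FrameRef")
    stacks = dict(stacks) if stacks else {}
    rows = []
    rect = None
    for ref in refs:
        if ref.event is None:
            raise ClassifyError(f"whole-file ref {ref.path} must be expanded "
                                "to per-event refs before feature extraction")
        if ref.path not in stacks:
            try:
                stacks[ref.path] = open_stack(ref.path, data_path)
            except (OSError, ValueError) as exc:
                raise ClassifyError(f"cannot read {ref}: {exc}") from exc
        stack = stacks[ref.path]
        if rect is None:
            rect = roi.resolve(geom, frame_shape=stack.frame_shape)
        frame = read_frame(stack, ref.event)
        (ss0, ss1), (fs0, fs1) = rect
        rows.append(frame[ss0:ss1, fs0:fs1].ravel())
    return FeatureMatrix(np.asarray(rows, dtype=float), tuple(refs),
                         roi.fingerprint())


def split_dataset(labelset: LabelSet, spec: SplitSpec = SplitSpec()
                  ) -> tuple[tuple[tuple[FrameRef, ...], tuple[str, ...]],
                             tuple[tuple[FrameRef, ...], tuple[str, ...]]]:
    """Seeded uniform random split of the good/bad-labelled frames.

    Frames are put in canonical (path, event) order, permuted under the
    seed, and the first floor(train_frac * N) become the training side.
    The test side is excluded from training by construction.  Skip labels
    are ignored.
    """
    refs = sorted((r for r, l in labelset.labels.items() if l in (GOOD, BAD)),
                  key=FrameRef.sort_key)
    if len(refs) < 2:
        raise ClassifyError("need at least 2 good/bad-labelled frames to split")
    labs = [labelset[r] for r in refs]
    if len(set(labs)) < 2:
        raise ClassifyError("both classes (good and bad) must be present")

    # dedicated stream: the same user seed must not replay another
    # module's permutation (e.g. the synthetic generator's class shuffle)
    rng = np.random.default_rng([spec.seed, _SPLIT_STREAM])
    if spec.stratify:
        perm: list[int] = []
        train_idx: list[int] = []
        test_idx: list[int] = []
        for cls in (GOOD, BAD):
            cls_idx = [i for i, l in enumerate(labs) if l == cls]
            cls_perm = rng.permutation(len(cls_idx))
            n_train = int(math.floor(spec.train_frac * len(cls_idx)))
            ordered = [cls_idx[j] for j in cls_perm]
            train_idx.extend(ordered[:n_train])
            test_idx.extend(ordered[n_train:])
    else:
        order = rng.permutation(len(refs))
        n_train = int(math.floor(spec.train_frac * len(refs)))
        train_idx = list(order[:n_train])
        test_idx = list(order[n_train:])

    if not train_idx or not test_idx:
        raise ClassifyError(
            f"split of {len(refs)} frames at {spec.train_frac:.0%}/"
            f"{spec.test_frac:.0%} leaves one side empty")
    train = (tuple(refs[i] for i in train_idx), tuple(labs[i] for i in train_idx))
    test = (tuple(refs[i] for i in test_idx), tuple(labs[i] for i in test_idx))
    return train, test


def _make_estimator(algorithm: str, hyperparams: dict, seed: int | None,
                    standardize: bool):
    if algorithm not in ALGORITHMS:
        raise ClassifyError(
            f"unknown algorithm {algorithm!r}; supported: {sorted(ALGORITHMS)}")
    params = {**ALGORITHMS[algorithm], **(hyperparams or {})}
    if algorithm == "logreg":
        est = LogisticRegression(max_iter=1000, random_state=seed, **params)
    elif algorithm == "knn":
        est = KNeighborsClassifier(**params)
    elif algorithm == "dtree":
        est = DecisionTreeClassifier(random_state=seed, **params)
    else:
        est = RandomForestClassifier(random_state=seed, **params)
    if standardize:
        # scale-sensitive families benefit; trees are scale-invariant
        est = Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est, params


def _encode(labels: Sequence[str]) -> np.ndarray:
    bad_vals = {l for l in labels if l not in (GOOD, BAD)}
    if bad_vals:
        raise ClassifyError(f"training labels must be good/bad; found {sorted(bad_vals)}")
    return np.asarray([1 if l == GOOD else 0 for l in labels], dtype=int)


class FrameClassifier:
    """Model object: a classifier family bound to features and labels.

    Parameters
    ----------
    features : FeatureMatrix
        Training rows (ROI pixels), with their FrameRefs and ROI identity.
    labels : sequence of str
        One good/bad label per feature row.
    algorithm : {"logreg", "knn", "dtree", "rforest"}
    hyperparams : dict, optional
        Overrides of the family defaults (e.g. ``n_neighbors``,
        ``n_estimators``).
    seed : int
        Seeds the stochastic families (forest bootstrap, solver).
    standardize : bool
        Per-feature standardization fitted on the training rows only;
        off by default since raw pixel intensities are the declared
        feature definition and tree families are scale-invariant.
    """

    def __init__(self, features: FeatureMatrix, labels: Sequence[str],
                 algorithm: str = "rforest", hyperparams: dict | None = None,
                 seed: int = 0, standardize: bool = False) -> None:
        if len(labels) != features.n_frames:
            raise ClassifyError(
                f"{features.n_frames} feature rows but {len(labels)} labels")
        y = _encode(labels)
        if len(np.unique(y)) < 2:
            raise ClassifyError(
                "training set must contain both good and bad frames")
        self.features = features
        self.labels = tuple(labels)
        self.algorithm = algorithm
        self.seed = seed
        self.standardize = standardize
        self._estimator, self.hyperparams = _make_estimator(
            algorithm, hyperparams or {}, seed, standardize)
        self._y = y

    def fit(self) -> "FrameClassifierResults":
        self._estimator.fit(self.features.X, self._y)
        counts = {GOOD: int(self._y.sum()), BAD: int((1 - self._y).sum())}
        return FrameClassifierResults(
            algorithm=self.algorithm,
            estimator=self._estimator,
            hyperparams=dict(self.hyperparams),
            roi_fingerprint=self.features.roi_fingerprint,
            n_features=self.features.n_features,
            seed=self.seed,
            standardize=self.standardize,
            training_class_counts=counts,
        )


@dataclass
class FrameClassifierResults:
    """Fitted classifier state plus its provenance and diagnostics API.

    Predictions require a feature matrix with the same width and ROI
    fingerprint the model was trained on; anything else is an error, never
    a silent reinterpretation of pixels.
    """

    algorithm: str
    estimator: object
    hyperparams: dict
    roi_fingerprint: str
    n_features: int
    seed: int
    standardize: bool
    training_class_counts: dict[str, int]

    def _check(self, features: FeatureMatrix) -> None:
        if features.n_features != self.n_features:
            raise ClassifyError(
                f"feature width {features.n_features} (roi "
                f"{features.roi_fingerprint!r}) does not match model width "
                f"{self.n_features} (roi {self.roi_fingerprint!r})")
        if features.roi_fingerprint != self.roi_fingerprint:
            raise ClassifyError(
                f"ROI fingerprint mismatch: features {features.roi_fingerprint!r} "
                f"vs model {self.roi_fingerprint!r}")

    def predict(self, features: FeatureMatrix) -> tuple[str, ...]:
        """One good/bad label per feature row."""
        self._check(features)
        y = self.estimator.predict(features.X)
        return tuple(GOOD if v == 1 else BAD for v in y)

    def predict_scores(self, features: FeatureMatrix) -> np.ndarray:
        """P(good) per row, from the family's probability estimate."""
        self._check(features)
        proba = self.estimator.predict_proba(features.X)
        classes = getattr(self.estimator, "classes_", None)
        if classes is None:  # Pipeline
            classes = self.estimator[-1].classes_
        return proba[:, list(classes).index(1)]

    def evaluate(self, features: FeatureMatrix,
                 y_true: Sequence[str]) -> ClassificationReport:
        """Confusion matrix + classification report on held-out frames."""
        return classification_report(tuple(y_true), self.predict(features))

    def summary(self, report: ClassificationReport | None = None) -> str:
        lines = [
            "FrameClassifier results",
            f"  algorithm:       {self.algorithm}",
            f"  hyperparams:     {self.hyperparams or 'defaults'}",
            f"  n_features:      {self.n_features}",
            f"  roi:             {self.roi_fingerprint}",
            f"  seed:            {self.seed}",
            f"  training counts: {self.training_class_counts}",
        ]
        if report is not None:
            lines += ["", report.to_text()]
        return "\n".join(lines)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "format": _MODEL_FORMAT,
            "algorithm": self.algorithm,
            "estimator": self.estimator,
            "hyperparams": self.hyperparams,
            "roi_fingerprint": self.roi_fingerprint,
            "n_features": self.n_features,
            "seed": self.seed,
            "standardize": self.standardize,
            "training_class_counts": self.training_class_counts,
        }
        joblib.dump(payload, path)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FrameClassifierResults":
        try:
            payload = joblib.load(path)
        except Exception as exc:
            raise ClassifyError(f"cannot restore model from {path}: {exc}") from exc
        if not isinstance(payload, dict) or payload.get("format") != _MODEL_FORMAT:
            raise ClassifyError(
                f"{path} is not a {_MODEL_FORMAT} model file")
        payload = dict(payload)
        payload.pop("format")
        return cls(**payload)


#: The fitted-model type, under its pipeline-facing name.
TrainedModel = FrameClassifierResults


def train_model(features: FeatureMatrix, labels: Sequence[str],
                algorithm: str = "rforest", hyperparams: dict | None = None,
                seed: int = 0, standardize: bool = False) -> TrainedModel:
    """Fit one of the four supported families; good encodes as 1."""
    return FrameClassifier(features, labels, algorithm=algorithm,
                           hyperparams=hyperparams, seed=seed,
                           standardize=standardize).fit()


def predict(model: TrainedModel, features: FeatureMatrix) -> tuple[str, ...]:
    return model.predict(features)


def persist_model(model: TrainedModel, path: str | Path) -> Path:
    return model.save(path)


def restore_model(path: str | Path) -> TrainedModel:
    return FrameClassifierResults.load(path)
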