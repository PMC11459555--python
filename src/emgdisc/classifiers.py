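"""Discrete gesture classifiers: majority-vote LDA and 1NN-DTW.

Both architectures consume windowed feature sequences (see
:mod:`emgdisc.features`) extracted from variable-length gesture templates and
emit a single :class:`DiscretePrediction` per template — a hard label plus a
per-class confidence vector, the uniform interface the rejection analysis
relies on.

* MVLDA runs a linear discriminant over every window (default 200 ms windows,
  25 ms increments) and discretizes the resulting decision stream by majority
  vote (mode), optionally ignoring rest-class votes.
* 1NN-DTW assigns the label of the stored template with the smallest dynamic
  time warping distance; template banks can be reduced to one representative
  per class either by DTW medoid ("closest") or by resampled averaging
  ("mean").

Ties are always broken toward the lowest class index (classes sorted
lexicographically), which keeps every pipeline deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import GestureTemplate
from .dtw import dtw_distance
from .features import FeatureSequence, WindowingConfig, featurize_template

__all__ = [
    "DiscretePrediction",
    "DecisionStream",
    "Standardizer",
    "LDAModel",
    "fit_lda",
    "predict_stream",
    "majority_vote",
    "MVLDAClassifier",
    "dtw_1nn",
    "reduce_templates_closest",
    "reduce_templates_mean",
    "DTW1NNClassifier",
]

#: MVLDA default windowing: 200 ms windows, 25 ms increments at 200 Hz
MVLDA_WINDOWING = WindowingConfig(window_length=40, increment=5)
REST_LABEL = "rest"


@dataclass
class DiscretePrediction:
    """A single discrete label with a per-class confidence vector."""

    label: str
    classes: tuple[str, ...]
    confidence: np.ndarray

    def __post_init__(self) -> None:
        self.confidence = np.asarray(self.confidence, dtype=float)
        if len(self.confidence) != len(self.classes):
            raise ValueError("confidence length must match classes")
        if np.any(self.confidence < 0) or not np.isfinite(self.confidence).all():
            raise ValueError("confidence entries must be finite and >= 0")
        if abs(self.confidence.sum() - 1.0) > 1e-6:
            raise ValueError("confidence must sum to 1")

    @property
    def max_confidence(self) -> float:
        return float(self.confidence.max())


@dataclass
class DecisionStream:
    """Ordered per-window labels and class-score vectors."""

    labels: list[str]
    classes: tuple[str, ...]
    scores: np.ndarray  # (n_windows, n_classes)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class Standardizer:
    """Per-dimension z-scoring with training-set statistics."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        std = X.std(axis=0)
        return cls(mean=X.mean(axis=0), std=np.where(std > 1e-12, std, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.std


# ---------------------------------------------------------------------------
# Linear discriminant analysis

@dataclass
class LDAModel:
    """Gaussian equal-covariance linear classifier."""

    classes: tuple[str, ...]
    means: np.ndarray  # (k, d)
    covariance: np.ndarray  # (d, d), pooled within-class
    priors: np.ndarray  # (k,)
    _cov_inv: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self._cov_inv is None:
            self._cov_inv = np.linalg.inv(self.covariance)

    def discriminants(self, X: np.ndarray) -> np.ndarray:
        """Linear discriminant scores delta_k(x) per class, (n, k)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        W = self._cov_inv @ self.means.T  # (d, k)
        const = -0.5 * np.sum(self.means * W.T, axis=1) + np.log(self.priors)
        return X @ W + const

    def posterior(self, X: np.ndarray) -> np.ndarray:
        s = self.discriminants(X)
        s -= s.max(axis=1, keepdims=True)
        p = np.exp(s)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> list[str]:
        # argmax returns the first maximum: lowest class index wins ties
        return [self.classes[i] for i in np.argmax(self.discriminants(X), axis=1)]


def fit_lda(
    features: np.ndarray, labels, ridge: float = 1e-8
) -> LDAModel:
    """Fit an LDA with per-class means and pooled within-class covariance.

    The covariance is the within-class scatter normalized by (n - k); a ridge
    of ``ridge * trace / d`` is added on the diagonal whenever the matrix is
    singular (always added in tiny amount for stability).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) < 2:
        raise ValueError("LDA needs at least two classes")
    n, d = X.shape
    k = len(classes)
    means = np.empty((k, d))
    priors = np.empty(k)
    scatter = np.zeros((d, d))
    for i, c in enumerate(classes):
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {c!r} needs at least 2 samples")
        means[i] = Xc.mean(axis=0)
        priors[i] = Xc.shape[0] / n
        R = Xc - means[i]
        scatter += R.T @ R
    cov = scatter / (n - k)
    lam = ridge * np.trace(cov) / d
    cov_reg = cov + lam * np.eye(d)
    # escalate the ridge until invertible / well-conditioned
    while True:
        try:
            inv = np.linalg.inv(cov_reg)
            if np.isfinite(inv).all():
                break
        except np.linalg.LinAlgError:
            pass
        lam = max(lam * 100, 1e-10 * max(np.trace(cov) / d, 1.0))
        cov_reg = cov + lam * np.eye(d)
    return LDAModel(
        classes=classes, means=means, covariance=cov_reg, priors=priors,
        _cov_inv=inv,
    )


def predict_stream(
    model: LDAModel,
    template: GestureTemplate,
    cfg: WindowingConfig = MVLDA_WINDOWING,
    feature_set: str = "RMS",
    standardizer: Standardizer | None = None,
) -> DecisionStream:
    """Continuous per-window LDA decisions over one gesture template."""
    seq = featurize_template(template.samples, cfg, feature_set)
    X = seq.values
    if standardizer is not None:
        X = standardizer.transform(X)
    post = model.posterior(X)
    labels = [model.classes[i] for i in np.argmax(post, axis=1)]
    return DecisionStream(labels=labels, classes=model.classes, scores=post)


def majority_vote(
    stream: DecisionStream, exclude_rest: bool = False,
    rest_label: str = REST_LABEL,
) -> DiscretePrediction:
    """Discretize a decision stream by taking the modal window prediction.

    With ``exclude_rest`` only non-rest votes are counted (falling back to
    rest when there are none).  Confidence is the normalized vote count over
    the voted windows; label ties break toward the lowest class index.
    """
    if len(stream) == 0:
        raise ValueError("empty decision stream")
    votes = stream.labels
    if exclude_rest:
        active = [v for v in votes if v != rest_label]
        if not active:
            conf = np.array(
                [1.0 if c == rest_label else 0.0 for c in stream.classes]
            )
            return DiscretePrediction(rest_label, stream.classes, conf)
        votes = active
    counts = np.array([votes.count(c) for c in stream.classes], dtype=float)
    label = stream.classes[int(np.argmax(counts))]
    return DiscretePrediction(label, stream.classes, counts / counts.sum())


class MVLDAClassifier:
    """Majority-vote LDA pipeline over windowed features."""

    def __init__(
        self,
        cfg: WindowingConfig = MVLDA_WINDOWING,
        feature_set: str = "RMS",
        exclude_rest: bool = False,
    ) -> None:
        self.cfg = cfg
        self.feature_set = feature_set
        self.exclude_rest = exclude_rest
        self.model: LDAModel | None = None
        self.standardizer: Standardizer | None = None

    def fit(self, templates: list[GestureTemplate], rng=None) -> "MVLDAClassifier":
        X, y = [], []
        for t in templates:
            seq = featurize_template(t.samples, self.cfg, self.feature_set)
            X.append(seq.values)
            y.extend([t.label] * len(seq))
        X = np.vstack(X)
        self.standardizer = Standardizer.fit(X)
        self.model = fit_lda(self.standardizer.transform(X), y)
        return self

    @property
    def classes(self) -> tuple[str, ...]:
        return self.model.classes

    def predict(self, template: GestureTemplate) -> DiscretePrediction:
        if self.model is None:
            raise RuntimeError("classifier not fitted")
        stream = predict_stream(
            self.model, template, self.cfg, self.feature_set,
            self.standardizer,
        )
        return majority_vote(stream, exclude_rest=self.exclude_rest)

    def save(self, out_dir) -> None:
        """Serialize the bundle: config JSON + parameter arrays."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "model.json").write_text(json.dumps({
            "kind": "mvlda",
            "windowing": [self.cfg.window_length, self.cfg.increment],
            "feature_set": self.feature_set,
            "exclude_rest": self.exclude_rest,
            "classes": list(self.model.classes),
        }, indent=1))
        np.savez(
            out / "weights.npz",
            means=self.model.means,
            covariance=self.model.covariance,
            priors=self.model.priors,
            std_mean=self.standardizer.mean,
            std_std=self.standardizer.std,
        )

    @classmethod
    def load(cls, in_dir) -> "MVLDAClassifier":
        import json
        from pathlib import Path

        p = Path(in_dir)
        meta = json.loads((p / "model.json").read_text())
        arrays = np.load(p / "weights.npz")
        clf = cls(
            cfg=WindowingConfig(*meta["windowing"]),
            feature_set=meta["feature_set"],
            exclude_rest=meta["exclude_rest"],
        )
        clf.model = LDAModel(
            classes=tuple(meta["classes"]),
            means=arrays["means"],
            covariance=arrays["covariance"],
            priors=arrays["priors"],
        )
        clf.standardizer = Standardizer(arrays["std_mean"], arrays["std_std"])
        return clf


# ---------------------------------------------------------------------------
# 1NN-DTW

def dtw_1nn(
    query: FeatureSequence | np.ndarray,
    bank: list[tuple[str, FeatureSequence | np.ndarray]],
    temperature: float = 1.0,
) -> DiscretePrediction:
    """Label of the DTW-nearest stored sequence, with softmin confidence.

    ``bank`` is a list of (label, sequence) pairs.  Confidence is a softmin
    over per-class minimum distances; distance ties break toward the lowest
    class index.
    """
    if not bank:
        raise ValueError("empty template bank")
    classes = tuple(sorted({label for label, _ in bank}))
    dmin = {c: np.inf for c in classes}
    for label, seq in bank:
        d = dtw_distance(query, seq)
        if d < dmin[label]:
            dmin[label] = d
    dist = np.array([dmin[c] for c in classes])
    label = classes[int(np.argmin(dist))]
    s = -(dist - dist.min()) / temperature
    conf = np.exp(s)
    return DiscretePrediction(label, classes, conf / conf.sum())


def reduce_templates_closest(
    bank: dict[str, list[FeatureSequence | np.ndarray]],
) -> dict[str, FeatureSequence | np.ndarray]:
    """DTW medoid per class: minimal summed distance to same-class templates.

    Index ties break toward the lowest template index.
    """
    out = {}
    for label, seqs in bank.items():
        if not seqs:
            raise ValueError(f"class {label!r} has no templates")
        n = len(seqs)
        if n == 1:
            out[label] = seqs[0]
            continue
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = dtw_distance(seqs[i], seqs[j])
        out[label] = seqs[int(np.argmin(D.sum(axis=1)))]
    return out


def _resample(values: np.ndarray, target_len: int) -> np.ndarray:
    """Linear per-column interpolation to ``target_len`` rows."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n == target_len:
        return values.copy()
    src = np.linspace(0.0, 1.0, n)
    dst = np.linspace(0.0, 1.0, target_len)
    return np.column_stack(
        [np.interp(dst, src, values[:, c]) for c in range(values.shape[1])]
    )


def reduce_templates_mean(
    bank: dict[str, list[FeatureSequence | np.ndarray]],
    target_len: int | None = None,
) -> dict[str, np.ndarray]:
    """Mean template per class after resampling all to a common length.

    ``target_len`` defaults to the per-class median length (>= 2).
    """
    out = {}
    for label, seqs in bank.items():
        if not seqs:
            raise ValueError(f"class {label!r} has no templates")
        mats = [np.asarray(s.values if isinstance(s, FeatureSequence) else s,
                           dtype=float) for s in seqs]
        tl = target_len or max(2, int(np.median([m.shape[0] for m in mats])))
        if tl < 2:
            raise ValueError("target_len must be >= 2")
        out[label] = np.mean([_resample(m, tl) for m in mats], axis=0)
    return out


class DTW1NNClassifier:
    """1NN-DTW over windowed feature sequences, with optional reduction.

    ``reduction`` is one of ``None`` (full bank), ``"closest"`` (per-class
    DTW medoid) or ``"mean"`` (per-class resampled average).
    """

    #: default DTW windowing: non-overlapping 25 ms RMS windows
    DEFAULT_WINDOWING = WindowingConfig(window_length=5, increment=5)

    def __init__(
        self,
        cfg: WindowingConfig = DEFAULT_WINDOWING,
        feature_set: str = "RMS",
        reduction: str | None = None,
        temperature: float = 1.0,
    ) -> None:
        if reduction not in (None, "closest", "mean"):
            raise ValueError(f"unknown reduction {reduction!r}")
        self.cfg = cfg
        self.feature_set = feature_set
        self.reduction = reduction
        self.temperature = temperature
        self.bank: list[tuple[str, np.ndarray]] | None = None
        self.standardizer: Standardizer | None = None

    def _featurize(self, t: GestureTemplate) -> np.ndarray:
        seq = featurize_template(t.samples, self.cfg, self.feature_set)
        return self.standardizer.transform(seq.values)

    def fit(self, templates: list[GestureTemplate], rng=None) -> "DTW1NNClassifier":
        raw = [featurize_template(t.samples, self.cfg, self.feature_set).values
               for t in templates]
        self.standardizer = Standardizer.fit(np.vstack(raw))
        per_class: dict[str, list[np.ndarray]] = {}
        for t, v in zip(templates, raw):
            per_class.setdefault(t.label, []).append(
                self.standardizer.transform(v)
            )
        per_class = dict(sorted(per_class.items()))
        if self.reduction == "closest":
            reduced = reduce_templates_closest(per_class)
            self.bank = [(c, reduced[c]) for c in reduced]
        elif self.reduction == "mean":
            reduced = reduce_templates_mean(per_class)
            self.bank = [(c, reduced[c]) for c in reduced]
        else:
            self.bank = [(c, v) for c, vs in per_class.items() for v in vs]
        return self

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted({c for c, _ in self.bank}))

    def predict(self, template: GestureTemplate) -> DiscretePrediction:
        if self.bank is None:
            raise RuntimeError("classifier not fitted")
        return dtw_1nn(self._featurize(template), self.bank, self.temperature)

    def save(self, out_dir) -> None:
        """Serialize the bundle: config JSON + the stored template bank."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        labels = [label for label, _ in self.bank]
        (out / "model.json").write_text(json.dumps({
            "kind": "dtw_1nn",
            "windowing": [self.cfg.window_length, self.cfg.increment],
            "feature_set": self.feature_set,
            "reduction": self.reduction,
            "temperature": self.temperature,
            "bank_labels": labels,
        }, indent=1))
        arrays = {
            f"bank{i}": np.asarray(
                seq.values if isinstance(seq, FeatureSequence) else seq
            )
            for i, (_, seq) in enumerate(self.bank)
        }
        arrays["std_mean"] = self.standardizer.mean
        arrays["std_std"] = self.standardizer.std
        np.savez(out / "weights.npz", **arrays)

    @classmethod
    def load(cls, in_dir) -> "DTW1NNClassifier":
        import json
        from pathlib import Path

        p = Path(in_dir)
        meta = json.loads((p / "model.json").read_text())
        arrays = np.load(p / "weights.npz")
        clf = cls(
            cfg=WindowingConfig(*meta["windowing"]),
            feature_set=meta["feature_set"],
            reduction=meta["reduction"],
            temperature=meta["temperature"],
        )
        clf.standardizer = Standardizer(arrays["std_mean"], arrays["std_std"])
        clf.bank = [
            (label, arrays[f"bank{i}"])
            for i, label in enumerate(meta["bank_labels"])
        ]
        return clf
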