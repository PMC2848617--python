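"""Equal-frequency discretization and the AODE classifier.

AODE (Averaged One-Dependence Estimators) averages over all one-dependence
estimators whose parent attribute value is sufficiently frequent:

    score(y) = sum over known attributes i with F(x_i) >= m of
               P(y, x_i) * prod over known j != i of P(x_j | y, x_i)

with add-one (Laplace) smoothing of every probability estimate:

    P(y, x_i)      = (N(y, x_i) + 1) / (N_i + k * v_i)
    P(x_j | y, x_i) = (N(x_j, y, x_i) + 1) / (N(y, x_i) + v_j)

where N_i counts training rows in which attribute i is known, k is the
number of classes and v_i the number of values of attribute i.  Missing
values are a first-class sentinel (code ``-1``): they contribute to no
count and to no factor at prediction time — predictions never error on
missing data.  When no attribute qualifies as a parent the classifier
falls back to a Naive Bayes estimate over the known attributes (with
P(x_i | y) taken as P(y, x_i) / P(y), so a single-attribute AODE and NB
agree exactly).

A zero-dependence (Naive Bayes) twin with identical smoothing and
missing-value semantics is provided as an internal oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1  # band code for a missing value; never a real band

DEFAULT_MIN_PER_BAND = 50
DEFAULT_TARGET_BANDS = 10
DEFAULT_PARENT_FREQUENCY = 1  # m: minimum training frequency of a parent value


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

@dataclass
class DiscretizationModel:
    """Per-attribute strictly increasing cut points.

    Attribute values are mapped to bands with a left-closed convention:
    band index = number of cut points <= value, i.e. a value equal to a cut
    point falls in the band to its right.  Attributes that were entirely
    missing at fit time stay always-missing.
    """

    cuts: dict[str, np.ndarray]
    always_missing: set[str] = field(default_factory=set)

    def n_bands(self, attribute: str) -> int:
        if attribute in self.always_missing:
            return 1
        return len(self.cuts[attribute]) + 1

    @property
    def attributes(self) -> list[str]:
        return list(self.cuts)


def _equal_frequency_cuts(
    values: np.ndarray, n_bands: int, min_per_band: int
) -> np.ndarray:
    """Cut points giving ~equal-count, left-closed bands, each holding at
    least ``min_per_band`` values (bands breaking the floor are merged)."""
    ordered = np.sort(values)
    n = ordered.shape[0]
    positions = [int(round(i * n / n_bands)) for i in range(1, n_bands)]
    cuts = np.unique(ordered[[min(p, n - 1) for p in positions]])
    while cuts.size:
        counts = np.bincount(
            np.searchsorted(cuts, ordered, side="right"), minlength=cuts.size + 1
        )
        smallest = int(np.argmin(counts))
        if counts[smallest] >= min_per_band:
            break
        # merge the smallest band with its smaller neighbour
        if smallest == 0:
            drop = 0
        elif smallest == cuts.size:
            drop = cuts.size - 1
        elif counts[smallest - 1] <= counts[smallest + 1]:
            drop = smallest - 1
        else:
            drop = smallest
        cuts = np.delete(cuts, drop)
    return cuts


def fit_discretizer(
    training: pd.DataFrame,
    min_per_band: int = DEFAULT_MIN_PER_BAND,
    target_bands: int = DEFAULT_TARGET_BANDS,
) -> DiscretizationModel:
    """Equal-frequency binning with a minimum band population.

    The band count per attribute is ``max(1, min(target_bands,
    n_nonmissing // min_per_band))``; cut points sit at empirical
    quantiles, duplicates merged.
    """
    cuts: dict[str, np.ndarray] = {}
    always_missing: set[str] = set()
    for attribute in training.columns:
        values = training[attribute].to_numpy(dtype=float)
        values = values[~np.isnan(values)]
        if values.size == 0:
            log.warning("attribute %r entirely missing; modeled as always-missing", attribute)
            always_missing.add(attribute)
            cuts[attribute] = np.array([])
            continue
        n_bands = max(1, min(target_bands, values.size // min_per_band))
        cuts[attribute] = (
            _equal_frequency_cuts(values, n_bands, min_per_band)
            if n_bands > 1
            else np.array([])
        )
    return DiscretizationModel(cuts=cuts, always_missing=always_missing)


def discretize(
    values: pd.DataFrame | Mapping[str, float | None],
    model: DiscretizationModel,
) -> np.ndarray:
    """Map raw attribute values to band codes (``MISSING`` for NaN/None).

    Accepts a DataFrame (rows = instances) or a single mapping; returns an
    int array of shape (n, n_attributes) or (n_attributes,).  Out-of-range
    values clamp to the first/last band via the searchsorted convention.
    """
    single = not isinstance(values, pd.DataFrame)
    if single:
        frame = pd.DataFrame([dict(values)])
    else:
        frame = values
    n = len(frame)
    codes = np.full((n, len(model.attributes)), MISSING, dtype=np.int64)
    for j, attribute in enumerate(model.attributes):
        if attribute in model.always_missing:
            continue
        column = frame[attribute].to_numpy(dtype=float)
        known = ~np.isnan(column)
        codes[known, j] = np.searchsorted(
            model.cuts[attribute], column[known], side="right"
        )
    return codes[0] if single else codes


# ---------------------------------------------------------------------------
# Count-table models
# ---------------------------------------------------------------------------

@dataclass
class AODEModel:
    """Class/attribute count tables for the averaged one-dependence model."""

    attributes: list[str]
    classes: list[str]
    n_values: np.ndarray  # values per attribute (v_i)
    joint: np.ndarray  # (A, K, V): N(y, x_i = v)
    pair: np.ndarray  # (A, A, K, V, V): N(x_i = v_i, x_j = v_j, y)
    n_known: np.ndarray  # (A,): rows where attribute i is known
    class_counts: np.ndarray  # (K,)
    n_rows: int
    m: int = DEFAULT_PARENT_FREQUENCY
    discretizer: DiscretizationModel | None = None

    # -- derived probability tables (cached) --------------------------------

    def __post_init__(self) -> None:
        self._tables: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None

    def _probability_tables(self):
        if self._tables is None:
            A = len(self.attributes)
            K = len(self.classes)
            V = int(self.n_values.max())
            p_joint = np.zeros((A, K, V))
            for a in range(A):
                v = int(self.n_values[a])
                p_joint[a, :, :v] = (self.joint[a, :, :v] + 1.0) / (
                    self.n_known[a] + K * v
                )
            p_cond = np.zeros((A, A, K, V, V))  # P(x_j = vj | y, x_i = vi)
            for a in range(A):
                for b in range(A):
                    if a == b:
                        continue
                    vb = int(self.n_values[b])
                    denom = self.joint[a][:, :, None] + vb  # (K, V, 1)
                    p_cond[a, b] = (self.pair[a, b] + 1.0) / denom
            freq = self.joint.sum(axis=1)  # (A, V): F(x_i = v)
            p_class = (self.class_counts + 1.0) / (self.n_rows + K)
            self._tables = (p_joint, p_cond, freq, p_class)
        return self._tables

    # -- serialization ------------------------------------------------------

    def to_json_dict(self) -> dict:
        payload = {
            "attributes": self.attributes,
            "classes": self.classes,
            "n_values": self.n_values.tolist(),
            "joint": self.joint.tolist(),
            "pair": self.pair.tolist(),
            "n_known": self.n_known.tolist(),
            "class_counts": self.class_counts.tolist(),
            "n_rows": self.n_rows,
            "m": self.m,
        }
        if self.discretizer is not None:
            payload["discretizer"] = {
                "cuts": {a: c.tolist() for a, c in self.discretizer.cuts.items()},
                "always_missing": sorted(self.discretizer.always_missing),
            }
        return payload

    @classmethod
    def from_json_dict(cls, payload: dict) -> "AODEModel":
        discretizer = None
        if "discretizer" in payload:
            spec = payload["discretizer"]
            discretizer = DiscretizationModel(
                cuts={a: np.asarray(c, dtype=float) for a, c in spec["cuts"].items()},
                always_missing=set(spec["always_missing"]),
            )
        return cls(
            attributes=list(payload["attributes"]),
            classes=list(payload["classes"]),
            n_values=np.asarray(payload["n_values"], dtype=np.int64),
            joint=np.asarray(payload["joint"], dtype=np.int64),
            pair=np.asarray(payload["pair"], dtype=np.int64),
            n_known=np.asarray(payload["n_known"], dtype=np.int64),
            class_counts=np.asarray(payload["class_counts"], dtype=np.int64),
            n_rows=int(payload["n_rows"]),
            m=int(payload["m"]),
            discretizer=discretizer,
        )


@dataclass
class NBModel:
    """Zero-dependence twin of :class:`AODEModel` (internal oracle)."""

    attributes: list[str]
    classes: list[str]
    n_values: np.ndarray
    joint: np.ndarray
    n_known: np.ndarray
    class_counts: np.ndarray
    n_rows: int


def _encode_labels(y: Sequence[str]) -> tuple[list[str], np.ndarray]:
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes, got {classes}")
    index = {c: i for i, c in enumerate(classes)}
    return classes, np.fromiter((index[label] for label in y), dtype=np.int64, count=len(y))


def _count_tables(X: np.ndarray, y_codes: np.ndarray, K: int, n_values: np.ndarray):
    N, A = X.shape
    V = int(n_values.max())
    joint = np.zeros((A, K, V), dtype=np.int64)
    n_known = np.zeros(A, dtype=np.int64)
    known = X >= 0
    for a in range(A):
        mask = known[:, a]
        n_known[a] = int(mask.sum())
        np.add.at(joint[a], (y_codes[mask], X[mask, a]), 1)
    return joint, n_known, known


def fit_aode(
    X: np.ndarray,
    y: Sequence[str],
    attributes: Sequence[str],
    n_values: Sequence[int] | None = None,
    m: int = DEFAULT_PARENT_FREQUENCY,
    discretizer: DiscretizationModel | None = None,
) -> AODEModel:
    """Single-pass count tables over a discretized training set.

    ``X`` is an (N, A) integer array of band codes with ``MISSING`` for
    unknown values; ``y`` the class labels (>= 2 classes required).
    Missing values contribute to no count involving that attribute.
    """
    X = np.asarray(X, dtype=np.int64)
    if X.ndim != 2 or X.shape[1] != len(attributes):
        raise ValueError("X must be (N, n_attributes)")
    classes, y_codes = _encode_labels(list(y))
    K = len(classes)
    A = X.shape[1]
    if n_values is None:
        n_values = np.maximum(X.max(axis=0), 0) + 1
    n_values = np.asarray(n_values, dtype=np.int64)
    if (X >= n_values[None, :]).any():
        raise ValueError("band code out of declared range")
    joint, n_known, known = _count_tables(X, y_codes, K, n_values)
    V = int(n_values.max())
    pair = np.zeros((A, A, K, V, V), dtype=np.int64)
    for a in range(A):
        for b in range(a + 1, A):
            both = known[:, a] & known[:, b]
            if not both.any():
                continue
            np.add.at(pair[a, b], (y_codes[both], X[both, a], X[both, b]), 1)
            pair[b, a] = pair[a, b].transpose(0, 2, 1)
    class_counts = np.bincount(y_codes, minlength=K).astype(np.int64)
    return AODEModel(
        attributes=list(attributes),
        classes=classes,
        n_values=n_values,
        joint=joint,
        pair=pair,
        n_known=n_known,
        class_counts=class_counts,
        n_rows=X.shape[0],
        m=m,
        discretizer=discretizer,
    )


def fit_nb(
    X: np.ndarray,
    y: Sequence[str],
    attributes: Sequence[str],
    n_values: Sequence[int] | None = None,
) -> NBModel:
    X = np.asarray(X, dtype=np.int64)
    classes, y_codes = _encode_labels(list(y))
    K = len(classes)
    if n_values is None:
        n_values = np.maximum(X.max(axis=0), 0) + 1
    n_values = np.asarray(n_values, dtype=np.int64)
    joint, n_known, _ = _count_tables(X, y_codes, K, n_values)
    class_counts = np.bincount(y_codes, minlength=K).astype(np.int64)
    return NBModel(
        attributes=list(attributes),
        classes=classes,
        n_values=n_values,
        joint=joint,
        n_known=n_known,
        class_counts=class_counts,
        n_rows=X.shape[0],
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _nb_scores_from_tables(
    X: np.ndarray,
    classes: Sequence[str],
    n_values: np.ndarray,
    joint: np.ndarray,
    n_known: np.ndarray,
    class_counts: np.ndarray,
    n_rows: int,
) -> np.ndarray:
    """Unnormalized NB scores: P(y) * prod_i P(y, x_i) / P(y) over known i."""
    K = len(classes)
    N, A = X.shape
    p_class = (class_counts + 1.0) / (n_rows + K)
    Xc = np.clip(X, 0, None)
    known = X >= 0
    scores = np.tile(p_class, (N, 1))
    for a in range(A):
        v = int(n_values[a])
        p_joint_a = (joint[a, :, :v] + 1.0) / (n_known[a] + K * v)  # (K, v)
        factor = p_joint_a[:, Xc[:, a]].T / p_class[None, :]  # (N, K)
        scores = np.where(known[:, a][:, None], scores * factor, scores)
    return scores


def predict_proba(model: AODEModel, X: np.ndarray) -> np.ndarray:
    """Class probability distribution(s) for discretized instance(s).

    Accepts a single instance (1-D) or a matrix (N, A); returns the
    matching shape with probabilities summing to one per instance.  Never
    errors on missing values; instances where no parent qualifies fall
    back to Naive Bayes over the known attributes (prior if none known).
    """
    X = np.asarray(X, dtype=np.int64)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    N, A = X.shape
    if A != len(model.attributes):
        raise ValueError(f"instance has {A} attributes, model expects {len(model.attributes)}")
    p_joint, p_cond, freq, _ = model._probability_tables()
    K = len(model.classes)
    Xc = np.clip(X, 0, None)
    known = X >= 0
    scores = np.zeros((N, K))
    for a in range(A):
        ka = known[:, a]
        if not ka.any():
            continue
        qualifies = ka & (freq[a, Xc[:, a]] >= model.m)
        if not qualifies.any():
            continue
        for c in range(K):
            term = p_joint[a, c, Xc[:, a]].copy()
            for b in range(A):
                if b == a:
                    continue
                factor = p_cond[a, b, c][Xc[:, a], Xc[:, b]]
                term = np.where(known[:, b], term * factor, term)
            scores[:, c] += np.where(qualifies, term, 0.0)
    fallback = ~(scores.sum(axis=1) > 0.0)
    if fallback.any():
        scores[fallback] = _nb_scores_from_tables(
            X[fallback],
            model.classes,
            model.n_values,
            model.joint,
            model.n_known,
            model.class_counts,
            model.n_rows,
        )
    probs = scores / scores.sum(axis=1, keepdims=True)
    return probs[0] if single else probs


def nb_predict(model: NBModel, X: np.ndarray) -> np.ndarray:
    """Naive Bayes posterior(s) with AODE-consistent smoothing."""
    X = np.asarray(X, dtype=np.int64)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    scores = _nb_scores_from_tables(
        X, model.classes, model.n_values, model.joint,
        model.n_known, model.class_counts, model.n_rows,
    )
    probs = scores / scores.sum(axis=1, keepdims=True)
    return probs[0] if single else probs


def positive_probability(
    model: AODEModel, X: np.ndarray, positive: str = "positive"
) -> np.ndarray | float:
    probs = predict_proba(model, X)
    index = model.classes.index(positive)
    return probs[..., index]


def predict(
    model: AODEModel,
    X: np.ndarray,
    threshold: float = 0.5,
    positive: str = "positive",
):
    """Label + positive-class probability at a decision threshold.

    Positive iff P(positive | x) >= threshold, except an exact tie with the
    best other class, which is resolved conservatively as negative.
    Returns ``(labels, probabilities)`` (scalars for a single instance).
    """
    probs = predict_proba(model, X)
    single = probs.ndim == 1
    probs2 = np.atleast_2d(probs)
    index = model.classes.index(positive)
    p_pos = probs2[:, index]
    others = np.delete(probs2, index, axis=1)
    other_labels = [c for c in model.classes if c != positive]
    best_other = others.max(axis=1)
    tie = p_pos == best_other
    rest = np.asarray(other_labels)[others.argmax(axis=1)]
    labels = np.where((p_pos >= threshold) & ~tie, positive, rest)
    if single:
        return str(labels[0]), float(p_pos[0])
    return labels, p_pos
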