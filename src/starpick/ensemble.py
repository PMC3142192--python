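"""Voting-ensemble classifier with wrapper feature selection.

Training proceeds in two stages: forward feature selection keeps,
for each subset size 1..10, the ten subsets with the best leave-one-out
cross-validation accuracy (a beam of width ten); every recorded subset is
then put through a stability analysis of repeated random 75/25
train/test partitions, whose mean test accuracy is the stability index.
The subset with the highest stability index wins (ties: smaller subset,
then lexicographic feature order) and the classifiers trained during its
stability rounds become the voting ensemble: the reported interaction
probability is the fraction of base classifiers voting "interacting".

The base learner is a depth-limited decision tree (information-gain
splits, deterministic tie-breaking by feature index then threshold).  It
is scale-free, cheap enough for the thousands of fits the wrapper needs,
and interpretable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from starpick.features import FEATURE_NAMES

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

N_BASE_CLASSIFIERS = 1000
#: minimum samples per leaf of the base tree; a variance floor that keeps
#: depth-3 trees from memorizing handfuls of rows on ~130-sample tables
MIN_LEAF = 5
TRAIN_FRACTION = 0.75
POSITIVE, NEGATIVE = "positive", "negative"


# ---------------------------------------------------------------------------
# base learner


class DecisionTree:
    """Depth-limited binary decision tree with information-gain splits.

    Ties between candidate splits are broken by smaller feature index,
    then smaller threshold; leaves predict the majority label with ties
    going to the negative class.  Entirely deterministic.
    """

    def __init__(self, max_depth: int = 3, min_leaf: int = MIN_LEAF):
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        # flat arrays: for node k, feature[k] < 0 marks a leaf with value[k]
        self.feature = np.empty(0, dtype=np.int64)
        self.threshold = np.empty(0)
        self.left = np.empty(0, dtype=np.int64)
        self.right = np.empty(0, dtype=np.int64)
        self.value = np.empty(0, dtype=np.int8)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DecisionTree":
        from starpick import _tree

        X = np.ascontiguousarray(X, dtype=float)
        y = np.ascontiguousarray(y, dtype=np.int8)
        (
            self.feature,
            self.threshold,
            self.left,
            self.right,
            self.value,
        ) = _tree.fit_tree(X, y, self.max_depth, self.min_leaf)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        from starpick import _tree

        X = np.atleast_2d(np.ascontiguousarray(X, dtype=float))
        return _tree.predict_tree(
            X, self.feature, self.threshold, self.left, self.right, self.value
        )

    def to_dict(self) -> dict:
        return {
            "max_depth": self.max_depth,
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "value": self.value.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        t = cls(max_depth=d["max_depth"])
        t.feature = np.asarray(d["feature"], dtype=np.int64)
        t.threshold = np.asarray(d["threshold"], dtype=float)
        t.left = np.asarray(d["left"], dtype=np.int64)
        t.right = np.asarray(d["right"], dtype=np.int64)
        t.value = np.asarray(d["value"], dtype=np.int8)
        return t


# ---------------------------------------------------------------------------
# training table


class TrainingTable:
    """Labeled 22-feature table with per-row provenance.

    Backed by a DataFrame with columns f1..f22, label (positive/negative)
    and optional pair_id/seed_id provenance columns.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in FEATURE_NAMES if c not in frame.columns]
        if missing:
            raise ValueError(f"feature table lacks columns {missing}")
        if "label" not in frame.columns:
            raise ValueError("feature table lacks a label column")
        bad = set(frame["label"]) - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"unrecognized labels {sorted(bad)}")
        counts = frame["label"].value_counts()
        if counts.get(POSITIVE, 0) < 2 or counts.get(NEGATIVE, 0) < 2:
            raise ValueError("need at least 2 rows per class")
        if {"pair_id", "seed_id"} <= set(frame.columns):
            if frame.duplicated(subset=["pair_id", "seed_id"]).any():
                raise ValueError("duplicate (pair, site) rows in training table")
        self.frame = frame.reset_index(drop=True)
        self.X = self.frame[list(FEATURE_NAMES)].to_numpy(dtype=float)
        self.y = (self.frame["label"] == POSITIVE).to_numpy().astype(np.int8)

    def __len__(self) -> int:
        return len(self.frame)

    def columns(self, subset: Sequence[int]) -> np.ndarray:
        """Design matrix restricted to 1-based feature ids."""
        return self.X[:, [i - 1 for i in subset]]

    def checksum(self) -> str:
        return hashlib.sha256(
            self.frame[list(FEATURE_NAMES) + ["label"]]
            .to_csv(index=False)
            .encode()
        ).hexdigest()[:16]


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def build_training_samples(
    candidates: dict[str, list],
    validated_sites: dict[str, list[tuple[int, int]]],
) -> list[tuple[str, object, object, str]]:
    """Label extended binding sites as positive/negative training samples.

    ``candidates`` maps a pair id to its (SeedMatch, BindingSite) tuples;
    ``validated_sites`` maps a pair id to experimentally verified target
    intervals.  Per pair: among candidates whose target site overlaps a
    validated interval, the one with the smallest seed ddG becomes the
    positive sample; remaining candidates overlapping the positive are
    discarded; mutually overlapping negatives are deduplicated keeping the
    smallest seed ddG.  Returns (pair_id, seed, site, label) rows.
    """
    rows: list[tuple[str, object, object, str]] = []
    for pair_id, cands in candidates.items():
        validated = validated_sites.get(pair_id, [])
        consistent = [
            (seed, site)
            for seed, site in cands
            if any(_overlap(site.target_site, v) for v in validated)
        ]
        positive = None
        if validated:
            if consistent:
                positive = min(consistent, key=lambda c: c[0].ddg_seed)
                rows.append((pair_id, positive[0], positive[1], POSITIVE))
            else:
                logger.warning(
                    "pair %s: no candidate consistent with validated site",
                    pair_id,
                )
        pool = [
            (seed, site)
            for seed, site in cands
            if positive is None
            or (
                site is not positive[1]
                and not _overlap(site.target_site, positive[1].target_site)
            )
        ]
        accepted: list = []
        for seed, site in sorted(pool, key=lambda c: c[0].ddg_seed):
            if not any(_overlap(site.target_site, a[1].target_site) for a in accepted):
                accepted.append((seed, site))
        accepted.sort(key=lambda c: c[1].target_site)
        rows.extend((pair_id, seed, site, NEGATIVE) for seed, site in accepted)
    return rows


# ---------------------------------------------------------------------------
# feature selection


def loocv_accuracy(
    table: TrainingTable, subset: Sequence[int], max_depth: int = 3
) -> float:
    """Leave-one-out accuracy of the base learner on the given features."""
    X = table.columns(subset)
    y = table.y
    n = len(y)
    correct = 0
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        tree = DecisionTree(max_depth).fit(X[mask], y[mask])
        correct += int(tree.predict(X[i : i + 1])[0] == y[i])
    return correct / n


def loocv_forward_selection(
    table: TrainingTable,
    max_features: int = 10,
    n_best: int = 10,
    max_depth: int = 3,
) -> dict[int, list[tuple[tuple[int, ...], float]]]:
    """Greedy forward selection keeping the ``n_best`` subsets per size.

    Returns {size: [(subset, loocv_accuracy), ...]} with each list sorted
    by descending accuracy, ties broken lexicographically.  Stops early
    when fewer features remain than the requested size.
    """
    n_feat = len(FEATURE_NAMES)
    max_features = min(max_features, n_feat)
    cache: dict[tuple[int, ...], float] = {}

    def acc(subset: tuple[int, ...]) -> float:
        if subset not in cache:
            cache[subset] = loocv_accuracy(table, subset, max_depth)
        return cache[subset]

    results: dict[int, list[tuple[tuple[int, ...], float]]] = {}
    beam: list[tuple[int, ...]] = [()]
    for k in range(1, max_features + 1):
        candidates = {
            tuple(sorted(base + (f,)))
            for base in beam
            for f in range(1, n_feat + 1)
            if f not in base
        }
        scored = sorted(
            ((s, acc(s)) for s in candidates),
            key=lambda t: (-t[1], t[0]),
        )[:n_best]
        if not scored:
            break
        results[k] = scored
        beam = [s for s, _ in scored]
    return results


# ---------------------------------------------------------------------------
# stability analysis and the ensemble


@dataclasses.dataclass
class BaseClassifier:
    """One voter: a tree trained on one random 75 percent split."""

    tree: DecisionTree
    training_split_id: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.tree.predict(X)


def _round_seed(master: int, subset: Sequence[int], round_idx: int) -> int:
    """Deterministic per-round seed below 2**31."""
    key = f"{master}:{','.join(map(str, subset))}:{round_idx}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def stability_analysis(
    subset: Sequence[int],
    table: TrainingTable,
    n_rounds: int = N_BASE_CLASSIFIERS,
    train_fraction: float = TRAIN_FRACTION,
    rng_seed: int = 0,
    max_depth: int = 3,
) -> tuple[float, list[BaseClassifier]]:
    """Repeated random 75/25 partitions: train, score on the held-out 25%.

    The stability index is the mean of the ``n_rounds`` test accuracies;
    the trained classifiers are returned for use as ensemble voters.
    Rounds whose training portion misses a class are resampled (logged).
    """
    if not subset:
        raise ValueError("subset must be nonempty")
    X = table.columns(subset)
    y = table.y
    n = len(y)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    accs = np.empty(n_rounds)
    classifiers: list[BaseClassifier] = []
    for r in range(n_rounds):
        for attempt in range(100):
            rng = np.random.default_rng(_round_seed(rng_seed, subset, r * 100 + attempt))
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if 0 < y[tr].sum() < n_train:
                break
            logger.debug("round %d: degenerate split, resampling", r)
        tree = DecisionTree(max_depth).fit(X[tr], y[tr])
        accs[r] = float((tree.predict(X[te]) == y[te]).mean())
        classifiers.append(BaseClassifier(tree, training_split_id=r))
    return float(accs.mean()), classifiers


@dataclasses.dataclass
class EnsembleModel:
    """The trained predictor: a feature subset and its voting classifiers."""

    feature_subset: tuple[int, ...]
    base: list[BaseClassifier]
    rng_seed: int
    engine_metadata: dict
    stability_index: float
    training_checksum: str = ""

    def __post_init__(self):
        if not self.base:
            raise ValueError("ensemble needs at least one base classifier")

    @property
    def n_base(self) -> int:
        return len(self.base)

    def predict_probability(self, features) -> float:
        """Fraction of base classifiers voting positive, on the 0.001 grid."""
        x = self._design_row(features)
        votes = sum(int(c.predict(x)[0]) for c in self.base)
        return round(votes / self.n_base, 3)

    def _design_row(self, features) -> np.ndarray:
        from starpick.features import FeatureVector

        if isinstance(features, FeatureVector):
            return np.array([[features[i] for i in self.feature_subset]])
        arr = np.asarray(features, dtype=float)
        if arr.ndim == 1 and arr.size == len(FEATURE_NAMES):
            return arr[[i - 1 for i in self.feature_subset]][None, :]
        if arr.ndim == 1 and arr.size == len(self.feature_subset):
            return arr[None, :]
        raise ValueError(
            "features must be a FeatureVector, a 22-vector, or a subset vector"
        )

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "feature_subset": list(self.feature_subset),
            "rng_seed": self.rng_seed,
            "engine_metadata": self.engine_metadata,
            "stability_index": self.stability_index,
            "training_checksum": self.training_checksum,
            "base": [
                {"split_id": c.training_split_id, "tree": c.tree.to_dict()}
                for c in self.base
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {d.get('format_version')}"
            )
        return cls(
            feature_subset=tuple(d["feature_subset"]),
            base=[
                BaseClassifier(DecisionTree.from_dict(b["tree"]), b["split_id"])
                for b in d["base"]
            ],
            rng_seed=d["rng_seed"],
            engine_metadata=d["engine_metadata"],
            stability_index=d["stability_index"],
            training_checksum=d.get("training_checksum", ""),
        )


def select_final_subset_by_stability(
    candidates: Sequence[tuple[int, ...]],
    table: TrainingTable,
    rng_seed: int = 0,
    n_rounds: int = N_BASE_CLASSIFIERS,
    engine_metadata: Optional[dict] = None,
    max_depth: int = 3,
) -> tuple[tuple[int, ...], EnsembleModel]:
    """Evaluate each candidate subset's stability index and keep the best.

    Ties prefer the smaller subset, then lexicographic order.  The winning
    subset's stability-round classifiers become the ensemble.
    """
    if not candidates:
        raise ValueError("no candidate subsets")
    best = None
    for subset in candidates:
        idx, classifiers = stability_analysis(
            subset, table, n_rounds=n_rounds, rng_seed=rng_seed, max_depth=max_depth
        )
        key = (-idx, len(subset), subset)
        if best is None or key < best[0]:
            best = (key, subset, idx, classifiers)
    _, subset, idx, classifiers = best
    model = EnsembleModel(
        feature_subset=subset,
        base=classifiers,
        rng_seed=rng_seed,
        engine_metadata=engine_metadata or {},
        stability_index=idx,
        training_checksum=table.checksum(),
    )
    return subset, model


def train_model(
    table: TrainingTable,
    rng_seed: int = 0,
    max_features: int = 10,
    n_rounds: int = N_BASE_CLASSIFIERS,
    engine_metadata: Optional[dict] = None,
    max_depth: int = 3,
) -> EnsembleModel:
    """Full training path: forward selection, stability ranking, ensemble.

    Stability analysis compares the best LOOCV subset of each size (one
    stability value per feature count); pass the full
    per-size candidate lists to :func:`select_final_subset_by_stability`
    directly to rank every recorded subset instead.
    """
    ranked = loocv_forward_selection(table, max_features=max_features, max_depth=max_depth)
    candidates = [ranked[size][0][0] for size in sorted(ranked)]
    _, model = select_final_subset_by_stability(
        candidates,
        table,
        rng_seed=rng_seed,
        n_rounds=n_rounds,
        engine_metadata=engine_metadata,
        max_depth=max_depth,
    )
    return model


def classify(probability: float, threshold: float = 0.5) -> str:
    """"interacting" iff probability is strictly greater than the threshold."""
    if not (0.0 <= probability <= 1.0):
        raise ValueError("probability must lie in [0, 1]")
    return "interacting" if probability > threshold else "non-interacting"
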