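"""Information-gain-ratio feature ranking for continuous features.

Continuous features are discretized by recursive entropy minimization with
the minimum-description-length (MDL) stopping rule (Fayyad & Irani style):
at each step the cut point minimizing the class-entropy of the induced
partition is accepted only if its information gain exceeds the MDL coding
cost, and the procedure recurses on both sides.  A feature on which no cut
is accepted is uninformative.

The gain ratio of a discretized feature is

    GR = IG / SplitInfo,
    IG = H(Y) - sum_v (n_v / n) H(Y | bin v),
    SplitInfo = - sum_v (n_v / n) log2(n_v / n),

all entropies in bits.  Normalizing by SplitInfo penalizes features whose
apparent gain comes only from splitting the data into many small bins.
A feature with a single bin (SplitInfo = 0) scores 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import LabeledDataset


def _entropy_from_counts(counts: np.ndarray) -> float:
    """Shannon entropy (bits) of a count vector."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def class_entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    return _entropy_from_counts(counts)


def _best_cut(values: np.ndarray, codes: np.ndarray, n_classes: int):
    """Best single cut of a (sorted) block by weighted class entropy.

    Returns (cut_value, left_mask_len, gain, k1, k2, H1, H2) or None when no
    candidate boundary exists.  Vectorized scan over all boundaries between
    distinct adjacent values.
    """
    n = len(values)
    if n < 2:
        return None
    # cumulative class counts after each position
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), codes] = 1.0
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]
    # candidate boundaries: between distinct adjacent values
    boundary = np.nonzero(values[1:] > values[:-1])[0]  # split after index i
    if boundary.size == 0:
        return None
    left = cum[boundary]                       # (b, k)
    right = total - left
    nl = left.sum(axis=1)
    nr = right.sum(axis=1)

    def ent(block, tot):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = block / tot[:, None]
            t = np.where(p > 0, p * np.log2(p), 0.0)
        return -t.sum(axis=1)

    h_left = ent(left, nl)
    h_right = ent(right, nr)
    weighted = (nl * h_left + nr * h_right) / n
    j = int(np.argmin(weighted))
    i = boundary[j]
    cut = 0.5 * (values[i] + values[i + 1])
    h_parent = _entropy_from_counts(total.astype(np.int64))
    gain = h_parent - weighted[j]
    k1 = int((left[j] > 0).sum())
    k2 = int((right[j] > 0).sum())
    return cut, i + 1, float(gain), k1, k2, float(h_left[j]), float(h_right[j])


def _mdl_accept(n: int, k: int, h: float, gain: float,
                k1: int, k2: int, h1: float, h2: float) -> bool:
    """MDL criterion: accept the cut iff gain exceeds its coding cost."""
    delta = np.log2(3.0 ** k - 2.0) - (k * h - k1 * h1 - k2 * h2)
    threshold = (np.log2(n - 1) + delta) / n
    return gain > threshold


def discretize_mdl(values: Sequence[float], labels: Sequence) -> list[float]:
    """Cut points from recursive entropy partitioning with MDL stopping.

    Returns a strictly increasing list; an empty list marks a feature on
    which no statistically justified split exists.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    _, codes = np.unique(labels[order], return_inverse=True)
    n_classes = int(codes.max()) + 1 if len(codes) else 0
    cuts: list[float] = []

    def recurse(lo: int, hi: int):
        block_v = v[lo:hi]
        block_c = codes[lo:hi]
        present = np.unique(block_c)
        if len(present) < 2:
            return
        res = _best_cut(block_v, block_c, n_classes)
        if res is None:
            return
        cut, split_at, gain, k1, k2, h1, h2 = res
        n = hi - lo
        h = _entropy_from_counts(np.bincount(block_c, minlength=n_classes))
        if not _mdl_accept(n, len(present), h, gain, k1, k2, h1, h2):
            return
        cuts.append(cut)
        recurse(lo, lo + split_at)
        recurse(lo + split_at, hi)

    recurse(0, len(v))
    return sorted(cuts)


def gain_ratio(values: Sequence[float], labels: Sequence,
               cuts: Sequence[float] | None = None) -> float:
    """Gain ratio (bits/bits, unitless >= 0) of a continuous feature.

    ``cuts`` overrides the MDL discretization (used by tests with
    hand-chosen bins).  Returns 0.0 when the discretization leaves a single
    bin (SplitInfo = 0).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    if cuts is None:
        cuts = discretize_mdl(values, labels)
    bins = np.searchsorted(np.asarray(cuts, dtype=float), values, side="left")
    bin_ids, bin_counts = np.unique(bins, return_counts=True)
    if len(bin_ids) < 2:
        return 0.0
    n = len(values)
    h_y = class_entropy(labels)
    cond = 0.0
    for b, nb in zip(bin_ids, bin_counts):
        cond += (nb / n) * class_entropy(labels[bins == b])
    split_info = _entropy_from_counts(bin_counts)
    if split_info == 0.0:
        return 0.0
    return max((h_y - cond) / split_info, 0.0)


@dataclass(frozen=True)
class RankedFeatureList:
    """Features sorted non-increasing by gain ratio.

    Ties are broken by canonical (input) feature order, so the ranking is a
    deterministic function of the data.
    """

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self):
        scores = [s for _, s in self.entries]
        if any(b > a + 1e-12 for a, b in zip(scores, scores[1:])):
            raise ValueError("entries must be sorted non-increasing by score")

    @property
    def features(self) -> list[str]:
        return [f for f, _ in self.entries]

    @property
    def scores(self) -> dict[str, float]:
        return dict(self.entries)

    def top(self, k: int) -> list[str]:
        return self.features[:k]

    def __len__(self) -> int:
        return len(self.entries)

    def to_records(self) -> list[dict]:
        return [{"feature": f, "gain_ratio": s} for f, s in self.entries]


def rank_features(dataset: LabeledDataset,
                  features: Sequence[str] | None = None) -> RankedFeatureList:
    """Rank features of a labeled dataset by gain ratio.

    Deterministic: invariant under instance order; ties keep the canonical
    feature order of the dataset.
    """
    feats = list(features) if features is not None else list(dataset.feature_names)
    y = dataset.y
    if len(np.unique(y)) < 2 or dataset.n_instances < 2:
        raise ValueError("ranking needs >= 2 classes and >= 2 instances")
    X = dataset.X(feats)
    scored = [(f, gain_ratio(X[:, j], y)) for j, f in enumerate(feats)]
    order = sorted(range(len(feats)), key=lambda j: (-scored[j][1], j))
    return RankedFeatureList(tuple(scored[j] for j in order))
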