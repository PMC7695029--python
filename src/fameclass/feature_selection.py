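"""Minimal-feature search over a gain-ratio-ranked prefix.

Given features ranked by discriminative power, the question "how many of
the top features does a classifier need to reach a target accuracy?" is
answered by a binary search over prefix lengths, assuming prefix accuracy
is (approximately) non-decreasing in the number of features.  A linear scan
over all prefixes is provided as the definitional reference; the two agree
whenever the accuracy sequence is monotone.

Two deliberate corrections to the published bisection sketch this search
follows: the success predicate is ``accuracy >= threshold`` (a strict
comparison leaves accuracy exactly at threshold driving neither branch),
and on termination the result is ``R + 1`` — the smallest prefix length
whose accuracy met the threshold among evaluated prefixes — which is always
re-verified against the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .feature_ranking import RankedFeatureList

Evaluator = Callable[[int], float]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a minimal-feature search.

    ``prefix_accuracies`` maps each evaluated prefix length to its accuracy
    (the evaluator is memoized, so each length appears at most once).  When
    even the full feature set misses the threshold, ``k`` equals the feature
    count and ``used_all_features`` is set.
    """

    k: int
    selected: tuple[str, ...]
    threshold: float
    prefix_accuracies: dict[int, float] = field(default_factory=dict)
    used_all_features: bool = False

    def __post_init__(self):
        if not self.used_all_features:
            acc = self.prefix_accuracies.get(self.k)
            if acc is None or acc < self.threshold:
                raise ValueError("selected prefix does not meet the threshold")


def _normalize_threshold(threshold: float) -> float:
    # accept 0.99 and 99 (percent) interchangeably
    if threshold > 1.0:
        threshold = threshold / 100.0
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1] (or (0, 100] as %)")
    return threshold


def _memoized(evaluator: Evaluator, cache: dict[int, float]) -> Evaluator:
    def call(prefix_len: int) -> float:
        if prefix_len not in cache:
            acc = float(evaluator(prefix_len))
            if not (0.0 <= acc <= 1.0):
                raise ValueError(f"evaluator returned {acc!r}, outside [0, 1]")
            cache[prefix_len] = acc
        return cache[prefix_len]
    return call


def minimal_feature_search(ranking: RankedFeatureList, evaluator: Evaluator,
                           threshold: float = 0.99) -> SelectionResult:
    """Binary search for the minimal ranked prefix meeting ``threshold``.

    ``evaluator`` maps a prefix length (1-based count of top-ranked
    features) to an accuracy fraction and must be deterministic for a fixed
    prefix.  Calls are memoized; at most O(log n) evaluations plus the
    initial full-set call.  Assumes monotone prefix accuracy — when that
    fails the result may differ from :func:`linear_scan_minimal`, but it is
    always a prefix whose accuracy was verified against the threshold.
    """
    if len(ranking) == 0:
        raise ValueError("empty ranking")
    threshold = _normalize_threshold(threshold)
    n = len(ranking)
    cache: dict[int, float] = {}
    acc_at = _memoized(evaluator, cache)

    if acc_at(n) < threshold:
        return SelectionResult(n, tuple(ranking.features), threshold,
                               dict(cache), used_all_features=True)
    # 0-based index bisection; index m stands for the prefix of m+1 features
    L, R = 0, n - 1
    m_old = R
    while True:
        m = (L + R) // 2
        if acc_at(m + 1) >= threshold:
            R = m
        else:
            L = m
        if m == m_old:
            break
        m_old = m
    k = R + 1
    if acc_at(k) < threshold:  # post-hoc verification of the returned prefix
        raise AssertionError("bisection returned a prefix below threshold; "
                             "prefix accuracies are not monotone")
    return SelectionResult(k, tuple(ranking.features[:k]), threshold,
                           dict(cache))


def linear_scan_minimal(ranking: RankedFeatureList, evaluator: Evaluator,
                        threshold: float = 0.99) -> SelectionResult:
    """Evaluate prefixes 1..n in order; first prefix meeting the threshold.

    The definitional answer regardless of monotonicity; O(n) evaluator
    calls in the worst case, but lazy — stops at the first success.
    """
    if len(ranking) == 0:
        raise ValueError("empty ranking")
    threshold = _normalize_threshold(threshold)
    n = len(ranking)
    cache: dict[int, float] = {}
    acc_at = _memoized(evaluator, cache)
    for k in range(1, n + 1):
        if acc_at(k) >= threshold:
            return SelectionResult(k, tuple(ranking.features[:k]), threshold,
                                   dict(cache))
    return SelectionResult(n, tuple(ranking.features), threshold, dict(cache),
                           used_all_features=True)
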