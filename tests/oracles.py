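"""Independent brute-force reference implementations used only by tests.

Everything here is written with explicit loops and textbook formulas,
deliberately sharing no code with the package, so agreement between the
two routes is meaningful.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import combinations


def partitions_up_to_k(n: int, max_blocks: int) -> list[tuple[int, ...]]:
    """All set partitions of n items into at most max_blocks blocks.

    Encoded as restricted-growth label strings (first occurrence of each
    block label in increasing order).
    """
    out: list[tuple[int, ...]] = []

    def grow(labels: list[int], used: int) -> None:
        if len(labels) == n:
            out.append(tuple(labels))
            return
        for lab in range(min(used + 1, max_blocks)):
            grow(labels + [lab], max(used, lab + 1))

    grow([], 0)
    return out


def cocluster_entries(labels) -> list[int]:
    """Vectorized binary co-clustering matrix, diagonal included."""
    n = len(labels)
    return [1 if labels[i] == labels[j] else 0 for i in range(n) for j in range(n)]


def brute_pearson(a: list[int], b: list[int]) -> float:
    """Exact agreement of constant vectors -> 1; other degeneracies -> 0."""
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / n
    va = sum((x - ma) ** 2 for x in a) / n
    vb = sum((y - mb) ** 2 for y in b) / n
    if va == 0 or vb == 0:
        return 1.0 if a == b else 0.0
    return cov / math.sqrt(va * vb)


def brute_mcc(reference: list[int], prediction: list[int]) -> float:
    """Exact agreement -> 1; other zero-denominator cases -> 0."""
    tp = sum(1 for x, y in zip(reference, prediction) if x == 1 and y == 1)
    tn = sum(1 for x, y in zip(reference, prediction) if x == 0 and y == 0)
    fp = sum(1 for x, y in zip(reference, prediction) if x == 0 and y == 1)
    fn = sum(1 for x, y in zip(reference, prediction) if x == 1 and y == 0)
    if fp == 0 and fn == 0:
        return 1.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def brute_v_measure(classes, clusters) -> float:
    """V-measure with natural-log entropies; reference entropy 0 -> 1."""
    n = len(classes)
    class_counts = Counter(classes)
    cluster_counts = Counter(clusters)
    joint = Counter(zip(classes, clusters))

    def entropy(counts: Counter) -> float:
        return -sum((c / n) * math.log(c / n) for c in counts.values())

    h_c = entropy(class_counts)
    h_k = entropy(cluster_counts)
    # H(C|K) and H(K|C) from the joint distribution
    h_c_given_k = -sum(
        (c / n) * math.log(c / cluster_counts[k]) for (_, k), c in joint.items()
    )
    h_k_given_c = -sum(
        (c / n) * math.log(c / class_counts[cl]) for (cl, _), c in joint.items()
    )
    homogeneity = 1.0 if h_c == 0 else 1.0 - h_c_given_k / h_c
    completeness = 1.0 if h_k == 0 else 1.0 - h_k_given_c / h_k
    if homogeneity + completeness == 0:
        return 0.0
    return 2 * homogeneity * completeness / (homogeneity + completeness)


def brute_rescale(raw: float, raw_allones: float, raw_identity: float) -> float:
    worst = min(raw_allones, raw_identity)
    if 1.0 - worst < 1e-12:
        return 1.0 if raw >= worst else 0.0
    return min(max((raw - worst) / (1.0 - worst), 0.0), 1.0)


def brute_raw_scores(reference, prediction) -> tuple[float, float, float]:
    m1 = cocluster_entries(reference)
    m2 = cocluster_entries(prediction)
    return (
        brute_pearson(m1, m2),
        brute_mcc(m1, m2),
        brute_v_measure(reference, prediction),
    )


def brute_score2a(reference, prediction) -> float:
    """Full pipeline: raw scores, bad scenarios, rescaling, mean."""
    n = len(reference)
    allones = [0] * n
    identity = list(range(n))
    raw = brute_raw_scores(reference, prediction)
    raw_ones = brute_raw_scores(reference, allones)
    raw_id = brute_raw_scores(reference, identity)
    rescaled = [
        brute_rescale(r, r1, ri) for r, r1, ri in zip(raw, raw_ones, raw_id)
    ]
    return sum(rescaled) / 3.0


def brute_concordance(scores, time, event) -> float:
    num = 0.0
    pairs = 0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i != j and time[i] >= time[j] and event[j] == 1:
                pairs += 1
                if scores[j] > scores[i]:
                    num += 1.0
                elif scores[j] == scores[i]:
                    num += 0.5
    return num / pairs


def brute_paired_t_pvalue(a, b) -> float:
    """Two-sided paired t-test from the textbook formula."""
    from scipy.stats import t as t_dist

    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    t_stat = mean / math.sqrt(var / n)
    return 2 * t_dist.sf(abs(t_stat), df=n - 1)


def brute_bh(pvals: list[float], fdr: float) -> list[bool]:
    """Step-up Benjamini-Hochberg rejection decisions."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * fdr / m:
            k_max = rank
    reject = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= k_max:
            reject[idx] = True
    return reject
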