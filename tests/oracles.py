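"""Independent brute-force oracles for the decision rules and macro metrics.

Deliberately written as literal scans of the stated rules, sharing no
code with the package implementations they check.
"""

from __future__ import annotations

from collections import Counter

import numpy as np


def mp_oracle(vectors: list[np.ndarray]) -> int:
    """Exhaustive scan for the largest entry; ties -> lowest class index."""
    best_prob, best_class = -1.0, None
    k = len(vectors[0])
    for c in range(k):  # class-major scan so the lowest class wins ties
        for v in vectors:
            if v[c] > best_prob:
                best_prob, best_class = v[c], c
    return best_class


def mv_oracle(vectors: list[np.ndarray]) -> int:
    """Literal majority vote with the stated MP fallbacks."""
    votes = []
    for v in vectors:
        best, arg = -1.0, None
        for c, p in enumerate(v):
            if p > best:
                best, arg = p, c
        votes.append(arg)
    counts = Counter(votes)
    top = max(counts.values())
    if top == 1:
        return mp_oracle(vectors)
    tied = [c for c, n in counts.items() if n == top]
    if len(tied) == 1:
        return tied[0]
    # MP restricted to the tied classes
    best_prob, best_class = -1.0, None
    for c in sorted(tied):
        for v in vectors:
            if v[c] > best_prob:
                best_prob, best_class = v[c], c
    return best_class


def ap_oracle(vectors: list[np.ndarray]) -> int:
    mean = np.zeros_like(vectors[0])
    for v in vectors:
        mean = mean + v
    mean = mean / len(vectors)
    best, arg = -1.0, None
    for c, p in enumerate(mean):
        if p > best:
            best, arg = p, c
    return arg


def macro_f1_oracle(conf: np.ndarray) -> float:
    """Per-class one-vs-rest F1, averaged unweighted."""
    k = conf.shape[0]
    f1s = []
    for c in range(k):
        tp = conf[c, c]
        fp = conf[:, c].sum() - tp
        fn = conf[c, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0)
    return float(np.mean(f1s))


def random_instances(n: int, seed: int, m_max: int = 5, k_max: int = 6):
    """Random probability-vector ensembles (includes engineered exact ties)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        m = int(rng.integers(1, m_max + 1))
        k = int(rng.integers(2, k_max + 1))
        vecs = [rng.dirichlet(np.ones(k)) for _ in range(m)]
        if i % 7 == 0:  # quantise to force occasional exact ties
            vecs = [np.round(v * 4) / 4 for v in vecs]
            vecs = [v / v.sum() if v.sum() > 0 else np.ones(k) / k for v in vecs]
        out.append(vecs)
    return out
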