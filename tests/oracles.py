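"""Independent brute-force oracles used to cross-check the fast paths."""

from itertools import combinations

import numpy as np
import pandas as pd


def exact_rank_sum_p(case, ref):
    """Two-sided rank-sum p by enumerating every split of the pooled sample
    into groups of the observed sizes."""
    pooled = np.concatenate([case, ref])
    ranks = pd.Series(pooled).rank().to_numpy()
    n = len(pooled)
    n_case = len(case)
    obs = ranks[:n_case].sum()
    mean = n_case * (n + 1) / 2
    count = total = 0
    for idx in combinations(range(n), n_case):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


def enumerate_upper_tail(x, N, K, n):
    """Brute-force P[overlap >= x] by enumerating every n-subset of an
    N-element background containing K marked elements."""
    marked = set(range(K))
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(marked & set(draw)) >= x:
            hits += 1
    return hits / total


def brute_force_auc(scores, labels):
    """Pair-counting AUC: concordant pairs + half credit for ties."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))
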