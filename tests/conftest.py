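import numpy as np
import pytest

from circdrug import synthetic


def dp_levenshtein_ratio(a: str, b: str) -> float:
    """Quadratic DP oracle: (|a|+|b| - D2)/(|a|+|b|), substitution cost 2."""
    m, n = len(a), len(b)
    if m + n == 0:
        return 1.0
    dp = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        dp[i][0] = i
    for j in range(n + 1):
        dp[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sub = 0 if a[i - 1] == b[j - 1] else 2
            dp[i][j] = min(dp[i - 1][j] + 1, dp[i][j - 1] + 1,
                           dp[i - 1][j - 1] + sub)
    return (m + n - dp[m][n]) / (m + n)


def pair_counting_auc(labels, scores) -> float:
    """O(n^2) AUC estimator: fraction of (pos, neg) pairs ranked correctly,
    ties counted 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted-structure dataset shared by pipeline tests."""
    cfg = synthetic.SyntheticConfig(n_circ=40, n_drug=30, n_blocks=3,
                                    seq_len=120, fp_bits=128, seed=7)
    ds, truth = synthetic.generate(cfg)
    return ds, truth, cfg
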