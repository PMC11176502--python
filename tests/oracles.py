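"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def _global_score(u: str, v: str) -> int:
    """Needleman-Wunsch global score (match +1, mismatch -1, linear gap -2)."""
    prev = [-2 * j for j in range(len(v) + 1)]
    for i in range(1, len(u) + 1):
        cur = [-2 * i] + [0] * len(v)
        for j in range(1, len(v) + 1):
            s = 1 if u[i - 1] == v[j - 1] else -1
            cur[j] = max(prev[j - 1] + s, prev[j] - 2, cur[j - 1] - 2)
        prev = cur
    return prev[-1]


def exhaustive_local_score(a: str, b: str) -> int:
    """Best local score by exhaustively aligning every substring pair globally."""
    best = 0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(best, _global_score(a[i1:i2], b[j1:j2]))
    return best


def brute_force_auc(scores, labels):
    """All-pairs concordance probability, ties counting one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
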