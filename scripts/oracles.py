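"""Brute-force reference implementations used only for cross-checking."""

import numpy as np


def brute_auc(scores, labels):
    """Mann-Whitney: P(score+ > score-) + 0.5 P(tie), by pair enumeration."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_auprc(scores, labels):
    """Step-wise average precision with tie groups."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(labels)[order]
    s = np.asarray(scores)[order]
    npos = y.sum()
    total, tp, i = 0.0, 0, 0
    while i < len(y):
        j = i
        while j < len(y) and s[j] == s[i]:
            j += 1
        tp_new = tp + y[i:j].sum()
        total += (tp_new / j) * (tp_new - tp)
        tp = tp_new
        i = j
    return total / npos
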