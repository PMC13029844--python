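"""Independent brute-force reference for the rank-fusion scoring rules.

Loops literally over the indicator definition (does classifier j put class i
at position p?) without any of the vectorised bookkeeping of the package,
and re-derives the tie rule from first principles.  Used only to
cross-check the implementation.
"""

from __future__ import annotations

import numpy as np


def brute_scores(rankings, weight, lam=None, strategy="topT"):
    """(M, C) score matrix from nested loops over samples/classes/positions."""
    k = len(rankings)
    m = rankings[0].classes.shape[0]
    t = rankings[0].classes.shape[1]
    c = rankings[0].n_classes
    scores = np.zeros((m, c))
    for mm in range(m):
        for i in range(c):
            s = 0.0
            for j in range(k):
                for p in range(1, t + 1):
                    d = 1.0 if rankings[j].classes[mm, p - 1] == i else 0.0
                    if strategy == "rank_order":
                        if p == 1:
                            s += weight[j, 0] * d
                    else:
                        f_p = (t + 1 - p) / t
                        s += (lam * f_p + (1.0 - lam) * weight[j, p - 1]) * d
            scores[mm, i] = s
    return scores


def brute_decide(scores, rankings, acc_top1, tol=1e-9):
    """Decisions with the best-classifier tie rule, derived independently."""
    out = []
    for mm in range(scores.shape[0]):
        row = scores[mm]
        winners = [i for i in range(len(row)) if row[i] >= row.max() - tol]
        if len(winners) == 1:
            out.append(winners[0])
            continue
        best_clfs = [j for j in range(len(acc_top1)) if acc_top1[j] == max(acc_top1)]
        top1s = {int(rankings[j].classes[mm, 0]) for j in best_clfs}
        if len(top1s) == 1 and next(iter(top1s)) in winners:
            out.append(next(iter(top1s)))
        else:
            out.append(None)
    return out
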