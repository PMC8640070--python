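"""Independent longhand oracles used to check the library implementations.

Everything here is written the slow, obvious way -- dictionaries of
contingency counts and literal term-by-term transcriptions of the
criterion formulas -- and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter


def counts_of(*cols):
    return Counter(zip(*cols))


def entropy_oracle(*cols) -> float:
    """Plug-in joint entropy by direct summation over observed cells."""
    c = counts_of(*cols)
    n = sum(c.values())
    return -sum((k / n) * math.log2(k / n) for k in c.values())


def mi_oracle(x, y) -> float:
    """I(X;Y) summed cell by cell over the empirical joint."""
    nxy = counts_of(x, y)
    nx = Counter(x)
    ny = Counter(y)
    n = len(x)
    total = 0.0
    for (a, b), k in nxy.items():
        total += (k / n) * math.log2((k / n) / ((nx[a] / n) * (ny[b] / n)))
    return total


def cmi_oracle(x, z, y) -> float:
    """I(X;Z|Y) = sum_y p(y) I(X;Z | Y=y), each stratum by direct summation."""
    n = len(y)
    total = 0.0
    for v in set(y):
        idx = [i for i in range(n) if y[i] == v]
        total += (len(idx) / n) * mi_oracle([x[i] for i in idx], [z[i] for i in idx])
    return total


def jmi_oracle(x1, x2, y) -> float:
    """I(X1X2;Y) with the pair mapped onto a product alphabet."""
    paired = list(zip(x1, x2))
    return mi_oracle(paired, y)


def criterion_score_oracle(criterion, xk, y, selected_cols, beta=1.0) -> float:
    """Term-by-term transcription of the seven scoring formulas."""
    rel = mi_oracle(xk, y)
    S = selected_cols
    if criterion == "MIM":
        return rel
    if criterion == "MIFS":
        return rel - beta * sum(mi_oracle(xk, xj) for xj in S)
    if criterion == "mRMR":
        return rel if not S else rel - sum(mi_oracle(xk, xj) for xj in S) / len(S)
    if criterion == "CMIM":
        if not S:
            return rel
        return rel - max(mi_oracle(xk, xj) - cmi_oracle(xk, xj, y) for xj in S)
    if criterion == "ICAP":
        return rel - sum(max(0.0, mi_oracle(xk, xj) - cmi_oracle(xk, xj, y)) for xj in S)
    if criterion == "JMI":
        return rel if not S else sum(jmi_oracle(xk, xj, y) for xj in S)
    if criterion == "DISR":
        if not S:
            return rel / entropy_oracle(xk, y)
        return sum(
            jmi_oracle(xk, xj, y) / entropy_oracle(xk, xj, y) for xj in S
        )
    raise ValueError(criterion)


def brute_force_greedy(criterion, columns, names, y, K, beta=1.0):
    """From-scratch forward selection: re-scores every candidate every step.

    ``columns`` is a dict name -> list of codes.  Ties break by name.
    """
    selected = []
    for _ in range(K):
        best_name, best_score = None, None
        for name in sorted(n for n in names if n not in selected):
            s = criterion_score_oracle(
                criterion, columns[name], y, [columns[f] for f in selected], beta
            )
            if best_score is None or s > best_score:
                best_name, best_score = name, s
        selected.append(best_name)
    return selected
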