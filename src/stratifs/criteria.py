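"""Greedy filter feature selection under seven information-theoretic criteria.

Each criterion scores a candidate feature Xk against the label Y given
the set S of already-selected features, trading relevance I(Xk;Y)
against redundancy with S:

* MIM    J = I(Xk;Y)
* MIFS   J = I(Xk;Y) - beta * sum_j I(Xk;Xj)
* JMI    J = sum_j I(XkXj;Y)
* mRMR   J = I(Xk;Y) - mean_j I(Xk;Xj)
* CMIM   J = I(Xk;Y) - max_j [I(Xk;Xj) - I(Xk;Xj|Y)]
* ICAP   J = I(Xk;Y) - sum_j max(0, I(Xk;Xj) - I(Xk;Xj|Y))
* DISR   J = sum_j I(XkXj;Y) / H(Xk,Xj,Y)

Empty-S conventions: sums over S are 0 and the CMIM max is 0, so every
criterion except DISR reduces to I(Xk;Y) for the first pick (JMI
included -- its literal empty sum would tie all candidates at 0).  DISR
falls back to the normalised univariate score I(Xk;Y)/H(Xk,Y), keeping
its normalisation idea for the first pick.

Ties are broken by ascending feature name everywhere, for bit-level
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .info import (
    DiscreteMatrix,
    PairwiseCache,
    conditional_mutual_information,
    entropy,
    joint_mutual_information,
    mutual_information,
)

CRITERIA = ("MIM", "MIFS", "JMI", "mRMR", "CMIM", "ICAP", "DISR")
_CANON = {c.lower(): c for c in CRITERIA}


def canonical_criterion(name: str) -> str:
    try:
        return _CANON[name.lower()]
    except KeyError:
        raise ValueError(f"unknown criterion {name!r}; expected one of {CRITERIA}") from None


@dataclass
class SelectionState:
    """Ordered set S of already-selected features (by name)."""

    selected: list[str] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)


@dataclass
class SelectionResult:
    """One criterion's ranked top-K features; rank 1 = first selected."""

    criterion: str
    ranked_features: list[str]
    scores: list[float]


def score_candidate(
    criterion: str,
    xk: np.ndarray,
    y: np.ndarray,
    state: SelectionState,
    data: DiscreteMatrix,
    beta: float = 1.0,
    xk_name: str | None = None,
) -> float:
    """Reference (per-column) evaluation of one criterion for one candidate.

    The greedy loop uses a cached vectorized path; this function is the
    plain transcription of the formulas above and the two must agree,
    which the test suite asserts.
    """
    criterion = canonical_criterion(criterion)
    if xk_name is not None:
        _check_candidate(criterion, xk_name, state)
    sel = [data.column(f) for f in state.selected]
    rel = mutual_information(xk, y)
    if criterion == "MIM":
        return rel
    if criterion == "MIFS":
        return rel - beta * sum(mutual_information(xk, xj) for xj in sel)
    if criterion == "mRMR":
        if not sel:
            return rel
        return rel - sum(mutual_information(xk, xj) for xj in sel) / len(sel)
    if criterion == "CMIM":
        worst = max(
            (mutual_information(xk, xj) - conditional_mutual_information(xk, xj, y) for xj in sel),
            default=0.0,
        )
        return rel - worst
    if criterion == "ICAP":
        return rel - sum(
            max(0.0, mutual_information(xk, xj) - conditional_mutual_information(xk, xj, y))
            for xj in sel
        )
    if criterion == "JMI":
        if not sel:
            return rel
        return sum(joint_mutual_information(xk, xj, y) for xj in sel)
    # DISR
    if not sel:
        return rel / entropy(xk, y)
    return sum(joint_mutual_information(xk, xj, y) / entropy(xk, xj, y) for xj in sel)


def _check_candidate(criterion: str, name: str, state: SelectionState) -> None:
    if name in state.selected:
        raise ValueError(f"candidate {name!r} already selected under {criterion}")


class _GreedyScorer:
    """Running per-candidate score vectors over a :class:`PairwiseCache`."""

    def __init__(self, criterion: str, cache: PairwiseCache, beta: float):
        self.criterion = criterion
        self.cache = cache
        self.beta = beta
        p = cache.dm.p
        self.k = 0
        self.sum_mi = np.zeros(p)  # sum_j I(Xi;Xj)
        self.max_ii = np.full(p, -np.inf)  # max_j [I - CMI]; -inf = empty S
        self.sum_cap = np.zeros(p)  # sum_j max(0, I - CMI)
        self.sum_jmi = np.zeros(p)
        self.sum_disr = np.zeros(p)

    def add_selected(self, j: int) -> None:
        row = self.cache.row(j)
        ii = row["mi"] - row["cmi"]
        self.sum_mi += row["mi"]
        self.max_ii = np.maximum(self.max_ii, ii)
        self.sum_cap += np.maximum(0.0, ii)
        self.sum_jmi += row["jmi"]
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(row["hxxy"] > 0, row["jmi"] / row["hxxy"], 0.0)
        self.sum_disr += d
        self.k += 1

    def scores(self) -> np.ndarray:
        rel = self.cache.mi_y
        c = self.criterion
        if c == "MIM":
            return rel.copy()
        if c == "MIFS":
            return rel - self.beta * self.sum_mi
        if c == "mRMR":
            return rel - self.sum_mi / self.k if self.k else rel.copy()
        if c == "CMIM":
            return rel - self.max_ii if self.k else rel.copy()
        if c == "ICAP":
            return rel - self.sum_cap
        if c == "JMI":
            return self.sum_jmi if self.k else rel.copy()
        # DISR
        if self.k:
            return self.sum_disr
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.cache.h_xy > 0, rel / self.cache.h_xy, 0.0)


def greedy_select(
    criterion: str,
    data: DiscreteMatrix,
    K: int,
    beta: float = 1.0,
    cache: PairwiseCache | None = None,
) -> SelectionResult:
    """Forward selection of the top-K features under one criterion.

    At each step the unselected feature with the maximal criterion score
    is added (ties by ascending name).  MIM therefore reduces to sorting
    by univariate mutual information.
    """
    criterion = canonical_criterion(criterion)
    if not 1 <= K <= data.p:
        raise ValueError(f"K={K} outside [1, {data.p}]")
    cache = cache or PairwiseCache(data)
    names = np.asarray(data.feature_names)
    order = np.argsort(names, kind="stable")  # lexicographic tie-break helper
    scorer = _GreedyScorer(criterion, cache, beta)
    available = np.ones(data.p, dtype=bool)
    picked: list[int] = []
    picked_scores: list[float] = []
    for _ in range(K):
        s = scorer.scores()
        s_masked = np.where(available, s, -np.inf)
        best = s_masked.max()
        # exact-tie break: lexicographically smallest name among the argmaxes
        tied = np.flatnonzero(s_masked == best)
        j = int(tied[np.argsort(names[tied], kind="stable")[0]])
        picked.append(j)
        picked_scores.append(float(s[j]))
        available[j] = False
        scorer.add_selected(j)
    return SelectionResult(criterion, [data.feature_names[j] for j in picked], picked_scores)
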