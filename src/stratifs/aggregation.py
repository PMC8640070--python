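"""Bootstrap stability voting and cross-criterion rank aggregation.

Feature selection on a single sample is unstable; the pipeline instead
repeats each criterion's greedy top-K selection on B bootstrap resamples
and accumulates, per feature:

* vote ``V``  -- the number of bootstraps in which the feature entered
  the top K (0..B);
* rank ``R``  -- the mean of its rank over exactly those bootstraps
  (1..K, undefined when V = 0).

Across the seven criteria, features are then aggregated into the
overall ranking via

* Technique Vote -- the number of criteria whose (vote-sorted) top-K
  contains the feature (0..7);
* ABV = (sum of V over criteria) / (number of criteria);
* ABR = mean of R over the criteria where R is defined.

The overall order is (Technique Vote desc, ABV desc, ABR asc, name asc).

Bootstraps are class-stratified -- each resample draws, within each
class, as many rows with replacement as the class has -- so no resample
can collapse to a single class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .criteria import CRITERIA, canonical_criterion, greedy_select
from .info import BinScheme, PairwiseCache, discretize
from .io import DosageMatrix


@dataclass
class BootstrapAggregate:
    """Per-feature vote V and mean rank R for one criterion over B bootstraps."""

    criterion: str
    B: int
    K: int
    feature_names: list[str]
    votes: np.ndarray  # int, per feature
    mean_rank: np.ndarray  # float, NaN where votes == 0

    def table(self) -> pd.DataFrame:
        """Per-criterion ranking, sorted (V desc, R asc, name asc)."""
        df = pd.DataFrame(
            {"feature": self.feature_names, "vote": self.votes, "mean_rank": self.mean_rank}
        )
        df["_r"] = df["mean_rank"].fillna(np.inf)
        df = df.sort_values(["vote", "_r", "feature"], ascending=[False, True, True])
        return df.drop(columns="_r").reset_index(drop=True)

    def top_k_features(self) -> list[str]:
        """The criterion's top-K list; features never voted for cannot enter."""
        df = self.table()
        return df[df["vote"] > 0]["feature"].head(self.K).tolist()


@dataclass
class OverallRanking:
    """Cross-criterion aggregate: Technique Vote, ABV, ABR, sorted."""

    table: pd.DataFrame  # columns: feature, technique_vote, abv, abr

    @property
    def features(self) -> list[str]:
        return self.table["feature"].tolist()


def _resample_indices(label: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Class-stratified bootstrap row indices (preserves class counts)."""
    parts = []
    for c in (0, 1):
        idx = np.flatnonzero(label == c)
        parts.append(rng.choice(idx, size=len(idx), replace=True))
    return np.concatenate(parts)


def bootstrap_votes_multi(
    data: DosageMatrix,
    criteria: list[str],
    K: int,
    B: int,
    seed: int,
    scheme: BinScheme | None = None,
    include_confounders: bool = False,
    beta: float = 1.0,
) -> dict[str, BootstrapAggregate]:
    """Run all requested criteria on one shared set of B bootstrap resamples.

    The resamples (and therefore single-criterion results) depend only
    on ``seed`` and ``B``, not on which criteria are requested.
    """
    criteria = [canonical_criterion(c) for c in criteria]
    if B < 1:
        raise ValueError("B must be >= 1")
    dm = discretize(data, scheme, include_confounders=include_confounders)
    if not 1 <= K <= dm.p:
        raise ValueError(f"K={K} outside [1, {dm.p}]")
    p = dm.p
    votes = {c: np.zeros(p, dtype=int) for c in criteria}
    rank_sum = {c: np.zeros(p, dtype=float) for c in criteria}
    name_idx = {f: j for j, f in enumerate(dm.feature_names)}
    root = np.random.SeedSequence([int(seed), 0xB007])
    for b, child in enumerate(root.spawn(B)):
        rng = np.random.default_rng(child)
        rows = _resample_indices(dm.y, rng)
        sub = dm.rows(rows)
        cache = PairwiseCache(sub)
        for c in criteria:
            result = greedy_select(c, sub, K, beta=beta, cache=cache)
            for rank, f in enumerate(result.ranked_features, start=1):
                j = name_idx[f]
                votes[c][j] += 1
                rank_sum[c][j] += rank
    out = {}
    for c in criteria:
        with np.errstate(invalid="ignore"):
            mean_rank = np.where(votes[c] > 0, rank_sum[c] / np.maximum(votes[c], 1), np.nan)
        out[c] = BootstrapAggregate(c, B, K, list(dm.feature_names), votes[c], mean_rank)
    return out


def bootstrap_votes(
    data: DosageMatrix,
    criterion: str,
    K: int,
    B: int,
    seed: int,
    scheme: BinScheme | None = None,
    include_confounders: bool = False,
    beta: float = 1.0,
) -> BootstrapAggregate:
    """Single-criterion wrapper over :func:`bootstrap_votes_multi`."""
    return bootstrap_votes_multi(
        data, [criterion], K, B, seed, scheme, include_confounders, beta
    )[canonical_criterion(criterion)]


def aggregate_techniques(aggregates: dict[str, BootstrapAggregate] | list[BootstrapAggregate]) -> OverallRanking:
    """Combine per-criterion aggregates into the overall feature ranking.

    ABV keeps the number of criteria as its denominator; ABR averages
    only over criteria where the feature was ever selected (R defined).
    """
    aggs = list(aggregates.values()) if isinstance(aggregates, dict) else list(aggregates)
    if not aggs:
        raise ValueError("no aggregates")
    first = aggs[0]
    for a in aggs[1:]:
        if a.B != first.B or a.K != first.K:
            raise ValueError("aggregates disagree on B or K")
        if a.feature_names != first.feature_names:
            raise ValueError("aggregates disagree on the feature universe")
    n_crit = len(aggs)
    features = first.feature_names
    vote_mat = np.stack([a.votes for a in aggs])  # criteria x features
    rank_mat = np.stack([a.mean_rank for a in aggs])
    topk_sets = [set(a.top_k_features()) for a in aggs]
    technique_vote = np.array([sum(f in s for s in topk_sets) for f in features])
    abv = vote_mat.sum(axis=0) / n_crit
    defined = ~np.isnan(rank_mat)
    n_def = defined.sum(axis=0)
    abr = np.full(len(features), np.nan)
    has = n_def > 0
    abr[has] = np.where(defined, rank_mat, 0.0).sum(axis=0)[has] / n_def[has]
    df = pd.DataFrame(
        {"feature": features, "technique_vote": technique_vote, "abv": abv, "abr": abr}
    )
    df["_r"] = df["abr"].fillna(np.inf)
    df = df.sort_values(
        ["technique_vote", "abv", "_r", "feature"], ascending=[False, False, True, True]
    )
    return OverallRanking(df.drop(columns="_r").reset_index(drop=True))


def top_subset(ranking: OverallRanking | BootstrapAggregate, n: int) -> list[str]:
    """First n features of the sorted order (prefix-stable in n)."""
    if isinstance(ranking, BootstrapAggregate):
        ordered = ranking.table()["feature"].tolist()
    else:
        ordered = ranking.features
    if n > len(ordered):
        raise ValueError(f"n={n} exceeds the {len(ordered)} available features")
    return ordered[:n]
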