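"""Confounder mitigation by stratification and within-stratum class balancing.

Samples are divided into strata over the cross-product of the binned
confounders (20-year age-of-onset bins x sign of PC1 x sign of PC2).
Within every stratum that contains both classes, the minority class is
upsampled with replacement until the two class counts are equal; strata
containing a single class are dropped with a logged warning.  After
balancing, class membership is independent of the stratum id by
construction, which removes the marginal confounder-label association
that ascertainment induced.

A ``sequential`` mode stratifies and rebalances one confounder at a
time (aao, then pc1, then pc2) for fidelity experiments; the default
joint mode controls all three at once and is order-invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .info import BinScheme
from .io import DosageMatrix

logger = logging.getLogger(__name__)


@dataclass
class StratumTable:
    """Per-sample stratum ids and per-stratum class counts."""

    stratum_ids: list[tuple]  # one tuple per sample
    counts: pd.DataFrame  # index: stratum, columns: n_class0, n_class1

    @property
    def strata(self) -> list[tuple]:
        return list(self.counts.index)


@dataclass
class MitigatedDataset:
    """Balanced dataset: all retained original rows plus resampled duplicates."""

    matrix: DosageMatrix
    provenance: dict[str, str]  # duplicate sample id -> source sample id
    seed: int
    audit: pd.DataFrame  # per-stratum class counts before/after balancing
    dropped_strata: list[tuple]


def assign_strata(matrix: DosageMatrix, scheme: BinScheme | None = None) -> StratumTable:
    """Deterministic stratum id (aao bin, pc1 sign-bin, pc2 sign-bin) per sample."""
    scheme = scheme or BinScheme()
    for name, arr in (("aao", matrix.aao), ("pc1", matrix.pc1), ("pc2", matrix.pc2)):
        if not np.all(np.isfinite(arr)):
            i = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise ValueError(f"non-finite {name} at sample {matrix.sample_ids[i]!r}")
    ids = list(
        zip(
            (int(b) for b in scheme.bin_aao(matrix.aao)),
            (int(b) for b in scheme.bin_pc(matrix.pc1)),
            (int(b) for b in scheme.bin_pc(matrix.pc2)),
        )
    )
    df = pd.DataFrame({"stratum": ids, "label": matrix.label})
    counts = (
        df.groupby("stratum", sort=True)["label"]
        .agg(n_class0=lambda s: int((s == 0).sum()), n_class1=lambda s: int((s == 1).sum()))
    )
    return StratumTable(stratum_ids=ids, counts=counts)


def balance_strata(
    matrix: DosageMatrix, strata: StratumTable, seed: int
) -> MitigatedDataset:
    """Upsample the minority class within each two-class stratum to parity.

    Original rows of retained strata are always kept; added rows are
    exact copies drawn uniformly with replacement from the minority
    rows of that stratum.  Single-class strata are dropped.
    """
    if len(strata.stratum_ids) != matrix.n:
        raise ValueError("strata were not computed on this matrix")
    if len(np.unique(matrix.label)) < 2:
        raise ValueError("dataset contains a single class; nothing to balance")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x57A7]))
    keep_rows: list[int] = []
    extra_rows: list[int] = []
    audit_rows = []
    dropped: list[tuple] = []
    members: dict[tuple, list[int]] = {}
    for i, s in enumerate(strata.stratum_ids):
        members.setdefault(s, []).append(i)
    for stratum in strata.strata:
        in_s = np.asarray(members[stratum], dtype=int)
        labs = matrix.label[in_s]
        n0, n1 = int((labs == 0).sum()), int((labs == 1).sum())
        if n0 == 0 or n1 == 0:
            dropped.append(stratum)
            audit_rows.append((stratum, n0, n1, None, None, False))
            continue
        keep_rows.extend(in_s.tolist())
        short = abs(n0 - n1)
        if short:
            minority = in_s[labs == (0 if n0 < n1 else 1)]
            extra_rows.extend(rng.choice(minority, size=short, replace=True).tolist())
        m = max(n0, n1)
        audit_rows.append((stratum, n0, n1, m, m, True))
    if not keep_rows:
        raise ValueError("every stratum is single-class; nothing retainable")
    for s in dropped:
        logger.warning("dropping single-class stratum %s", s)
    rows = np.array(keep_rows + extra_rows, dtype=int)
    out = matrix.subset(rows, suffix_duplicates=True)
    prov = {
        out.sample_ids[len(keep_rows) + k]: matrix.sample_ids[r]
        for k, r in enumerate(extra_rows)
    }
    audit = pd.DataFrame(
        audit_rows,
        columns=["stratum", "pre_class0", "pre_class1", "post_class0", "post_class1", "retained"],
    )
    return MitigatedDataset(matrix=out, provenance=prov, seed=int(seed), audit=audit, dropped_strata=dropped)


def mitigate(
    matrix: DosageMatrix,
    scheme: BinScheme | None = None,
    seed: int = 0,
    mode: str = "joint",
) -> MitigatedDataset:
    """Stratify and balance in one call (``joint`` or ``sequential`` mode)."""
    scheme = scheme or BinScheme()
    if mode == "joint":
        return balance_strata(matrix, assign_strata(matrix, scheme), seed)
    if mode != "sequential":
        raise ValueError(f"unknown mitigation mode {mode!r}")
    current = matrix
    audits = []
    prov: dict[str, str] = {}
    dropped: list[tuple] = []
    for stage, kind in enumerate(("aao", "pc1", "pc2")):
        ids: list[tuple]
        if kind == "aao":
            ids = [(int(b),) for b in scheme.bin_aao(current.aao)]
        elif kind == "pc1":
            ids = [(int(b),) for b in scheme.bin_pc(current.pc1)]
        else:
            ids = [(int(b),) for b in scheme.bin_pc(current.pc2)]
        counts = (
            pd.DataFrame({"stratum": ids, "label": current.label})
            .groupby("stratum", sort=True)["label"]
            .agg(n_class0=lambda s: int((s == 0).sum()), n_class1=lambda s: int((s == 1).sum()))
        )
        step = balance_strata(current, StratumTable(ids, counts), seed + stage)
        audits.append(step.audit.assign(confounder=kind))
        prov.update(step.provenance)
        dropped.extend(step.dropped_strata)
        current = step.matrix
    return MitigatedDataset(
        matrix=current,
        provenance=prov,
        seed=int(seed),
        audit=pd.concat(audits, ignore_index=True),
        dropped_strata=dropped,
    )
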