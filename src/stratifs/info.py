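"""Discretization and plug-in (histogram) information estimates.

All criteria consume the same primitives: Shannon entropy and (joint /
conditional) mutual information of empirical distributions over binned
columns, in bits.  Dosages are cut at 1.0 (non-carrier vs carrier of at
least one allele copy), principal components at 0, and age of onset into
20-year bins.  No smoothing is applied: empty cells contribute 0, the
standard plug-in convention.

Boundary convention: half-open on the left, so dosage [0,1) -> 0 and
[1,2] -> 1, PCs (-inf,0) -> 0 and [0,inf) -> 1.  Age bins are the closed
integer ranges 0-20, 21-40, 41-60, 61-80, 81-100 on rounded years, with
out-of-range values clipped to the nearest bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .io import DosageMatrix

_LN2 = np.log(2.0)

CONFOUNDER_FEATURES = ("aao", "pc1", "pc2")


@dataclass(frozen=True)
class BinScheme:
    """Cutpoints used for discretization and for confounder strata."""

    dosage_cutpoint: float = 1.0
    pc_cutpoint: float = 0.0
    #: closed upper bounds of the age-of-onset bins on integer-rounded years
    aao_edges: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0, 100.0)

    def __post_init__(self) -> None:
        edges = np.asarray(self.aao_edges, dtype=float)
        if edges.size < 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("aao_edges must be strictly increasing")

    @property
    def n_aao_bins(self) -> int:
        return len(self.aao_edges)

    def bin_dosage(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) >= self.dosage_cutpoint).astype(np.int16)

    def bin_pc(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) >= self.pc_cutpoint).astype(np.int16)

    def bin_aao(self, x: np.ndarray) -> np.ndarray:
        # closed integer ranges: 20 -> bin 0, 21 -> bin 1; out of range clipped
        r = np.round(np.asarray(x, dtype=float))
        idx = np.searchsorted(np.asarray(self.aao_edges), r, side="left")
        # searchsorted puts 20 at bin 0 (20 <= edge), 21 at bin 1
        return np.clip(idx, 0, self.n_aao_bins - 1).astype(np.int16)


@dataclass
class DiscreteMatrix:
    """Binned feature columns (integer category codes) plus the label."""

    feature_names: list[str]
    codes: np.ndarray  # n x p int16, each column in [0, n_categories[j])
    n_categories: np.ndarray  # per column
    y: np.ndarray  # binary labels

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int16)
        self.n_categories = np.asarray(self.n_categories, dtype=int)
        self.y = np.asarray(self.y, dtype=np.int16)
        n, p = self.codes.shape
        if len(self.feature_names) != p or self.n_categories.shape != (p,) or self.y.shape != (n,):
            raise ValueError("inconsistent DiscreteMatrix shapes")
        if np.any(self.n_categories < 1):
            raise ValueError("every column needs at least one category")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def p(self) -> int:
        return self.codes.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.codes[:, self.feature_names.index(name)]

    def rows(self, idx: np.ndarray) -> "DiscreteMatrix":
        return DiscreteMatrix(self.feature_names, self.codes[idx], self.n_categories, self.y[idx])


def discretize(
    matrix: DosageMatrix,
    scheme: BinScheme | None = None,
    include_confounders: bool = False,
) -> DiscreteMatrix:
    """Bin every dosage column (and optionally aao/pc1/pc2 as extra features).

    Dosage and PC columns become binary codes, aao a 20-year bin index.
    Labels pass through unchanged.
    """
    scheme = scheme or BinScheme()
    for name, arr in (("aao", matrix.aao), ("pc1", matrix.pc1), ("pc2", matrix.pc2)):
        if not np.all(np.isfinite(arr)):
            i = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise ValueError(f"non-finite {name} at sample {matrix.sample_ids[i]!r}")
    cols = [scheme.bin_dosage(matrix.dosages[:, j]) for j in range(matrix.p)]
    names = list(matrix.feature_names)
    ncat = [2] * matrix.p
    if include_confounders:
        cols += [scheme.bin_aao(matrix.aao), scheme.bin_pc(matrix.pc1), scheme.bin_pc(matrix.pc2)]
        names += list(CONFOUNDER_FEATURES)
        ncat += [scheme.n_aao_bins, 2, 2]
    codes = np.stack(cols, axis=1) if cols else np.empty((matrix.n, 0), dtype=np.int16)
    return DiscreteMatrix(names, codes, np.asarray(ncat), matrix.label)


# ---------------------------------------------------------------------------
# plug-in estimators


def _joint_counts(*cols: np.ndarray) -> np.ndarray:
    """Flat contingency counts of one or more integer-coded columns."""
    if not cols:
        raise ValueError("need at least one column")
    n = len(cols[0])
    if n == 0:
        raise ValueError("empty input")
    for c in cols:
        if len(c) != n:
            raise ValueError("columns differ in length")
    code = np.zeros(n, dtype=np.int64)
    for c in cols:
        c = np.asarray(c, dtype=np.int64)
        if c.min() < 0:
            raise ValueError("negative category code")
        code = code * (c.max() + 1) + c
    return np.bincount(code)


def _H(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(xlogy(p, p)).sum() / _LN2)


def entropy(*cols: np.ndarray) -> float:
    """Plug-in Shannon entropy (joint over all given columns), in bits."""
    return _H(_joint_counts(*cols))


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """I(X;Y) of the empirical joint, in bits (>= 0 up to rounding)."""
    return entropy(x) + entropy(y) - entropy(x, y)


def conditional_mutual_information(x: np.ndarray, z: np.ndarray, y: np.ndarray) -> float:
    """I(X;Z|Y) = H(X,Y) + H(Z,Y) - H(X,Z,Y) - H(Y), in bits."""
    return entropy(x, y) + entropy(z, y) - entropy(x, z, y) - entropy(y)


def joint_mutual_information(x1: np.ndarray, x2: np.ndarray, y: np.ndarray) -> float:
    """I(X1X2;Y): the pair (X1,X2) treated as one variable on the product alphabet."""
    return entropy(x1, x2) + entropy(y) - entropy(x1, x2, y)


# ---------------------------------------------------------------------------
# fast pairwise cache used by the greedy selection loop


class PairwiseCache:
    """Lazily computed pairwise information tables for one discrete dataset.

    The greedy criteria need, for a selected feature j against every
    candidate i: I(Xi;Xj), I(Xi;Xj|Y), I(XiXj;Y) and H(Xi,Xj,Y).  Rows
    are computed vectorized on demand from a one-hot encoding and
    cached; results are identical (to float rounding) to the per-column
    estimators above, which tests assert.
    """

    def __init__(self, dm: DiscreteMatrix):
        self.dm = dm
        n, p = dm.n, dm.p
        self.offsets = np.concatenate([[0], np.cumsum(dm.n_categories)])
        total = int(self.offsets[-1])
        Z = np.zeros((n, total), dtype=np.float32)
        flat = self.offsets[:-1][None, :] + dm.codes
        Z[np.arange(n)[:, None], flat] = 1.0
        self._Z = Z
        y = dm.y.astype(np.int64)
        self._ymask = [(y == 0).astype(np.float32), (y == 1).astype(np.float32)]
        self.n_y = np.array([float(m.sum()) for m in self._ymask])
        self.n = float(n)
        # univariate-by-class counts U[g, col]
        self.U = np.stack([m @ Z for m in self._ymask])  # 2 x total
        self.colsum = self.U.sum(axis=0)
        self._rows: dict[int, dict[str, np.ndarray]] = {}
        self.h_y = _H(self.n_y.astype(np.int64))
        self.mi_y = self._univariate_mi()
        self.h_xy = self._univariate_hxy()

    # -- helpers ---------------------------------------------------------
    def _seg_sum(self, flat: np.ndarray) -> np.ndarray:
        return np.add.reduceat(flat, self.offsets[:-1])

    @staticmethod
    def _plog(num: np.ndarray, ratio_num: np.ndarray, ratio_den: np.ndarray) -> np.ndarray:
        """num/n * log2(ratio_num/ratio_den) with 0 where num == 0."""
        out = np.zeros_like(num, dtype=np.float64)
        m = num > 0
        out[m] = num[m] * (np.log(ratio_num[m]) - np.log(ratio_den[m])) / _LN2
        return out

    def _univariate_mi(self) -> np.ndarray:
        # I(Xi;Y) = sum_{g,b} (U/n) log2(U*n / (n_b * n_g))
        U = self.U.astype(np.float64)
        num = U * self.n
        den = self.colsum[None, :] * self.n_y[:, None]
        flat = self._plog(U, num, den).sum(axis=0) / self.n
        return self._seg_sum(flat)

    def _univariate_hxy(self) -> np.ndarray:
        U = self.U.astype(np.float64)
        flat = self._plog(U, np.full_like(U, self.n), U).sum(axis=0) / self.n
        return self._seg_sum(flat)

    # -- pairwise rows ---------------------------------------------------
    def row(self, j: int) -> dict[str, np.ndarray]:
        """Arrays (length p) of I(Xi;Xj), I(Xi;Xj|Y), I(XiXj;Y), H(Xi,Xj,Y)."""
        if j in self._rows:
            return self._rows[j]
        cj = int(self.dm.n_categories[j])
        oj = int(self.offsets[j])
        # indicator rows for (a, g): t = a*2 + g
        M = np.empty((cj * 2, self.dm.n), dtype=np.float32)
        for a in range(cj):
            za = self._Z[:, oj + a]
            for g in (0, 1):
                M[a * 2 + g] = za * self._ymask[g]
        F = (M @ self._Z).astype(np.float64)  # (a,g) x total
        n = self.n
        n_ag = M.sum(axis=1).astype(np.float64)  # counts of (xj=a, y=g)
        n_a = n_ag.reshape(cj, 2).sum(axis=1)  # counts of xj=a
        n_g = self.n_y
        # N2[a, col] = counts (xj=a, xi=b) pooled over y
        N2 = F.reshape(cj, 2, -1).sum(axis=1)
        n_b = self.colsum.astype(np.float64)  # counts of xi=b
        n_bg = self.U.astype(np.float64)  # (g, col)

        # I(Xi;Xj): sum_ab (N2/n) log2(N2*n / (n_a*n_b))
        mi_flat = self._plog(N2, N2 * n, n_a[:, None] * n_b[None, :]).sum(axis=0) / n
        mi_xx = self._seg_sum(mi_flat)

        # I(Xi;Xj|Y): sum_{a,g,b} (N3/n) log2(N3*n_g / (n_ag*n_bg))
        g_idx = np.tile([0, 1], cj)
        num = F * n_g[g_idx][:, None]
        den = n_ag[:, None] * n_bg[g_idx, :]
        cmi_flat = self._plog(F, num, den).sum(axis=0) / n
        cmi_xx = self._seg_sum(cmi_flat)

        # H(Xi,Xj,Y) = -sum (N3/n) log2(N3/n)
        hxxy_flat = self._plog(F, np.full_like(F, n), F).sum(axis=0) / n
        hxxy = self._seg_sum(hxxy_flat)

        # H(Xi,Xj) from N2, then I(XiXj;Y) = H(XiXj) + H(Y) - H(Xi,Xj,Y)
        hxx_flat = self._plog(N2, np.full_like(N2, n), N2).sum(axis=0) / n
        hxx = self._seg_sum(hxx_flat)
        jmi = hxx + self.h_y - hxxy

        out = {"mi": mi_xx, "cmi": cmi_xx, "jmi": jmi, "hxxy": hxxy}
        self._rows[j] = out
        return out
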