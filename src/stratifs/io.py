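"""Dosage-table and results I/O.

The pipeline's universal input is a flat delimited table: one row per
sample, a sample-id column, a binary phenotype label (PsA=1, PsC=0), age
of psoriasis onset in years (``aao``), the top two ancestry principal
components (``pc1``, ``pc2``), and one column per imputed HLA-allele
dosage in [0, 2].  Imputation-dialect files (SNP2HLA/PLINK dosage) are
not parsed; convert upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_SCHEMA: dict[str, str] = {
    "sample_id": "sample_id",
    "label": "label",
    "aao": "aao",
    "pc1": "pc1",
    "pc2": "pc2",
}

#: reserved column roles; every other numeric column is a dosage feature
_ROLES = ("sample_id", "label", "aao", "pc1", "pc2")


class ValidationError(ValueError):
    """A dosage table violated one of its invariants."""


@dataclass
class DosageMatrix:
    """Samples x HLA-dosage features plus confounders and binary labels.

    Invariants (enforced on construction): consistent shapes, dosages in
    [0, 2], unique sample ids and feature names, labels in {0, 1},
    aao >= 0.
    """

    sample_ids: list[str]
    feature_names: list[str]
    dosages: np.ndarray
    aao: np.ndarray
    pc1: np.ndarray
    pc2: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.aao = np.asarray(self.aao, dtype=float)
        self.pc1 = np.asarray(self.pc1, dtype=float)
        self.pc2 = np.asarray(self.pc2, dtype=float)
        self.label = np.asarray(self.label, dtype=int)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        n, p = self.dosages.shape if self.dosages.ndim == 2 else (len(self.dosages), 0)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D (samples x features) array")
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_names) != p:
            raise ValidationError(f"{len(self.feature_names)} feature names for {p} columns")
        for name, arr in (("aao", self.aao), ("pc1", self.pc1), ("pc2", self.pc2), ("label", self.label)):
            if arr.shape != (n,):
                raise ValidationError(f"{name} has shape {arr.shape}, expected ({n},)")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicated sample id")
        if len(set(self.feature_names)) != p:
            raise ValidationError("duplicated feature name")
        if not np.all(np.isfinite(self.dosages)):
            i, j = np.argwhere(~np.isfinite(self.dosages))[0]
            raise ValidationError(
                f"non-finite dosage at sample {self.sample_ids[i]!r}, feature {self.feature_names[j]!r}"
            )
        bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage {self.dosages[i, j]!r} outside [0, 2] at sample "
                f"{self.sample_ids[i]!r}, feature {self.feature_names[j]!r}"
            )
        if not np.isin(self.label, (0, 1)).all():
            raise ValidationError("labels must be binary 0/1")
        if np.any(self.aao < 0) or not np.all(np.isfinite(self.aao)):
            raise ValidationError("aao must be finite and >= 0")
        if not (np.all(np.isfinite(self.pc1)) and np.all(np.isfinite(self.pc2))):
            raise ValidationError("principal components must be finite")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    def subset(self, rows: np.ndarray, suffix_duplicates: bool = False) -> "DosageMatrix":
        """Row-subset (or resample) preserving all per-sample fields.

        With ``suffix_duplicates`` repeated rows get unique ids
        (``<id>.r<k>``) so the result still satisfies the uniqueness
        invariant -- used by the mitigation/bootstrap resamplers.
        """
        rows = np.asarray(rows)
        ids = [self.sample_ids[i] for i in rows]
        if suffix_duplicates:
            seen: dict[str, int] = {}
            used = set(ids)
            out = []
            for s in ids:
                k = seen.get(s, 0)
                if k == 0:
                    cand = s
                else:
                    cand = f"{s}.r{k}"
                    while cand in used:
                        k += 1
                        cand = f"{s}.r{k}"
                    used.add(cand)
                seen[s] = k + 1
                out.append(cand)
            ids = out
        return DosageMatrix(
            sample_ids=ids,
            feature_names=list(self.feature_names),
            dosages=self.dosages[rows],
            aao=self.aao[rows],
            pc1=self.pc1[rows],
            pc2=self.pc2[rows],
            label=self.label[rows],
        )

    def select_features(self, names: Sequence[str]) -> np.ndarray:
        """Dosage sub-matrix for the named features, in the given order."""
        idx = {f: j for j, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in idx]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        return self.dosages[:, [idx[f] for f in names]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "label": self.label,
                "aao": self.aao,
                "pc1": self.pc1,
                "pc2": self.pc2,
            }
        )
        for j, f in enumerate(self.feature_names):
            df[f] = self.dosages[:, j]
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DosageMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_names == other.feature_names
            and np.array_equal(self.dosages, other.dosages)
            and np.array_equal(self.aao, other.aao)
            and np.array_equal(self.pc1, other.pc1)
            and np.array_equal(self.pc2, other.pc2)
            and np.array_equal(self.label, other.label)
        )


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_dosage_table(path: str | Path, schema: Mapping[str, str] | None = None) -> DosageMatrix:
    """Read a delimited dosage table into a validated :class:`DosageMatrix`.

    ``schema`` maps the roles sample_id/label/aao/pc1/pc2 to column
    names; every remaining column is treated as a dosage feature.  Row
    order is preserved.  Missing values and out-of-range cells are
    rejected with the offending row/column named.
    """
    path = Path(path)
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, sep=_sep_for(path))
    for role in _ROLES:
        if schema[role] not in df.columns:
            raise ValidationError(f"column {schema[role]!r} (role {role}) missing from {path}")
    feature_cols = [c for c in df.columns if c not in set(schema.values())]
    if df[feature_cols + [schema[r] for r in _ROLES if r != "sample_id"]].isna().any().any():
        na = df.isna()
        r = int(na.any(axis=1).idxmax())
        c = na.loc[r][na.loc[r]].index[0]
        raise ValidationError(f"missing value at row {r}, column {c!r}")
    labels = df[schema["label"]].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError(f"non-binary label in column {schema['label']!r}")
    return DosageMatrix(
        sample_ids=df[schema["sample_id"]].astype(str).tolist(),
        feature_names=feature_cols,
        dosages=df[feature_cols].to_numpy(dtype=float),
        aao=df[schema["aao"]].to_numpy(dtype=float),
        pc1=df[schema["pc1"]].to_numpy(dtype=float),
        pc2=df[schema["pc2"]].to_numpy(dtype=float),
        label=labels.astype(int),
    )


def write_dosage_table(matrix: DosageMatrix, path: str | Path) -> None:
    """Write a dosage table readable by :func:`read_dosage_table` (round-trip safe)."""
    if matrix.n == 0:
        raise ValidationError("refusing to write an empty dosage table")
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# results tables

RESULT_COLUMNS = ["model", "criterion", "n_features", "phase", "metric", "value"]


def write_results(records: Sequence, path: str | Path) -> None:
    """Write evaluation records as a long-format delimited table.

    One row per (record, phase, metric); column order is fixed so two
    identical runs produce byte-identical files.
    """
    if not records:
        raise ValueError("no records to write")
    rows = []
    for rec in records:
        for phase in sorted(rec.metrics):
            for metric in sorted(rec.metrics[phase]):
                rows.append(
                    (rec.model, rec.criterion, rec.n_features, phase, metric, rec.metrics[phase][metric])
                )
    path = Path(path)
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep=_sep_for(path), index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path))
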