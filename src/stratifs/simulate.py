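"""Synthetic HLA-dosage cohorts with ascertainment-induced confounding.

The generator emulates a case-control psoriasis cohort (PsA cases vs
cutaneous-only PsC controls) in which one allele (an HLA-B*27 analogue)
raises PsA risk directly, while a second allele (an HLA-C*06 analogue)
has *no* direct effect on the outcome: it lowers age of psoriasis onset,
and controls are preferentially recruited at early onset.  That
outcome-dependent, onset-biased sampling induces a marginal association
between the confounded allele and the label -- the structure the
stratification stage is designed to remove.

Recipe per candidate sample:

1. latent ancestry ``u ~ N(0,1)``; ``pc1 = u + noise``, ``pc2`` independent noise;
2. dosages: per LD block of 5 features, exchangeably correlated latent
   Gaussians cut at the Hardy-Weinberg genotype quantiles of each
   feature's allele frequency (shifted by ``pc_effect * u``), giving
   genotypes {0,1,2} plus a small clipped jitter to mimic imputed dosages;
3. case status: logistic in ``beta_causal * dosage(causal)`` plus a small
   pc1 term; the confounded allele gets no term;
4. ``aao = N(45, 15) + gamma_conf * dosage(confounded)``, clipped to [1, 99];
5. ascertainment: cases are sampled uniformly, controls accept/reject
   sampled with weight ``exp(-ascertain_strength * aao / 15)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .io import DosageMatrix, write_dosage_table  # re-exported: writer lives with the reader

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "write_dosage_table",
]

_GENES = ("A", "B", "C", "DRB1", "DQB1", "DQA1", "DPB1")

CAUSAL_NAME = "HLA_B_27"
CONFOUNDED_NAME = "HLA_C_06"

#: indices placed in different LD blocks (blocks of 5)
_CAUSAL_IDX = 7
_CONFOUNDED_IDX = 12


def _special_indices(p: int) -> tuple[int, int]:
    """Positions of the causal and confounded features (distinct, distinct blocks when possible)."""
    ci = _CAUSAL_IDX if p > _CAUSAL_IDX else 0
    fi = _CONFOUNDED_IDX if p > _CONFOUNDED_IDX else p - 1
    if fi == ci:
        fi = (ci + 1) % p
    return ci, fi


def default_feature_names(p: int) -> list[str]:
    ci, fi = _special_indices(p)
    special = {CAUSAL_NAME, CONFOUNDED_NAME}
    names: list[str] = []
    i = 0
    while len(names) < p:
        cand = f"HLA_{_GENES[i % len(_GENES)]}_{i // len(_GENES) + 1:02d}"
        i += 1
        if cand not in special:
            names.append(cand)
    names[ci] = CAUSAL_NAME
    names[fi] = CONFOUNDED_NAME
    return names


@dataclass
class SyntheticConfig:
    """Generative parameters; defaults are the package's study conditions."""

    n_case: int = 1300
    n_control: int = 1200
    p: int = 70
    allele_freqs: np.ndarray | None = None  # drawn in (0.02, 0.40) when None
    ld_rho: float = 0.4
    ld_block: int = 5
    beta_causal: float = 0.6  # log-odds per dosage unit of the causal allele
    gamma_conf: float = -12.0  # years of onset per dosage unit of the confounded allele
    ascertain_strength: float = 1.0  # control sampling weight exp(-s * aao / 15)
    ascertain_scale: float = 15.0
    pc_effect: float = 0.05  # allele-frequency shift per unit latent ancestry
    pc_beta: float = 0.2  # log-odds per unit pc1 on case status
    jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 20 or self.n_control < 20:
            raise ValueError("need at least 20 cases and 20 controls")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.p < 2:
            raise ValueError("need at least 2 features")
        if self.allele_freqs is not None:
            f = np.asarray(self.allele_freqs, dtype=float)
            if f.shape != (self.p,) or np.any(f <= 0.01) or np.any(f >= 0.5):
                raise ValueError("allele_freqs must be length p, each in (0.01, 0.5)")


@dataclass
class GroundTruth:
    """Which generated features carry the direct vs the induced association."""

    causal_feature: str
    confounded_feature: str
    beta_causal: float
    gamma_conf: float
    ascertain_strength: float

    def __post_init__(self) -> None:
        if self.causal_feature == self.confounded_feature:
            raise ValueError("causal and confounded features must differ")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _draw_freqs(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.allele_freqs is not None:
        return np.asarray(cfg.allele_freqs, dtype=float)
    f = rng.uniform(0.02, 0.40, size=cfg.p)
    ci, fi = _special_indices(cfg.p)
    f[ci] = 0.15  # B*27-analogue allele frequency
    f[fi] = 0.20  # C*06 analogue, the common psoriasis allele
    return f


def _genotypes(cfg: SyntheticConfig, freqs: np.ndarray, u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Correlated genotypes via block-exchangeable latent Gaussians cut at HW quantiles."""
    m = len(u)
    z = np.empty((m, cfg.p))
    r = cfg.ld_rho
    for start in range(0, cfg.p, cfg.ld_block):
        width = min(cfg.ld_block, cfg.p - start)
        shared = rng.standard_normal(m)[:, None]
        eps = rng.standard_normal((m, width))
        z[:, start : start + width] = np.sqrt(r) * shared + np.sqrt(1 - r) * eps
    f = np.clip(freqs[None, :] + cfg.pc_effect * u[:, None], 0.01, 0.99)
    # Hardy-Weinberg: P(g=0) = (1-f)^2, P(g<=1) = 1 - f^2
    q0 = norm.ppf((1 - f) ** 2)
    q1 = norm.ppf(1 - f**2)
    g = (z >= q0).astype(float) + (z >= q1)
    if cfg.jitter > 0:
        g = np.clip(g + rng.uniform(-cfg.jitter, cfg.jitter, size=g.shape), 0.0, 2.0)
    return g


def generate_cohort(config: SyntheticConfig) -> tuple[DosageMatrix, GroundTruth]:
    """Generate exactly ``n_case`` cases and ``n_control`` controls.

    Controls are accept/reject sampled on early onset; if the target
    counts are not reached within a 100x oversampling budget a
    ``RuntimeError`` advises weakening ``ascertain_strength``.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x5EED]))
    causal_idx, conf_idx = _special_indices(cfg.p)
    freqs = _draw_freqs(cfg, rng)
    target = cfg.n_case + cfg.n_control
    kept_case: list[np.ndarray] = []
    kept_ctrl: list[np.ndarray] = []
    n_case = n_ctrl = 0
    drawn = 0
    batch = 8 * target
    while (n_case < cfg.n_case or n_ctrl < cfg.n_control) and drawn < 100 * target:
        m = min(batch, 100 * target - drawn)
        drawn += m
        u = rng.standard_normal(m)
        pc1 = u + 0.5 * rng.standard_normal(m)
        pc2 = rng.standard_normal(m)
        dos = _genotypes(cfg, freqs, u, rng)
        logit = cfg.beta_causal * dos[:, causal_idx] + cfg.pc_beta * pc1 - 0.2
        label = (rng.random(m) < 1 / (1 + np.exp(-logit))).astype(int)
        aao = np.clip(
            rng.normal(45.0, 15.0, size=m) + cfg.gamma_conf * dos[:, conf_idx], 1.0, 99.0
        )
        accept = np.ones(m, dtype=bool)
        ctrl = label == 0
        if cfg.ascertain_strength > 0:
            w = np.exp(-cfg.ascertain_strength * aao / cfg.ascertain_scale)
            accept[ctrl] = rng.random(ctrl.sum()) < w[ctrl]
        block = np.column_stack([dos, aao, pc1, pc2, label])
        is_case = label == 1
        kept_case.append(block[is_case][: cfg.n_case - n_case])
        kept_ctrl.append(block[ctrl & accept][: cfg.n_control - n_ctrl])
        n_case += len(kept_case[-1])
        n_ctrl += len(kept_ctrl[-1])
    if n_case < cfg.n_case or n_ctrl < cfg.n_control:
        raise RuntimeError(
            f"rejection sampling exhausted {100 * target} draws "
            f"(got {n_case}/{cfg.n_case} cases, {n_ctrl}/{cfg.n_control} controls); "
            "weaken ascertain_strength or lower the target counts"
        )
    pool = np.vstack(kept_case + kept_ctrl)
    # deterministic interleave: shuffle rows so case/control order carries no signal
    pool = pool[rng.permutation(len(pool))]
    names = default_feature_names(cfg.p)
    matrix = DosageMatrix(
        sample_ids=[f"S{i:05d}" for i in range(target)],
        feature_names=names,
        dosages=pool[:, : cfg.p],
        aao=pool[:, cfg.p],
        pc1=pool[:, cfg.p + 1],
        pc2=pool[:, cfg.p + 2],
        label=pool[:, cfg.p + 3].astype(int),
    )
    truth = GroundTruth(
        causal_feature=names[causal_idx],
        confounded_feature=names[conf_idx],
        beta_causal=cfg.beta_causal,
        gamma_conf=cfg.gamma_conf,
        ascertain_strength=cfg.ascertain_strength,
    )
    return matrix, truth
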