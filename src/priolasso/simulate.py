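"""Seeded generator of block-structured multi-omics datasets.

The generative model is a shared latent-factor design: L standard-normal
latent factors Z drive every block through per-block loading matrices, so the
overlap of the loading patterns of two blocks is a *redundancy dial* — blocks
loading the same factors carry the same predictive signal, which is exactly
the situation the hierarchical fit is designed to arbitrate. Independent
Gaussian noise is added per feature and each continuous feature is scaled to
unit variance; binary features are thresholded at a configurable prevalence.

The outcome is generated from a true linear predictor eta = sum_m X_m beta_m
with user-chosen sparse direct effects:

* continuous — y = eta + sigma * N(0, 1), sigma set from a target
  signal-to-noise ratio when requested;
* binary     — Bernoulli(expit(eta));
* survival   — T from a Weibull (default exponential) hazard
  h0 * shape * t^(shape-1) * exp(eta), with independent uniform-window
  censoring whose upper bound is calibrated by bisection to the target
  censoring fraction.

``aml_like_preset`` mirrors the shape of a typical AML multi-omics study:
a 2-variable prioritized clinical risk score, 8 clinical covariates, 40
binary mutation indicators and a large continuous expression block (15809
features at scale 1), with redundancy between score and clinical blocks and
between mutation and expression blocks, and roughly 50% censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import DataValidationError
from .io import BlockSpec, Dataset, Outcome


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic dataset."""

    n: int
    block_sizes: tuple[int, ...]
    block_types: tuple[str, ...]  # "continuous" | "binary" per block
    n_factors: int
    loadings: tuple[np.ndarray, ...]  # per block, (p_m, L)
    direct_effects: tuple[np.ndarray, ...]  # per block, (p_m,) true coefficients
    family: str = "survival"
    noise_sd: float = 1.0  # feature-level noise, pre-scaling
    outcome_noise_sd: float = 1.0  # continuous family only
    snr: float | None = None  # overrides outcome_noise_sd when set
    binary_prevalence: float = 0.3
    baseline_hazard: float = 0.2
    weibull_shape: float = 1.0
    censoring_rate: float = 0.5
    block_names: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        M = len(self.block_sizes)
        if M == 0 or any(p <= 0 for p in self.block_sizes):
            raise DataValidationError("block sizes must be positive")
        if len(self.block_types) != M or len(self.loadings) != M or len(self.direct_effects) != M:
            raise DataValidationError("per-block fields must all have length M")
        if self.family not in ("continuous", "binary", "survival"):
            raise DataValidationError(f"unknown family {self.family!r}")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise DataValidationError("censoring rate must be in [0, 1)")
        if self.n_factors < 0 or self.noise_sd <= 0:
            raise DataValidationError("invalid factor count or noise level")
        loads = []
        for m, (p, lam) in enumerate(zip(self.block_sizes, self.loadings)):
            lam = np.asarray(lam, float)
            if lam.shape != (p, self.n_factors):
                raise DataValidationError(
                    f"loadings for block {m} must be ({p}, {self.n_factors})"
                )
            if not np.isfinite(lam).all():
                raise DataValidationError("loadings must be finite")
            loads.append(lam)
        effects = []
        for m, (p, b) in enumerate(zip(self.block_sizes, self.direct_effects)):
            b = np.asarray(b, float)
            if b.shape != (p,):
                raise DataValidationError(f"direct effects for block {m} must be ({p},)")
            effects.append(b)
        names = self.block_names or tuple(f"block{m + 1}" for m in range(M))
        if len(names) != M:
            raise DataValidationError("block_names length mismatch")
        object.__setattr__(self, "loadings", tuple(loads))
        object.__setattr__(self, "direct_effects", tuple(effects))
        object.__setattr__(self, "block_names", tuple(names))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows and the fit is asked to recover."""

    beta: dict  # block name -> true coefficient vector (final X scale)
    factors: np.ndarray  # (n, L)
    eta: np.ndarray  # true linear predictor
    outcome_noise_sd: float | None = None
    censoring_bound: float | None = None


def _calibrate_censoring(T: np.ndarray, U: np.ndarray, target: float) -> float:
    """Bisection on the uniform-window upper bound c: C_i = c * U_i.

    The realized censored fraction mean(c * U < T) decreases in c; find the
    c hitting the target on this very sample (deterministic given T, U).
    """
    lo, hi = 1e-8, float(T.max()) * 2
    frac = lambda c: float(np.mean(c * U < T))
    while frac(hi) > target and hi < T.max() * 1e6:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate(config: SimConfig, seed: int | None = None) -> tuple[Dataset, GroundTruth]:
    """Draw one dataset (plus its ground truth) from the generative model."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, L = config.n, config.n_factors
    Z = rng.standard_normal((n, L)) if L > 0 else np.zeros((n, 0))

    blocks: dict[str, list[str]] = {}
    columns: dict[str, np.ndarray] = {}
    beta: dict[str, np.ndarray] = {}
    eta = np.zeros(n)
    for name, p, btype, lam, b in zip(
        config.block_names,
        config.block_sizes,
        config.block_types,
        config.loadings,
        config.direct_effects,
    ):
        raw = Z @ lam.T + config.noise_sd * rng.standard_normal((n, p))
        if btype == "binary":
            # threshold the latent feature at the prevalence quantile
            thr = np.quantile(raw, 1 - config.binary_prevalence, axis=0)
            X = (raw > thr[None, :]).astype(float)
            b_eff = b.copy()
        elif btype == "continuous":
            sd = np.sqrt((lam**2).sum(axis=1) + config.noise_sd**2)
            X = raw / sd[None, :]
            b_eff = b.copy()
        else:
            raise DataValidationError(f"unknown block type {btype!r}")
        feats = [f"{name}_{j + 1}" for j in range(p)]
        blocks[name] = feats
        for f, col in zip(feats, X.T):
            columns[f] = col
        beta[name] = b_eff
        eta = eta + X @ b_eff

    noise_sd = config.outcome_noise_sd
    if config.family == "continuous":
        if config.snr is not None:
            sd_eta = float(eta.std())
            noise_sd = sd_eta / np.sqrt(config.snr) if sd_eta > 0 else 1.0
        y = eta + noise_sd * rng.standard_normal(n)
        outcome = Outcome.continuous(y)
        truth = GroundTruth(beta, Z, eta, outcome_noise_sd=noise_sd)
    elif config.family == "binary":
        y = (rng.uniform(size=n) < expit(eta)).astype(float)
        outcome = Outcome.binary(y)
        truth = GroundTruth(beta, Z, eta)
    else:
        # Weibull hazard h(t) = h0 * k * t^(k-1) * exp(eta):
        # T = (-log U / (h0 exp(eta)))^(1/k)
        u = rng.uniform(size=n)
        k = config.weibull_shape
        T = (-np.log(u) / (config.baseline_hazard * np.exp(eta))) ** (1.0 / k)
        if config.censoring_rate > 0:
            uc = rng.uniform(size=n)
            bound = _calibrate_censoring(T, uc, config.censoring_rate)
            C = bound * uc
            time = np.minimum(T, C)
            status = (T <= C).astype(int)
        else:
            bound = None
            time, status = T, np.ones(n, int)
        time = np.maximum(time, 1e-12)
        outcome = Outcome.survival(time, status)
        truth = GroundTruth(beta, Z, eta, censoring_bound=bound)

    X = pd.DataFrame(columns, index=[f"s{i + 1}" for i in range(n)])
    spec = BlockSpec(blocks, priority=list(config.block_names))
    return Dataset(X, spec, outcome), truth


def write_truth(truth: GroundTruth, path) -> None:
    """Ground-truth coefficient table (never read by the fitting code)."""
    rows = [
        (block, j + 1, float(c))
        for block, coefs in truth.beta.items()
        for j, c in enumerate(coefs)
    ]
    pd.DataFrame(rows, columns=["block", "feature_index", "true_coefficient"]).to_csv(
        path, sep="\t", index=False
    )


def _spread_effects(p: int, k: int, magnitude: float) -> np.ndarray:
    """k alternating-sign effects of the given size on the first k features."""
    b = np.zeros(p)
    k = min(k, p)
    b[:k] = magnitude * np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
    return b


def aml_like_preset(
    scale: float,
    n: int = 447,
    seed: int = 0,
    family: str = "survival",
    censoring_rate: float = 0.5,
) -> SimConfig:
    """Study-shaped configuration: score, clinical, mutation, expression.

    Block sizes are (2, 8, 40, round(15809 * scale)). Six latent factors:
    the score and clinical blocks share factors 1-3, the mutation and
    expression blocks share factors 4-6, creating cross-block redundancy
    within each pair. Direct effects sit on the score (both variables),
    4 clinical covariates, 5 mutations and 10 expression features.
    """
    if scale <= 0:
        raise DataValidationError("scale must be positive")
    p_expr = int(round(15809 * scale))
    sizes = (2, 8, 40, max(p_expr, 1))
    L = 6
    rng = np.random.default_rng(seed + 7)  # loading patterns, fixed per seed

    def load(p, factors, strength):
        lam = np.zeros((p, L))
        lam[:, factors] = strength * rng.choice([-1.0, 1.0], size=(p, len(factors)))
        return lam

    loadings = (
        load(sizes[0], [0, 1, 2], 0.9),
        load(sizes[1], [0, 1, 2], 0.7),
        load(sizes[2], [3, 4, 5], 0.8),
        load(sizes[3], [3, 4, 5], 0.6),
    )
    effects = (
        _spread_effects(sizes[0], 2, 0.5),
        _spread_effects(sizes[1], 4, 0.3),
        _spread_effects(sizes[2], 5, 0.4),
        _spread_effects(sizes[3], 10, 0.2),
    )
    return SimConfig(
        n=n,
        block_sizes=sizes,
        block_types=("continuous", "continuous", "binary", "continuous"),
        n_factors=L,
        loadings=loadings,
        direct_effects=effects,
        family=family,
        censoring_rate=censoring_rate,
        baseline_hazard=0.2,
        block_names=("score", "clinical", "mutation", "expression"),
        seed=seed,
    )


def independent_blocks_config(
    n: int = 500,
    block_sizes: Sequence[int] = (5, 20),
    effects: Sequence[int] = (2, 3),
    magnitude: float = 1.0,
    family: str = "continuous",
    snr: float | None = 3.0,
    seed: int = 0,
) -> SimConfig:
    """Independent blocks (no shared factors) with known sparse effects —
    the parameter-recovery benchmark."""
    M = len(block_sizes)
    return SimConfig(
        n=n,
        block_sizes=tuple(int(p) for p in block_sizes),
        block_types=("continuous",) * M,
        n_factors=0,
        loadings=tuple(np.zeros((p, 0)) for p in block_sizes),
        direct_effects=tuple(
            _spread_effects(p, k, magnitude) for p, k in zip(block_sizes, effects)
        ),
        family=family,
        snr=snr,
        seed=seed,
    )


def redundant_blocks_config(
    n: int = 150,
    p: int = 10,
    strength: float = 1.0,
    effect: float = 0.8,
    family: str = "continuous",
    snr: float | None = 3.0,
    seed: int = 0,
) -> SimConfig:
    """Two blocks with identical loadings and signal only through the shared
    factors — the redundancy-absorption benchmark."""
    L = 3
    rng = np.random.default_rng(seed + 13)
    lam = strength * rng.choice([-1.0, 1.0], size=(p, L))
    return SimConfig(
        n=n,
        block_sizes=(p, p),
        block_types=("continuous", "continuous"),
        n_factors=L,
        loadings=(lam, lam.copy()),
        direct_effects=(
            _spread_effects(p, 4, effect),
            np.zeros(p),
        ),
        family=family,
        snr=snr,
        block_names=("blockA", "blockB"),
        seed=seed,
    )
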