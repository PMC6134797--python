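"""The hierarchical fit: sequential per-block Lasso with accumulated offsets.

Blocks are fitted in the user's priority order. Step m fits an L1-penalized
model to block pi_m with the accumulated linear score of steps 1..m-1 entering
as an offset (coefficient fixed to 1), so a block can only pick up signal not
already explained by higher-priority blocks. Two offset flavours exist:

* plain     — the full-data score of the previous steps (in-sample, tends to
              under-credit lower-priority blocks because it is over-optimistic
              about what the earlier blocks explain);
* cross-validated — each sample's carried offset comes from fits that
              excluded that sample's fold, restoring signal to later blocks.

Either way, the *final* reported coefficients of every step are full-data
estimates; cross-validation only changes what downstream steps condition on,
and the final linear predictor decomposes exactly into per-block
contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DataValidationError, NotFittedError
from .io import BlockSpec, Dataset, FitOptions, Outcome, SparseLinearModel
from .solver import (
    CvCurve,
    StepFit,
    constrain_nonzero,
    cv_error,
    family_loss,
    fit_path,
    make_folds,
    select_lambda,
)


@dataclass(frozen=True)
class CvOffsetRecord:
    """Cross-validated offsets for one step.

    ``offsets[i]`` = prior offset of sample i + the block score from the fold
    fit that excluded i's fold (including that fold's intercept for the
    continuous and binary families).
    """

    step: int
    fold_assignment: np.ndarray
    offsets: np.ndarray
    fold_coefs: tuple[np.ndarray, ...]
    fold_intercepts: tuple[float, ...]
    fold_lambdas: tuple[float, ...]


@dataclass(frozen=True)
class PriorityModel:
    """A fitted hierarchical model: ordered StepFits plus bookkeeping."""

    block_spec: BlockSpec
    options: FitOptions
    family: str
    step_fits: tuple[StepFit, ...]
    n_train: int
    cv_offset_records: tuple[CvOffsetRecord, ...] = ()

    @property
    def priority(self) -> tuple[str, ...]:
        return self.block_spec.priority

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f for sf in self.step_fits for f in sf.features)

    @property
    def intercept(self) -> float:
        return float(sum(sf.intercept for sf in self.step_fits))

    def coef_series(self) -> pd.Series:
        """All coefficients (including zeros), indexed by feature name."""
        vals = np.concatenate([sf.coef for sf in self.step_fits])
        return pd.Series(vals, index=list(self.feature_names), dtype=float)

    def n_nonzero(self) -> dict[str, int]:
        return {sf.block_name: sf.n_nonzero for sf in self.step_fits}

    def to_sparse(self) -> SparseLinearModel:
        if not self.step_fits:
            raise NotFittedError("model has no fitted steps")
        coefs = self.coef_series()
        coefs = coefs[coefs != 0]
        block_of = {
            f: sf.block_name for sf in self.step_fits for f in sf.features
        }
        return SparseLinearModel(
            family=self.family,
            intercept=self.intercept,
            coefficients=coefs,
            block_of={f: block_of[f] for f in coefs.index},
            priority=self.priority,
            options=self.options.to_dict(),
        )

    def fit_log(self) -> pd.DataFrame:
        """Per-step summary: chosen penalty, nonzero count, CV error."""
        return pd.DataFrame(
            {
                "step": [sf.block_index + 1 for sf in self.step_fits],
                "block": [sf.block_name for sf in self.step_fits],
                "lambda": [sf.lam for sf in self.step_fits],
                "rule": [sf.rule for sf in self.step_fits],
                "unpenalized": [sf.unpenalized for sf in self.step_fits],
                "n_nonzero": [sf.n_nonzero for sf in self.step_fits],
                "cv_error": [sf.cv_mean_error for sf in self.step_fits],
            }
        )


def _step_seeds(options: FitOptions, n_steps: int) -> list[dict[str, int]]:
    """Deterministic per-step sub-seeds derived from the master seed."""
    ss = np.random.SeedSequence(options.seed)
    children = ss.spawn(n_steps)
    out = []
    for child in children:
        lam_seed, off_seed = child.generate_state(2) % (2**31 - 1)
        out.append({"lambda": int(lam_seed), "offset": int(off_seed)})
    return out


def _fit_one_block(
    Xb: np.ndarray,
    outcome: Outcome,
    offset: np.ndarray,
    options: FitOptions,
    cap: int | None,
    penalized: bool,
    seed: int,
) -> tuple[np.ndarray, float, float, float, CvCurve | None]:
    """Full lambda-selection fit of a single block.

    Returns (coef, intercept, chosen lambda, cv error at that lambda, curve).
    """
    if not penalized:
        path = fit_path(Xb, outcome, offset, penalized=False)
        coef, b0 = path.coef_at(0.0)
        return coef, b0, 0.0, np.nan, None
    dfmax = None
    if cap is not None:
        # a small buffer past the cap keeps the CV curve informative around it
        dfmax = max(cap + 5, int(1.5 * cap))
    path = fit_path(
        Xb,
        outcome,
        offset,
        standardize=options.standardize,
        nlambda=options.nlambda,
        dfmax=dfmax,
    )
    curve = cv_error(
        Xb,
        outcome,
        offset,
        nfolds=options.nfolds_lambda,
        seed=seed,
        path=path,
        standardize=options.standardize,
    )
    if cap is not None:
        lam = constrain_nonzero(path, curve, cap, options.lambda_rule)
    else:
        lam = select_lambda(curve, options.lambda_rule)
    coef, b0 = path.coef_at(lam)
    cvm = float(np.asarray(curve.mean_cv_error)[path.index_of(lam)])
    return coef, b0, lam, cvm, curve


def compute_cv_offsets(
    dataset: Dataset,
    step: int,
    prior_offsets: np.ndarray,
    options: FitOptions,
    *,
    block_name: str | None = None,
    seed: int | None = None,
) -> CvOffsetRecord:
    """Cross-validated offsets after fitting step ``step`` (0-based).

    The dataset is split into K = ``nfolds_offset`` folds; the step's block is
    refitted on each complement (same lambda-selection procedure, fold-internal
    CV) and samples of the held-out fold are scored by that external fit.
    """
    if step < 0 or step >= dataset.block_spec.n_blocks:
        raise DataValidationError(f"step {step} out of range")
    block = block_name or dataset.block_spec.priority[step]
    prior_offsets = np.asarray(prior_offsets, float)
    if prior_offsets.shape != (dataset.n,):
        raise DataValidationError("prior_offsets must have one entry per sample")
    if seed is None:
        seed = _step_seeds(options, dataset.block_spec.n_blocks)[step]["offset"]
    Xb = dataset.block_matrix(block)
    outcome = dataset.outcome
    cap = options.cap_for(block)
    penalized = options.penalize_first_block or step > 0
    K = options.nfolds_offset
    folds = make_folds(outcome, K, seed)
    offsets = np.empty(dataset.n)
    fold_coefs, fold_b0s, fold_lams = [], [], []
    inner_seeds = np.random.SeedSequence(seed).generate_state(K) % (2**31 - 1)
    for k in range(K):
        tr = folds != k
        te = ~tr
        coef, b0, lam, _, _ = _fit_one_block(
            Xb[tr],
            outcome.subset(tr),
            prior_offsets[tr],
            options,
            cap,
            penalized,
            int(inner_seeds[k]),
        )
        offsets[te] = prior_offsets[te] + b0 + Xb[te] @ coef
        fold_coefs.append(coef)
        fold_b0s.append(float(b0))
        fold_lams.append(float(lam))
    return CvOffsetRecord(
        step=step,
        fold_assignment=folds,
        offsets=offsets,
        fold_coefs=tuple(fold_coefs),
        fold_intercepts=tuple(fold_b0s),
        fold_lambdas=tuple(fold_lams),
    )


def fit(dataset: Dataset, options: FitOptions | None = None) -> PriorityModel:
    """Fit the hierarchical model on ``dataset`` in its priority order."""
    options = options or FitOptions()
    spec = dataset.block_spec
    outcome = dataset.outcome
    M = spec.n_blocks
    if not options.penalize_first_block:
        p1 = len(spec.features_of(spec.priority[0]))
        if p1 >= dataset.n:
            raise DataValidationError(
                "unpenalized top block requires p < n "
                f"(block {spec.priority[0]!r} has p={p1}, n={dataset.n})"
            )
    seeds = _step_seeds(options, M)
    used_offset = np.zeros(dataset.n)
    step_fits: list[StepFit] = []
    records: list[CvOffsetRecord] = []
    for m, block in enumerate(spec.priority):
        Xb = dataset.block_matrix(block)
        penalized = options.penalize_first_block or m > 0
        cap = options.cap_for(block)
        coef, b0, lam, cvm, _ = _fit_one_block(
            Xb, outcome, used_offset, options, cap, penalized, seeds[m]["lambda"]
        )
        step_fits.append(
            StepFit(
                block_name=block,
                block_index=m,
                features=spec.features_of(block),
                lam=lam,
                coef=coef,
                intercept=float(b0),
                offset_used=used_offset.copy(),
                rule="none" if not penalized else options.lambda_rule,
                unpenalized=not penalized,
                cv_mean_error=cvm,
            )
        )
        if m < M - 1:
            if options.cv_offsets:
                rec = compute_cv_offsets(
                    dataset,
                    m,
                    used_offset,
                    options,
                    block_name=block,
                    seed=seeds[m]["offset"],
                )
                records.append(rec)
                used_offset = rec.offsets
            else:
                used_offset = used_offset + b0 + Xb @ coef
    return PriorityModel(
        block_spec=spec,
        options=options,
        family=outcome.family,
        step_fits=tuple(step_fits),
        n_train=dataset.n,
        cv_offset_records=tuple(records),
    )


def choose_order(
    dataset: Dataset,
    candidate_orders: list,
    options: FitOptions | None = None,
    *,
    nfolds_outer: int = 5,
) -> tuple[tuple[str, ...], PriorityModel, list[float]]:
    """Fit each candidate priority order; keep the one with lowest CV loss.

    Candidates are scored by ``nfolds_outer``-fold cross-validated prediction
    loss of the whole pipeline (outer folds are distinct from the inner folds
    used for penalty selection). Ties break by candidate list position.
    """
    options = options or FitOptions()
    if not candidate_orders:
        raise DataValidationError("need at least one candidate order")
    candidates = [tuple(map(str, c)) for c in candidate_orders]
    for cand in candidates:
        if sorted(cand) != sorted(dataset.block_spec.block_names):
            raise DataValidationError(
                f"candidate {cand} is not a permutation of the block names"
            )
    outer_seed = int(
        np.random.SeedSequence([options.seed, 0x5EED]).generate_state(1)[0]
        % (2**31 - 1)
    )
    folds = make_folds(dataset.outcome, nfolds_outer, outer_seed)
    errors: list[float] = []
    for cand in candidates:
        spec = dataset.block_spec.with_priority(cand)
        ds = Dataset(dataset.X, spec, dataset.outcome)
        fold_losses = []
        for k in range(nfolds_outer):
            tr = np.flatnonzero(folds != k)
            te = np.flatnonzero(folds == k)
            inner = replace(options, seed=int((options.seed * nfolds_outer + k) % (2**31 - 1)))
            m = fit(ds.subset(tr), inner)
            eta = _model_eta(m, ds.X.iloc[te])
            fold_losses.append(family_loss(dataset.outcome.subset(te), eta))
        errors.append(float(np.mean(fold_losses)))
    best = int(np.argmin(errors))
    spec = dataset.block_spec.with_priority(candidates[best])
    model = fit(Dataset(dataset.X, spec, dataset.outcome), options)
    return candidates[best], model, errors


def _model_eta(model: PriorityModel, X: pd.DataFrame) -> np.ndarray:
    from .predict import linear_score

    scores, _ = linear_score(model, X)
    return scores
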