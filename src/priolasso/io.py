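"""Domain types and plain-text I/O.

The central containers are :class:`BlockSpec` (feature-to-block assignment
plus a priority order over blocks), :class:`Outcome` (continuous, binary or
right-censored survival response), :class:`Dataset` (covariate matrix bound
to a block spec and an outcome) and :class:`FitOptions` (everything the
hierarchical fit is allowed to tune).

File formats are deliberately minimal and text-only so that fitted models are
transportable: users of an exported model need nothing but the coefficient
table to score new patients.

* covariate matrix  — CSV, header row, first column = sample ID
* outcome           — CSV, first column = sample ID, then either a single
                      ``value`` column or ``time``/``status`` columns
* block spec        — YAML with a ``blocks`` mapping (name -> feature list)
                      and a ``priority`` list of block names
* model export      — TSV coefficient table with a commented header carrying
                      family, intercept and fit options
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DataValidationError,
    DegenerateOutcomeError,
    DuplicateFeatureError,
    FeatureMismatchError,
    MissingValuesError,
    NonPositiveTimeError,
    NotFittedError,
    UncoveredFeatureError,
    UnknownFeatureError,
)

FAMILIES = ("continuous", "binary", "survival")


@dataclass(frozen=True)
class BlockSpec:
    """Partition of features into M named blocks plus a priority permutation.

    ``blocks`` is an ordered list of ``(block_name, feature_names)`` pairs;
    ``priority`` lists block names from highest to lowest priority and must be
    a permutation of the block names.
    """

    blocks: tuple[tuple[str, tuple[str, ...]], ...]
    priority: tuple[str, ...]

    def __init__(
        self,
        blocks: Sequence[tuple[str, Sequence[str]]] | Mapping[str, Sequence[str]],
        priority: Sequence[str] | None = None,
    ):
        if isinstance(blocks, Mapping):
            items = tuple((str(k), tuple(map(str, v))) for k, v in blocks.items())
        else:
            items = tuple((str(k), tuple(map(str, v))) for k, v in blocks)
        if not items:
            raise DataValidationError("block spec must define at least one block")
        names = [name for name, _ in items]
        if len(set(names)) != len(names):
            raise DuplicateFeatureError(f"duplicated block names in {names}")
        seen: set[str] = set()
        for name, feats in items:
            if not feats:
                raise DataValidationError(f"block {name!r} is empty")
            for f in feats:
                if f in seen:
                    raise DuplicateFeatureError(
                        f"feature {f!r} assigned to more than one block"
                    )
                seen.add(f)
        prio = tuple(names) if priority is None else tuple(map(str, priority))
        if sorted(prio) != sorted(names):
            raise DataValidationError(
                f"priority {prio} is not a permutation of block names {names}"
            )
        object.__setattr__(self, "blocks", items)
        object.__setattr__(self, "priority", prio)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def block_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.blocks)

    @property
    def feature_names(self) -> tuple[str, ...]:
        """All features, in block-spec order (concatenated over blocks)."""
        return tuple(f for _, feats in self.blocks for f in feats)

    def features_of(self, block: str) -> tuple[str, ...]:
        for name, feats in self.blocks:
            if name == block:
                return feats
        raise KeyError(block)

    def block_sizes(self) -> dict[str, int]:
        return {name: len(feats) for name, feats in self.blocks}

    def with_priority(self, priority: Sequence[str]) -> "BlockSpec":
        return BlockSpec(self.blocks, priority)

    def to_dict(self) -> dict:
        return {
            "blocks": {name: list(feats) for name, feats in self.blocks},
            "priority": list(self.priority),
        }


@dataclass(frozen=True)
class Outcome:
    """Per-sample response: continuous value, binary label, or (time, status).

    For survival, ``time`` holds strictly positive follow-up times in study
    time units and ``status`` is 1 for an observed event, 0 for censoring.
    """

    family: str
    values: np.ndarray | None = None
    time: np.ndarray | None = None
    status: np.ndarray | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise DataValidationError(
                f"family must be one of {FAMILIES}, got {self.family!r}"
            )
        if self.family == "survival":
            if self.time is None or self.status is None:
                raise DataValidationError("survival outcome needs time and status")
            time = np.asarray(self.time, dtype=float)
            status = np.asarray(self.status, dtype=float)
            if time.shape != status.shape or time.ndim != 1:
                raise DataValidationError("time and status must be 1-d, same length")
            if np.isnan(time).any() or np.isnan(status).any():
                raise MissingValuesError("missing values in survival outcome")
            if (time <= 0).any():
                raise NonPositiveTimeError("survival times must be strictly positive")
            if not np.isin(status, (0.0, 1.0)).all():
                raise DataValidationError("status must be 0 (censored) or 1 (event)")
            object.__setattr__(self, "time", time)
            object.__setattr__(self, "status", status.astype(int))
        else:
            if self.values is None:
                raise DataValidationError(f"{self.family} outcome needs values")
            values = np.asarray(self.values, dtype=float)
            if values.ndim != 1:
                raise DataValidationError("outcome values must be 1-d")
            if np.isnan(values).any():
                raise MissingValuesError("missing values in outcome")
            if self.family == "binary" and not np.isin(values, (0.0, 1.0)).all():
                raise DataValidationError("binary labels must be in {0, 1}")
            object.__setattr__(self, "values", values)

    @classmethod
    def continuous(cls, values) -> "Outcome":
        return cls("continuous", values=values)

    @classmethod
    def binary(cls, values) -> "Outcome":
        return cls("binary", values=values)

    @classmethod
    def survival(cls, time, status) -> "Outcome":
        return cls("survival", time=time, status=status)

    @property
    def n(self) -> int:
        return len(self.time if self.family == "survival" else self.values)

    @property
    def n_events(self) -> int:
        if self.family != "survival":
            raise DataValidationError("n_events only defined for survival outcomes")
        return int(self.status.sum())

    def subset(self, idx) -> "Outcome":
        if self.family == "survival":
            return Outcome.survival(self.time[idx], self.status[idx])
        return Outcome(self.family, values=self.values[idx])

    def check_fittable(self) -> None:
        """Raise if the outcome cannot support a model fit."""
        if self.family == "survival":
            if self.n_events == 0:
                raise DegenerateOutcomeError("no events in survival outcome")
        elif np.ptp(self.values) == 0:
            raise DegenerateOutcomeError("constant outcome")


@dataclass(frozen=True)
class Dataset:
    """Covariate matrix + block spec + outcome, with invariants enforced.

    ``X`` columns are re-indexed to block-spec order at construction, so a
    permutation of input columns never changes downstream fits.
    """

    X: pd.DataFrame
    block_spec: BlockSpec
    outcome: Outcome

    def __post_init__(self):
        X = self.X
        if not isinstance(X, pd.DataFrame):
            raise DataValidationError("X must be a pandas DataFrame")
        cols = set(map(str, X.columns))
        spec_feats = self.block_spec.feature_names
        missing = [f for f in spec_feats if f not in cols]
        if missing:
            raise UnknownFeatureError(
                f"block spec names features absent from the matrix: {missing[:5]}"
            )
        extra = sorted(cols - set(spec_feats))
        if extra:
            raise UncoveredFeatureError(
                f"matrix columns not covered by any block: {extra[:5]}"
            )
        X = X.reindex(columns=list(spec_feats))
        try:
            X = X.astype(float)
        except (TypeError, ValueError) as exc:
            raise DataValidationError(f"non-numeric covariate column: {exc}") from exc
        if X.isna().to_numpy().any():
            bad = X.columns[X.isna().any(axis=0)].tolist()
            raise MissingValuesError(
                f"missing values in covariates (e.g. columns {bad[:5]}); "
                "impute or drop before loading"
            )
        if len(X) != self.outcome.n:
            raise DataValidationError(
                f"matrix has {len(X)} rows but outcome has {self.outcome.n}"
            )
        object.__setattr__(self, "X", X)

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def sample_ids(self) -> tuple:
        return tuple(self.X.index)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.X.columns)

    def block_matrix(self, block: str) -> np.ndarray:
        return self.X[list(self.block_spec.features_of(block))].to_numpy(float)

    def subset(self, idx) -> "Dataset":
        idx = np.asarray(idx)
        return Dataset(self.X.iloc[idx], self.block_spec, self.outcome.subset(idx))


@dataclass(frozen=True)
class FitOptions:
    """Tuning options for the hierarchical fit.

    cv_offsets
        If True, the offset carried from step m to step m+1 for sample i is
        computed from a fit that excluded i's fold (counteracts the
        over-optimism of in-sample scores).
    nfolds_lambda / nfolds_offset
        Fold counts for penalty selection and for offset cross-validation.
    lambda_rule
        "min" (minimal mean CV error) or "1se" (sparsest model within one
        standard error of the minimum).
    max_nonzero
        Per-block cap on nonzero coefficients: None (unlimited), an int
        applied to every penalized block, or a mapping block name -> cap.
    penalize_first_block
        If False, the top-priority block is fitted unpenalized (requires
        p < n for that block).
    standardize
        Scale features to unit variance inside the solver (coefficients are
        always reported on the original covariate scale). Centering is
        always applied.
    """

    cv_offsets: bool = False
    nfolds_lambda: int = 10
    nfolds_offset: int = 10
    lambda_rule: str = "min"
    max_nonzero: int | Mapping[str, int] | None = None
    penalize_first_block: bool = True
    seed: int = 0
    standardize: bool = True
    nlambda: int = 100

    def __post_init__(self):
        if self.nfolds_lambda < 2 or self.nfolds_offset < 2:
            raise DataValidationError("fold counts must be >= 2")
        if self.lambda_rule not in ("min", "1se"):
            raise DataValidationError("lambda_rule must be 'min' or '1se'")
        if isinstance(self.max_nonzero, int) and self.max_nonzero < 0:
            raise DataValidationError("max_nonzero must be nonnegative")

    def cap_for(self, block: str) -> int | None:
        if self.max_nonzero is None:
            return None
        if isinstance(self.max_nonzero, Mapping):
            cap = self.max_nonzero.get(block)
            return None if cap is None else int(cap)
        return int(self.max_nonzero)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["max_nonzero"], Mapping):
            d["max_nonzero"] = dict(d["max_nonzero"])
        return d


# ---------------------------------------------------------------------------
# readers / writers


def read_blockspec(path) -> BlockSpec:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "blocks" not in cfg:
        raise DataValidationError(f"{path}: block spec must define a 'blocks' mapping")
    return BlockSpec(cfg["blocks"], cfg.get("priority"))


def write_blockspec(spec: BlockSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


def read_outcome(path, family: str | None = None) -> tuple[Outcome, pd.Index]:
    """Read an outcome CSV; returns the outcome and its sample index.

    Survival is recognised by ``time``/``status`` columns. For a single
    ``value`` column the family is ``family`` if given, else binary when all
    values lie in {0, 1}, else continuous.
    """
    df = pd.read_csv(path, index_col=0)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "time" in cols and "status" in cols:
        if family not in (None, "survival"):
            raise DataValidationError(
                f"{path}: outcome file has time/status but family={family!r}"
            )
        return Outcome.survival(df["time"].to_numpy(), df["status"].to_numpy()), df.index
    if "value" not in cols:
        raise DataValidationError(
            f"{path}: outcome file needs either time/status or a value column"
        )
    values = df["value"].to_numpy(float)
    if family is None:
        ok = ~np.isnan(values)
        family = "binary" if np.isin(values[ok], (0.0, 1.0)).all() else "continuous"
    return Outcome(family, values=values), df.index


def write_outcome(outcome: Outcome, path, sample_ids=None) -> None:
    ids = sample_ids if sample_ids is not None else range(outcome.n)
    if outcome.family == "survival":
        df = pd.DataFrame({"time": outcome.time, "status": outcome.status}, index=ids)
    else:
        df = pd.DataFrame({"value": outcome.values}, index=ids)
    df.index.name = "sample_id"
    df.to_csv(path)


def read_dataset(matrix_path, outcome_path, blockspec_path, family: str | None = None) -> Dataset:
    """Load a dataset from the three plain-text inputs and validate it.

    The matrix is CSV with a header and the sample ID in the first column;
    samples are aligned to the outcome file by ID.
    """
    spec = read_blockspec(blockspec_path)
    X = pd.read_csv(matrix_path, index_col=0)
    outcome, oidx = read_outcome(outcome_path, family=family)
    if len(oidx) != len(X) or not X.index.equals(oidx):
        if set(X.index) != set(oidx):
            raise DataValidationError(
                f"sample IDs differ between {matrix_path} and {outcome_path}"
            )
        X = X.loc[oidx]
    return Dataset(X, spec, outcome)


def write_dataset(dataset: Dataset, matrix_path, outcome_path, blockspec_path) -> None:
    X = dataset.X.copy()
    X.index.name = "sample_id"
    X.to_csv(matrix_path)
    write_outcome(dataset.outcome, outcome_path, dataset.X.index)
    write_blockspec(dataset.block_spec, blockspec_path)


@dataclass(frozen=True)
class SparseLinearModel:
    """A transportable fitted score: nonzero coefficients + intercept.

    This is all a downstream user needs to apply the model; it is what
    :func:`export_model` writes and :func:`import_model` reads back.
    """

    family: str
    intercept: float
    coefficients: pd.Series  # indexed by feature name, nonzero entries only
    block_of: Mapping[str, str] = field(default_factory=dict)
    priority: tuple[str, ...] = ()
    options: Mapping | None = None

    def linear_score(self, X: pd.DataFrame) -> np.ndarray:
        feats = list(self.coefficients.index)
        missing = [f for f in feats if f not in X.columns]
        if missing:
            raise FeatureMismatchError(f"matrix lacks model features: {missing[:5]}")
        return self.intercept + X[feats].to_numpy(float) @ self.coefficients.to_numpy()


def export_model(model, path) -> None:
    """Write a fitted model as a TSV coefficient table with a header block.

    Only nonzero coefficients are written; the round trip through
    :func:`import_model` reproduces linear scores to full precision.
    """
    from .model import PriorityModel  # local import to avoid a cycle

    if isinstance(model, PriorityModel):
        if not model.step_fits:
            raise NotFittedError("model has no fitted steps")
        sparse = model.to_sparse()
    elif isinstance(model, SparseLinearModel):
        sparse = model
    else:
        raise TypeError(f"cannot export {type(model).__name__}")

    prio_rank = {b: i + 1 for i, b in enumerate(sparse.priority)}
    lines = ["# priolasso model v1"]
    lines.append(f"# family: {sparse.family}")
    lines.append(f"# intercept: {sparse.intercept!r}")
    if sparse.options is not None:
        lines.append(f"# options: {json.dumps(dict(sparse.options))}")
    lines.append(f"# priority: {json.dumps(list(sparse.priority))}")
    lines.append("block_priority\tblock_name\tfeature\tcoefficient")
    for feat, coef in sparse.coefficients.items():
        block = sparse.block_of.get(feat, "")
        lines.append(f"{prio_rank.get(block, '')}\t{block}\t{feat}\t{coef!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def import_model(path) -> SparseLinearModel:
    family = None
    intercept = 0.0
    options = None
    priority: tuple[str, ...] = ()
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("family:"):
                    family = body.split(":", 1)[1].strip()
                elif body.startswith("intercept:"):
                    intercept = float(body.split(":", 1)[1])
                elif body.startswith("options:"):
                    options = json.loads(body.split(":", 1)[1])
                elif body.startswith("priority:"):
                    priority = tuple(json.loads(body.split(":", 1)[1]))
            elif line and not line.startswith("block_priority"):
                rows.append(line.split("\t"))
    if family is None:
        raise DataValidationError(f"{path}: not a priolasso model file")
    feats = [r[2] for r in rows]
    coefs = pd.Series([float(r[3]) for r in rows], index=feats, dtype=float)
    block_of = {r[2]: r[1] for r in rows}
    return SparseLinearModel(
        family=family,
        intercept=intercept,
        coefficients=coefs,
        block_of=block_of,
        priority=priority,
        options=options,
    )
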