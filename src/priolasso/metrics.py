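"""External-validation metric suite for survival risk scores.

Given a score fitted on training data and an independent validation cohort,
this module computes the full report used to judge a prognostic model:

* discrimination — Uno's IPCW concordance index, time-dependent Brier score
  curve and its integral (IBS) over configurable horizons, AUC/TPR/TNR of the
  dichotomised score at a clinical horizon;
* calibration — calibration slope (Cox coefficient of the score as sole
  covariate) on training and validation data, and their difference
  ("optimism");
* risk stratification — three risk groups from the two cutpoints maximizing
  the three-group logrank statistic on the training scores, with hazard
  ratios (intermediate group as baseline), Wald CIs and a likelihood-ratio
  test, plus observed and predicted Kaplan-Meier curves per group.

IPCW weights use the Kaplan-Meier estimate G of the censoring distribution
with the left-limit convention G(t-) for event weights; ties between event
and censoring times are treated as event-first.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import DataValidationError, DegenerateOutcomeError

LOW, INTERMEDIATE, HIGH = "low", "intermediate", "high"


# ---------------------------------------------------------------------------
# censoring-distribution Kaplan-Meier


def censoring_km(time, status):
    """KM estimator of the censoring distribution G(t) = P(C > t).

    Returns ``(G, G_minus)``: callables evaluating G(t) and the left limit
    G(t-) at arbitrary times. Censoring is the "event" here; at tied times
    true events happen first, so subjects with an event at t remain in the
    risk set of a censoring at t.
    """
    time = np.asarray(time, float)
    status = np.asarray(status)
    order = np.argsort(time, kind="stable")
    t, s = time[order], status[order]
    new = np.empty(len(t), bool)
    new[0] = True
    new[1:] = t[1:] != t[:-1]
    first = np.flatnonzero(new)
    grp = np.cumsum(new) - 1
    n_at_risk = len(t) - first  # #{time >= t_k}
    dc = np.bincount(grp, weights=(s == 0).astype(float))  # censorings at t_k
    utimes = t[first]
    surv = np.cumprod(1.0 - dc / n_at_risk)

    def G(x):
        x = np.asarray(x, float)
        idx = np.searchsorted(utimes, x, side="right") - 1
        return np.where(idx >= 0, surv[np.maximum(idx, 0)], 1.0)

    def G_minus(x):
        x = np.asarray(x, float)
        idx = np.searchsorted(utimes, x, side="left") - 1
        return np.where(idx >= 0, surv[np.maximum(idx, 0)], 1.0)

    return G, G_minus


# ---------------------------------------------------------------------------
# discrimination


def uno_c(scores, time, status, tau=None) -> float:
    """Uno's IPCW concordance index truncated at tau.

    Comparable pairs (i, j): subject i has an event before min(tau, T_j);
    each pair is weighted 1 / G(T_i-)^2. Higher scores must rank shorter
    survival; score ties count 1/2.
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    status = np.asarray(status)
    if tau is None:
        tau = time[status == 1].max() if (status == 1).any() else time.max()
    _, G_minus = censoring_km(time, status)
    w = 1.0 / G_minus(time) ** 2
    # pair masks: i indexes rows (the earlier event), j columns
    comparable = (
        (status[:, None] == 1)
        & (time[:, None] < tau)
        & (time[:, None] < time[None, :])
    )
    if not comparable.any():
        raise DegenerateOutcomeError("no comparable pairs before tau")
    conc = np.where(
        scores[:, None] > scores[None, :],
        1.0,
        np.where(scores[:, None] == scores[None, :], 0.5, 0.0),
    )
    wmat = np.broadcast_to(w[:, None], comparable.shape)
    num = (wmat * conc)[comparable].sum()
    den = wmat[comparable].sum()
    return float(num / den)


def brier_curve(pred_surv, time, status, eval_times) -> np.ndarray:
    """IPCW Brier score BS(t) at each evaluation time.

    ``pred_surv`` is (n_samples, n_times): predicted P(T > t | x). Subjects
    with an observed event by t contribute S(t)^2 / G(T_i-); subjects still
    under observation past t contribute (1 - S(t))^2 / G(t); subjects
    censored by t contribute nothing.
    """
    pred_surv = np.atleast_2d(np.asarray(pred_surv, float))
    time = np.asarray(time, float)
    status = np.asarray(status)
    eval_times = np.asarray(eval_times, float)
    n = len(time)
    if pred_surv.shape != (n, len(eval_times)):
        raise DataValidationError(
            f"pred_surv must be (n_samples, n_times) = ({n}, {len(eval_times)})"
        )
    G, G_minus = censoring_km(time, status)
    g_event = G_minus(time)
    g_t = G(eval_times)
    if np.any(g_t[eval_times <= np.max(time[status == 1], initial=np.inf)] <= 0):
        raise DataValidationError(
            "censoring survival reaches 0 before the evaluation horizon"
        )
    bs = np.empty(len(eval_times))
    for k, t in enumerate(eval_times):
        died = (time <= t) & (status == 1)
        alive = time > t
        terms = np.zeros(n)
        terms[died] = pred_surv[died, k] ** 2 / g_event[died]
        if alive.any():
            terms[alive] = (1.0 - pred_surv[alive, k]) ** 2 / g_t[k]
        bs[k] = terms.sum() / n
    return bs


def integrated_brier(eval_times, bs, t_max) -> float:
    """IBS = (1/t_max) * integral_0^t_max BS(t) dt by the trapezoid rule.

    The curve is linearly interpolated on the supplied grid; include t = 0
    in ``eval_times`` for an exact lower end.
    """
    eval_times = np.asarray(eval_times, float)
    bs = np.asarray(bs, float)
    if t_max <= 0:
        raise DataValidationError("t_max must be positive")
    if t_max > eval_times.max() * (1 + 1e-12):
        raise DataValidationError("t_max beyond the evaluated grid")
    inside = eval_times < t_max
    ts = np.concatenate([[0.0], eval_times[inside & (eval_times > 0)], [t_max]])
    vals = np.interp(ts, eval_times, bs)
    return float(np.trapezoid(vals, ts) / t_max)


def binary_metrics_at(
    score, time, status, horizon, cutoff="median"
) -> dict[str, float]:
    """TPR / TNR / AUC of the score for event-by-horizon classification.

    Cases are subjects with an observed event at or before the horizon;
    controls are subjects still under observation past it. Subjects censored
    before the horizon have unknown status and are excluded. TPR and TNR use
    ``cutoff`` ("median" = median of the score over the evaluated cohort, or
    a numeric value); the AUC is the rank statistic of the score for the same
    case/control definition.
    """
    score = np.asarray(score, float)
    time = np.asarray(time, float)
    status = np.asarray(status)
    case = (time <= horizon) & (status == 1)
    control = time > horizon
    included = case | control
    if not case.any() or not control.any():
        raise DegenerateOutcomeError("need at least one case and one control")
    c = float(np.median(score[included])) if cutoff == "median" else float(cutoff)
    tpr = float(np.mean(score[case] > c))
    tnr = float(np.mean(score[control] <= c))
    auc = float(roc_auc_score(case[included].astype(int), score[included]))
    return {
        "tpr": tpr,
        "tnr": tnr,
        "auc": auc,
        "cutoff": c,
        "n_cases": int(case.sum()),
        "n_controls": int(control.sum()),
    }


def ipcw_auc_at(score, time, status, horizon) -> float:
    """Time-dependent (IPCW) AUC at the horizon — sensitivity variant."""
    from sksurv.metrics import cumulative_dynamic_auc

    y = np.array(
        [(bool(s), t) for s, t in zip(status, time)],
        dtype=[("event", bool), ("time", float)],
    )
    auc, _ = cumulative_dynamic_auc(y, y, np.asarray(score, float), [horizon])
    return float(auc[0])


# ---------------------------------------------------------------------------
# calibration


def calibration_slope(score, time, status) -> float:
    """Cox coefficient of the score entered as the sole covariate.

    Exactly 1 when the score is the linear predictor of an unpenalized Cox
    model evaluated on its own training data; deviations on validation data
    measure mis-calibration of the effect scale.
    """
    score = np.asarray(score, float)
    if np.ptp(score) == 0:
        raise DataValidationError("calibration slope undefined for a constant score")
    from lifelines import CoxPHFitter

    df = pd.DataFrame({"score": score, "time": time, "status": status})
    cph = CoxPHFitter()
    # tight Newton precision: the training-data identity holds to ~1e-8
    cph.fit(df, duration_col="time", event_col="status",
            fit_options={"precision": 1e-10})
    return float(cph.params_["score"])


def optimism(slope_train: float, slope_validation: float) -> float:
    """Difference of calibration slopes, training minus validation."""
    return float(slope_train) - float(slope_validation)


# ---------------------------------------------------------------------------
# risk stratification


@dataclass(frozen=True)
class RiskGroups:
    """Three risk groups defined by two score cutpoints (higher score =
    higher risk)."""

    cutpoints: tuple[float, float]
    labels: np.ndarray  # labels on the data that defined the cutpoints
    chi2: float

    def __post_init__(self):
        c1, c2 = self.cutpoints
        if not c1 < c2:
            raise DataValidationError("cutpoints must satisfy c1 < c2")
        for g in (LOW, INTERMEDIATE, HIGH):
            if not (np.asarray(self.labels) == g).any():
                raise DataValidationError(f"risk group {g!r} is empty")

    def assign(self, scores) -> np.ndarray:
        scores = np.asarray(scores, float)
        c1, c2 = self.cutpoints
        return np.where(scores < c1, LOW, np.where(scores < c2, INTERMEDIATE, HIGH))

    def sizes(self) -> dict[str, int]:
        lab = np.asarray(self.labels)
        return {g: int((lab == g).sum()) for g in (LOW, INTERMEDIATE, HIGH)}


def multigroup_logrank_chi2(labels, time, status) -> float:
    """k-group logrank chi-square statistic (k - 1 degrees of freedom)."""
    labels = np.asarray(labels)
    time = np.asarray(time, float)
    status = np.asarray(status)
    groups = pd.unique(labels)
    k = len(groups)
    onehot = np.stack([(labels == g).astype(float) for g in groups], axis=1)
    utimes = np.unique(time[status == 1])
    O = np.array([status[labels == g].sum() for g in groups], dtype=float)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in utimes:
        at_risk = time >= t
        n_t = at_risk.sum()
        d_t = ((time == t) & (status == 1)).sum()
        n_g = onehot[at_risk].sum(axis=0)
        E += d_t * n_g / n_t
        if n_t > 1:
            u = d_t * (n_t - d_t) / (n_t - 1)
            V += u * (np.diag(n_g / n_t) - np.outer(n_g, n_g) / n_t**2)
    v = (O - E)[: k - 1]
    Vs = V[: k - 1, : k - 1]
    try:
        return float(v @ np.linalg.solve(Vs, v))
    except np.linalg.LinAlgError:
        return 0.0


def logrank_cutpoints(score, time, status, min_group_frac: float = 0.1) -> RiskGroups:
    """Exhaustive maximal three-group logrank stratification.

    Candidate cutpoints are midpoints between consecutive distinct score
    values; every ordered pair whose three groups each hold at least
    ``min_group_frac`` of the samples is evaluated and the pair with the
    largest logrank chi-square wins. Ties break toward the most balanced
    group sizes, then the smaller first cutpoint.
    """
    score = np.asarray(score, float)
    time = np.asarray(time, float)
    status = np.asarray(status)
    n = len(score)
    min_size = max(1, int(np.ceil(min_group_frac * n)))
    if n < 3 * min_size:
        raise DataValidationError("too few samples for three risk groups")

    perm = np.argsort(score, kind="stable")
    ssc, st, ss = score[perm], time[perm], status[perm]
    # candidate split ranks: between distinct consecutive scores
    splits = np.flatnonzero(ssc[1:] != ssc[:-1]) + 1  # group = ranks [0, r)
    splits = splits[(splits >= min_size) & (splits <= n - min_size)]
    if len(splits) < 2:
        raise DataValidationError("no admissible cutpoint pair")

    utimes = np.unique(st[ss == 1])
    K = len(utimes)
    at_risk = st[None, :] >= utimes[:, None]  # (K, n) in score order
    C = np.concatenate(
        [np.zeros((K, 1)), np.cumsum(at_risk.astype(float), axis=1)], axis=1
    )  # C[k, r] = at-risk count among r lowest scores
    n_k = C[:, -1]
    d_k = np.array([((st == t) & (ss == 1)).sum() for t in utimes], dtype=float)
    oc = np.concatenate([[0.0], np.cumsum(ss.astype(float))])  # events among r lowest
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(n_k > 1, d_k * (n_k - d_k) / (n_k - 1), 0.0)
    w1 = u / n_k
    w2 = u / n_k**2
    e = (d_k / n_k) @ C  # expected events among r lowest
    A1 = w1 @ C
    B = w2 @ (C**2)
    O_tot = ss.sum()

    best = None  # (chi2, -balance, -c1rank, i, j)
    for a, i in enumerate(splits[:-1]):
        js = splits[a + 1 :]
        js = js[(js - i >= min_size)]
        if len(js) == 0:
            continue
        D = (w2 * C[:, i]) @ C[:, js]  # sum_k w2 C_k(i) C_k(j)
        O1 = oc[i]
        O2 = oc[js] - O1
        v1 = O1 - e[i]
        v2 = O2 - (e[js] - e[i])
        V11 = A1[i] - B[i]
        V22 = (A1[js] - A1[i]) - (B[js] + B[i] - 2 * D)
        V12 = -(D - B[i])
        det = V11 * V22 - V12**2
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(
                det > 1e-12, (v1**2 * V22 - 2 * v1 * v2 * V12 + v2**2 * V11) / det, 0.0
            )
        for b, j in enumerate(js):
            sizes = np.array([i, j - i, n - j], dtype=float)
            balance = float(((sizes - n / 3.0) ** 2).sum())
            key = (float(chi2[b]), -balance, -float(i))
            if best is None or key > best[0]:
                best = (key, int(i), int(j))
    if best is None:
        raise DataValidationError("no admissible cutpoint pair")
    _, i, j = best
    c1 = float((ssc[i - 1] + ssc[i]) / 2.0)
    c2 = float((ssc[j - 1] + ssc[j]) / 2.0)
    groups = RiskGroups(
        cutpoints=(c1, c2),
        labels=np.where(score < c1, LOW, np.where(score < c2, INTERMEDIATE, HIGH)),
        chi2=best[0][0],
    )
    assert groups.sizes() == {LOW: i, INTERMEDIATE: j - i, HIGH: n - j}
    return groups


def group_hazard_ratios(groups, time, status) -> dict:
    """Cox model on low/high indicators vs the intermediate baseline.

    Returns hazard ratios with Wald 95% CIs for the low and high groups and
    the likelihood-ratio p-value of the two-indicator model against the null.
    """
    labels = np.asarray(groups.labels if isinstance(groups, RiskGroups) else groups)
    time = np.asarray(time, float)
    status = np.asarray(status)
    for g in (LOW, INTERMEDIATE, HIGH):
        sel = labels == g
        if not sel.any() or status[sel].sum() == 0:
            raise DegenerateOutcomeError(f"risk group {g!r} has no events")
    from lifelines import CoxPHFitter

    df = pd.DataFrame(
        {
            "low": (labels == LOW).astype(float),
            "high": (labels == HIGH).astype(float),
            "time": time,
            "status": status,
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="status")
    ci = np.exp(cph.confidence_intervals_)
    lr = cph.log_likelihood_ratio_test()
    return {
        "hr_low": float(np.exp(cph.params_["low"])),
        "hr_low_ci": (float(ci.loc["low"].iloc[0]), float(ci.loc["low"].iloc[1])),
        "hr_high": float(np.exp(cph.params_["high"])),
        "hr_high_ci": (float(ci.loc["high"].iloc[0]), float(ci.loc["high"].iloc[1])),
        "lr_pvalue": float(lr.p_value),
    }


# ---------------------------------------------------------------------------
# report assembly


@dataclass(frozen=True)
class ValidationReport:
    """The external-validation metric bundle for one model."""

    tpr: float
    tnr: float
    auc: float
    c_uno: float
    ibs_horizon: float
    ibs_full: float
    horizon: float
    t_last_event: float
    slope_train: float
    slope_validation: float
    optimism: float
    hr_low: float
    hr_low_ci: tuple[float, float]
    hr_high: float
    hr_high_ci: tuple[float, float]
    lr_pvalue: float
    cutpoints: tuple[float, float]
    group_sizes: dict

    def check(self) -> None:
        """Raise if any field violates its type invariant."""
        for name in ("tpr", "tnr", "auc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataValidationError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.c_uno <= 1.0:
            raise DataValidationError(f"c_uno={self.c_uno} outside [0, 1]")
        if self.ibs_horizon < 0 or self.ibs_full < 0:
            raise DataValidationError("integrated Brier scores must be >= 0")
        if not self.hr_low_ci[0] <= self.hr_low <= self.hr_low_ci[1]:
            raise DataValidationError("low-risk CI does not contain its estimate")
        if not self.hr_high_ci[0] <= self.hr_high <= self.hr_high_ci[1]:
            raise DataValidationError("high-risk CI does not contain its estimate")
        if not 0.0 <= self.lr_pvalue <= 1.0:
            raise DataValidationError("LR p-value outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("TPR", self.tpr),
            ("TNR", self.tnr),
            ("AUC", self.auc),
            ("C_Uno", self.c_uno),
            (f"IBS_{self.horizon:g}", self.ibs_horizon),
            (f"IBS_{self.t_last_event:.3g}", self.ibs_full),
            ("Optimism", self.optimism),
            ("CI_L_lower", self.hr_low_ci[0]),
            ("HR_L", self.hr_low),
            ("CI_L_upper", self.hr_low_ci[1]),
            ("CI_H_lower", self.hr_high_ci[0]),
            ("HR_H", self.hr_high),
            ("CI_H_upper", self.hr_high_ci[1]),
            ("p_value_LR", self.lr_pvalue),
        ]
        return pd.DataFrame(rows, columns=["measure", "value"])


def external_validation(
    model,
    train_dataset,
    val_dataset,
    horizon: float = 2.0,
    min_group_frac: float = 0.1,
):
    """Full validation of a fitted survival model on an independent cohort.

    Cutpoints, the baseline hazard and the calibration reference come from
    the training data; every accuracy measure is computed on the validation
    data. Returns ``(ValidationReport, extras)`` where ``extras`` carries the
    long-format prediction-error-curve and per-group observed/predicted
    Kaplan-Meier tables.
    """
    from lifelines import KaplanMeierFitter

    from .predict import breslow_baseline, linear_score, predict_survival

    if train_dataset.outcome.family != "survival":
        raise DataValidationError("external validation requires a survival outcome")
    sc_tr, _ = linear_score(model, train_dataset.X)
    sc_va, _ = linear_score(model, val_dataset.X)
    t_tr, s_tr = train_dataset.outcome.time, train_dataset.outcome.status
    t_va, s_va = val_dataset.outcome.time, val_dataset.outcome.status
    t_last = float(t_va[s_va == 1].max())

    c_uno = uno_c(sc_va, t_va, s_va, tau=t_last)
    base = breslow_baseline(t_tr, s_tr, sc_tr)
    grid = np.unique(np.concatenate([[0.0, horizon, t_last], t_va[s_va == 1]]))
    grid = grid[grid <= t_last]
    curves = predict_survival(base, sc_va, grid)
    bs = brier_curve(curves, t_va, s_va, grid)
    ibs_h = integrated_brier(grid, bs, min(horizon, t_last))
    ibs_full = integrated_brier(grid, bs, t_last)

    slope_tr = calibration_slope(sc_tr, t_tr, s_tr)
    slope_va = calibration_slope(sc_va, t_va, s_va)

    groups_tr = logrank_cutpoints(sc_tr, t_tr, s_tr, min_group_frac=min_group_frac)
    lab_va = groups_tr.assign(sc_va)
    hrs = group_hazard_ratios(lab_va, t_va, s_va)
    bm = binary_metrics_at(sc_va, t_va, s_va, horizon)

    report = ValidationReport(
        tpr=bm["tpr"],
        tnr=bm["tnr"],
        auc=bm["auc"],
        c_uno=c_uno,
        ibs_horizon=ibs_h,
        ibs_full=ibs_full,
        horizon=horizon,
        t_last_event=t_last,
        slope_train=slope_tr,
        slope_validation=slope_va,
        optimism=optimism(slope_tr, slope_va),
        hr_low=hrs["hr_low"],
        hr_low_ci=hrs["hr_low_ci"],
        hr_high=hrs["hr_high"],
        hr_high_ci=hrs["hr_high_ci"],
        lr_pvalue=hrs["lr_pvalue"],
        cutpoints=groups_tr.cutpoints,
        group_sizes={g: int((lab_va == g).sum()) for g in (LOW, INTERMEDIATE, HIGH)},
    )
    report.check()

    pec = pd.DataFrame({"time": grid, "brier": bs})
    km_rows = []
    for g in (LOW, INTERMEDIATE, HIGH):
        sel = lab_va == g
        if sel.any():
            km = KaplanMeierFitter().fit(t_va[sel], s_va[sel])
            obs = km.survival_function_at_times(grid).to_numpy()
            pred = curves[sel].mean(axis=0)
            for t, o, p in zip(grid, obs, pred):
                km_rows.append((g, float(t), float(o), float(p)))
    km_table = pd.DataFrame(km_rows, columns=["group", "time", "observed", "predicted"])
    extras = {
        "prediction_error_curve": pec,
        "km_by_group": km_table,
        "risk_groups_train": groups_tr,
        "scores_train": sc_tr,
        "scores_validation": sc_va,
    }
    return report, extras


def report_to_dict(report: ValidationReport) -> dict:
    d = dataclasses.asdict(report)
    d["hr_low_ci"] = list(d["hr_low_ci"])
    d["hr_high_ci"] = list(d["hr_high_ci"])
    d["cutpoints"] = list(d["cutpoints"])
    return d
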