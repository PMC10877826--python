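"""Cross-validated training and survival evaluation statistics.

Implements the threefold 1:1:1 cross-validation protocol (train /
validation / test roles rotate so every case receives exactly one
out-of-fold risk score), minibatch training of the MIL survival model,
and the evaluation stack: Harrell's C-index, Kaplan-Meier
dichotomization with log-rank test and hazard ratio, a cut-off
percentile sweep, integrated time-dependent AUC with case-level
bootstrap, and the continuous net reclassification improvement (NRI).

Ordinary survival-model fits (KM curves, log-rank, Cox hazard ratios)
are thin wrappers over lifelines; the time-dependent AUC uses
scikit-survival's IPCW cumulative/dynamic estimator.  The C-index and
NRI are computed here directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import FeatureBag, FeatureStore
from .model import (
    Adam,
    MILConfig,
    MILSurvivalModel,
    SurvivalLabel,
    make_time_grid,
)

__all__ = [
    "CaseRecord",
    "CVPlan",
    "TrainConfig",
    "ExperimentConfig",
    "EvalReport",
    "ExperimentResult",
    "make_cv_plan",
    "train",
    "harrell_cindex",
    "dichotomize_km",
    "cutoff_sweep",
    "iauc_bootstrap",
    "continuous_nri",
    "run_experiment",
    "records_to_frame",
]


# ---------------------------------------------------------------------------
# case manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CaseRecord:
    """One patient: slides, clinical covariates and survival labels."""

    case_id: str
    slide_ids: Tuple[str, ...] = ()
    age: float = 60.0
    sex: str = "female"  # "female" / "male"
    os_time: float = 1.0  # months
    os_event: int = 0
    dfs_time: Optional[float] = None
    dfs_event: Optional[int] = None

    def __post_init__(self) -> None:
        if self.os_time <= 0:
            raise ValueError("os_time must be positive")
        if self.os_event not in (0, 1):
            raise ValueError("os_event must be 0/1")


def records_to_frame(records: Sequence[CaseRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(case_id=r.case_id, age=r.age, sex=r.sex,
                 os_time=r.os_time, os_event=r.os_event,
                 dfs_time=r.dfs_time, dfs_event=r.dfs_event)
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# cross-validation plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVPlan:
    """Random 1:1:1 fold assignment; roles rotate across repeats."""

    n_folds: int
    assignments: Dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> List[str]:
        return [cid for cid, f in self.assignments.items() if f == fold]

    def roles(self, repeat_index: int) -> Tuple[int, int, int]:
        """(test, validation, training) fold for the given repeat."""
        r = repeat_index % self.n_folds
        return r, (r + 1) % self.n_folds, (r + 2) % self.n_folds


def make_cv_plan(cases: Sequence, seed: int = 0, n_folds: int = 3) -> CVPlan:
    """Random partition into ``n_folds`` folds with sizes differing by <= 1,
    deterministic for a given seed."""
    ids = [c.case_id if isinstance(c, CaseRecord) else str(c) for c in cases]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case ids")
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} cases, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignments = {ids[j]: int(i % n_folds) for i, j in enumerate(order)}
    return CVPlan(n_folds=n_folds, assignments=assignments, seed=int(seed))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (batch size is one case: bags vary in size).

    ``weight_decay`` is decoupled (AdamW-style) and deliberately strong:
    with hundreds of cases against 1024-d embeddings the head can
    memorise per-case noise, and the effective per-step shrinkage
    ``lr * weight_decay`` must be of order 1e-2 to hold the fit near the
    ridge solution.  Interpretation-oriented runs that train on the full
    cohort may lower it so the attention module keeps capacity.
    """

    lr: float = 2e-4
    weight_decay: float = 64.0
    max_epochs: int = 50
    patience: int = 10
    event_weight: float = 1.0
    seed: int = 0


def _labels_for(records: Sequence[CaseRecord], grid) -> Dict[str, SurvivalLabel]:
    return {
        r.case_id: SurvivalLabel.from_grid(r.os_time, r.os_event, grid)
        for r in records
    }


def _clinical_of(model: MILSurvivalModel, rec: CaseRecord):
    if not model.config.use_clinical:
        return None
    return model.encode_clinical(rec.sex, rec.age)


def _mean_loss(model: MILSurvivalModel, ids, bags, labels, clin) -> float:
    total = 0.0
    for cid in ids:
        loss, _, _ = model.loss_and_grads(bags[cid], clin[cid], labels[cid],
                                          train=False)
        total += loss
    return total / len(ids)


def train(model_config: MILConfig,
          bags: Mapping[str, Mapping[str, FeatureBag]],
          records: Sequence[CaseRecord],
          plan: CVPlan,
          repeat_index: int,
          train_config: Optional[TrainConfig] = None,
          ) -> Tuple[MILSurvivalModel, pd.DataFrame]:
    """Train one fold rotation; returns the fitted model and a per-epoch
    history (train/validation loss).

    The time grid (event-time quantiles) and the age z-score parameters
    are estimated on the training fold only.  Early stopping monitors
    validation loss; the best parameters are restored.  Fully
    deterministic for a given seed.
    """
    tc = train_config or TrainConfig()
    _, val_fold, train_fold = plan.roles(repeat_index)
    by_id = {r.case_id: r for r in records}
    train_ids = [cid for cid in plan.fold_ids(train_fold) if cid in by_id]
    val_ids = [cid for cid in plan.fold_ids(val_fold) if cid in by_id]
    if not train_ids:
        raise ValueError("training fold is empty")
    for cid in train_ids:
        missing = [s for s in model_config.scales if s not in bags.get(cid, {})]
        if missing:
            raise ValueError(f"case {cid!r} lacks bags for scales {missing}")

    tr_recs = [by_id[c] for c in train_ids]
    grid = make_time_grid([r.os_time for r in tr_recs],
                          [r.os_event for r in tr_recs], n=model_config.n_bins)

    eff_seed = (int(tc.seed) * 100003 + repeat_index * 7919
                + model_config.seed) % (2 ** 31)
    model = MILSurvivalModel(replace(model_config, seed=eff_seed), time_grid=grid)
    ages = np.array([r.age for r in tr_recs], dtype=float)
    model.set_age_norm(ages.mean(), ages.std() if ages.std() > 0 else 1.0)
    centers = {}
    for s in model_config.scales:
        feats = [np.asarray(bags[cid][s].features, dtype=float)
                 for cid in train_ids]
        allf = np.vstack(feats)
        centers[s] = allf.mean(axis=0)
    model.set_feature_center(centers)

    labels = _labels_for(records, grid)
    clin = {r.case_id: _clinical_of(model, r) for r in records}

    opt = Adam(model.params, lr=tc.lr, weight_decay=tc.weight_decay)
    rng = np.random.default_rng(eff_seed + 1)
    best_val = np.inf
    best_params = model.copy_params()
    best_epoch = -1
    history = []
    since_best = 0
    for epoch in range(tc.max_epochs):
        order = rng.permutation(len(train_ids))
        ep_loss = 0.0
        for j in order:
            cid = train_ids[j]
            loss, grads, _ = model.loss_and_grads(
                bags[cid], clin[cid], labels[cid], rng=rng, train=True,
                event_weight=tc.event_weight)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, case {cid!r} "
                    f"(lr={tc.lr}); aborting")
            opt.step(model.params, grads)
            ep_loss += loss
        ep_loss /= len(train_ids)
        val_loss = (_mean_loss(model, val_ids, bags, labels, clin)
                    if val_ids else ep_loss)
        history.append(dict(epoch=epoch, train_loss=ep_loss, val_loss=val_loss))
        if val_loss < best_val - 1e-9:
            best_val, best_epoch = val_loss, epoch
            best_params = model.copy_params()
            since_best = 0
        else:
            since_best += 1
            if since_best >= tc.patience:
                break
    model.set_params(best_params)
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    return model, hist


# ---------------------------------------------------------------------------
# Harrell's concordance index
# ---------------------------------------------------------------------------

def harrell_cindex(scores, times, events) -> float:
    """Harrell's C-index for a risk score (higher score = shorter survival).

    Permissible pairs: ``i`` experienced the event and ``t_i < t_j``, or
    ``t_i == t_j`` with ``i`` an event and ``j`` censored.  A pair is
    concordant when the earlier event carries the higher score; score
    ties count 0.5.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if not (s.shape == t.shape == e.shape):
        raise ValueError("scores/times/events length mismatch")
    ti, tj = t[:, None], t[None, :]
    ei, ej = e[:, None], e[None, :]
    perm = (ei & (ti < tj)) | (ei & ~ej & (ti == tj))
    np.fill_diagonal(perm, False)
    n_perm = perm.sum()
    if n_perm == 0:
        raise ValueError("no permissible pairs (all censored or identical)")
    si, sj = s[:, None], s[None, :]
    num = (perm & (si > sj)).sum() + 0.5 * (perm & (si == sj)).sum()
    return float(num / n_perm)


# ---------------------------------------------------------------------------
# KM dichotomization, hazard ratios, cut-off sweep
# ---------------------------------------------------------------------------

@dataclass
class KMResult:
    high: np.ndarray          # boolean group membership (score > cutoff)
    cutoff: float
    km_low: object            # fitted lifelines KaplanMeierFitter
    km_high: object
    logrank_p: float
    hr: float
    hr_ci: Tuple[float, float]


def _cox_hr(times, events, covariate, name="x") -> Tuple[float, Tuple[float, float]]:
    from lifelines import CoxPHFitter

    df = pd.DataFrame({"t": times, "e": events, name: covariate})
    for pen in (0.0, 0.1):
        try:
            cph = CoxPHFitter(penalizer=pen)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="t", event_col="e")
            coef = float(cph.params_[name])
            se = float(cph.standard_errors_[name])
            return np.exp(coef), (np.exp(coef - 1.96 * se), np.exp(coef + 1.96 * se))
        except Exception:
            continue
    return np.nan, (np.nan, np.nan)


def dichotomize_km(scores, times, events,
                   cutoff_percentile: float = 50.0) -> KMResult:
    """Split cases at a score percentile and compare survival.

    High-risk group: ``score > percentile cutoff``.  Returns per-group
    Kaplan-Meier fits, the two-sided log-rank p-value and the univariate
    hazard ratio (high vs low) from a proportional-hazards fit.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    cutoff = float(np.percentile(s, cutoff_percentile))
    high = s > cutoff
    if high.all() or not high.any():
        raise ValueError(
            f"cutoff percentile {cutoff_percentile} leaves an empty group; "
            "choose a different cutoff")
    km_low, km_high = KaplanMeierFitter(), KaplanMeierFitter()
    km_low.fit(t[~high], e[~high], label="low")
    km_high.fit(t[high], e[high], label="high")
    lr = logrank_test(t[high], t[~high], e[high], e[~high])
    hr, ci = _cox_hr(t, e, high.astype(float), name="high")
    return KMResult(high=high, cutoff=cutoff, km_low=km_low, km_high=km_high,
                    logrank_p=float(lr.p_value), hr=hr, hr_ci=ci)


def cutoff_sweep(scores, times, events,
                 percentiles: Sequence[float] = tuple(range(5, 100, 5)),
                 dfs_times=None, dfs_events=None) -> pd.DataFrame:
    """HR and log-rank p across a series of dichotomization percentiles.

    Cut-offs leaving an empty group are flagged, not fatal.  Optional
    disease-free survival labels add an ``hr_dfs`` column.
    """
    rows = []
    for pct in percentiles:
        row = dict(percentile=float(pct), hr_os=np.nan, logrank_p=np.nan,
                   hr_dfs=np.nan, flagged=False)
        try:
            km = dichotomize_km(scores, times, events, cutoff_percentile=pct)
            row.update(hr_os=km.hr, logrank_p=km.logrank_p)
            if dfs_times is not None and dfs_events is not None:
                row["hr_dfs"] = _cox_hr(dfs_times, dfs_events,
                                        km.high.astype(float))[0]
        except ValueError:
            row["flagged"] = True
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# integrated time-dependent AUC
# ---------------------------------------------------------------------------

def _default_horizons(times, events) -> np.ndarray:
    ev = np.asarray(times, float)[np.asarray(events, bool)]
    lo, hi = np.quantile(ev, [0.10, 0.90])
    grid = np.linspace(lo, hi, 9)
    tmax = np.asarray(times, float).max()
    return np.unique(grid[grid < tmax])


def iauc_bootstrap(scores, times, events, horizon_grid=None,
                   n_boot: int = 1000, seed: int = 0,
                   ) -> Tuple[float, Optional[Tuple[float, float]]]:
    """Integrated cumulative/dynamic time-dependent AUC.

    The AUC(t) curve (IPCW estimator) is integrated with weights from
    the estimated event distribution — scikit-survival's mean AUC — over
    a horizon grid defaulting to the 10th-90th percentile range of the
    observed event times.  The 95% CI is a percentile bootstrap over
    case-level resamples (``n_boot = 0`` skips it).  Deterministic for a
    given seed.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if not e.any():
        raise ValueError("no events in cohort")
    if horizon_grid is None:
        horizon_grid = _default_horizons(t, e)
    horizon_grid = np.asarray(horizon_grid, dtype=float)

    def _iauc(idx) -> float:
        ti, ei, si = t[idx], e[idx], s[idx]
        y = Surv.from_arrays(event=ei, time=ti)
        hg = horizon_grid[(horizon_grid >= ti.min()) & (horizon_grid < ti.max())]
        if hg.size == 0 or not ei.any():
            raise ValueError("degenerate resample")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, mean_auc = cumulative_dynamic_auc(y, y, si, hg)
        return float(mean_auc)

    point = _iauc(np.arange(t.size))
    if n_boot <= 0:
        return point, None
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, t.size, size=t.size)
        try:
            reps.append(_iauc(idx))
        except Exception:
            continue
    if not reps:
        return point, None
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return point, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# continuous net reclassification improvement
# ---------------------------------------------------------------------------

def continuous_nri(pred_base, pred_combined, outcome,
                   n_boot: int = 0, seed: int = 0,
                   ) -> Tuple[float, Optional[Tuple[float, float]]]:
    """Continuous NRI of a combined risk model over a base model.

    ``NRI = [P(up|event) - P(down|event)] + [P(down|nonevent) -
    P(up|nonevent)]`` where up/down is the sign of
    ``pred_combined - pred_base`` (zero changes count neither way).
    Antisymmetric under swapping the models; bounded in [-2, 2].
    """
    pb = np.asarray(pred_base, dtype=float)
    pc = np.asarray(pred_combined, dtype=float)
    y = np.asarray(outcome, dtype=bool)
    if pb.shape != pc.shape or pb.shape != y.shape:
        raise ValueError("predictions/outcome length mismatch")
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")

    def _nri(idx) -> float:
        up = pc[idx] > pb[idx]
        down = pc[idx] < pb[idx]
        ev, ne = y[idx], ~y[idx]
        if not ev.any() or not ne.any():
            raise ValueError("single-class resample")
        return float((up[ev].mean() - down[ev].mean())
                     + (down[ne].mean() - up[ne].mean()))

    point = _nri(np.arange(y.size))
    if n_boot <= 0:
        return point, None
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, y.size, size=y.size)
        try:
            reps.append(_nri(idx))
        except ValueError:
            continue
    if not reps:
        return point, None
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return point, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    model: MILConfig = field(default_factory=MILConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_boot: int = 1000          # bootstrap resamples for CIs
    nri_horizon: Optional[float] = None  # months; default: median event time
    compute_iauc: bool = True
    compute_nri: bool = True
    compute_sweep: bool = True
    seed: int = 0


@dataclass
class EvalReport:
    c_index: float
    c_index_ci: Optional[Tuple[float, float]]
    iauc: Optional[float]
    iauc_ci: Optional[Tuple[float, float]]
    nri: Optional[float]
    nri_ci: Optional[Tuple[float, float]]
    logrank_p: float
    hr: float
    km: KMResult
    cutoff_table: pd.DataFrame


@dataclass
class ExperimentResult:
    dps: pd.DataFrame                      # one row per case (out-of-fold)
    report: EvalReport
    attention: Dict[str, Dict[str, np.ndarray]]  # case -> scale -> weights
    plan: CVPlan
    models: List[MILSurvivalModel]
    histories: List[pd.DataFrame]
    config: ExperimentConfig


def _bootstrap_cindex(scores, times, events, n_boot, seed):
    if n_boot <= 0:
        return None
    rng = np.random.default_rng(seed)
    reps = []
    n = len(scores)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            reps.append(harrell_cindex(scores[idx], times[idx], events[idx]))
        except ValueError:
            continue
    if not reps:
        return None
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return (float(lo), float(hi))


def _cox_linear_predictor(df: pd.DataFrame, covariates: List[str]):
    from lifelines import CoxPHFitter

    cph = CoxPHFitter(penalizer=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[["t", "e"] + covariates], duration_col="t", event_col="e")
    return cph.predict_partial_hazard(df).to_numpy()


def _nri_over_clinical(table: pd.DataFrame, horizon: float, n_boot: int,
                       seed: int):
    """NRI of (clinical + DPS) over clinical-only for mortality by `horizon`.

    Cases censored before the horizon are excluded (their status is
    unknown)."""
    known = (table.os_time.to_numpy() >= horizon) | (table.os_event.to_numpy() == 1)
    sub = table[known].copy()
    outcome = (sub.os_time.to_numpy() <= horizon) & (sub.os_event.to_numpy() == 1)
    if outcome.all() or not outcome.any() or len(sub) < 10:
        return None, None
    df = pd.DataFrame({
        "t": sub.os_time.to_numpy(), "e": sub.os_event.to_numpy(),
        "age": sub.age.to_numpy(),
        "sex": (sub.sex == "female").astype(float).to_numpy(),
        "dps": sub.dps.to_numpy(),
    })
    try:
        base = _cox_linear_predictor(df, ["age", "sex"])
        comb = _cox_linear_predictor(df, ["age", "sex", "dps"])
    except Exception:
        return None, None
    return continuous_nri(base, comb, outcome, n_boot=n_boot, seed=seed)


def run_experiment(records: Sequence[CaseRecord],
                   bags, config: Optional[ExperimentConfig] = None,
                   ) -> ExperimentResult:
    """Threefold rotated cross-validation and pooled out-of-fold evaluation.

    ``bags`` is either ``{case_id: {scale: FeatureBag}}`` or a
    :class:`FeatureStore`.  Cases with missing features are excluded
    with a warning.  Every remaining case receives exactly one
    out-of-fold DPS; the evaluation report is computed on the pooled
    scores.  Deterministic for a given config seed.
    """
    config = config or ExperimentConfig()
    scales = config.model.scales
    if isinstance(bags, FeatureStore):
        store = bags
        bags = {}
        for cid in store.cases():
            try:
                bags[cid] = {s: store.load_bag(cid, s) for s in scales}
            except KeyError:
                continue
    usable, dropped = [], []
    for r in records:
        if all(s in bags.get(r.case_id, {}) for s in scales):
            usable.append(r)
        else:
            dropped.append(r.case_id)
    if dropped:
        warnings.warn(f"excluding {len(dropped)} cases with missing features: "
                      f"{dropped[:5]}...", stacklevel=2)
    if len(usable) < 3:
        raise ValueError("need at least 3 usable cases")

    tc = replace(config.train, seed=config.train.seed + config.seed)
    plan = make_cv_plan(usable, seed=config.seed)
    by_id = {r.case_id: r for r in usable}
    rows = []
    attention: Dict[str, Dict[str, np.ndarray]] = {}
    models, histories = [], []
    for repeat in range(plan.n_folds):
        model, hist = train(config.model, bags, usable, plan, repeat, tc)
        models.append(model)
        histories.append(hist)
        test_fold, _, _ = plan.roles(repeat)
        for cid in plan.fold_ids(test_fold):
            if cid not in by_id:
                continue
            rec = by_id[cid]
            clinical = (rec.sex, rec.age) if config.model.use_clinical else None
            risk, weights = model.infer_case(bags[cid], clinical)
            row = dict(case_id=cid, fold=test_fold, dps=risk.dps,
                       os_time=rec.os_time, os_event=rec.os_event,
                       age=rec.age, sex=rec.sex)
            for i, (pi, si) in enumerate(zip(risk.p, risk.S), start=1):
                row[f"p_{i}"] = pi
                row[f"S_{i}"] = si
            rows.append(row)
            attention[cid] = {s: w.a for s, w in weights.items()}
    table = pd.DataFrame(rows).sort_values("case_id").reset_index(drop=True)
    assert len(table) == len(usable), "out-of-fold coverage must be exactly 1"
    table.attrs["seed"] = config.seed
    table.attrs["config_hash"] = config.model.config_hash()

    scores = table.dps.to_numpy()
    times = table.os_time.to_numpy()
    events = table.os_event.to_numpy()
    c = harrell_cindex(scores, times, events)
    c_ci = _bootstrap_cindex(scores, times, events, config.n_boot,
                             seed=config.seed + 11)
    km = dichotomize_km(scores, times, events, cutoff_percentile=50)
    sweep = (cutoff_sweep(scores, times, events) if config.compute_sweep
             else pd.DataFrame())
    iauc = iauc_ci = None
    if config.compute_iauc:
        iauc, iauc_ci = iauc_bootstrap(scores, times, events,
                                       n_boot=config.n_boot,
                                       seed=config.seed + 13)
    nri = nri_ci = None
    if config.compute_nri:
        horizon = config.nri_horizon
        if horizon is None:
            ev = times[events.astype(bool)]
            horizon = float(np.median(ev)) if ev.size else None
        if horizon is not None:
            nri, nri_ci = _nri_over_clinical(table, horizon, config.n_boot,
                                             seed=config.seed + 17)
    report = EvalReport(c_index=c, c_index_ci=c_ci, iauc=iauc, iauc_ci=iauc_ci,
                        nri=nri, nri_ci=nri_ci, logrank_p=km.logrank_p,
                        hr=km.hr, km=km, cutoff_table=sweep)
    return ExperimentResult(dps=table, report=report, attention=attention,
                            plan=plan, models=models, histories=histories,
                            config=config)
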