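"""Cox proportional-hazards signature modelling and evaluation.

The top-N ranked genes form the covariates X of a Cox PH model
``h(t|X) = h0(t) exp(beta'X)``. A new patient's risk score is the centred
linear predictor ``r_i = beta'(X_i - mean(X_train))``; discrimination is
measured by the concordance index over comparable censored pairs, and
clinical separation by the hazard ratio between the median-dichotomized
high- and low-risk groups, with Kaplan-Meier curves and a log-rank test.
Model fitting, KM estimation, and the log-rank test are delegated to
lifelines (Efron handling of tied event times); the concordance index and
risk scoring are computed directly to match the exact pairwise definition
used here (ties in score earn no credit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from sklearn.model_selection import StratifiedKFold

from .io_formats import ClinicalTable, ExpressionMatrix, ValidationError


@dataclass
class SurvivalDataset:
    """Bulk expression aligned with per-sample survival outcomes."""

    expression: ExpressionMatrix
    clinical: ClinicalTable

    def __post_init__(self) -> None:
        if list(self.expression.cell_ids) != list(self.clinical.sample_ids):
            if set(self.expression.cell_ids) != set(self.clinical.sample_ids):
                raise ValidationError("expression and clinical sample sets differ")
            pos = {s: i for i, s in enumerate(self.clinical.sample_ids)}
            order = np.asarray([pos[s] for s in self.expression.cell_ids])
            self.clinical = self.clinical.subset(order)

    @property
    def n_samples(self) -> int:
        return self.expression.n_cells

    def subset_samples(self, order) -> "SurvivalDataset":
        order = np.asarray(order)
        return SurvivalDataset(self.expression.subset_cells(order),
                               self.clinical.subset(order))


@dataclass
class CoxModel:
    """Fitted signature model: genes, log-hazard coefficients, training means."""

    genes: np.ndarray
    beta: np.ndarray
    train_means: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=str)
        self.beta = np.asarray(self.beta, dtype=float)
        self.train_means = np.asarray(self.train_means, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in Cox model")
        if not np.all(np.isfinite(self.beta)):
            raise ValidationError("non-finite Cox coefficients")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.beta, "train_mean": self.train_means},
                            index=pd.Index(self.genes, name="gene"))


def fit_cox(data: SurvivalDataset, genes, ridge: float = 0.0) -> CoxModel:
    """Fit the Cox PH model on the given genes by partial likelihood.

    Uses Efron's approximation for tied event times. ``ridge`` adds an
    optional L2 penalty for signatures approaching the event count (the
    default is the unpenalized fit).
    """
    genes = list(genes)
    if data.clinical.event.sum() == 0:
        raise ValidationError("no events in the training data; Cox model undefined")
    sub = data.expression.subset_genes(genes)
    df = pd.DataFrame(sub.values.T, columns=genes)
    df["time"] = data.clinical.time
    df["event"] = data.clinical.event
    cph = CoxPHFitter(penalizer=ridge, l1_ratio=0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise RuntimeError(
            "Cox model failed to converge (singular or separable design); "
            "consider the ridge penalty flag") from exc
    beta = cph.params_.reindex(genes).to_numpy()
    means = sub.values.mean(axis=1)
    return CoxModel(np.asarray(genes), beta, means)


def cox_standard_errors(data: SurvivalDataset, genes, ridge: float = 0.0) -> pd.Series:
    """Standard errors of the Cox coefficients (for coverage diagnostics)."""
    genes = list(genes)
    sub = data.expression.subset_genes(genes)
    df = pd.DataFrame(sub.values.T, columns=genes)
    df["time"] = data.clinical.time
    df["event"] = data.clinical.event
    cph = CoxPHFitter(penalizer=ridge, l1_ratio=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    return cph.standard_errors_.reindex(genes)


def risk_score(model: CoxModel, new_expression: ExpressionMatrix) -> pd.Series:
    """Centred linear predictor ``r_i = beta'(X_i - train_means)`` per sample."""
    for gene in model.genes:
        if gene not in new_expression.gene_ids:
            raise ValidationError(f"model gene {gene!r} missing from new data")
    sub = new_expression.subset_genes(model.genes)
    r = model.beta @ (sub.values - model.train_means[:, None])
    return pd.Series(r, index=new_expression.cell_ids, name="risk_score")


def c_index(times, events, scores) -> float:
    """Concordance index for right-censored data.

    Among ordered pairs, a pair is comparable when the earlier observed time
    carries an event; it is concordant when that earlier-failing patient also
    has the strictly higher risk score. Ties in time or score earn nothing.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    r = np.asarray(scores, dtype=float)
    if not len(t) == len(d) == len(r):
        raise ValidationError("times, events and scores must be aligned")
    ti, tj = t[:, None], t[None, :]
    ri, rj = r[:, None], r[None, :]
    di = d[:, None].astype(bool)
    comparable = (ti < tj) & di
    concordant = comparable & (ri > rj)
    denom = int(comparable.sum())
    if denom == 0:
        raise ValidationError("no comparable pairs; C-index undefined")
    return float(concordant.sum()) / denom


def stratify(scores) -> np.ndarray:
    """Median dichotomization: score > median -> ``"high"``, else ``"low"``."""
    s = np.asarray(scores, dtype=float)
    if len(s) < 2:
        raise ValidationError("need at least two samples to stratify")
    if np.all(s == s[0]):
        raise ValidationError("all risk scores identical; median split degenerate")
    med = float(np.median(s))
    return np.where(s > med, "high", "low")


def hazard_ratio(groups, clinical: ClinicalTable):
    """Hazard ratio between risk groups: exp(beta) of a univariate Cox fit.

    ``groups`` is an array of "high"/"low" labels; high is coded 1. Returns
    ``(hr, (ci_low, ci_high))`` with a Wald 95% interval.
    """
    groups = np.asarray(groups)
    high = (groups == "high").astype(int)
    if high.all() or not high.any():
        raise ValidationError("both risk groups must be non-empty")
    if clinical.event.sum() == 0:
        raise ValidationError("no events; hazard ratio undefined")
    for label in ("high", "low"):
        if clinical.event[groups == label].sum() == 0:
            warnings.warn(f"no events in the {label}-risk group; CI may be non-finite")
    df = pd.DataFrame({"group": high, "time": clinical.time, "event": clinical.event})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    return float(np.exp(beta)), (float(np.exp(beta - 1.96 * se)),
                                 float(np.exp(beta + 1.96 * se)))


def km_logrank(groups, clinical: ClinicalTable):
    """Kaplan-Meier curves per risk group and the two-sample log-rank p.

    Returns ``(curves, p)`` where ``curves`` maps group label to a DataFrame
    with columns time, survival, at_risk.
    """
    groups = np.asarray(groups)
    if clinical.event.sum() == 0:
        raise ValidationError("no events anywhere; log-rank test undefined")
    curves = {}
    for label in ("high", "low"):
        sel = groups == label
        if not sel.any():
            raise ValidationError(f"empty {label}-risk group")
        km = KaplanMeierFitter()
        km.fit(clinical.time[sel], clinical.event[sel])
        table = km.event_table
        curves[label] = pd.DataFrame({
            "time": km.survival_function_.index.to_numpy(),
            "survival": km.survival_function_.iloc[:, 0].to_numpy(),
            "at_risk": table["at_risk"].reindex(km.survival_function_.index).to_numpy(),
        })
    sel = groups == "high"
    res = logrank_test(clinical.time[sel], clinical.time[~sel],
                       clinical.event[sel], clinical.event[~sel])
    return curves, float(res.p_value)


@dataclass
class CVResult:
    """Repeated k-fold cross-validation summary."""

    mean_cindex: float
    mean_hr: float
    per_run: pd.DataFrame = field(repr=False, default=None)


def cross_validate(data: SurvivalDataset, genes, folds: int = 10,
                   runs: int = 5, seed: int = 0, ridge: float = 0.0) -> CVResult:
    """Repeated k-fold CV of the signature model.

    Per run: event-stratified random fold assignment; the model is fitted on
    k-1 folds and scores the held-out fold; held-out predictions are pooled
    within the run before computing that run's C-index and hazard ratio.
    A run whose fold assignment leaves some training fold without events is
    reshuffled (up to 10 seeded attempts). Reported values are means over
    runs (HR ignores runs where the group split degenerates).
    """
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    genes = list(genes)
    n = data.n_samples
    events = data.clinical.event
    rows = []
    ss = np.random.SeedSequence(seed)
    run_seeds = ss.generate_state(runs * 10)
    for run in range(runs):
        for attempt in range(10):
            rs = int(run_seeds[run * 10 + attempt] % (2 ** 31))
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                splits = list(skf.split(np.zeros(n), events))
            if all(events[tr].sum() > 0 for tr, _ in splits):
                break
        else:
            raise ValidationError("could not build folds with events in every training set")
        pooled = np.empty(n)
        for tr, te in splits:
            model = fit_cox(data.subset_samples(tr), genes, ridge=ridge)
            pooled[te] = risk_score(model, data.expression.subset_cells(te)).to_numpy()
        ci = c_index(data.clinical.time, events, pooled)
        try:
            hr, _ = hazard_ratio(stratify(pooled), data.clinical)
        except (ValidationError, RuntimeError):
            hr = np.nan
        rows.append({"run": run, "cindex": ci, "hr": hr})
    per_run = pd.DataFrame(rows)
    return CVResult(float(per_run["cindex"].mean()),
                    float(np.nanmean(per_run["hr"])), per_run)
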