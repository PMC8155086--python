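"""Statistical validation battery for cohort-level ALM analyses.

Four families of analysis, mirroring a standard discriminant-validity
workup of candidate clinical measures:

* group comparison — Kruskal-Wallis one-way ANOVA on ranks per measure,
  with the rank eta-squared effect size ``(H - k + 1) / (n - k)`` and
  Games-Howell pairwise post-hoc contrasts (Welch degrees of freedom,
  studentized-range p-values);
* convergent validity — Spearman rank correlations between measures and
  clinical scores, pairwise-complete;
* discriminant validity — binary logistic regressions of case status on
  each ordinal-recoded measure (entered as a 4-level categorical factor,
  joint Wald test with 3 df) adjusted for age and IQ, reporting -2 log
  likelihood, Nagelkerke pseudo-R^2 and in-sample accuracy, sensitivity
  and specificity at a 0.5 cutoff;
* ROC curves with AUC for the baseline (covariates-only), per-measure and
  combined models, all fitted on one identical listwise-complete
  subsample.

Model fitting is delegated to statsmodels; ROC construction to
scikit-learn.  The eta-squared formula, the Games-Howell machinery and
the Nagelkerke rescaling are implemented here.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

from .measures import ALM_NAMES

__all__ = [
    "GroupComparison",
    "PairwiseContrast",
    "CorrelationMatrix",
    "LogisticFit",
    "ROCResult",
    "ValidationReport",
    "kruskal_wallis_eta2",
    "games_howell",
    "spearman_matrix",
    "fit_logistic",
    "classification_metrics",
    "roc_auc",
    "run_validation",
    "plot_roc",
]


# --------------------------------------------------------------------------
# group comparison
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseContrast:
    group_a: str
    group_b: str
    mean_diff: float
    se: float
    df: float
    p: float


@dataclass(frozen=True)
class GroupComparison:
    H: float
    p: float
    eta2: float
    posthoc: tuple[PairwiseContrast, ...] = ()


def kruskal_wallis_eta2(samples: Sequence[Sequence[float]]) -> GroupComparison:
    """Tie-corrected Kruskal-Wallis H with chi-squared p (df = k - 1) and
    the rank eta-squared effect size, reported unclamped (it can be
    slightly negative under the null)."""
    groups = [np.asarray(g, dtype=float) for g in samples]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    H, p = sps.kruskal(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    eta2 = (H - k + 1) / (n - k)
    return GroupComparison(H=float(H), p=float(p), eta2=float(eta2))


def games_howell(samples: Sequence[Sequence[float]],
                 labels: Optional[Sequence[str]] = None
                 ) -> list[PairwiseContrast]:
    """Games-Howell pairwise comparisons, robust to unequal variances.

    For each pair: mean difference, unpooled standard error,
    Welch-Satterthwaite df, and a p-value from the studentized range
    distribution with k groups.
    """
    groups = [np.asarray(g, dtype=float) for g in samples]
    if any(g.size < 3 for g in groups):
        raise ValueError("Games-Howell requires n >= 3 per group")
    k = len(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    means = [g.mean() for g in groups]
    vn = [g.var(ddof=1) / g.size for g in groups]
    out: list[PairwiseContrast] = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        se = np.sqrt(vn[i] + vn[j])
        df = (vn[i] + vn[j]) ** 2 / (
            vn[i] ** 2 / (groups[i].size - 1)
            + vn[j] ** 2 / (groups[j].size - 1))
        if se == 0:
            p = 1.0
        else:
            q = abs(diff) / (se / np.sqrt(2.0))
            p = float(sps.studentized_range.sf(q, k, df))
        out.append(PairwiseContrast(
            group_a=str(labels[i]), group_b=str(labels[j]),
            mean_diff=float(diff), se=float(se), df=float(df),
            p=min(max(p, 0.0), 1.0)))
    return out


# --------------------------------------------------------------------------
# convergent validity
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationMatrix:
    variables: tuple[str, ...]
    rho: pd.DataFrame
    p: pd.DataFrame


def spearman_matrix(table: pd.DataFrame, min_pairs: int = 3
                    ) -> CorrelationMatrix:
    """Pairwise-complete Spearman rank correlations with two-sided
    p-values.  Cells with fewer than ``min_pairs`` complete pairs are
    NaN."""
    cols = tuple(table.columns)
    n = len(cols)
    rho = np.full((n, n), np.nan)
    pval = np.full((n, n), np.nan)
    for i in range(n):
        rho[i, i] = 1.0
        pval[i, i] = 0.0
        for j in range(i + 1, n):
            sub = table.iloc[:, [i, j]].dropna()
            if len(sub) < min_pairs:
                continue
            r, p = sps.spearmanr(sub.iloc[:, 0], sub.iloc[:, 1])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    return CorrelationMatrix(
        variables=cols,
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        p=pd.DataFrame(pval, index=cols, columns=cols),
    )


# --------------------------------------------------------------------------
# logistic classification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WaldTest:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    wald: dict[str, WaldTest]
    minus2_loglik: float
    nagelkerke_r2: float
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    n_used: int
    separated: bool
    probs: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)


def _ordinal_dummies(series: pd.Series, name: str) -> pd.DataFrame:
    """Expand an ordinal 1-4 score into indicator columns with level 1 as
    the reference category."""
    levels = sorted(set(series.astype(int)))
    cols = {}
    for lvl in levels:
        if lvl == min(levels):
            continue  # reference
        cols[f"{name}[{lvl}]"] = (series.astype(int) == lvl).astype(float)
    return pd.DataFrame(cols, index=series.index)


def fit_logistic(outcome: pd.Series,
                 ordinal: Optional[pd.DataFrame] = None,
                 covariates: Optional[pd.DataFrame] = None,
                 cutoff: float = 0.5) -> LogisticFit:
    """Maximum-likelihood binary logistic regression.

    ``ordinal`` columns are 1-4 impairment scores entered as categorical
    factors (reference level 1; joint Wald test over the level contrasts,
    df = #levels - 1).  ``covariates`` enter linearly with 1-df Wald
    tests.  Quasi-complete separation is flagged, not raised.
    """
    y = outcome.astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    parts = [pd.Series(1.0, index=y.index, name="intercept")]
    term_cols: dict[str, list[str]] = {}
    if covariates is not None:
        for c in covariates.columns:
            parts.append(covariates[c].astype(float))
            term_cols[c] = [c]
    if ordinal is not None:
        for c in ordinal.columns:
            dummies = _ordinal_dummies(ordinal[c], c)
            parts.append(dummies)
            term_cols[c] = list(dummies.columns)
    X = pd.concat(parts, axis=1)
    if X.isna().any().any() or y.isna().any():
        raise ValueError("missing values in design; exclude upstream")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")

    separated = False
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:  # perfect separation raises in statsmodels
            separated = True
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
        probs = np.asarray(res.predict(X), dtype=float)
    params = pd.Series(np.asarray(res.params), index=X.columns)
    if np.any(np.abs(params.drop("intercept", errors="ignore")) > 20):
        separated = True

    # log-likelihood from the fitted probabilities (robust to the
    # diverging coefficients of a separated fit)
    clipped = np.clip(probs, 1e-12, 1 - 1e-12)
    yv = y.to_numpy()
    llf = float(np.sum(yv * np.log(clipped) + (1 - yv) * np.log(1 - clipped)))
    n = len(y)
    # null (intercept-only) log-likelihood
    p1 = y.mean()
    if p1 in (0.0, 1.0):
        raise ValueError("outcome has a single class")
    llnull = float(n * (p1 * np.log(p1) + (1 - p1) * np.log(1 - p1)))
    cox_snell = 1.0 - np.exp(2.0 * (llnull - llf) / n)
    max_cs = 1.0 - np.exp(2.0 * llnull / n)
    nagelkerke = float(cox_snell / max_cs) if max_cs > 0 else 0.0
    if abs(nagelkerke) < 1e-12:
        nagelkerke = 0.0

    wald: dict[str, WaldTest] = {}
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        cov = np.asarray(res.cov_params())
        bse = np.asarray(res.bse)
    beta = params.to_numpy()
    for term, cols in term_cols.items():
        idx = [X.columns.get_loc(c) for c in cols]
        b = beta[idx]
        V = cov[np.ix_(idx, idx)]
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            stat = float("nan")
        df = len(idx)
        wald[term] = WaldTest(statistic=stat, df=df,
                              p=float(sps.chi2.sf(stat, df)))

    acc, sens, spec = classification_metrics(probs, y.to_numpy(), cutoff)
    auc = float(roc_auc_score(y, probs)) if 0 < y.sum() < n else float("nan")
    return LogisticFit(
        params=params,
        bse=pd.Series(bse, index=X.columns),
        wald=wald,
        minus2_loglik=-2.0 * llf,
        nagelkerke_r2=nagelkerke,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n_used=n,
        separated=separated,
        probs=probs,
        y=y.to_numpy(),
    )


def classification_metrics(probs: np.ndarray, y: np.ndarray,
                           cutoff: float = 0.5
                           ) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) with predicted-positive iff
    probability >= cutoff (ties go to positive)."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    pred = (probs >= cutoff).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    acc = (tp + tn) / len(y)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return float(acc), float(sens), float(spec)


# --------------------------------------------------------------------------
# ROC
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """Empirical ROC over all score thresholds; AUC equals the pairwise
    concordance probability with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("labels must contain both classes")
    fpr, tpr, thr = roc_curve(labels, scores)
    return ROCResult(thresholds=thr, tpr=tpr, fpr=fpr,
                     auc=float(roc_auc_score(labels, scores)))


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

@dataclass
class ValidationReport:
    group_comparisons: dict[str, GroupComparison]
    group_means: pd.DataFrame
    spearman: Optional[CorrelationMatrix]
    models: dict[str, LogisticFit]
    roc: dict[str, ROCResult]
    n_used: int
    excluded_ids: tuple[str, ...]

    def models_table(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.models.items():
            rows.append({
                "model": name,
                "minus2_loglik": fit.minus2_loglik,
                "nagelkerke_r2": fit.nagelkerke_r2,
                "accuracy": fit.accuracy,
                "specificity": fit.specificity,
                "sensitivity": fit.sensitivity,
                "auc": fit.auc,
                "n_used": fit.n_used,
            })
        return pd.DataFrame(rows).set_index("model")

    def to_dict(self) -> dict:
        return {
            "n_used": self.n_used,
            "excluded_ids": list(self.excluded_ids),
            "group_comparisons": {
                a: {"H": g.H, "p": g.p, "eta2": g.eta2,
                    "posthoc": [vars(c) for c in g.posthoc]}
                for a, g in self.group_comparisons.items()},
            "models": {
                name: {
                    "minus2_loglik": f.minus2_loglik,
                    "nagelkerke_r2": f.nagelkerke_r2,
                    "accuracy": f.accuracy,
                    "specificity": f.specificity,
                    "sensitivity": f.sensitivity,
                    "auc": f.auc,
                    "n_used": f.n_used,
                    "separated": f.separated,
                    "wald": {t: vars(w) for t, w in f.wald.items()},
                    "coefficients": f.params.to_dict(),
                } for name, f in self.models.items()},
        }


def run_validation(cohort: pd.DataFrame,
                   group_col: str = "group",
                   case_label: str = "asd",
                   covariate_cols: Sequence[str] = ("iq", "age"),
                   alm_cols: Sequence[str] = ALM_NAMES,
                   score_suffix: str = "_score",
                   clinical_cols: Optional[Sequence[str]] = None,
                   id_col: str = "participant_id") -> ValidationReport:
    """The full cohort battery.

    ``cohort`` holds one row per participant with raw ALM columns, their
    ordinal recodings (``<alm>_score``), the diagnostic group, covariates
    and optional clinical-score columns.  Group comparisons and Spearman
    correlations use all available (pairwise-complete) values; the nine
    logistic models — covariates-only baseline, one per ALM, and the
    combined model — are all fitted on the single listwise-complete
    subsample (rows with an undefined measure or a missing covariate are
    excluded from *every* model so the models stay comparable).
    """
    cohort = cohort.reset_index(drop=True)
    if id_col in cohort.columns and cohort[id_col].duplicated().any():
        raise ValueError("duplicate participant ids")
    alm_cols = [c for c in alm_cols if c in cohort.columns]
    if group_col not in cohort.columns:
        raise ValueError(f"missing group column {group_col!r}")

    # 1. per-ALM group comparison on raw values
    group_labels = sorted(cohort[group_col].astype(str).unique())
    comparisons: dict[str, GroupComparison] = {}
    for alm in alm_cols:
        by_group = [cohort.loc[cohort[group_col].astype(str) == g, alm]
                    .dropna().to_numpy() for g in group_labels]
        gc = kruskal_wallis_eta2(by_group)
        if len(group_labels) >= 3 and all(len(g) >= 3 for g in by_group):
            gc = GroupComparison(
                H=gc.H, p=gc.p, eta2=gc.eta2,
                posthoc=tuple(games_howell(by_group, group_labels)))
        comparisons[alm] = gc
    group_means = cohort.groupby(group_col)[alm_cols].agg(["mean", "std"])

    # 2. convergent validity
    spearman = None
    corr_cols = list(alm_cols) + list(clinical_cols or [])
    if len(corr_cols) >= 2:
        spearman = spearman_matrix(cohort[corr_cols])

    # 3 & 4. logistic models + ROC on one listwise-complete subsample
    score_cols = [a + score_suffix for a in alm_cols
                  if a + score_suffix in cohort.columns]
    needed = list(covariate_cols) + score_cols
    complete = cohort[needed].notna().all(axis=1)
    sub = cohort.loc[complete].reset_index(drop=True)
    excluded = tuple(
        cohort.loc[~complete, id_col].astype(str)
        if id_col in cohort.columns else map(str, cohort.index[~complete]))
    y = (sub[group_col].astype(str) == case_label).astype(int)
    if y.nunique() < 2:
        raise ValueError("need both case and control rows after exclusions")
    cov = sub[list(covariate_cols)].astype(float)

    models: dict[str, LogisticFit] = {}
    roc: dict[str, ROCResult] = {}
    models["baseline"] = fit_logistic(y, ordinal=None, covariates=cov)
    for alm in alm_cols:
        sc = alm + score_suffix
        if sc not in sub.columns:
            continue
        models[alm] = fit_logistic(y, ordinal=sub[[sc]].rename(
            columns={sc: alm}), covariates=cov)
    if score_cols:
        combined = sub[score_cols].rename(
            columns={a + score_suffix: a for a in alm_cols})
        models["combined"] = fit_logistic(y, ordinal=combined, covariates=cov)
    for name, fit in models.items():
        roc[name] = roc_auc(fit.probs, fit.y)

    return ValidationReport(
        group_comparisons=comparisons,
        group_means=group_means,
        spearman=spearman,
        models=models,
        roc=roc,
        n_used=int(len(sub)),
        excluded_ids=excluded,
    )


def plot_roc(report: ValidationReport, path: str) -> None:
    """Overlaid ROC curves for every fitted model, one figure file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for name, r in report.roc.items():
        ax.plot(r.fpr, r.tpr, label=f"{name} (AUC = {r.auc:.3f})", lw=1.2)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title("ROC curves, in-sample prediction probabilities")
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
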