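"""Repeated stratified cross-validation, AUC aggregation, model comparison
statistics and logistic-regression feature importance.

The experiment design follows the study protocol: stratified k-fold
cross-validation repeated with different shuffles (default 10 x 10), model
performance summarised as AUC averaged over all folds and runs, one-way
ANOVA over per-repeat mean AUCs with Tukey-HSD post-hoc pairwise
comparisons for the three hypothesis batteries (models vs dummy; novel vs
established tasks; task fusion vs individual tasks), and Wald t-statistics
/ odds ratios for LR coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .classify import ModelSpec, fit_predict_unimodal, fuse_modalities, fuse_tasks
from .errors import CohortCompositionError, ContractViolationError, StratificationError

#: model ids in report order: (task set, modality)
UNIMODAL_MODELS = (
    ("pupil_calibration", "eye"),
    ("picture", "eye"),
    ("picture", "language"),
    ("reading", "eye"),
    ("reading", "language"),
    ("memory", "language"),
)
FUSED_TASK_MODELS = (("picture", "eye+language"), ("reading", "eye+language"))
TASK_FUSION_MODEL = ("task_fusion", "eye+language")


# ---------------------------------------------------------------------------
# cross-validation and AUC
# ---------------------------------------------------------------------------


def repeated_stratified_cv(labels, k: int = 10, repeats: int = 10, seed: int = 0) -> list:
    """Per-repeat stratified k-fold partitions, reproducible from ``seed``.

    Returns ``repeats`` lists of ``k`` ``(train_idx, test_idx)`` pairs.
    Each repeat uses a distinct seeded shuffle; per-fold class counts
    differ from exact proportionality by at most one.
    """
    y = np.asarray(labels)
    counts = pd.Series(y).value_counts()
    if len(counts) < 2:
        raise CohortCompositionError("both classes are required for stratified CV")
    if counts.min() < k:
        raise StratificationError(
            f"class with {counts.min()} members cannot be split into {k} folds"
        )
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7_001)))
    out = []
    for _ in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2 ** 31 - 1)))
        out.append([(tr.copy(), te.copy()) for tr, te in skf.split(np.zeros(len(y)), y)])
    return out


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the fraction of (patient, control) pairs in which the patient
    scores higher, ties counting one half.  Raises when only one class is
    present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise CohortCompositionError("AUC undefined for single-class input")
    ranks = sps.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Mean AUC over all folds with sd over per-repeat means, per model.

    ``records`` columns: model, algorithm, repeat, fold, auc.  The ``sd``
    column is the standard deviation of the per-repeat mean AUCs (the
    repeat is the unit of analysis); ``sd_folds`` over all fold AUCs is
    reported alongside.
    """
    required = {"model", "algorithm", "repeat", "fold", "auc"}
    if not required.issubset(records.columns):
        raise ContractViolationError(f"records need columns {sorted(required)}")
    gaps = records[records["auc"].isna()]
    if len(gaps):
        raise ContractViolationError(
            "missing fold AUCs for: "
            + ", ".join(sorted(set(gaps["model"] + "/" + gaps["algorithm"])))
        )
    rows = []
    for (model, algo), grp in records.groupby(["model", "algorithm"], sort=False):
        per_repeat = grp.groupby("repeat")["auc"].mean()
        rows.append(
            {
                "model": model,
                "algorithm": algo,
                "mean_auc": grp["auc"].mean(),
                "sd": per_repeat.std(ddof=1) if len(per_repeat) > 1 else 0.0,
                "sd_folds": grp["auc"].std(ddof=1) if len(grp) > 1 else 0.0,
                "n_records": len(grp),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD model comparison
# ---------------------------------------------------------------------------


def per_repeat_means(records: pd.DataFrame) -> pd.DataFrame:
    df = (
        records.groupby(["model", "algorithm", "repeat"], sort=False)["auc"]
        .mean()
        .reset_index()
    )
    df["model_id"] = df["model"] + "/" + df["algorithm"]
    return df


def compare_models(records: pd.DataFrame, factors: tuple = ("model_id",)):
    """ANOVA over per-repeat mean AUCs plus Tukey-HSD pairwise comparisons.

    One factor gives a one-way ANOVA over combined model ids; passing
    ``("model", "algorithm")`` gives the two-way design with tasks and
    algorithms as factors.  Designs must be balanced.
    """
    df = per_repeat_means(records)
    sizes = df.groupby(list(factors)).size()
    if sizes.nunique() > 1:
        raise ContractViolationError("unbalanced design: equal record counts required")
    if sizes.size < 2:
        raise ContractViolationError("need at least two groups to compare")
    terms = " + ".join(f"C({f})" for f in factors)
    fit = ols(f"auc ~ {terms}", data=df).fit()
    anova = anova_lm(fit, typ=2)
    tukey = pairwise_tukeyhsd(df["auc"].to_numpy(), df["model_id"].to_numpy())
    pairs = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    ).rename(columns={"p-adj": "p_adj"})
    return anova, pairs


def hypothesis_batteries(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """The three comparison batteries as Tukey-adjusted pairwise outcomes.

    H1 — every model vs the uniform dummy; H2 — novel-task models (pupil
    calibration, memory) vs established-task models (picture, reading);
    H3 — task fusion vs every individual-task model.  Uses one combined
    one-way ANOVA + Tukey HSD over all model ids, from which the relevant
    pairs are extracted.
    """
    _, pairs = compare_models(records)
    means = per_repeat_means(records).groupby("model_id")["auc"].mean()

    def _battery(pair_row):
        g1, g2 = pair_row["group1"], pair_row["group2"]
        tasks = {g.split("/")[0].split(":")[0] for g in (g1, g2)}
        if "dummy" in tasks:
            return "H1"
        if "task_fusion" in tasks:
            return "H3"
        novel = {"pupil_calibration", "memory"}
        established = {"picture", "reading"}
        if tasks & novel and tasks & established:
            return "H2"
        return ""

    pairs = pairs.copy()
    pairs["battery"] = pairs.apply(_battery, axis=1)
    pairs["significant"] = pairs["p_adj"].astype(float) < alpha
    pairs["mean_diff_sign"] = [
        np.sign(means[r["group2"]] - means[r["group1"]]) for _, r in pairs.iterrows()
    ]
    return pairs[pairs["battery"] != ""].reset_index(drop=True)


# ---------------------------------------------------------------------------
# dummy baseline
# ---------------------------------------------------------------------------


def dummy_baseline(labels, cv: list, seed: int = 0) -> pd.DataFrame:
    """Uniform-random classifier evaluated under the same CV protocol."""
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 4_242)))
    rows = []
    for r, folds in enumerate(cv):
        for f, (_, test_idx) in enumerate(folds):
            probs = rng.uniform(0.0, 1.0, len(test_idx))
            rows.append(
                {
                    "model": "dummy",
                    "algorithm": "uniform",
                    "repeat": r,
                    "fold": f,
                    "auc": auc(probs, y[test_idx]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LR feature importance (Wald statistics, odds ratios)
# ---------------------------------------------------------------------------


def odds_ratio_ci(coefficient: float, se: float | None = None) -> tuple:
    """Odds ratio per raw unit and its Wald 95% CI: ``exp(b +/- 1.96 se)``."""
    with np.errstate(over="ignore"):
        or_ = float(np.exp(coefficient))
        if se is None or not np.isfinite(se) or se <= 0:
            return or_, (float("nan"), float("nan"))
        return or_, (
            float(np.exp(coefficient - 1.96 * se)),
            float(np.exp(coefficient + 1.96 * se)),
        )


@dataclass(frozen=True)
class ImportanceRow:
    feature: str
    direction: str
    coefficient: float
    t_statistic: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    separation_flag: bool


def lr_importance(X: pd.DataFrame, y, spec: ModelSpec | None = None) -> pd.DataFrame:
    """Rank LR features by Wald t-statistics, with odds ratios and 95% CIs.

    The model is the study's L2-regularised logistic regression fitted on
    the full cohort; standard errors come from the unpenalised observed
    information evaluated at the fitted coefficients.  Odds ratios are per
    raw feature unit, ``exp(coefficient)``.  Features with signs of
    separation (non-finite standard error) are flagged and carry no CI.
    """
    from sklearn.linear_model import LogisticRegression

    spec = spec or ModelSpec("LR")
    y = np.asarray(y, dtype=int)
    medians = X.median()
    Xi = X.fillna(medians)
    est = LogisticRegression(C=spec.lr_inverse_regularization,
                             solver="lbfgs", max_iter=5000)
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        est.fit(Xi.to_numpy(), y)
    coefs = est.coef_.ravel()
    intercept = float(est.intercept_[0])

    X1 = np.column_stack([np.ones(len(Xi)), Xi.to_numpy(dtype=float)])
    beta = np.concatenate([[intercept], coefs])
    eta = X1 @ beta
    with np.errstate(over="ignore"):  # saturated probabilities are fine here
        p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = X1.T @ (X1 * w[:, None])
    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.diag(cov))[1:]
        except np.linalg.LinAlgError:
            se = np.full(len(coefs), np.nan)

    rows = []
    for name, b, s in zip(Xi.columns, coefs, se):
        sep = not np.isfinite(s) or s <= 0 or abs(b) > 30
        t = b / s if not sep else np.nan
        or_, (lo, hi) = odds_ratio_ci(b, None if sep else s)
        rows.append(
            ImportanceRow(
                feature=name,
                direction="+" if b >= 0 else "-",
                coefficient=float(b),
                t_statistic=float(t) if t == t else np.nan,
                odds_ratio=or_,
                ci_low=lo,
                ci_high=hi,
                separation_flag=bool(sep),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["abs_t"] = df["t_statistic"].abs()
    df = df.sort_values("abs_t", ascending=False, na_position="last")
    return df.drop(columns="abs_t").reset_index(drop=True)


# ---------------------------------------------------------------------------
# full experiment engine
# ---------------------------------------------------------------------------


def run_evaluation(
    features: dict,
    labels: pd.Series,
    gaze_valid: pd.Series,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    algorithms: tuple = ("GNB", "LR", "RF"),
) -> tuple:
    """Run the complete multi-task, multimodal CV experiment.

    ``features`` maps ``(task, modality)`` to a participant-indexed
    DataFrame; ``labels`` is a participant-indexed Series of
    ``patient``/``control``; ``gaze_valid`` flags participants whose gaze
    data passed validity screening (only they enter eye models).

    Returns ``(records, predictions)``: fold-level AUC records for every
    unimodal, modality-fused, task-fused and dummy model, and the
    participant-level probability table.
    """
    pids = list(labels.index)
    y = (labels == "patient").astype(int)
    if y.sum() == 0 or (1 - y).sum() == 0:
        raise CohortCompositionError("classification requires both patients and controls")
    cv = repeated_stratified_cv(y.to_numpy(), k=k, repeats=repeats, seed=seed)
    eye_ok = set(labels.index[gaze_valid.reindex(labels.index).fillna(False)])

    rec_rows, pred_rows = [], []
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11_003)))
    rf_seeds = rng.integers(2 ** 31 - 1, size=(len(algorithms), repeats, len(cv[0])))

    for a_i, algo in enumerate(algorithms):
        spec = ModelSpec(algo)
        for r, folds in enumerate(cv):
            for f, (train_idx, test_idx) in enumerate(folds):
                train_ids = [pids[i] for i in train_idx]
                test_ids = [pids[i] for i in test_idx]
                fold_seed = int(rf_seeds[a_i, r, f])
                probs: dict = {}
                for task, modality in UNIMODAL_MODELS:
                    X = features[(task, modality)]
                    if modality == "eye":
                        tr = [p for p in train_ids if p in eye_ok and p in X.index]
                        te = [p for p in test_ids if p in eye_ok and p in X.index]
                    else:
                        tr = [p for p in train_ids if p in X.index]
                        te = [p for p in test_ids if p in X.index]
                    if not te or len(set(y[tr])) < 2:
                        probs[(task, modality)] = pd.Series(dtype=float)
                        continue
                    pr = fit_predict_unimodal(
                        spec, X.loc[tr], y[tr].to_numpy(), X.loc[te], seed=fold_seed
                    )
                    probs[(task, modality)] = pd.Series(pr, index=te)
                    _record(rec_rows, f"{task}:{modality}", algo, r, f, probs[(task, modality)], y)

                # modality fusion inside picture and reading
                for task, _ in FUSED_TASK_MODELS:
                    fused = fuse_modalities(
                        probs.get((task, "eye")), probs[(task, "language")]
                    )
                    probs[(task, "fused")] = fused
                    _record(rec_rows, f"{task}:eye+language", algo, r, f, fused, y)

                # four-task fusion
                task_probs = {
                    "pupil_calibration": probs[("pupil_calibration", "eye")],
                    "picture": probs[("picture", "fused")],
                    "reading": probs[("reading", "fused")],
                    "memory": probs[("memory", "language")],
                }
                fused_all = fuse_tasks(
                    task_probs, algorithm=algo,
                    algorithms={t: algo for t in task_probs},
                )
                _record(rec_rows, "task_fusion:eye+language", algo, r, f, fused_all, y)

                for (task, modality), series in probs.items():
                    for pid, prob in series.items():
                        pred_rows.append(
                            {
                                "participant_id": pid, "run": r, "fold": f,
                                "task": task, "modality": modality,
                                "algorithm": algo, "probability": prob,
                                "label": labels[pid],
                            }
                        )
                for pid, prob in fused_all.items():
                    pred_rows.append(
                        {
                            "participant_id": pid, "run": r, "fold": f,
                            "task": "task_fusion", "modality": "eye+language",
                            "algorithm": algo, "probability": prob,
                            "label": labels[pid],
                        }
                    )

    records = pd.DataFrame(rec_rows)
    records = pd.concat(
        [records, dummy_baseline(y.to_numpy(), cv, seed=seed)], ignore_index=True
    )
    return records, pd.DataFrame(pred_rows)


def _record(rows, model, algo, repeat, fold, series: pd.Series, y: pd.Series):
    if len(series) == 0:
        return
    sub_y = y[series.index]
    if sub_y.nunique() < 2:
        return  # AUC undefined on this fold subset; no record emitted
    rows.append(
        {
            "model": model,
            "algorithm": algo,
            "repeat": repeat,
            "fold": fold,
            "auc": auc(series.to_numpy(), sub_y.to_numpy()),
        }
    )
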