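"""Cross-validated logistic-regression classification of videos (GTS vs HC).

Videos are classified from their tic summary scores with univariate or
multivariate logistic regression. To avoid class-imbalance bias and to
preserve the matched-pair design, evaluation uses leave-pair-out
cross-validation: each video's prediction comes from a model trained with
all videos of that participant AND their individually matched partner held
out. Performance is summarized by balanced accuracy (mean of sensitivity
and specificity) and the area under the ROC curve, and score validity is
checked by correlation with manual tic counts.

The fit maximizes the binomial log-likelihood by iteratively reweighted
least squares (Newton), with an optional tiny ridge penalty on the slope
coefficients for numerical stability: univariate fits on ~40-pair training
sets can separate the classes perfectly, in which case the unpenalized MLE
does not exist. A separation warning is flagged when the fitted model
classifies its training data essentially perfectly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import roc_auc_score, roc_curve

from .simulate import GTS, HC, CohortDataset

MAX_IRLS_ITER = 100
GRADIENT_TOL = 1e-8
DEFAULT_RIDGE = 1e-6


class SeparationWarning(UserWarning):
    """The training data are (near-)perfectly separated; slope estimates
    are determined mainly by the ridge penalty."""


@dataclass(frozen=True)
class LogisticModel:
    """Fitted logistic regression; GTS is the positive class."""

    intercept: float
    coefficients: dict[str, float]
    predictor_names: tuple[str, ...]
    converged: bool
    separation: bool
    n_iter: int

    def linear_predictor(self, scores: pd.DataFrame) -> np.ndarray:
        missing = [n for n in self.predictor_names if n not in scores.columns]
        if missing:
            raise KeyError(f"predictors missing from scores: {missing}")
        X = scores[list(self.predictor_names)].to_numpy(dtype=float)
        beta = np.array([self.coefficients[n] for n in self.predictor_names])
        return self.intercept + X @ beta


@dataclass(frozen=True)
class CVPrediction:
    """Cross-validated GTS probability for one video."""

    video_id: str
    true_group: str
    p_gts: float
    fold_id: str


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auroc: float


def _encode_labels(labels) -> np.ndarray:
    y = np.asarray([1 if g == GTS else 0 for g in labels], dtype=float)
    return y


def fit_logistic(
    scores: pd.DataFrame,
    labels,
    predictors: list[str] | None = None,
    ridge: float = DEFAULT_RIDGE,
    standardize: bool = False,
) -> LogisticModel:
    """Maximum-(penalized-)likelihood logistic fit of group on score columns.

    Parameters
    ----------
    scores
        Per-video predictor values; one row per video.
    labels
        Group labels aligned with ``scores`` rows; GTS coded 1.
    ridge
        Quadratic penalty weight on slope coefficients (the intercept is
        not penalized); 0 gives the plain MLE.
    standardize
        Z-score predictors before fitting and transform coefficients back
        to the original score units.

    The objective ``loglik - ridge * ||slopes||^2`` is maximized by Newton
    steps with step-halving; convergence is declared at max-norm gradient
    below 1e-8, otherwise a non-convergence warning is emitted.
    """
    if predictors is None:
        predictors = [c for c in scores.columns if c not in ("video_id", "participant_id", "group")]
    if ridge < 0:
        raise ValueError(f"ridge must be >= 0, got {ridge}")
    y = _encode_labels(labels)
    if len(y) != len(scores):
        raise ValueError("labels and scores must have equal length")
    if y.min() == y.max():
        raise ValueError("both groups must be present to fit a classifier")
    X = scores[list(predictors)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite predictor values")

    mu = np.zeros(X.shape[1])
    sd = np.ones(X.shape[1])
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd

    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    pen = 2.0 * ridge * np.diag([0.0, *([1.0] * p)])  # intercept unpenalized
    beta = np.zeros(p + 1)

    def objective(b: np.ndarray) -> float:
        eta = Xd @ b
        # log-likelihood via log1p(exp) for stability
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        return ll - ridge * float(b[1:] @ b[1:])

    converged = False
    n_iter = 0
    obj = objective(beta)
    for n_iter in range(1, MAX_IRLS_ITER + 1):
        eta = Xd @ beta
        prob = expit(eta)
        grad = Xd.T @ (y - prob) - pen @ beta
        if np.max(np.abs(grad)) < GRADIENT_TOL:
            converged = True
            break
        w = prob * (1.0 - prob)
        H = (Xd * w[:, None]).T @ Xd + pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            new_obj = objective(beta + scale * step)
            if new_obj >= obj - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        obj = objective(beta)
    else:
        warnings.warn("logistic fit did not reach gradient tolerance 1e-8", RuntimeWarning)

    prob = expit(Xd @ beta)
    separation = bool(np.all(np.abs(prob - y) < 1e-3)) and p > 0
    if separation:
        warnings.warn(
            "training data are (near-)perfectly separated; slopes are ridge-determined",
            SeparationWarning,
        )

    slopes = beta[1:] / sd
    intercept = float(beta[0] - slopes @ mu)
    return LogisticModel(
        intercept=intercept,
        coefficients={name: float(b) for name, b in zip(predictors, slopes)},
        predictor_names=tuple(predictors),
        converged=converged,
        separation=separation,
        n_iter=n_iter,
    )


def predict_p_gts(model: LogisticModel, scores: pd.DataFrame) -> np.ndarray:
    """P(GTS) per video: logistic of the model's linear predictor."""
    return expit(model.linear_predictor(scores))


def log_likelihood(model: LogisticModel, scores: pd.DataFrame, labels) -> float:
    """Binomial log-likelihood of the model on the given videos."""
    y = _encode_labels(labels)
    eta = model.linear_predictor(scores)
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def leave_pair_out_cv(
    dataset: CohortDataset | pd.DataFrame,
    scores: pd.DataFrame,
    predictors: list[str],
    ridge: float = DEFAULT_RIDGE,
    standardize: bool = False,
) -> list[CVPrediction]:
    """Leave-pair-out cross-validated GTS probabilities for every video.

    One fold per matched pair: the fold's model is trained on all videos
    excluding those of both pair members, then applied to the held-out
    videos. ``dataset`` may be a :class:`CohortDataset` or a manifest
    DataFrame with columns (video_id, participant_id, group,
    matched_partner_id); ``scores`` must hold one row per video.
    """
    manifest = dataset.manifest() if isinstance(dataset, CohortDataset) else dataset
    merged = manifest.merge(scores[["video_id", *predictors]], on="video_id", validate="1:1")
    if len(merged) != len(manifest):
        raise ValueError("scores must contain exactly one row per manifest video")

    part = manifest.drop_duplicates("participant_id").set_index("participant_id")
    pairs: dict[str, tuple[str, str]] = {}
    for pid, row in part.iterrows():
        partner = row["matched_partner_id"]
        if partner not in part.index:
            raise ValueError(f"participant {pid}: matched partner {partner} has no videos")
        gts_id, hc_id = (pid, partner) if row["group"] == GTS else (partner, pid)
        pairs[f"{gts_id}|{hc_id}"] = (gts_id, hc_id)

    predictions: list[CVPrediction] = []
    for fold_id, members in sorted(pairs.items()):
        held = merged["participant_id"].isin(members)
        train = merged.loc[~held]
        test = merged.loc[held]
        if train["group"].nunique() < 2:
            raise ValueError(f"fold {fold_id}: training videos contain only one class")
        model = fit_logistic(
            train, train["group"], predictors=predictors, ridge=ridge, standardize=standardize
        )
        p = predict_p_gts(model, test)
        for (_, row), p_i in zip(test.iterrows(), p):
            predictions.append(
                CVPrediction(
                    video_id=row["video_id"],
                    true_group=row["group"],
                    p_gts=float(p_i),
                    fold_id=fold_id,
                )
            )
    return predictions


def predictions_frame(predictions: list[CVPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"video_id": p.video_id, "true_group": p.true_group, "p_gts": p.p_gts, "fold_id": p.fold_id}
            for p in predictions
        ]
    )


def _split_by_truth(predictions: list[CVPrediction]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([1 if p.true_group == GTS else 0 for p in predictions])
    s = np.array([p.p_gts for p in predictions])
    if y.size == 0 or y.min() == y.max():
        raise ValueError("both groups must be present")
    return y, s


def balanced_accuracy(
    predictions: list[CVPrediction], decision_threshold: float = 0.5
) -> float:
    """100 x (sensitivity + specificity) / 2; predicted GTS iff p_gts >= threshold."""
    y, s = _split_by_truth(predictions)
    pred = s >= decision_threshold
    sensitivity = float(pred[y == 1].mean())
    specificity = float((~pred[y == 0]).mean())
    return 100.0 * (sensitivity + specificity) / 2.0


def roc_auroc(predictions: list[CVPrediction]) -> ROCResult:
    """ROC curve and AUROC of cross-validated GTS probabilities.

    The AUROC equals the Mann-Whitney probability that a random GTS
    video's p_gts exceeds a random HC video's, with ties counted 1/2.
    """
    y, s = _split_by_truth(predictions)
    fpr, tpr, thr = roc_curve(y, s)
    order = np.argsort(thr)  # ascending thresholds -> non-increasing sensitivity
    return ROCResult(
        thresholds=thr[order],
        sensitivity=tpr[order],
        specificity=1.0 - fpr[order],
        auroc=float(roc_auc_score(y, s)),
    )


def score_rating_correlation(
    scores, manual_counts, method: str = "pearson"
) -> float:
    """Correlation between an automated tic score and manual tic counts."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(manual_counts, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equally sized samples of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in scores or manual counts")
    if method == "pearson":
        return float(pearsonr(x, y).statistic)
    if method == "spearman":
        return float(spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")
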