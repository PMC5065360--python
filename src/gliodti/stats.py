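"""Cohort-level statistics: ROC with a low-is-positive rule, PPV,
weighted Cohen's kappa, and two-group ANOVA with Bonferroni correction.

The discrimination question is whether a low minimum diffusivity flags
malignant transformation, so the diagnostic test is "positive if the
value is less than or equal to the cutoff". The ROC curve is evaluated
at midpoints between consecutive sorted unique values (plus the two
infinite endpoints); the AUC is the trapezoidal area over
(1 - specificity, sensitivity), which equals the Mann–Whitney
concordance probability with half credit for ties. The operating
cutoff maximizes Youden's J = sensitivity + specificity - 1, ties
resolved toward the smaller cutoff, and the AUC standard error uses
the Hanley–McNeil formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ROCSummary",
    "KappaResult",
    "GroupComparison",
    "roc_analysis",
    "ppv_from_confusion",
    "weighted_kappa",
    "kappa_band",
    "group_compare",
]


@dataclass(frozen=True)
class ROCSummary:
    parameter_name: str
    cutoff: float
    sensitivity: float  # percent
    specificity: float  # percent
    auc: float
    auc_se: float
    ppv: float  # percent
    confusion: tuple[int, int, int, int]  # TP, FP, TN, FN at cutoff
    curve: tuple[tuple[float, float, float], ...]  # (threshold, sens%, spec%)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    weighting: str
    band_label: str
    contingency: np.ndarray
    categories: tuple


@dataclass(frozen=True)
class GroupComparison:
    parameter_name: str
    mean_stable: float
    sd_stable: float
    ci_stable: tuple[float, float]
    mean_transformed: float
    sd_transformed: float
    ci_transformed: tuple[float, float]
    f_statistic: float
    p_raw: float
    p_bonferroni: float


def _confusion_le(values: np.ndarray, labels: np.ndarray, cutoff: float) -> tuple[int, int, int, int]:
    pos = values <= cutoff
    tp = int(np.count_nonzero(pos & (labels == 1)))
    fp = int(np.count_nonzero(pos & (labels == 0)))
    tn = int(np.count_nonzero(~pos & (labels == 0)))
    fn = int(np.count_nonzero(~pos & (labels == 1)))
    return tp, fp, tn, fn


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_analysis(values, labels, parameter_name: str = "", direction: str = "le") -> ROCSummary:
    """ROC analysis with low-value positivity.

    Parameters
    ----------
    values : per-subject biomarker values (any positive scale).
    labels : 0 (stable) / 1 (transformed).
    direction : only ``"le"`` is supported — a subject tests positive
        when its value is <= the threshold.
    """
    if direction != "le":
        raise ValueError(f"only direction='le' is supported, got {direction!r}")
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be equal-length 1D")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite biomarker values")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    n_pos = int(np.count_nonzero(y == 1))
    n_neg = int(np.count_nonzero(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")

    uniq = np.unique(v)
    thresholds = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))

    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        tp, fp, tn, fn = _confusion_le(v, y, t)
        sens[i] = tp / n_pos
        spec[i] = tn / n_neg

    fpr = 1.0 - spec
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(sens[order], fpr[order]))

    finite = np.isfinite(thresholds)
    cand = thresholds[finite]
    if cand.size == 0:
        raise ValueError("no finite cutoff candidates (all values identical)")
    j = sens[finite] + spec[finite] - 1.0
    tied = np.flatnonzero(np.isclose(j, j.max(), rtol=0, atol=1e-12))
    cutoff = float(cand[tied.min()])  # tie -> smallest cutoff

    tp, fp, tn, fn = _confusion_le(v, y, cutoff)
    curve = tuple(
        (float(t), float(100 * s), float(100 * sp))
        for t, s, sp in zip(thresholds, sens, spec)
    )
    return ROCSummary(
        parameter_name=parameter_name,
        cutoff=cutoff,
        sensitivity=100.0 * tp / n_pos,
        specificity=100.0 * tn / n_neg,
        auc=auc,
        auc_se=_hanley_mcneil_se(auc, n_pos, n_neg),
        ppv=ppv_from_confusion((tp, fp, tn, fn)),
        confusion=(tp, fp, tn, fn),
        curve=curve,
    )


def ppv_from_confusion(confusion: tuple[int, int, int, int]) -> float:
    """Positive predictive value, percent: 100 * TP / (TP + FP)."""
    tp, fp, _, _ = confusion
    if tp + fp < 1:
        raise ValueError("PPV undefined: no positive test results (TP + FP = 0)")
    return 100.0 * tp / (tp + fp)


_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "very good"),
    (1.00, "substantial"),
)


def kappa_band(kappa: float) -> str:
    """Agreement band for a kappa value (upper bounds inclusive)."""
    for upper, label in _BANDS:
        if kappa <= upper + 1e-12:
            return label
    return "substantial"


def weighted_kappa(ratings_r1, ratings_r2, weighting: str = "linear") -> KappaResult:
    """Weighted Cohen's kappa between two raters.

    kappa = 1 - sum(w * o) / sum(w * e), with observed proportions o,
    expected proportions e from the marginal products, and disagreement
    weights w_ij = |i - j| (linear) or (i - j)^2 (quadratic) over the
    sorted shared category set. For binary ratings both weightings
    reduce to the unweighted kappa.
    """
    r1 = np.asarray(ratings_r1)
    r2 = np.asarray(ratings_r2)
    if r1.shape != r2.shape or r1.ndim != 1 or r1.size < 2:
        raise ValueError("ratings must be two equal-length 1D sequences of length >= 2")
    if weighting not in ("linear", "quadratic"):
        raise ValueError(f"weighting must be 'linear' or 'quadratic', got {weighting!r}")

    cats = np.unique(np.concatenate([r1, r2]))
    k = cats.size
    index = {c: i for i, c in enumerate(cats)}
    o = np.zeros((k, k))
    for a, b in zip(r1, r2):
        o[index[a], index[b]] += 1
    n = r1.size
    o /= n
    e = np.outer(o.sum(axis=1), o.sum(axis=0))

    ii, jj = np.indices((k, k))
    w = np.abs(ii - jj) if weighting == "linear" else (ii - jj) ** 2

    denom = float((w * e).sum())
    if denom == 0.0:
        raise ValueError(
            "kappa undefined: expected agreement is 1 (degenerate marginals — "
            "at least one rater uses a single category)"
        )
    kappa = 1.0 - float((w * o).sum()) / denom
    return KappaResult(
        kappa=kappa,
        weighting=weighting,
        band_label=kappa_band(kappa),
        contingency=(o * n).astype(int),
        categories=tuple(cats.tolist()),
    )


def _group_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    n = x.size
    m = float(np.mean(x))
    se = float(np.std(x, ddof=1)) / np.sqrt(n)
    t = sps.t.ppf(0.5 + level / 2.0, n - 1)
    return (m - t * se, m + t * se)


def group_compare(cohort: pd.DataFrame, bonferroni_factor: int = 3) -> list[GroupComparison]:
    """One-way two-group ANOVA per biomarker, Bonferroni-corrected.

    The cohort table must carry ``label`` (0/1) and the three
    ``*_min`` columns. With two groups the ANOVA F statistic equals the
    square of the pooled-variance t statistic; the Bonferroni factor
    defaults to the three-parameter family.
    """
    out: list[GroupComparison] = []
    labels = cohort["label"].to_numpy()
    for p in ("ad", "md", "rd"):
        x0 = cohort.loc[labels == 0, f"{p}_min"].to_numpy(dtype=float)
        x1 = cohort.loc[labels == 1, f"{p}_min"].to_numpy(dtype=float)
        if x0.size < 2 or x1.size < 2:
            raise ValueError("both groups need >= 2 subjects")
        if np.std(np.concatenate([x0 - x0.mean(), x1 - x1.mean()])) == 0:
            raise ValueError(f"{p}_min: zero pooled variance; F undefined")
        f, p_raw = sps.f_oneway(x0, x1)
        out.append(
            GroupComparison(
                parameter_name=f"{p}_min",
                mean_stable=float(np.mean(x0)),
                sd_stable=float(np.std(x0, ddof=1)),
                ci_stable=_group_ci(x0),
                mean_transformed=float(np.mean(x1)),
                sd_transformed=float(np.std(x1, ddof=1)),
                ci_transformed=_group_ci(x1),
                f_statistic=float(f),
                p_raw=float(p_raw),
                p_bonferroni=float(min(1.0, bonferroni_factor * p_raw)),
            )
        )
    return out
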