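"""Cohort-level inference for the reconstruction-quality comparison.

* a paired permutation test on the pAUC difference between two conditions
  (per-patient condition-label swapping, the pairing unit being the
  patient);
* patient-level ROC with sensitivity/specificity/PPV/NPV at an operating
  threshold chosen once on the reference condition (Youden index) and then
  held fixed;
* Cohen's kappa with an asymptotic 95% CI for the reader-concordance
  analysis, on the {consistent, minor variation} vs {inconsistent}
  collapse of the three-category ratings;
* selection of the most/least condition-consistent cases for a reader
  study.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.inter_rater import cohens_kappa as _sm_kappa

from .froc import PatientDetections, froc_curve

__all__ = [
    "PermutationResult",
    "PatientRocResult",
    "KappaResult",
    "permutation_test_pauc",
    "patient_score",
    "patient_roc",
    "cohens_kappa",
    "select_inconsistency_sets",
]

RATING_CATEGORIES = ("consistent", "minor variation", "inconsistent")


@dataclass(frozen=True)
class PermutationResult:
    """Observed pAUC difference with its permutation null."""

    observed_diff: float
    null_diffs: tuple[float, ...]
    p_value: float
    n_permutations: int
    exact: bool
    seed: int


def permutation_test_pauc(
    cohort_a: Sequence[PatientDetections],
    cohort_b: Sequence[PatientDetections],
    n_permutations: int = 1000,
    seed: int = 0,
    min_overlap: float = 0.10,
) -> PermutationResult:
    """Paired permutation test on pAUC(a) - pAUC(b).

    The two cohorts must hold the *same patients* under two conditions,
    index-aligned.  The null swaps each patient's pair of conditions
    independently and recomputes both pAUCs.  When all 2^n swap patterns
    fit inside ``n_permutations`` the null is enumerated exactly
    (p = #{|null| >= |obs|} / 2^n); otherwise it is sampled and
    p = (1 + #{|null| >= |obs|}) / (n_permutations + 1).
    """
    if len(cohort_a) != len(cohort_b):
        raise ValueError("cohorts must be paired (same patients, same order)")
    n = len(cohort_a)
    for pa, pb in zip(cohort_a, cohort_b):
        if pa.lesions.labelmap.shape != pb.lesions.labelmap.shape:
            raise ValueError("paired patients must share a grid")

    def diff(swap: np.ndarray) -> float:
        a = [cohort_b[i] if s else cohort_a[i] for i, s in enumerate(swap)]
        b = [cohort_a[i] if s else cohort_b[i] for i, s in enumerate(swap)]
        return (
            froc_curve(a, min_overlap=min_overlap).pauc
            - froc_curve(b, min_overlap=min_overlap).pauc
        )

    observed = diff(np.zeros(n, dtype=bool))
    exact = 2**n <= n_permutations
    null: list[float] = []
    if exact:
        for code in range(2**n):
            swap = np.array([(code >> i) & 1 for i in range(n)], dtype=bool)
            null.append(diff(swap))
        count = sum(abs(d) >= abs(observed) - 1e-12 for d in null)
        p = count / len(null)
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_permutations):
            null.append(diff(rng.random(n) < 0.5))
        count = sum(abs(d) >= abs(observed) - 1e-12 for d in null)
        p = (1 + count) / (n_permutations + 1)
    return PermutationResult(
        observed_diff=observed,
        null_diffs=tuple(null),
        p_value=float(p),
        n_permutations=len(null),
        exact=exact,
        seed=seed,
    )


@dataclass(frozen=True)
class PatientRocResult:
    """Patient-level ROC with confusion-derived metrics at a threshold."""

    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    scores: tuple[float, ...]
    labels: tuple[int, ...]


def patient_score(detections: PatientDetections) -> float:
    """Patient-level detection score: maximum candidate confidence (0 if none)."""
    if not detections.candidates:
        return 0.0
    return max(c.confidence for c in detections.candidates)


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Threshold maximising sensitivity + specificity - 1 (Youden index)."""
    fpr, tpr, thresholds = roc_curve(labels, scores)
    best = int(np.argmax(tpr - fpr))
    return float(thresholds[best])


def patient_roc(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float | None = None,
) -> PatientRocResult:
    """Patient-level ROC analysis at a fixed or Youden-derived threshold.

    AUC is the rank (Mann-Whitney) statistic with tie correction.  If no
    threshold is given the Youden maximiser is chosen from these data; to
    evaluate a degraded condition at the reference condition's operating
    point, pass that condition's threshold explicitly.  A patient is called
    positive when score >= threshold.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary")
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(y, s))
    thr = youden_threshold(s, y) if threshold is None else float(threshold)
    pred = s >= thr
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return PatientRocResult(
        auc=auc,
        threshold=thr,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        ppv=tp / (tp + fp) if tp + fp else 0.0,
        npv=tn / (tn + fn) if tn + fn else 0.0,
        scores=tuple(float(v) for v in s),
        labels=tuple(int(v) for v in y),
    )


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with an asymptotic 95% confidence interval."""

    kappa: float
    ci: tuple[float, float]
    table: np.ndarray
    collapsed: bool


def _collapse(ratings: Sequence[str]) -> np.ndarray:
    for r in ratings:
        if r not in RATING_CATEGORIES:
            raise ValueError(f"unknown rating {r!r}; expected one of {RATING_CATEGORIES}")
    return np.asarray([1 if r == "inconsistent" else 0 for r in ratings])


def cohens_kappa(
    rater_a: Sequence[str],
    rater_b: Sequence[str],
    collapse: bool = True,
) -> KappaResult:
    """Chance-corrected agreement between two raters' consistency calls.

    Ratings come from {consistent, minor variation, inconsistent}.  By
    default the table is collapsed to binary ({consistent, minor} vs
    {inconsistent}); ``collapse=False`` keeps the 3x3 table (unweighted
    kappa).  The CI uses the standard asymptotic variance.  Degenerate
    marginals (chance agreement 1) return kappa 0 with a (0, 0) CI.
    """
    if len(rater_a) != len(rater_b):
        raise ValueError("raters must rate the same cases")
    if len(rater_a) < 2:
        raise ValueError("need at least 2 cases")
    if collapse:
        a, b = _collapse(rater_a), _collapse(rater_b)
        k = 2
    else:
        cat = {c: i for i, c in enumerate(RATING_CATEGORIES)}
        _collapse(rater_a), _collapse(rater_b)  # validate categories
        a = np.asarray([cat[r] for r in rater_a])
        b = np.asarray([cat[r] for r in rater_b])
        k = 3
    table = np.zeros((k, k))
    for i, j in zip(a, b):
        table[i, j] += 1
    marg_a = table.sum(axis=1) / table.sum()
    marg_b = table.sum(axis=0) / table.sum()
    if np.isclose(float(marg_a @ marg_b), 1.0):
        return KappaResult(kappa=0.0, ci=(0.0, 0.0), table=table, collapsed=collapse)
    res = _sm_kappa(table, return_results=True)
    return KappaResult(
        kappa=float(res.kappa),
        ci=(float(res.kappa_low), float(res.kappa_upp)),
        table=table,
        collapsed=collapse,
    )


def select_inconsistency_sets(
    case_ids: Sequence[str],
    scores_reference: Sequence[float],
    scores_condition: Sequence[float],
    k: int = 15,
) -> tuple[list[str], list[str]]:
    """Pick the k most and k least condition-consistent cases.

    The per-case difference is |patient score under the reference condition
    minus under the degraded condition|; the top-k form the inconsistent
    set, the bottom-k the consistent set.  Ties break by patient id so the
    selection is deterministic.
    """
    if len(case_ids) != len(scores_reference) or len(case_ids) != len(scores_condition):
        raise ValueError("ids and score vectors must align")
    if len(case_ids) < 2 * k:
        raise ValueError(f"need at least {2 * k} cases")
    diffs = np.abs(np.asarray(scores_reference) - np.asarray(scores_condition))
    ranked = sorted(zip(diffs, case_ids), key=lambda t: (-t[0], t[1]))
    inconsistent = [cid for _, cid in ranked[:k]]
    ranked_low = sorted(zip(diffs, case_ids), key=lambda t: (t[0], t[1]))
    consistent = [cid for _, cid in ranked_low[:k]]
    return inconsistent, consistent
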