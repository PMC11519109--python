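"""The diagnostic-quality metric (DiagQM): FROC analysis of lesion detection.

Free-response ROC evaluates lesion-level sensitivity against false
positives per patient, since a patient can carry several lesions.  The
pipeline is: iterative peak extraction turns a likelihood heatmap into
scored candidate regions; candidates are matched one-to-one against
ground-truth lesions requiring at least 10% overlap (intersection-over-
union by default); sweeping the confidence threshold gives the FROC curve;
the partial area under the curve between 0.1 and 2.5 false positives per
patient summarises diagnostic quality (pAUC in [0, 2.4]); patient-level
bootstrap gives its confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
from scipy import ndimage

from .models import Heatmap
from .volume import LesionSet

__all__ = [
    "CandidateParams",
    "LesionCandidate",
    "PatientDetections",
    "MatchResult",
    "FrocResult",
    "extract_candidates",
    "match_candidates",
    "froc_curve",
    "pauc",
    "bootstrap_pauc_ci",
]

FP_WINDOW = (0.1, 2.5)  # false positives per patient


@dataclass(frozen=True)
class CandidateParams:
    """Iterative peak-extraction settings.

    ``floor`` is the minimum peak likelihood considered; regions grow over
    the connected set above ``relative_threshold * peak`` (26-connectivity);
    regions smaller than ``min_volume`` voxels are dropped (but still
    suppressed); at most ``max_candidates`` candidates are returned.
    """

    floor: float = 0.10
    relative_threshold: float = 0.40
    max_candidates: int = 10
    min_volume: int = 3


@dataclass(frozen=True)
class LesionCandidate:
    """A connected candidate region with its peak likelihood as confidence."""

    indices: np.ndarray  # sorted flat voxel indices on the heatmap grid
    confidence: float
    centroid_mm: tuple[float, float, float]
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.size == 0:
            raise ValueError("candidate region must be non-empty")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")
        object.__setattr__(self, "indices", np.sort(idx))

    @property
    def n_voxels(self) -> int:
        return int(self.indices.size)


@dataclass(frozen=True)
class PatientDetections:
    """Everything FROC needs for one patient: candidates plus ground truth."""

    candidates: tuple[LesionCandidate, ...]
    lesions: LesionSet

    def __post_init__(self) -> None:
        for c in self.candidates:
            if c.grid_shape != self.lesions.labelmap.shape:
                raise ValueError("candidate and lesion grids differ")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of confidence-ordered one-to-one candidate/lesion matching."""

    lesion_hits: dict[int, int | None]  # lesion label -> candidate index (or None)
    candidate_status: tuple[str, ...]  # "TP" | "FP" | "discarded"
    overlaps: dict[tuple[int, int], float]  # (candidate index, label) -> overlap

    @property
    def n_tp(self) -> int:
        return sum(s == "TP" for s in self.candidate_status)

    @property
    def n_fp(self) -> int:
        return sum(s == "FP" for s in self.candidate_status)

    @property
    def n_missed(self) -> int:
        return sum(c is None for c in self.lesion_hits.values())


@dataclass(frozen=True)
class FrocResult:
    """FROC operating points with the pAUC summary."""

    thresholds: tuple[float, ...]
    sensitivities: tuple[float, ...]
    fp_per_patient: tuple[float, ...]
    pauc: float
    fp_window: tuple[float, float] = FP_WINDOW
    ci: tuple[float, float] | None = None
    n_patients: int = 0
    n_lesions: int = 0


def extract_candidates(
    heatmap: Heatmap, params: CandidateParams = CandidateParams()
) -> list[LesionCandidate]:
    """Peak-wise extraction of scored candidate regions.

    Every local maximum above the floor seeds a watershed basin of the
    likelihood field (26-connectivity, masked at the floor), so each peak
    owns its own territory: nearby lesions stay separate candidates and a
    blob's tail can never re-surface as a duplicate rim candidate.  Peaks
    are visited in descending height; the recorded region is the part of
    the peak's basin above ``relative_threshold`` times the peak, its
    confidence is the peak value.  Regions smaller than ``min_volume``
    voxels are dropped; extraction stops after ``max_candidates``.
    Deterministic; an empty list is a valid outcome.
    """
    from skimage.segmentation import watershed

    h = heatmap.likelihood
    shape = h.shape
    structure = np.ones((3, 3, 3), dtype=bool)
    mask = h >= params.floor
    if not mask.any():
        return []
    plateau = (ndimage.maximum_filter(h, footprint=structure) == h) & mask
    markers, n_markers = ndimage.label(plateau, structure=structure)
    if n_markers == 0:
        return []
    basins = watershed(-h, markers, mask=mask, connectivity=structure)
    peak_vals = ndimage.maximum(h, labels=basins, index=np.arange(1, n_markers + 1))
    order = sorted(range(1, n_markers + 1), key=lambda k: (-peak_vals[k - 1], k))
    out: list[LesionCandidate] = []
    for lab in order:
        if len(out) >= params.max_candidates:
            break
        peak_val = float(peak_vals[lab - 1])
        region = (basins == lab) & (h >= params.relative_threshold * peak_val)
        if int(region.sum()) < params.min_volume:
            continue
        flat = np.flatnonzero(region)
        coords = np.array(np.unravel_index(flat, shape)).mean(axis=1)
        centroid = tuple(float(c * s) for c, s in zip(coords, heatmap.spacing))
        out.append(
            LesionCandidate(
                indices=flat,
                confidence=peak_val,
                centroid_mm=centroid,  # type: ignore[arg-type]
                grid_shape=shape,  # type: ignore[arg-type]
            )
        )
    return out


def _overlap(
    cand: LesionCandidate, lesion_flat: np.ndarray, mode: str
) -> float:
    inter = np.intersect1d(cand.indices, lesion_flat, assume_unique=True).size
    if inter == 0:
        return 0.0
    if mode == "iou":
        union = cand.indices.size + lesion_flat.size - inter
        return inter / union
    if mode == "lesion_fraction":
        return inter / lesion_flat.size
    raise ValueError(f"unknown overlap mode {mode!r}")


def match_candidates(
    candidates: Sequence[LesionCandidate],
    lesions: LesionSet,
    min_overlap: float = 0.10,
    mode: str = "iou",
) -> MatchResult:
    """Greedy one-to-one matching in descending candidate confidence.

    A candidate claims the unmatched lesion with the highest overlap if
    that overlap reaches ``min_overlap``; candidates whose only sufficient
    overlap is with an already-matched lesion are discarded (neither TP nor
    FP — standard FROC handling of split detections); everything else is a
    false positive.  Unmatched lesions are misses.
    """
    for c in candidates:
        if c.grid_shape != lesions.labelmap.shape:
            raise ValueError("candidate and lesion grids differ")
    lesion_flats = {
        lab: np.flatnonzero(lesions.labelmap.ravel() == lab) for lab in lesions.labels
    }
    order = sorted(
        range(len(candidates)), key=lambda i: (-candidates[i].confidence, i)
    )
    hits: dict[int, int | None] = {lab: None for lab in lesion_flats}
    status = ["FP"] * len(candidates)
    overlaps: dict[tuple[int, int], float] = {}
    matched: set[int] = set()
    for i in order:
        eligible: list[tuple[float, int]] = []
        for lab, flat in lesion_flats.items():
            ov = _overlap(candidates[i], flat, mode)
            if ov > 0:
                overlaps[(i, lab)] = ov
            if ov >= min_overlap:
                eligible.append((ov, -lab))
        if not eligible:
            continue  # stays FP
        eligible.sort(reverse=True)  # highest overlap, ties to smaller label
        free = [(ov, lab) for ov, lab in eligible if -lab not in matched]
        if free:
            lab = -free[0][1]
            hits[lab] = i
            matched.add(lab)
            status[i] = "TP"
        else:
            status[i] = "discarded"
    return MatchResult(
        lesion_hits=hits, candidate_status=tuple(status), overlaps=overlaps
    )


def froc_curve(
    cohort: Sequence[PatientDetections],
    min_overlap: float = 0.10,
    mode: str = "iou",
) -> FrocResult:
    """Sweep the confidence threshold and build the FROC operating points.

    At each threshold only candidates with confidence >= threshold enter
    the matching.  Sensitivity is hit lesions over all lesions cohort-wide;
    the FP rate averages false positives over *all* patients, lesion-free
    ones included.

    Because the greedy matching processes candidates in descending
    confidence, its decisions for the top-k candidates are identical
    whether or not lower-confidence candidates are present; each patient is
    therefore matched once and the sweep reads cumulative TP/FP counts.
    """
    if len(cohort) < 1:
        raise ValueError("cohort must contain at least 1 patient")
    n_lesions = sum(p.lesions.n_lesions for p in cohort)
    if n_lesions == 0:
        raise ValueError("cohort has no lesions; sensitivity is undefined")
    # per patient: candidate confidences (desc) and cumulative TP/FP prefixes
    per_patient: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for p in cohort:
        order = sorted(
            range(len(p.candidates)), key=lambda i: (-p.candidates[i].confidence, i)
        )
        m = match_candidates(p.candidates, p.lesions, min_overlap=min_overlap, mode=mode)
        confs = np.array([p.candidates[i].confidence for i in order])
        statuses = [m.candidate_status[i] for i in order]
        cum_tp = np.cumsum([s == "TP" for s in statuses])
        cum_fp = np.cumsum([s == "FP" for s in statuses])
        per_patient.append((confs, cum_tp, cum_fp))
    confidences = sorted(
        {c.confidence for p in cohort for c in p.candidates}, reverse=True
    )
    thresholds: list[float] = []
    sens: list[float] = []
    fp: list[float] = []
    for t in confidences:
        tp_total = 0
        fp_total = 0
        for confs, cum_tp, cum_fp in per_patient:
            k = int(np.searchsorted(-confs, -t, side="right"))
            if k > 0:
                tp_total += int(cum_tp[k - 1])
                fp_total += int(cum_fp[k - 1])
        thresholds.append(t)
        sens.append(tp_total / n_lesions)
        fp.append(fp_total / len(cohort))
    points = FrocResult(
        thresholds=tuple(thresholds),
        sensitivities=tuple(sens),
        fp_per_patient=tuple(fp),
        pauc=0.0,
        n_patients=len(cohort),
        n_lesions=n_lesions,
    )
    return FrocResult(
        thresholds=points.thresholds,
        sensitivities=points.sensitivities,
        fp_per_patient=points.fp_per_patient,
        pauc=pauc(points),
        n_patients=points.n_patients,
        n_lesions=points.n_lesions,
    )


def pauc(froc: FrocResult, fp_window: tuple[float, float] = FP_WINDOW) -> float:
    """Trapezoidal pAUC of sensitivity over FP/patient on the linear axis.

    Linear interpolation between operating points (and from the implicit
    (0, 0) origin), right-constant extension past the last point.  The
    perfect detector scores the window width (2.4); bounds are [0, 2.4].
    """
    lo, hi = fp_window
    if not froc.fp_per_patient:
        warnings.warn("no operating points; pAUC = 0", stacklevel=2)
        return 0.0
    fps = np.asarray(froc.fp_per_patient)
    sens = np.asarray(froc.sensitivities)
    order = np.argsort(fps, kind="stable")
    fps, sens = fps[order], sens[order]
    # collapse duplicate FP rates to the best achievable sensitivity there
    uniq_fp, inverse = np.unique(fps, return_inverse=True)
    uniq_sens = np.zeros_like(uniq_fp)
    np.maximum.at(uniq_sens, inverse, sens)
    if uniq_fp[0] > 0:  # interpolate from the origin
        uniq_fp = np.concatenate([[0.0], uniq_fp])
        uniq_sens = np.concatenate([[0.0], uniq_sens])
    xs = np.unique(np.concatenate([[lo, hi], uniq_fp[(uniq_fp > lo) & (uniq_fp < hi)]]))
    ys = np.interp(xs, uniq_fp, uniq_sens)  # flat right-extension built in
    return float(np.trapezoid(ys, xs))


def bootstrap_pauc_ci(
    cohort: Sequence[PatientDetections],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    min_overlap: float = 0.10,
) -> tuple[float, float, int]:
    """Patient-level bootstrap percentile interval for the pAUC.

    Resamples patients with replacement; degenerate resamples without any
    lesion are redrawn and counted (third return value).
    """
    if len(cohort) < 10:
        raise ValueError("need at least 10 patients for a bootstrap CI")
    rng = np.random.default_rng(seed)
    values = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, len(cohort), size=len(cohort))
            sample = [cohort[i] for i in idx]
            if sum(p.lesions.n_lesions for p in sample) > 0:
                break
            n_redrawn += 1
        values[b] = froc_curve(sample, min_overlap=min_overlap).pauc
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi), n_redrawn
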