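"""FROC machinery against brute-force oracles.

The oracles re-derive the matching as an exhaustive lexicographic-optimal
assignment (candidates in descending confidence prefer being matched, then
higher overlap), the curve as an explicit per-threshold re-evaluation, and
the pAUC as a hand-rolled trapezoid over segment intersections — all
independent of the library's incremental implementation.
"""

import itertools

import numpy as np
import pytest

from diagqm import (
    CandidateParams,
    FrocResult,
    Heatmap,
    LesionSet,
    PatientDetections,
    bootstrap_pauc_ci,
    extract_candidates,
    froc_curve,
    match_candidates,
    pauc,
)
from diagqm.froc import LesionCandidate

GRID = (6, 6, 2)


def _candidate(voxels, confidence):
    flat = np.ravel_multi_index(np.array(voxels).T, GRID)
    return LesionCandidate(
        indices=np.asarray(flat), confidence=confidence,
        centroid_mm=(0, 0, 0), grid_shape=GRID,
    )


def _lesionset(blocks):
    lm = np.zeros(GRID, dtype=np.int16)
    for label, voxels in enumerate(blocks, start=1):
        for v in voxels:
            lm[v] = label
    return LesionSet(lm)


def _iou(cand, lesion_voxels):
    a = set(cand.indices.tolist())
    b = set(np.ravel_multi_index(np.array(lesion_voxels).T, GRID).tolist())
    inter = len(a & b)
    return inter / len(a | b) if inter else 0.0


def _oracle_match(candidates, lesion_blocks, min_overlap=0.10):
    """Exhaustive assignment oracle.

    Enumerates every one-to-one candidate->lesion assignment where each
    matched pair overlaps at least ``min_overlap``, and picks the
    lexicographically best one over candidates in descending confidence
    (being matched beats not; higher overlap beats lower).  Unmatched
    candidates are discarded when some lesion was eligible, FP otherwise.
    """
    order = sorted(range(len(candidates)), key=lambda i: (-candidates[i].confidence, i))
    n_les = len(lesion_blocks)
    best_key, best_assign = None, None
    for perm in itertools.product(range(-1, n_les), repeat=len(candidates)):
        used = [p for p in perm if p >= 0]
        if len(used) != len(set(used)):
            continue
        ok = all(
            p < 0 or _iou(candidates[i], lesion_blocks[p]) >= min_overlap
            for i, p in enumerate(perm)
        )
        if not ok:
            continue
        key = tuple(
            (1, _iou(candidates[i], lesion_blocks[perm[i]])) if perm[i] >= 0 else (0, 0.0)
            for i in order
        )
        if best_key is None or key > best_key:
            best_key, best_assign = key, perm
    statuses = []
    for i, p in enumerate(best_assign):
        if p >= 0:
            statuses.append("TP")
        elif any(_iou(candidates[i], b) >= min_overlap for b in lesion_blocks):
            statuses.append("discarded")
        else:
            statuses.append("FP")
    return best_assign, tuple(statuses)


def _oracle_curve(patients, min_overlap=0.10):
    """Exhaustive threshold sweep using the assignment oracle."""
    confs = sorted(
        {c.confidence for cands, _ in patients for c in cands}, reverse=True
    )
    n_lesions = sum(len(blocks) for _, blocks in patients)
    points = []
    for t in confs:
        tp = fp = 0
        for cands, blocks in patients:
            kept = [c for c in cands if c.confidence >= t]
            _, statuses = _oracle_match(kept, blocks, min_overlap)
            tp += statuses.count("TP")
            fp += statuses.count("FP")
        points.append((t, tp / n_lesions, fp / len(patients)))
    return points


class TestExtractCandidates:
    def test_all_zero_heatmap_gives_no_candidates(self):
        heat = Heatmap(np.zeros((16, 16, 4)))
        assert extract_candidates(heat) == []

    def test_floor_above_global_max_gives_no_candidates(self):
        heat = Heatmap(np.full((16, 16, 4), 0.3))
        params = CandidateParams(floor=0.5)
        assert extract_candidates(heat, params) == []

    def test_two_disjoint_blobs_recovered_with_level_set_regions(self):
        x = np.arange(32)
        blob_a = 0.9 * np.exp(-((x[:, None] - 8) ** 2 + (x[None, :] - 8) ** 2) / 8.0)
        blob_b = 0.5 * np.exp(-((x[:, None] - 24) ** 2 + (x[None, :] - 24) ** 2) / 8.0)
        field = np.maximum(blob_a, blob_b)[:, :, None]
        heat = Heatmap(field)
        cands = extract_candidates(heat)
        assert len(cands) == 2
        assert cands[0].confidence == pytest.approx(0.9)
        assert cands[1].confidence == pytest.approx(0.5)
        # regions equal the 0.4-relative level sets of each blob
        lvl_a = np.flatnonzero((blob_a >= 0.4 * 0.9)[:, :, None])
        lvl_b = np.flatnonzero((blob_b >= 0.4 * 0.5)[:, :, None])
        assert set(cands[0].indices) == set(lvl_a)
        assert set(cands[1].indices) == set(lvl_b)

    def test_min_volume_drops_speckles(self):
        field = np.zeros((16, 16, 2))
        field[4, 4, 0] = 0.9  # single-voxel speck
        heat = Heatmap(field)
        assert extract_candidates(heat, CandidateParams(min_volume=3)) == []
        assert len(extract_candidates(heat, CandidateParams(min_volume=1))) == 1

    def test_max_candidates_cap(self):
        field = np.zeros((32, 32, 1))
        for k in range(6):
            field[2 + 5 * k : 5 + 5 * k, 2:5, 0] = 0.9 - 0.1 * k
        heat = Heatmap(field)
        assert len(extract_candidates(heat, CandidateParams(max_candidates=3))) == 3


class TestMatchCandidates:
    def test_perfect_overlap_single_pair(self):
        voxels = [(1, 1, 0), (1, 2, 0), (2, 1, 0)]
        cand = _candidate(voxels, 0.8)
        lesions = _lesionset([voxels])
        m = match_candidates([cand], lesions)
        assert m.n_tp == 1 and m.n_fp == 0 and m.n_missed == 0

    def test_overlap_below_threshold_is_fp_and_miss(self):
        lesion = [(0, 0, 0), (0, 1, 0), (1, 0, 0), (1, 1, 0)] + [
            (2, y, 0) for y in range(4)
        ] + [(3, y, 0) for y in range(4)]
        cand_voxels = [(0, 0, 0)] + [(4, y, 1) for y in range(6)] + [
            (5, y, 1) for y in range(6)
        ]
        cand = _candidate(cand_voxels, 0.9)
        lesions = _lesionset([lesion])
        m = match_candidates([cand], lesions, min_overlap=0.10)
        # IoU = 1 / (12 + 13 - 1) = 0.042 < 0.10
        assert m.n_tp == 0 and m.n_fp == 1 and m.n_missed == 1

    def test_duplicate_hit_on_matched_lesion_is_discarded(self):
        lesion = [(1, y, 0) for y in range(4)]
        c1 = _candidate(lesion, 0.9)
        c2 = _candidate(lesion[:2], 0.7)
        m = match_candidates([c1, c2], _lesionset([lesion]))
        assert m.candidate_status == ("TP", "discarded")

    def test_three_candidates_two_lesions_matches_assignment_oracle(self):
        lesion_a = [(0, y, 0) for y in range(4)]
        lesion_b = [(4, y, 0) for y in range(4)]
        cands = [
            _candidate(lesion_a[:3] + [(1, 0, 0)], 0.9),  # strong on A
            _candidate(lesion_a[1:] + [(1, 1, 0)], 0.8),  # also on A
            _candidate(lesion_b[:2] + [(5, 0, 0), (5, 1, 0)], 0.7),  # on B
        ]
        blocks = [lesion_a, lesion_b]
        m = match_candidates(cands, _lesionset(blocks))
        _, oracle_status = _oracle_match(cands, blocks)
        assert m.candidate_status == oracle_status

    def test_random_instances_match_oracle(self, rng):
        """Randomised equivalence with the exhaustive assignment oracle."""
        for trial in range(30):
            n_les = int(rng.integers(1, 4))
            n_cand = int(rng.integers(0, 5))
            blocks, occupied = [], set()
            for _ in range(n_les):
                x, y = int(rng.integers(0, 4)), int(rng.integers(0, 4))
                block = [(x + dx, y + dy, 0) for dx in range(2) for dy in range(2)]
                if occupied & set(block):
                    continue
                occupied |= set(block)
                blocks.append(block)
            if not blocks:
                continue
            cands = []
            for _ in range(n_cand):
                x, y = int(rng.integers(0, 4)), int(rng.integers(0, 4))
                z = int(rng.integers(0, 2))
                vox = [(x + dx, y + dy, z) for dx in range(2) for dy in range(2)]
                cands.append(_candidate(vox, float(rng.integers(1, 10)) / 10))
            m = match_candidates(cands, _lesionset(blocks))
            _, oracle_status = _oracle_match(cands, blocks)
            assert m.candidate_status == oracle_status, f"trial {trial}"


def _random_cohort(rng, n_patients):
    patients = []
    for _ in range(n_patients):
        n_les = int(rng.integers(0, 3))
        blocks, occupied = [], set()
        for _ in range(n_les):
            x, y = int(rng.integers(0, 4)), int(rng.integers(0, 4))
            block = [(x + dx, y + dy, 0) for dx in range(2) for dy in range(2)]
            if occupied & set(block):
                continue
            occupied |= set(block)
            blocks.append(block)
        cands = []
        for _ in range(int(rng.integers(0, 4))):
            x, y = int(rng.integers(0, 4)), int(rng.integers(0, 4))
            z = int(rng.integers(0, 2))
            vox = [(x + dx, y + dy, z) for dx in range(2) for dy in range(2)]
            cands.append(_candidate(vox, float(rng.integers(1, 10)) / 10))
        patients.append((cands, blocks))
    if not any(blocks for _, blocks in patients):
        patients[0] = (patients[0][0], [[(0, 0, 0), (0, 1, 0), (1, 0, 0), (1, 1, 0)]])
    return patients


def _to_detections(patients):
    return [
        PatientDetections(candidates=tuple(cands), lesions=_lesionset(blocks))
        for cands, blocks in patients
    ]


class TestFrocCurve:
    def test_perfect_detector_full_sensitivity_at_zero_fp(self):
        lesion = [(2, y, 0) for y in range(3)]
        patients = [
            PatientDetections(
                candidates=(_candidate(lesion, 1.0),), lesions=_lesionset([lesion])
            )
            for _ in range(3)
        ]
        res = froc_curve(patients)
        assert res.sensitivities == (1.0,)
        assert res.fp_per_patient == (0.0,)
        assert res.pauc == pytest.approx(2.4)

    def test_two_patient_toy_matches_exhaustive_threshold_oracle(self, rng):
        patients = _random_cohort(rng, 2)
        res = froc_curve(_to_detections(patients))
        oracle = _oracle_curve(patients)
        assert len(res.thresholds) == len(oracle)
        for (t, s, f), (to, so, fo) in zip(
            zip(res.thresholds, res.sensitivities, res.fp_per_patient), oracle
        ):
            assert t == pytest.approx(to)
            assert s == pytest.approx(so)
            assert f == pytest.approx(fo)

    def test_monotone_in_threshold(self, rng):
        for seed in range(5):
            patients = _random_cohort(np.random.default_rng(seed), 4)
            res = froc_curve(_to_detections(patients))
            assert all(
                a <= b + 1e-12
                for a, b in zip(res.sensitivities[:-1], res.sensitivities[1:])
            )
            assert all(
                a <= b + 1e-12
                for a, b in zip(res.fp_per_patient[:-1], res.fp_per_patient[1:])
            )

    def test_lesion_free_cohort_rejected(self):
        p = PatientDetections(candidates=(), lesions=_lesionset([]))
        with pytest.raises(ValueError):
            froc_curve([p])


class TestPauc:
    def test_constant_sensitivity_scales_window_width(self):
        full = FrocResult((1.0,), (1.0,), (0.0,), 0.0)
        half = FrocResult((1.0,), (0.5,), (0.0,), 0.0)
        assert pauc(full) == pytest.approx(2.4)
        assert pauc(half) == pytest.approx(1.2)

    def test_piecewise_linear_toy_matches_hand_integration(self):
        res = FrocResult(
            thresholds=(0.9, 0.5, 0.2),
            sensitivities=(0.2, 0.6, 0.9),
            fp_per_patient=(0.5, 1.5, 3.0),
            pauc=0.0,
        )
        # segments: [0.1,0.5] from (0,0)-(0.5,0.2); [0.5,1.5]; [1.5,2.5]
        expected = (0.04 + 0.2) / 2 * 0.4 + (0.2 + 0.6) / 2 * 1.0 + (0.6 + 0.8) / 2 * 1.0
        assert pauc(res) == pytest.approx(expected)

    def test_oracle_equivalence_on_small_cohorts(self, rng):
        """Curve + pAUC equal the exhaustive oracle on tiny cohorts."""
        for seed in range(8):
            patients = _random_cohort(np.random.default_rng(100 + seed), 4)
            res = froc_curve(_to_detections(patients))
            oracle_pts = _oracle_curve(patients)
            fps = [f for _, _, f in oracle_pts]
            sens = [s for _, s, _ in oracle_pts]
            assert list(res.fp_per_patient) == pytest.approx(fps)
            assert list(res.sensitivities) == pytest.approx(sens)
            oracle_res = FrocResult(
                tuple(t for t, _, _ in oracle_pts), tuple(sens), tuple(fps), 0.0
            )
            assert res.pauc == pytest.approx(pauc(oracle_res))

    def test_empty_curve_warns_and_returns_zero(self):
        res = FrocResult((), (), (), 0.0)
        with pytest.warns(UserWarning):
            assert pauc(res) == 0.0


class TestBootstrap:
    def test_identical_patients_give_zero_width_ci(self):
        lesion = [(2, y, 0) for y in range(3)]
        p = PatientDetections(
            candidates=(_candidate(lesion, 0.8),), lesions=_lesionset([lesion])
        )
        lo, hi, _ = bootstrap_pauc_ci([p] * 12, n_boot=50, seed=0)
        assert lo == hi

    def test_ci_contains_point_estimate(self, rng):
        patients = _to_detections(_random_cohort(rng, 12))
        point = froc_curve(patients).pauc
        lo, hi, _ = bootstrap_pauc_ci(patients, n_boot=200, seed=1)
        assert lo <= point <= hi

    def test_coverage_on_generative_cohort(self):
        """Nested Monte-Carlo: percentile CI covers the generative-model
        pAUC at roughly the nominal rate (reduced n_boot)."""

        def sample_patient(rng):
            lesion = [(1, y, 0) for y in range(3)]
            cands = []
            if rng.random() < 0.8:
                cands.append(_candidate(lesion, float(rng.integers(5, 10)) / 10))
            for _ in range(rng.poisson(1.0)):
                vox = [(4, y, 1) for y in range(3)]
                cands.append(_candidate(vox, float(rng.integers(1, 6)) / 10))
            return PatientDetections(
                candidates=tuple(cands), lesions=_lesionset([lesion])
            )

        rng = np.random.default_rng(7)
        truth = froc_curve([sample_patient(rng) for _ in range(3000)]).pauc
        covered = 0
        reps = 40
        for _ in range(reps):
            cohort = [sample_patient(rng) for _ in range(40)]
            lo, hi, _ = bootstrap_pauc_ci(cohort, n_boot=80, seed=int(rng.integers(2**31)))
            covered += lo - 0.005 <= truth <= hi + 0.005
        assert covered / reps >= 0.85
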