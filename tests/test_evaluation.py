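import numpy as np
import pytest
from scipy import sparse

from comseg import CellAssignment, CellProfileMatrix, UNASSIGNED
from comseg import evaluate as ev
from comseg.datatypes import NucleusLandmarks

from helpers import make_cloud, set_metrics


def assignment(ids, cells):
    cells = np.asarray(cells)
    return CellAssignment(
        molecule_ids=np.asarray(ids),
        cell_ids=cells,
        provenance=np.where(cells != 0, "graph", "unassigned").astype(object),
    )


def truth(ids, cells, scope=None):
    cells = np.asarray(cells)
    if scope is None:
        scope = np.unique(cells[cells > 0])
    return ev.GroundTruth(
        molecule_ids=np.asarray(ids), true_cell_ids=cells, in_scope_cells=np.asarray(scope)
    )


class TestMatching:
    def test_identical_assignment_identity_matching(self):
        gt = truth([1, 2, 3], [1, 1, 2])
        pred = assignment([1, 2, 3], [1, 1, 2])
        assert ev.match_cells(gt, pred, "by_overlap") == {1: 1, 2: 2}

    def test_max_overlap_wins(self):
        gt = truth([1, 2, 3], [7, 7, 7])
        pred = assignment([1, 2, 3], [4, 4, 5])
        assert ev.match_cells(gt, pred, "by_overlap") == {7: 4}

    def test_matches_contingency_oracle(self):
        rng = np.random.default_rng(5)
        n = 300
        ids = np.arange(n)
        gt_cells = rng.integers(1, 8, n)
        pred_cells = rng.integers(1, 10, n)
        gt = truth(ids, gt_cells)
        pred = assignment(ids, pred_cells)
        got = ev.match_cells(gt, pred, "by_overlap")
        for c in np.unique(gt_cells):
            overlaps = {
                p: np.sum((gt_cells == c) & (pred_cells == p)) for p in np.unique(pred_cells)
            }
            best = max(overlaps.values())
            winners = [p for p, v in overlaps.items() if v == best]
            assert got[c] == min(winners)


class TestMetrics:
    def test_perfect_prediction(self):
        gt = truth([1, 2, 3, 4], [1, 1, 2, 2])
        rep = ev.jaccard_wa_ms(gt, assignment([1, 2, 3, 4], [1, 1, 2, 2]))
        assert rep.mean_jaccard == 1.0
        assert rep.mean_wa == 0.0
        assert rep.mean_ms == 0.0

    def test_worked_example(self):
        # X = {a,b,c}, Y = {b,c,d}: J = 2/4, WA = 1/3, MS = 1/3
        gt = truth([1, 2, 3, 4], [1, 1, 1, 0], scope=[1])
        rep = ev.jaccard_wa_ms(gt, assignment([1, 2, 3, 4], [0, 1, 1, 1]))
        row = rep.per_cell.iloc[0]
        assert row.jaccard == pytest.approx(0.5)
        assert row.wa == pytest.approx(1 / 3)
        assert row.ms == pytest.approx(1 / 3)

    def test_empty_prediction_scores(self):
        gt = truth([1, 2], [1, 1])
        rep = ev.jaccard_wa_ms(gt, assignment([1, 2], [0, 0]))
        assert rep.per_cell.iloc[0].jaccard == 0.0
        assert np.isnan(rep.per_cell.iloc[0].wa)  # excluded from WA mean
        assert rep.per_cell.iloc[0].ms == 1.0

    def test_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(8)
        n = 500
        ids = np.arange(n)
        gt_cells = rng.integers(1, 21, n)
        pred_cells = rng.integers(0, 21, n)
        gt = truth(ids, gt_cells)
        rep = ev.jaccard_wa_ms(gt, assignment(ids, pred_cells))
        js, was, mss = [], [], []
        for c in np.unique(gt_cells):
            x = set(ids[gt_cells == c].tolist())
            y = set(ids[pred_cells == c].tolist())
            j, wa, ms = set_metrics(x, y)
            js.append(j)
            mss.append(ms)
            if y:
                was.append(wa)
        assert rep.mean_jaccard == pytest.approx(np.mean(js))
        assert rep.mean_wa == pytest.approx(np.mean(was))
        assert rep.mean_ms == pytest.approx(np.mean(mss))

    def test_jaccard_one_iff_no_errors(self):
        rng = np.random.default_rng(9)
        ids = np.arange(100)
        gt_cells = rng.integers(1, 6, 100)
        pred_cells = gt_cells.copy()
        flip = rng.random(100) < 0.3
        pred_cells[flip] = rng.integers(1, 6, flip.sum())
        rep = ev.jaccard_wa_ms(truth(ids, gt_cells), assignment(ids, pred_cells))
        for _, row in rep.per_cell.iterrows():
            perfect = row.jaccard == 1.0
            assert perfect == (row.wa == 0.0 and row.ms == 0.0)


class TestWatershed:
    def test_nearest_centroid_wins(self):
        cloud = make_cloud([[1, 0], [9, 0]], [0, 0])
        lm = NucleusLandmarks(nucleus_ids=[1, 2], centroids=np.array([[0.0, 0, 0], [10.0, 0, 0]]))
        out = ev.watershed_baseline(cloud, lm, max_distance=20.0)
        assert out.cell_ids.tolist() == [1, 2]

    def test_max_distance_cutoff(self):
        cloud = make_cloud([[100, 0]], [0])
        lm = NucleusLandmarks(nucleus_ids=[1], centroids=np.zeros((1, 3)))
        out = ev.watershed_baseline(cloud, lm, max_distance=10.0)
        assert out.cell_ids[0] == UNASSIGNED

    def test_raster_distance_is_to_region_not_centroid(self):
        # nucleus 1 is a wide region whose edge is closer than nucleus 2's center
        lab = np.zeros((20, 40), dtype=np.int32)
        lab[8:12, 0:20] = 1
        lab[10, 35] = 2
        lm = NucleusLandmarks.from_label_image(lab, (1.0, 1.0, 1.0))
        cloud = make_cloud([[24.0, 10.0]], [0])  # 4 px from region 1 edge, 11 from nucleus 2
        out = ev.watershed_baseline(cloud, lm, max_distance=50.0)
        assert out.cell_ids[0] == 1

    def test_matches_brute_force_nearest_region(self):
        rng = np.random.default_rng(10)
        lab = np.zeros((30, 30), dtype=np.int32)
        lab[5:9, 5:9] = 1
        lab[20:24, 18:22] = 2
        lab[3:6, 22:26] = 3
        lm = NucleusLandmarks.from_label_image(lab, (0.5, 0.5, 1.0))
        pts = rng.uniform(0, 15, (50, 2))
        cloud = make_cloud(pts, [0] * 50)
        out = ev.watershed_baseline(cloud, lm, max_distance=100.0)
        yy, xx = np.nonzero(lab[:, :] if lab.ndim == 2 else lab[0])
        vox = np.column_stack([(xx + 0.5) * 0.5, (yy + 0.5) * 0.5])
        vlab = lab[yy, xx]
        for i in range(50):
            d = np.sqrt(((vox - pts[i]) ** 2).sum(axis=1))
            assert out.cell_ids[i] == vlab[np.argmin(d)]


class TestCellTypeCall:
    def _profiles(self, counts, cell_ids=None):
        counts = np.asarray(counts)
        if cell_ids is None:
            cell_ids = np.arange(1, len(counts) + 1)
        return CellProfileMatrix(
            counts=sparse.csr_matrix(counts),
            cell_ids=cell_ids,
            gene_names=[f"g{i}" for i in range(counts.shape[1])],
        )

    def test_proportional_vector_distance_zero(self):
        ref = np.array([[10.0, 0.0, 0.0], [0.0, 10.0, 0.0]])
        prof = self._profiles([[30, 0, 0]])
        calls = ev.cell_type_call(prof, ref, normalization="log")
        assert calls.iloc[0].type_index == 0
        assert calls.iloc[0].cosine_distance == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_vector_ties_to_smallest_type(self):
        ref = np.array([[10.0, 0.0, 0.0], [0.0, 10.0, 0.0]])
        prof = self._profiles([[0, 0, 30]])
        calls = ev.cell_type_call(prof, ref, normalization="log")
        assert calls.iloc[0].type_index == 0
        assert calls.iloc[0].cosine_distance == pytest.approx(1.0)

    def test_min_molecule_filter_is_strict(self):
        ref = np.eye(2) * 10
        prof = self._profiles([[5, 0], [6, 0]])
        calls = ev.cell_type_call(prof, ref, normalization="log", min_molecules=5)
        assert calls.cell_id.tolist() == [2]  # exactly 5 molecules excluded

    def test_matches_independent_cosine_oracle(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 20, (10, 4))
        counts[:, 0] += 3  # ensure > 5 molecules everywhere
        ref = rng.uniform(0.1, 10, (3, 4))
        prof = self._profiles(counts)
        calls = ev.cell_type_call(prof, ref, normalization="log")

        def lognorm(m):
            tot = m.sum(axis=1)
            target = np.median(tot)
            return np.log1p(m * (target / tot)[:, None])

        x = lognorm(counts.astype(float))
        r = lognorm(ref)
        for _, row in calls.iterrows():
            v = x[int(row.cell_id) - 1]
            d = [1 - v @ r[t] / (np.linalg.norm(v) * np.linalg.norm(r[t])) for t in range(3)]
            assert row.type_index == int(np.argmin(d))
            assert row.cosine_distance == pytest.approx(min(d))

    def test_pearson_normalization_runs(self):
        rng = np.random.default_rng(12)
        counts = rng.integers(0, 15, (6, 5)) + 2
        ref = rng.uniform(1, 10, (2, 5))
        calls = ev.cell_type_call(self._profiles(counts), ref, normalization="pearson")
        assert len(calls) == 6


class TestGroundTruthFilter:
    def test_cell_without_nucleus_excluded(self):
        cell = np.zeros((10, 10), dtype=int)
        cell[0:5, 0:5] = 1
        nuc = np.zeros_like(cell)
        assert ev.gt_filter_one_nucleus(cell, nuc).tolist() == []

    def test_cell_with_two_strong_nuclei_excluded(self):
        cell = np.ones((10, 10), dtype=int)
        nuc = np.zeros_like(cell)
        nuc[0:5, 0:5] = 1  # 25 px overlap
        nuc[5:10, 5:10] = 2  # 25 px overlap
        assert ev.gt_filter_one_nucleus(cell, nuc).tolist() == []

    def test_weak_second_overlap_tolerated(self):
        cell = np.ones((10, 10), dtype=int)
        nuc = np.zeros_like(cell)
        nuc[0:5, 0:5] = 1  # 25 px: counts
        nuc[9, 0:5] = 2  # 5 px: below the 20 px threshold
        assert ev.gt_filter_one_nucleus(cell, nuc).tolist() == [1]

    def test_hand_counted_fixture(self):
        cell = np.zeros((12, 12), dtype=int)
        cell[0:6, :] = 1
        cell[6:12, :] = 2
        nuc = np.zeros_like(cell)
        nuc[2:5, 2:10] = 1  # 24 px in cell 1
        nuc[7:9, 1:11] = 2  # 20 px in cell 2
        nuc[5, 0:2] = 3  # 2 px in cell 1: weak
        kept = ev.gt_filter_one_nucleus(cell, nuc, min_overlap_px=20)
        assert kept.tolist() == [1, 2]
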