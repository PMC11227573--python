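"""Benchmarking a molecule-to-cell assignment against ground truth.

Per ground-truth cell c with true molecule set X_c matched to a
predicted set Y_c:

    J_c  = |X_c ∩ Y_c| / |X_c ∪ Y_c|          (Jaccard index)
    WA_c = |Y_c \\ X_c| / |Y_c|               (wrongly associated, FDR)
    MS_c = |X_c \\ Y_c| / |X_c|               (missing, FNR)

Means are unweighted over the in-scope cells (cells with a nucleus and
a non-empty true set).  Cells with an empty prediction are excluded
from the WA mean (its denominator vanishes) and score MS = 1.

Also provided: the nearest-nucleus ("watershed") baseline — equivalent
to a Voronoi tessellation seeded by the nucleus regions with a maximum
distance cut-off — cosine cell-type calling against reference
centroids, and the exactly-one-nucleus filter used to build ground
truth from paired cell/nucleus segmentations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .datatypes import (
    UNASSIGNED,
    CellAssignment,
    CellProfileMatrix,
    NucleusLandmarks,
    RNAPointCloud,
    ValidationError,
)


@dataclass
class GroundTruth:
    """True molecule-to-cell mapping with the cells that are in scope."""

    molecule_ids: np.ndarray
    true_cell_ids: np.ndarray
    in_scope_cells: np.ndarray  # cells evaluated (e.g., cells with a nucleus)

    @classmethod
    def from_simulation(cls, sim) -> "GroundTruth":
        scope = sim.cell_ids[sim.has_nucleus]
        return cls(
            molecule_ids=sim.cloud.ids.copy(),
            true_cell_ids=sim.true_cell_ids.copy(),
            in_scope_cells=np.asarray(scope),
        )

    def sets(self) -> dict[int, set[int]]:
        out: dict[int, set[int]] = {}
        for m, c in zip(self.molecule_ids, self.true_cell_ids):
            out.setdefault(int(c), set()).add(int(m))
        return out


@dataclass
class EvaluationReport:
    """Per-cell and mean segmentation metrics."""

    per_cell: pd.DataFrame
    mean_jaccard: float
    mean_wa: float
    mean_ms: float
    matching: dict[int, int] = field(default_factory=dict)
    cell_type_accuracy: float | None = None


def _pred_sets(pred: CellAssignment) -> dict[int, set[int]]:
    out: dict[int, set[int]] = {}
    for m, c in zip(pred.molecule_ids, pred.cell_ids):
        if c != UNASSIGNED:
            out.setdefault(int(c), set()).add(int(m))
    return out


def match_cells(
    gt: GroundTruth, pred: CellAssignment, mode: str = "by_nucleus"
) -> dict[int, int]:
    """Match every in-scope ground-truth cell to a predicted cell.

    ``by_nucleus``: identity on cell ids (simulations share nucleus
    labels between truth and prediction).  ``by_overlap``: the
    predicted cell with the most molecules in common, ties toward the
    smaller predicted id; cells with no overlapping prediction map to
    the background sentinel.
    """
    if mode == "by_nucleus":
        return {int(c): int(c) for c in gt.in_scope_cells}
    if mode != "by_overlap":
        raise ValidationError(f"unknown matching mode {mode!r}")
    gt_sets = gt.sets()
    pred_sets = _pred_sets(pred)
    matching: dict[int, int] = {}
    for c in gt.in_scope_cells:
        x = gt_sets.get(int(c), set())
        best_p, best_n = UNASSIGNED, 0
        for p in sorted(pred_sets):
            n = len(x & pred_sets[p])
            if n > best_n:
                best_p, best_n = p, n
        matching[int(c)] = best_p
    return matching


def jaccard_wa_ms(
    gt: GroundTruth, pred: CellAssignment, matching: dict[int, int] | None = None
) -> EvaluationReport:
    """Compute J, WA and MS per in-scope cell and their unweighted means."""
    if matching is None:
        matching = match_cells(gt, pred, mode="by_nucleus")
    gt_sets = gt.sets()
    pred_sets = _pred_sets(pred)
    rows = []
    for c in gt.in_scope_cells:
        x = gt_sets.get(int(c), set())
        if not x:
            continue  # cells with an empty true set are out of scope
        p = matching.get(int(c), UNASSIGNED)
        y = pred_sets.get(int(p), set())
        inter = len(x & y)
        union = len(x | y)
        j = inter / union if union else 0.0
        wa = (len(y - x) / len(y)) if y else np.nan
        ms = len(x - y) / len(x)
        rows.append(
            {"cell_id": int(c), "matched_to": int(p), "jaccard": j, "wa": wa, "ms": ms,
             "n_true": len(x), "n_pred": len(y)}
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValidationError("no in-scope cell with molecules to evaluate")
    return EvaluationReport(
        per_cell=df,
        mean_jaccard=float(df["jaccard"].mean()),
        mean_wa=float(df["wa"].mean(skipna=True)),
        mean_ms=float(df["ms"].mean()),
        matching=matching,
    )


def watershed_baseline(
    cloud: RNAPointCloud,
    landmarks: NucleusLandmarks,
    max_distance: float,
    z_anisotropy_factor: float = 1.0,
) -> CellAssignment:
    """Nearest-nucleus assignment with a distance cut-off.

    Distance is to the closest voxel of the nucleus region when a label
    image is available, else to the centroid.  Equivalent to a Voronoi
    tessellation seeded by the nuclei, so it implicitly assumes convex
    cells.
    """
    if len(landmarks) == 0:
        raise ValidationError("watershed baseline needs at least one nucleus")
    pos = cloud.scaled_positions(z_anisotropy_factor)
    if landmarks.label_image is not None:
        lab = landmarks.label_image
        vx, vy, vz = landmarks.voxel_size
        zz, yy, xx = np.nonzero(lab)
        ref = np.column_stack(
            [(xx + 0.5) * vx, (yy + 0.5) * vy, (zz + 0.5) * vz * z_anisotropy_factor]
        )
        ref_labels = lab[zz, yy, xx]
    else:
        ref = landmarks.centroids * np.array([1.0, 1.0, z_anisotropy_factor])
        ref_labels = landmarks.nucleus_ids
    tree = cKDTree(ref)
    dist, idx = tree.query(pos)
    cell_ids = np.where(dist <= max_distance, ref_labels[idx], UNASSIGNED).astype(np.int64)
    provenance = np.where(cell_ids != UNASSIGNED, "graph", "unassigned").astype(object)
    return CellAssignment(
        molecule_ids=cloud.ids,
        cell_ids=cell_ids,
        provenance=provenance,
        cell_centroids={int(i): c for i, c in zip(landmarks.nucleus_ids, landmarks.centroids)},
    )


def _lognorm(matrix: np.ndarray) -> np.ndarray:
    totals = matrix.sum(axis=1)
    target = np.median(totals[totals > 0]) if np.any(totals > 0) else 1.0
    scale = np.divide(target, totals, out=np.ones_like(totals, dtype=float), where=totals > 0)
    return np.log1p(matrix * scale[:, None])


def _pearson_residuals(matrix: np.ndarray, theta: float = 100.0) -> np.ndarray:
    """Analytic Pearson residuals of a count matrix under a NB null with
    cell and gene factors — a variance-stabilizing normalization."""
    total = matrix.sum()
    if total == 0:
        return matrix.astype(float)
    mu = np.outer(matrix.sum(axis=1), matrix.sum(axis=0)) / total
    resid = (matrix - mu) / np.sqrt(mu + mu**2 / theta + 1e-12)
    n = matrix.shape[0]
    return np.clip(resid, -np.sqrt(n), np.sqrt(n))


def cell_type_call(
    profiles: CellProfileMatrix,
    reference_centroids: np.ndarray,
    type_names: list[str] | None = None,
    normalization: str = "log",
    min_molecules: int = 5,
) -> pd.DataFrame:
    """Classify each cell to the nearest reference centroid by cosine
    distance.

    Both the cell profiles and the (type × gene) reference centroids
    are normalized by the selected scheme (``"log"`` total-count +
    log1p, or ``"pearson"`` residuals).  Only cells with strictly more
    than ``min_molecules`` molecules are called; cells reducing to a
    zero vector are excluded.  Cosine ties break toward the smallest
    type index.
    """
    counts = profiles.to_dense().astype(float)
    ref = np.asarray(reference_centroids, dtype=float)
    if ref.shape[1] != counts.shape[1]:
        raise ValidationError("reference centroids must cover the profile genes")
    norm = {"log": _lognorm, "pearson": _pearson_residuals}.get(normalization)
    if norm is None:
        raise ValidationError(f"unknown normalization {normalization!r}")
    x = norm(counts)
    r = norm(ref)
    rows = []
    r_norms = np.linalg.norm(r, axis=1)
    for i, cell in enumerate(profiles.cell_ids):
        if counts[i].sum() <= min_molecules:
            continue
        v = x[i]
        nv = np.linalg.norm(v)
        if nv == 0:
            continue
        with np.errstate(invalid="ignore"):
            cos = 1.0 - (r @ v) / (r_norms * nv)
        cos = np.where(np.isfinite(cos), cos, 1.0)
        t = int(np.argmin(cos))  # argmin takes the smallest index on ties
        rows.append(
            {
                "cell_id": int(cell),
                "type_index": t,
                "type": type_names[t] if type_names else t,
                "cosine_distance": float(cos[t]),
            }
        )
    return pd.DataFrame(rows)


def gt_filter_one_nucleus(
    cell_mask: np.ndarray, nucleus_mask: np.ndarray, min_overlap_px: int = 20
) -> np.ndarray:
    """Cells overlapping exactly one nucleus by at least ``min_overlap_px``
    pixels — the high-confidence set used as automatic ground truth."""
    cell = np.asarray(cell_mask).ravel()
    nuc = np.asarray(nucleus_mask).ravel()
    if cell.shape != nuc.shape:
        raise ValidationError("cell and nucleus masks must be congruent")
    both = (cell > 0) & (nuc > 0)
    pairs, counts = np.unique(
        np.column_stack([cell[both], nuc[both]]), axis=0, return_counts=True
    )
    strong = pairs[counts >= min_overlap_px]
    cells, n_nuclei = np.unique(strong[:, 0], return_counts=True)
    return cells[n_nuclei == 1]
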