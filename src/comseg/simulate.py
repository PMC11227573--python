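"""Synthetic ground-truth tissue generation.

Two families of geometry are produced: regular patterns (checkerboard
grids of 15 µm square cells, interlocking L-shaped cells made of four
such squares) and grown tissue, where cells expand from nucleus seeds
at random per-cell speeds inside an allowed mask with optional lacunae
(cell-free regions such as airways).  Rasters use a 0.150 µm pixel,
matching a typical 60x objective; nuclei are discs/spheres of 3.75 µm
radius.  A fraction of nuclei can be dropped to mimic nuclei lost when
the section is cut, while their cells and RNAs remain.

RNA content: each cell draws a cell type and an expression profile
(constant, negative-binomial around a type mean, or a row sampled from
a user-supplied reference matrix), counts are multiplied by a capture
scale factor — 3 by default, compensating the ~30 % capture rate of
droplet scRNA-seq relative to the near-100 % sensitivity of smFISH —
and molecules are placed uniformly over the cell's voxels.  Everything
is reproducible from (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .datatypes import NucleusLandmarks, RNAPointCloud, ValidationError

DEFAULT_PIXEL_UM = 0.150
DEFAULT_CELL_UM = 15.0
DEFAULT_NUCLEUS_RADIUS_UM = 3.75


@dataclass
class ExpressionModel:
    """Cell-type expression model used to sample per-cell profiles.

    ``mean_profiles`` is a (types × genes) table of expected molecule
    counts per cell before capture scaling; ``frequencies`` the cell
    type proportions; ``dispersion`` the negative-binomial size
    parameter (larger = closer to Poisson); ``mode`` one of
    ``"nb"``, ``"constant"`` (profile used verbatim) or
    ``"reference"`` (rows drawn from ``reference_matrix`` whose rows
    are typed by ``reference_types``).
    """

    gene_names: list[str]
    type_names: list[str]
    mean_profiles: np.ndarray
    frequencies: np.ndarray
    capture_scale: float = 3.0
    dispersion: float = 20.0
    mode: str = "nb"
    reference_matrix: np.ndarray | None = None
    reference_types: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean_profiles = np.asarray(self.mean_profiles, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(self.mean_profiles < 0):
            raise ValidationError("expression profiles must be non-negative")
        if not np.isclose(self.frequencies.sum(), 1.0):
            raise ValidationError("type frequencies must sum to 1")

    @classmethod
    def marker_panel(
        cls,
        n_types: int = 2,
        markers_per_type: int = 5,
        mean_count: float = 5.0,
        leak: float = 0.0,
        capture_scale: float = 3.0,
        dispersion: float = 20.0,
        frequencies: np.ndarray | None = None,
    ) -> "ExpressionModel":
        """Disjoint marker panel: each type expresses its own genes at
        ``mean_count`` and every other gene at ``leak``."""
        n_genes = n_types * markers_per_type
        genes = [f"g{t}_{m}" for t in range(n_types) for m in range(markers_per_type)]
        prof = np.full((n_types, n_genes), leak, dtype=float)
        for t in range(n_types):
            prof[t, t * markers_per_type : (t + 1) * markers_per_type] = mean_count
        freq = (
            np.full(n_types, 1.0 / n_types) if frequencies is None else np.asarray(frequencies)
        )
        return cls(
            gene_names=genes,
            type_names=[f"type{t}" for t in range(n_types)],
            mean_profiles=prof,
            frequencies=freq,
            capture_scale=capture_scale,
            dispersion=dispersion,
        )


@dataclass
class TissueSimulation:
    """A simulated tissue with full ground truth.

    Rasters are (z, y, x); ``voxel_size`` is µm per voxel along
    (x, y, z).  ``cloud`` and ``true_cell_ids`` appear after
    :func:`place_rna`.
    """

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    voxel_size: tuple[float, float, float]
    cell_ids: np.ndarray
    has_nucleus: np.ndarray
    params: dict = field(default_factory=dict)
    cell_types: np.ndarray | None = None
    profiles: np.ndarray | None = None
    gene_names: list[str] | None = None
    type_names: list[str] | None = None
    cloud: RNAPointCloud | None = None
    true_cell_ids: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def nucleus_landmarks(self) -> NucleusLandmarks:
        """Landmarks of the retained nuclei (dropped ones are absent)."""
        return NucleusLandmarks.from_label_image(self.nucleus_labels, self.voxel_size)


def _paint_disc(raster: np.ndarray, center_zyx, radius_vox: float, label: int) -> None:
    """Rasterize a disc (single z plane) into ``raster`` in place,
    touching only the disc's bounding window."""
    cz, cy, cx = center_zyx
    _, ny, nx = raster.shape
    r = int(np.ceil(radius_vox))
    y0, y1 = max(int(cy) - r - 1, 0), min(int(cy) + r + 2, ny)
    x0, x1 = max(int(cx) - r - 1, 0), min(int(cx) + r + 2, nx)
    yy, xx = np.ogrid[y0:y1, x0:x1]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_vox**2
    raster[int(round(cz)), y0:y1, x0:x1][mask] = label


def simulate_grid(
    n_cells_x: int,
    n_cells_y: int,
    pixel_um: float = DEFAULT_PIXEL_UM,
    cell_um: float = DEFAULT_CELL_UM,
    nucleus_radius_um: float = DEFAULT_NUCLEUS_RADIUS_UM,
) -> TissueSimulation:
    """Checkerboard of square cells with concentric disc nuclei (2D)."""
    if n_cells_x < 1 or n_cells_y < 1:
        raise ValidationError("grid dimensions must be positive")
    side = int(round(cell_um / pixel_um))
    h, w = n_cells_y * side, n_cells_x * side
    cells = np.zeros((1, h, w), dtype=np.int32)
    nuclei = np.zeros_like(cells)
    r_vox = nucleus_radius_um / pixel_um
    label = 0
    for gy in range(n_cells_y):
        for gx in range(n_cells_x):
            label += 1
            cells[0, gy * side : (gy + 1) * side, gx * side : (gx + 1) * side] = label
            cy, cx = (gy + 0.5) * side - 0.5, (gx + 0.5) * side - 0.5
            _paint_disc(nuclei, (0, cy, cx), r_vox, label)
    ids = np.arange(1, label + 1)
    return TissueSimulation(
        cell_labels=cells,
        nucleus_labels=nuclei,
        voxel_size=(pixel_um, pixel_um, 1.0),
        cell_ids=ids,
        has_nucleus=np.ones(label, dtype=bool),
        params={
            "scenario": "grid",
            "n_cells_x": n_cells_x,
            "n_cells_y": n_cells_y,
            "pixel_um": pixel_um,
            "cell_um": cell_um,
            "nucleus_radius_um": nucleus_radius_um,
        },
    )


# An L-tetromino pair tiling a 2 x 4 block of unit squares; offsets are
# (row, col) of the squares belonging to each of the two cells.
_L_PAIR = (
    ((0, 0), (0, 1), (0, 2), (1, 0)),
    ((1, 1), (1, 2), (1, 3), (0, 3)),
)


def simulate_lshapes(
    n_shapes: int,
    seed: int = 0,
    pixel_um: float = DEFAULT_PIXEL_UM,
    cell_um: float = DEFAULT_CELL_UM,
    nucleus_radius_um: float = DEFAULT_NUCLEUS_RADIUS_UM,
) -> TissueSimulation:
    """Interlocking L-shaped cells, each the union of four 15 µm squares.

    Cells come in pairs tiling 2 × 4 blocks of squares; blocks are laid
    out row-major.  Each nucleus is a disc placed at the center of a
    seeded-random one of the cell's four squares.
    """
    if n_shapes < 1:
        raise ValidationError("need at least one L-shape")
    rng = np.random.default_rng(seed)
    side = int(round(cell_um / pixel_um))
    n_blocks = (n_shapes + 1) // 2
    blocks_x = int(np.ceil(np.sqrt(n_blocks)))
    blocks_y = int(np.ceil(n_blocks / blocks_x))
    h, w = blocks_y * 2 * side, blocks_x * 4 * side
    cells = np.zeros((1, h, w), dtype=np.int32)
    nuclei = np.zeros_like(cells)
    r_vox = nucleus_radius_um / pixel_um
    label = 0
    for b in range(n_blocks):
        by, bx = divmod(b, blocks_x)
        oy, ox = by * 2 * side, bx * 4 * side
        for piece in _L_PAIR:
            if label >= n_shapes:
                break
            label += 1
            for r, c in piece:
                cells[
                    0,
                    oy + r * side : oy + (r + 1) * side,
                    ox + c * side : ox + (c + 1) * side,
                ] = label
            r, c = piece[rng.integers(len(piece))]
            cy = oy + (r + 0.5) * side - 0.5
            cx = ox + (c + 0.5) * side - 0.5
            _paint_disc(nuclei, (0, cy, cx), r_vox, label)
    ids = np.arange(1, label + 1)
    return TissueSimulation(
        cell_labels=cells,
        nucleus_labels=nuclei,
        voxel_size=(pixel_um, pixel_um, 1.0),
        cell_ids=ids,
        has_nucleus=np.ones(label, dtype=bool),
        params={
            "scenario": "lshape",
            "n_shapes": n_shapes,
            "seed": seed,
            "pixel_um": pixel_um,
            "cell_um": cell_um,
            "nucleus_radius_um": nucleus_radius_um,
        },
    )


def grow_cells(
    nucleus_labels: np.ndarray,
    allowed_mask: np.ndarray,
    seed: int = 0,
    speed_range: tuple[float, float] = (0.5, 1.0),
    max_rounds: int = 100000,
) -> np.ndarray:
    """Grow cytoplasms from nucleus seeds by stochastic frontier dilation.

    Each cell draws a per-round expansion probability once, uniformly
    from ``speed_range``; each round (cells visited in seeded-random
    order) a cell whose coin lands dilates its frontier by one voxel
    inside ``allowed_mask``, claiming free voxels only — contested
    voxels go to the first claimant of the round.  Stops when no
    frontier can move.
    """
    nuc = np.asarray(nucleus_labels)
    squeeze = False
    if nuc.ndim == 2:
        nuc, allowed_mask, squeeze = nuc[None], np.asarray(allowed_mask)[None], True
    allowed = np.asarray(allowed_mask).astype(bool)
    if not np.all(allowed[nuc > 0]):
        raise ValidationError("allowed_mask must cover all nuclei")
    rng = np.random.default_rng(seed)
    labels = np.unique(nuc)
    labels = labels[labels > 0]
    cells = np.where(allowed, nuc, 0).astype(np.int32)
    speeds = rng.uniform(*speed_range, size=len(labels))
    struct = ndimage.generate_binary_structure(3, 1)
    if nuc.shape[0] == 1:
        struct = struct.copy()
        struct[0] = struct[2] = False  # planar growth for single-slice input
    for _ in range(max_rounds):
        free = allowed & (cells == 0)
        frontier_possible = ndimage.binary_dilation(cells > 0, struct) & free
        if not frontier_possible.any():
            break
        for i in rng.permutation(len(labels)):
            if rng.random() > speeds[i]:
                continue
            mask_c = cells == labels[i]
            grown = ndimage.binary_dilation(mask_c, struct) & allowed & (cells == 0)
            cells[grown] = labels[i]
    return cells[0] if squeeze else cells


def random_lacunae(
    shape_yx: tuple[int, int],
    n_lacunae: int,
    radius_range_vox: tuple[float, float],
    seed: int = 0,
) -> np.ndarray:
    """Allowed mask with ``n_lacunae`` random elliptic holes (True = allowed)."""
    rng = np.random.default_rng(seed)
    h, w = shape_yx
    mask = np.ones((h, w), dtype=bool)
    yy, xx = np.ogrid[:h, :w]
    for _ in range(n_lacunae):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry = rng.uniform(*radius_range_vox)
        rx = rng.uniform(*radius_range_vox)
        mask &= ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 > 1
    return mask


def poisson_disc_nuclei(
    shape_yx: tuple[int, int],
    min_dist_vox: float,
    nucleus_radius_vox: float,
    allowed_mask: np.ndarray | None = None,
    seed: int = 0,
    n_candidates: int = 3000,
) -> np.ndarray:
    """Dart-throwing nucleus field: disc nuclei at centers at least
    ``min_dist_vox`` apart, inside the allowed mask."""
    rng = np.random.default_rng(seed)
    h, w = shape_yx
    centers: list[tuple[float, float]] = []
    for _ in range(n_candidates):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        if allowed_mask is not None and not allowed_mask[int(cy), int(cx)]:
            continue
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_dist_vox**2 for y, x in centers):
            centers.append((cy, cx))
    nuclei = np.zeros((1, h, w), dtype=np.int32)
    for i, (cy, cx) in enumerate(centers, start=1):
        _paint_disc(nuclei, (0, cy, cx), nucleus_radius_vox, i)
    return nuclei[0]


def drop_nuclei(sim: TissueSimulation, fraction: float, seed: int = 0) -> TissueSimulation:
    """Remove ⌊fraction·N⌋ seeded-random nuclei from the nucleus raster.

    Cells (and any RNAs) are retained; only ``has_nucleus`` and the
    nucleus raster change — mimicking nuclei lost to the sectioning
    plane.
    """
    if not 0 <= fraction < 1:
        raise ValidationError("fraction must be in [0, 1)")
    n_drop = int(np.floor(fraction * sim.n_cells))
    rng = np.random.default_rng(seed)
    dropped = rng.choice(sim.cell_ids, size=n_drop, replace=False)
    nuclei = sim.nucleus_labels.copy()
    nuclei[np.isin(nuclei, dropped)] = 0
    has_nucleus = sim.has_nucleus.copy()
    has_nucleus[np.isin(sim.cell_ids, dropped)] = False
    return TissueSimulation(
        cell_labels=sim.cell_labels,
        nucleus_labels=nuclei,
        voxel_size=sim.voxel_size,
        cell_ids=sim.cell_ids,
        has_nucleus=has_nucleus,
        params={**sim.params, "nucleus_dropout": fraction, "dropout_seed": seed},
        cell_types=sim.cell_types,
        profiles=sim.profiles,
        gene_names=sim.gene_names,
        type_names=sim.type_names,
        cloud=sim.cloud,
        true_cell_ids=sim.true_cell_ids,
    )


def _stochastic_round(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Floor + Bernoulli on the fractional part: unbiased integerization."""
    floor = np.floor(values)
    frac = values - floor
    return (floor + (rng.random(values.shape) < frac)).astype(np.int64)


def sample_expression(
    sim: TissueSimulation,
    model: ExpressionModel,
    seed: int = 0,
    types: np.ndarray | None = None,
) -> TissueSimulation:
    """Draw a cell type and an integer expression profile for every cell.

    Counts come from the model's law (negative binomial around the type
    mean, the constant mean itself, or a sampled reference row) and are
    multiplied by the capture-scale factor with stochastic rounding, so
    expectations scale exactly.  ``types`` fixes the per-cell type
    instead of drawing from the model frequencies (e.g., to alternate
    types between interlocking cells).
    """
    rng = np.random.default_rng(seed)
    n_cells = sim.n_cells
    n_types = len(model.type_names)
    if types is None:
        types = rng.choice(n_types, size=n_cells, p=model.frequencies)
    else:
        types = np.asarray(types, dtype=int)
        if len(types) != n_cells:
            raise ValidationError("types must give one type per cell")
    n_genes = len(model.gene_names)
    counts = np.zeros((n_cells, n_genes))
    if model.mode == "constant":
        counts = model.mean_profiles[types]
    elif model.mode == "nb":
        mu = model.mean_profiles[types]
        theta = model.dispersion
        lam = np.where(mu > 0, rng.gamma(theta, np.maximum(mu, 1e-12) / theta), 0.0)
        counts = rng.poisson(lam).astype(float)
    elif model.mode == "reference":
        if model.reference_matrix is None or model.reference_types is None:
            raise ValidationError("reference mode needs reference_matrix and reference_types")
        for i, t in enumerate(types):
            rows = np.where(model.reference_types == t)[0]
            counts[i] = model.reference_matrix[rng.choice(rows)]
    else:
        raise ValidationError(f"unknown expression mode {model.mode!r}")
    scaled = _stochastic_round(counts * model.capture_scale, rng)
    sim.cell_types = types
    sim.profiles = scaled
    sim.gene_names = list(model.gene_names)
    sim.type_names = list(model.type_names)
    sim.params = {**sim.params, "capture_scale": model.capture_scale, "expression_seed": seed}
    return sim


def place_rna(sim: TissueSimulation, seed: int = 0) -> TissueSimulation:
    """Place each cell's molecules uniformly over its voxels (µm, with
    sub-voxel jitter) and record the true cell id per molecule."""
    if sim.profiles is None:
        raise ValidationError("sample_expression must run before place_rna")
    rng = np.random.default_rng(seed)
    vx, vy, vz = sim.voxel_size
    two_d = sim.cell_labels.shape[0] == 1
    pos_list, gene_list, truth = [], [], []
    flat = sim.cell_labels.ravel()
    order = np.argsort(flat, kind="stable")
    sorted_labels = flat[order]
    bounds = np.searchsorted(sorted_labels, np.arange(sim.cell_ids.max() + 2))
    shape = sim.cell_labels.shape
    for ci, cell in enumerate(sim.cell_ids):
        lo, hi = bounds[cell], bounds[cell + 1]
        vox = order[lo:hi]
        if len(vox) == 0:
            continue
        total = int(sim.profiles[ci].sum())
        if total == 0:
            continue
        chosen = vox[rng.integers(0, len(vox), size=total)]
        zz, yy, xx = np.unravel_index(chosen, shape)
        jitter = rng.random((total, 3))
        x = (xx + jitter[:, 0]) * vx
        y = (yy + jitter[:, 1]) * vy
        z = np.zeros(total) if two_d else (zz + jitter[:, 2]) * vz
        pos = np.column_stack([x, y, z])
        genes = np.repeat(np.arange(len(sim.gene_names)), sim.profiles[ci])
        rng.shuffle(genes)
        pos_list.append(pos)
        gene_list.append(genes)
        truth.append(np.full(total, cell, dtype=np.int64))
    if pos_list:
        positions = np.vstack(pos_list)
        genes = np.concatenate(gene_list)
        truth_arr = np.concatenate(truth)
    else:
        positions = np.zeros((0, 3))
        genes = np.zeros(0, dtype=np.int64)
        truth_arr = np.zeros(0, dtype=np.int64)
    sim.cloud = RNAPointCloud(
        positions=positions,
        genes=genes,
        ids=np.arange(len(positions)),
        gene_names=list(sim.gene_names),
    )
    sim.true_cell_ids = truth_arr
    sim.params = {**sim.params, "placement_seed": seed}
    return sim
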