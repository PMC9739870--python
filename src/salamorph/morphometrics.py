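"""Procrustes superimposition and thin-plate-spline pattern standardization.

The head of each specimen is described by 33 planar points: 9 anatomical
landmarks plus 24 outline semi-landmarks (treated as fixed points; no sliding
is performed).  Generalized Procrustes Analysis (GPA) removes position,
orientation and scale, yielding a unit-centroid-size consensus shape.  Each
individual's binary colour pattern is then brought into a common raster frame
built around the consensus by backward thin-plate-spline (TPS) warping with
nearest-neighbour sampling, and the in-head pixels are stacked into the
n x J binary pixel matrix that the clustering stage consumes.

Conventions: raster coordinates are 0-based with pixel centers at integer
(row, col); point arrays are (x, y) with x = column, y = row (origin
top-left — TPS-file coordinates must be passed through
:func:`salamorph.formats.flip_y` first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

__all__ = [
    "LandmarkConfiguration",
    "ConsensusShape",
    "TpsMapping",
    "ConsensusFrame",
    "PixelMatrix",
    "N_LANDMARKS",
    "N_SEMILANDMARKS",
    "centroid_size",
    "align_pair",
    "gpa_consensus",
    "tps_fit",
    "tps_evaluate",
    "warp_to_consensus",
    "build_mask",
    "build_pixel_matrix",
]

N_LANDMARKS = 9
N_SEMILANDMARKS = 24


@dataclass
class LandmarkConfiguration:
    """One individual's 33-point configuration (9 landmarks + 24 semi-landmarks).

    The first ``n_landmarks`` rows are anatomical landmarks; the remainder are
    the outline semi-landmarks in outline order.
    """

    points: np.ndarray
    id: str = ""
    n_landmarks: int = N_LANDMARKS

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if np.isnan(self.points).any():
            raise ValueError("points contain NaN")

    @property
    def landmarks(self) -> np.ndarray:
        return self.points[: self.n_landmarks]

    @property
    def semilandmarks(self) -> np.ndarray:
        return self.points[self.n_landmarks :]


@dataclass
class ConsensusShape:
    """GPA output: the consensus (mean) shape and the aligned specimens."""

    mean: np.ndarray                      # (p, 2), centered, unit centroid size
    aligned: list[np.ndarray]             # per-individual aligned copies
    procrustes_distances: np.ndarray      # per-individual distance to the mean
    iterations: int
    n_landmarks: int = N_LANDMARKS


@dataclass
class TpsMapping:
    """A fitted thin-plate spline f: R^2 -> R^2.

    ``affine`` is a 3x2 matrix (rows: intercept, x, y coefficients);
    ``weights`` are the p x 2 kernel weights.  Bending energy is the
    quadratic non-affine penalty tr(W' K W), zero iff the map is affine.
    """

    source: np.ndarray
    affine: np.ndarray
    weights: np.ndarray
    bending_energy: float


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of the summed squared distances of points from their centroid."""
    pts = config.points if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centered = pts - pts.mean(axis=0)
    size = float(np.sqrt((centered**2).sum()))
    if size == 0.0:
        raise ValueError("degenerate configuration: all points identical")
    return size


def _center_and_scale(pts: np.ndarray) -> np.ndarray:
    centered = pts - pts.mean(axis=0)
    return centered / centroid_size(centered)


@dataclass
class AlignResult:
    aligned: np.ndarray
    angle: float          # rotation applied to the moving shape, radians
    scale: float          # extra Procrustes scale applied after unit-size normalization
    distance: float       # full Procrustes distance to the unit-size centered target


def align_pair(
    moving: LandmarkConfiguration | np.ndarray,
    target: LandmarkConfiguration | np.ndarray,
) -> AlignResult:
    """Full Procrustes superimposition of ``moving`` onto ``target``.

    Both configurations are centered and scaled to unit centroid size; the
    optimal rotation (reflections forbidden) comes from the SVD of the
    cross-covariance, and the optimal scale from its singular values.  The
    returned distance is the root-sum-square residual to the unit-size
    centered target.
    """
    x = _center_and_scale(moving.points if isinstance(moving, LandmarkConfiguration) else np.asarray(moving, float))
    y = _center_and_scale(target.points if isinstance(target, LandmarkConfiguration) else np.asarray(target, float))
    if x.shape != y.shape:
        raise ValueError(f"point counts differ: {x.shape[0]} vs {y.shape[0]}")

    u, s, vt = np.linalg.svd(x.T @ y)
    # forbid reflections: constrain det(R) = +1
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, d])
    rot = u @ corr @ vt
    beta = float((s * np.diag(corr)).sum())  # optimal scale (||x|| = 1)
    aligned = beta * (x @ rot)
    distance = float(np.linalg.norm(aligned - y))
    angle = float(np.arctan2(rot[0, 1], rot[0, 0]))
    return AlignResult(aligned=aligned, angle=angle, scale=beta, distance=distance)


def gpa_consensus(
    configs: list[LandmarkConfiguration],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ConsensusShape:
    """Generalized Procrustes Analysis over a sample of configurations.

    Iterates {align every specimen to the current mean; recompute the mean;
    rescale it to unit centroid size} until the mean moves by less than
    ``tol`` (Frobenius norm) or ``max_iter`` rounds have run.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    p = configs[0].points.shape[0]
    for c in configs:
        if c.points.shape[0] != p:
            raise ValueError("all configurations must have the same point count")

    shapes = [c.points for c in configs]
    mean = _center_and_scale(shapes[0])
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        aligned = [align_pair(s, mean).aligned for s in shapes]
        new_mean = _center_and_scale(np.mean(aligned, axis=0))
        shift = float(np.linalg.norm(new_mean - mean))
        mean = new_mean
        if shift < tol:
            break
    else:
        raise RuntimeError(f"GPA did not converge in {max_iter} iterations; last shift {shift:.3e}")

    aligned = [align_pair(s, mean).aligned for s in shapes]
    distances = np.array([float(np.linalg.norm(a - mean)) for a in aligned])
    return ConsensusShape(
        mean=mean,
        aligned=aligned,
        procrustes_distances=distances,
        iterations=n_iter,
        n_landmarks=configs[0].n_landmarks,
    )


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 ln r^2 with U(0) = 0, expressed in squared distance r2."""
    out = np.zeros_like(r2)
    pos = r2 > 0
    out[pos] = r2[pos] * np.log(r2[pos])
    return out


def tps_fit(source: np.ndarray, target: np.ndarray) -> TpsMapping:
    """Fit the interpolating thin-plate spline mapping source points to targets.

    Solves the standard TPS linear system with kernel U(r) = r^2 ln r^2; the
    resulting map satisfies f(source_i) = target_i exactly.  With exactly 3
    collinear source points the kernel system is singular and the fit falls
    back to the (least-squares) affine map.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    p = src.shape[0]
    if p < 3:
        raise ValueError("TPS needs at least 3 source points")
    if src.shape != tgt.shape:
        raise ValueError("source and target shapes differ")
    d2 = ((src[:, None, :] - src[None, :, :]) ** 2).sum(-1)
    if (d2[~np.eye(p, dtype=bool)] == 0).any():
        raise ValueError("source points must be pairwise distinct")

    K = _tps_kernel(d2)
    P = np.column_stack([np.ones(p), src])
    L = np.zeros((p + 3, p + 3))
    L[:p, :p] = K
    L[:p, p:] = P
    L[p:, :p] = P.T
    rhs = np.zeros((p + 3, 2))
    rhs[:p] = tgt
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError:
        if p == 3:
            affine, *_ = np.linalg.lstsq(P, tgt, rcond=None)
            return TpsMapping(source=src, affine=affine, weights=np.zeros((3, 2)), bending_energy=0.0)
        raise
    weights = sol[:p]
    affine = sol[p:]
    be = float(np.trace(weights.T @ K @ weights))
    return TpsMapping(source=src, affine=affine, weights=weights, bending_energy=max(be, 0.0))


def tps_evaluate(mapping: TpsMapping, points: np.ndarray) -> np.ndarray:
    """Evaluate a fitted TPS at arbitrary points (affine part + kernel expansion)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d2 = ((pts[:, None, :] - mapping.source[None, :, :]) ** 2).sum(-1)
    U = _tps_kernel(d2)
    P = np.column_stack([np.ones(len(pts)), pts])
    return P @ mapping.affine + U @ mapping.weights


@dataclass
class ConsensusFrame:
    """Raster frame holding the consensus shape with a 10% margin.

    Maps unit-centroid-size consensus coordinates (y up) to raster
    coordinates (row down) by ``col = scale*x + cx``, ``row = -scale*y + cy``.
    """

    rows: int
    cols: int
    scale: float
    cx: float
    cy: float
    landmarks: np.ndarray = field(default=None)  # consensus points placed in the frame, (p, 2) as (x=col, y=row)

    @classmethod
    def fit(cls, mean: np.ndarray, rows: int = 96, cols: int = 72, margin: float = 0.10) -> "ConsensusFrame":
        if rows < 32 or cols < 32:
            raise ValueError("consensus frame must be at least 32x32")
        lo = mean.min(axis=0)
        hi = mean.max(axis=0)
        span = hi - lo
        usable_x = (cols - 1) * (1 - 2 * margin)
        usable_y = (rows - 1) * (1 - 2 * margin)
        scale = min(usable_x / span[0], usable_y / span[1])
        center = (lo + hi) / 2
        cx = (cols - 1) / 2 - scale * center[0]
        cy = (rows - 1) / 2 + scale * center[1]
        frame = cls(rows=rows, cols=cols, scale=scale, cx=cx, cy=cy)
        frame.landmarks = frame.place(mean)
        return frame

    def place(self, shape_points: np.ndarray) -> np.ndarray:
        """Map consensus-space points into frame pixel coordinates (x=col, y=row)."""
        pts = np.asarray(shape_points, dtype=float)
        return np.column_stack([self.scale * pts[:, 0] + self.cx, -self.scale * pts[:, 1] + self.cy])

    def pixel_centers(self) -> np.ndarray:
        """All (x=col, y=row) pixel centers, row-major order."""
        rr, cc = np.mgrid[0 : self.rows, 0 : self.cols]
        return np.column_stack([cc.ravel().astype(float), rr.ravel().astype(float)])


@dataclass
class PixelMatrix:
    """n x J binary matrix over the J in-mask consensus-frame pixels."""

    values: np.ndarray                 # (n, J) uint8
    mask_index: np.ndarray             # (J, 2) of (row, col), row-major order
    frame: ConsensusFrame
    ids: list[str] = field(default_factory=list)


def warp_to_consensus(
    image: np.ndarray,
    individual: LandmarkConfiguration | np.ndarray,
    frame: ConsensusFrame,
) -> np.ndarray:
    """Standardize one binary pattern image into the consensus frame.

    Backward warping: a TPS is fitted from the consensus-frame landmark
    positions to the individual's image landmarks (raster convention, x=col,
    y=row); each consensus-frame pixel center is mapped into the source image
    and sampled by nearest neighbour.  Out-of-bounds samples are 0.  Sampling
    is nearest-neighbour because patterns are strictly binary.
    """
    if frame.rows < 32 or frame.cols < 32:
        raise ValueError("consensus frame must be at least 32x32")
    pts = individual.points if isinstance(individual, LandmarkConfiguration) else np.asarray(individual, float)
    mapping = tps_fit(frame.landmarks, pts)
    sample_xy = tps_evaluate(mapping, frame.pixel_centers())
    col = np.rint(sample_xy[:, 0]).astype(int)
    row = np.rint(sample_xy[:, 1]).astype(int)
    h, w = image.shape
    inside = (row >= 0) & (row < h) & (col >= 0) & (col < w)
    out = np.zeros(frame.rows * frame.cols, dtype=np.uint8)
    out[inside] = image[row[inside], col[inside]]
    return out.reshape(frame.rows, frame.cols)


def build_mask(frame: ConsensusFrame, n_landmarks: int = N_LANDMARKS) -> np.ndarray:
    """In-head pixels of the consensus frame, as (row, col) pairs in row-major order.

    The head area is the closed polygon through the 24 outline semi-landmarks
    of the placed consensus, in file order; a pixel belongs to the mask when
    its center falls strictly inside under the even-odd rule.
    """
    outline = frame.landmarks[n_landmarks:]
    poly = shapely.Polygon(outline)
    if not poly.is_valid:
        raise ValueError("outline polygon is self-intersecting")
    centers = frame.pixel_centers()
    inside = shapely.contains_xy(poly, centers[:, 0], centers[:, 1])
    sel = centers[inside]
    return np.column_stack([sel[:, 1].astype(int), sel[:, 0].astype(int)])


def build_pixel_matrix(
    warped: list[np.ndarray],
    mask_index: np.ndarray,
    frame: ConsensusFrame,
    ids: list[str] | None = None,
) -> PixelMatrix:
    """Stack warped consensus-frame images into the n x J binary pixel matrix."""
    expected = (frame.rows, frame.cols)
    for i, img in enumerate(warped):
        if img.shape != expected:
            raise ValueError(f"image {i} has shape {img.shape}, frame is {expected}")
    rows = mask_index[:, 0]
    cols = mask_index[:, 1]
    values = np.stack([img[rows, cols] for img in warped]).astype(np.uint8)
    return PixelMatrix(values=values, mask_index=mask_index, frame=frame, ids=list(ids or []))
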