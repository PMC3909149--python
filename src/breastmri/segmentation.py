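"""Two-step semi-automated lesion segmentation: FCM clustering + GVF snake.

Step 1 clusters the intensities of the user-supplied rectangular region of
interest on the first post-contrast frame with fuzzy c-means (FCM) and takes
the enhancing cluster as an initial mask.  Step 2 refines that mask's
contour with a gradient-vector-flow (GVF) active contour (snake), which is
robust to initialization distance and boundary concavities.

`FuzzyCMeans` follows the scikit-learn estimator protocol (fit / predict,
fitted attributes with a trailing underscore) so it composes with sklearn
tooling; the remaining steps are plain functions over rasters and polygons.
Coordinates are 0-based (row, col) at pixel centres; masks are strictly
boolean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.linalg import solve_circulant
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage import measure
from skimage.draw import polygon2mask
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationError",
    "FuzzyCMeans",
    "FCMResult",
    "SnakeParams",
    "LesionGeometry",
    "fcm_cluster",
    "initial_mask",
    "gvf_field",
    "evolve_snake",
    "segment_lesion",
    "dice",
]


class SegmentationError(RuntimeError):
    """Raised when a segmentation stage cannot produce a valid lesion mask."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


# ---------------------------------------------------------------------------
# fuzzy c-means
# ---------------------------------------------------------------------------


@dataclass
class FCMResult:
    centers: np.ndarray            # (c,) cluster centres (intensities)
    memberships: np.ndarray        # (n_samples, c), rows sum to 1
    objective_history: np.ndarray  # per-iteration objective J
    fuzzifier: float
    n_iter: int
    converged: bool


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means clustering of scalar intensities.

    Minimizes J = Σ_i Σ_k u_ik^m ||x_i - c_k||² under Σ_k u_ik = 1 by the
    classical alternating updates

        c_k = Σ_i u_ik^m x_i / Σ_i u_ik^m
        u_ik = 1 / Σ_j (d_ik / d_ij)^(2/(m-1))

    stopping when the largest centre shift falls below ``tol``.  Centres are
    initialized at evenly spaced intensity percentiles (10th/90th for c=2),
    which is deterministic; ``random_state`` only seeds the fallback jitter
    applied when initial centres coincide.

    Parameters
    ----------
    n_clusters : int
        Number of clusters c (>= 2).
    m : float
        Fuzzifier (> 1); 2.0 is the conventional choice.
    tol : float
        Convergence threshold on the maximum centre displacement.
    max_iter : int
        Iteration cap.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters,)
    memberships_ : ndarray of shape (n_samples, n_clusters)
    objective_history_ : ndarray
    labels_ : ndarray of shape (n_samples,) — hard argmax assignment
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, n_clusters: int = 2, m: float = 2.0, tol: float = 1e-5,
                 max_iter: int = 300, random_state: int | None = 0):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _memberships(self, x: np.ndarray, centers: np.ndarray) -> np.ndarray:
        # u_ik = 1 / sum_j (d_ik/d_ij)^(2/(m-1)); pixels exactly on a centre
        # get full membership there (shared equally among coincident centres).
        d = np.abs(x[:, None] - centers[None, :])
        exact = d < 1e-12
        u = np.zeros_like(d)
        any_exact = exact.any(axis=1)
        if any_exact.any():
            u[any_exact] = exact[any_exact] / exact[any_exact].sum(axis=1, keepdims=True)
        rest = ~any_exact
        if rest.any():
            power = 2.0 / (self.m - 1.0)
            inv = d[rest] ** (-power)
            u[rest] = inv / inv.sum(axis=1, keepdims=True)
        return u

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.m <= 1.0:
            raise ValueError("fuzzifier m must be > 1")
        spread = float(np.ptp(x))
        if np.unique(x).size < self.n_clusters or spread < 1e-9 * max(1.0, np.abs(x).max()):
            raise SegmentationError(
                "fcm", f"need >= {self.n_clusters} distinct intensities "
                       f"(got {np.unique(x).size}); no contrast to cluster")
        # percentile initialization: 10th..90th evenly spaced
        qs = np.linspace(10.0, 90.0, self.n_clusters)
        centers = np.percentile(x, qs).astype(float)
        if np.unique(centers).size < self.n_clusters:
            rng = np.random.default_rng(self.random_state)
            centers = centers + rng.normal(0.0, 1e-6 * (spread + 1.0), centers.shape)

        history = []
        converged = False
        u = self._memberships(x, centers)
        for it in range(1, self.max_iter + 1):
            um = u ** self.m
            new_centers = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
            u = self._memberships(x, new_centers)
            um = u ** self.m
            J = float((um * (x[:, None] - new_centers[None, :]) ** 2).sum())
            history.append(J)
            shift = np.max(np.abs(new_centers - centers))
            centers = new_centers
            if shift < self.tol:
                converged = True
                break
        order = np.argsort(centers)
        self.cluster_centers_ = centers[order]
        self.memberships_ = u[:, order]
        self.objective_history_ = np.asarray(history)
        self.labels_ = np.argmax(self.memberships_, axis=1)
        self.n_iter_ = it
        self.converged_ = converged
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        x = np.asarray(X, dtype=float).ravel()
        return np.argmax(self._memberships(x, self.cluster_centers_), axis=1)

    def membership(self, X) -> np.ndarray:
        """Fuzzy memberships of new intensities against the fitted centres."""
        check_is_fitted(self, "cluster_centers_")
        return self._memberships(np.asarray(X, dtype=float).ravel(),
                                 self.cluster_centers_)

    def result(self) -> FCMResult:
        check_is_fitted(self, "cluster_centers_")
        return FCMResult(self.cluster_centers_, self.memberships_,
                         self.objective_history_, self.m, self.n_iter_,
                         self.converged_)


def fcm_cluster(intensities, c: int = 2, m: float = 2.0, tol: float = 1e-5,
                max_iter: int = 300, seed: int | None = 0) -> FCMResult:
    """Functional wrapper over :class:`FuzzyCMeans` for 1-D intensity data."""
    est = FuzzyCMeans(n_clusters=c, m=m, tol=tol, max_iter=max_iter,
                      random_state=seed).fit(np.asarray(intensities))
    return est.result()


def initial_mask(fcm: FCMResult, roi_shape: tuple[int, int],
                 enhancement_image: np.ndarray) -> np.ndarray:
    """FCM step-1 mask: the brightest cluster, cleaned up.

    Pixels whose membership in the cluster with the highest centre (the
    enhancing lesion cluster) exceeds 0.5 are kept; then the largest
    connected component is retained and interior holes are filled.
    ``enhancement_image`` must be the ROI raster the FCM was fitted on, used
    only for shape/bookkeeping.
    """
    if enhancement_image.shape != roi_shape:
        raise ValueError("enhancement_image shape must match roi_shape")
    lesion_k = int(np.argmax(fcm.centers))
    mask = (fcm.memberships[:, lesion_k] > 0.5).reshape(roi_shape)
    if not mask.any():
        raise SegmentationError("initial_mask", "empty lesion-cluster mask")
    labeled, n_comp = ndimage.label(mask)
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n_comp + 1))
        mask = labeled == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


# ---------------------------------------------------------------------------
# gradient vector flow
# ---------------------------------------------------------------------------


def gvf_field(edge_map: np.ndarray, mu: float = 0.2, gvf_iters: int = 80) -> np.ndarray:
    """Gradient vector flow of an edge map.

    Solves the diffusion equations minimizing
    ∫ mu·|∇v|² + |∇f|²·|v − ∇f|² by explicit iteration
    v ← v + dt·(mu·∇²v − |∇f|²·(v − ∇f)), extending edge gradients into
    homogeneous regions.  The edge map is first normalized to [0, 1] (the
    GVF energy is not scale invariant, and normalization keeps the explicit
    scheme stable with a usable time step); the returned (H, W, 2) field
    (row, col components) is on that normalized scale.
    """
    f = np.asarray(edge_map, dtype=float)
    if not np.isfinite(f).all() or (f < 0).any():
        raise ValueError("edge map must be finite and non-negative")
    if f.max() > f.min():
        f = (f - f.min()) / (f.max() - f.min())
    fy, fx = np.gradient(f)  # fy: d/drow, fx: d/dcol
    mag2 = fx ** 2 + fy ** 2
    if mag2.max() == 0:
        logger.warning("gvf_field: zero edge map; snake will not move")
        return np.zeros(f.shape + (2,))
    u, v = fy.copy(), fx.copy()
    # explicit Euler; dt within the stability bound of diffusion + reaction
    dt = 1.0 / (4.0 * mu + float(mag2.max()) + 1e-12)
    for _ in range(gvf_iters):
        u += dt * (mu * ndimage.laplace(u, mode="nearest") - mag2 * (u - fy))
        v += dt * (mu * ndimage.laplace(v, mode="nearest") - mag2 * (v - fx))
    return np.stack([u, v], axis=-1)


# ---------------------------------------------------------------------------
# snake
# ---------------------------------------------------------------------------


@dataclass
class SnakeParams:
    alpha: float = 0.01     # tension (first-derivative penalty)
    beta: float = 0.005     # rigidity (second-derivative penalty)
    gamma: float = 1.0      # time step
    kappa: float = 0.5      # external (GVF) force weight
    mu: float = 0.05        # GVF regularization
    gvf_iters: int = 300
    snake_iters: int = 600
    convergence_tol: float = 0.02  # mean vertex displacement, px
    edge_sigma: float = 0.8         # Gaussian smoothing of the image before |∇·|²
    resample_every: int = 10        # uniform arc-length resampling period
    supersample: int = 2            # ROI upsampling factor before segmentation

    def validate(self) -> list[str]:
        errs = []
        for name in ("alpha", "beta", "mu", "gamma"):
            val = getattr(self, name)
            if not np.isfinite(val) or val < 0:
                errs.append(f"{name} must be finite and >= 0")
        if self.gamma <= 0:
            errs.append("gamma must be > 0")
        if self.mu <= 0:
            errs.append("mu must be > 0")
        if self.gvf_iters < 1 or self.snake_iters < 1:
            errs.append("iteration counts must be >= 1")
        if self.resample_every < 1:
            errs.append("resample_every must be >= 1")
        if self.supersample < 1:
            errs.append("supersample must be >= 1")
        return errs


def _resample_closed(contour: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to n vertices uniformly spaced in arc length."""
    closed = np.vstack([contour, contour[:1]])
    seg = np.sqrt(((np.diff(closed, axis=0)) ** 2).sum(axis=1))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise SegmentationError("snake", "degenerate contour with zero perimeter")
    targets = np.linspace(0.0, total, n, endpoint=False)
    rows = np.interp(targets, s, closed[:, 0])
    cols = np.interp(targets, s, closed[:, 1])
    return np.column_stack([rows, cols])


def _is_simple(contour: np.ndarray) -> bool:
    """Cheap simplicity check via the shoelace-area / perimeter heuristic plus
    segment intersection testing on the (small) vertex set."""
    from shapely.geometry import Polygon

    ring = np.vstack([contour, contour[:1]])
    return Polygon(np.column_stack([ring[:, 1], ring[:, 0]])).is_valid


def evolve_snake(init_contour: np.ndarray, field: np.ndarray,
                 params: SnakeParams) -> np.ndarray:
    """Evolve a closed snake under internal tension/rigidity and a GVF force.

    Uses the semi-implicit scheme: with A the circulant internal-energy
    matrix built from alpha (tension) and beta (rigidity),
    x_{t+1} = (I + γA)⁻¹ (x_t + γκ·F(x_t)), where F is the unit-normalized
    GVF field (direction only; the sign flip across the edge ridge makes
    the ridge a stable equilibrium).  Vertices are resampled to uniform arc
    length every ``resample_every`` iterations (resampling every step blurs
    high-curvature features); evolution stops when the mean vertex
    displacement drops below ``convergence_tol``.
    """
    errs = params.validate()
    if errs:
        raise ValueError("invalid SnakeParams: " + "; ".join(errs))
    contour = np.asarray(init_contour, dtype=float)
    if contour.shape[0] < 16:
        raise ValueError("init_contour must have >= 16 vertices")
    n = contour.shape[0]

    # circulant pentadiagonal internal-energy operator
    a, b = params.alpha, params.beta
    col = np.zeros(n)
    col[0] = 2 * a + 6 * b
    col[1] = col[-1] = -a - 4 * b
    col[2] = col[-2] = b
    c_solve = np.zeros(n)
    c_solve[0] = 1.0 + params.gamma * col[0]
    c_solve[1] = params.gamma * col[1]
    c_solve[-1] = params.gamma * col[-1]
    c_solve[2] = params.gamma * col[2]
    c_solve[-2] = params.gamma * col[-2]

    h, w = field.shape[:2]
    mag = np.sqrt((field ** 2).sum(axis=-1))
    unit = field / (mag[..., None] + 1e-12)
    for it in range(params.snake_iters):
        coords = np.clip(contour.T, [[0.0], [0.0]], [[h - 1.0], [w - 1.0]])
        frow = map_coordinates(unit[..., 0], coords, order=1, mode="nearest")
        fcol = map_coordinates(unit[..., 1], coords, order=1, mode="nearest")
        step = params.gamma * params.kappa
        new = np.column_stack([
            solve_circulant(c_solve, contour[:, 0] + step * frow),
            solve_circulant(c_solve, contour[:, 1] + step * fcol),
        ])
        if (it + 1) % params.resample_every == 0:
            new = _resample_closed(new, n)
        disp = float(np.mean(np.sqrt(((new - contour) ** 2).sum(axis=1))))
        contour = new
        if disp < params.convergence_tol:
            break
    contour = _resample_closed(contour, n)
    if not _is_simple(contour):
        contour = _repair_contour(contour, n, it)
    return contour


def _repair_contour(contour: np.ndarray, n: int, it: int) -> np.ndarray:
    """Remove small self-intersection loops via the zero-width buffer trick;
    keeps the largest resulting ring."""
    from shapely.geometry import MultiPolygon, Polygon

    ring = np.vstack([contour, contour[:1]])
    fixed = Polygon(np.column_stack([ring[:, 1], ring[:, 0]])).buffer(0)
    if isinstance(fixed, MultiPolygon):
        fixed = max(fixed.geoms, key=lambda g: g.area)
    if fixed.is_empty or fixed.area == 0:
        raise SegmentationError("snake", f"irreparable self-intersecting contour at iteration {it}")
    xy = np.asarray(fixed.exterior.coords)[:-1]
    repaired = _resample_closed(np.column_stack([xy[:, 1], xy[:, 0]]), n)
    if not _is_simple(repaired):
        raise SegmentationError("snake", f"irreparable self-intersecting contour at iteration {it}")
    return repaired


# ---------------------------------------------------------------------------
# end-to-end lesion geometry
# ---------------------------------------------------------------------------


@dataclass
class LesionGeometry:
    """Binary lesion mask plus its closed boundary polygon (full-image grid)."""

    mask: np.ndarray     # bool raster
    contour: np.ndarray  # (n, 2) float (row, col), implicitly closed

    @classmethod
    def from_contour(cls, image_shape: tuple[int, int], contour: np.ndarray) -> "LesionGeometry":
        return cls(mask=polygon2mask(image_shape, contour), contour=np.asarray(contour, float))

    def validate(self) -> list[str]:
        errs = []
        if self.mask.dtype != bool:
            errs.append("mask must be boolean")
        if not self.mask.any():
            errs.append("mask is empty")
        else:
            _, n_comp = ndimage.label(self.mask)
            if n_comp != 1:
                errs.append(f"mask has {n_comp} connected components (expected 1)")
        if self.contour.shape[0] < 3:
            errs.append("contour must have >= 3 vertices")
        return errs


def segment_lesion(series, roi_box: tuple[int, int, int, int],
                   fcm_c: int = 2, fcm_m: float = 2.0,
                   snake_params: SnakeParams | None = None,
                   seed: int | None = 0) -> LesionGeometry:
    """Full two-step segmentation of one lesion.

    FCM (c clusters) on the first post-contrast frame inside the ROI gives
    the initial mask; its boundary initializes a GVF snake on the edge map
    |∇(Gaussian-smoothed frame)|².  The ROI is bilinearly upsampled by
    ``supersample`` before both steps (sub-pixel boundary placement), and
    the converged contour is mapped back and rasterized onto the full
    image grid.
    """
    params = snake_params or SnakeParams()
    image = series.first
    r0, c0, r1, c1 = roi_box
    if not (0 <= r0 < r1 <= image.shape[0] and 0 <= c0 < c1 <= image.shape[1]):
        raise SegmentationError("roi", f"roi_box {roi_box} not inside image {image.shape}")
    roi = image[r0:r1, c0:c1].astype(float)
    ss = params.supersample
    if ss > 1:
        roi = ndimage.zoom(roi, ss, order=1)

    fcm = fcm_cluster(roi.ravel(), c=fcm_c, m=fcm_m, seed=seed)
    mask0 = initial_mask(fcm, roi.shape, roi)

    contours = measure.find_contours(mask0.astype(float), 0.5)
    if not contours:
        raise SegmentationError("initial_mask", "no contour found on the initial mask")
    init = max(contours, key=lambda c: c.shape[0])
    n_vertices = max(64, min(600, 2 * init.shape[0]))
    init = _resample_closed(init, n_vertices)

    smoothed = gaussian_filter(roi, params.edge_sigma * ss)
    gy, gx = np.gradient(smoothed)
    edge = gy ** 2 + gx ** 2
    field = gvf_field(edge, mu=params.mu, gvf_iters=params.gvf_iters)
    contour = evolve_snake(init, field, params)

    if ss > 1:
        # pixel-centre mapping of the bilinear zoom: x_lo = (x_hi - (ss-1)/2)/ss
        contour = (contour - 0.5 * (ss - 1)) / ss
    contour_full = contour + np.array([r0, c0], dtype=float)
    mask = polygon2mask(image.shape, contour_full)
    if not mask.any():
        raise SegmentationError("snake", "converged contour rasterized to an empty mask")
    labeled, n_comp = ndimage.label(mask)
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n_comp + 1))
        mask = labeled == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    geom = LesionGeometry(mask=mask, contour=contour_full)
    errs = geom.validate()
    if errs:
        raise SegmentationError("geometry", "; ".join(errs))
    return geom


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|)."""
    a, b = mask_a.astype(bool), mask_b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return float("nan")
    return 2.0 * np.logical_and(a, b).sum() / denom
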