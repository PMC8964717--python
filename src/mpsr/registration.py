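"""Feature-based preregistration of fast-scan images onto the slow-scan frame.

The two scanning systems of a hybrid microscope are not collinear, so paired
acquisitions are misaligned by up to hundreds of pixels.  Before any learned
alignment, an ORB (oriented FAST keypoints + rotated BRIEF binary
descriptors) pipeline estimates a planar projective transform by Hamming
matching and RANSAC, and warps the fast-scan image into the slow-scan frame.

Conventions: transform matrices are 3x3 homogeneous acting on (x, y, 1)
column vectors (x = column, y = row), the native convention of
scikit-image's geometric transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac as _ransac
from skimage.transform import AffineTransform, ProjectiveTransform, resize, warp as _warp


class RegistrationError(RuntimeError):
    """Raised when no trustworthy transform can be estimated; carries
    match diagnostics in ``details``."""

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


@dataclass
class KeypointSet:
    """Detected corners with orientations, scores and binary descriptors."""

    positions: np.ndarray     # (N, 2) as (x, y)
    orientations: np.ndarray  # (N,) radians
    responses: np.ndarray     # (N,) corner scores
    descriptors: np.ndarray   # (N, 256) bool

    def __len__(self):
        return len(self.positions)


@dataclass
class PlanarTransform:
    """3x3 projective transform with fit diagnostics."""

    matrix: np.ndarray
    n_inliers: int = 0
    rms_residual_px: float = 0.0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError("matrix must be 3x3")
        if abs(m[2, 2]) < 1e-12:
            raise ValueError("degenerate projective matrix")
        self.matrix = m / m[2, 2]

    @classmethod
    def identity(cls) -> "PlanarTransform":
        return cls(matrix=np.eye(3))

    @classmethod
    def from_similarity(cls, shift_xy=(0.0, 0.0), rot_deg: float = 0.0,
                        scale: float = 1.0, center_xy=(0.0, 0.0)) -> "PlanarTransform":
        """Similarity transform rotating/scaling about a centre, then shifting."""
        th = np.deg2rad(rot_deg)
        c, s = np.cos(th), np.sin(th)
        a = scale * np.array([[c, -s], [s, c]])
        ctr = np.asarray(center_xy, dtype=np.float64)
        m = np.eye(3)
        m[:2, :2] = a
        m[:2, 2] = ctr - a @ ctr + np.asarray(shift_xy, dtype=np.float64)
        return cls(matrix=m)

    def apply(self, points_xy: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points_xy)
        hom = np.column_stack([pts, np.ones(len(pts))])
        out = hom @ self.matrix.T
        return out[:, :2] / out[:, 2:3]

    def invert(self) -> "PlanarTransform":
        return PlanarTransform(matrix=np.linalg.inv(self.matrix),
                               n_inliers=self.n_inliers,
                               rms_residual_px=self.rms_residual_px)

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:2, 2].copy()

    def rescaled(self, factor: float) -> "PlanarTransform":
        """The same geometric mapping expressed on a grid scaled by 1/factor
        (e.g. express a GT-scale transform in the low-resolution frame)."""
        s = np.diag([factor, factor, 1.0])
        return PlanarTransform(matrix=np.linalg.inv(s) @ self.matrix @ s,
                               n_inliers=self.n_inliers,
                               rms_residual_px=self.rms_residual_px)


def transform_rms_deviation(t_a: PlanarTransform, t_b: PlanarTransform,
                            shape, n: int = 32,
                            coupled_only: bool = False) -> float:
    """RMS distance between two transforms evaluated on an n x n point grid.

    With ``coupled_only`` the grid is restricted to coupled pixels: points
    whose image under the reference transform ``t_b`` lies inside ``shape``
    (pixels with no counterpart in the other frame carry no registration
    information).
    """
    h, w = shape
    xs = np.linspace(0, w - 1, n)
    ys = np.linspace(0, h - 1, n)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    if coupled_only:
        mapped = t_b.apply(pts)
        keep = ((mapped[:, 0] >= 0) & (mapped[:, 0] <= w - 1)
                & (mapped[:, 1] >= 0) & (mapped[:, 1] <= h - 1))
        pts = pts[keep]
    d = t_a.apply(pts) - t_b.apply(pts)
    return float(np.sqrt((d ** 2).sum(axis=1).mean()))


# ---------------------------------------------------------------------------
# detection / matching / warping
# ---------------------------------------------------------------------------

def _as_gray_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.sum(axis=2)
    img = img.astype(np.float64)
    rng_ = img.max() - img.min()
    if rng_ > 0:
        img = (img - img.min()) / rng_
    return img


def detect_orb(image: np.ndarray, n_features: int = 1000) -> KeypointSet:
    """ORB keypoints + 256-bit rotated-BRIEF descriptors, best-first."""
    img = _as_gray_float(image)
    empty = KeypointSet(positions=np.empty((0, 2)), orientations=np.empty(0),
                        responses=np.empty(0), descriptors=np.empty((0, 256), dtype=bool))
    if min(img.shape) < 16 or img.max() == img.min():
        return empty
    orb = ORB(n_keypoints=n_features)
    try:
        orb.detect_and_extract(img)
    except (RuntimeError, ValueError, IndexError):
        return empty
    if orb.keypoints is None or len(orb.keypoints) == 0:
        return empty
    return KeypointSet(positions=orb.keypoints[:, ::-1].copy(),
                       orientations=orb.orientations.copy(),
                       responses=orb.responses.copy(),
                       descriptors=orb.descriptors.copy())


def match_and_estimate(a: KeypointSet, b: KeypointSet, ransac_thresh_px: float = 3.0,
                       seed: int = 0, model: str = "projective",
                       max_ratio: float = 0.8) -> PlanarTransform:
    """Hamming matching (cross-checked, ratio test) + RANSAC planar fit.

    Returns the transform mapping a-coordinates onto b-coordinates, refined
    by least squares on the RANSAC inliers.
    """
    if len(a) == 0 or len(b) == 0:
        raise RegistrationError("no keypoints to match",
                                {"n_a": len(a), "n_b": len(b)})
    matches = match_descriptors(a.descriptors, b.descriptors,
                                cross_check=True, max_ratio=max_ratio)
    if len(matches) < 4:
        raise RegistrationError(
            f"only {len(matches)} usable matches (need >= 4)",
            {"n_a": len(a), "n_b": len(b), "n_matches": int(len(matches))})
    src = a.positions[matches[:, 0]]
    dst = b.positions[matches[:, 1]]
    model_cls = ProjectiveTransform if model == "projective" else AffineTransform
    try:
        fit, inliers = _ransac((src, dst), model_cls, min_samples=4,
                               residual_threshold=ransac_thresh_px,
                               max_trials=2000, rng=seed)
    except ValueError as exc:
        raise RegistrationError(f"RANSAC failed: {exc}",
                                {"n_matches": int(len(matches))}) from exc
    if fit is None or inliers is None or int(inliers.sum()) < 4:
        raise RegistrationError("RANSAC found no consensus",
                                {"n_matches": int(len(matches))})
    def _ls_fit(mask):
        if hasattr(model_cls, "from_estimate"):
            est = model_cls.from_estimate(src[mask], dst[mask])
            return est if est else None
        est = model_cls()
        return est if est.estimate(src[mask], dst[mask]) else None

    refined = _ls_fit(inliers) or fit
    # one inlier-tightening pass: re-select against the refined model, refit
    resid = np.sqrt(((refined(src) - dst) ** 2).sum(axis=1))
    tightened = resid < ransac_thresh_px
    if tightened.sum() >= max(4, int(inliers.sum())):
        refit = _ls_fit(tightened)
        if refit is not None:
            refined, inliers = refit, tightened
    fwd = refined(src[inliers]) - dst[inliers]
    bwd = refined.inverse(dst[inliers]) - src[inliers]
    rms = float(np.sqrt(0.5 * ((fwd ** 2).sum(1) + (bwd ** 2).sum(1)).mean()))
    return PlanarTransform(matrix=refined.params, n_inliers=int(inliers.sum()),
                           rms_residual_px=rms)


def warp(image: np.ndarray, transform: PlanarTransform, out_shape=None) -> np.ndarray:
    """Resample `image` under `transform` (input -> output mapping) with
    bilinear interpolation; out-of-domain pixels are 0."""
    m = transform.matrix
    if not np.isfinite(m).all():
        raise ValueError("non-finite transform matrix")
    out_shape = tuple(out_shape) if out_shape is not None else image.shape[:2]
    if np.allclose(m, np.eye(3), atol=0.0):
        out = np.zeros(out_shape + image.shape[2:], dtype=np.float32)
        h = min(out_shape[0], image.shape[0])
        w = min(out_shape[1], image.shape[1])
        out[:h, :w] = image[:h, :w]
        return out
    inv = ProjectiveTransform(matrix=np.linalg.inv(m))
    warped = _warp(image.astype(np.float64), inv, output_shape=out_shape,
                   order=1, cval=0.0, preserve_range=True)
    return warped.astype(np.float32)


def preregister(input_img: np.ndarray, gt_img: np.ndarray,
                downsample_factor: int = 4, n_features: int = 1200,
                ransac_thresh_px: float = 3.0, seed: int = 0,
                model: str = "projective"):
    """Estimate and apply the fast-scan -> slow-scan alignment.

    The low-resolution input is bicubically upscaled to the ground-truth
    grid (descriptors need comparable spatial frequency content), features
    are matched against the ground truth, and the estimated transform is
    applied to the input in its own low-resolution frame.  Registration is
    channel-agnostic: both images are reduced to their channel sum.

    Returns (warped_input, transform_at_gt_scale).
    """
    gt_gray = _as_gray_float(gt_img)
    in_gray = _as_gray_float(input_img)
    f = downsample_factor
    if tuple(np.array(in_gray.shape) * f) != gt_gray.shape:
        raise ValueError("input dims x downsample_factor must equal GT dims")
    up = resize(in_gray, gt_gray.shape, order=3, anti_aliasing=False)
    kp_in = detect_orb(up, n_features)
    kp_gt = detect_orb(gt_gray, n_features)
    tform = match_and_estimate(kp_in, kp_gt, ransac_thresh_px, seed=seed, model=model)
    t_lr = tform.rescaled(f)
    warped = warp(input_img, t_lr, out_shape=input_img.shape[:2])
    return warped, tform
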