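"""Landmark-based registration between fluorescence and EM frames.

Fluorescence (SIM) and TEM images of the same section live in different
coordinate frames related by an unknown smooth distortion (stage rotation,
magnification, section deformation).  Corresponding fiducials — beads or
nuclear features, picked manually — define the mapping.  Two warp families
are provided: a least-squares affine and a thin-plate spline (TPS) with
optional regularization, the standard smooth interpolating warp minimizing
bending energy.

Registration accuracy is scored the way the field does it: fit ellipses to
the same granule in both modalities, warp the fluorescence center into the
EM frame, and summarize the center-to-center distances.

Conventions: 0-based pixel-center coordinates, x = column, y = row;
physical units are nm via per-image pixel size (EM acquisition default
1.8844194 nm/px).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "EM_PIXEL_SIZE_NM",
    "LandmarkPair",
    "WarpTransform",
    "EllipseFit",
    "RegistrationErrorReport",
    "fit_affine",
    "fit_tps",
    "apply_transform",
    "warp_points",
    "warp_image",
    "invert_affine",
    "ellipse_from_mask",
    "registration_error",
]

EM_PIXEL_SIZE_NM = 1.8844194  # TEM acquisition pixel size, nm/px


@dataclass(frozen=True)
class LandmarkPair:
    """One manually picked correspondence between the two frames (nm)."""

    p_flm: tuple[float, float]
    p_em: tuple[float, float]
    label: str = ""

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.p_flm)) and np.all(np.isfinite(self.p_em))):
            raise ValueError(f"landmark {self.label!r} has non-finite coordinates")


@dataclass
class WarpTransform:
    """2-D mapping from the FLM frame to the EM frame.

    ``kind='affine'`` uses only ``matrix`` and ``translation``;
    ``kind='tps'`` adds radial-basis terms with kernel U(r) = r^2 log r on
    the stored control points.
    """

    kind: str
    matrix: np.ndarray  # 2x2
    translation: np.ndarray  # (2,)
    control_points: np.ndarray | None = None  # (n, 2) source points
    coefficients: np.ndarray | None = None  # (n, 2) kernel weights
    regularization: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float).reshape(2, 2)
        self.translation = np.asarray(self.translation, float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-15:
            raise ValueError("affine matrix is singular")
        if self.kind not in ("affine", "tps"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "tps" and (self.control_points is None or self.coefficients is None):
            raise ValueError("tps transform requires control points and coefficients")

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return warp_points(self, points)

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "matrix": self.matrix.tolist(),
            "translation": self.translation.tolist(),
            "regularization": self.regularization,
        }
        if self.kind == "tps":
            d["control_points"] = self.control_points.tolist()
            d["coefficients"] = self.coefficients.tolist()
        return d

    @staticmethod
    def from_dict(d: dict) -> "WarpTransform":
        return WarpTransform(
            kind=d["kind"],
            matrix=np.asarray(d["matrix"]),
            translation=np.asarray(d["translation"]),
            control_points=np.asarray(d["control_points"]) if "control_points" in d else None,
            coefficients=np.asarray(d["coefficients"]) if "coefficients" in d else None,
            regularization=float(d.get("regularization", 0.0)),
        )


@dataclass(frozen=True)
class EllipseFit:
    """Moment-based ellipse of one granule footprint (nm units)."""

    center: tuple[float, float]
    major_radius: float
    minor_radius: float
    orientation: float  # radians, CCW from +x axis

    def __post_init__(self) -> None:
        if not self.major_radius >= self.minor_radius > 0:
            raise ValueError("ellipse radii must satisfy major >= minor > 0")


@dataclass(frozen=True)
class RegistrationErrorReport:
    """Center-to-center shift distances between correlated granule pairs."""

    distances: np.ndarray  # nm
    mean: float
    sd: float
    n: int


def _as_points(points) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    return pts


def fit_affine(landmarks: list[LandmarkPair]) -> WarpTransform:
    """Least-squares affine FLM->EM from >=3 non-collinear landmark pairs."""
    if len(landmarks) < 3:
        raise ValueError(
            f"affine fit needs at least 3 landmark pairs, got {len(landmarks)}"
        )
    src = np.array([lm.p_flm for lm in landmarks])
    dst = np.array([lm.p_em for lm in landmarks])
    design = np.hstack([src, np.ones((len(src), 1))])
    if np.linalg.matrix_rank(design - design.mean(0)) < 2:
        raise ValueError("landmark configuration is collinear; affine is underdetermined")
    sol, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return WarpTransform(kind="affine", matrix=sol[:2].T, translation=sol[2])


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r, with U(0) = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 * r2 * np.log(r2)  # r^2 log r = 0.5 r^2 log r^2
    return np.where(r2 > 0, out, 0.0)


def fit_tps(landmarks: list[LandmarkPair], regularization: float = 0.0) -> WarpTransform:
    """Thin-plate spline FLM->EM (Bookstein formulation).

    With ``regularization=0`` the warp interpolates the landmarks exactly;
    increasing it trades landmark fidelity for smoothness and in the limit
    approaches the affine fit.
    """
    if len(landmarks) < 4:
        raise ValueError(f"tps fit needs at least 4 landmark pairs, got {len(landmarks)}")
    if regularization < 0:
        raise ValueError("regularization must be non-negative")
    src = np.array([lm.p_flm for lm in landmarks])
    dst = np.array([lm.p_em for lm in landmarks])
    n = len(src)
    d2 = np.sum((src[:, None, :] - src[None, :, :]) ** 2, axis=-1)
    if np.any(d2[~np.eye(n, dtype=bool)] == 0):
        raise ValueError("duplicate source points; tps system is singular")
    K = _tps_kernel(d2) + regularization * np.eye(n)
    P = np.hstack([np.ones((n, 1)), src])
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = dst
    sol = np.linalg.solve(A, rhs)
    w, affine = sol[:n], sol[n:]
    return WarpTransform(
        kind="tps",
        matrix=affine[1:].T,
        translation=affine[0],
        control_points=src,
        coefficients=w,
        regularization=regularization,
    )


def warp_points(transform: WarpTransform, points) -> np.ndarray:
    """Map points (n, 2) through the transform; preserves input arity."""
    pts = _as_points(points)
    out = pts @ transform.matrix.T + transform.translation
    if transform.kind == "tps":
        d2 = np.sum((pts[:, None, :] - transform.control_points[None, :, :]) ** 2, axis=-1)
        out = out + _tps_kernel(d2) @ transform.coefficients
    return out


def invert_affine(transform: WarpTransform) -> WarpTransform:
    if transform.kind != "affine":
        raise ValueError("only affine transforms have a closed-form inverse")
    inv = np.linalg.inv(transform.matrix)
    return WarpTransform(kind="affine", matrix=inv, translation=-inv @ transform.translation)


def warp_image(
    transform: WarpTransform,
    image: np.ndarray,
    output_shape: tuple[int, int] | None = None,
    src_pixel_size_nm: float = 1.0,
    dst_pixel_size_nm: float = 1.0,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample ``image`` (source frame) onto the target grid.

    For each target pixel center the source location is found through the
    *inverse* mapping and sampled bilinearly.  For a TPS the inverse has no
    closed form; it is approximated by a TPS fitted in the reverse direction
    on the control points, which is accurate for the smooth, gentle
    distortions fiducial-based correlation deals with.
    """
    image = np.asarray(image, float)
    if image.ndim != 2:
        raise ValueError("only single-plane 2-D images are supported")
    if output_shape is None:
        output_shape = image.shape
    if transform.kind == "affine":
        inverse = invert_affine(transform)
    else:
        fwd = warp_points(transform, transform.control_points)
        pairs = [LandmarkPair(tuple(p), tuple(q)) for p, q in zip(fwd, transform.control_points)]
        inverse = fit_tps(pairs, regularization=transform.regularization)
    rows, cols = np.mgrid[0 : output_shape[0], 0 : output_shape[1]]
    dst_nm = np.column_stack([cols.ravel(), rows.ravel()]).astype(float) * dst_pixel_size_nm
    src_nm = warp_points(inverse, dst_nm)
    src_px = src_nm / src_pixel_size_nm
    coords = np.vstack([src_px[:, 1], src_px[:, 0]])  # map_coordinates wants (row, col)
    sampled = ndimage.map_coordinates(image, coords, order=1, mode="constant", cval=cval)
    return sampled.reshape(output_shape)


def apply_transform(transform: WarpTransform, data, **image_kwargs):
    """Warp points (array of shape (n, 2) or (2,)) or a 2-D image.

    Point arrays are mapped exactly through the forward transform; images
    are resampled bilinearly (see :func:`warp_image` for keyword options).
    """
    arr = np.asarray(data, float)
    if arr.ndim == 1 and arr.shape == (2,):
        return warp_points(transform, arr)[0]
    if arr.ndim == 2 and arr.shape[1] == 2 and not image_kwargs:
        return warp_points(transform, arr)
    return warp_image(transform, arr, **image_kwargs)


def ellipse_from_mask(mask: np.ndarray, pixel_size_nm: float = 1.0) -> EllipseFit:
    """Moment-based ellipse of a single thresholded footprint.

    The center is the intensity-free centroid of the footprint and the radii
    come from the second central moments (the same ellipse regionprops
    reports), all scaled to nm.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty; no footprint to fit")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    cy, cx = props.centroid
    major = max(props.axis_major_length / 2.0, 1e-9)
    minor = max(props.axis_minor_length / 2.0, 1e-9)
    minor = min(minor, major)
    # regionprops orientation is measured from the vertical (row) axis
    orientation = math.pi / 2.0 - props.orientation
    return EllipseFit(
        center=(cx * pixel_size_nm, cy * pixel_size_nm),
        major_radius=major * pixel_size_nm,
        minor_radius=minor * pixel_size_nm,
        orientation=orientation,
    )


def registration_error(pairs: list[tuple[EllipseFit, EllipseFit]]) -> RegistrationErrorReport:
    """Center shift between warped-FLM and EM ellipses of the same granules.

    ``pairs`` holds (FLM ellipse already warped into the EM frame, EM
    ellipse).  Returns per-pair Euclidean distances with their mean and
    sample SD (ddof=1; 0 for a single pair).
    """
    if not pairs:
        raise ValueError("need at least one ellipse pair")
    d = np.array(
        [math.dist(flm.center, em.center) for flm, em in pairs], dtype=float
    )
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return RegistrationErrorReport(distances=d, mean=float(d.mean()), sd=sd, n=d.size)
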