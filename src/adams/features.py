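"""SIFT keypoint extraction from distance-matrix images.

Keypoints are detected as extrema of a difference-of-Gaussians scale
space and described by the standard 128-dimension gradient-orientation
histogram. Detection and description are delegated to scikit-image's
SIFT; descriptor rows are then re-normalized to unit Euclidean norm so
that downstream matching can read cosine similarity directly off a dot
product.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.feature import SIFT

from .errors import DegenerateInputError, InvalidInputError

__all__ = ["SiftParams", "Keypoint", "FeatureMatrix", "extract_features",
           "count_features", "DESCRIPTOR_DIM"]

DESCRIPTOR_DIM = 128

#: Feature counts below this are flagged in search output: structures with
#: very few keypoints sit outside the method's reliable detection range.
LOW_FEATURE_FLOOR = 5


@dataclass(frozen=True)
class SiftParams:
    """Detector/descriptor hyperparameters.

    Defaults are the stock values of the underlying SIFT implementation;
    they are exposed here so a database records exactly what it was built
    with. ``max_features`` optionally caps the number of keypoints kept
    (first-come in detection order) for memory control; ``None`` keeps all.
    """

    upsampling: int = 2
    n_octaves: int = 8
    n_scales: int = 3
    sigma_min: float = 1.6
    sigma_in: float = 0.5
    c_dog: float = 0.04 / 3
    c_edge: float = 10.0
    max_features: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SiftParams":
        return cls(**d)

    def _detector(self) -> SIFT:
        return SIFT(
            upsampling=self.upsampling,
            n_octaves=self.n_octaves,
            n_scales=self.n_scales,
            sigma_min=self.sigma_min,
            sigma_in=self.sigma_in,
            c_dog=self.c_dog,
            c_edge=self.c_edge,
        )


@dataclass(frozen=True)
class Keypoint:
    """One detected keypoint: subpixel image position, scale (sigma of the
    detection level), dominant gradient orientation in degrees, and the
    detector response (0.0 when the backend does not expose one)."""

    row: float
    col: float
    scale: float
    orientation: float
    response: float = 0.0


@dataclass
class FeatureMatrix:
    """Unit-norm descriptor rows plus keypoint metadata for one structure.

    ``descriptors`` is ``n_features x 128`` float64; every row has unit
    Euclidean norm and non-negative entries (gradient histograms are
    non-negative, and L2 normalization preserves sign).
    """

    id: str
    descriptors: np.ndarray
    keypoints: list[Keypoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.descriptors = np.asarray(self.descriptors, dtype=np.float64)
        if self.descriptors.ndim != 2:
            raise InvalidInputError("descriptors must be a 2D matrix")
        if self.descriptors.shape[0] and (
            self.descriptors.shape[1] != DESCRIPTOR_DIM
        ):
            raise InvalidInputError(
                f"descriptor width must be {DESCRIPTOR_DIM}, "
                f"got {self.descriptors.shape[1]}"
            )

    @property
    def n_features(self) -> int:
        return self.descriptors.shape[0]

    @classmethod
    def empty(cls, structure_id: str) -> "FeatureMatrix":
        return cls(
            id=structure_id,
            descriptors=np.zeros((0, DESCRIPTOR_DIM), dtype=np.float64),
        )


def extract_features(
    img: np.ndarray,
    params: SiftParams | None = None,
    structure_id: str = "",
) -> FeatureMatrix:
    """Detect SIFT keypoints on an 8-bit image and describe each one.

    Returns all detected keypoints with their descriptors, rows
    L2-normalized to unit length. Zero keypoints is a valid outcome
    (flat or near-featureless images), not an error.

    Raises
    ------
    InvalidInputError
        If ``img`` is not a 2D array.
    DegenerateInputError
        If the smaller image dimension is below 8 pixels, too small for
        the scale space.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise InvalidInputError(f"image must be 2D, got ndim={img.ndim}")
    if min(img.shape) < 8:
        raise DegenerateInputError(
            f"image {img.shape} too small for scale-space detection"
        )
    if params is None:
        params = SiftParams()

    detector = params._detector()
    try:
        detector.detect_and_extract(img.astype(np.uint8))
    except RuntimeError:
        # backend signals "no features found" by raising
        return FeatureMatrix.empty(structure_id)

    raw = detector.descriptors.astype(np.float64)
    norms = np.linalg.norm(raw, axis=1)
    keep = norms > 0
    descriptors = raw[keep] / norms[keep, np.newaxis]
    positions = detector.positions[keep]
    sigmas = detector.sigmas[keep]
    orientations = np.rad2deg(detector.orientations[keep])

    if params.max_features is not None:
        descriptors = descriptors[: params.max_features]
        positions = positions[: params.max_features]
        sigmas = sigmas[: params.max_features]
        orientations = orientations[: params.max_features]

    keypoints = [
        Keypoint(row=float(p[0]), col=float(p[1]), scale=float(s),
                 orientation=float(o))
        for p, s, o in zip(positions, sigmas, orientations)
    ]
    return FeatureMatrix(id=structure_id, descriptors=descriptors,
                         keypoints=keypoints)


def count_features(fm: FeatureMatrix) -> int:
    """Number of keypoints in a feature matrix.

    A low count is itself diagnostic: structures whose distance image is
    too plain to anchor keypoints are the method's characteristic false
    negatives, so search output flags queries below ``LOW_FEATURE_FLOOR``.
    """
    return fm.n_features
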