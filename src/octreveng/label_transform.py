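"""Transfer of follow-up FAF atrophy annotations into baseline OCT space.

The follow-up FAF image is registered onto the baseline en-face OCT
projection with a projective homography fitted to manually selected
keypoint pairs (vessel landmarks). The registered 2D atrophy mask is then
resampled to the volume's (width, depth) grid and extruded through every
A-scan column between the ILM and C-S retinal boundaries, producing one
binary ground-truth mask per B-scan.

Coordinate conventions
----------------------
* Images are indexed (row, column); keypoints are (x, y) = (column, row),
  0-based, matching the JSON interchange format.
* En-face arrays are (width, depth) of the source volume, width as rows.
* A homography maps source (follow-up) coordinates to destination
  (baseline) coordinates; ``warp`` pushes image content forward through
  the transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import transform as sktf


# ----------------------------------------------------------------------
# resampling helpers (exact for integer scale factors)
# ----------------------------------------------------------------------

def resize_nearest(arr: np.ndarray, shape) -> np.ndarray:
    """Nearest-neighbor resize preserving dtype/binarity.

    Integer up/down factors take an exact block path (repeat / centered
    stride sampling) so that upscale followed by downscale is the identity;
    anything else falls back to coordinate-mapped resampling.
    """
    arr = np.asarray(arr)
    h0, w0 = arr.shape
    h1, w1 = shape
    if h1 % h0 == 0 and w1 % w0 == 0:
        return np.repeat(np.repeat(arr, h1 // h0, axis=0), w1 // w0, axis=1)
    if h0 % h1 == 0 and w0 % w1 == 0:
        fy, fx = h0 // h1, w0 // w1
        return arr[fy // 2::fy, fx // 2::fx].copy()
    out = sktf.resize(arr.astype(float), shape, order=0,
                      anti_aliasing=False, preserve_range=True)
    return out.astype(arr.dtype) if arr.dtype == bool else out.astype(arr.dtype)


def resize_bilinear(arr: np.ndarray, shape) -> np.ndarray:
    """Bilinear resize; downscaling applies the Gaussian anti-alias
    prefilter (skimage's default) so fine speckle does not alias."""
    return sktf.resize(np.asarray(arr, dtype=float), shape, order=1,
                       anti_aliasing=None, preserve_range=True)


# ----------------------------------------------------------------------
# keypoints and planar transforms
# ----------------------------------------------------------------------

@dataclass
class KeypointSet:
    """Point correspondences (source = follow-up frame, destination =
    baseline en-face frame), each pair ((x_src, y_src), (x_dst, y_dst))."""

    pairs: list

    def __post_init__(self):
        self.pairs = [((float(s[0]), float(s[1])), (float(d[0]), float(d[1])))
                      for s, d in self.pairs]

    def __len__(self):
        return len(self.pairs)

    @property
    def src(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=float)

    @property
    def dst(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=float)

    def to_json(self, path):
        Path(path).write_text(json.dumps(
            {"pairs": [[list(s), list(d)] for s, d in self.pairs]}))

    @classmethod
    def from_json(cls, path):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"missing keypoint file: {path}")
        return cls(pairs=[(tuple(s), tuple(d))
                          for s, d in json.loads(path.read_text())["pairs"]])


class PlanarTransform:
    """3x3 projective homography on (x, y) points, normalized so the
    bottom-right entry is 1 whenever it is nonzero."""

    def __init__(self, matrix):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("homography matrix must be 3x3")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("homography matrix is singular")
        if m[2, 2] != 0:
            m = m / m[2, 2]
        self.matrix = m

    @classmethod
    def identity(cls):
        return cls(np.eye(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) (x, y) points through the homography."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ph = np.column_stack([pts, np.ones(len(pts))])
        out = ph @ self.matrix.T
        return out[:, :2] / out[:, 2:3]

    def inverse(self) -> "PlanarTransform":
        return PlanarTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "PlanarTransform") -> "PlanarTransform":
        """self ∘ other (apply ``other`` first)."""
        return PlanarTransform(self.matrix @ other.matrix)

    def to_skimage(self) -> sktf.ProjectiveTransform:
        return sktf.ProjectiveTransform(matrix=self.matrix)

    def to_json(self, path):
        Path(path).write_text(json.dumps({"matrix": self.matrix.tolist()}))

    @classmethod
    def from_json(cls, path):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"missing transform file: {path}")
        return cls(json.loads(path.read_text())["matrix"])


def fit_planar_transform(kp: KeypointSet) -> PlanarTransform:
    """Least-squares homography from keypoint pairs (normalized DLT).

    Exact for noiseless, consistent pairs; raises on fewer than 4 pairs or
    a degenerate (rank-deficient) configuration.
    """
    if len(kp) < 4:
        raise ValueError(f"projective fit needs >= 4 keypoint pairs, got {len(kp)}")
    t = sktf.ProjectiveTransform.from_estimate(kp.src, kp.dst)
    if not t or not np.all(np.isfinite(t.params)) or \
            abs(np.linalg.det(t.params)) < 1e-12:
        raise ValueError("degenerate keypoint configuration: homography "
                         "system is rank-deficient")
    return PlanarTransform(t.params)


def warp(image: np.ndarray, t: PlanarTransform, out_shape=None,
         order: int | None = None) -> np.ndarray:
    """Push an image forward through ``t`` (source -> destination frame).

    Inverse-mapping resampling: bilinear for grayscale, nearest-neighbor
    for boolean masks; samples falling outside the source frame are 0.
    """
    image = np.asarray(image)
    is_mask = image.dtype == bool
    if order is None:
        order = 0 if is_mask else 1
    if out_shape is None:
        out_shape = image.shape
    inv = t.inverse().to_skimage()  # maps destination coords -> source coords
    out = sktf.warp(image.astype(float), inverse_map=inv,
                    output_shape=tuple(out_shape), order=order, cval=0.0,
                    preserve_range=True)
    if is_mask:
        return out > 0.5
    return out


# ----------------------------------------------------------------------
# en-face projection, registration, extrusion
# ----------------------------------------------------------------------

def project_volume(oct_volume: np.ndarray) -> np.ndarray:
    """Mean-intensity en-face projection along the height (axial) axis.

    (height, width, depth) volume -> (width, depth) map; for volumes in
    [0, 1] the projection stays in [0, 1].
    """
    vol = np.asarray(oct_volume)
    if vol.ndim != 3:
        raise ValueError("expected a 3D (height, width, depth) volume")
    return vol.mean(axis=0)


def register_annotation(followup_mask: np.ndarray, kp: KeypointSet,
                        out_shape=None) -> np.ndarray:
    """Map a binary follow-up annotation into baseline en-face coordinates
    using the homography fitted to the keypoints. Result is binary."""
    mask = np.asarray(followup_mask).astype(bool)
    t = fit_planar_transform(kp)
    return warp(mask, t, out_shape=out_shape or mask.shape)


@dataclass
class LayerBoundaries:
    """Per-A-scan ILM (inner) and C-S (outer) boundary rows, indexed
    (width, depth)."""

    ilm_row: np.ndarray
    cs_row: np.ndarray

    def __post_init__(self):
        self.ilm_row = np.asarray(self.ilm_row, dtype=int)
        self.cs_row = np.asarray(self.cs_row, dtype=int)
        if self.ilm_row.shape != self.cs_row.shape:
            raise ValueError("ILM and C-S arrays must share shape")
        if np.any(self.ilm_row < 0) or np.any(self.ilm_row >= self.cs_row):
            raise ValueError("layer ordering violated: need 0 <= ilm < cs")

    def validate_height(self, height: int):
        if np.any(self.cs_row >= height):
            raise ValueError("C-S boundary exceeds volume height")


def extrude_label(enface_mask: np.ndarray, layers: LayerBoundaries,
                  volume_shape) -> np.ndarray:
    """Extrude a 2D en-face mask through the retina of each A-scan column.

    For every positive en-face pixel (w, d), rows ilm..cs (inclusive) of
    column w in B-scan d become positive; everything else is negative.
    The mask is nearest-resampled to (width, depth) first if needed.
    """
    h, w, d = volume_shape
    if layers.ilm_row.shape != (w, d):
        raise ValueError(
            f"layer shape {layers.ilm_row.shape} does not match volume "
            f"(width, depth) = {(w, d)}")
    layers.validate_height(h)
    mask = np.asarray(enface_mask).astype(bool)
    if mask.shape != (w, d):
        mask = resize_nearest(mask, (w, d))
    rows = np.arange(h)[:, None, None]
    band = (rows >= layers.ilm_row[None]) & (rows <= layers.cs_row[None])
    return band & mask[None]


def collapse_stack(stack: np.ndarray) -> np.ndarray:
    """En-face support of a per-B-scan label stack: any positive voxel
    along height -> (width, depth) binary map."""
    return np.asarray(stack).astype(bool).any(axis=0)
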