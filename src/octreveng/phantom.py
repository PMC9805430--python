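"""Synthetic retinal phantoms: paired baseline OCT + FAF with known truth.

Each phantom case is the synthetic twin of one patient visit pair: a
baseline OCT volume with layered B-scan anatomy and speckle, a baseline
FAF-like en-face image, a follow-up FAF image related to baseline by a
known planar (projective) misalignment, and a binary geographic-atrophy
annotation on the follow-up image.

Three lesion classes are rendered into the volume:

* druse clusters — confluent dome-shaped RPE elevations;
* hyper-reflective foci (HRF) — small bright intraretinal blobs;
* subretinal drusenoid deposits (SDD) — thin bright sheets above the RPE.

The generative conversion rule is fixed: druse clusters convert to GA at
follow-up; isolated HRF and SDD do not. The follow-up GA annotation is
therefore the union of converting footprints, optionally dilated, warped
into follow-up coordinates by the inverse of the ground-truth transform.
Because every ingredient (lesions, layers, transform, keypoints) is known
exactly, each downstream stage can be validated against ground truth.

All intensities are quantized to their on-disk precision (16-bit volume,
8-bit 2D images) at generation time, so a write/read round trip
reproduces the in-memory case exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage

from .label_transform import (KeypointSet, LayerBoundaries, PlanarTransform,
                              resize_nearest, warp)

FAF_SIZE = 512  # en-face FAF frame is FAF_SIZE x FAF_SIZE

LESION_KINDS = ("druse_cluster", "hyper_reflective_focus", "sdd")


@dataclass
class PhantomSpec:
    """Generation parameters for one phantom case.

    Geometry is (height, width, depth); lesion radii are given in FAF-frame
    pixels (the 512 x 512 en-face frame) except the HRF radius, which is a
    3D blob radius in volume pixels. ``transform_jitter`` bounds the random
    baseline/follow-up misalignment as (max translation px, max rotation
    deg, max projective perturbation). ``conversion_margin`` dilates GA
    footprints (FAF px) before they are declared atrophic.
    """

    volume_shape: tuple = (256, 128, 32)
    n_druse_clusters: int = 2
    n_foci: int = 3
    n_sdd: int = 2
    druse_radius_range: tuple = (24.0, 40.0)
    focus_radius_range: tuple = (2.0, 3.5)
    noise_sigma: float = 0.08
    transform_jitter: tuple = (10.0, 3.0, 4e-5)
    conversion_margin: int = 4
    seed: int = 0

    def __post_init__(self):
        h, w, d = self.volume_shape
        if min(h, w, d) <= 0:
            raise ValueError("volume_shape must be strictly positive")
        for name in ("n_druse_clusters", "n_foci", "n_sdd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("druse_radius_range", "focus_radius_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must satisfy 0 < min <= max")
        if not 0 <= self.noise_sigma <= 1:
            raise ValueError("noise_sigma must lie in [0, 1]")
        if self.conversion_margin < 0:
            raise ValueError("conversion_margin must be >= 0")


@dataclass
class LesionRecord:
    """One rendered lesion: its en-face footprint on the volume's
    (width, depth) grid, the axial anchor row per footprint pixel, and
    whether it converts to GA (true exactly for druse clusters)."""

    kind: str
    enface_footprint: np.ndarray
    axial_anchor: np.ndarray
    converts: bool

    def __post_init__(self):
        if self.kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.converts != (self.kind == "druse_cluster"):
            raise ValueError("conversion rule violated: druse clusters and "
                             "only druse clusters convert")
        if not np.any(self.enface_footprint):
            raise ValueError("lesion footprint is empty")


@dataclass
class RetinalLayers:
    """ILM, RPE and C-S boundary rows per A-scan, indexed (width, depth)."""

    ilm_row: np.ndarray
    rpe_row: np.ndarray
    cs_row: np.ndarray

    def boundaries(self) -> LayerBoundaries:
        return LayerBoundaries(ilm_row=self.ilm_row, cs_row=self.cs_row)


@dataclass
class PhantomCase:
    oct: np.ndarray                 # (H, W, D) float32 in [0, 1]
    baseline_faf: np.ndarray        # (512, 512) float32 in [0, 1]
    followup_faf: np.ndarray        # (512, 512) float32 in [0, 1]
    followup_ga_mask: np.ndarray    # (512, 512) bool
    true_transform: PlanarTransform
    keypoints: KeypointSet
    layers: RetinalLayers
    lesions: list
    spec: PhantomSpec
    vessel_points: np.ndarray       # (V, 2) float (x, y) in baseline frame


# ----------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------

def _smooth_field(rng, shape, sigma, amplitude):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    s = f.std()
    if s > 0:
        f = f / s
    return amplitude * f


def _sample_transform(rng, jitter):
    """Random planar misalignment: rotation about the frame center,
    translation, and a mild projective perturbation, resampled until the
    frame-corner displacement stays bounded."""
    max_t, max_rot_deg, max_proj = jitter
    c = (FAF_SIZE - 1) / 2.0
    corners = np.array([[0, 0], [FAF_SIZE - 1, 0], [0, FAF_SIZE - 1],
                        [FAF_SIZE - 1, FAF_SIZE - 1]], dtype=float)
    for _ in range(100):
        th = np.deg2rad(rng.uniform(-max_rot_deg, max_rot_deg))
        tx, ty = rng.uniform(-max_t, max_t, size=2)
        g, hh = rng.uniform(-max_proj, max_proj, size=2)
        ca, sa = np.cos(th), np.sin(th)
        rot = np.array([[ca, -sa, c - ca * c + sa * c + tx],
                        [sa, ca, c - sa * c - ca * c + ty],
                        [0.0, 0.0, 1.0]])
        rot[2, 0], rot[2, 1] = g, hh
        t = PlanarTransform(rot)
        disp = np.linalg.norm(t.apply(corners) - corners, axis=1).max()
        if disp <= 0.15 * FAF_SIZE:
            return t
    raise RuntimeError("could not sample a bounded planar transform")


def _ellipse_footprint(shape, center, semi_w, semi_d):
    w, d = shape
    ww, dd = np.ogrid[:w, :d]
    q = ((ww - center[0]) / max(semi_w, 1e-9)) ** 2 + \
        ((dd - center[1]) / max(semi_d, 1e-9)) ** 2
    return q <= 1.0


def _place(rng, occupied, make_footprint, sep, attempts=300, what="lesion"):
    """Rejection-sample a footprint that stays ``sep`` px clear of previous
    lesions and the en-face border."""
    w, d = occupied.shape
    struct = _disk_structure(sep)
    for _ in range(attempts):
        fp, extra = make_footprint()
        if not fp.any():
            continue
        ws, ds = np.nonzero(fp)
        if ws.min() < sep or ws.max() >= w - sep or \
                ds.min() < 1 or ds.max() >= d - 1:
            continue
        grown = ndimage.binary_dilation(fp, structure=struct)
        if (grown & occupied).any():
            continue
        occupied |= grown
        return fp, extra
    raise RuntimeError(
        f"could not place {what} within the en-face area after "
        f"{attempts} rejection-sampling attempts; reduce lesion counts "
        f"or sizes")


def _disk_structure(radius):
    r = max(1, int(np.ceil(radius)))
    y, x = np.ogrid[-r:r + 1, -r:r + 1]
    return x * x + y * y <= r * r


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render one phantom case; a deterministic function of ``spec`` (all
    randomness derives from ``spec.seed``)."""
    h, w, d = spec.volume_shape
    ss = np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 0x0C7])
    (r_layers, r_lesions, r_noise, r_faf,
     r_transform, r_keypoints) = [np.random.default_rng(c) for c in ss.spawn(6)]

    scale_w = FAF_SIZE / w   # FAF px per volume-width px
    scale_d = FAF_SIZE / d

    # --- smooth retinal surfaces (rows grow downward) -------------------
    sig = (max(2, w // 16), max(1, d // 10))
    ilm = 0.22 * h + _smooth_field(r_layers, (w, d), sig, 0.030 * h)
    rpe0 = 0.60 * h + _smooth_field(r_layers, (w, d), sig, 0.020 * h)
    cs = 0.80 * h + _smooth_field(r_layers, (w, d), sig, 0.020 * h)

    # --- lesions --------------------------------------------------------
    occupied = np.zeros((w, d), dtype=bool)
    sep = max(1, int(np.ceil(spec.conversion_margin / min(scale_w, scale_d))) + 1)
    lesions = []
    elevation = np.zeros((w, d))

    for _ in range(spec.n_druse_clusters):
        def make_druse():
            r_faf_px = r_lesions.uniform(*spec.druse_radius_range)
            cw = r_lesions.uniform(0.15 * w, 0.85 * w)
            cd = r_lesions.uniform(0.2 * d, 0.8 * d)
            n_bumps = r_lesions.integers(2, 5)
            elev = np.zeros((w, d))
            for _ in range(n_bumps):
                bw = cw + r_lesions.uniform(-0.5, 0.5) * r_faf_px / scale_w
                bd = cd + r_lesions.uniform(-0.5, 0.5) * r_faf_px / scale_d
                rr = r_lesions.uniform(0.5, 1.0) * r_faf_px
                hgt = r_lesions.uniform(0.055, 0.10) * h
                ww, dd = np.ogrid[:w, :d]
                q = ((ww - bw) / (rr / scale_w)) ** 2 + \
                    ((dd - bd) / (rr / scale_d)) ** 2
                elev = np.maximum(elev, hgt * np.clip(1.0 - q, 0, None))
            fp = elev > 0.02 * h
            return fp, elev
        fp, elev = _place(r_lesions, occupied, make_druse, sep,
                          what="druse cluster")
        elev = np.where(fp, elev, 0.0)
        elevation = np.maximum(elevation, elev)
        anchor = np.where(fp, np.round(rpe0 - elev).astype(int), -1)
        lesions.append(LesionRecord("druse_cluster", fp, anchor, True))

    hrf_blobs = []
    for _ in range(spec.n_foci):
        def make_focus():
            r_px = r_lesions.uniform(*spec.focus_radius_range)
            cw = r_lesions.uniform(0.1 * w, 0.9 * w)
            cd = r_lesions.uniform(0.15 * d, 0.85 * d)
            rw = max(1.0, r_px)
            rd = max(1.0, r_px * d / w)
            fp = _ellipse_footprint((w, d), (cw, cd), rw, rd)
            return fp, (cw, cd, r_px, rw, rd)
        fp, (cw, cd, r_px, rw, rd) = _place(r_lesions, occupied, make_focus,
                                            sep, what="hyper-reflective focus")
        iw, idp = int(round(cw)), int(round(cd))
        row = int(r_lesions.uniform(ilm[iw, idp] + 0.06 * h,
                                    rpe0[iw, idp] - 0.08 * h))
        anchor = np.where(fp, row, -1)
        hrf_blobs.append((cw, cd, row, r_px, rw, rd))
        lesions.append(LesionRecord("hyper_reflective_focus", fp, anchor, False))

    sdd_patches = []
    for _ in range(spec.n_sdd):
        def make_sdd():
            r_faf_px = 0.5 * r_lesions.uniform(*spec.druse_radius_range)
            cw = r_lesions.uniform(0.15 * w, 0.85 * w)
            cd = r_lesions.uniform(0.2 * d, 0.8 * d)
            fp = _ellipse_footprint((w, d), (cw, cd),
                                    r_faf_px / scale_w, r_faf_px / scale_d)
            return fp, None
        fp, _x = _place(r_lesions, occupied, make_sdd, sep,
                        what="subretinal drusenoid deposit")
        anchor = np.where(fp, np.round(rpe0 - 0.03 * h).astype(int), -1)
        sdd_patches.append(fp)
        lesions.append(LesionRecord("sdd", fp, anchor, False))

    # --- integer surfaces (after druse elevation of the RPE) ------------
    rpe = rpe0 - elevation
    ilm_i = np.clip(np.round(ilm).astype(int), 2, h - 10)
    rpe_i = np.round(rpe).astype(int)
    rpe0_i = np.round(rpe0).astype(int)
    cs_i = np.round(cs).astype(int)
    rpe_i = np.clip(rpe_i, ilm_i + 4, h - 6)
    rpe0_i = np.clip(rpe0_i, rpe_i, h - 5)
    cs_i = np.clip(cs_i, rpe0_i + 3, h - 2)
    layers = RetinalLayers(ilm_row=ilm_i, rpe_row=rpe_i, cs_row=cs_i)

    # --- render the volume ----------------------------------------------
    rows = np.arange(h)[:, None, None]
    vol = np.full((h, w, d), 0.06)
    vol = np.where(rows >= ilm_i[None], 0.32, vol)              # retina
    vol = np.where(rows >= rpe_i[None] + 2, 0.55, vol)          # druse material
    vol = np.where(rows >= rpe0_i[None] + 2, 0.25, vol)         # choroid
    vol = np.where(np.abs(rows - rpe_i[None]) <= 1, 0.88, vol)  # RPE band
    vol = np.where(rows > cs_i[None], 0.10, vol)                # sclera

    for cw, cd, row, r_px, rw, rd in hrf_blobs:
        rr = np.arange(h)[:, None, None]
        ww, dd = np.ogrid[:w, :d]
        q = (((rr - row) / max(r_px, 1.0)) ** 2 +
             (((ww - cw) / rw) ** 2 + ((dd - cd) / rd) ** 2)[None, :, :])
        vol = np.where(q <= 1.0, 0.95, vol)

    for fp in sdd_patches:
        band = (rows >= rpe_i[None] - 4) & (rows <= rpe_i[None] - 3)
        vol = np.where(band & fp[None], 0.85, vol)

    if spec.noise_sigma > 0:
        vol = vol * (1.0 + spec.noise_sigma * r_noise.standard_normal(vol.shape))
    vol = np.clip(vol, 0.0, 1.0)
    vol = (np.round(vol * 65535) / 65535).astype(np.float32)

    # --- ground-truth GA in baseline then follow-up coordinates ---------
    converting = np.zeros((w, d), dtype=bool)
    for les in lesions:
        if les.converts:
            converting |= les.enface_footprint
    ga_base = resize_nearest(converting, (FAF_SIZE, FAF_SIZE))
    if spec.conversion_margin > 0 and ga_base.any():
        ga_base = ndimage.binary_dilation(
            ga_base, structure=_disk_structure(spec.conversion_margin))

    t_true = _sample_transform(r_transform, spec.transform_jitter)

    # --- FAF scenes ------------------------------------------------------
    base = 0.55 + _smooth_field(r_faf, (FAF_SIZE, FAF_SIZE), 40, 0.04)
    vessel_mask, vessel_points = _draw_vessels(r_faf, FAF_SIZE)
    druse_glow = ndimage.gaussian_filter(ga_base.astype(float), 6)
    base = base + 0.10 * druse_glow
    base = np.where(vessel_mask, 0.25, base)
    baseline_faf = np.clip(base, 0, 1)

    follow_scene = np.where(ga_base, 0.12, baseline_faf)  # GA is dark on FAF
    followup_faf = warp(follow_scene, t_true.inverse())
    followup_ga = warp(ga_base, t_true.inverse())

    baseline_faf = (np.round(np.clip(baseline_faf, 0, 1) * 255) / 255
                    ).astype(np.float32)
    followup_faf = (np.round(np.clip(followup_faf, 0, 1) * 255) / 255
                    ).astype(np.float32)

    case = PhantomCase(
        oct=vol, baseline_faf=baseline_faf, followup_faf=followup_faf,
        followup_ga_mask=followup_ga, true_transform=t_true,
        keypoints=KeypointSet(pairs=[]), layers=layers, lesions=lesions,
        spec=spec, vessel_points=vessel_points)
    case.keypoints = make_keypoints(case, n=8, rng=r_keypoints)
    return case


def _draw_vessels(rng, size):
    """Dark vessel-like curves; returns (mask, sample points on centerlines)."""
    mask = np.zeros((size, size), dtype=bool)
    pts = []
    yy, xx = np.ogrid[:size, :size]
    for _ in range(5):
        p0 = rng.uniform(0.05, 0.95, 2) * size
        p2 = rng.uniform(0.05, 0.95, 2) * size
        p1 = (p0 + p2) / 2 + rng.uniform(-0.3, 0.3, 2) * size
        ts = np.linspace(0, 1, 160)
        curve = ((1 - ts) ** 2)[:, None] * p0 + \
            (2 * ts * (1 - ts))[:, None] * p1 + (ts ** 2)[:, None] * p2
        for cx, cy in curve:
            xi, yi = int(round(cx)), int(round(cy))
            if 2 <= xi < size - 2 and 2 <= yi < size - 2:
                mask[yi - 1:yi + 2, xi - 1:xi + 2] = True
        keep = (curve[:, 0] > 0.08 * size) & (curve[:, 0] < 0.92 * size) & \
               (curve[:, 1] > 0.08 * size) & (curve[:, 1] < 0.92 * size)
        pts.extend(curve[keep][::8])
    return mask, np.array(pts)


def _general_position(points: np.ndarray, tol: float = 50.0) -> bool:
    """No 3 points (nearly) collinear: all triangle areas exceed ``tol``."""
    n = len(points)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                a, b, c = points[i], points[j], points[k]
                area = 0.5 * abs((b[0] - a[0]) * (c[1] - a[1]) -
                                 (c[0] - a[0]) * (b[1] - a[1]))
                if area < tol:
                    return False
    return True


def make_keypoints(case: PhantomCase, n: int = 8,
                   rng: np.random.Generator | None = None,
                   seed: int | None = None) -> KeypointSet:
    """Select ``n`` vessel-landmark correspondences that are exact under the
    case's ground-truth transform and in general position.

    Destination points lie on baseline vessel centerlines; source points
    are their pre-images in the follow-up frame. Pairs are stored so that
    ``true_transform.apply(src) == dst`` bitwise.
    """
    if n < 4:
        raise ValueError("need at least 4 keypoints for projective fitting")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([case.spec.seed & 0x7FFFFFFF, 0x8EE])
            if seed is None else seed)
    pool = case.vessel_points
    if len(pool) < n:
        raise RuntimeError("not enough vessel landmarks to choose from")
    t_inv = case.true_transform.inverse()
    lim = FAF_SIZE - 1
    for _ in range(500):
        idx = rng.choice(len(pool), size=n, replace=False)
        dst0 = pool[idx]
        # minimum pairwise spread keeps the fit well-conditioned
        dmin = np.min([np.linalg.norm(dst0[i] - dst0[j])
                       for i in range(n) for j in range(i + 1, n)])
        if dmin < 0.06 * FAF_SIZE or not _general_position(dst0):
            continue
        src = t_inv.apply(dst0)
        if np.any(src < 0) or np.any(src > lim):
            continue
        dst = case.true_transform.apply(src)  # exact by construction
        return KeypointSet(pairs=[(tuple(s), tuple(dd))
                                  for s, dd in zip(src, dst)])
    raise RuntimeError("could not find keypoints in general position")


# ----------------------------------------------------------------------
# case I/O (text/image formats only; lossless round trip)
# ----------------------------------------------------------------------

_FILES = {
    "oct": "oct.tif",
    "baseline_faf": "baseline_faf.png",
    "followup_faf": "followup_faf.png",
    "ga_mask": "followup_ga_mask.png",
    "keypoints": "keypoints.json",
    "transform": "transform.json",
    "layers": "layers.csv",
    "lesions": "lesions.json",
    "meta": "meta.json",
}


def write_case(case: PhantomCase, directory):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vol16 = np.round(case.oct.astype(np.float64) * 65535).astype(np.uint16)
    tifffile.imwrite(directory / _FILES["oct"],
                     np.moveaxis(vol16, 2, 0), photometric="minisblack")
    for key, img in (("baseline_faf", case.baseline_faf),
                     ("followup_faf", case.followup_faf)):
        iio.imwrite(directory / _FILES[key],
                    np.round(img.astype(np.float64) * 255).astype(np.uint8))
    iio.imwrite(directory / _FILES["ga_mask"],
                (case.followup_ga_mask.astype(np.uint8) * 255))
    case.keypoints.to_json(directory / _FILES["keypoints"])
    case.true_transform.to_json(directory / _FILES["transform"])

    w, d = case.layers.ilm_row.shape
    wi, di = np.meshgrid(np.arange(w), np.arange(d), indexing="ij")
    table = np.column_stack([wi.ravel(), di.ravel(),
                             case.layers.ilm_row.ravel(),
                             case.layers.rpe_row.ravel(),
                             case.layers.cs_row.ravel()])
    header = "width_index,depth_index,ilm_row,rpe_row,cs_row"
    np.savetxt(directory / _FILES["layers"], table, fmt="%d", delimiter=",",
               header=header, comments="")

    lesions = []
    for les in case.lesions:
        ws, ds = np.nonzero(les.enface_footprint)
        lesions.append({
            "kind": les.kind, "converts": bool(les.converts),
            "footprint": np.column_stack([ws, ds]).tolist(),
            "axial_anchor": les.axial_anchor[ws, ds].tolist(),
        })
    (directory / _FILES["lesions"]).write_text(json.dumps({"lesions": lesions}))

    meta = {"spec": {**asdict(case.spec),
                     "volume_shape": list(case.spec.volume_shape),
                     "druse_radius_range": list(case.spec.druse_radius_range),
                     "focus_radius_range": list(case.spec.focus_radius_range),
                     "transform_jitter": list(case.spec.transform_jitter)},
            "vessel_points": case.vessel_points.tolist()}
    (directory / _FILES["meta"]).write_text(json.dumps(meta))


def read_case(directory) -> PhantomCase:
    directory = Path(directory)
    for key in _FILES.values():
        if not (directory / key).exists():
            raise FileNotFoundError(f"missing case file: {directory / key}")
    meta = json.loads((directory / _FILES["meta"]).read_text())
    spec_d = meta["spec"]
    spec = PhantomSpec(**{**spec_d,
                          "volume_shape": tuple(spec_d["volume_shape"]),
                          "druse_radius_range": tuple(spec_d["druse_radius_range"]),
                          "focus_radius_range": tuple(spec_d["focus_radius_range"]),
                          "transform_jitter": tuple(spec_d["transform_jitter"])})
    vol16 = tifffile.imread(directory / _FILES["oct"])
    oct_vol = (np.moveaxis(vol16, 0, 2).astype(np.float64) / 65535
               ).astype(np.float32)
    baseline = (iio.imread(directory / _FILES["baseline_faf"]).astype(np.float64)
                / 255).astype(np.float32)
    followup = (iio.imread(directory / _FILES["followup_faf"]).astype(np.float64)
                / 255).astype(np.float32)
    ga = iio.imread(directory / _FILES["ga_mask"]) > 127

    table = np.loadtxt(directory / _FILES["layers"], delimiter=",", skiprows=1,
                       dtype=int)
    w, d = oct_vol.shape[1], oct_vol.shape[2]
    ilm = np.zeros((w, d), dtype=int)
    rpe = np.zeros((w, d), dtype=int)
    cs = np.zeros((w, d), dtype=int)
    ilm[table[:, 0], table[:, 1]] = table[:, 2]
    rpe[table[:, 0], table[:, 1]] = table[:, 3]
    cs[table[:, 0], table[:, 1]] = table[:, 4]

    lesions = []
    for entry in json.loads((directory / _FILES["lesions"]).read_text())["lesions"]:
        fp = np.zeros((w, d), dtype=bool)
        anchor = np.full((w, d), -1, dtype=int)
        coords = np.array(entry["footprint"], dtype=int)
        fp[coords[:, 0], coords[:, 1]] = True
        anchor[coords[:, 0], coords[:, 1]] = entry["axial_anchor"]
        lesions.append(LesionRecord(entry["kind"], fp, anchor,
                                    entry["converts"]))

    return PhantomCase(
        oct=oct_vol, baseline_faf=baseline, followup_faf=followup,
        followup_ga_mask=ga,
        true_transform=PlanarTransform.from_json(directory / _FILES["transform"]),
        keypoints=KeypointSet.from_json(directory / _FILES["keypoints"]),
        layers=RetinalLayers(ilm_row=ilm, rpe_row=rpe, cs_row=cs),
        lesions=lesions, spec=spec,
        vessel_points=np.array(meta["vessel_points"]))


def cases_equal(a: PhantomCase, b: PhantomCase) -> bool:
    """Field-by-field equality (exact array comparison)."""
    if not (np.array_equal(a.oct, b.oct) and
            np.array_equal(a.baseline_faf, b.baseline_faf) and
            np.array_equal(a.followup_faf, b.followup_faf) and
            np.array_equal(a.followup_ga_mask, b.followup_ga_mask) and
            np.array_equal(a.true_transform.matrix, b.true_transform.matrix) and
            a.keypoints.pairs == b.keypoints.pairs and
            np.array_equal(a.layers.ilm_row, b.layers.ilm_row) and
            np.array_equal(a.layers.rpe_row, b.layers.rpe_row) and
            np.array_equal(a.layers.cs_row, b.layers.cs_row) and
            np.array_equal(a.vessel_points, b.vessel_points) and
            asdict(a.spec) == asdict(b.spec) and
            len(a.lesions) == len(b.lesions)):
        return False
    for la, lb in zip(a.lesions, b.lesions):
        if not (la.kind == lb.kind and la.converts == lb.converts and
                np.array_equal(la.enface_footprint, lb.enface_footprint) and
                np.array_equal(np.where(la.enface_footprint, la.axial_anchor, -1),
                               np.where(lb.enface_footprint, lb.axial_anchor, -1))):
            return False
    return True
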