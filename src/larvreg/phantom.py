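"""Seeded generator of synthetic larval-CNS-like scans.

Each phantom is a smooth random deformation of one canonical anatomy (two
ellipsoidal brain lobes plus a tapering ventral cord with thoracic and
abdominal nerve-root bumps), with NP/NT/GE channels, 30 labeled landmarks,
the ground-truth deformation, and optional injected failure modes.

The stored ``applied_transform`` maps *scan space to canonical space*
(resampling convention: the scan image is the canonical image resampled
through it).  Scan landmarks are the preimages of the canonical landmarks
under that transform, so applying it to the scan landmarks reproduces the
canonical positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .model import BrainScan, Grid, LandmarkSet, VolumetricImage
from .transforms import (
    BSplineTransform,
    CompositeTransform,
    DisplacementField,
    LinearTransform,
    resample,
    to_displacement_field,
)

__all__ = [
    "PhantomTruth",
    "generate_phantom",
    "phantom_cohort",
    "canonical_anatomy",
    "canonical_landmarks",
    "LANDMARK_LABELS",
    "VNC_ANCHOR_LABELS",
    "THORACIC_ANCHOR_LABELS",
    "QA_ANCHOR_LABELS",
    "CORRUPTIONS",
]

DEFAULT_SHAPE = (128, 96, 24)
DEFAULT_SPACING = (0.5, 0.5, 2.0)

CORRUPTIONS = ("none", "vnc_shift", "thoracic_fold", "weak_staining", "truncated", "no_np")

LANDMARK_LABELS = [
    "left antennal nerve",
    "right antennal nerve",
    "left tip of vertical lobe",
    "right tip of vertical lobe",
    "end of ventral nerve cord",
    "left thoracic nerve entry T1",
    "right thoracic nerve entry T1",
    "left thoracic nerve entry T2",
    "right thoracic nerve entry T2",
    "left thoracic nerve entry T3",
    "right thoracic nerve entry T3",
    "left upper peduncle",
    "right upper peduncle",
    "anterior upper commisure",
    "posterior upper commisure",
    "left anterior LON nerve",
    "right anterior LON nerve",
    "left MB vertical medial lobe connection",
    "right MB vertical medial lobe connection",
    "center SEZ neuropil fusion",
    "left upper most anterior nerve entry",
    "right upper most anterior nerve entry",
    "right basal brain neuropil border posterior",
    "left basal brain neuropil border posterior",
    "left A8 nerve entry",
    "right A8 nerve entry",
    "right A7 nerve entry",
    "left A7 nerve entry",
    "left A6 nerve entry",
    "right A6 nerve entry",
]

THORACIC_ANCHOR_LABELS = (
    "left thoracic nerve entry T1",
    "right thoracic nerve entry T1",
    "left thoracic nerve entry T2",
    "right thoracic nerve entry T2",
    "left thoracic nerve entry T3",
    "right thoracic nerve entry T3",
)
# the terminal-most paired nerve entries anchor the VNC-terminal indicator
VNC_ANCHOR_LABELS = ("left A8 nerve entry", "right A8 nerve entry")
QA_ANCHOR_LABELS = VNC_ANCHOR_LABELS + THORACIC_ANCHOR_LABELS


@dataclass
class PhantomTruth:
    scan: BrainScan
    landmarks: LandmarkSet
    applied_transform: object  # scan space -> canonical space
    seed: int
    corruption: str
    deform_amplitude: float


# ---------------------------------------------------------------------------
# canonical anatomy
# ---------------------------------------------------------------------------

def _extents(shape, spacing) -> np.ndarray:
    return (np.asarray(shape) - 1) * np.asarray(spacing)


def _vnc_half_width(fl: float, ex: float) -> float:
    """Tapering cord half-width (μm) at relative axial (y) position fl."""
    taper = np.clip((0.92 - fl) / (0.92 - 0.30), 0.0, 1.0)
    return float((0.066 + 0.06 * taper) * ex)


def canonical_landmarks(
    shape=DEFAULT_SHAPE, spacing=DEFAULT_SPACING
) -> LandmarkSet:
    """The 30-landmark schema placed on the canonical anatomy (μm).

    The anatomy's long (anterior→posterior) axis runs along y with the brain
    lobes near the top (small y) — the dorsal-ventral orientation stage
    relies on this mass asymmetry — and left/right across x.
    """
    ex, ey, ez = _extents(shape, spacing)
    t_y = {"T1": 0.38, "T2": 0.46, "T3": 0.54}
    a_y = {"A6": 0.70, "A7": 0.78, "A8": 0.86}

    pts = {
        "left antennal nerve": (0.33 * ex, 0.10 * ey, 0.56 * ez),
        "right antennal nerve": (0.67 * ex, 0.10 * ey, 0.56 * ez),
        "left tip of vertical lobe": (0.33 * ex, 0.22 * ey, 0.78 * ez),
        "right tip of vertical lobe": (0.67 * ex, 0.22 * ey, 0.78 * ez),
        "end of ventral nerve cord": (0.50 * ex, 0.92 * ey, 0.42 * ez),
        "left upper peduncle": (0.40 * ex, 0.20 * ey, 0.65 * ez),
        "right upper peduncle": (0.60 * ex, 0.20 * ey, 0.65 * ez),
        "anterior upper commisure": (0.50 * ex, 0.18 * ey, 0.60 * ez),
        "posterior upper commisure": (0.50 * ex, 0.26 * ey, 0.60 * ez),
        "left anterior LON nerve": (0.28 * ex, 0.14 * ey, 0.55 * ez),
        "right anterior LON nerve": (0.72 * ex, 0.14 * ey, 0.55 * ez),
        "left MB vertical medial lobe connection": (0.41 * ex, 0.24 * ey, 0.55 * ez),
        "right MB vertical medial lobe connection": (0.59 * ex, 0.24 * ey, 0.55 * ez),
        "center SEZ neuropil fusion": (0.50 * ex, 0.30 * ey, 0.46 * ez),
        "left upper most anterior nerve entry": (0.40 * ex, 0.08 * ey, 0.60 * ez),
        "right upper most anterior nerve entry": (0.60 * ex, 0.08 * ey, 0.60 * ez),
        "right basal brain neuropil border posterior": (0.62 * ex, 0.28 * ey, 0.32 * ez),
        "left basal brain neuropil border posterior": (0.38 * ex, 0.28 * ey, 0.32 * ez),
    }
    for seg, fl in t_y.items():
        w = _vnc_half_width(fl, ex) + 1.5
        pts[f"left thoracic nerve entry {seg}"] = (0.5 * ex - w, fl * ey, 0.42 * ez)
        pts[f"right thoracic nerve entry {seg}"] = (0.5 * ex + w, fl * ey, 0.42 * ez)
    for seg, fl in a_y.items():
        w = _vnc_half_width(fl, ex) + 1.0
        pts[f"left {seg} nerve entry"] = (0.5 * ex - w, fl * ey, 0.42 * ez)
        pts[f"right {seg} nerve entry"] = (0.5 * ex + w, fl * ey, 0.42 * ez)
    coords = np.array([pts[l] for l in LANDMARK_LABELS])
    return LandmarkSet(LANDMARK_LABELS, coords, frame_id="canonical")


def canonical_anatomy(
    shape=DEFAULT_SHAPE, spacing=DEFAULT_SPACING
) -> BrainScan:
    """Noise-free canonical NP/NT/GE channels (float in [0, 255]); cached."""
    return _canonical_anatomy_cached(tuple(int(n) for n in shape), tuple(spacing))


@lru_cache(maxsize=4)
def _canonical_anatomy_cached(shape, spacing) -> BrainScan:
    ex, ey, ez = _extents(shape, spacing)
    grid = Grid(shape, tuple(spacing))
    p = grid.physical_points()
    x, y, z = p[..., 0], p[..., 1], p[..., 2]

    def ellipsoid(cx, cy, cz, rx, ry, rz):
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0

    # paired brain lobes anterior (small y), left/right across x
    lobes = ellipsoid(0.345 * ex, 0.22 * ey, 0.56 * ez, 0.17 * ex, 0.17 * ey, 0.32 * ez)
    lobes |= ellipsoid(0.655 * ex, 0.22 * ey, 0.56 * ez, 0.17 * ex, 0.17 * ey, 0.32 * ez)

    fl = np.clip(y / ey, 0.0, 1.0)
    taper = np.clip((0.92 - fl) / (0.92 - 0.30), 0.0, 1.0)
    half_w = (0.066 + 0.06 * taper) * ex
    in_axis = (y >= 0.28 * ey) & (y <= 0.92 * ey)
    vnc = in_axis & (
        ((x - 0.5 * ex) / np.maximum(half_w, 1e-6)) ** 2
        + ((z - 0.42 * ez) / np.maximum(1.8 * half_w, 1e-6)) ** 2
        <= 1.0
    )

    bumps = np.zeros(shape, dtype=bool)
    lm = canonical_landmarks(shape, spacing)
    for label in QA_ANCHOR_LABELS + ("left A7 nerve entry", "right A7 nerve entry",
                                     "left A6 nerve entry", "right A6 nerve entry"):
        cx, cy, cz = lm[label]
        bumps |= ((x - cx) / 2.5) ** 2 + ((y - cy) / 2.5) ** 2 + ((z - cz) / 3.0) ** 2 <= 1.0

    fg = lobes | vnc | bumps
    np_img = np.where(fg, 170.0, 8.0)

    # deterministic internal texture (shared across the whole cohort) gives
    # the similarity metrics something to latch onto inside the neuropil
    tex_rng = np.random.default_rng(1729)
    n_blobs = 60
    centers = tex_rng.uniform([0.15 * ex, 0.05 * ey, 0.15 * ez],
                              [0.85 * ex, 0.95 * ey, 0.85 * ez], size=(n_blobs, 3))
    radii = tex_rng.uniform(2.0, 6.0, size=n_blobs)
    amps = tex_rng.uniform(-60.0, 70.0, size=n_blobs)
    texture = np.zeros(shape)
    for c, r, a in zip(centers, radii, amps):
        d2 = ((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) / r**2
        texture += a * np.exp(-d2)
    np_img = np.where(fg, np.clip(np_img + texture, 40.0, 255.0), np_img)
    sig = (1.0 / spacing[0], 1.0 / spacing[1], 1.0 / spacing[2])
    np_img = ndimage.gaussian_filter(np_img, sigma=sig)

    # NT: thin bright tracts — cord centerline, two paramedian lines, a loop
    # through each lobe
    d_axis = np.sqrt((x - 0.5 * ex) ** 2 + (z - 0.42 * ez) ** 2)
    nt = in_axis & (d_axis <= 1.2)
    for off in (-2.5, 2.5):
        nt |= in_axis & (np.sqrt((x - (0.5 * ex + off)) ** 2 + (z - 0.42 * ez) ** 2) <= 1.0)
    for cx in (0.345 * ex, 0.655 * ex):
        ring = np.abs(np.sqrt((x - cx) ** 2 + (y - 0.22 * ey) ** 2) - 6.0) <= 1.2
        nt |= ring & (np.abs(z - 0.56 * ez) <= 0.12 * ez) & lobes
    nt_img = ndimage.gaussian_filter(np.where(nt & fg, 200.0, 5.0), sigma=sig)

    ge_img = np.zeros(shape)  # per-phantom expression blobs are added later

    mk = lambda a, lab: VolumetricImage(a.astype(np.float32), tuple(spacing), channel_label=lab)
    return BrainScan(
        "canonical",
        {"NP": mk(np_img, "NP"), "NT": mk(nt_img, "NT"), "GE": mk(ge_img, "GE")},
    )


# ---------------------------------------------------------------------------
# deformation and corruption machinery
# ---------------------------------------------------------------------------

def _random_bspline(
    grid: Grid, amplitude: float, rng: np.random.Generator, control_spacing: float = 16.0
) -> BSplineTransform:
    t = BSplineTransform.domain_covering(grid, control_spacing)
    coeffs = rng.normal(0.0, 1.0, size=t.coefficients.shape)
    coeffs = ndimage.gaussian_filter(coeffs, sigma=(1.0, 1.0, 1.0, 0.0))
    field = to_displacement_field(
        BSplineTransform(t.grid_origin, t.grid_spacing, coeffs), grid
    )
    peak = np.max(np.linalg.norm(field.vectors, axis=-1))
    if peak > 0:
        coeffs *= amplitude / peak
    # damp motion near the z faces: only ~24 slices are available
    nz = t.coefficients.shape[2]
    wz = np.minimum(np.arange(nz), np.arange(nz)[::-1]).clip(max=3) / 3.0
    coeffs *= wz[None, None, :, None] * 0.7 + 0.3
    return BSplineTransform(t.grid_origin, t.grid_spacing, coeffs)


def _invert_at_points(transform, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Solve T(x) = p by damped fixed-point iteration.

    The damping keeps the iteration convergent for the steep (but locally
    invertible) corruption fields; smooth deformations converge in a few
    dozen steps regardless.
    """
    pts = np.atleast_2d(points)
    x = pts.copy()
    for _ in range(400):
        residual = transform.apply(x) - pts
        x = x - 0.5 * residual
        if np.max(np.abs(residual)) < tol:
            break
    return x


def _windowed_offset_field(
    grid: Grid,
    center: np.ndarray,
    offset: np.ndarray,
    plateau: float = 0.0,
    falloff: float = 4.0,
) -> DisplacementField:
    """Offset applied rigidly within ``plateau`` μm of ``center``, decaying
    over ``falloff`` μm outside.  Inside the plateau the map is an exact
    translation (invertible); the thin falloff shell tears, as a genuinely
    failed registration would."""
    p = grid.physical_points()
    r = np.sqrt(np.sum((p - center) ** 2, axis=-1))
    w = np.exp(-0.5 * (np.maximum(r - plateau, 0.0) / falloff) ** 2)
    return DisplacementField(w[..., None] * offset, grid)


def _corruption_preimage(
    grid: Grid, points: np.ndarray, center, offset, plateau: float, falloff: float
) -> np.ndarray:
    """Preimages under the windowed-offset corruption map C(x) = x + w(x)·v.

    Points whose shifted preimage lies in the rigid plateau map back exactly
    by −v; points outside the window's reach are untouched; the thin torn
    shell in between is solved by a heavily damped fixed point (the tear
    makes those positions approximate by construction).
    """
    center = np.asarray(center, dtype=float)
    offset = np.asarray(offset, dtype=float)
    reach = plateau + 3.0 * falloff
    field = _windowed_offset_field(grid, center, offset, plateau, falloff)
    out = np.empty_like(points)
    for k, p in enumerate(points):
        if np.linalg.norm(p - offset - center) <= plateau:
            out[k] = p - offset
        elif np.linalg.norm(p - center) >= reach + np.linalg.norm(offset):
            out[k] = p
        else:
            x = p.copy()
            for _ in range(3000):
                res = field.apply(x) - p
                x -= 0.2 * res
                if np.linalg.norm(res) < 1e-6:
                    break
            out[k] = x
    return out


def _plateau_window(img: VolumetricImage, center, plateau: float, falloff: float) -> np.ndarray:
    p = img.grid.physical_points()
    r = np.sqrt(np.sum((p - np.asarray(center)) ** 2, axis=-1))
    return np.exp(-0.5 * (np.maximum(r - plateau, 0.0) / falloff) ** 2)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_phantom(
    seed: int,
    shape=DEFAULT_SHAPE,
    spacing=DEFAULT_SPACING,
    deform_amplitude: float = 6.0,
    corruption: str = "none",
    corruption_magnitude: float = 30.0,
    corruption_profile: str = "hard",
    noise_sigma: float = 3.0,
    scan_id: Optional[str] = None,
) -> PhantomTruth:
    """Generate one synthetic scan with ground truth.

    ``corruption`` injects a failure mode after the smooth deformation:
    ``vnc_shift`` offsets the cord terminal by ``corruption_magnitude`` μm
    and dims its staining (the weak-staining condition under which such
    failures occur); ``thoracic_fold`` injects a local high-strain fold at a
    thoracic nerve; ``weak_staining`` only dims; ``truncated`` crops 20% of
    z; ``no_np`` zeroes the NP channel.

    ``corruption_profile`` selects the displacement transition of
    ``vnc_shift``: ``hard`` tears at the window edge (detection scenarios),
    ``soft`` decays smoothly and stays invertible (correction scenarios,
    where an annotator could meaningfully point at the displaced anatomy).
    """
    shape = tuple(int(n) for n in shape)
    if any(n < m for n, m in zip(shape, (64, 48, 16))):
        raise ValueError(f"shape must be at least (64, 48, 16), got {shape}")
    if corruption not in CORRUPTIONS:
        raise ValueError(f"corruption must be one of {CORRUPTIONS}")
    grid = Grid(shape, tuple(spacing))
    extent = _extents(shape, spacing)
    if deform_amplitude > 0.5 * float(np.min(extent)):
        raise ValueError(
            f"deform_amplitude {deform_amplitude} exceeds half the grid extent"
        )
    rng = np.random.default_rng(seed)
    canonical = canonical_anatomy(shape, spacing)
    lms_canonical = canonical_landmarks(shape, spacing)

    transforms: List[object] = []
    if deform_amplitude > 0:
        transforms.append(_random_bspline(grid, deform_amplitude, rng))

    ex, ey, ez = extent
    dim_windows = []
    corr_spec = None
    if corruption == "vnc_shift":
        # cord terminal (incl. both A8 entries) rigidly shifted sideways by
        # the stated magnitude.  The pull window sits where the shifted
        # content lands in scan space, so the plateau maps the terminal
        # anatomy as an exact translation.  The vacated source region is
        # erased to background and the moved tail is dimmed — the
        # weak-staining condition under which such failures occur.
        shift = np.array([np.sign(rng.standard_normal()) * corruption_magnitude, 0.0, 0.0])
        terminal = np.array([0.5 * ex, 0.91 * ey, 0.42 * ez])
        center = terminal + shift
        if corruption_profile == "hard":
            plateau, falloff = 12.0, 4.0
            erase = (terminal, 12.0, 5.0, 0.03)
            dim_windows = [erase, (center, 12.0, 4.0, 0.55)]
        else:  # soft: |∇u| < 1, invertible; only the stretched core is erased
            plateau, falloff = 6.0, max(4.0, 0.65 * corruption_magnitude)
            dim_windows = [(terminal, 6.0, 3.0, 0.12)]
        corr_spec = (center, -shift, plateau, falloff)
        transforms.append(_windowed_offset_field(grid, center, -shift,
                                                 plateau=plateau, falloff=falloff))
    elif corruption == "thoracic_fold":
        anchor = lms_canonical["right thoracic nerve entry T2"]
        fold = np.array([-corruption_magnitude * 0.6, 0.0, 0.0])
        corr_spec = (anchor, fold, 0.0, 5.0)
        transforms.append(_windowed_offset_field(grid, anchor, fold,
                                                 plateau=0.0, falloff=5.0))
        dim_windows = [(anchor, 8.0, 4.0, 0.5)]

    # members apply right-to-left: the scan-side corruption acts first, the
    # smooth deformation then carries the point into canonical space
    if transforms:
        truth_transform = transforms[0] if len(transforms) == 1 else CompositeTransform(
            transforms
        )
    else:
        truth_transform = LinearTransform.identity()

    channels = {}
    for label in ("NP", "NT"):
        channels[label] = resample(canonical.channels[label], truth_transform, grid)

    # GE: sparse per-phantom expression blobs inside the deformed anatomy
    ge = np.zeros(shape, dtype=np.float32)
    p = grid.physical_points()
    np_fg = channels["NP"].data > 40
    for _ in range(4):
        c = rng.uniform([0.3 * ex, 0.1 * ey, 0.3 * ez], [0.7 * ex, 0.85 * ey, 0.7 * ez])
        r = rng.uniform(2.0, 5.0)
        ge += 180.0 * np.exp(-0.5 * np.sum((p - c) ** 2, axis=-1) / r**2)
    ge *= np_fg
    channels["GE"] = VolumetricImage(ge, tuple(spacing), channel_label="GE")

    # landmark positions in scan space: invert the smooth deformation by
    # fixed point, then peel the scan-side corruption off analytically
    # (exact inside the rigid plateau and in the far field)
    pts = lms_canonical.coords
    if deform_amplitude > 0:
        pts = _invert_at_points(transforms[0], pts)
    if corr_spec is not None:
        pts = _corruption_preimage(grid, pts, *corr_spec)
    lms = pts

    # corruption post-processing on intensities / geometry
    if corruption == "weak_staining":
        center = np.array([0.5 * ex, 0.8 * ey, 0.42 * ez])
        dim_windows = [(center, 0.0, 0.15 * ey, 0.2)]
    for c, plateau, falloff, factor in dim_windows:
        w = _plateau_window(channels["NP"], c, plateau, falloff)
        scale = 1.0 - (1.0 - factor) * w
        channels["NP"] = channels["NP"].copy(data=channels["NP"].data * scale)

    # acquisition noise: Gaussian read noise + intensity-dependent shot term
    for label in ("NP", "NT", "GE"):
        img = channels[label]
        base = np.clip(img.data, 0, None)
        noisy = (
            img.data
            + rng.normal(0.0, noise_sigma, shape)
            + rng.normal(0.0, 1.0, shape) * np.sqrt(base) * 0.5
        )
        channels[label] = img.copy(data=np.clip(noisy, 0, 255).astype(np.uint8))
    if corruption == "no_np":
        channels["NP"] = channels["NP"].copy(
            data=np.zeros(shape, dtype=np.uint8)
        )

    if corruption == "truncated":
        keep = int(round(shape[2] * 0.8))
        for label in list(channels):
            img = channels[label]
            channels[label] = VolumetricImage(
                img.data[:, :, :keep].copy(), img.spacing, img.origin, img.channel_label
            )

    sid = scan_id or f"phantom-{seed:05d}-{corruption}"
    scan = BrainScan(sid, channels)
    return PhantomTruth(
        scan=scan,
        landmarks=LandmarkSet(lms_canonical.labels, lms, frame_id=sid),
        applied_transform=truth_transform,
        seed=seed,
        corruption=corruption,
        deform_amplitude=deform_amplitude,
    )


def phantom_cohort(
    n: int,
    seed: int,
    shape=DEFAULT_SHAPE,
    spacing=DEFAULT_SPACING,
    deform_amplitude: Tuple[float, float] = (4.0, 8.0),
    corruption: str = "none",
) -> List[PhantomTruth]:
    """A cohort of phantoms sharing one canonical space."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        amp = float(rng.uniform(*deform_amplitude))
        out.append(
            generate_phantom(
                seed=int(rng.integers(0, 2**31 - 1)),
                shape=shape,
                spacing=spacing,
                deform_amplitude=amp,
                corruption=corruption,
                scan_id=f"cohort{seed}-{i:02d}",
            )
        )
    return out
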