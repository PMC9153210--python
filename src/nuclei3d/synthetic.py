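"""Synthetic 3D specimens with exact per-nucleus ground truth.

The generator emulates DAPI-stained nuclei in confocal z-stacks: bright
ellipsoids of varying size, eccentricity and orientation (optionally clipped
to half-moon shapes), touching clusters at higher confluency, multiplicative
intensity attenuation with scanning depth, a confocal-like Gaussian blur, and
either uniform or directionally trending background noise. Every voxel of the
noiseless render carries exactly one ground-truth label (overlap voxels go to
the nearer centre in ellipsoid-normalised metric), so detection and
delineation metrics can be computed without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

from .stack_io import (
    DEFAULT_SPACING_NM,
    GroundTruthLayer,
    IntensityVolume,
    LabelVolume,
)

#: minimum-centre-distance factor (in units of summed per-axis semi-axes)
CONFLUENCY_SPACING = {"low": 1.10, "moderate": 0.80, "high": 0.55}


class OvercrowdedSpecError(RuntimeError):
    """Raised when nuclei cannot be placed at the requested confluency."""


@dataclass
class SpecimenSpec:
    """Recipe for one synthetic specimen.

    Defaults describe the desk-scale study conditions used throughout the
    test suite: a 30x256x256 stack of 20 well-separated (low-confluency)
    ellipsoidal nuclei, 12-bit intensities, gentle depth attenuation and 5%
    uniform noise.

    Attributes
    ----------
    shape:
        Volume dimensions ``(Z, Y, X)`` in voxels.
    n_nuclei:
        Number of nuclei to place (may be 0 for an all-noise volume).
    radius_range:
        Per-axis semi-axis bounds in voxels, ``((z_lo, z_hi), (y_lo, y_hi),
        (x_lo, x_hi))``.
    confluency:
        ``low`` / ``moderate`` / ``high``; controls minimum centre spacing
        and thereby the amount of touching/overlap.
    intensity_range:
        Bounds for the per-nucleus mean intensity (digital numbers).
    z_attenuation:
        Multiplicative intensity decay per optical section (1 = none);
        layer ``z`` is scaled by ``z_attenuation ** z``.
    noise_model:
        ``uniform`` (additive uniform noise everywhere) or ``directional``
        (the same plus a linear ramp along ``noise_axis``).
    noise_amplitude:
        Uniform-noise amplitude as a fraction of the brightest nucleus
        intensity, in [0, 0.5].
    noise_slope:
        Peak of the directional ramp as a fraction of the brightest nucleus
        intensity (only used by the directional model).
    noise_axis:
        Axis (0=z, 1=y, 2=x) of the directional trend.
    blur_sigma:
        Gaussian PSF width in voxels, ``(z, y, x)``.
    half_moon_prob:
        Probability that a nucleus is clipped by a random plane into a
        half-moon shape.
    bit_depth:
        Output bit depth (intensities clipped to ``2**bit_depth - 1``).
    seed:
        RNG seed; identical spec + seed gives bitwise-identical output.
    """

    shape: tuple[int, int, int] = (30, 256, 256)
    n_nuclei: int = 20
    radius_range: tuple[tuple[float, float], ...] = ((5.0, 8.0), (14.0, 20.0), (14.0, 20.0))
    confluency: str = "low"
    intensity_range: tuple[float, float] = (1200.0, 3600.0)
    z_attenuation: float = 0.985
    noise_model: str = "uniform"
    noise_amplitude: float = 0.05
    noise_slope: float = 0.05
    noise_axis: int = 0
    blur_sigma: tuple[float, float, float] = (0.5, 1.0, 1.0)
    half_moon_prob: float = 0.0
    bit_depth: int = 12
    spacing: tuple[float, float, float] = DEFAULT_SPACING_NM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if len(self.radius_range) != 3 or any(
            lo <= 0 or hi < lo for lo, hi in self.radius_range
        ):
            raise ValueError("radius_range must hold positive (lo, hi) per axis")
        if not 0.0 <= self.noise_amplitude <= 0.5:
            raise ValueError("noise amplitude must lie in [0, 0.5]")
        if self.confluency not in CONFLUENCY_SPACING:
            raise ValueError(f"unknown confluency {self.confluency!r}")
        if self.noise_model not in ("uniform", "directional"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PlacedNucleus:
    centre: np.ndarray            # (z, y, x)
    semi_axes: np.ndarray         # (z, y, x)
    rotation: np.ndarray          # 3x3, maps world offsets to body frame
    intensity: float
    clip_plane: tuple[np.ndarray, float] | None = None  # (normal, offset)


def _random_rotation(rng: np.random.Generator, max_tilt: float = 0.15) -> np.ndarray:
    """Random nucleus orientation: free in-plane rotation, small tilt only.

    Nuclei of adherent cells grown on a slide are oblate ellipsoids whose
    short axis stays close to the optical (Z) axis; orientation is free only
    in the imaging plane. ``max_tilt`` (radians) bounds the out-of-plane
    wobble.
    """
    phi = rng.uniform(0, 2 * np.pi)          # in-plane rotation about z
    tilt = rng.uniform(-max_tilt, max_tilt)  # small tilt about y
    c, s = np.cos(phi), np.sin(phi)
    rz = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    ct, st = np.cos(tilt), np.sin(tilt)
    ry = np.array([[ct, 0.0, st], [0.0, 1.0, 0.0], [-st, 0.0, ct]])
    return rz @ ry


def _place_nuclei(spec: SpecimenSpec, rng: np.random.Generator) -> list[PlacedNucleus]:
    shape = np.asarray(spec.shape, dtype=float)
    spacing_factor = CONFLUENCY_SPACING[spec.confluency]
    placed: list[PlacedNucleus] = []
    max_retries = 200
    for _ in range(spec.n_nuclei):
        for attempt in range(max_retries):
            semi = np.array([rng.uniform(lo, hi) for lo, hi in spec.radius_range])
            margin = 0.8 * semi
            centre = np.array(
                [rng.uniform(m, s - m) if s - m > m else s / 2 for m, s in zip(margin, shape)]
            )
            ok = True
            for other in placed:
                delta = centre - other.centre
                norm = np.linalg.norm(delta / (semi + other.semi_axes))
                if norm < spacing_factor:
                    ok = False
                    break
            if ok:
                break
        else:
            raise OvercrowdedSpecError(
                f"could not place nucleus {len(placed) + 1}/{spec.n_nuclei} "
                f"after {max_retries} attempts at confluency={spec.confluency!r}"
            )
        rot = _random_rotation(rng)
        intensity = rng.uniform(*spec.intensity_range)
        clip = None
        if spec.half_moon_prob > 0 and rng.uniform() < spec.half_moon_prob:
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            clip = (n, rng.uniform(-0.3, 0.3))
        placed.append(PlacedNucleus(centre, semi, rot, intensity, clip))
    return placed


def _rasterize(
    placed: Sequence[PlacedNucleus], shape: tuple[int, int, int]
) -> np.ndarray:
    """Exact per-nucleus label volume; overlaps go to the nearer centre
    (smaller ellipsoid-normalised distance)."""
    labels = np.zeros(shape, dtype=np.int32)
    best_q = np.full(shape, np.inf, dtype=np.float64)
    for idx, nuc in enumerate(placed, start=1):
        lo = np.maximum(np.floor(nuc.centre - nuc.semi_axes.max() - 1), 0).astype(int)
        hi = np.minimum(
            np.ceil(nuc.centre + nuc.semi_axes.max() + 2), np.asarray(shape)
        ).astype(int)
        if np.any(hi <= lo):
            continue
        grids = np.meshgrid(
            *[np.arange(lo[a], hi[a], dtype=np.float64) for a in range(3)],
            indexing="ij",
        )
        offsets = np.stack([g - c for g, c in zip(grids, nuc.centre)], axis=-1)
        body = offsets @ nuc.rotation.T
        q = np.sum((body / nuc.semi_axes) ** 2, axis=-1)
        inside = q <= 1.0
        if nuc.clip_plane is not None:
            normal, offset = nuc.clip_plane
            inside &= (offsets @ normal) <= offset * nuc.semi_axes.max()
        box = tuple(slice(lo[a], hi[a]) for a in range(3))
        claim = inside & (q < best_q[box])
        labels[box][claim] = idx
        best_q[box][claim] = q[claim]
    return labels


def generate_specimen(
    spec: SpecimenSpec,
) -> tuple[IntensityVolume, LabelVolume, GroundTruthLayer]:
    """Render one synthetic specimen.

    Returns the noisy intensity volume, the exact per-nucleus label volume
    (from the noiseless render) and the mid-Z slice of the labels as the
    designated expert layer.
    """
    rng = np.random.default_rng(spec.seed)
    placed = _place_nuclei(spec, rng)
    labels = _rasterize(placed, spec.shape)

    render = np.zeros(spec.shape, dtype=np.float64)
    for idx, nuc in enumerate(placed, start=1):
        render[labels == idx] = nuc.intensity
    if spec.z_attenuation != 1.0:
        atten = spec.z_attenuation ** np.arange(spec.shape[0], dtype=np.float64)
        render *= atten[:, None, None]
    if any(s > 0 for s in spec.blur_sigma):
        render = ndimage.gaussian_filter(render, sigma=spec.blur_sigma)

    i_ref = spec.intensity_range[1]
    if spec.noise_amplitude > 0:
        render += rng.uniform(0.0, spec.noise_amplitude * i_ref, size=spec.shape)
    if spec.noise_model == "directional" and spec.noise_slope > 0:
        n = spec.shape[spec.noise_axis]
        ramp = np.linspace(0.0, spec.noise_slope * i_ref, n)
        shape_vec = [1, 1, 1]
        shape_vec[spec.noise_axis] = n
        render += ramp.reshape(shape_vec)

    i_cap = 2**spec.bit_depth - 1
    data = np.clip(np.rint(render), 0, i_cap).astype(np.uint16)
    vol = IntensityVolume(data=data, spacing=spec.spacing, bit_depth=spec.bit_depth)

    label_vol = LabelVolume(labels=labels)
    mid = spec.shape[0] // 2
    gt = GroundTruthLayer(mask=labels[mid].copy(), layer_index=mid)
    return vol, label_vol, gt


def generate_cluster(
    radii: Sequence[float | Sequence[float]],
    centres: Sequence[Sequence[float]],
) -> tuple[np.ndarray, LabelVolume]:
    """Rasterize a fused cluster of digital balls/ellipsoids.

    Returns the union as one binary mask plus the true per-ball labels
    (overlap voxels to the nearer centre), on a minimal padded bounding box.
    Used to exercise cluster splitting in isolation.
    """
    if len(radii) != len(centres) or len(radii) == 0:
        raise ValueError("radii and centres must be equally long and non-empty")
    semi = np.array(
        [np.broadcast_to(np.asarray(r, dtype=float), (3,)) for r in radii]
    )
    centres = np.asarray(centres, dtype=float)
    pad = 2.0
    lo = np.floor((centres - semi).min(axis=0) - pad)
    hi = np.ceil((centres + semi).max(axis=0) + pad)
    shape = tuple((hi - lo).astype(int) + 1)
    placed = [
        PlacedNucleus(c - lo, s, np.eye(3), intensity=1.0)
        for c, s in zip(centres, semi)
    ]
    labels = _rasterize(placed, shape)
    return labels > 0, LabelVolume(labels=labels)
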