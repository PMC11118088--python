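"""Synthetic branching-vessel phantoms.

Each phantom emulates the gross appearance of a fundus photograph: a dark
frame outside a circular field of view, a smoothly shaded background inside
it (brighter toward the center), a binary tree of straight anti-aliased
vessel segments whose width and contrast shrink with branching generation,
and additive Gaussian noise.  The paired ground-truth mask is exact by
construction and the tree is a single connected component.

What the phantoms deliberately do NOT emulate: the optic disc and macula,
vessel tortuosity and crossings, pathology, and camera color response.

Randomness is keyed per tree node (a hash of the branching path), so the
phantom at depth d is a strict sub-tree of the phantom at depth d+1 for the
same seed, and repeated calls are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data_pipeline import ImageSample, PreprocessConfig, preprocess

_F32 = np.float32


@dataclass
class PhantomSpec:
    """Generation parameters for one phantom.

    size: image side in pixels.
    depth: branching generations (1 = the root segment only).
    root_width: root vessel width in pixels; each generation multiplies the
        width by width_decay (floored at 1 px so thin branches stay connected).
    branch_angle: half-spread of the child branching angle, radians.
    background_mean / vessel_mean: 8-bit-scale intensities (0..1) of the FOV
        background and of the root vessel; contrast fades slightly with
        generation, giving the bright-to-dark look of real vessel trees.
    noise_sd: Gaussian noise standard deviation on the 0..1 intensity scale.
    fov_radius: FOV radius as a fraction of the image side.
    """

    size: int = 448
    depth: int = 7
    root_width: float = 6.0
    width_decay: float = 0.75
    branch_angle: float = 0.55
    background_mean: float = 0.55
    vessel_mean: float = 0.25
    noise_sd: float = 8.0 / 255.0
    fov_radius: float = 0.46
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.root_width <= 0:
            raise ValueError(f"root_width must be positive, got {self.root_width}")
        if not (0.0 < self.width_decay <= 1.0):
            raise ValueError(f"width_decay must lie in (0, 1], got {self.width_decay}")
        if not (0.0 < self.fov_radius <= 0.5 * np.sqrt(2.0)):
            raise ValueError(f"fov_radius must lie in (0, 0.707], got {self.fov_radius}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _node_rng(seed: int, path: tuple[int, ...]) -> np.random.Generator:
    # Stable per-node stream: geometry of a node never depends on tree depth.
    return np.random.default_rng(np.random.SeedSequence([seed, *path]))


def _segments(spec: PhantomSpec) -> list[tuple[np.ndarray, np.ndarray, float, int]]:
    """List of (start, end, width, generation) for the full tree."""
    size = spec.size
    center = np.array([size / 2.0, size / 2.0])
    R = spec.fov_radius * size
    rng0 = _node_rng(spec.seed, (0,))
    theta0 = rng0.uniform(0, 2 * np.pi)
    start = center + R * np.array([np.cos(theta0), np.sin(theta0)])
    heading = theta0 + np.pi + rng0.uniform(-0.3, 0.3)  # roughly toward center
    base_len = 0.28 * size
    segs: list[tuple[np.ndarray, np.ndarray, float, int]] = []

    def grow(p0: np.ndarray, ang: float, gen: int, path: tuple[int, ...]) -> None:
        if gen >= spec.depth:
            return
        rng = _node_rng(spec.seed, path)
        length = base_len * (0.78 ** gen) * rng.uniform(0.85, 1.15)
        width = max(spec.root_width * (spec.width_decay ** gen), 1.0)
        p1 = p0 + length * np.array([np.cos(ang), np.sin(ang)])
        # steer back inside if the endpoint leaves the field of view
        if np.linalg.norm(p1 - center) > 0.92 * R:
            to_center = np.arctan2(*(center - p0)[::-1])
            ang = 0.4 * ang + 0.6 * to_center
            p1 = p0 + length * np.array([np.cos(ang), np.sin(ang)])
        # hard radial clamp: descendants never cross the rim, so FOV clipping
        # cannot sever the tree (segments between interior points stay
        # interior because the disc is convex)
        radial = np.linalg.norm(p1 - center)
        if radial > 0.90 * R:
            p1 = center + (p1 - center) * (0.90 * R / radial)
        segs.append((p0, p1, width, gen))
        for k, sign in enumerate((-1.0, 1.0)):
            jitter = rng.uniform(0.7, 1.3)
            child_ang = ang + sign * spec.branch_angle * jitter
            grow(p1, child_ang, gen + 1, path + (k + 1,))

    grow(start, heading, 0, (1,))
    return segs


def _rasterize(spec: PhantomSpec, segs) -> tuple[np.ndarray, np.ndarray]:
    """Anti-aliased coverage map (for the image) and hard mask (d <= w/2)."""
    size = spec.size
    alpha = np.zeros((size, size), dtype=_F32)
    mask = np.zeros((size, size), dtype=bool)
    for p0, p1, width, gen in segs:
        r = width / 2.0
        lo = np.floor(np.minimum(p0, p1) - r - 1).astype(int)
        hi = np.ceil(np.maximum(p0, p1) + r + 2).astype(int)
        lo = np.clip(lo, 0, size)
        hi = np.clip(hi, 0, size)
        if (hi <= lo).any():
            continue
        ys, xs = np.mgrid[lo[1] : hi[1], lo[0] : hi[0]]
        pts = np.stack([xs, ys], axis=-1).astype(np.float64)
        d = _dist_to_segment(pts, p0, p1)
        fade = 0.92 ** gen  # thinner generations are slightly fainter
        cov = np.clip(r + 0.5 - d, 0.0, 1.0).astype(_F32) * fade
        sub = (slice(lo[1], hi[1]), slice(lo[0], hi[0]))
        alpha[sub] = np.maximum(alpha[sub], cov)
        mask[sub] |= d <= r
    return alpha, mask


def _dist_to_segment(pts: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    v = p1 - p0
    vv = float(v @ v)
    if vv == 0.0:
        return np.linalg.norm(pts - p0, axis=-1)
    t = np.clip(((pts - p0) @ v) / vv, 0.0, 1.0)
    proj = p0[None, None, :] + t[..., None] * v[None, None, :]
    return np.linalg.norm(pts - proj, axis=-1)


def generate_phantom(spec: PhantomSpec | None = None,
                     pre: PreprocessConfig | None = None) -> ImageSample:
    """Render one phantom and run it through the standard preprocessing."""
    spec = spec or PhantomSpec()
    spec.validate()
    size = spec.size
    segs = _segments(spec)
    alpha, mask = _rasterize(spec, segs)

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    center = size / 2.0
    rr = np.hypot(xx - center, yy - center)
    R = spec.fov_radius * size
    fov = rr <= R

    # radial shading: background intensity falls off toward the FOV rim
    shade = spec.background_mean * (1.0 - 0.25 * np.clip(rr / R, 0.0, 1.2) ** 2)
    img = shade - (spec.background_mean - spec.vessel_mean) * alpha
    img = np.where(fov, img, 0.04)
    rng = _node_rng(spec.seed, (9999,))
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img8 = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
    rgb = np.stack([img8, img8, (img8 * 0.85).astype(np.uint8)], axis=-1)

    pre = pre or PreprocessConfig(target_size=size)
    hard_mask = (mask & fov).astype(np.uint8)
    fov_mask = fov.astype(np.uint8)
    if pre.target_size != size:
        from .data_pipeline import resize_mask

        hard_mask = resize_mask(hard_mask, pre.target_size)
        fov_mask = resize_mask(fov_mask, pre.target_size)
    sample = ImageSample(
        image=preprocess(rgb, pre),
        mask=hard_mask,
        fov=fov_mask,
        source=f"phantom(seed={spec.seed}, depth={spec.depth})",
    )
    sample.validate()
    return sample


def generate_phantom_set(n: int, spec: PhantomSpec | None = None,
                         pre: PreprocessConfig | None = None) -> list[ImageSample]:
    """n phantoms with consecutive seeds starting at spec.seed."""
    spec = spec or PhantomSpec()
    out = []
    for i in range(n):
        s = PhantomSpec(**{**spec.__dict__, "seed": spec.seed + i})
        out.append(generate_phantom(s, pre))
    return out


def is_connected(mask: np.ndarray) -> bool:
    """True if the foreground is one 8-connected component."""
    _, n = ndimage.label(np.asarray(mask) > 0, structure=np.ones((3, 3)))
    return n == 1
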