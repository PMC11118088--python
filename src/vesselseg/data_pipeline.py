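"""Dataset reading, preprocessing and augmentation for fundus images.

Directory layout (both supported dataset styles):

    <root>/images/<stem>.<png|tif|jpg|jpeg|gif>
    <root>/masks/<stem>[_annotsuffix].<png|gif>
    <root>/fov/<stem>*.<png|gif>          (optional)

Masks are matched to images by stem prefix; when a dataset ships two expert
annotations per image (e.g. `*_1stHO` / `*_2ndHO`), the first annotator's
file is selected.  Preprocessing follows: resize (bilinear for images,
nearest for masks/FOV) -> CLAHE on the Lab luminance channel -> gamma
correction -> linear map of 8-bit values to [-1, 1] via x / 127.5 - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import color, exposure, transform

from .errors import DatasetError, DimensionError

_F32 = np.float32

IMAGE_EXTS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".gif")


@dataclass
class PreprocessConfig:
    """Preprocessing chain parameters.

    clahe_clip is scikit-image's normalized clip limit (fraction of the tile
    histogram); tiles is the number of CLAHE tiles per image side.  gamma > 1
    mildly brightens mid-tones, typical for fundus work.
    """

    target_size: int = 448
    clahe: bool = True
    clahe_clip: float = 0.02
    clahe_tiles: int = 8
    gamma: float = 1.2


@dataclass
class ImageSample:
    """One preprocessed sample: image in [-1, 1], binary mask, optional FOV."""

    image: np.ndarray
    mask: np.ndarray
    fov: np.ndarray | None
    source: str

    def validate(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise DimensionError(f"image must be (H,W,3), got {self.image.shape}")
        if self.mask.shape != self.image.shape[:2]:
            raise DimensionError(
                f"mask {self.mask.shape} does not match image {self.image.shape[:2]}"
            )
        if self.fov is not None and self.fov.shape != self.image.shape[:2]:
            raise DimensionError(
                f"FOV {self.fov.shape} does not match image {self.image.shape[:2]}"
            )
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be binary {{0,1}}, got {vals[:5]}")


@dataclass
class RawSample:
    image: np.ndarray  # uint8 RGB
    mask: np.ndarray   # uint8 {0,1}
    fov: np.ndarray | None
    source: str


def _load_rgb(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"))
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise DatasetError(f"cannot read image {path}: {exc}") from exc


def _load_binary(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except Exception as exc:  # noqa: BLE001
        raise DatasetError(f"cannot read mask {path}: {exc}") from exc
    return (arr > 127).astype(np.uint8)


def _match(stem: str, pool: list[Path]) -> Path | None:
    cands = sorted(p for p in pool if p.stem == stem or p.stem.startswith(stem + "_")
                   or p.stem.startswith(stem))
    if not cands:
        return None
    if len(cands) > 1:
        first = [p for p in cands if "1st" in p.stem.lower()]
        if first:
            return first[0]
    return cands[0]


def read_dataset(root, layout: str = "drive") -> list[RawSample]:
    """Enumerate `<root>/{images,masks[,fov]}`, sorted by image filename.

    `layout` is accepted for documentation symmetry ("drive" or "chasedb1");
    both styles resolve through the same stem-prefix matching, which picks the
    first annotator's mask when two are present.
    """
    if layout not in ("drive", "chasedb1"):
        raise ValueError(f"unknown layout {layout!r}")
    root = Path(root)
    img_dir, mask_dir, fov_dir = root / "images", root / "masks", root / "fov"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise DatasetError(f"{root} must contain images/ and masks/ subdirectories")
    images = sorted(p for p in img_dir.iterdir() if p.suffix.lower() in IMAGE_EXTS)
    if not images:
        raise DatasetError(f"no images found under {img_dir}")
    masks = [p for p in mask_dir.iterdir() if p.suffix.lower() in IMAGE_EXTS]
    fovs = [p for p in fov_dir.iterdir() if p.suffix.lower() in IMAGE_EXTS] if fov_dir.is_dir() else []
    samples = []
    for img_path in images:
        mask_path = _match(img_path.stem, masks)
        if mask_path is None:
            raise DatasetError(f"no mask found for image stem '{img_path.stem}'")
        fov_path = _match(img_path.stem, fovs) if fovs else None
        samples.append(RawSample(
            image=_load_rgb(img_path),
            mask=_load_binary(mask_path),
            fov=_load_binary(fov_path) if fov_path else None,
            source=str(img_path),
        ))
    return samples


# -- preprocessing -----------------------------------------------------------

def resize_image(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of an RGB uint8 image to size x size."""
    if image.shape[:2] == (size, size):
        return image.astype(np.uint8, copy=False)
    out = transform.resize(image, (size, size), order=1, preserve_range=True,
                           anti_aliasing=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def resize_mask(mask: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbor resize; binarity is preserved."""
    if mask.shape == (size, size):
        return mask.astype(np.uint8, copy=False)
    out = transform.resize(mask.astype(np.uint8), (size, size), order=0,
                           preserve_range=True, anti_aliasing=False)
    return (out > 0.5).astype(np.uint8)


def apply_clahe(image: np.ndarray, clip: float = 0.02, tiles: int = 8) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on Lab luminance."""
    lab = color.rgb2lab(image)
    L = lab[..., 0] / 100.0
    kernel = max(image.shape[0] // tiles, 1)
    lab[..., 0] = exposure.equalize_adapthist(L, kernel_size=kernel, clip_limit=clip) * 100.0
    rgb = color.lab2rgb(lab)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def normalize_to_unit_range(image: np.ndarray) -> np.ndarray:
    """Map 8-bit intensities to [-1, 1]: x / 127.5 - 1."""
    return (np.asarray(image, dtype=_F32) / _F32(127.5)) - _F32(1.0)


def preprocess(image: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Full image chain: resize -> CLAHE -> gamma -> [-1, 1] normalization."""
    cfg = cfg or PreprocessConfig()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise DatasetError(f"preprocess expects an RGB image, got shape {image.shape}")
    out = resize_image(image, cfg.target_size)
    if cfg.clahe:
        out = apply_clahe(out, cfg.clahe_clip, cfg.clahe_tiles)
    if cfg.gamma != 1.0:
        out = np.clip(np.rint(exposure.adjust_gamma(out, cfg.gamma)), 0, 255).astype(np.uint8)
    return normalize_to_unit_range(out)


def prepare_sample(raw: RawSample, cfg: PreprocessConfig | None = None) -> ImageSample:
    cfg = cfg or PreprocessConfig()
    sample = ImageSample(
        image=preprocess(raw.image, cfg),
        mask=resize_mask(raw.mask, cfg.target_size),
        fov=resize_mask(raw.fov, cfg.target_size) if raw.fov is not None else None,
        source=raw.source,
    )
    sample.validate()
    return sample


# -- augmentation ------------------------------------------------------------

def augment(sample: ImageSample, seed_or_rng) -> ImageSample:
    """Independent 0.5-probability horizontal and vertical flips, applied
    identically to image, mask and FOV.  Deterministic for a given seed."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    flip_h = rng.random() < 0.5
    flip_v = rng.random() < 0.5

    def _flip(arr):
        if arr is None:
            return None
        if flip_h:
            arr = arr[:, ::-1]
        if flip_v:
            arr = arr[::-1, :]
        return np.ascontiguousarray(arr)

    return replace(sample, image=_flip(sample.image), mask=_flip(sample.mask),
                   fov=_flip(sample.fov))


def write_dataset(samples, out_dir) -> Path:
    """Write samples in the documented layout (8-bit PNGs, masks {0,255})."""
    out_dir = Path(out_dir)
    for sub in ("images", "masks", "fov"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(samples):
        stem = f"phantom_{i:03d}"
        img8 = np.clip(np.rint((s.image + 1.0) * 127.5), 0, 255).astype(np.uint8)
        Image.fromarray(img8).save(out_dir / "images" / f"{stem}.png")
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(out_dir / "masks" / f"{stem}.png")
        if s.fov is not None:
            Image.fromarray((s.fov * 255).astype(np.uint8)).save(out_dir / "fov" / f"{stem}.png")
    return out_dir
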