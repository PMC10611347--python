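"""Deterministic phantom datasets for multi-class segmentation.

The generator emulates the structure of the clinical data the network
targets — several soft-tissue "organs" of different sizes and intensities on
a dark, noisy background — without any anatomy: each structure is a rotated
ellipse with a structure-specific intensity band, later structures overwrite
earlier ones where they overlap (stable, documented semantics), and the
image is corrupted by additive Gaussian noise. The ultrasound-like variant
additionally applies multiplicative speckle noise and a Gaussian blur that
softens boundaries, mimicking the low-contrast, speckled appearance of
echocardiography. Everything is fully determined by the spec's seed.

Samples are 8-bit grayscale images with 8-bit integer label masks
(0 = background, 1..K = structures) and round-trip losslessly through
PNG pairs or NIfTI volumes; the reader also accepts TIFF image/mask pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse

__all__ = ["LabeledSample", "PhantomSpec", "generate_phantom_dataset",
           "write_dataset", "read_dataset"]


@dataclass
class LabeledSample:
    """Grayscale image + integer mask + identifier (one 'patient')."""

    image: np.ndarray          # uint8 (H, W)
    mask: np.ndarray           # uint8 (H, W), labels 0..K
    sample_id: str
    spacing: tuple[float, float] = (1.0, 1.0)

    def image_float(self) -> np.ndarray:
        """Image scaled to [0, 1] float for the network."""
        return self.image.astype(np.float64) / 255.0


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one phantom dataset."""

    n_samples: int = 64
    image_size: int = 64
    n_structures: int = 3
    noise_sigma: float = 0.03          # additive Gaussian, [0,1] intensity scale
    speckle: bool = False
    speckle_strength: float = 0.25     # sd of the multiplicative field
    blur_sigma: float = 1.0            # boundary blur (px), speckle variant only
    contrast: tuple[float, float] = (0.35, 0.95)
    background: float = 0.10
    min_pixels: int = 20               # guaranteed per foreground label
    max_occlusion: float = 0.5         # structures stay non-degenerate: a later
                                       # draw may cover at most this fraction
                                       # of any earlier structure
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.image_size < 8:
            raise ValueError("need n_samples >= 1 and image_size >= 8")
        if not 1 <= self.n_structures <= 8:
            raise ValueError(
                f"n_structures must be in 1..8, got {self.n_structures}")


def _one_phantom(spec: PhantomSpec, rng: np.random.Generator,
                 index: int) -> LabeledSample:
    size = spec.image_size
    lo, hi = spec.contrast
    bands = np.linspace(lo, hi, spec.n_structures + 1)
    for _ in range(50):   # bounded retries for the generator guarantees
        mask = np.zeros((size, size), dtype=np.uint8)
        intensity = np.full((size, size), spec.background)
        areas = np.zeros(spec.n_structures + 1)
        ok = True
        for label in range(1, spec.n_structures + 1):
            for _ in range(30):   # placement retries against over-occlusion
                r0 = rng.uniform(0.22 * size, 0.78 * size)
                c0 = rng.uniform(0.22 * size, 0.78 * size)
                ra = rng.uniform(0.10 * size, 0.22 * size)
                rb = rng.uniform(0.10 * size, 0.22 * size)
                angle = rng.uniform(0, np.pi)
                rr, cc = draw_ellipse(r0, c0, ra, rb, shape=(size, size),
                                      rotation=angle)
                covered = np.bincount(mask[rr, cc],
                                      minlength=spec.n_structures + 1)
                if all(covered[k] <= spec.max_occlusion * areas[k]
                       for k in range(1, label)):
                    break
            else:
                ok = False
                break
            value = rng.uniform(bands[label - 1], bands[label])
            mask[rr, cc] = label
            intensity[rr, cc] = value
            areas = np.bincount(mask.ravel(), minlength=spec.n_structures + 1)
        counts = np.bincount(mask.ravel(), minlength=spec.n_structures + 1)
        if ok and (counts[1:] >= spec.min_pixels).all():
            break
    else:
        raise RuntimeError(
            f"could not place {spec.n_structures} structures with "
            f">= {spec.min_pixels} pixels each in a {size}x{size} image")

    if spec.speckle:
        intensity = gaussian_filter(intensity, spec.blur_sigma)
        # gamma-distributed multiplicative field, mean 1
        k = 1.0 / spec.speckle_strength ** 2
        intensity = intensity * rng.gamma(k, 1.0 / k, size=intensity.shape)
    image = intensity + rng.normal(0.0, spec.noise_sigma, size=intensity.shape)
    image = np.clip(image, 0.0, 1.0)
    return LabeledSample(
        image=np.round(image * 255).astype(np.uint8),
        mask=mask,
        sample_id=f"phantom_{index:04d}",
    )


def generate_phantom_dataset(spec: PhantomSpec) -> list[LabeledSample]:
    """Generate ``spec.n_samples`` phantoms, fully determined by the seed."""
    rng = np.random.default_rng(spec.seed)
    return [_one_phantom(spec, rng, i) for i in range(spec.n_samples)]


# ---------------------------------------------------------------------------
# On-disk formats


def write_dataset(samples: list[LabeledSample], directory, fmt: str = "png-pair") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt == "png-pair":
        for s in samples:
            Image.fromarray(s.image, mode="L").save(
                directory / f"image_{s.sample_id}.png")
            Image.fromarray(s.mask, mode="L").save(
                directory / f"mask_{s.sample_id}.png")
    elif fmt == "nifti":
        import nibabel as nib
        for s in samples:
            affine = np.diag([s.spacing[0], s.spacing[1], 1.0, 1.0])
            nib.save(nib.Nifti1Image(s.image[..., None], affine),
                     directory / f"image_{s.sample_id}.nii.gz")
            nib.save(nib.Nifti1Image(s.mask[..., None], affine),
                     directory / f"mask_{s.sample_id}.nii.gz")
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'png-pair' or 'nifti'")


def read_dataset(directory) -> list[LabeledSample]:
    """Read image/mask pairs (PNG or NIfTI) back; inverse of write_dataset."""
    directory = Path(directory)
    images: dict[str, Path] = {}
    masks: dict[str, Path] = {}
    pattern = re.compile(r"^(image|mask)_(.+?)\.(png|tiff?|nii(?:\.gz)?)$")
    for path in sorted(directory.iterdir()):
        m = pattern.match(path.name)
        if not m:
            continue
        (images if m.group(1) == "image" else masks)[m.group(2)] = path
    orphans = sorted(set(images) ^ set(masks))
    if orphans:
        raise ValueError(f"unpaired image/mask files for ids: {orphans}")
    if not images:
        raise ValueError(f"no image/mask pairs found in {directory}")

    samples = []
    shapes = set()
    for sid in sorted(images):
        img_path, mask_path = images[sid], masks[sid]
        if img_path.suffix in (".png", ".tif", ".tiff"):
            image = np.asarray(Image.open(img_path), dtype=np.uint8)
            mask = np.asarray(Image.open(mask_path), dtype=np.uint8)
            spacing = (1.0, 1.0)
        else:
            import nibabel as nib
            img = nib.load(img_path)
            image = np.asarray(img.dataobj)[..., 0].astype(np.uint8)
            mask = np.asarray(nib.load(mask_path).dataobj)[..., 0].astype(np.uint8)
            zooms = img.header.get_zooms()
            spacing = (float(zooms[0]), float(zooms[1]))
        shapes.add(image.shape)
        samples.append(LabeledSample(image, mask, sid, spacing))
    if len(shapes) > 1:
        raise ValueError(f"mixed image sizes in {directory}: {sorted(shapes)}")
    return samples
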