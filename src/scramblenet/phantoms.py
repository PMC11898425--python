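"""Seeded synthetic brain-like phantoms in two classes (normal / tumor).

Each phantom is a square 8-bit grayscale image: a bright centered ellipse
("brain") on a dark field, with a smooth zero-mean intensity ramp across the
brain and additive Gaussian noise.  Tumor-class phantoms additionally carry
exactly one compact bright elliptical lesion placed uniformly at random
inside the brain; normal-class phantoms carry none.  The lesion's mean
intensity uplift and its radius (as a fraction of the brain radius) are the
separability dials: at the defaults the two classes are strongly separable,
and as the uplift goes to zero the class-conditional intensity distributions
converge.

Generation is a pure function of (spec, seed): identical inputs give
bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "PhantomError",
    "PhantomSpec",
    "ImageRecord",
    "ImageDataset",
    "make_phantom",
    "make_dataset",
    "save_dataset",
    "load_image_folder",
    "NORMAL",
    "TUMOR",
]

#: Class labels, matching the "no"/"yes" convention of the emulated dataset
#: (tumor = positive class).
NORMAL = "no"
TUMOR = "yes"


class PhantomError(ValueError):
    """Invalid phantom specification."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom generator.

    Attributes
    ----------
    side : int
        Image side length in pixels (square), >= 16.
    n_normal, n_tumor : int
        Class counts; the defaults mirror a 251-image clinical set with
        97 normal and 154 tumor images.
    brain_radius_frac : float
        Brain ellipse semi-axes as a fraction of ``side / 2``.
    background_level, brain_level : float
        Mean intensity of the dark field and of the brain interior.
    gradient_amplitude : float
        Peak-to-trough amplitude of the smooth zero-mean ramp across the
        brain (random direction per image).
    lesion_uplift : (float, float)
        Uniform range of the lesion's additive intensity uplift; the default
        60 +/- 10 makes the classes strongly separable.
    lesion_radius_frac : (float, float)
        Uniform range of the lesion radius as a fraction of the brain
        radius; must lie inside (0, 0.5).
    noise_sigma : float
        Standard deviation of the additive Gaussian noise on the 0-255
        scale (clipped to [0, 255] after adding).
    seed : int
        Master seed for :func:`make_dataset`.
    """

    side: int = 224
    n_normal: int = 97
    n_tumor: int = 154
    brain_radius_frac: float = 0.8
    background_level: float = 20.0
    brain_level: float = 120.0
    gradient_amplitude: float = 30.0
    lesion_uplift: tuple = (50.0, 70.0)
    lesion_radius_frac: tuple = (0.10, 0.25)
    noise_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.side < 16:
            raise PhantomError(f"side must be >= 16, got {self.side}")
        if self.n_normal < 0 or self.n_tumor < 0:
            raise PhantomError("class counts must be >= 0")
        lo, hi = self.lesion_radius_frac
        if not (0.0 < lo <= hi < 0.5):
            raise PhantomError(
                f"lesion_radius_frac must lie inside (0, 0.5), got {self.lesion_radius_frac}"
            )
        if self.noise_sigma < 0:
            raise PhantomError("noise_sigma must be >= 0")
        if not (0.0 < self.brain_radius_frac < 1.0):
            raise PhantomError("brain_radius_frac must lie in (0, 1)")


def _ellipse_mask(side: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def make_phantom(
    spec: PhantomSpec,
    label: Literal["no", "yes"],
    rng: np.random.Generator,
    return_meta: bool = False,
) -> np.ndarray:
    """Draw one phantom of the given class from the generator's RNG stream.

    Returns a ``side x side`` uint8 array.  Tumor-class images contain
    exactly one bright lesion whose interior mean exceeds the local
    background by the configured uplift; the lesion is rejected-sampled so
    it fits entirely inside the brain ellipse.

    With ``return_meta=True`` also returns a dict of the drawn geometry
    (brain axes, and for tumors the lesion center/radius/uplift), useful
    for validating the generator itself.
    """
    if label not in (NORMAL, TUMOR):
        raise PhantomError(f"label must be {NORMAL!r} or {TUMOR!r}, got {label!r}")
    side = spec.side
    c = (side - 1) / 2.0
    brain_r = spec.brain_radius_frac * side / 2.0
    # mild per-image anisotropy so brains are ellipses, not perfect circles
    ry = brain_r * rng.uniform(0.9, 1.0)
    rx = brain_r * rng.uniform(0.75, 0.9)
    brain = _ellipse_mask(side, c, c, ry, rx)

    meta = {"center": c, "ry": ry, "rx": rx}
    img = np.full((side, side), spec.background_level, dtype=np.float64)
    img[brain] = spec.brain_level

    # smooth zero-mean linear ramp across the image, random direction
    theta = rng.uniform(0.0, 2.0 * np.pi)
    yy, xx = np.mgrid[0:side, 0:side]
    ramp = ((yy - c) * np.sin(theta) + (xx - c) * np.cos(theta)) / side
    img[brain] += spec.gradient_amplitude * ramp[brain]

    if label == TUMOR:
        r_frac = rng.uniform(*spec.lesion_radius_frac)
        lesion_r = r_frac * min(rx, ry)
        if lesion_r < 1.0:
            raise PhantomError(
                f"lesion radius {lesion_r:.2f} px is below 1 px; "
                "increase side or lesion_radius_frac"
            )
        uplift = rng.uniform(*spec.lesion_uplift)
        for _ in range(1000):
            ly = rng.uniform(c - ry, c + ry)
            lx = rng.uniform(c - rx, c + rx)
            # lesion must fit entirely inside the brain ellipse
            margin_ok = ((ly - c) / (ry - lesion_r)) ** 2 + (
                (lx - c) / (rx - lesion_r)
            ) ** 2 <= 1.0 if min(rx, ry) > lesion_r else False
            if margin_ok:
                break
        else:
            raise PhantomError("could not place lesion inside brain mask")
        lesion = _ellipse_mask(side, ly, lx, lesion_r, lesion_r)
        img[lesion] += uplift
        meta.update(
            {"lesion_y": ly, "lesion_x": lx, "lesion_r": lesion_r, "uplift": uplift}
        )

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    out = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return (out, meta) if return_meta else out


@dataclass(frozen=True)
class ImageRecord:
    """One labeled image with its split assignment."""

    id: str
    image: np.ndarray
    label: str
    split: Literal["train", "test"]


@dataclass
class ImageDataset:
    """A labeled collection of square grayscale images with a train/test
    split.  Ids are unique; labels are binary ("no"/"yes")."""

    records: list = field(default_factory=list)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise PhantomError("image ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ImageRecord]:
        return iter(self.records)

    def subset(self, split: str) -> "ImageDataset":
        return ImageDataset([r for r in self.records if r.split == split])

    @property
    def images(self) -> list:
        return [r.image for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    def class_counts(self) -> dict:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def with_images(self, images: Sequence[np.ndarray]) -> "ImageDataset":
        """Same ids/labels/split with the images replaced (e.g. encrypted)."""
        if len(images) != len(self.records):
            raise PhantomError("image count mismatch")
        return ImageDataset(
            [replace(r, image=img) for r, img in zip(self.records, images)]
        )


def _stratified_split(
    labels: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-class test counts are round(count * test_fraction)."""
    split = np.full(labels.shape, "train", dtype=object)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        n_test = int(np.floor(len(idx) * test_fraction + 0.5))
        chosen = rng.permutation(idx)[:n_test]
        split[chosen] = "test"
    return split.astype(str)


def make_dataset(
    spec: PhantomSpec,
    test_fraction: float = 0.2,
    seed: int | None = None,
) -> ImageDataset:
    """Generate the full phantom dataset with a stratified train/test split.

    *seed* overrides ``spec.seed`` when given.  Per-class test counts are
    ``round(count * test_fraction)`` (e.g. 97/154 at 0.2 gives 19 + 31 test
    images).  Determinism: identical (spec, seed) gives a bit-identical
    dataset including split membership.
    """
    if not (0.0 < test_fraction < 1.0):
        raise PhantomError(f"test_fraction must be in (0, 1), got {test_fraction}")
    if seed is None:
        seed = spec.seed
    if (spec.n_normal == 0) != (spec.n_tumor == 0) and min(
        spec.n_normal, spec.n_tumor
    ) == 0:
        raise PhantomError("both classes need at least one image for a split")
    rng = np.random.default_rng(seed)
    records = []
    labels = [NORMAL] * spec.n_normal + [TUMOR] * spec.n_tumor
    for i, lab in enumerate(labels):
        img = make_phantom(spec, lab, rng)
        records.append(ImageRecord(id=f"img{i:04d}", image=img, label=lab, split="train"))
    split = _stratified_split(
        np.array([r.label for r in records]), test_fraction, rng
    )
    records = [replace(r, split=sp) for r, sp in zip(records, split)]
    return ImageDataset(records)


# ---------------------------------------------------------------------------
# On-disk folder-of-PNGs + labels.csv interchange
# ---------------------------------------------------------------------------

def save_dataset(dataset: ImageDataset, out_dir: str | Path) -> Path:
    """Write PNG images plus ``labels.csv`` (filename,label,split)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in dataset:
        fname = f"{rec.id}.png"
        Image.fromarray(rec.image, mode="L").save(out / fname)
        rows.append({"filename": fname, "label": rec.label, "split": rec.split})
    csv_path = out / "labels.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return csv_path


def load_image_folder(
    folder: str | Path, labels_csv: str | Path | None = None
) -> ImageDataset:
    """Load a folder of grayscale PNG/TIFF images described by a labels CSV.

    The CSV must have columns filename, label and (optionally) split; a
    missing split column assigns everything to "train".  Lossy formats are
    rejected because the cipher round-trip contract requires bit-exact IO.
    """
    folder = Path(folder)
    if labels_csv is None:
        labels_csv = folder / "labels.csv"
    table = pd.read_csv(labels_csv)
    for col in ("filename", "label"):
        if col not in table.columns:
            raise PhantomError(f"labels CSV lacks required column {col!r}")
    if "split" not in table.columns:
        table = table.assign(split="train")
    records = []
    for row in table.itertuples(index=False):
        path = folder / row.filename
        if path.suffix.lower() in (".jpg", ".jpeg"):
            raise PhantomError(
                f"{path.name}: lossy JPEG input is not supported; use PNG or TIFF"
            )
        with Image.open(path) as im:
            img = np.asarray(im.convert("L"))
        records.append(
            ImageRecord(id=path.stem, image=img, label=str(row.label), split=str(row.split))
        )
    return ImageDataset(records)
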