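"""Reading, writing and augmenting fundus images, masks and FOV files.

A sample is an RGB image plus a binary ground-truth mask and an optional
binary field-of-view mask, all sharing one spatial size.  Datasets are
described by CSV manifests with ``image,gt,fov`` columns so any on-disk
layout (DRIVE-style, IDRiD-style, synthetic) can be pointed at without
hard-coded paths.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

__all__ = [
    "SamplePair",
    "load_sample",
    "save_sample",
    "resize_for_lesions",
    "augment_six",
    "read_manifest",
    "write_manifest",
]

LESION_TARGET = (712, 1072)  # (height, width) used for the lesion datasets


@dataclass
class SamplePair:
    image: np.ndarray  # H x W x 3 uint8
    gt: np.ndarray  # H x W binary {0,1} uint8
    fov: np.ndarray | None  # H x W binary {0,1} uint8, or None
    identifier: str = ""

    def __post_init__(self) -> None:
        hw = self.image.shape[:2]
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"image must be H x W x 3, got {self.image.shape}")
        if self.gt.shape != hw:
            raise ValueError(
                f"gt size {self.gt.shape} does not match image size {hw}"
            )
        if self.fov is not None and self.fov.shape != hw:
            raise ValueError(
                f"fov size {self.fov.shape} does not match image size {hw}"
            )


def _binarize(mask: np.ndarray) -> np.ndarray:
    if mask.ndim == 3:
        mask = mask[..., 0]
    return (mask > 0).astype(np.uint8)


def _read_rgb(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    return arr.astype(np.uint8)


def load_sample(image_path, gt_path, fov_path=None, identifier=None) -> SamplePair:
    """Load an image + mask (+ optional FOV); masks binarized (nonzero -> 1)."""
    image = _read_rgb(image_path)
    gt = _binarize(iio.imread(gt_path))
    fov = None if fov_path is None else _binarize(iio.imread(fov_path))
    ident = identifier if identifier is not None else Path(image_path).stem
    return SamplePair(image=image, gt=gt, fov=fov, identifier=ident)


def save_sample(sample: SamplePair, out_dir, prefix: str | None = None) -> dict:
    """Write image/gt/fov as PNGs; returns the manifest row (paths)."""
    out_dir = Path(out_dir).resolve()
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or sample.identifier or "sample"
    row = {}
    row["image"] = str(out_dir / f"{prefix}_image.png")
    iio.imwrite(row["image"], sample.image)
    row["gt"] = str(out_dir / f"{prefix}_gt.png")
    iio.imwrite(row["gt"], (sample.gt * 255).astype(np.uint8))
    if sample.fov is not None:
        row["fov"] = str(out_dir / f"{prefix}_fov.png")
        iio.imwrite(row["fov"], (sample.fov * 255).astype(np.uint8))
    else:
        row["fov"] = ""
    return row


def resize_for_lesions(sample: SamplePair, target=LESION_TARGET) -> SamplePair:
    """Resize to the lesion-training resolution (default 712 x 1072, H x W).

    The image is resized bilinearly; masks use nearest-neighbour so they
    stay binary without an interpolation rule.
    """
    h, w = target
    image = resize(sample.image, (h, w), order=1, preserve_range=True,
                   anti_aliasing=True).round().astype(np.uint8)
    gt = _binarize(resize(sample.gt, (h, w), order=0, preserve_range=True))
    fov = None
    if sample.fov is not None:
        fov = _binarize(resize(sample.fov, (h, w), order=0, preserve_range=True))
    return SamplePair(image=image, gt=gt, fov=fov, identifier=sample.identifier)


# The x6 augmentation: identity, horizontal/vertical flips, and the three
# right-angle rotations.  Right angles keep masks interpolation-free; the
# same transform is applied to image, gt and fov.
_TRANSFORMS = (
    ("id", lambda a: a),
    ("hflip", lambda a: a[:, ::-1]),
    ("vflip", lambda a: a[::-1]),
    ("rot90", lambda a: np.rot90(a, 1)),
    ("rot180", lambda a: np.rot90(a, 2)),
    ("rot270", lambda a: np.rot90(a, 3)),
)


def augment_six(sample: SamplePair) -> list[SamplePair]:
    """Return the 6 augmented copies of a sample (so 54 inputs -> 324)."""
    out = []
    for tag, f in _TRANSFORMS:
        out.append(
            SamplePair(
                image=np.ascontiguousarray(f(sample.image)),
                gt=np.ascontiguousarray(f(sample.gt)),
                fov=None if sample.fov is None
                else np.ascontiguousarray(f(sample.fov)),
                identifier=f"{sample.identifier}_{tag}",
            )
        )
    return out


def read_manifest(path) -> list[dict]:
    """Read a CSV manifest with columns image,gt[,fov]; paths are resolved
    relative to the manifest's directory when not absolute."""
    path = Path(path)
    base = path.parent
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out = {}
            for key in ("image", "gt", "fov"):
                val = (row.get(key) or "").strip()
                if val and not Path(val).is_absolute():
                    val = str(base / val)
                out[key] = val or None
            if out["image"] is None or out["gt"] is None:
                raise ValueError(f"manifest row missing image/gt: {row}")
            rows.append(out)
    if not rows:
        raise ValueError(f"manifest {path} is empty")
    return rows


def write_manifest(rows: list[dict], path) -> None:
    """Write rows to CSV; paths under the manifest's directory are stored
    relative to it (so the dataset folder can be moved wholesale)."""
    path = Path(path).resolve()
    path.parent.mkdir(parents=True, exist_ok=True)

    def _rel(p):
        if not p:
            return ""
        p = Path(p).resolve()
        try:
            return str(p.relative_to(path.parent))
        except ValueError:
            return str(p)

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["image", "gt", "fov"])
        writer.writeheader()
        for row in rows:
            writer.writerow({k: _rel(row.get(k)) for k in ("image", "gt", "fov")})


def load_manifest_samples(path) -> list[SamplePair]:
    return [
        load_sample(r["image"], r["gt"], r.get("fov"))
        for r in read_manifest(path)
    ]
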