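"""Reading micrographs and sample manifests; writing particle tables.

Micrographs are bright-field images of fungal pellets, stored as 8- or
16-bit grayscale TIFF or PNG.  A *sample manifest* is a CSV that organises
images by biological sample, cultivation time point and replicate, so a
whole time course can be processed in one call.

The pixel-to-area calibration used throughout the package is
``DEFAULT_PIXEL_AREA_UM2`` = 5.44 µm² per pixel (40x bright-field
magnification of the reference setup).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ImageFormatError, IOFailureError, ValidationError

#: Physical area of one pixel at the reference magnification (µm² px⁻¹).
DEFAULT_PIXEL_AREA_UM2 = 5.44

# ITU-R BT.709 luminance weights, as used by scikit-image's rgb2gray.
_LUMA_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])

MANIFEST_REQUIRED_COLUMNS = ("sample_id", "time_h", "replicate", "image_path")

PARTICLE_CSV_COLUMNS = (
    "image_id",
    "label",
    "area_px",
    "area_um2",
    "centroid_x",
    "centroid_y",
)


@dataclass(frozen=True)
class RawImage:
    """A 2-D grayscale micrograph with its physical pixel calibration.

    Parameters
    ----------
    pixels : numpy.ndarray
        2-D array of non-negative intensities (8- or 16-bit range).
    pixel_area_um2 : float
        Physical area covered by one pixel, µm² px⁻¹ (> 0).
    source_path : str
        Provenance string, usually the file the image was read from.
    """

    pixels: np.ndarray
    pixel_area_um2: float = DEFAULT_PIXEL_AREA_UM2
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ImageFormatError(
                f"image must be 2-D grayscale, got shape {px.shape}"
                + (f" ({self.source_path})" if self.source_path else "")
            )
        if px.size and px.min() < 0:
            raise ImageFormatError("image intensities must be non-negative")
        if not self.pixel_area_um2 > 0:
            raise ValidationError("pixel_area_um2 must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def read_image(path: str | Path, pixel_area_um2: float = DEFAULT_PIXEL_AREA_UM2) -> RawImage:
    """Read a TIFF/PNG micrograph as a :class:`RawImage`.

    16-bit data is preserved without rescaling.  RGB images are converted
    to luminance (with a warning — reference micrographs are grayscale);
    an RGB image with equal channels converts to exactly that gray value.

    Raises
    ------
    ImageFormatError
        If the file is not a readable 2-D image (e.g. a multi-page stack).
    IOFailureError
        If the file does not exist or cannot be read at all.
    """
    path = Path(path)
    if not path.is_file():
        raise IOFailureError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except ImageFormatError:
        raise
    except Exception as exc:  # noqa: BLE001 - backend errors vary widely
        raise ImageFormatError(f"could not decode image {path}: {exc}") from exc

    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        warnings.warn(
            f"RGB image converted to luminance: {path}", UserWarning, stacklevel=2
        )
        rgb = arr[..., :3].astype(np.float64)
        gray = rgb @ _LUMA_WEIGHTS
        arr = np.round(gray).astype(arr.dtype)
    if arr.ndim != 2:
        raise ImageFormatError(
            f"expected a single 2-D frame, got shape {arr.shape} in {path}"
        )
    return RawImage(pixels=arr, pixel_area_um2=pixel_area_um2, source_path=str(path))


def write_image(img: RawImage | np.ndarray, path: str | Path) -> None:
    """Write a grayscale image as PNG or TIFF (by extension)."""
    pixels = img.pixels if isinstance(img, RawImage) else np.asarray(img)
    try:
        iio.imwrite(Path(path), pixels)
    except Exception as exc:  # noqa: BLE001
        raise IOFailureError(f"could not write image {path}: {exc}") from exc


@dataclass
class SampleManifest:
    """Rows of (sample_id, time_h, replicate, image_path[, temperature_C]).

    Encodes how replicate micrographs map onto cultivation time points,
    e.g. 300 images per time point as 100 images for each of three
    biological replicates.
    """

    rows: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in MANIFEST_REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"manifest missing required columns: {missing}")
        if df["image_path"].duplicated().any():
            dups = df.loc[df["image_path"].duplicated(), "image_path"].tolist()
            raise ValidationError(f"duplicate image_path entries: {dups[:5]}")
        if (df["time_h"] < 0).any():
            bad = df.index[df["time_h"] < 0].tolist()
            raise ValidationError(f"negative time_h at rows {bad}")

    def __len__(self) -> int:
        return len(self.rows)

    def groups(self) -> Iterator[tuple[tuple[str, float], pd.DataFrame]]:
        """Iterate (sample_id, time_h) groups sorted by sample then time."""
        for key, grp in self.rows.groupby(["sample_id", "time_h"], sort=True):
            yield key, grp  # type: ignore[misc]


def load_manifest(path: str | Path, check_files: bool = True) -> SampleManifest:
    """Load and validate a sample-manifest CSV.

    Every referenced image file must exist; missing files are reported
    with their (1-based, header-exclusive) row numbers.
    """
    path = Path(path)
    if not path.is_file():
        raise IOFailureError(f"manifest not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"sample_id": str, "image_path": str})
    except Exception as exc:  # noqa: BLE001
        raise ValidationError(f"could not parse manifest {path}: {exc}") from exc

    manifest = SampleManifest(rows=df)
    if check_files and len(df):
        root = path.parent
        missing = []
        for i, p in enumerate(df["image_path"], start=1):
            candidate = Path(p)
            if not candidate.is_absolute():
                candidate = root / candidate
            if not candidate.is_file():
                missing.append((i, p))
        if missing:
            listing = "; ".join(f"row {i}: {p}" for i, p in missing[:10])
            raise ValidationError(f"manifest references missing files: {listing}")
    return manifest


def resolve_image_path(manifest_path: str | Path, image_path: str) -> Path:
    """Resolve a manifest-relative image path against the manifest location."""
    p = Path(image_path)
    return p if p.is_absolute() else Path(manifest_path).parent / p


def write_particles(table, path: str | Path) -> None:
    """Write a ParticleTable as CSV (schema: image_id,label,area_px,area_um2,
    centroid_x,centroid_y), with the segmentation-parameter snapshot embedded
    as ``#``-prefixed metadata header lines.

    Reading the file back with :func:`read_particles` reproduces the table's
    data rows exactly.
    """
    df = table.to_dataframe()
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            for line in table.params_header_lines():
                fh.write(f"# {line}\n")
            df.to_csv(fh, index=False)
    except OSError as exc:
        raise IOFailureError(f"could not write particle table {path}: {exc}") from exc


def read_particles(path: str | Path) -> pd.DataFrame:
    """Read a particle CSV written by :func:`write_particles` as a DataFrame."""
    path = Path(path)
    if not path.is_file():
        raise IOFailureError(f"particle table not found: {path}")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PARTICLE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"particle CSV {path} missing columns {missing}")
    return df
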