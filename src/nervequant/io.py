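"""Reading, writing and standardisation of corneal confocal microscopy images.

CCM devices deliver greyscale rasters at a variety of frame sizes and pixel
pitches (Heidelberg HRT/RCM frames are 384x384 px covering 400x400 um;
ConfoScan exports 768x576 px covering 460x350 um).  Morphometry in physical
units requires a known pitch, so every image carries its pixel size in um/px
and all images are standardised to a common working pitch of 1.04 um/px in a
384x384 frame before patch extraction.

Conventions: rasters are ``float`` arrays in [0, 1], indexed (row, col) with
row 0 at the top.  Pixel pitch is stored per axis as (row_um, col_um); most
sources are isotropic and the two entries are equal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage.transform import resize

TARGET_PIXEL_UM = 1.04
TARGET_SIZE_PX = 384

# ITU-R BT.601 luma weights for collapsing RGB exports to grey
_BT601 = np.array([0.299, 0.587, 0.114])


@dataclass
class CCMImage:
    """A greyscale CCM raster with physical pixel pitch and provenance.

    Parameters
    ----------
    pixels : ndarray
        2-D float array with intensities in [0, 1].
    pixel_size_um : tuple of float or None
        (row_pitch, col_pitch) in um/px; ``None`` when the pitch is unknown
        (no field of view was supplied and no usable metadata was found).
    source_id : str
        Opaque provenance string (usually the file stem).
    """

    pixels: np.ndarray
    pixel_size_um: tuple[float, float] | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.size == 0:
            raise ValueError("pixels: zero-sized image")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"pixels: intensities must lie in [0, 1], got [{lo}, {hi}]")
        if self.pixel_size_um is not None:
            p = self.pixel_size_um
            if np.isscalar(p):
                p = (float(p), float(p))
            self.pixel_size_um = (float(p[0]), float(p[1]))
            if self.pixel_size_um[0] <= 0 or self.pixel_size_um[1] <= 0:
                raise ValueError("pixel_size_um: pitch must be positive")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def isotropic_pixel_um(self) -> float:
        """Scalar pitch; raises if unknown or anisotropic beyond 0.1%."""
        if self.pixel_size_um is None:
            raise ValueError("pixel size unknown; supply field_of_view_um at load time")
        r, c = self.pixel_size_um
        if abs(r - c) > 1e-3 * max(r, c):
            raise ValueError(f"anisotropic pitch {self.pixel_size_um}; standardise first")
        return r


@dataclass
class AnnotationMask:
    """Binary annotation raster (manual tracing or model output)."""

    pixels: np.ndarray
    pixel_size_um: tuple[float, float] | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.pixels.shape}")
        vals = np.unique(self.pixels)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("mask pixels must be strictly binary (0/1)")
        self.pixels = self.pixels.astype(bool)


def _to_unit_grey(arr: np.ndarray) -> np.ndarray:
    """Collapse channels by BT.601 luminance and rescale to [0, 1]."""
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr.astype(float) @ _BT601
        else:
            arr = arr[:, :, 0].astype(float)
        if np.issubdtype(np.asarray(arr).dtype, np.floating):
            # channel dot-product already float; scale below by original range
            pass
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / info.max
    arr = arr.astype(float)
    if arr.max() > 1.0:  # float image stored on an 8- or 16-bit scale
        arr = arr / (255.0 if arr.max() <= 255 else 65535.0)
    return np.clip(arr, 0.0, 1.0)


def _pitch_from_fov(shape: tuple[int, int],
                    field_of_view_um: tuple[float, float]) -> tuple[float, float]:
    # field of view is given as (width_um, height_um)
    w_um, h_um = field_of_view_um
    h_px, w_px = shape
    return (h_um / h_px, w_um / w_px)


def load_image(path: str | os.PathLike,
               field_of_view_um: tuple[float, float] | None = None) -> CCMImage:
    """Load a greyscale CCM image from TIFF/BMP/JPG/PNG.

    Parameters
    ----------
    path : path-like
        Image file.  RGB files are collapsed by BT.601 luminance.
    field_of_view_um : (width_um, height_um), optional
        Physical extent of the frame.  When given, the pixel pitch is
        ``extent / pixels`` per axis; otherwise TIFF resolution metadata is
        consulted, and failing that the pitch is left unknown.

    Returns
    -------
    CCMImage with intensities rescaled to [0, 1].
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:  # noqa: BLE001 - report decode failures as I/O errors
        raise IOError(f"could not decode image {path}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    pixels = _to_unit_grey(arr)
    pitch: tuple[float, float] | None = None
    if field_of_view_um is not None:
        pitch = _pitch_from_fov(pixels.shape, field_of_view_um)
    else:
        pitch = _pitch_from_tiff_metadata(path)
    return CCMImage(pixels=pixels, pixel_size_um=pitch,
                    source_id=os.path.splitext(os.path.basename(path))[0])


def _pitch_from_tiff_metadata(path: str) -> tuple[float, float] | None:
    """Read pixel pitch from TIFF resolution tags if present (um/px)."""
    if not path.lower().endswith((".tif", ".tiff")):
        return None
    try:
        import tifffile

        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is None or yres is None:
                return None
            # resolution = pixels per unit; unit 3 = cm, 2 = inch
            unit_um = {2: 25400.0, 3: 10000.0}.get(getattr(unit, "value", 2), None)
            if unit_um is None:
                return None
            xr = xres.value[0] / xres.value[1]
            yr = yres.value[0] / yres.value[1]
            if xr <= 0 or yr <= 0:
                return None
            return (unit_um / yr, unit_um / xr)
    except Exception:  # noqa: BLE001 - metadata is best-effort
        return None


def load_mask(path: str | os.PathLike) -> AnnotationMask:
    """Load a binary annotation mask; values >= half dynamic range become 1."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"mask file not found: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"could not decode mask {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3].astype(float) @ _BT601
    if np.issubdtype(np.asarray(arr).dtype, np.integer):
        half = np.iinfo(arr.dtype).max / 2.0
    else:
        half = (arr.max() / 2.0) if arr.max() > 1 else 0.5
    return AnnotationMask(pixels=(np.asarray(arr, dtype=float) >= half).astype(np.uint8),
                          source_id=os.path.splitext(os.path.basename(path))[0])


def pair_mask(image: CCMImage, mask: AnnotationMask) -> AnnotationMask:
    """Validate that a mask matches its image's frame; returns mask with pitch set."""
    if mask.pixels.shape != image.pixels.shape:
        raise ValueError(
            f"mask shape {mask.pixels.shape} does not match image {image.pixels.shape}")
    return AnnotationMask(pixels=mask.pixels.astype(np.uint8),
                          pixel_size_um=image.pixel_size_um, source_id=mask.source_id)


def _crop_pad_centre(arr: np.ndarray, target: int) -> np.ndarray:
    """Centre-crop larger axes; zero-pad smaller ones symmetrically."""
    out = arr
    for axis in (0, 1):
        n = out.shape[axis]
        if n > target:
            start = (n - target) // 2
            sl = [slice(None), slice(None)]
            sl[axis] = slice(start, start + target)
            out = out[tuple(sl)]
        elif n < target:
            before = (target - n) // 2
            after = target - n - before
            pad = [(0, 0), (0, 0)]
            pad[axis] = (before, after)
            out = np.pad(out, pad, mode="constant")
    return out


def standardise(image: CCMImage,
                target_pixel_um: float = TARGET_PIXEL_UM,
                target_size_px: int = TARGET_SIZE_PX) -> CCMImage:
    """Resample an image to the working pitch and frame.

    The pitch wins over the frame: the raster is bilinearly resampled to
    ``target_pixel_um`` on both axes (preserving the physical extent to within
    one pixel), then centre-cropped or zero-padded to a
    ``target_size_px`` square.  Images already conformant are returned
    unchanged.
    """
    if image.pixel_size_um is None:
        raise ValueError(
            "pixel size unknown; supply field_of_view_um when loading the image")
    ry, rx = image.pixel_size_um
    conformant = (abs(ry - target_pixel_um) < 1e-9 and abs(rx - target_pixel_um) < 1e-9
                  and image.pixels.shape == (target_size_px, target_size_px))
    if conformant:
        return image
    new_h = int(round(image.height_px * ry / target_pixel_um))
    new_w = int(round(image.width_px * rx / target_pixel_um))
    if new_h < 1 or new_w < 1:
        raise ValueError("target pitch coarser than the whole image")
    if (new_h, new_w) != image.pixels.shape:
        resampled = resize(image.pixels, (new_h, new_w), order=1, mode="edge",
                           anti_aliasing=False, preserve_range=True)
    else:
        resampled = image.pixels
    framed = _crop_pad_centre(np.clip(resampled, 0.0, 1.0), target_size_px)
    return CCMImage(pixels=framed,
                    pixel_size_um=(target_pixel_um, target_pixel_um),
                    source_id=image.source_id)


def save_image(image: CCMImage, path: str | os.PathLike) -> None:
    """Write an image as 8-bit greyscale (format from the extension)."""
    arr = np.clip(np.round(image.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(os.fspath(path))


def save_mask(mask: AnnotationMask | np.ndarray, path: str | os.PathLike) -> None:
    """Write a binary mask as a 0/255 8-bit file."""
    pixels = mask.pixels if isinstance(mask, AnnotationMask) else np.asarray(mask)
    arr = (pixels.astype(bool).astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(os.fspath(path))
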