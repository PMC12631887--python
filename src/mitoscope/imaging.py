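"""Image I/O, segmentation, and per-object rendering.

Conventions used throughout the package:

* coordinates are 0-based ``(row, col)``, row increasing downward;
* connected components are labeled under 8-connectivity by default
  (diagonal neighbors connect), configurable to 4;
* labels in a :class:`LabeledMask` are consecutive integers ``1..N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage import measure

Channel = str  # viscosity | ROS | MMP-aggregate | MMP-monomer | generic

_CONNECTIVITY_STRUCTS = {
    4: ndi.generate_binary_structure(2, 1),
    8: ndi.generate_binary_structure(2, 2),
}


@dataclass
class ImageFrame:
    """One 2D intensity channel with pixel-size metadata.

    Parameters
    ----------
    pixels
        2D array of non-negative intensities.
    pixel_size_um
        Physical edge length of one pixel in micrometres.  The default of
        0.05 um matches super-resolution (SIM-scale) sampling.
    channel
        Biomarker tag: ``viscosity``, ``ROS``, ``MMP-aggregate``,
        ``MMP-monomer`` or ``generic``.
    frame_index
        Position in a time-lapse stack (0 for still images).
    """

    pixels: np.ndarray
    pixel_size_um: float = 0.05
    channel: Channel = "generic"
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("ImageFrame requires a non-empty 2D array")
        if np.issubdtype(self.pixels.dtype, np.integer) and self.pixels.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def bit_depth(self) -> int:
        if self.pixels.dtype == np.uint8:
            return 8
        if self.pixels.dtype == np.uint16:
            return 16
        return self.pixels.dtype.itemsize * 8


@dataclass
class LabeledMask:
    """Integer-labeled segmentation; 0 is background, labels run 1..N."""

    labels: np.ndarray
    connectivity: int = 8

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2D")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("negative labels are not allowed")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def object_mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class ColorMapSpec:
    """Piecewise-linear pseudo-color map over the 8-bit intensity range.

    ``anchors`` is an ordered list of ``(scalar, (r, g, b))`` pairs with
    strictly increasing scalars spanning [0, 255].  The default ramp is
    blue -> green -> yellow -> red at 0/85/170/255.
    """

    anchors: list[tuple[float, tuple[int, int, int]]] = field(
        default_factory=lambda: [
            (0.0, (0, 0, 255)),
            (85.0, (0, 255, 0)),
            (170.0, (255, 255, 0)),
            (255.0, (255, 0, 0)),
        ]
    )

    def __post_init__(self) -> None:
        scalars = [a[0] for a in self.anchors]
        if len(scalars) < 2 or any(b <= a for a, b in zip(scalars, scalars[1:])):
            raise ValueError("anchor scalars must be strictly increasing (>= 2 anchors)")
        if scalars[0] > 0 or scalars[-1] < 255:
            raise ValueError("anchors must span [0, 255]")

    def color_for(self, value: float) -> tuple[int, int, int]:
        """Interpolate ``value`` between anchors; round half up to int RGB."""
        scalars = np.array([a[0] for a in self.anchors], dtype=float)
        rgbs = np.array([a[1] for a in self.anchors], dtype=float)
        rgb = [np.interp(value, scalars, rgbs[:, c]) for c in range(3)]
        return tuple(int(np.floor(v + 0.5)) for v in rgb)


# ---------------------------------------------------------------------------
# I/O


def read_stack(path: str | Path) -> list[ImageFrame]:
    """Read a (multi-page) TIFF into a list of frames with frame indices."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # tifffile raises various types on corrupt input
        raise ValueError(f"not a readable TIFF image: {path}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"unsupported TIFF layout with shape {pages.shape}")
    return [ImageFrame(pages[i], frame_index=i) for i in range(pages.shape[0])]


def write_image(data: ImageFrame | np.ndarray, path: str | Path) -> Path:
    """Write a frame, mask array, or RGB render to TIFF/PNG by extension."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    pixels = data.pixels if isinstance(data, ImageFrame) else np.asarray(data)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, pixels)
    return path


def write_stack(frames: list[np.ndarray], path: str | Path) -> Path:
    """Write a list of same-shaped 2D arrays as a multi-page TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.stack(frames), photometric="minisblack")
    return path


# ---------------------------------------------------------------------------
# Conversion and segmentation


def to_8bit(frame: ImageFrame) -> ImageFrame:
    """Linearly rescale a frame to the 8-bit range [0, 255].

    Per-image min-max scaling; a constant image maps to all zeros.
    """
    pixels = frame.pixels.astype(float)
    lo, hi = pixels.min(), pixels.max()
    if hi == lo:
        out = np.zeros_like(pixels, dtype=np.uint8)
    else:
        out = np.floor((pixels - lo) / (hi - lo) * 255 + 0.5).astype(np.uint8)
    return ImageFrame(out, frame.pixel_size_um, frame.channel, frame.frame_index)


def segment_by_threshold(
    frame: ImageFrame, threshold: int = 127, connectivity: int = 8
) -> LabeledMask:
    """Threshold an 8-bit frame (strictly ``> threshold``) and label components."""
    if frame.pixels.dtype != np.uint8:
        raise ValueError("segment_by_threshold expects an 8-bit frame; use to_8bit first")
    fg = frame.pixels > threshold
    labels = measure.label(fg, connectivity=2 if connectivity == 8 else 1)
    return LabeledMask(labels.astype(np.int32), connectivity=connectivity)


def ingest_mask(
    mask: np.ndarray | str | Path, connectivity: int = 8
) -> LabeledMask:
    """Accept a binary or integer-labeled mask (array or image file).

    Output of an external segmenter (e.g. a deep-learning model) drops in
    here in place of the built-in threshold segmenter.  Binary input is
    component-labeled; labeled input is compacted to consecutive labels,
    and any label whose pixels form several connected components is split.
    """
    if isinstance(mask, (str, Path)):
        mask = read_stack(mask)[0].pixels
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    if mask.min() < 0:
        raise ValueError("negative labels are not a valid mask encoding")
    struct = _CONNECTIVITY_STRUCTS[connectivity]
    uniq = np.unique(mask)
    uniq = uniq[uniq > 0]
    if uniq.size <= 1 and (uniq.size == 0 or mask.max() == 1):
        labels, _ = ndi.label(mask > 0, structure=struct)
        return LabeledMask(labels.astype(np.int32), connectivity=connectivity)
    out = np.zeros(mask.shape, dtype=np.int32)
    next_label = 1
    for value in uniq:
        sub, n = ndi.label(mask == value, structure=struct)
        for k in range(1, n + 1):
            out[sub == k] = next_label
            next_label += 1
    return LabeledMask(out, connectivity=connectivity)


# ---------------------------------------------------------------------------
# Renderers


def render_pseudocolor(
    mask: LabeledMask, intensity: ImageFrame, cmap: ColorMapSpec | None = None
) -> np.ndarray:
    """Paint each object a single color keyed to its mean 8-bit intensity.

    The mean grayscale intensity of every labeled region is interpolated
    between the color-map anchors; background stays black.  Renders are
    deterministic and byte-identical across runs.
    """
    if mask.labels.shape != intensity.shape:
        raise ValueError("mask and intensity frame must share dimensions")
    cmap = cmap or ColorMapSpec()
    gray = intensity if intensity.pixels.dtype == np.uint8 else to_8bit(intensity)
    out = np.zeros(mask.labels.shape + (3,), dtype=np.uint8)
    for label in range(1, mask.n_objects + 1):
        obj = mask.labels == label
        if not obj.any():
            continue
        mean = float(gray.pixels[obj].mean())
        out[obj] = cmap.color_for(mean)
    return out


def overlay_skeleton(raw: ImageFrame, skeleton: np.ndarray) -> np.ndarray:
    """Superimpose a 3x3-dilated skeleton in pure red over the grayscale raw."""
    skeleton = np.asarray(skeleton).astype(bool)
    if raw.shape != skeleton.shape:
        raise ValueError("raw frame and skeleton must share dimensions")
    gray = to_8bit(raw).pixels if raw.pixels.dtype != np.uint8 else raw.pixels
    rgb = np.stack([gray] * 3, axis=-1)
    dilated = ndi.binary_dilation(skeleton, structure=np.ones((3, 3), bool))
    rgb[dilated] = (255, 0, 0)
    return rgb


#: Morphotype outline colors: network orange, rod blue, dot green.
DEFAULT_PALETTE = {
    "network": (255, 165, 0),
    "rod": (0, 0, 255),
    "dot": (0, 255, 0),
}


def object_boundaries(mask: LabeledMask) -> np.ndarray:
    """Boundary pixels: foreground with at least one background 4-neighbor."""
    labels = mask.labels
    fg = labels > 0
    padded = np.pad(fg, 1, constant_values=False)
    has_bg_neighbor = ~(
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return fg & has_bg_neighbor


def outline_by_morphotype(
    mask: LabeledMask,
    classes: dict[int, str],
    palette: dict[str, tuple[int, int, int]] | None = None,
    base: np.ndarray | None = None,
) -> np.ndarray:
    """Draw each object's 1-px contour in its morphotype color."""
    palette = palette or DEFAULT_PALETTE
    missing = [lb for lb in range(1, mask.n_objects + 1) if lb not in classes]
    if missing:
        raise KeyError(f"no class assigned for labels {missing}")
    if base is None:
        out = np.zeros(mask.labels.shape + (3,), dtype=np.uint8)
    else:
        out = np.array(base, dtype=np.uint8, copy=True)
        if out.ndim == 2:
            out = np.stack([out] * 3, axis=-1)
    boundary = object_boundaries(mask)
    for label in range(1, mask.n_objects + 1):
        edge = boundary & (mask.labels == label)
        out[edge] = palette[classes[label]]
    return out
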