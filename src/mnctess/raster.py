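"""Grayscale image containers and gradient-orientation fields.

The tessellation pipeline starts from a 2D scalar image ``img(x, y)``
(``x`` = column, ``y`` = row, both 0-based, origin at the top-left).  Every
downstream step is driven by the intensity gradient: at each pixel we
estimate ``Gx = d img/dx`` and ``Gy = d img/dy`` and the gradient
orientation (GO) angle

    theta = arctan(Gy / Gx)

folded into the half-open range [-90, 90) degrees.  The orientation is a
*line* direction (a gradient and its negation describe the same local edge
orientation), which is why the 180-degree range suffices.  Pixels where the
gradient vanishes exactly carry no orientation and are flagged undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ScalarImage2D",
    "GradientField",
    "load_image",
    "compute_gradient",
    "fold_angle",
]

#: Rec.601 luma weights used to collapse RGB input to one channel.
_LUMA_601 = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ScalarImage2D:
    """A single-channel raster image with finite real intensities.

    ``values`` is indexed ``[row, col]`` i.e. ``[y, x]``; ``width`` is the
    number of columns and ``height`` the number of rows.
    """

    values: np.ndarray
    source: str = "<array>"
    slice_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2D array, got shape {arr.shape}")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(f"image must be at least 2x2, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite intensities")
        object.__setattr__(self, "values", arr)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GradientField:
    """Per-pixel gradient components and folded orientation angles.

    ``theta`` is in degrees in [-90, 90) wherever ``defined`` is True and
    NaN elsewhere; ``defined`` is False exactly where ``gx == gy == 0``.
    """

    gx: np.ndarray
    gy: np.ndarray
    theta: np.ndarray
    defined: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.gx, self.gy)

    @property
    def shape(self) -> tuple[int, int]:
        return self.gx.shape


def fold_angle(theta_deg):
    """Fold an angle in degrees into the half-open range [-90, 90).

    Orientations are line-like (period 180 degrees), so folding identifies
    theta with theta + 180.
    """
    return (np.asarray(theta_deg, dtype=float) + 90.0) % 180.0 - 90.0


def load_image(
    path: str | Path,
    *,
    axis: int = 2,
    index: int | None = None,
    time: int | None = None,
    rgb: str = "luminance",
) -> ScalarImage2D:
    """Load a 2D grayscale image from PNG/TIFF or a slice of a NIfTI volume.

    Parameters
    ----------
    path
        Image file.  ``.nii``/``.nii.gz`` are read with nibabel; anything
        else is decoded with Pillow.
    axis, index, time
        For NIfTI volumes: ``axis`` selects the slicing axis (0, 1 or 2 of
        the spatial axes; default 2 = z), ``index`` the slice along it, and
        ``time`` the volume for 4D files.  Both ``index`` and (for 4D)
        ``time`` must be given explicitly; there is no default slab.
    rgb
        How to reduce multi-band raster input: ``"luminance"`` applies
        Rec.601 weights; any other value raises on multi-band files.

    Returns
    -------
    ScalarImage2D with the source path and slice indices recorded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return _load_nifti_slice(path, axis=axis, index=index, time=time)
    return _load_raster(path, rgb=rgb)


def _load_raster(path: Path, *, rgb: str) -> ScalarImage2D:
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im, dtype=float)
    if arr.ndim == 2:
        values = arr
    elif arr.ndim == 3:
        if rgb != "luminance":
            raise ValueError(
                f"{path} has {arr.shape[2]} bands; pass rgb='luminance' to reduce"
            )
        values = arr[:, :, :3] @ _LUMA_601
    else:
        raise ValueError(f"{path}: unsupported raster dimensionality {arr.ndim}")
    return ScalarImage2D(values, source=str(path))


def _load_nifti_slice(
    path: Path, *, axis: int, index: int | None, time: int | None
) -> ScalarImage2D:
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
    if vol.ndim == 4:
        if time is None:
            raise ValueError(f"{path} is 4D; a --time index is required")
        if not 0 <= time < vol.shape[3]:
            raise IndexError(f"time index {time} out of range for {vol.shape}")
        vol = vol[..., time]
    elif vol.ndim != 3:
        raise ValueError(f"{path}: expected a 3D/4D NIfTI, got {vol.ndim}D")
    if not 0 <= axis <= 2:
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    if index is None:
        raise ValueError(f"{path} is a volume; a --slice index is required")
    if not 0 <= index < vol.shape[axis]:
        raise IndexError(f"slice index {index} out of range for {vol.shape}")
    slab = np.take(vol, index, axis=axis)
    # nibabel data axes are (i, j, k); present the slab as rows x cols.
    return ScalarImage2D(
        slab.T,
        source=str(path),
        slice_info={"axis": axis, "index": index, "time": time},
    )


def compute_gradient(img: ScalarImage2D) -> GradientField:
    """Estimate Gx, Gy and the folded orientation angle at every pixel.

    Central differences on interior pixels, one-sided differences at the
    borders (``np.gradient`` convention).  theta is the two-argument
    arctangent of (Gy, Gx) folded into [-90, 90), which coincides with
    arctan(Gy/Gx) wherever Gx != 0 and extends it continuously to the
    vertical-gradient limit.  Pixels with a exactly-zero gradient vector
    have no orientation: theta is NaN and ``defined`` is False there.
    """
    # np.gradient axis 0 is y (rows), axis 1 is x (cols)
    gy, gx = np.gradient(img.values)
    defined = ~((gx == 0.0) & (gy == 0.0))
    theta = np.full(img.values.shape, np.nan)
    ang = np.degrees(np.arctan2(gy[defined], gx[defined]))
    theta[defined] = fold_angle(ang)
    return GradientField(gx=gx, gy=gy, theta=theta, defined=defined)
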