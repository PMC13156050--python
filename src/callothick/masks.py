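"""Binary midsagittal masks: container, analytic fixtures, and I/O.

A :class:`MaskGrid` is a 2-D binary image of the corpus callosum on the
midsagittal plane together with its (isotropic) pixel size in mm and a flag
saying which image direction is anterior.  Masks can be loaded from PNG,
single-slice NIfTI, or a plain-text 0/1 grid whose first line carries the
pixel size; two analytic generators (a horizontal band and a half-annulus
arch) provide shapes whose true cross-sectional thickness is known exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "MaskGrid",
    "make_band_mask",
    "make_arch_mask",
    "load_mask",
    "save_mask_png",
    "save_mask_text",
]

#: margin (pixels) of background kept around the foreground on every side
MARGIN = 2


@dataclass
class MaskGrid:
    """2-D binary midsagittal mask with physical pixel size.

    Parameters
    ----------
    grid : ndarray of bool, shape (rows, cols)
        Foreground is True.  Rows increase inferiorly (image convention).
    pixel_mm : float
        Isotropic pixel edge length in mm.
    anterior : {"right", "left"}
        Image direction of the anterior (rostral) end of the structure.
    """

    grid: np.ndarray
    pixel_mm: float
    anterior: str = "right"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be positive")
        if self.anterior not in ("right", "left"):
            raise ValueError("anterior must be 'right' or 'left'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def n_foreground(self) -> int:
        return int(self.grid.sum())

    def mirrored(self) -> "MaskGrid":
        """Left-right mirrored copy (anterior flag flipped accordingly)."""
        flipped = "left" if self.anterior == "right" else "right"
        return MaskGrid(self.grid[:, ::-1].copy(), self.pixel_mm, flipped)


def _with_margin(fg: np.ndarray) -> np.ndarray:
    """Crop to the foreground bounding box and pad MARGIN background pixels."""
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    core = fg[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    return np.pad(core, MARGIN)


def make_band_mask(height_mm: float, width_mm: float, pixel_mm: float) -> MaskGrid:
    """Solid horizontal rectangle; true thickness everywhere = ``height_mm``.

    The band is the simplest analytic fixture for the Laplace thickness
    solver: streamlines are vertical and all have length ``height_mm``.
    """
    if height_mm <= 0 or width_mm <= 0 or pixel_mm <= 0:
        raise ValueError("band dimensions and pixel size must be positive")
    h = round(height_mm / pixel_mm)
    w = round(width_mm / pixel_mm)
    if h < 8 or w < 8:
        raise ValueError(
            f"band must span >= 8 pixels in each direction (got {h} x {w})"
        )
    fg = np.ones((h, w), dtype=bool)
    return MaskGrid(_with_margin(fg), pixel_mm)


def make_arch_mask(
    inner_radius_mm: float,
    outer_radius_mm: float,
    pixel_mm: float,
    angular_extent: float = np.pi,
) -> MaskGrid:
    """Half-annulus opening downward, mimicking the callosal arch.

    Both ends sit at the bottom, like the splenium and genu on a midsagittal
    slice.  By radial symmetry of the harmonic potential between the two
    arcs, the true streamline thickness is ``outer_radius_mm -
    inner_radius_mm`` at every node.
    """
    if inner_radius_mm <= 0 or outer_radius_mm <= inner_radius_mm:
        raise ValueError("need outer_radius > inner_radius > 0")
    if pixel_mm <= 0:
        raise ValueError("pixel_mm must be positive")
    if not 0 < angular_extent <= np.pi:
        raise ValueError("angular_extent must be in (0, pi]")

    r2 = outer_radius_mm / pixel_mm
    r1 = inner_radius_mm / pixel_mm
    n = int(np.ceil(2 * r2)) + 2
    # pixel centres; y measured upward from the annulus centre at the bottom row
    cols = np.arange(n) - (n - 1) / 2.0
    rows = np.arange(n)
    y = (n - 1) - rows  # y >= 0 is the upper half-plane
    xx, yy = np.meshgrid(cols, y)
    rr = np.hypot(xx, yy)
    theta = np.arctan2(yy, xx)  # in [0, pi] for the upper half-plane
    half = angular_extent / 2.0
    in_sector = np.abs(theta - np.pi / 2.0) <= half + 1e-12
    fg = (rr >= r1) & (rr <= r2) & (yy >= 0) & in_sector
    if not fg.any():
        raise ValueError("arch mask came out empty; check dimensions")
    return MaskGrid(_with_margin(fg), pixel_mm)


# ---------------------------------------------------------------------------
# I/O


def _cleanup(fg: np.ndarray) -> np.ndarray:
    """Keep the largest 4-connected component and fill interior holes."""
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    labels, n = ndimage.label(fg, structure=structure)
    if n == 0:
        raise ValueError("mask has no foreground pixels")
    sizes = ndimage.sum_labels(np.ones_like(fg, dtype=int), labels, range(1, n + 1))
    largest = sizes.max()
    winners = np.flatnonzero(sizes == largest)
    if len(winners) > 1:
        raise ValueError(
            f"mask has {len(winners)} equally largest components "
            f"({int(largest)} px each); cannot choose one"
        )
    fg = labels == winners[0] + 1
    fg = ndimage.binary_fill_holes(fg)
    return _with_margin(fg)


def load_mask(
    path: str | Path, pixel_mm: float | None = None, anterior: str = "right"
) -> MaskGrid:
    """Load a mask from PNG, single-slice NIfTI, or text grid.

    Values > 0 are foreground.  The largest 4-connected component is kept,
    interior holes are filled, and a 2-pixel background margin is enforced.
    For NIfTI, the pixel size is read from the header when ``pixel_mm`` is
    not given; the text format carries it on its header line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.squeeze(np.asanyarray(img.dataobj))
        if data.ndim != 2:
            raise ValueError(f"expected a single-slice NIfTI, got shape {data.shape}")
        if pixel_mm is None:
            zooms = [z for z, s in zip(img.header.get_zooms(), img.shape) if s > 1]
            zooms = zooms or list(img.header.get_zooms()[:2])
            if not np.allclose(zooms, zooms[0], rtol=1e-3):
                raise ValueError(f"anisotropic pixels {zooms}; pass pixel_mm explicitly")
            pixel_mm = float(zooms[0])
        fg = data > 0
    elif suffixes.endswith(".png"):
        import imageio.v3 as iio

        data = np.asarray(iio.imread(path))
        if data.ndim == 3:
            data = data[..., :3].max(axis=-1)
        if pixel_mm is None:
            raise ValueError("pixel_mm is required for PNG masks")
        fg = data > 0
    else:  # plain-text 0/1 grid
        text = path.read_text().splitlines()
        if not text:
            raise ValueError(f"{path} is empty")
        header = text[0]
        m = re.search(r"pixel_mm\s*=\s*([0-9.eE+-]+)", header)
        if m:
            file_px = float(m.group(1))
            pixel_mm = file_px if pixel_mm is None else pixel_mm
            rows = text[1:]
            ma = re.search(r"anterior\s*=\s*(left|right)", header)
            if ma:
                anterior = ma.group(1)
        else:
            rows = text
        if pixel_mm is None:
            raise ValueError("pixel_mm missing from header and not provided")
        fg = np.array(
            [[int(ch) for ch in line.split()] for line in rows if line.strip()]
        ) > 0
    if not fg.any():
        raise ValueError(f"{path}: mask has no foreground pixels")
    return MaskGrid(_cleanup(fg), float(pixel_mm), anterior)


def save_mask_png(mask: MaskGrid, path: str | Path) -> None:
    """Write the mask as an 8-bit PNG (foreground 255, background 0)."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (mask.grid.astype(np.uint8) * 255))


def save_mask_text(mask: MaskGrid, path: str | Path) -> None:
    """Write the mask as a 0/1 text grid with a pixel-size header line."""
    lines = [f"# pixel_mm={mask.pixel_mm:g} anterior={mask.anterior}"]
    for row in mask.grid.astype(int):
        lines.append(" ".join(str(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")
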