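"""Per-slice classification maps distinguishing TP/TN/FP/FN pixels.

After pixel-wise prediction the estimated class of every foreground
pixel is folded back to image coordinates and coded against the slice's
true class: slices of the positive (cooking) class contain TP/FN pixels,
negative (frying) slices contain TN/FP pixels.  Rendering writes a PNG
with a small legend strip; bytes are deterministic for a fixed palette.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
from PIL import Image

from .cube_io import fold
from .errors import ParameterError

__all__ = [
    "CODE_BACKGROUND",
    "CODE_TP",
    "CODE_TN",
    "CODE_FP",
    "CODE_FN",
    "DEFAULT_PALETTE",
    "CategoryImage",
    "categorize",
    "render",
]

CODE_BACKGROUND = 0
CODE_TP = 1
CODE_TN = 2
CODE_FP = 3
CODE_FN = 4

_CODE_NAMES = {
    CODE_BACKGROUND: "background",
    CODE_TP: "TP",
    CODE_TN: "TN",
    CODE_FP: "FP",
    CODE_FN: "FN",
}

#: TP dark green, TN dark blue, FP light green, FN yellow; background black.
DEFAULT_PALETTE = {
    CODE_BACKGROUND: (0, 0, 0),
    CODE_TP: (0, 100, 0),
    CODE_TN: (0, 0, 139),
    CODE_FP: (144, 238, 144),
    CODE_FN: (255, 255, 0),
}


@dataclasses.dataclass
class CategoryImage:
    """Coded raster {background, TP, TN, FP, FN} plus per-code counts."""

    data: np.ndarray
    counts: dict[str, int]
    sample_id: str | None = None

    def write_counts(self, path: str | pathlib.Path) -> None:
        payload = {"sample_id": self.sample_id, "counts": self.counts}
        pathlib.Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def categorize(
    pred_labels,
    true_label,
    coords: np.ndarray,
    shape: tuple[int, int],
    positive_class,
    sample_id: str | None = None,
) -> CategoryImage:
    """Code each pixel of a single-class slice as TP/FN or TN/FP.

    ``true_label`` is the slice's class; pixels of a positive-class slice
    are TP where predicted positive and FN otherwise, and symmetrically
    for negative-class slices.
    """
    pred_labels = np.asarray(pred_labels)
    coords = np.asarray(coords, dtype=int)
    if len(pred_labels) != len(coords):
        raise ParameterError(
            f"{len(pred_labels)} predictions for {len(coords)} coordinates"
        )
    pred_pos = pred_labels == positive_class
    if true_label == positive_class:
        codes = np.where(pred_pos, CODE_TP, CODE_FN).astype(np.uint8)
    else:
        codes = np.where(pred_pos, CODE_FP, CODE_TN).astype(np.uint8)
    image = fold(codes, coords, shape, background_value=np.uint8(CODE_BACKGROUND))
    counts = {
        name: int(np.sum(image == code)) for code, name in _CODE_NAMES.items()
    }
    return CategoryImage(image, counts, sample_id)


def render(
    category_image: CategoryImage,
    path: str | pathlib.Path,
    palette: dict[int, tuple[int, int, int]] | None = None,
    legend_height: int = 10,
) -> pathlib.Path:
    """Write the category image as an RGB PNG with a legend strip.

    The legend is a bottom strip of equal-width blocks in code order
    (background, TP, TN, FP, FN).  Output bytes depend only on the input
    raster and palette.
    """
    palette = DEFAULT_PALETTE if palette is None else palette
    data = np.asarray(category_image.data)
    unknown = set(np.unique(data)) - set(palette)
    if unknown:
        raise ParameterError(f"codes without palette entry: {sorted(unknown)}")
    lut = np.zeros((max(palette) + 1, 3), dtype=np.uint8)
    for code, rgb in palette.items():
        lut[code] = rgb
    rgb = lut[data]
    rows, cols = data.shape
    legend = np.zeros((legend_height, cols, 3), dtype=np.uint8)
    codes = sorted(palette)
    block = max(cols // len(codes), 1)
    for i, code in enumerate(codes):
        legend[:, i * block : (i + 1) * block if i < len(codes) - 1 else cols] = lut[code]
    canvas = np.concatenate([rgb, legend], axis=0)
    out = pathlib.Path(path)
    Image.fromarray(canvas, mode="RGB").save(out, format="PNG")
    return out
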