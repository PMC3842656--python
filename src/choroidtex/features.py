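"""Connected-component analysis and the 20-dimensional texture feature vector.

Each refined binary map L_Ki (one per structuring-element scale 3, 5, 7, 9,
11) is decomposed into 8-connected objects — candidate choroidal vessels and
shadow structures.  Four summary statistics per scale give the fixed-order
feature vector fed to the classifier:

    w(1)..w(5)    number of objects per scale
    w(6)..w(10)   mean object centroid x (column) per scale
    w(11)..w(15)  mean object centroid y (row) per scale
    w(16)..w(20)  population std of the per-object mean brightness per scale

Brightness is sampled from the brightness-corrected grey image at object
pixels.  A scale with zero objects contributes 0 for its centroid and std
entries (the classifier needs complete vectors); a single object has std 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .morphology import CorrectedChoroid, ScaleStack

__all__ = ["ObjectSet", "FEATURE_NAMES", "N_FEATURES", "label_objects", "extract_features"]

N_FEATURES = 20
FEATURE_NAMES: tuple[str, ...] = tuple(f"w{k}" for k in range(1, N_FEATURES + 1))

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class ObjectSet:
    """Objects of one binary map: label image plus per-object statistics.

    ``centroids_x`` / ``centroids_y`` are arithmetic means of member column /
    row coordinates; ``mean_brightness`` is the mean of the corrected grey
    image over member pixels.  Objects touching the border are retained.
    """

    labels: np.ndarray
    count: int
    centroids_x: np.ndarray
    centroids_y: np.ndarray
    mean_brightness: np.ndarray


def label_objects(binary: np.ndarray, grey: np.ndarray | None = None) -> ObjectSet:
    """8-connected component labelling with centroids and mean brightness."""
    binary = np.asarray(binary)
    if not np.isin(binary, (0, 1)).all():
        raise ValueError("label_objects expects a binary image")
    labels, count = ndimage.label(binary, structure=_EIGHT_CONN)
    if count == 0:
        empty = np.empty(0, dtype=np.float64)
        return ObjectSet(labels, 0, empty, empty.copy(), empty.copy())
    index = np.arange(1, count + 1)
    cy, cx = zip(*ndimage.center_of_mass(binary, labels, index))
    if grey is None:
        brightness = np.zeros(count, dtype=np.float64)
    else:
        grey = np.asarray(grey, dtype=np.float64)
        if grey.shape != binary.shape:
            raise ValueError("grey image shape mismatch")
        brightness = ndimage.mean(grey, labels, index)
    return ObjectSet(labels, int(count), np.asarray(cx, dtype=np.float64),
                     np.asarray(cy, dtype=np.float64),
                     np.asarray(brightness, dtype=np.float64))


def extract_features(stack: ScaleStack, corrected: CorrectedChoroid | np.ndarray) -> np.ndarray:
    """The 20-element feature vector over the fixed scale order 3, 5, 7, 9, 11."""
    grey = corrected.pixels if isinstance(corrected, CorrectedChoroid) else np.asarray(corrected)
    scales = tuple(sorted(stack.scales))
    if len(scales) != 5:
        raise ValueError(f"expected 5 scales, got {scales}")
    w = np.zeros(N_FEATURES, dtype=np.float64)
    for k, size in enumerate(scales):
        if size not in stack.refined:
            raise ValueError(f"scale {size} missing from the stack")
        objs = label_objects(stack.refined[size], grey)
        w[k] = objs.count
        if objs.count > 0:
            w[5 + k] = objs.centroids_x.mean()
            w[10 + k] = objs.centroids_y.mean()
            # population std: dispersion of object brightness, 0 for one object
            w[15 + k] = objs.mean_brightness.std()
    return w
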