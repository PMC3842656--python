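"""Synthetic OCT B-scan phantoms with known RPE geometry and class structure.

No clinical scans ship with this package, so every downstream stage is
exercised on phantoms that encode exactly the qualitative markers of the
three choroidal imaging types and nothing else:

* a bright, smoothly curved RPE band over a darker choroid,
* dark elliptical vessel blobs in the choroid (dark on bright, because the
  binarization stage selects low-intensity pixels),
* **Z1** — vertical shadow bands under retinal lesions: column bands of the
  sub-RPE region are attenuated,
* **Z2** — global brightness reduction: all sub-RPE intensities are scaled
  by a dimming factor,
* **Z3** — uniform texture: vessel blobs of near-identical contrast placed
  at a common depth, low texture noise,
* salt-and-pepper noise applied last (independent per-pixel replacement with
  0 or 255, half the density each).

The generator defines the "true" RPE contour as the lower median row of the
constant-brightness RPE band, i.e. the row the cluster-median detector
recovers exactly on a noise-free phantom — which is what makes phantoms a
usable ground truth for the contour-recovery checks.

This is deliberately not a physical OCT model: no speckle statistics, no
depth attenuation, no A-scan simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import RPEContour

__all__ = [
    "PhantomSpec",
    "LabelledDataset",
    "default_spec",
    "generate_bscan",
    "generate_dataset",
]

CLASS_LABELS = ("Z1", "Z2", "Z3")

# grey-level layout: the RPE band must be the strict column maximum and the
# only region above 0.9 * max, so every other structure stays below
# 0.9 * 230 = 207 even after texture noise.
RPE_BRIGHTNESS = 230
RETINA_BRIGHTNESS = 100
CHOROID_BRIGHTNESS = 150
VESSEL_BRIGHTNESS = 80
NON_RPE_CEILING = 205


@dataclass
class PhantomSpec:
    """Full description of one synthetic B-scan.

    ``rpe_curve_coeffs`` are polynomial coefficients (highest power first,
    ``numpy.polyval`` convention) of the true RPE row as a function of the
    column; the curve must stay inside the image with room for the band.
    ``shadow_band_spec`` lists ``(column_centre, width, attenuation)``
    triples applied below the RPE (Z1); ``global_dimming_factor`` scales all
    sub-RPE intensities (Z2); ``texture_uniformity`` is the grey-level noise
    scale and ``vessel_contrast_jitter`` the per-vessel brightness spread
    (both small for Z3).
    """

    height: int = 256
    width: int = 1024
    rpe_curve_coeffs: tuple[float, ...] = (40.0,)
    rpe_brightness: int = RPE_BRIGHTNESS
    rpe_thickness: int = 4
    choroid_base_brightness: int = CHOROID_BRIGHTNESS
    retina_brightness: int = RETINA_BRIGHTNESS
    vessel_brightness: int = VESSEL_BRIGHTNESS
    vessel_count: int = 25
    vessel_radius_range: tuple[int, int] = (3, 8)   # objects stay under 20x20 px
    vessel_contrast_jitter: float = 18.0
    vessel_depth_spread: float = 1.0                # 1 = full choroid depth, Z3 small
    class_label: str = "Z3"
    shadow_band_spec: tuple[tuple[int, int, float], ...] = ()
    global_dimming_factor: float = 1.0
    texture_uniformity: float = 7.0
    sp_noise_density: float = 0.0
    seed: int = 0

    def true_contour(self) -> np.ndarray:
        """True RPE row per column: lower-median row of the band."""
        cols = np.arange(self.width)
        return np.rint(np.polyval(self.rpe_curve_coeffs, cols)).astype(np.intp)

    def validate(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")
        if not 0.0 < self.global_dimming_factor <= 1.0:
            raise ValueError("global_dimming_factor must be in (0, 1]")
        if not 0.0 <= self.sp_noise_density < 1.0:
            raise ValueError("sp_noise_density must be in [0, 1)")
        if self.vessel_radius_range[0] <= 0:
            raise ValueError("vessel radii must be positive")
        if 2 * self.vessel_radius_range[1] >= 20:
            raise ValueError("vessel objects must not exceed 20x20 pixels")
        contour = self.true_contour()
        t = self.rpe_thickness
        top = contour - (t - 1) // 2
        bottom = contour + t // 2
        if top.min() < 0 or bottom.max() > self.height - 1:
            raise ValueError(
                "RPE curve (with band thickness) leaves the image: rows "
                f"{top.min()}..{bottom.max()} outside [0, {self.height - 1}]")


@dataclass
class LabelledDataset:
    """Images with class labels, true contours and a stratified split."""

    images: list[np.ndarray]
    contours: list[RPEContour]
    labels: list[str]
    split_assignment: list[str]
    specs: list[PhantomSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, split: str) -> tuple[list[np.ndarray], list[str]]:
        idx = [i for i, s in enumerate(self.split_assignment) if s == split]
        return [self.images[i] for i in idx], [self.labels[i] for i in idx]


def generate_bscan(spec: PhantomSpec, return_meta: bool = False):
    """Render one phantom B-scan and its true RPE contour.

    Layer order: retina above the band, the constant-brightness RPE band,
    choroid with vessels below; then class effects (shadow bands, global
    dimming), then salt-and-pepper noise.  Identical spec + seed is
    bit-reproducible.  With ``return_meta`` a third dict is returned carrying
    the drawn vessel centres and grey levels (ground truth for texture
    statistics).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    contour = spec.true_contour()
    t = spec.rpe_thickness
    band_top = contour - (t - 1) // 2
    band_bottom = contour + t // 2          # inclusive

    img = np.empty((h, w), dtype=np.float64)
    rows = np.arange(h)[:, None]

    # retina and choroid backgrounds with smooth texture noise
    img[:] = spec.retina_brightness
    below = rows > band_bottom[None, :]
    img[below] = spec.choroid_base_brightness
    img += rng.normal(0.0, spec.texture_uniformity, size=(h, w))

    # dark elliptical vessel blobs in the choroid
    depth = h - 1 - (band_bottom.max() + 1)
    margin = spec.vessel_radius_range[1] + 2
    centre_depth = 0.45 * depth
    vessel_meta: list[dict] = []
    for _ in range(spec.vessel_count):
        cx = rng.integers(margin, w - margin)
        rel = rng.normal(centre_depth,
                         spec.vessel_depth_spread * 0.28 * depth)
        cy = int(np.clip(band_bottom[cx] + 1 + margin + rel,
                         band_bottom[cx] + 1 + margin, h - 1 - margin))
        ry = rng.integers(spec.vessel_radius_range[0], spec.vessel_radius_range[1] + 1)
        rx = rng.integers(spec.vessel_radius_range[0], spec.vessel_radius_range[1] + 1)
        level = spec.vessel_brightness + rng.normal(0.0, spec.vessel_contrast_jitter)
        yy, xx = np.mgrid[max(cy - ry, 0):min(cy + ry + 1, h),
                          max(cx - rx, 0):min(cx + rx + 1, w)]
        inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        inside &= yy > band_bottom[xx]      # vessels never overwrite the band
        img[yy[inside], xx[inside]] = level
        vessel_meta.append({"centre": (cy, cx), "radii": (int(ry), int(rx)),
                            "level": float(level)})

    # class-conditional effects on the sub-RPE region only
    sub_rpe = rows > band_bottom[None, :]
    for centre, width, attenuation in spec.shadow_band_spec:
        lo, hi = max(centre - width // 2, 0), min(centre + width // 2 + 1, w)
        cols_band = np.zeros(w, dtype=bool)
        cols_band[lo:hi] = True
        region = sub_rpe & cols_band[None, :]
        img[region] *= attenuation
    if spec.global_dimming_factor != 1.0:
        img[sub_rpe] *= spec.global_dimming_factor

    # everything but the band stays below the RPE-detection threshold
    img = np.clip(img, 0, NON_RPE_CEILING)
    in_band = (rows >= band_top[None, :]) & (rows <= band_bottom[None, :])
    img[in_band] = spec.rpe_brightness

    if spec.sp_noise_density > 0:
        u = rng.random((h, w))
        img[u < spec.sp_noise_density / 2] = 0
        img[(u >= spec.sp_noise_density / 2) & (u < spec.sp_noise_density)] = 255

    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = RPEContour(rows=contour)
    if return_meta:
        # class effects applied after vessel drawing also scale the levels
        for v in vessel_meta:
            cy, cx = v["centre"]
            for centre, width_b, attenuation in spec.shadow_band_spec:
                if abs(cx - centre) <= width_b // 2:
                    v["level"] *= attenuation
            v["level"] *= spec.global_dimming_factor
        return out, truth, {"vessels": vessel_meta}
    return out, truth


def default_spec(class_label: str, rng: np.random.Generator) -> PhantomSpec:
    """Draw a randomized per-image spec with the class's default markers.

    Per-image variation: a gentle random quadratic RPE curve, Poisson-spread
    vessel count, and randomized shadow-band placement for Z1.  Effect sizes
    are fixed design choices, not tuned per dataset.
    """
    width = 1024
    # gentle quadratic: apex row ~35-60, total sag a few pixels
    apex = rng.uniform(35, 60)
    curvature = rng.uniform(0.5e-5, 2.5e-5)
    centre = width / 2 + rng.uniform(-100, 100)
    coeffs = (curvature, -2 * curvature * centre,
              apex + curvature * centre ** 2)
    common = dict(rpe_curve_coeffs=coeffs,
                  vessel_count=int(rng.poisson(25)),
                  seed=int(rng.integers(2 ** 31)))
    if class_label == "Z1":
        n_bands = int(rng.integers(2, 5))
        centres = rng.choice(np.arange(80, width - 80), size=n_bands, replace=False)
        bands = tuple((int(c), int(rng.integers(70, 140)),
                       float(rng.uniform(0.45, 0.6))) for c in centres)
        return PhantomSpec(class_label="Z1", shadow_band_spec=bands, **common)
    if class_label == "Z2":
        return PhantomSpec(class_label="Z2",
                           global_dimming_factor=float(rng.uniform(0.55, 0.65)),
                           **common)
    if class_label == "Z3":
        return PhantomSpec(class_label="Z3", vessel_contrast_jitter=2.0,
                           vessel_depth_spread=0.15, texture_uniformity=3.0,
                           **common)
    raise ValueError(f"unknown class label {class_label!r}")


def _split_counts(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n items over the proportions."""
    raw = [n * p for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([-(r - np.floor(r)) for r in raw], kind="stable")
    for j in order[:remainder]:
        counts[j] += 1
    return counts


def generate_dataset(n_per_class: int,
                     split: tuple[float, float, float] = (0.6, 0.2, 0.2),
                     seed: int = 0,
                     sp_noise_density: float = 0.02,
                     classes: tuple[str, ...] = CLASS_LABELS) -> LabelledDataset:
    """Stratified labelled dataset of phantoms, reproducible under ``seed``.

    Each class contributes ``n_per_class`` images assigned to the
    learning/validation/test splits in the given proportions (60/20/20 by
    default, the study's group layout) by largest-remainder apportionment
    within each class, then shuffled.
    """
    if n_per_class < 5:
        raise ValueError("n_per_class must be >= 5")
    if not np.isclose(sum(split), 1.0):
        raise ValueError(f"split proportions must sum to 1, got {split}")
    rng = np.random.default_rng(seed)
    split_names = ("learning", "validation", "test")
    ds = LabelledDataset(images=[], contours=[], labels=[], split_assignment=[])
    for label in classes:
        counts = _split_counts(n_per_class, split)
        assignments = [name for name, c in zip(split_names, counts) for _ in range(c)]
        rng.shuffle(assignments)
        for assignment in assignments:
            spec = replace(default_spec(label, rng),
                           sp_noise_density=sp_noise_density)
            image, contour = generate_bscan(spec)
            ds.images.append(image)
            ds.contours.append(contour)
            ds.labels.append(label)
            ds.split_assignment.append(assignment)
            ds.specs.append(spec)
    return ds
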