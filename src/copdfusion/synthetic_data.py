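"""Seeded synthetic paired-modality cohorts and annular airway phantoms.

The cohort generator emits network-ready 28x28 grayscale pairs (a CT-like
cross-section and an X-ray-like projection) whose class signal is split
across the two modalities:

* CT channel: class-1 subjects get a thicker bright annulus (wall
  thickening with a narrowed dark lumen), scaled by ``ct_effect``.
* X-ray channel: class-1 subjects get a global lucency shift scaled by
  ``xray_effect``.

A shared per-subject latent severity scales both channels so the modalities
are correlated but not redundant. With both effects at zero the two classes
are pixel-identical. The phantom generator provides closed-form ground truth
for the airway measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LabeledImagePair",
    "CohortSpec",
    "PhantomSpec",
    "generate_cohort",
    "generate_phantom",
    "split_cohort",
]

IMAGE_SIZE = 28


@dataclass
class LabeledImagePair:
    """One subject's paired-modality sample: CT-like image, X-ray-like image, label."""

    subject_id: str
    ct_image: np.ndarray  # (28, 28) float in [0, 1]
    xray_image: np.ndarray  # (28, 28) float in [0, 1]
    label: int  # 0 = healthy, 1 = diseased

    def __post_init__(self) -> None:
        self.ct_image = np.asarray(self.ct_image, dtype=np.float64)
        self.xray_image = np.asarray(self.xray_image, dtype=np.float64)
        for name, img in (("ct_image", self.ct_image), ("xray_image", self.xray_image)):
            if img.shape != (IMAGE_SIZE, IMAGE_SIZE):
                raise ValueError(f"{name} must be {IMAGE_SIZE}x{IMAGE_SIZE}, got {img.shape}")
            if not np.all(np.isfinite(img)) or img.min() < 0 or img.max() > 1:
                raise ValueError(f"{name} intensities must be finite and in [0, 1]")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class CohortSpec:
    n_subjects: int
    copd_fraction: float = 0.5
    ct_effect: float = 1.0
    xray_effect: float = 1.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not 0.0 < self.copd_fraction < 1.0:
            raise ValueError("copd_fraction must be in (0, 1)")
        if self.ct_effect < 0 or self.xray_effect < 0 or self.noise_sd < 0:
            raise ValueError("effects and noise_sd must be nonnegative")


@dataclass
class PhantomSpec:
    image_size: int = 64
    # lattice-point center: pixel-center counting of disc areas is closest to
    # the analytic value there (half-integer centers bias the count upward)
    center: tuple[float, float] | None = None
    lumen_radius: float = 8.0
    outer_radius: float = 12.0
    lumen_intensity: float = 0.1
    wall_intensity: float = 0.9
    background_intensity: float = 0.3
    noise_sd: float = 0.0
    pixel_size: float = 1.0  # mm per pixel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 1:
            raise ValueError("image_size must be positive")
        if self.center is None:
            self.center = (float(self.image_size // 2), float(self.image_size // 2))
        if not self.outer_radius > self.lumen_radius > 0:
            raise ValueError("need outer_radius > lumen_radius > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not (self.wall_intensity > self.background_intensity and self.wall_intensity > self.lumen_intensity):
            raise ValueError("wall must be the brightest compartment")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


# ---------------------------------------------------------------------------
# cohort generation

_CENTER = (IMAGE_SIZE - 1) / 2.0  # 13.5
_BASE_LUMEN_R = 4.5
_BASE_OUTER_R = 6.5


def _radial_distance(size: int, center: tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return np.hypot(yy - center[0], xx - center[1])


def _ct_pattern(wall_gain: float) -> np.ndarray:
    """Bright annulus on a dark background; wall thickens (and lumen narrows)
    with wall_gain."""
    d = _radial_distance(IMAGE_SIZE, (_CENTER, _CENTER))
    lumen_r = max(_BASE_LUMEN_R - 1.5 * wall_gain, 1.5)
    outer_r = min(_BASE_OUTER_R + 3.0 * wall_gain, 12.0)
    img = np.full((IMAGE_SIZE, IMAGE_SIZE), 0.30)
    img[d <= outer_r] = 0.70
    img[d <= lumen_r] = 0.10
    return img


def _xray_pattern(lucency: float) -> np.ndarray:
    """Soft-tissue-like base pattern with a global lucency shift."""
    d = _radial_distance(IMAGE_SIZE, (_CENTER, _CENTER))
    base = 0.55 - 0.25 * np.exp(-((d / 9.0) ** 2))
    return base + 0.35 * lucency


def generate_cohort(spec: CohortSpec) -> list[LabeledImagePair]:
    """Deterministic seeded cohort; class counts match ``copd_fraction`` to rounding."""
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n_subjects * spec.copd_fraction))
    n_pos = min(max(n_pos, 1), spec.n_subjects - 1)
    labels = np.array([1] * n_pos + [0] * (spec.n_subjects - n_pos))
    rng.shuffle(labels)

    pairs: list[LabeledImagePair] = []
    for i, label in enumerate(labels):
        severity = rng.uniform(0.5, 1.0)  # shared latent, applied on class 1 only
        s = severity if label == 1 else 0.0
        ct = _ct_pattern(spec.ct_effect * s)
        xray = _xray_pattern(spec.xray_effect * s)
        if spec.noise_sd > 0:
            ct = ct + rng.normal(0.0, spec.noise_sd, ct.shape)
            xray = xray + rng.normal(0.0, spec.noise_sd, xray.shape)
        else:
            # keep the RNG stream aligned across noise settings
            rng.normal(0.0, 1.0, ct.shape)
            rng.normal(0.0, 1.0, xray.shape)
        pairs.append(
            LabeledImagePair(
                subject_id=f"S{i:04d}",
                ct_image=np.clip(ct, 0.0, 1.0),
                xray_image=np.clip(xray, 0.0, 1.0),
                label=int(label),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# phantoms


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, dict[str, float]]:
    """Annular airway phantom plus analytic ground truth.

    Pixel intensity is assigned by compartment membership of the pixel center
    (lumen disc / wall annulus / background), then seeded Gaussian noise is
    added and the image clipped to [0, 1]. Ground truth (mm^2):

        true_LA = pi (r_lumen px)^2,  true_WA = pi (R^2 - r^2) px^2,
        true_WA_percent = 100 WA / (WA + LA).
    """
    d = _radial_distance(spec.image_size, spec.center)
    img = np.full((spec.image_size, spec.image_size), spec.background_intensity)
    img[d <= spec.outer_radius] = spec.wall_intensity
    img[d <= spec.lumen_radius] = spec.lumen_intensity
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = np.clip(img + rng.normal(0.0, spec.noise_sd, img.shape), 0.0, 1.0)

    r_mm = spec.lumen_radius * spec.pixel_size
    R_mm = spec.outer_radius * spec.pixel_size
    la = np.pi * r_mm**2
    wa = np.pi * (R_mm**2 - r_mm**2)
    truth = {
        "true_LA": la,
        "true_WA": wa,
        "true_WA_percent": 100.0 * wa / (wa + la),
    }
    return img, truth


# ---------------------------------------------------------------------------
# splitting


def split_cohort(
    dataset: list[LabeledImagePair], train_fraction: float, seed: int = 0
) -> tuple[list[LabeledImagePair], list[LabeledImagePair]]:
    """Stratified, seeded train/test split; disjoint, union equals the input.

    Per-class train counts are allocated by largest remainder so the total
    train size equals ``round(n * train_fraction)`` and the class ratio is
    preserved to within one subject.
    """
    if not dataset:
        raise ValueError("dataset must be nonempty")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    n_train_total = int(round(n * train_fraction))

    by_class: dict[int, list[int]] = {}
    for i, pair in enumerate(dataset):
        by_class.setdefault(pair.label, []).append(i)

    classes = sorted(by_class)
    ideal = {c: len(by_class[c]) * train_fraction for c in classes}
    counts = {c: int(np.floor(ideal[c])) for c in classes}
    leftover = n_train_total - sum(counts.values())
    for c in sorted(classes, key=lambda c: (ideal[c] - counts[c], len(by_class[c])), reverse=True):
        if leftover <= 0:
            break
        counts[c] += 1
        leftover -= 1

    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in classes:
        idx = np.array(by_class[c])
        perm = rng.permutation(len(idx))
        k = counts[c]
        if k == 0 or k == len(idx):
            raise ValueError(
                f"train_fraction {train_fraction} leaves class {c} absent from one split"
            )
        train_idx.extend(idx[perm[:k]])
        test_idx.extend(idx[perm[k:]])
    train_idx.sort()
    test_idx.sort()
    return [dataset[i] for i in train_idx], [dataset[i] for i in test_idx]
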