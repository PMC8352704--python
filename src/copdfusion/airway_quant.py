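"""Lumen-area (LA) and wall-area-percentage (WA%) quantification of 2-D airway
cross-sections.

Segmentation is threshold + connected-component topology: the lumen is the
largest dark component fully enclosed by bright wall pixels, the wall is the
enclosing bright component. Areas are pixel counts scaled by the squared
pixel size; WA% = 100 * WA / (WA + LA), the standard airway-CT convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["AirwayMeasurement", "segment_airway", "measure_airway", "compare_groups"]


@dataclass(frozen=True)
class AirwayMeasurement:
    LA: float  # lumen area, mm^2
    WA: float  # wall area, mm^2
    WA_percent: float  # 100 * WA / (WA + LA)
    lumen_diameter_equivalent: float  # 2 sqrt(LA / pi), mm
    wall_thickness_equivalent: float  # (outer equiv. diameter - lumen equiv. diameter) / 2, mm


class SegmentationError(ValueError):
    """No enclosed lumen found: the image is not an airway cross-section."""


def segment_airway(
    image: np.ndarray, lumen_threshold: float = 0.2, wall_threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Split an airway cross-section into disjoint lumen and wall masks.

    Convention: lumen dark (< lumen_threshold), wall bright (> wall_threshold).
    The lumen is the largest below-threshold component whose surrounding
    non-wall region does not reach the image border (i.e. it is enclosed by
    wall); the wall mask is the bright component enclosing it.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if lumen_threshold >= wall_threshold:
        raise ValueError("lumen_threshold must be below wall_threshold")

    wall_cand = image > wall_threshold
    # regions of non-wall; any region touching the border is outside the airway
    non_wall_labels, _ = ndimage.label(~wall_cand)
    border_labels = set(np.unique(non_wall_labels[0, :])) | set(np.unique(non_wall_labels[-1, :]))
    border_labels |= set(np.unique(non_wall_labels[:, 0])) | set(np.unique(non_wall_labels[:, -1]))
    border_labels.discard(0)

    lumen_labels, n_lumen = ndimage.label(image < lumen_threshold)
    best_label, best_size = 0, 0
    for lab in range(1, n_lumen + 1):
        comp = lumen_labels == lab
        enclosing = np.unique(non_wall_labels[comp])
        if any(e in border_labels or e == 0 for e in enclosing):
            continue  # reaches the border through non-wall pixels: not enclosed
        size = int(comp.sum())
        if size > best_size:
            best_label, best_size = lab, size
    if best_label == 0:
        raise SegmentationError("no enclosed lumen found (not an airway cross-section)")
    lumen_mask = lumen_labels == best_label

    # wall = the bright connected component adjacent to the lumen
    wall_labels, _ = ndimage.label(wall_cand)
    ring = ndimage.binary_dilation(lumen_mask) & wall_cand
    touching = np.unique(wall_labels[ring])
    touching = touching[touching != 0]
    if touching.size == 0:
        # enclosed through non-wall gap pixels but no bright wall adjacent
        # to the lumen: grow until the wall is reached
        grown = lumen_mask
        for _ in range(max(image.shape)):
            grown = ndimage.binary_dilation(grown)
            touching = np.unique(wall_labels[grown & wall_cand])
            touching = touching[touching != 0]
            if touching.size:
                break
        else:
            raise SegmentationError("no wall component found around the lumen")
    wall_mask = np.isin(wall_labels, touching)
    wall_mask &= ~lumen_mask
    return lumen_mask, wall_mask


def measure_airway(
    masks: tuple[np.ndarray, np.ndarray], pixel_size: float
) -> AirwayMeasurement:
    """Areas from mask pixel counts; pixel_size is mm per pixel."""
    lumen_mask, wall_mask = masks
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    n_lumen = int(np.count_nonzero(lumen_mask))
    n_wall = int(np.count_nonzero(wall_mask))
    if n_lumen == 0:
        raise ValueError("empty lumen mask")
    la = n_lumen * pixel_size**2
    wa = n_wall * pixel_size**2
    wa_percent = 100.0 * wa / (wa + la)
    d_lumen = 2.0 * np.sqrt(la / np.pi)
    d_outer = 2.0 * np.sqrt((la + wa) / np.pi)
    return AirwayMeasurement(
        LA=la,
        WA=wa,
        WA_percent=wa_percent,
        lumen_diameter_equivalent=d_lumen,
        wall_thickness_equivalent=(d_outer - d_lumen) / 2.0,
    )


def compare_groups(
    measurements: dict[str, Sequence[AirwayMeasurement]],
    level_tags: dict[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Descriptive per-group (and per-level, if tags given) summary table.

    Returns mean and sample standard deviation of LA, WA and WA% per group;
    sd is NaN for single-measurement groups. Level tags are opaque labels.
    """
    rows = []
    for group, ms in measurements.items():
        if not ms:
            raise ValueError(f"group {group!r} has no measurements")
        tags = level_tags.get(group) if level_tags else None
        if tags is not None and len(tags) != len(ms):
            raise ValueError("level_tags must match measurements in length")
        for i, m in enumerate(ms):
            rows.append(
                {
                    "group": group,
                    "level": tags[i] if tags is not None else "all",
                    "LA_mm2": m.LA,
                    "WA_mm2": m.WA,
                    "WA_percent": m.WA_percent,
                }
            )
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["group", "level"])
        .agg(
            n=("LA_mm2", "size"),
            LA_mean=("LA_mm2", "mean"),
            LA_sd=("LA_mm2", "std"),
            WA_mean=("WA_mm2", "mean"),
            WA_sd=("WA_mm2", "std"),
            WA_percent_mean=("WA_percent", "mean"),
            WA_percent_sd=("WA_percent", "std"),
        )
        .reset_index()
    )
    return summary
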