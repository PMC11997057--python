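"""Fluorescence-image quantification and clonogenic-survival normalization.

Corrected total cell fluorescence (CTCF) of a nucleus is

    CTCF = integrated density - area * mean background fluorescence

i.e. the summed intensity over the nuclear region minus the region area times
the mean of the background pixels; it is invariant to a constant intensity
offset and linear in the image.  Nuclei are segmented from the DNA channel by
Otsu thresholding, hole filling and connected components; the background
defaults to the non-nuclear complement eroded by a few pixels, emulating
manual background readings taken away from cells.

Clonogenic survival at a dose is the percentage change in colony formation
relative to matched untreated cells,

    % survival = 100 * (colonies_treated / cells_seeded_treated)
                     / (colonies_untreated / cells_seeded_untreated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure, segmentation

__all__ = [
    "NucleusMeasurement",
    "SurvivalPoint",
    "segment_nuclei",
    "default_background_mask",
    "measure_ctcf",
    "measure_image",
    "gamma_h2ax_gate",
    "gate_threshold_from_controls",
    "survival_fraction",
    "survival_table",
    "read_image",
]


@dataclass(frozen=True)
class NucleusMeasurement:
    nucleus_id: int
    area: int
    integrated_density: float
    background_mean: float
    ctcf: float
    channel: str = ""

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be positive")


@dataclass(frozen=True)
class SurvivalPoint:
    dose: float
    colonies_treated: int
    colonies_untreated: int
    cells_seeded_treated: int
    cells_seeded_untreated: int
    percent_survival: float

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")


def segment_nuclei(dna_channel: np.ndarray, min_area: int = 100) -> np.ndarray:
    """Label nuclei in a DNA-stain channel.

    Otsu threshold -> hole filling -> connected components; regions smaller
    than ``min_area`` pixels are discarded and the rest relabeled 1..K.
    A constant image yields zero regions.
    """
    img = np.asarray(dna_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=int)
    mask = img > filters.threshold_otsu(img)
    mask = ndi.binary_fill_holes(mask)
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_area)
    labels[np.isin(labels, small)] = 0
    labels, _, _ = segmentation.relabel_sequential(labels)
    return labels.astype(int)


def default_background_mask(labels: np.ndarray, erode: int = 5) -> np.ndarray:
    """Non-nuclear complement eroded by ``erode`` pixels."""
    bg = labels == 0
    if erode > 0:
        bg = ndi.binary_erosion(bg, iterations=erode, border_value=1)
    return bg


def measure_ctcf(
    channel: np.ndarray,
    region: np.ndarray,
    background_pixels: np.ndarray,
    nucleus_id: int = 1,
    channel_name: str = "",
) -> NucleusMeasurement:
    """CTCF of one region against a background pixel set.

    ``region`` and ``background_pixels`` are boolean masks; they must be
    non-empty and disjoint.  CTCF may legitimately come out negative (a region
    dimmer than the background) and is reported as-is.
    """
    channel = np.asarray(channel, dtype=float)
    region = np.asarray(region, dtype=bool)
    background_pixels = np.asarray(background_pixels, dtype=bool)
    if not region.any():
        raise ValueError("region is empty")
    if not background_pixels.any():
        raise ValueError("background pixel set is empty")
    if np.any(region & background_pixels):
        raise ValueError("region and background pixel sets overlap")
    area = int(region.sum())
    integrated = float(channel[region].sum())
    bg_mean = float(channel[background_pixels].mean())
    return NucleusMeasurement(
        nucleus_id=int(nucleus_id),
        area=area,
        integrated_density=integrated,
        background_mean=bg_mean,
        ctcf=integrated - area * bg_mean,
        channel=channel_name,
    )


def measure_image(
    channels: dict[str, np.ndarray],
    labels: np.ndarray,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-nucleus CTCF for every channel; one row per (nucleus, channel).

    ``background`` defaults to the eroded non-nuclear complement.
    """
    if background is None:
        background = default_background_mask(labels)
    rows = []
    for nid in range(1, int(labels.max()) + 1):
        region = labels == nid
        for name, img in channels.items():
            m = measure_ctcf(img, region, background, nucleus_id=nid, channel_name=name)
            rows.append(
                {
                    "nucleus_id": m.nucleus_id,
                    "channel": name,
                    "area": m.area,
                    "integrated_density": m.integrated_density,
                    "background_mean": m.background_mean,
                    "ctcf": m.ctcf,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["nucleus_id", "channel", "area", "integrated_density",
                 "background_mean", "ctcf"],
    )


def gamma_h2ax_gate(
    measurements: pd.DataFrame,
    gate_channel: str,
    threshold: float,
    irradiated: bool = False,
) -> pd.DataFrame:
    """Select nuclei for quantification based on damage-marker staining.

    In untreated cells only nuclei whose gate-channel (e.g. gamma-H2AX) CTCF
    reaches ``threshold`` are analyzed; in irradiated cells every nucleus is
    kept.  All channels of a passing nucleus are retained.
    """
    if irradiated:
        return measurements.copy()
    gate = measurements[measurements["channel"] == gate_channel]
    if gate.empty:
        raise ValueError(f"gate channel {gate_channel!r} not present in measurements")
    keep = set(gate.loc[gate["ctcf"] >= threshold, "nucleus_id"])
    return measurements[measurements["nucleus_id"].isin(keep)].reset_index(drop=True)


def gate_threshold_from_controls(control_ctcf, quantile: float = 90.0) -> float:
    """Gate threshold as a percentile (default 90th) of negative-control CTCFs."""
    return float(np.percentile(np.asarray(control_ctcf, dtype=float), quantile))


def survival_fraction(
    dose: float,
    colonies_treated: int,
    colonies_untreated: int,
    cells_seeded_treated: int,
    cells_seeded_untreated: int,
) -> SurvivalPoint:
    """Colony survival as percent of the matched untreated plating efficiency."""
    if cells_seeded_treated <= 0 or cells_seeded_untreated <= 0:
        raise ValueError("cells seeded must be positive")
    if colonies_untreated <= 0:
        raise ZeroDivisionError(
            "untreated plating efficiency is zero; survival undefined"
        )
    pe_untreated = colonies_untreated / cells_seeded_untreated
    pe_treated = colonies_treated / cells_seeded_treated
    return SurvivalPoint(
        dose=dose,
        colonies_treated=int(colonies_treated),
        colonies_untreated=int(colonies_untreated),
        cells_seeded_treated=int(cells_seeded_treated),
        cells_seeded_untreated=int(cells_seeded_untreated),
        percent_survival=100.0 * pe_treated / pe_untreated,
    )


def survival_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Survival for a dose series.

    ``counts`` needs columns dose, colonies, cells_seeded; the dose-0 row is
    the matched untreated reference.
    """
    req = {"dose", "colonies", "cells_seeded"}
    if not req <= set(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(req)}")
    untreated = counts[counts["dose"] == 0]
    if untreated.empty:
        raise ValueError("a dose-0 (untreated) row is required")
    u = untreated.iloc[0]
    rows = []
    for _, row in counts.sort_values("dose").iterrows():
        p = survival_fraction(
            dose=float(row["dose"]),
            colonies_treated=int(row["colonies"]),
            colonies_untreated=int(u["colonies"]),
            cells_seeded_treated=int(row["cells_seeded"]),
            cells_seeded_untreated=int(u["cells_seeded"]),
        )
        rows.append(
            {
                "dose": p.dose,
                "colonies": p.colonies_treated,
                "cells_seeded": p.cells_seeded_treated,
                "percent_survival": p.percent_survival,
            }
        )
    return pd.DataFrame(rows)


def read_image(path) -> np.ndarray:
    """Read a (multi-channel) TIFF as a float array, channels first."""
    import tifffile

    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim == 2:
        arr = arr[None, ...]
    elif arr.ndim == 3 and arr.shape[-1] <= 4 and arr.shape[0] > 4:
        arr = np.moveaxis(arr, -1, 0)  # HWC -> CHW
    return arr
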