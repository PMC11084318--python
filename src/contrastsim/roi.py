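"""ROI measurements and contrast-agent deviation statistics.

The comparison statistic of the pipeline is the percent deviation of mean ROI
grey values (or line integrals) between the candidate agent (NaDITMB) and the
reference agent (Omnipaque),

    deviation = 100 * |mean_test - mean_reference| / |mean_reference|,

computed per cavity pair, grouped by tube voltage and filled volume.  ROIs
are fixed-size pixel sets placed declaratively from the phantom geometry (no
segmentation): a rasterized centered disk containing exactly N pixels
(default 1124), with a deterministic radius-then-angle tie-break.  The
statistic is invariant under any common positive rescaling of both means, so
it is robust to affine display transforms applied to a whole image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .phantom import DiskPrimitive, PhantomSpec
from .projector import AcquisitionGeometry, LineIntegralImage

__all__ = [
    "ROISpec",
    "Measurement",
    "DeviationReport",
    "GeometryError",
    "PairingError",
    "StatisticError",
    "disk_pixel_set",
    "measure_roi",
    "percent_deviation",
    "wellplate_roi_layout",
    "compare_agents",
    "line_integral_profile",
]

DEFAULT_ROI_PIXELS = 1124


class GeometryError(ValueError):
    """Raised for ROIs falling outside the image."""


class PairingError(ValueError):
    """Raised when test/reference ROI sets cannot be matched."""


class StatisticError(ValueError):
    """Raised for degenerate statistics (zero reference)."""


def disk_pixel_set(center: Tuple[float, float], n: int = DEFAULT_ROI_PIXELS
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Row/column offsets of the n pixels closest to ``center``.

    ``center`` is in (row, col) pixel coordinates.  Pixels are ranked by
    distance from the center with ties broken by angle (then row, col), making
    the rasterized disk deterministic for any n.
    """
    if n <= 0:
        raise ValueError("pixel count must be positive")
    r_max = int(np.ceil(np.sqrt(n / np.pi))) + 2
    cr, cc = center
    rr, cc_grid = np.mgrid[int(np.floor(cr)) - r_max:int(np.ceil(cr)) + r_max + 1,
                           int(np.floor(cc)) - r_max:int(np.ceil(cc)) + r_max + 1]
    d2 = (rr - cr) ** 2 + (cc_grid - cc) ** 2
    ang = np.arctan2(rr - cr, cc_grid - cc)
    order = np.lexsort((cc_grid.ravel(), rr.ravel(), ang.ravel(),
                        np.round(d2.ravel(), 9)))
    take = order[:n]
    return rr.ravel()[take], cc_grid.ravel()[take]


@dataclass(frozen=True)
class ROISpec:
    """A labelled fixed pixel set."""

    label: str
    center: Tuple[float, float]  # (row, col)
    rows: np.ndarray
    cols: np.ndarray

    @property
    def n(self) -> int:
        return len(self.rows)


def disk_roi(label: str, center: Tuple[float, float],
             n: int = DEFAULT_ROI_PIXELS) -> ROISpec:
    rows, cols = disk_pixel_set(center, n)
    return ROISpec(label=label, center=center, rows=rows, cols=cols)


@dataclass(frozen=True)
class Measurement:
    roi_label: str
    mean: float
    std: float  # population standard deviation
    n: int


def measure_roi(image: np.ndarray, roi: ROISpec) -> Measurement:
    """Arithmetic mean and population std of the image over the ROI pixel set."""
    img = np.asarray(image)
    if (roi.rows.min() < 0 or roi.cols.min() < 0
            or roi.rows.max() >= img.shape[0] or roi.cols.max() >= img.shape[1]):
        raise GeometryError(f"ROI {roi.label!r} outside image bounds {img.shape}")
    vals = img[roi.rows, roi.cols].astype(float)
    return Measurement(roi.label, float(vals.mean()), float(vals.std()), roi.n)


def percent_deviation(test_mean: float, reference_mean: float) -> float:
    """``100 * |test - reference| / |reference|`` (percent)."""
    if reference_mean == 0:
        raise StatisticError("reference mean is zero")
    return 100.0 * abs(test_mean - reference_mean) / abs(reference_mean)


@dataclass(frozen=True)
class DeviationReport:
    """Per-cavity deviations for one (kVp, volume) group."""

    kvp: float
    volume_ml: float
    pairs: Tuple[Tuple[str, float, float, float], ...]
    # (cavity label, mean_test, mean_reference, percent deviation)

    @property
    def max_deviation(self) -> float:
        return max(p[3] for p in self.pairs)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(list(self.pairs),
                          columns=["cavity", "mean_test", "mean_reference",
                                   "percent_deviation"])
        df.insert(0, "volume_ml", self.volume_ml)
        df.insert(0, "kvp", self.kvp)
        return df


def _well_roi_center(disk: DiskPrimitive, geometry: AcquisitionGeometry
                     ) -> Tuple[float, float]:
    """Detector pixel (row, col) of a well's magnified center."""
    zc = disk.center[2]
    xd, yd = geometry.object_to_detector_xy(disk.center[0], disk.center[1], zc)
    rows, cols = geometry.detector_shape
    col = xd / geometry.pixel_pitch + (cols - 1) / 2.0
    row = yd / geometry.pixel_pitch + (rows - 1) / 2.0
    return row, col


def wellplate_roi_layout(plate: PhantomSpec, geometry: AcquisitionGeometry,
                         n: int = DEFAULT_ROI_PIXELS) -> Dict[str, ROISpec]:
    """One fixed-size ROI per well, centered on its magnified footprint.

    ROI labels follow the well labels ("A1".."A8", "B1".."B8").
    """
    layout = {}
    for disk in plate.disks:
        layout[disk.label] = disk_roi(disk.label, _well_roi_center(disk, geometry), n)
    return layout


def compare_agents(
    images: Dict[float, np.ndarray],
    plate: PhantomSpec,
    geometry: AcquisitionGeometry,
    reference_row: str = "B",
    test_row: str = "A",
    n_pixels: int = DEFAULT_ROI_PIXELS,
    volumes_by_cavity: Optional[Dict[int, float]] = None,
) -> List[DeviationReport]:
    """Percent deviations of the test agent vs the reference, per (kVp, volume).

    Cavities are paired across the two rows by column index.  ``images`` maps
    tube voltage to a 2-D grey-value array.  The default cavity-volume map
    follows the study layout: cavities 1-3 hold 0.2 mL, 4-8 hold 0.1 mL.
    """
    layout = wellplate_roi_layout(plate, geometry, n_pixels)
    if volumes_by_cavity is None:
        volumes_by_cavity = {d.label[1:]: round(
            d.thickness * np.pi * d.radius ** 2 / 1000.0, 6)
            for d in plate.disks if d.label.startswith(test_row)}
    test_labels = sorted(k for k in layout if k.startswith(test_row))
    ref_labels = sorted(k for k in layout if k.startswith(reference_row))
    if [t[len(test_row):] for t in test_labels] != \
            [r[len(reference_row):] for r in ref_labels]:
        raise PairingError("test and reference ROI sets do not match by cavity")
    reports: List[DeviationReport] = []
    for kvp, image in sorted(images.items()):
        by_volume: Dict[float, List[Tuple[str, float, float, float]]] = {}
        for t_lab, r_lab in zip(test_labels, ref_labels):
            cavity = t_lab[len(test_row):]
            m_t = measure_roi(image, layout[t_lab])
            m_r = measure_roi(image, layout[r_lab])
            dev = percent_deviation(m_t.mean, m_r.mean)
            vol = float(volumes_by_cavity.get(cavity, np.nan))
            by_volume.setdefault(vol, []).append((cavity, m_t.mean, m_r.mean, dev))
        for vol, pairs in sorted(by_volume.items()):
            reports.append(DeviationReport(float(kvp), vol, tuple(pairs)))
    return reports


def line_integral_profile(image: LineIntegralImage, phantom: PhantomSpec,
                          footprint_fraction: float = 0.5) -> pd.DataFrame:
    """Mean line integral per disk over the central part of its footprint.

    For each disk the magnified footprint center and radius are computed from
    the acquisition geometry; pixels within ``footprint_fraction`` of the
    projected radius are averaged.  Returns a table keyed by disk thickness.
    """
    geometry = image.geometry
    rows_n, cols_n = image.values.shape
    rec = []
    for disk in phantom.disks:
        row_c, col_c = _well_roi_center(disk, geometry)
        zc = disk.center[2]
        r_proj = disk.radius * geometry.source_to_detector / zc / geometry.pixel_pitch
        r_sel = footprint_fraction * r_proj
        r0, r1 = int(np.floor(row_c - r_sel)), int(np.ceil(row_c + r_sel))
        c0, c1 = int(np.floor(col_c - r_sel)), int(np.ceil(col_c + r_sel))
        if r0 < 0 or c0 < 0 or r1 >= rows_n or c1 >= cols_n:
            raise GeometryError(f"footprint of {disk.label!r} outside image")
        rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
        mask = (rr - row_c) ** 2 + (cc - col_c) ** 2 <= r_sel ** 2
        vals = image.values[rr[mask], cc[mask]]
        rec.append(dict(label=disk.label, thickness_mm=disk.thickness,
                        mean_line_integral=float(vals.mean()),
                        std=float(vals.std()), n=int(mask.sum())))
    return pd.DataFrame(rec).sort_values("thickness_mm").reset_index(drop=True)
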