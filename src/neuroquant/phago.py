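"""Phagocytosis scoring of FITC-labeled amyloid-β uptake.

Given a cell segmentation (imported from an external segmenter or produced
by the built-in nuclei-seeded watershed) and a FITC channel, each cell is
scored positive when its above-threshold FITC area reaches a minimum
punctum size; the summary reports the proportion of phagocytic cells and
the mean FITC intensity within positive cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import relabel_sequential, watershed

from .plaques import _threshold


@dataclass
class CellSegmentation:
    """Label image (0 background, k = cell k) with physical calibration."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0:
            raise ValueError("negative labels")
        present = np.unique(self.labels)
        present = present[present > 0]
        if len(present) and not np.array_equal(
            present, np.arange(1, len(present) + 1)
        ):
            self.labels, _, _ = relabel_sequential(self.labels)

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    def table(self) -> pd.DataFrame:
        rows = []
        for rp in regionprops(self.labels):
            rows.append(
                {
                    "cell_id": rp.label,
                    "x_um": (rp.centroid[1] + 0.5) * self.pixel_size_um,
                    "y_um": (rp.centroid[0] + 0.5) * self.pixel_size_um,
                    "area_um2": rp.area * self.pixel_size_um**2,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class PhagoSummary:
    n_cells: int
    n_positive: int
    proportion_positive: float
    mean_fitc_positive: float  # NaN when no positive cell
    per_cell: pd.DataFrame


def segment_cells(
    iba1_channel: np.ndarray,
    nuclei_channel: np.ndarray,
    pixel_size_um: float,
    nucleus_diameter_um: float = 4.0,
    iba1_threshold=None,
    nuclei_threshold=None,
) -> CellSegmentation:
    """Nuclei-seeded watershed segmentation of the Iba1 (cell body) channel.

    Nuclei are detected by smoothing + Otsu and become watershed markers;
    the watershed floods the inverted smoothed Iba1 intensity restricted to
    the Iba1-positive mask, so touching cells split along intensity valleys
    between their nuclei.  Deterministic.
    """
    iba1 = np.asarray(iba1_channel, dtype=float)
    nuc = np.asarray(nuclei_channel, dtype=float)
    sigma = nucleus_diameter_um / (4.0 * pixel_size_um)
    nuc_sm = gaussian_filter(nuc, sigma)
    if np.ptp(nuc_sm) == 0:
        raise ValueError("no nuclei detected")
    nt = _threshold(nuc_sm, nuclei_threshold)
    markers = label(nuc_sm > nt, connectivity=1)
    if markers.max() == 0:
        raise ValueError("no nuclei detected")
    iba1_sm = gaussian_filter(iba1, sigma)
    # cell bodies can cover a large area fraction: no noise floor here
    it = _threshold(iba1_sm, iba1_threshold, noise_floor=False)
    cell_mask = iba1_sm > it
    labels = watershed(-iba1_sm, markers=markers, mask=cell_mask)
    return CellSegmentation(labels, pixel_size_um)


def quantify_phagocytosis(
    seg: CellSegmentation,
    fitc_channel: np.ndarray,
    positive_threshold=None,
    min_punctum_area_um2: float = 1.0,
) -> PhagoSummary:
    """Score each cell for FITC-Aβ uptake.

    The positivity threshold defaults to Otsu on FITC within cell pixels
    (with a robust noise floor).  A cell is positive when it contains at
    least one contiguous above-threshold punctum of
    ``min_punctum_area_um2`` — scattered single bright pixels do not
    qualify.  ``mean_fitc_positive`` is the mean intensity of
    above-threshold pixels within positive cells (NaN when none).
    """
    fitc = np.asarray(fitc_channel, dtype=float)
    if fitc.shape != seg.labels.shape:
        raise ValueError("segmentation and FITC channel shape mismatch")
    if seg.n_cells == 0:
        raise ValueError("zero cells in segmentation")
    in_cell = seg.labels > 0
    vals = fitc[in_cell]
    t = _threshold(vals, positive_threshold)

    px2 = seg.pixel_size_um**2
    min_px = max(1, int(np.ceil(min_punctum_area_um2 / px2)))
    rows = []
    pos_pixel_vals = []
    above_img = fitc > t
    for rp in regionprops(seg.labels, intensity_image=fitc):
        cell = seg.labels == rp.label
        cell_vals = fitc[cell]
        above = above_img & cell
        puncta = label(above, connectivity=2)
        largest = (
            max(np.bincount(puncta.ravel())[1:]) if puncta.max() else 0
        )
        positive = largest >= min_px
        rows.append(
            {
                "cell_id": rp.label,
                "area_um2": rp.area * px2,
                "mean_fitc": float(cell_vals.mean()),
                "fitc_positive_area_um2": float(above.sum() * px2),
                "positive": positive,
            }
        )
        if positive:
            pos_pixel_vals.append(fitc[above])
    per_cell = pd.DataFrame(rows)
    n_pos = int(per_cell["positive"].sum())
    mean_pos = (
        float(np.concatenate(pos_pixel_vals).mean()) if n_pos else np.nan
    )
    return PhagoSummary(
        n_cells=seg.n_cells,
        n_positive=n_pos,
        proportion_positive=n_pos / seg.n_cells,
        mean_fitc_positive=mean_pos,
        per_cell=per_cell,
    )
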