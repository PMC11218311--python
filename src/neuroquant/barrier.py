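"""Microglial barrier coverage and peri-plaque dystrophic-neurite analysis.

For each plaque, rays are cast from the centroid at a fixed angular
resolution (default 1°).  The outermost plaque-mask pixel along each ray is
the perimeter crossing; the ray's arc is "covered" when Iba1-positive signal
lies within a small band of that crossing.  Coverage is the fraction of the
360° perimeter covered.  The same angular sectors are then extended
radially to the limit of Lamp1-positive (dystrophic neurite) signal, and
Lamp1 area is accumulated per covered/uncovered sector class and normalized
by each class's total degrees.  Finally, coverage is correlated with total
Lamp1 area within plaque-diameter bins, and per-degree dystrophy is
compared between covered and uncovered sectors across plaques.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .plaques import Plaque, _threshold

DEFAULT_SIZE_BINS = [
    ("<9um", 0.0, 9.0),
    ("9-18um", 9.0, 18.0),
    (">=18um", 18.0, np.inf),
]


@dataclass
class AngularProfile:
    """Per-angular-bin record around one plaque.

    ``theta_start_deg[k]`` is the start of bin k (bins tile [0, 360) exactly);
    ``perimeter_radius_um`` the radial distance of the outermost plaque-mask
    crossing on the bin's central ray; ``iba1_at_perimeter`` whether Iba1 was
    found within the colocalization band of that crossing;
    ``lamp1_outer_extent_um`` the farthest Lamp1-positive point along the ray
    beyond the perimeter (NaN when absent).
    """

    plaque_id: int
    delta_theta_deg: float
    theta_start_deg: np.ndarray
    iba1_at_perimeter: np.ndarray
    perimeter_radius_um: np.ndarray
    lamp1_outer_extent_um: np.ndarray
    degenerate: bool = False

    @property
    def n_bins(self) -> int:
        return len(self.theta_start_deg)


@dataclass
class CoverageResult:
    plaque_id: int
    covered_deg: float
    uncovered_deg: float
    coverage: float


@dataclass
class DystrophyResult:
    plaque_id: int
    lamp1_area_covered_um2: float
    lamp1_area_uncovered_um2: float
    lamp1_per_deg_covered: float  # NaN when the class spans 0°
    lamp1_per_deg_uncovered: float
    total_lamp1_um2: float


def _angle_deg(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """CCW angle from +x axis in [0, 360)."""
    return np.degrees(np.arctan2(dy, dx)) % 360.0


def build_angular_profile(
    iba1_channel: np.ndarray,
    lamp1_channel: np.ndarray,
    plaque: Plaque,
    pixel_size_um: float,
    delta_theta_deg: float = 1.0,
    band_um: float = 1.0,
    iba1_threshold=None,
    lamp1_threshold=None,
) -> AngularProfile:
    """Ray-cast angular profile of one plaque.

    One ray per bin (through the bin center).  The perimeter point is the
    outermost plaque-mask sample on the ray; Iba1 colocalization is tested
    within ±``band_um`` of it along the ray; the Lamp1 extent is the farthest
    Lamp1-positive sample beyond the perimeter, plaque interior excluded.
    """
    if 360.0 % delta_theta_deg != 0:
        raise ValueError("delta_theta_deg must divide 360")
    if not plaque.mask.any():
        raise ValueError("empty plaque mask")
    iba1 = np.asarray(iba1_channel, dtype=float)
    lamp1 = np.asarray(lamp1_channel, dtype=float)
    iba1_mask = iba1 > _threshold(iba1, iba1_threshold)
    lamp1_mask = lamp1 > _threshold(lamp1, lamp1_threshold)

    ny, nx = plaque.mask.shape
    cx, cy = plaque.centroid_um
    crow = int(cy / pixel_size_um)
    ccol = int(cx / pixel_size_um)
    degenerate = not (
        0 <= crow < ny and 0 <= ccol < nx and plaque.mask[crow, ccol]
    )

    n_bins = int(round(360.0 / delta_theta_deg))
    theta_start = delta_theta_deg * np.arange(n_bins)
    theta = np.radians(theta_start + delta_theta_deg / 2.0)

    step = pixel_size_um / 2.0
    t_max = float(np.hypot(nx, ny) * pixel_size_um)
    t = step * np.arange(1, int(t_max / step) + 1)

    # sample positions for all rays: (n_bins, n_steps)
    px = cx + np.cos(theta)[:, None] * t[None, :]
    py = cy + np.sin(theta)[:, None] * t[None, :]
    col = (px / pixel_size_um).astype(int)
    row = (py / pixel_size_um).astype(int)
    inside = (row >= 0) & (row < ny) & (col >= 0) & (col < nx)
    rowc = np.clip(row, 0, ny - 1)
    colc = np.clip(col, 0, nx - 1)

    on_plaque = plaque.mask[rowc, colc] & inside
    on_iba1 = iba1_mask[rowc, colc] & inside
    on_lamp1 = lamp1_mask[rowc, colc] & inside & ~on_plaque

    perimeter = np.full(n_bins, np.nan)
    covered = np.zeros(n_bins, dtype=bool)
    lamp1_ext = np.full(n_bins, np.nan)

    any_plq = on_plaque.any(axis=1)
    # outermost plaque sample per ray
    last_idx = on_plaque.shape[1] - 1 - np.argmax(on_plaque[:, ::-1], axis=1)
    perimeter[any_plq] = t[last_idx[any_plq]]
    if degenerate:
        # centroid outside the mask (extreme concavity): fall back to the
        # nearest-to-farthest mask samples that do exist per ray; rays that
        # miss the mask keep NaN perimeter and are treated as uncovered.
        pass
    for k in np.nonzero(any_plq)[0]:
        tp = perimeter[k]
        near = np.abs(t - tp) <= band_um
        covered[k] = bool(np.any(on_iba1[k] & near))
        beyond = on_lamp1[k] & (t > tp)
        if beyond.any():
            lamp1_ext[k] = t[np.nonzero(beyond)[0][-1]]

    return AngularProfile(
        plaque_id=plaque.id,
        delta_theta_deg=delta_theta_deg,
        theta_start_deg=theta_start,
        iba1_at_perimeter=covered,
        perimeter_radius_um=perimeter,
        lamp1_outer_extent_um=lamp1_ext,
        degenerate=degenerate,
    )


def angular_profile_bruteforce(
    iba1_channel: np.ndarray,
    plaque: Plaque,
    pixel_size_um: float,
    delta_theta_deg: float = 1.0,
    band_um: float = 1.0,
    iba1_threshold=None,
) -> np.ndarray:
    """Independent per-pixel angular-histogram cross-check of coverage.

    Instead of marching along rays, every pixel of the field is assigned
    the interval of angles its footprint subtends seen from the centroid.
    For each angular bin, the perimeter radius is the largest radius of any
    plaque-mask pixel whose angular footprint contains the bin-center
    angle, and the bin is covered when any Iba1-positive pixel whose
    footprint contains that angle lies within ±``band_um`` of the perimeter
    radius.  Validates the ray-cast profile on convex plaques; not part of
    the production path.
    """
    iba1 = np.asarray(iba1_channel, dtype=float)
    iba1_mask = iba1 > _threshold(iba1, iba1_threshold)
    ny, nx = plaque.mask.shape
    cx, cy = plaque.centroid_um
    x = (np.arange(nx) + 0.5) * pixel_size_um
    y = (np.arange(ny) + 0.5) * pixel_size_um
    xx, yy = np.meshgrid(x, y)
    r = np.hypot(xx - cx, yy - cy)
    n_bins = int(round(360.0 / delta_theta_deg))
    bins = (_angle_deg(xx - cx, yy - cy) // delta_theta_deg).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)

    half = pixel_size_um / 2.0

    def _extent(rr_, cc_):
        """Angular interval [a0, a1] subtended by pixel (rr_, cc_); a1 may
        exceed 360 when the footprint spans the 0/360 seam."""
        pxc = (cc_ + 0.5) * pixel_size_um - cx
        pyc = (rr_ + 0.5) * pixel_size_um - cy
        corners = _angle_deg(
            np.array([pxc - half, pxc - half, pxc + half, pxc + half]),
            np.array([pyc - half, pyc + half, pyc - half, pyc + half]),
        )
        a0, a1 = corners.min(), corners.max()
        if a1 - a0 > 180:
            shifted = np.where(corners < 180, corners + 360, corners)
            a0, a1 = shifted.min(), shifted.max()
        return a0, a1

    def _center_bins(a0, a1):
        """Bins whose center angle lies inside [a0, a1]."""
        k0 = int(np.ceil(a0 / delta_theta_deg - 0.5))
        k1 = int(np.floor(a1 / delta_theta_deg - 0.5))
        return [k % n_bins for k in range(k0, k1 + 1)]

    r_out = np.full(n_bins, -np.inf)
    for rr_, cc_ in zip(*np.nonzero(plaque.mask)):
        for kk in _center_bins(*_extent(rr_, cc_)):
            r_out[kk] = max(r_out[kk], r[rr_, cc_])
    if not np.isfinite(r_out).any():
        return np.zeros(n_bins, dtype=bool)
    r_out[~np.isfinite(r_out)] = r_out[np.isfinite(r_out)].max()

    covered = np.zeros(n_bins, dtype=bool)
    for rr_, cc_ in zip(*np.nonzero(iba1_mask)):
        for kk in _center_bins(*_extent(rr_, cc_)):
            if abs(r[rr_, cc_] - r_out[kk]) <= band_um:
                covered[kk] = True
    return covered


def microglia_coverage(profile: AngularProfile) -> CoverageResult:
    """Coverage = summed covered degrees / 360 (exact in Δθ units)."""
    n_cov = int(profile.iba1_at_perimeter.sum())
    covered = n_cov * profile.delta_theta_deg
    return CoverageResult(
        plaque_id=profile.plaque_id,
        covered_deg=covered,
        uncovered_deg=360.0 - covered,
        coverage=n_cov / profile.n_bins,
    )


def dystrophy_by_sector(
    lamp1_channel: np.ndarray,
    profile: AngularProfile,
    coverage: CoverageResult,
    plaque: Plaque,
    pixel_size_um: float,
    lamp1_threshold=None,
) -> DystrophyResult:
    """Assign Lamp1-positive area outside the plaque to angular sectors.

    Every Lamp1⁺ pixel outside the plaque mask belongs to the angular bin of
    its angle from the centroid and is kept when within that bin's Lamp1
    outer extent (plus half a pixel diagonal of slack for off-ray pixels;
    bins whose ray saw no Lamp1 apply no radial cap).  Covered and uncovered
    areas sum to the total exactly by construction.  Per-degree values are
    NaN when a sector class spans 0°.
    """
    lamp1 = np.asarray(lamp1_channel, dtype=float)
    lamp1_mask = (lamp1 > _threshold(lamp1, lamp1_threshold)) & ~plaque.mask
    px2 = pixel_size_um**2
    rr, cc = np.nonzero(lamp1_mask)
    area_cov = area_unc = 0.0
    if len(rr):
        x = (cc + 0.5) * pixel_size_um
        y = (rr + 0.5) * pixel_size_um
        cx, cy = plaque.centroid_um
        r = np.hypot(x - cx, y - cy)
        bins = (
            _angle_deg(x - cx, y - cy) // profile.delta_theta_deg
        ).astype(int)
        cap = profile.lamp1_outer_extent_um[bins]
        slack = pixel_size_um * np.sqrt(2.0)
        keep = np.isnan(cap) | (r <= cap + slack)
        cov_bin = profile.iba1_at_perimeter[bins]
        area_cov = float(np.sum(keep & cov_bin) * px2)
        area_unc = float(np.sum(keep & ~cov_bin) * px2)
    per_cov = area_cov / coverage.covered_deg if coverage.covered_deg > 0 else np.nan
    per_unc = (
        area_unc / coverage.uncovered_deg if coverage.uncovered_deg > 0 else np.nan
    )
    return DystrophyResult(
        plaque_id=profile.plaque_id,
        lamp1_area_covered_um2=area_cov,
        lamp1_area_uncovered_um2=area_unc,
        lamp1_per_deg_covered=per_cov,
        lamp1_per_deg_uncovered=per_unc,
        total_lamp1_um2=area_cov + area_unc,
    )


def coverage_dystrophy_correlation(
    coverages: list[CoverageResult],
    dystrophies: list[DystrophyResult],
    diameters_um: np.ndarray,
    bins: list[tuple[str, float, float]] | None = None,
    lamp1_field: str = "total_lamp1_um2",
) -> pd.DataFrame:
    """Pearson correlation of coverage vs Lamp1 area within diameter bins.

    ``lamp1_field`` selects the DystrophyResult attribute correlated against
    coverage (total area by default).  Bins with fewer than 3 plaques or
    zero variance are reported as missing with a reason.
    """
    if bins is None:
        bins = DEFAULT_SIZE_BINS
    cov = np.array([c.coverage for c in coverages])
    lam = np.array([getattr(d, lamp1_field) for d in dystrophies])
    dia = np.asarray(diameters_um, dtype=float)
    rows = []
    for lab, lo, hi in bins:
        sel = (dia >= lo) & (dia < hi)
        n = int(sel.sum())
        row = {"bin": lab, "lo_um": lo, "hi_um": hi, "n": n,
               "pearson_r": np.nan, "p_value": np.nan, "reason": ""}
        if n < 3:
            row["reason"] = "fewer than 3 plaques"
        elif np.ptp(cov[sel]) == 0 or np.ptp(lam[sel]) == 0:
            row["reason"] = "zero variance"
        else:
            r, p = stats.pearsonr(cov[sel], lam[sel])
            row["pearson_r"], row["p_value"] = float(r), float(p)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_covered_vs_uncovered(dystrophies: list[DystrophyResult]) -> dict:
    """Paired comparison of per-degree Lamp1 area, covered vs uncovered
    sectors, across plaques with both sector classes defined.

    Returns group means, SDs, the paired two-sided t statistic and p-value.
    """
    cov = np.array([d.lamp1_per_deg_covered for d in dystrophies])
    unc = np.array([d.lamp1_per_deg_uncovered for d in dystrophies])
    ok = np.isfinite(cov) & np.isfinite(unc)
    if ok.sum() < 2:
        raise ValueError(
            "need at least 2 plaques with both covered and uncovered sectors"
        )
    cov, unc = cov[ok], unc[ok]
    if np.allclose(cov, unc):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(unc, cov)
    return {
        "n": int(ok.sum()),
        "mean_per_deg_covered": float(cov.mean()),
        "sd_per_deg_covered": float(cov.std(ddof=1)),
        "mean_per_deg_uncovered": float(unc.mean()),
        "sd_per_deg_uncovered": float(unc.std(ddof=1)),
        "t_statistic": float(t),
        "p_value": float(p),
    }
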