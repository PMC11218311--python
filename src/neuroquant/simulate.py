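"""Synthetic-data generators with exact ground truth.

Every downstream stage of the package is exercised on data from this
module: multi-channel histology stacks with disk-like plaques, microglial
coverage over known angular intervals and Lamp1 halos of known sector
density; branched neuron morphologies in SWC convention; phagocytosis
fields with a known fraction of FITC-positive cells; and negative-binomial
miRNA count matrices with known differential-expression labels.

All randomness flows from the seed in the relevant config: two runs with an
equal config are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .mirna import CASE, CONTROL, CountMatrix
from .plaques import ImageStack
from .sholl import SWC_BASAL, SWC_SOMA, NeuronMorphology

#: rendering amplitudes (arbitrary fluorescence units)
PLAQUE_AMP = 200.0
IBA1_AMP = 180.0
SOMA_AMP = 160.0
LAMP1_AMP = 170.0
NUCLEUS_AMP = 150.0
CELL_AMP = 120.0

SOMA_DIAMETER_UM = 6.0  # typical microglial soma scale
LAMP1_PUNCTUM_RADIUS_UM = 0.8

DEFAULT_CHANNEL_ROLES = {
    "plaque": 0, "iba1": 1, "lamp1": 2, "nuclei": 3, "fitc": 4,
}


@dataclass
class SimConfig:
    """Imaging-field configuration for the histology generator.

    Defaults emulate a 40× confocal acquisition: 0.5 µm pixels, 3 µm z-step,
    five optical slices, mild Gaussian PSF blur and additive Gaussian noise.
    """

    field_size_um: tuple[float, float] = (100.0, 100.0)
    pixel_size_um: float = 0.5
    z_slices: int = 5
    z_step_um: float = 3.0
    channel_roles: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_ROLES)
    )
    noise_sd: float = 4.0
    psf_sigma_um: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.z_slices < 1:
            raise ValueError("z_slices must be >= 1")

    @property
    def shape_px(self) -> tuple[int, int]:
        return (
            int(round(self.field_size_um[1] / self.pixel_size_um)),
            int(round(self.field_size_um[0] / self.pixel_size_um)),
        )


@dataclass
class PlaqueSpec:
    """Geometric ground truth for one synthetic plaque.

    ``covered_intervals_deg`` are half-open [start, end) degree intervals
    (CCW from +x) over which the microglial envelope is rendered;
    ``lamp1_density_*`` are the target Lamp1⁺ area fractions of the halo
    annulus within covered / uncovered sectors.
    """

    center_um: tuple[float, float]
    radius_um: float
    covered_intervals_deg: list[tuple[float, float]] = field(
        default_factory=list
    )
    lamp1_density_covered: float = 0.0
    lamp1_density_uncovered: float = 0.0
    lamp1_outer_radius_um: float | None = None
    n_somata_within_25um: int = 0
    n_somata_background: int = 0

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        if self.lamp1_outer_radius_um is None:
            self.lamp1_outer_radius_um = self.radius_um + 12.0
        if min(self.lamp1_density_covered, self.lamp1_density_uncovered) < 0:
            raise ValueError("lamp1 densities must be >= 0")
        ivals = sorted(self.covered_intervals_deg)
        for s, e in ivals:
            if not (0 <= s < e <= 360):
                raise ValueError(
                    f"interval [{s}, {e}) must lie within [0, 360)"
                )
        for (_, e0), (s1, _) in zip(ivals, ivals[1:]):
            if s1 < e0:
                raise ValueError("covered intervals must be disjoint")

    @property
    def true_coverage(self) -> float:
        return sum(e - s for s, e in self.covered_intervals_deg) / 360.0

    @property
    def covered_deg(self) -> float:
        return sum(e - s for s, e in self.covered_intervals_deg)


@dataclass
class GroundTruth:
    """Ground-truth tables emitted alongside every synthetic dataset."""

    plaques: pd.DataFrame | None = None
    somata: pd.DataFrame | None = None
    cells: pd.DataFrame | None = None
    mirna: pd.DataFrame | None = None


def _interval_mask(theta_deg: np.ndarray, intervals) -> np.ndarray:
    out = np.zeros(theta_deg.shape, dtype=bool)
    for s, e in intervals:
        out |= (theta_deg >= s) & (theta_deg < e)
    return out


def _pixel_grid(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = cfg.shape_px
    x = (np.arange(nx) + 0.5) * cfg.pixel_size_um
    y = (np.arange(ny) + 0.5) * cfg.pixel_size_um
    return np.meshgrid(x, y)


def _stamp_disk(
    mask: np.ndarray, cx: float, cy: float, radius: float, px: float
) -> None:
    r0 = max(0, int((cy - radius) / px) - 1)
    r1 = min(mask.shape[0], int((cy + radius) / px) + 2)
    c0 = max(0, int((cx - radius) / px) - 1)
    c1 = min(mask.shape[1], int((cx + radius) / px) + 2)
    if r0 >= r1 or c0 >= c1:
        return
    yy = (np.arange(r0, r1) + 0.5) * px
    xx = (np.arange(c0, c1) + 0.5) * px
    d2 = (xx[None, :] - cx) ** 2 + (yy[:, None] - cy) ** 2
    mask[r0:r1, c0:c1] |= d2 <= radius**2


def simulate_histology_stack(
    cfg: SimConfig, plaques: list[PlaqueSpec]
) -> tuple[ImageStack, GroundTruth]:
    """Render a multi-channel z-stack from plaque specifications.

    Plaque channel: one bright disk per plaque.  Iba1: an enveloping band
    over the covered angular intervals plus soma disks (6 µm).  Lamp1:
    puncta between the plaque edge and the halo outer radius with
    sector-class densities as specified.  Slices away from the central one
    fade with a Gaussian axial falloff; every slice is PSF-blurred and
    Gaussian noise is added.  Ground-truth Lamp1 areas are measured on the
    rendered noiseless masks (exact pixel counts).
    """
    rng = np.random.default_rng(cfg.seed)
    fx, fy = cfg.field_size_um
    for i, p in enumerate(plaques):
        cx, cy = p.center_um
        ro = p.lamp1_outer_radius_um
        if not (ro <= cx <= fx - ro and ro <= cy <= fy - ro):
            raise ValueError(
                f"plaque {i} at ({cx}, {cy}) with outer radius {ro} µm does "
                f"not fit inside the {fx} x {fy} µm field"
            )

    required = {"plaque", "iba1", "lamp1", "nuclei"}
    missing = required - set(cfg.channel_roles)
    if missing:
        raise ValueError(f"channel_roles missing {sorted(missing)}")

    ny, nx = cfg.shape_px
    px = cfg.pixel_size_um
    xx, yy = _pixel_grid(cfg)
    n_channels = max(cfg.channel_roles.values()) + 1

    plaque_mask = np.zeros((ny, nx), dtype=bool)
    iba1_band = np.zeros((ny, nx), dtype=bool)
    lamp1_mask = np.zeros((ny, nx), dtype=bool)
    soma_mask = np.zeros((ny, nx), dtype=bool)
    nucleus_mask = np.zeros((ny, nx), dtype=bool)

    punctum_area = np.pi * LAMP1_PUNCTUM_RADIUS_UM**2
    soma_rows = []
    truth_rows = []
    halo_info = []  # per plaque: (halo region selector data for truth)

    for i, p in enumerate(plaques):
        cx, cy = p.center_um
        r = np.hypot(xx - cx, yy - cy)
        theta = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
        plaque_mask |= r <= p.radius_um

        covered = _interval_mask(theta, p.covered_intervals_deg)
        band = (r >= p.radius_um - 0.5) & (r <= p.radius_um + 2.0)
        iba1_band |= band & covered

        halo = (r > p.radius_um) & (r <= p.lamp1_outer_radius_um)
        for dens, sector in (
            (p.lamp1_density_covered, halo & covered),
            (p.lamp1_density_uncovered, halo & ~covered),
        ):
            if dens <= 0 or not sector.any():
                continue
            area = sector.sum() * px**2
            n_puncta = int(round(dens * area / punctum_area))
            rows_s, cols_s = np.nonzero(sector)
            if n_puncta == 0:
                continue
            pick = rng.choice(len(rows_s), size=n_puncta, replace=True)
            for j in pick:
                _stamp_disk(
                    lamp1_mask,
                    (cols_s[j] + 0.5) * px,
                    (rows_s[j] + 0.5) * px,
                    LAMP1_PUNCTUM_RADIUS_UM,
                    px,
                )
        halo_info.append((halo, covered))

        # plaque-associated somata: centers within 25 µm of the plaque center
        inner = p.radius_um + SOMA_DIAMETER_UM / 2.0
        if p.n_somata_within_25um > 0 and inner >= 25.0:
            raise ValueError(
                f"plaque {i}: radius too large to place somata within 25 µm"
            )
        for _ in range(p.n_somata_within_25um):
            d = rng.uniform(inner, 25.0)
            a = rng.uniform(0, 2 * np.pi)
            soma_rows.append(
                {
                    "x_um": cx + d * np.cos(a),
                    "y_um": cy + d * np.sin(a),
                    "plaque_id": i + 1,
                }
            )

    # background somata: kept > 27 µm from every plaque center so that the
    # 25-µm association counts stay exactly the specified ones
    n_bg = sum(p.n_somata_background for p in plaques)
    centers = np.array([p.center_um for p in plaques]).reshape(-1, 2)
    margin = 4.0
    tries = 0
    placed = 0
    while placed < n_bg and tries < 1000 * max(1, n_bg):
        tries += 1
        q = rng.uniform([margin, margin], [fx - margin, fy - margin])
        if len(centers) and np.hypot(*(centers - q).T).min() <= 27.0:
            continue
        soma_rows.append({"x_um": q[0], "y_um": q[1], "plaque_id": 0})
        placed += 1
    if placed < n_bg:
        raise RuntimeError("could not place background somata in the field")

    for s in soma_rows:
        _stamp_disk(
            soma_mask, s["x_um"], s["y_um"], SOMA_DIAMETER_UM / 2.0, px
        )
        _stamp_disk(nucleus_mask, s["x_um"], s["y_um"], 1.5, px)

    # exact ground truth measured on the rendered noiseless Lamp1 mask
    lamp1_outside = lamp1_mask & ~plaque_mask
    for i, p in enumerate(plaques):
        halo, covered = halo_info[i]
        a_cov = float((lamp1_outside & halo & covered).sum() * px**2)
        a_unc = float((lamp1_outside & halo & ~covered).sum() * px**2)
        cd = p.covered_deg
        truth_rows.append(
            {
                "plaque_id": i + 1,
                "x_um": p.center_um[0],
                "y_um": p.center_um[1],
                "radius_um": p.radius_um,
                "equiv_diameter_um": 2 * p.radius_um,
                "coverage": p.true_coverage,
                "covered_deg": cd,
                "lamp1_area_covered_um2": a_cov,
                "lamp1_area_uncovered_um2": a_unc,
                "lamp1_per_deg_covered": a_cov / cd if cd > 0 else np.nan,
                "lamp1_per_deg_uncovered": (
                    a_unc / (360 - cd) if cd < 360 else np.nan
                ),
                "n_somata_within_25um": p.n_somata_within_25um,
            }
        )

    planes = np.zeros((n_channels, ny, nx))
    planes[cfg.channel_roles["plaque"]] = PLAQUE_AMP * plaque_mask
    planes[cfg.channel_roles["iba1"]] = np.maximum(
        IBA1_AMP * iba1_band, SOMA_AMP * soma_mask
    )
    planes[cfg.channel_roles["lamp1"]] = LAMP1_AMP * lamp1_outside
    planes[cfg.channel_roles["nuclei"]] = NUCLEUS_AMP * nucleus_mask

    zc = cfg.z_slices // 2
    falloff = np.exp(
        -0.5 * ((np.arange(cfg.z_slices) - zc) / 1.2) ** 2
    )
    pixels = planes[:, None, :, :] * falloff[None, :, None, None]
    sigma = cfg.psf_sigma_um / px
    if sigma > 0:
        pixels = gaussian_filter(pixels, sigma=(0, 0, sigma, sigma))
    if cfg.noise_sd > 0:
        pixels = pixels + rng.normal(0, cfg.noise_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0, None)

    stack = ImageStack(
        pixels, cfg.pixel_size_um, cfg.z_step_um, dict(cfg.channel_roles)
    )
    truth = GroundTruth(
        plaques=pd.DataFrame(truth_rows),
        somata=pd.DataFrame(
            soma_rows, columns=["x_um", "y_um", "plaque_id"]
        ),
    )
    return stack, truth


# ------------------------------------------------------------------ neurons


def simulate_neuron_swc(
    branch_depth: int,
    segment_len_um: float = 12.0,
    seed: int = 0,
    branch_angle_deg: float = 40.0,
) -> NeuronMorphology:
    """Random planar binary tree in SWC convention, soma at the origin.

    One stem leaves the soma in a random direction; at each of
    ``branch_depth`` branching levels every tip bifurcates, the children
    deviating ±branch_angle (with jitter) from the parent direction.  All
    segments have length ``segment_len_um``, so brute-force segment–circle
    intersection counts are computable from the node table alone.
    """
    if branch_depth < 0:
        raise ValueError("branch_depth must be >= 0")
    rng = np.random.default_rng(seed)
    rows = [
        {"id": 1, "type": SWC_SOMA, "x": 0.0, "y": 0.0, "z": 0.0,
         "radius": 3.0, "parent": -1}
    ]
    next_id = 2
    a0 = rng.uniform(0, 2 * np.pi)
    tips = []  # (node_id, x, y, direction)
    x, y = segment_len_um * np.cos(a0), segment_len_um * np.sin(a0)
    rows.append(
        {"id": next_id, "type": SWC_BASAL, "x": x, "y": y, "z": 0.0,
         "radius": 0.5, "parent": 1}
    )
    tips.append((next_id, x, y, a0))
    next_id += 1
    for _ in range(branch_depth):
        new_tips = []
        for pid, px_, py_, ang in tips:
            for sign in (1.0, -1.0):
                da = np.radians(
                    branch_angle_deg + rng.uniform(-10.0, 10.0)
                )
                a = ang + sign * da
                nx_ = px_ + segment_len_um * np.cos(a)
                ny_ = py_ + segment_len_um * np.sin(a)
                rows.append(
                    {"id": next_id, "type": SWC_BASAL, "x": nx_, "y": ny_,
                     "z": 0.0, "radius": 0.5, "parent": pid}
                )
                new_tips.append((next_id, nx_, ny_, a))
                next_id += 1
        tips = new_tips
    return NeuronMorphology(pd.DataFrame(rows))


def render_morphology_mask(
    morph: NeuronMorphology,
    pixel_size_um: float = 0.2,
    neurite_width_um: float = 0.5,
    pad_um: float = 10.0,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Rasterize a planar morphology to a binary mask.

    Edges are drawn as Bresenham lines and dilated to ``neurite_width_um``
    (thresholded fluorescence images of dendrites have finite width; a
    one-pixel-thin render could slip through a rasterized circle without
    sharing a pixel).  Returns the mask and the soma (x, y) in the mask's
    physical coordinates.
    """
    from skimage.draw import line
    from skimage.morphology import dilation, disk

    nodes = morph.nodes
    xs, ys = nodes["x"].to_numpy(), nodes["y"].to_numpy()
    x0, y0 = xs.min() - pad_um, ys.min() - pad_um
    w = int((xs.max() - x0 + pad_um) / pixel_size_um)
    h = int((ys.max() - y0 + pad_um) / pixel_size_um)
    mask = np.zeros((h, w), dtype=bool)
    idx = {nid: k for k, nid in enumerate(nodes["id"])}
    for _, row in nodes[nodes["parent"] != -1].iterrows():
        par = nodes.iloc[idx[row["parent"]]]
        rr, cc = line(
            int((par["y"] - y0) / pixel_size_um),
            int((par["x"] - x0) / pixel_size_um),
            int((row["y"] - y0) / pixel_size_um),
            int((row["x"] - x0) / pixel_size_um),
        )
        mask[rr, cc] = True
    wpx = max(1, int(round(neurite_width_um / (2 * pixel_size_um))))
    mask = dilation(mask, disk(wpx))
    soma = morph.soma_xyz
    return mask, (float(soma[0] - x0), float(soma[1] - y0))


# ------------------------------------------------------------- phagocytosis


def simulate_phagocytosis_image(
    n_cells: int,
    frac_positive: float,
    puncta_intensity: float = 150.0,
    seed: int = 0,
    pixel_size_um: float = 0.5,
    cell_radius_um: float = 8.0,
    punctum_radius_um: float = 1.25,
    n_puncta_per_cell: int = 3,
    noise_sd: float = 2.0,
    psf_sigma_um: float = 0.15,
) -> tuple[ImageStack, GroundTruth]:
    """Field of non-overlapping cells, a known fraction containing FITC
    puncta.

    Exactly ``round(frac_positive * n_cells)`` cells receive puncta; the
    per-cell labels are returned as ground truth.  Channels: iba1 (cell
    bodies), nuclei, fitc.
    """
    if not 0 <= frac_positive <= 1:
        raise ValueError("frac_positive must lie in [0, 1]")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    k = int(np.ceil(np.sqrt(n_cells)))
    margin = cell_radius_um + 2.0
    side = k * 3.2 * cell_radius_um + 2 * margin
    min_d = 2.3 * cell_radius_um

    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_cells:
        tries += 1
        if tries > 400 * n_cells:
            raise RuntimeError(
                "cell packing failed: field too crowded after bounded retries"
            )
        q = rng.uniform(margin, side - margin, size=2)
        if centers and np.hypot(*(np.array(centers) - q).T).min() < min_d:
            continue
        centers.append(q)
    centers_arr = np.array(centers)

    n_pos = int(round(frac_positive * n_cells))
    pos_idx = np.sort(rng.permutation(n_cells)[:n_pos])
    positive = np.zeros(n_cells, dtype=bool)
    positive[pos_idx] = True

    n_px = int(round(side / pixel_size_um))
    iba1 = np.zeros((n_px, n_px))
    nuclei = np.zeros((n_px, n_px))
    fitc = np.zeros((n_px, n_px))
    cell_mask = np.zeros((n_px, n_px), dtype=bool)
    nuc_mask = np.zeros((n_px, n_px), dtype=bool)
    for i, (cx, cy) in enumerate(centers_arr):
        _stamp_disk(cell_mask, cx, cy, cell_radius_um, pixel_size_um)
        _stamp_disk(nuc_mask, cx, cy, 2.0, pixel_size_um)
        if positive[i]:
            for _ in range(n_puncta_per_cell):
                d = rng.uniform(0, 0.5 * cell_radius_um)
                a = rng.uniform(0, 2 * np.pi)
                pm = np.zeros_like(cell_mask)
                _stamp_disk(
                    pm,
                    cx + d * np.cos(a),
                    cy + d * np.sin(a),
                    punctum_radius_um,
                    pixel_size_um,
                )
                fitc[pm] = puncta_intensity
    iba1[cell_mask] = CELL_AMP
    nuclei[nuc_mask] = NUCLEUS_AMP

    pixels = np.stack([iba1, nuclei, fitc])[:, None, :, :]
    sigma = psf_sigma_um / pixel_size_um
    if sigma > 0:
        pixels = gaussian_filter(pixels, sigma=(0, 0, sigma, sigma))
    if noise_sd > 0:
        pixels = pixels + rng.normal(0, noise_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0, None)

    stack = ImageStack(
        pixels, pixel_size_um, 1.0, {"iba1": 0, "nuclei": 1, "fitc": 2}
    )
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cells + 1),
            "x_um": centers_arr[:, 0],
            "y_um": centers_arr[:, 1],
            "positive": positive,
        }
    )
    return stack, GroundTruth(cells=cells)


# ------------------------------------------------------------------- counts


@dataclass
class CountSimSpec:
    """Negative-binomial miRNA count simulation.

    Defaults emulate the screened cohort: 11 case vs 14 control samples,
    moderate plasma-miRNA biological dispersion (0.15), baseline abundances
    log2-uniform over ``mean_log_range``, 10% DE features at log2FC 2.
    """

    n_case: int = 11
    n_control: int = 14
    n_mirna: int = 300
    dispersion: float = 0.15
    mean_log_range: tuple[float, float] = (3.0, 10.0)  # log2 counts
    frac_de: float = 0.1
    log2fc_de: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_de <= 1:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def simulate_count_matrix(
    spec: CountSimSpec,
) -> tuple[CountMatrix, GroundTruth]:
    """Simulate a miRNA count matrix with known DE labels.

    DE features have their case-group mean multiplied by 2**log2fc_de
    (expected log2 fold change = log2fc_de); null features have none.
    Per-sample depth factors vary log-uniformly over [0.7, 1.4].
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_case + spec.n_control
    base = 2.0 ** rng.uniform(*spec.mean_log_range, size=spec.n_mirna)
    n_de = int(round(spec.frac_de * spec.n_mirna))
    de_idx = np.sort(rng.permutation(spec.n_mirna)[:n_de])
    is_de = np.zeros(spec.n_mirna, dtype=bool)
    is_de[de_idx] = True
    lfc = np.where(is_de, spec.log2fc_de, 0.0)

    depth = np.exp(rng.uniform(np.log(0.7), np.log(1.4), size=n))
    groups = [CASE] * spec.n_case + [CONTROL] * spec.n_control
    mu = base[:, None] * depth[None, :]
    mu[:, : spec.n_case] *= (2.0**lfc)[:, None]

    if spec.dispersion <= 0:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / spec.dispersion
        counts = rng.negative_binomial(size, size / (size + mu))

    sample_ids = [f"case_{i + 1:02d}" for i in range(spec.n_case)] + [
        f"ctrl_{i + 1:02d}" for i in range(spec.n_control)
    ]
    feature_ids = [f"mir_{i + 1:04d}" for i in range(spec.n_mirna)]
    cm = CountMatrix(
        pd.DataFrame(counts, index=feature_ids, columns=sample_ids),
        pd.Series(groups, index=sample_ids),
    )
    truth = GroundTruth(
        mirna=pd.DataFrame(
            {"feature_id": feature_ids, "is_de": is_de, "log2fc": lfc}
        )
    )
    return cm, truth


def config_to_dict(cfg) -> dict:
    """Serializable dict view of a config dataclass (for YAML/JSON dumps)."""
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
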