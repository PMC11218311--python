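import numpy as np
import pytest

import neuroquant as nq


def make_scene(
    seed: int,
    coverage: float,
    radius_um: float = 7.0,
    dens_cov: float = 0.05,
    dens_unc: float = 0.25,
    field_um: float = 70.0,
    noise_sd: float = 4.0,
    n_somata: int = 0,
    n_background: int = 0,
):
    """One centered plaque with a single covered arc of the given total
    coverage at a seeded random orientation."""
    rng = np.random.default_rng(seed)
    if coverage >= 1.0:
        intervals = [(0.0, 360.0)]
    elif coverage <= 0.0:
        intervals = []
    else:
        start = float(rng.uniform(0, 360 - coverage * 360))
        intervals = [(start, start + coverage * 360)]
    cfg = nq.SimConfig(
        field_size_um=(field_um, field_um), seed=seed, noise_sd=noise_sd
    )
    spec = nq.PlaqueSpec(
        center_um=(field_um / 2, field_um / 2),
        radius_um=radius_um,
        covered_intervals_deg=intervals,
        lamp1_density_covered=dens_cov,
        lamp1_density_uncovered=dens_unc,
        n_somata_within_25um=n_somata,
        n_somata_background=n_background,
    )
    stack, truth = nq.simulate_histology_stack(cfg, [spec])
    return cfg, spec, stack, truth


def analyze_scene(cfg, stack):
    """Projection → segmentation → angular profile → coverage + dystrophy
    for a single-plaque scene."""
    proj = nq.project_central_slices(stack, stack.n_slices // 2)
    plq = nq.segment_plaques(
        proj[stack.channel_roles["plaque"]], cfg.pixel_size_um
    )
    assert len(plq) == 1
    prof = nq.build_angular_profile(
        proj[stack.channel_roles["iba1"]],
        proj[stack.channel_roles["lamp1"]],
        plq[0],
        cfg.pixel_size_um,
    )
    cov = nq.microglia_coverage(prof)
    dys = nq.dystrophy_by_sector(
        proj[stack.channel_roles["lamp1"]], prof, cov, plq[0],
        cfg.pixel_size_um,
    )
    return proj, plq[0], prof, cov, dys


@pytest.fixture
def single_plaque_scene():
    return make_scene(seed=3, coverage=0.5)
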