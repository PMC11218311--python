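"""Sholl analysis of neuronal arborization.

Intersections of neurites with concentric circles (spheres in 3D) centered
on the soma, sampled at a fixed radial increment (default 5 µm), summarized
by the area under the intersection-count curve.  Two input routes are
supported: reconstructed morphologies in SWC format, and 2D binary masks of
a filled neuron (e.g. a thresholded fluorescence image).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import circle_perimeter

SWC_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]

#: SWC structure-type codes (subset used here)
SWC_SOMA = 1
SWC_AXON = 2
SWC_BASAL = 3
SWC_APICAL = 4


@dataclass
class NeuronMorphology:
    """A rooted neuronal tree in SWC convention.

    ``nodes`` is a DataFrame with columns id, type, x, y, z, radius, parent
    (coordinates in µm; parent -1 marks the root).  The root is the soma.
    """

    nodes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SWC_COLUMNS if c not in self.nodes.columns]
        if missing:
            raise ValueError(f"morphology missing columns: {missing}")
        nodes = self.nodes.reset_index(drop=True)
        if nodes["id"].duplicated().any():
            raise ValueError("duplicate node ids")
        roots = nodes.index[nodes["parent"] == -1]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        if not np.isfinite(nodes[["x", "y", "z"]].to_numpy()).all():
            raise ValueError("non-finite coordinates")
        # cycle / dangling-parent check: every node must reach the root
        parent_of = dict(zip(nodes["id"], nodes["parent"]))
        for nid in nodes["id"]:
            seen = set()
            cur = nid
            while cur != -1:
                if cur in seen:
                    raise ValueError(f"cyclic parent links at node {nid}")
                seen.add(cur)
                if cur not in parent_of:
                    raise ValueError(f"node {nid} has dangling ancestor {cur}")
                cur = parent_of[cur]
        self.nodes = nodes

    @property
    def soma(self) -> pd.Series:
        return self.nodes.loc[self.nodes["parent"] == -1].iloc[0]

    @property
    def soma_xyz(self) -> np.ndarray:
        s = self.soma
        return np.array([s["x"], s["y"], s["z"]], dtype=float)


@dataclass
class ShollProfile:
    """Intersection counts on concentric circles plus AUC summary."""

    radii_um: np.ndarray
    intersections: np.ndarray
    auc: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.radii_um = np.asarray(self.radii_um, dtype=float)
        self.intersections = np.asarray(self.intersections, dtype=int)
        if self.radii_um.shape != self.intersections.shape:
            raise ValueError("radii and counts length mismatch")
        if len(self.radii_um) > 1 and not np.all(np.diff(self.radii_um) > 0):
            raise ValueError("radii must be strictly increasing")
        if np.any(self.intersections < 0):
            raise ValueError("negative intersection count")
        if self.auc is None:
            self.auc = (
                float(np.trapezoid(self.intersections, self.radii_um))
                if len(self.radii_um) >= 2
                else 0.0
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"radius_um": self.radii_um, "intersections": self.intersections}
        )


def read_swc(path) -> NeuronMorphology:
    """Read a standard 7-column SWC file ('#' comments allowed)."""
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None, names=SWC_COLUMNS
    )
    df = df.astype(
        {"id": int, "type": int, "parent": int, "x": float, "y": float,
         "z": float, "radius": float}
    )
    return NeuronMorphology(df)


def write_swc(morph: NeuronMorphology, path) -> None:
    buf = io.StringIO()
    buf.write("# id type x y z radius parent\n")
    for _, row in morph.nodes.iterrows():
        buf.write(
            f"{int(row['id'])} {int(row['type'])} {row['x']:.4f} "
            f"{row['y']:.4f} {row['z']:.4f} {row['radius']:.4f} "
            f"{int(row['parent'])}\n"
        )
    Path(path).write_text(buf.getvalue())


def _radius_grid(delta_r_um: float, max_r_um: float) -> np.ndarray:
    n = max(1, int(np.ceil(max_r_um / delta_r_um - 1e-9)))
    return delta_r_um * np.arange(1, n + 1)


def sholl_from_swc(
    morph: NeuronMorphology,
    delta_r_um: float = 5.0,
    max_r_um: float | None = None,
    types: list[int] | None = None,
) -> ShollProfile:
    """Sholl profile from an SWC tree by exact segment–sphere intersection.

    Each parent→child edge is a straight segment; for every radius the number
    of roots of ``|p(t)| = r`` with t in (0, 1] is counted (t = 0 excluded so
    a crossing at a shared node is attributed to a single edge).  ``types``
    optionally restricts to SWC structure codes (e.g. ``[SWC_BASAL]`` for
    basal dendrites); the soma node itself never contributes.
    """
    nodes = morph.nodes
    soma = morph.soma_xyz
    xyz = nodes[["x", "y", "z"]].to_numpy(dtype=float) - soma
    idx_of = {nid: i for i, nid in enumerate(nodes["id"])}

    child = nodes.index[nodes["parent"] != -1]
    if types is not None:
        child = child[nodes.loc[child, "type"].isin(types)]
    a = np.array([xyz[idx_of[nodes.loc[i, "parent"]]] for i in child]) if len(
        child
    ) else np.zeros((0, 3))
    b = xyz[child.to_numpy()] if len(child) else np.zeros((0, 3))

    dists = np.linalg.norm(xyz, axis=1)
    if max_r_um is None:
        far = dists.max() if len(dists) else 0.0
        max_r_um = max(delta_r_um, np.ceil(far / delta_r_um) * delta_r_um)
    if max_r_um < delta_r_um:
        raise ValueError("max_r_um must be at least delta_r_um")
    radii = _radius_grid(delta_r_um, max_r_um)

    if len(child) == 0:
        return ShollProfile(radii, np.zeros(len(radii), dtype=int))

    u = b - a
    A = np.einsum("ij,ij->i", u, u)  # |u|^2
    B = 2.0 * np.einsum("ij,ij->i", a, u)
    C0 = np.einsum("ij,ij->i", a, a)

    counts = np.zeros(len(radii), dtype=int)
    eps = 1e-12
    for k, r in enumerate(radii):
        C = C0 - r * r
        n_cross = np.zeros(len(A), dtype=int)
        nz = A > eps
        D = B[nz] ** 2 - 4 * A[nz] * C[nz]
        pos = D > eps
        sq = np.zeros_like(D)
        sq[pos] = np.sqrt(D[pos])
        t1 = (-B[nz] - sq) / (2 * A[nz])
        t2 = (-B[nz] + sq) / (2 * A[nz])
        in1 = (t1 > eps) & (t1 <= 1 + eps)
        in2 = (t2 > eps) & (t2 <= 1 + eps)
        c = np.where(D > eps, in1.astype(int) + in2.astype(int), 0)
        # tangency: single touching point
        tang = np.abs(D) <= eps
        c = np.where(tang & in1, 1, c)
        n_cross[nz] = c
        counts[k] = int(n_cross.sum())
    return ShollProfile(radii, counts)


def _circle_runs(mask: np.ndarray, r0: int, c0: int, radius_px: int) -> int:
    """Count 8-connected foreground clusters on a rasterized circle.

    The circle is drawn with the Andres midpoint variant (no diagonal
    holes, so any 8-connected curve crossing the ring shares a pixel with
    it); an intersection is one connected component of ring ∩ mask.
    """
    rr, cc = circle_perimeter(r0, c0, radius_px, method="andres",
                              shape=mask.shape)
    if len(rr) == 0:
        return 0
    ring = np.zeros_like(mask, dtype=bool)
    ring[rr, cc] = True
    hit = ring & mask
    if not hit.any():
        return 0
    from skimage.measure import label as _label

    return int(_label(hit, connectivity=2).max())


def sholl_from_mask(
    mask: np.ndarray,
    soma_xy_um: tuple[float, float],
    pixel_size_um: float,
    delta_r_um: float = 5.0,
    max_r_um: float | None = None,
) -> ShollProfile:
    """Sholl profile from a 2D binary mask.

    Circles are rasterized with the midpoint algorithm; an intersection is a
    maximal 8-connected run of foreground pixels along the circle path.
    ``soma_xy_um`` is the (x, y) soma position in physical coordinates
    (x along columns, y along rows, pixel centers at (i + 0.5) * pixel size).
    """
    mask = np.asarray(mask, dtype=bool)
    x0, y0 = soma_xy_um
    c0 = int(x0 / pixel_size_um)
    r0 = int(y0 / pixel_size_um)
    if not (0 <= r0 < mask.shape[0] and 0 <= c0 < mask.shape[1]):
        raise ValueError("soma position outside image")
    if max_r_um is None:
        far = (
            max(mask.shape[0], mask.shape[1]) * pixel_size_um
        )
        max_r_um = np.ceil(far / delta_r_um) * delta_r_um
    radii = _radius_grid(delta_r_um, max_r_um)
    counts = np.array(
        [
            _circle_runs(mask, r0, c0, max(1, int(round(r / pixel_size_um))))
            for r in radii
        ],
        dtype=int,
    )
    return ShollProfile(radii, counts)


def profile_auc(profile: ShollProfile, method: str = "trapezoid") -> float:
    """Area under the Sholl curve (µm·count).

    ``method`` is "trapezoid" (default) or "sum" (counts × Δr).
    """
    if len(profile.radii_um) < 2:
        raise ValueError("AUC requires at least two radii")
    if method == "trapezoid":
        return float(np.trapezoid(profile.intersections, profile.radii_um))
    if method == "sum":
        dr = float(np.diff(profile.radii_um).mean())
        return float(profile.intersections.sum() * dr)
    raise ValueError(f"unknown AUC method: {method}")
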