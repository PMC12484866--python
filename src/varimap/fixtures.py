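"""Seeded generators for every input class the toolkit consumes.

All generators are pure functions of their parameters and seed (identical
output across runs), so the full test suite and the worked examples run
without any external download.  Geometry is desk-scale: coordinates in mm,
particle counts in the hundreds to low thousands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lddmm import AtlasMeasure, FlowKernel, GeodesicState, shoot
from .rigid import RigidParams, SectionStack, apply_rigid
from .varifold import FeatureSpace, ParticleMeasure

__all__ = [
    "PhantomSpec",
    "make_fig2a_toy",
    "make_known_deformation_pair",
    "make_striped_gene_field",
    "make_censored_slab",
    "make_section_stack",
    "make_curvilinear_arc",
    "make_four_region_phantom",
    "make_fixture",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Named phantom with geometry parameters and a seed."""

    kind: str
    seed: int = 0
    params: tuple = ()  # (key, value) pairs; hashable

    def as_dict(self) -> dict:
        return dict(self.params)


def _grid2d(n: int, extent: float = 1.0, center: bool = True) -> np.ndarray:
    """n x n cell centers in the plane (z = 0)."""
    edges = (np.arange(n) + 0.5) / n * extent
    if center:
        edges = edges - extent / 2.0
    xx, yy = np.meshgrid(edges, edges, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])


def make_fig2a_toy(n_grid: int = 32, extent: float = 1.0):
    """Toy cross-modality pair: three-region atlas vs two-feature target.

    The atlas is a square parcelled into three asymmetric homogeneous
    regions over features {R, G, B}; the target shares the square's outline
    but its homogeneous {black, white} regions correspond to the atlas
    partition rotated by half a turn.  Both are discretized as identical
    particle grids centered at the origin, so a 180-degree rotation maps
    grid points onto grid points exactly.
    """
    pos = _grid2d(n_grid, extent)
    x, y = pos[:, 0], pos[:, 1]
    w = np.full(len(pos), (extent / n_grid) ** 2)

    # asymmetric partition: left half | upper-right | lower-right
    split_y = 0.1 * extent
    region = np.where(x < 0, 0, np.where(y >= split_y, 1, 2))
    region_space = FeatureSpace(("R", "G", "B"))
    pi = np.eye(3)[region]

    target_space = FeatureSpace(("black", "white"))
    # target layout = atlas partition under a half-turn; regions R and B
    # express black, region G expresses white
    region_rot = np.where(-x < 0, 0, np.where(-y >= split_y, 1, 2))
    color = np.where(region_rot == 1, 1, 0)  # 1 = white
    target = ParticleMeasure(pos, w, np.eye(2)[color], target_space,
                             normalized=True)
    atlas = AtlasMeasure(pos, w, pi, region_space, target_space)
    return atlas, target


def make_known_deformation_pair(seed: int = 0, n_side: int = 4,
                                flow_sigma: float = 0.3,
                                momenta_scale: float = 0.02,
                                n_steps: int = 10):
    """A measure, its deformation under a known geodesic, and the true momenta.

    Particles carry count-scale unit masses (as aggregated cell data do).
    Momenta are drawn at a scale small relative to the flow bandwidth; if the
    shot degenerates (nonpositive Jacobian) the momenta are halved and the
    shot repeated.
    """
    rng = np.random.default_rng(seed)
    g = (np.arange(n_side) + 0.5) / n_side
    xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
    pos = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    n = len(pos)
    w = np.ones(n)
    labels = (pos[:, 0] < 0.5).astype(int)
    space = FeatureSpace(("A", "B"))
    mu = ParticleMeasure(pos, w, np.eye(2)[labels], space, normalized=True)

    fk = FlowKernel(flow_sigma)
    rho_x = momenta_scale * rng.standard_normal((n, 3))
    rho_w = 0.1 * momenta_scale * rng.standard_normal(n)
    while True:
        try:
            _, diffeo = shoot(GeodesicState(pos, w, rho_x, rho_w), fk, n_steps)
        except FloatingPointError:
            rho_x, rho_w = rho_x / 2, rho_w / 2
            continue
        if np.all(diffeo.jacobian_dets > 0):
            break
        rho_x, rho_w = rho_x / 2, rho_w / 2
    deformed = ParticleMeasure(diffeo.mapped_positions,
                               diffeo.jacobian_dets * w,
                               mu.feature_dists.copy(), space, normalized=True)
    return mu, deformed, (rho_x, rho_w)


def make_striped_gene_field(seed: int = 0, mean_total: int = 3000,
                            extent: float = 1.0, band_width: float = 0.2,
                            contrast: float = 5.0) -> pd.DataFrame:
    """Detection table with one striped and one uniform gene, matched totals.

    ``striped`` follows an inhomogeneous Poisson field with alternating
    vertical bands of intensity ratio ``contrast``; ``uniform`` is spatially
    homogeneous with the same expected total.
    """
    rng = np.random.default_rng(seed)
    rows = []
    # striped gene: piecewise-constant intensity over vertical bands
    n_a = rng.poisson(mean_total)
    n_bands = int(np.ceil(extent / band_width))
    band_rate = np.where(np.arange(n_bands) % 2 == 0, contrast, 1.0)
    band_prob = band_rate / band_rate.sum()
    band_of = rng.choice(n_bands, size=n_a, p=band_prob)
    xa = np.minimum((band_of + rng.random(n_a)) * band_width, extent)
    ya = rng.random(n_a) * extent
    rows.append(pd.DataFrame({"x": xa, "y": ya, "feature": "striped"}))
    # uniform gene
    n_b = rng.poisson(mean_total)
    rows.append(pd.DataFrame({
        "x": rng.random(n_b) * extent,
        "y": rng.random(n_b) * extent,
        "feature": "uniform",
    }))
    return pd.concat(rows, ignore_index=True)


def make_censored_slab(seed: int = 0, nx: int = 10, nyz: int = 3,
                       length: float = 10.0, width: float = 2.25,
                       support_end: float = 5.0,
                       flow_sigma: float = 1.0,
                       momenta_scale: float = 0.2):
    """Full slab atlas and a half-covered, mildly deformed target.

    Brain-scale geometry (mm): the atlas spans [0, length] along the
    rostral-caudal x axis; the target keeps only particles with
    x < ``support_end`` and deforms them by a known small geodesic, so the
    support is long relative to the preferred censor bandwidth
    lambda ~ sqrt(0.1) mm.  Returns (atlas measure, target measure,
    (a0, n0, a1, n1)) with the true support planes in target coordinates.
    """
    rng = np.random.default_rng(seed)
    gx = (np.arange(nx) + 0.5) / nx * length
    gy = (np.arange(nyz) + 0.5) / nyz * width
    xx, yy, zz = np.meshgrid(gx, gy, gy, indexing="ij")
    pos = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    n = len(pos)
    w = np.ones(n)  # count-scale masses, as aggregated data carry
    quad = 2 * (pos[:, 1] >= width / 2).astype(int) + (pos[:, 2] >= width / 2)
    space = FeatureSpace(("q00", "q01", "q10", "q11"))
    feats = np.eye(4)[quad]
    atlas_mu = ParticleMeasure(pos, w, feats, space, normalized=True)

    inside = pos[:, 0] < support_end
    sub_pos = pos[inside]
    sub_w = w[inside]
    fk = FlowKernel(flow_sigma)
    rho_x = momenta_scale * rng.standard_normal((len(sub_pos), 3))
    # damp momenta within 2 sigma of the support boundary: the deformation
    # is interior to the measured volume, as tissue deformations are
    damp = np.clip((support_end - sub_pos[:, 0]) / (2 * flow_sigma), 0.0, 1.0)
    rho_x *= damp[:, None] ** 2
    rho_w = np.zeros(len(sub_pos))
    while True:
        try:
            _, diffeo = shoot(GeodesicState(sub_pos, sub_w, rho_x, rho_w),
                              fk, 10)
        except FloatingPointError:
            rho_x = rho_x / 2
            continue
        if np.all(diffeo.jacobian_dets > 0):
            break
        rho_x = rho_x / 2
    target = ParticleMeasure(diffeo.mapped_positions,
                             diffeo.jacobian_dets * sub_w,
                             feats[inside], space, normalized=True)
    planes = (np.zeros(3), np.array([1.0, 0.0, 0.0]),
              np.array([support_end, 0.0, 0.0]), np.array([-1.0, 0.0, 0.0]))
    return atlas_mu, target, planes


def _c_shape(seed: int, n_points: int = 150) -> tuple[np.ndarray, np.ndarray]:
    """Asymmetric C-shaped 2D point cloud (centered) with 2 labels."""
    rng = np.random.default_rng(seed)
    ang = rng.uniform(np.deg2rad(40), np.deg2rad(320), n_points)
    rad = rng.uniform(0.5, 1.0, n_points)
    pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang),
                           np.zeros(n_points)])
    blob = rng.normal([0.55, 0.55, 0.0], [0.06, 0.06, 0.0], (n_points // 5, 3))
    pts = np.vstack([pts, blob])
    labels = (np.arctan2(pts[:, 1], pts[:, 0]) > 0).astype(int)
    pts = pts - pts.mean(axis=0)
    return pts, labels


def make_section_stack(seed: int = 0, n_sections: int = 5,
                       max_angle_deg: float = 8.0,
                       spacing: float = 0.2):
    """Identical asymmetric sections with known rigid perturbations.

    Returns (stack, true RigidParams).  Ends carry the identity; recovered
    interior angles should invert the true ones (translations are absorbed
    by the per-section centering of the stack).
    """
    rng = np.random.default_rng(seed)
    pts, labels = _c_shape(seed)
    space = FeatureSpace(("inner", "outer"))
    w = np.full(len(pts), 1.0 / len(pts))
    base = ParticleMeasure(pts, w, np.eye(2)[labels], space, normalized=True)

    thetas = np.zeros(n_sections)
    taus = np.zeros((n_sections, 2))
    sections = []
    for s in range(n_sections):
        if 0 < s < n_sections - 1:
            thetas[s] = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg))
            taus[s] = rng.uniform(-0.05, 0.05, 2)
        sections.append(apply_rigid(base, thetas[s], taus[s]))
    return SectionStack(sections, spacing), RigidParams(thetas, taus)


def make_curvilinear_arc(seed: int = 0, n_points: int = 600,
                         radius: float = 1.0, thickness: float = 0.02):
    """Thin quarter-circle arc with two features split along arc length."""
    rng = np.random.default_rng(seed)
    ang = rng.uniform(0, np.pi / 2, n_points)
    rad = radius + rng.uniform(-thickness, thickness, n_points)
    pos = np.column_stack([rad * np.cos(ang), rad * np.sin(ang),
                           np.zeros(n_points)])
    labels = (ang > np.pi / 4).astype(int)
    space = FeatureSpace(("proximal", "distal"))
    w = np.full(n_points, 1.0 / n_points)
    return ParticleMeasure(pos, w, np.eye(2)[labels], space, normalized=True)


def make_four_region_phantom(n_grid: int = 10, extent: float = 1.0):
    """Atlas with four quadrant regions and a target whose features are
    concentrated per region -- the law-recovery test bed."""
    pos = _grid2d(n_grid, extent, center=False)
    w = np.full(len(pos), (extent / n_grid) ** 2)
    quad = 2 * (pos[:, 0] >= extent / 2).astype(int) + \
        (pos[:, 1] >= extent / 2).astype(int)
    region_space = FeatureSpace(("r0", "r1", "r2", "r3"))
    target_space = FeatureSpace(("f0", "f1", "f2", "f3"))
    pi = np.eye(4)[quad]
    atlas = AtlasMeasure(pos, w, pi, region_space, target_space)
    target = ParticleMeasure(pos, w, np.eye(4)[quad], target_space,
                             normalized=True)
    return atlas, target


_KINDS = {
    "fig2a_toy": lambda spec: make_fig2a_toy(**spec.as_dict()),
    "known_deformation_pair":
        lambda spec: make_known_deformation_pair(seed=spec.seed, **spec.as_dict()),
    "striped_gene_field":
        lambda spec: make_striped_gene_field(seed=spec.seed, **spec.as_dict()),
    "censored_slab":
        lambda spec: make_censored_slab(seed=spec.seed, **spec.as_dict()),
    "section_stack":
        lambda spec: make_section_stack(seed=spec.seed, **spec.as_dict()),
    "curvilinear_arc":
        lambda spec: make_curvilinear_arc(seed=spec.seed, **spec.as_dict()),
    "nested_regions": lambda spec: make_four_region_phantom(**spec.as_dict()),
}


def make_fixture(spec: PhantomSpec):
    """Dispatch a PhantomSpec to its generator."""
    if spec.kind not in _KINDS:
        raise ValueError(f"unknown phantom kind {spec.kind!r}; "
                         f"choose from {sorted(_KINDS)}")
    return _KINDS[spec.kind](spec)
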