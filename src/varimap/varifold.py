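"""Image-varifold measures and the kernel metric between them.

A spatial-omics dataset (mRNA detections, segmented cells, or an annotated
atlas) is represented as a weighted particle measure on position x feature
space: each particle ``i`` carries a mass ``w_i`` at a 3D location ``x_i``
(in millimeters) together with a distribution ``p_i`` over a shared discrete
feature space (genes, cell types, region labels).  Closeness between two such
measures is measured in a reproducing-kernel Hilbert space whose kernel is
the product of a spatial Gaussian (possibly a sum of Gaussians at several
bandwidths) and a feature kernel::

    <mu, nu> = sum_{i,j} w_i u_j K_sigma(x_i, y_j) <p_i, q_j>_F

For discrete labels the feature kernel is the identity indicator, so
``<p_i, q_j>_F`` is the plain dot product of the (possibly unnormalized)
feature vectors; real-valued feature vectors use the Euclidean inner product,
which is the same computation.

All coordinates and bandwidths are in millimeters.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

__all__ = [
    "FeatureSpace",
    "SpaceKernel",
    "FeatureKernel",
    "ParticleMeasure",
    "DiffeoSample",
    "space_kernel_eval",
    "inner_product",
    "norm_distance_sq",
    "apply_varifold_action",
    "distance_sq_with_grads",
]


@dataclass(frozen=True)
class FeatureSpace:
    """Ordered set of feature identifiers (genes, cell types, region labels)."""

    labels: tuple[str, ...]
    kind: str = "discrete"  # "discrete" | "real"

    def __post_init__(self):
        labels = tuple(str(label) for label in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) == 0:
            raise ValueError("feature space must be non-empty")
        if len(set(labels)) != len(labels):
            raise ValueError("feature labels must be unique")
        if self.kind not in ("discrete", "real"):
            raise ValueError(f"unknown feature-space kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class SpaceKernel:
    """Sum of Gaussians K(x, y) = sum_c a_c exp(-|x-y|^2 / (2 sigma_c^2)).

    ``components`` is a sequence of (bandwidth sigma in mm, nonnegative
    weight) pairs.  A two-component kernel at 0.15 and 0.75 mm is the typical
    multi-scale choice for whole-brain mapping.
    """

    components: tuple[tuple[float, float], ...] = ((1.0, 1.0),)

    def __post_init__(self):
        comps = tuple((float(s), float(a)) for s, a in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValueError("kernel needs at least one component")
        if any(s <= 0 for s, _ in comps):
            raise ValueError("kernel bandwidths must be positive")
        if any(a < 0 for _, a in comps):
            raise ValueError("kernel component weights must be nonnegative")

    def __call__(self, sqdist: np.ndarray) -> np.ndarray:
        """Evaluate on a (complex-safe) array of squared distances."""
        out = None
        for sigma, a in self.components:
            term = a * np.exp(-sqdist / (2.0 * sigma**2))
            out = term if out is None else out + term
        return out

    def grad_scale(self, sqdist: np.ndarray) -> np.ndarray:
        """Scalar g(r2) such that grad_x K(x,y) = g(|x-y|^2) (x - y)."""
        out = None
        for sigma, a in self.components:
            term = -a / sigma**2 * np.exp(-sqdist / (2.0 * sigma**2))
            out = term if out is None else out + term
        return out

    @property
    def value_at_zero(self) -> float:
        return sum(a for _, a in self.components)


@dataclass(frozen=True)
class FeatureKernel:
    """Feature kernel: identity indicator for labels, Euclidean for vectors.

    Both reduce to a dot product between per-particle feature vectors; the
    kind is kept so measures declare how their feature axis is interpreted.
    """

    kind: str = "identity"  # "identity" | "euclidean"

    def __post_init__(self):
        if self.kind not in ("identity", "euclidean"):
            raise ValueError(f"unknown feature kernel kind {self.kind!r}")


def _as_positions(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[-1] != 3:
        raise ValueError("positions must be 3D (shape (n, 3))")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    return x


@dataclass
class ParticleMeasure:
    """Weighted Diracs in 3D, each carrying a feature distribution.

    ``feature_dists`` rows may be normalized probability laws or unnormalized
    (weighted) laws; the flag records which, and the metric uses them exactly
    as stored -- no silent renormalization.
    """

    positions: np.ndarray  # (n, 3) mm
    weights: np.ndarray  # (n,)
    feature_dists: np.ndarray  # (n, |F|)
    feature_space: FeatureSpace
    normalized: bool = True

    def __post_init__(self):
        self.positions = _as_positions(self.positions)
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.feature_dists = np.atleast_2d(np.asarray(self.feature_dists, dtype=float))
        n = len(self.positions)
        if len(self.weights) != n or len(self.feature_dists) != n:
            raise ValueError("positions, weights and feature_dists must agree in length")
        if self.feature_dists.shape[1] != len(self.feature_space):
            raise ValueError("feature_dists width must match the feature space")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if self.normalized:
            sums = self.feature_dists.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("normalized measure with rows not summing to 1")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def total_mass(self) -> float:
        return float(self.weights.sum())

    def weighted_laws(self) -> np.ndarray:
        """Per-particle feature vectors scaled by mass, w_i p_i -- the
        quantity entering the metric together with unit weights."""
        return self.weights[:, None] * self.feature_dists

    def copy(self) -> "ParticleMeasure":
        return ParticleMeasure(
            self.positions.copy(), self.weights.copy(), self.feature_dists.copy(),
            self.feature_space, self.normalized,
        )


@dataclass
class DiffeoSample:
    """A diffeomorphism sampled at particle locations: phi(x_i) and |Dphi|_{x_i}."""

    mapped_positions: np.ndarray  # (n, 3)
    jacobian_dets: np.ndarray  # (n,)

    def __post_init__(self):
        self.mapped_positions = _as_positions(self.mapped_positions)
        self.jacobian_dets = np.asarray(self.jacobian_dets, dtype=float).ravel()
        if len(self.jacobian_dets) != len(self.mapped_positions):
            raise ValueError("mapped_positions and jacobian_dets must agree in length")


# ---------------------------------------------------------------------------
# Kernel and metric evaluation


def space_kernel_eval(kernel: SpaceKernel, x, y) -> np.ndarray:
    """K_sigma(x, y) for 3D points (broadcasting over leading axes)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite coordinates")
    sq = np.sum((x - y) ** 2, axis=-1)
    return kernel(sq)


def _sqdist(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pairwise squared distances, complex-step safe (no abs)."""
    d = x[:, None, :] - y[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


def _check_spaces(mu: ParticleMeasure, nu: ParticleMeasure) -> None:
    if mu.feature_space != nu.feature_space:
        raise ValueError("measures live on different feature spaces")


def cross_gram(
    x: np.ndarray, a: np.ndarray, y: np.ndarray, b: np.ndarray,
    ks: SpaceKernel, cutoff: float | None = None,
) -> float:
    """sum_{i,m} K_sigma(x_i, y_m) <a_i, b_m> for weighted feature rows a, b.

    ``cutoff`` (mm) zeroes kernel terms between particles farther apart,
    mirroring the 4-sigma truncation used at scale; exact when None.
    """
    sq = _sqdist(x, y)
    kmat = ks(sq)
    if cutoff is not None:
        kmat = np.where(sq.real > cutoff**2, 0.0, kmat)
    return np.einsum("im,if,mf->", kmat, a, b)


def inner_product(
    mu: ParticleMeasure, nu: ParticleMeasure,
    ks: SpaceKernel, kf: FeatureKernel = FeatureKernel(),
    cutoff: float | None = None,
) -> float:
    """Varifold inner product <mu, nu>_M under the product kernel."""
    _check_spaces(mu, nu)
    del kf  # identity and euclidean kinds share the dot-product reduction
    return float(
        cross_gram(mu.positions, mu.weighted_laws(), nu.positions, nu.weighted_laws(),
                   ks, cutoff=cutoff)
    )


def norm_distance_sq(
    mu: ParticleMeasure, nu: ParticleMeasure,
    ks: SpaceKernel, kf: FeatureKernel = FeatureKernel(),
    cutoff: float | None = None,
) -> float:
    """Squared varifold distance |mu - nu|_M^2 = <mu,mu> - 2<mu,nu> + <nu,nu>."""
    return (
        inner_product(mu, mu, ks, kf, cutoff=cutoff)
        - 2.0 * inner_product(mu, nu, ks, kf, cutoff=cutoff)
        + inner_product(nu, nu, ks, kf, cutoff=cutoff)
    )


def apply_varifold_action(mu: ParticleMeasure, phi: DiffeoSample) -> ParticleMeasure:
    """Push a measure through a diffeomorphism: positions move to phi(x_i),
    masses pick up the local volume change |Dphi|, laws are unchanged."""
    if len(phi.mapped_positions) != len(mu):
        raise ValueError("diffeomorphism sample length does not match measure")
    if np.any(phi.jacobian_dets <= 0):
        raise ValueError("nonpositive Jacobian determinant (degenerate or "
                         "orientation-reversing map)")
    return ParticleMeasure(
        positions=phi.mapped_positions.copy(),
        weights=phi.jacobian_dets * mu.weights,
        feature_dists=mu.feature_dists.copy(),
        feature_space=mu.feature_space,
        normalized=mu.normalized,
    )


# ---------------------------------------------------------------------------
# Analytic gradients of the squared distance (shared by the mapping and
# resampling optimizers).


def distance_sq_with_grads(
    x: np.ndarray, w: np.ndarray, u: np.ndarray,
    y: np.ndarray, m: np.ndarray, b: np.ndarray,
    ks: SpaceKernel,
):
    """E = | sum_i w_i delta_{x_i} (x) u_i  -  sum_m m_m delta_{y_m} (x) b_m |_M^2
    together with dE/dx, dE/dw, dE/du (the target side y, m, b is fixed).

    ``u`` and ``b`` are per-particle feature vectors (laws, possibly
    unnormalized); the effective weighted law is w_i u_i.
    """
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    u = np.atleast_2d(np.asarray(u, float))
    y = np.asarray(y, float)
    m = np.asarray(m, float)
    b = np.atleast_2d(np.asarray(b, float))

    sq_xx = _sqdist(x, x)
    sq_xy = _sqdist(x, y)
    k_xx = ks(sq_xx)
    k_xy = ks(sq_xy)
    f_xx = u @ u.T  # <u_i, u_j>
    f_xy = u @ b.T  # <u_i, b_m>

    ww = np.outer(w, w)
    wm = np.outer(w, m)
    self_term = np.sum(k_xx * ww * f_xx)
    cross_term = np.sum(k_xy * wm * f_xy)
    target_term = np.einsum("mn,m,n,mn->", ks(_sqdist(y, y)), m, m, b @ b.T)
    energy = self_term - 2.0 * cross_term + target_term

    # dE/dw
    dw = 2.0 * (k_xx * f_xx) @ w - 2.0 * (k_xy * f_xy) @ m

    # dE/du_i = 2 w_i [ sum_j w_j k_ij u_j - sum_m m_m k_im b_m ]
    du = 2.0 * w[:, None] * ((k_xx * w[None, :]) @ u - (k_xy * m[None, :]) @ b)

    # dE/dx_i = 2 w_i [ sum_j w_j f_xx_ij g(r2_ij)(x_i-x_j)
    #                  - sum_m m_m f_xy_im g(r2_im)(x_i-y_m) ]
    g_xx = ks.grad_scale(sq_xx)
    g_xy = ks.grad_scale(sq_xy)
    coef_xx = w[None, :] * f_xx * g_xx  # (n, n)
    coef_xy = m[None, :] * f_xy * g_xy  # (n, nt)
    dx = 2.0 * w[:, None] * (
        coef_xx.sum(axis=1)[:, None] * x - coef_xx @ x
        - coef_xy.sum(axis=1)[:, None] * x + coef_xy @ y
    )
    return float(energy), dx, dw, du
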