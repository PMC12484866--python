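"""Diffeomorphic mapping of particle measures by geodesic shooting.

The deformation is a flow of smooth velocity fields (LDDMM).  With particle
measures the flow is finite-dimensional: each particle carries a vector
"space" momentum rho^x_i and a scalar "mass" momentum rho^w_i, and the
velocity field they generate under a Gaussian flow kernel k_sigma is

    v(x) = sum_i k_sigma(x, x_i) rho^x_i
         + ((x - x_i)/sigma^2) w_i rho^w_i k_sigma(x, x_i).

The state q = (x_i, w_i) and momenta evolve under the Hamiltonian system
q_dot = dH/drho, rho_dot = -dH/dq, where for the optimal velocity
H = (1/2)|v|_V^2 has the closed form implemented in ``_ham_grads``.  Mass
transport ``w_dot = div(v) w`` makes the endpoint weight ratio w_1/w_0 equal
to the Jacobian determinant |Dphi| at each particle.

Matching minimizes  reg * H(q_0, rho_0) + |phi_1 . mu - mu'|_M^2  over the
initial momenta (single modality), optionally joint with latent per-region
feature laws and a censoring bandwidth (cross-modality, partial volumes).
Gradients are exact: the Hamiltonian gradient is analytic, the reverse sweep
through the RK4 integrator uses Hessian-vector products of H obtained by
complex-step differentiation of the analytic gradient, and the data-term
gradient at the endpoint is analytic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .varifold import (
    DiffeoSample,
    FeatureKernel,
    FeatureSpace,
    ParticleMeasure,
    SpaceKernel,
    distance_sq_with_grads,
    norm_distance_sq,
)

__all__ = [
    "FlowKernel",
    "GeodesicState",
    "AtlasMeasure",
    "MappingConfig",
    "MappingResult",
    "velocity_field",
    "velocity_divergence",
    "hamiltonian",
    "shoot",
    "kl_prior",
    "match_single_modality",
    "match_cross_modality",
    "estimate_feature_laws",
    "rotation_sweep",
]

_CSTEP = 1e-100  # complex-step size; second-order terms underflow harmlessly


@dataclass(frozen=True)
class FlowKernel:
    """Gaussian kernel of the velocity RKHS; sigma sets deformation scale (mm)."""

    sigma: float
    weight: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("flow kernel bandwidth must be positive")

    def __call__(self, sqdist):
        return self.weight * np.exp(-sqdist / (2.0 * self.sigma**2))


@dataclass
class GeodesicState:
    """Particle state (positions, weights) and conjugate momenta at time t."""

    x: np.ndarray  # (n, 3)
    w: np.ndarray  # (n,)
    rho_x: np.ndarray  # (n, 3)
    rho_w: np.ndarray  # (n,)
    t: float = 0.0

    def __post_init__(self):
        self.x = np.atleast_2d(np.asarray(self.x, float))
        self.w = np.asarray(self.w, float).ravel()
        self.rho_x = np.atleast_2d(np.asarray(self.rho_x, float))
        self.rho_w = np.asarray(self.rho_w, float).ravel()
        n = len(self.x)
        if not (len(self.w) == n and len(self.rho_x) == n and len(self.rho_w) == n):
            raise ValueError("state arrays must share the particle count")

    @classmethod
    def at_rest(cls, x, w) -> "GeodesicState":
        x = np.atleast_2d(np.asarray(x, float))
        return cls(x, w, np.zeros_like(x), np.zeros(len(x)))

    def copy(self) -> "GeodesicState":
        return GeodesicState(self.x.copy(), self.w.copy(),
                             self.rho_x.copy(), self.rho_w.copy(), self.t)


@dataclass
class AtlasMeasure:
    """Particle measure over atlas regions, with latent per-region feature laws.

    ``region_probs`` row i is pi_i, particle i's membership law over the
    region labels (one-hot away from boundaries).  ``feature_laws`` row l is
    the unnormalized law p_l over the *target* feature space; the effective
    feature vector of particle i is sum_l pi_i(l) p_l.
    """

    positions: np.ndarray  # (n, 3)
    weights: np.ndarray  # (n,)
    region_probs: np.ndarray  # (n, |L|)
    region_space: FeatureSpace
    target_space: FeatureSpace | None = None
    feature_laws: np.ndarray | None = None  # (|L|, |F|), nonnegative

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.weights = np.asarray(self.weights, float).ravel()
        self.region_probs = np.atleast_2d(np.asarray(self.region_probs, float))
        if self.region_probs.shape != (len(self.positions), len(self.region_space)):
            raise ValueError("region_probs must be (n_particles, n_regions)")
        if not np.allclose(self.region_probs.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("region membership rows must sum to 1")
        if self.feature_laws is not None:
            self.feature_laws = np.atleast_2d(np.asarray(self.feature_laws, float))
            if np.any(self.feature_laws < 0):
                raise ValueError("feature laws must be nonnegative")

    def __len__(self) -> int:
        return len(self.positions)

    def as_region_measure(self) -> ParticleMeasure:
        return ParticleMeasure(self.positions, self.weights, self.region_probs,
                               self.region_space, normalized=True)

    def with_laws(self, laws: np.ndarray) -> ParticleMeasure:
        """Mixture measure mu_A^p with feature vectors sum_l pi_i(l) p_l."""
        if self.target_space is None:
            raise ValueError("atlas has no target feature space")
        u = self.region_probs @ laws
        return ParticleMeasure(self.positions, self.weights, u,
                               self.target_space, normalized=False)


@dataclass
class MappingConfig:
    """Hyperparameters of a mapping run."""

    flow_kernel: FlowKernel = field(default_factory=lambda: FlowKernel(0.2))
    space_kernel: SpaceKernel = field(default_factory=lambda: SpaceKernel(((0.1, 1.0),)))
    reg_weight: float = 1.0  # on H(q0, rho0), i.e. (1/2) int |v|^2
    data_weight: float = 1.0
    kl_weight: float = 1.0  # on the KL prior of the latent laws
    censor_weight: float = 1.0  # on the bandwidth penalty J_s(lambda)
    n_steps: int = 10
    max_iter: int = 150
    seed: int = 0

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.max_iter < 1:
            raise ValueError("iteration budget must be positive")


@dataclass
class MappingResult:
    """Optimized momenta, laws and diagnostics of a matching run."""

    rho_x0: np.ndarray
    rho_w0: np.ndarray
    feature_laws: np.ndarray | None
    censor_lambda: float | None
    objective: float
    trajectory: list
    deformed: ParticleMeasure
    diffeo: DiffeoSample


# ---------------------------------------------------------------------------
# Hamiltonian dynamics (complex-step safe throughout)


def _pair_terms(x, fk: FlowKernel):
    d = x[:, None, :] - x[None, :, :]  # (n, n, 3)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    k = fk(r2)
    return d, r2, k


def _velocity_raw(x, w, rho_x, rho_w, fk: FlowKernel, query):
    d = query[:, None, :] - x[None, :, :]  # (m, n, 3)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    k = fk(r2)
    s2 = fk.sigma**2
    v = k @ rho_x + np.einsum("mn,mnk->mk", k * (w * rho_w)[None, :] / s2, d)
    return v


def _divergence_raw(x, w, rho_x, rho_w, fk: FlowKernel, query):
    d = query[:, None, :] - x[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", d, d)
    k = fk(r2)
    s2 = fk.sigma**2
    term_x = -np.einsum("mn,mnk,nk->m", k, d, rho_x) / s2
    term_w = (k * (3.0 / s2 - r2 / s2**2)) @ (w * rho_w)
    return term_x + term_w


def _ham_grads(x, w, rho_x, rho_w, fk: FlowKernel):
    """H and its gradient w.r.t. (x, w, rho_x, rho_w), closed form.

    H = (1/2) sum_i [rho^x_i . v(x_i) + w_i rho^w_i div v(x_i)] for the
    optimal velocity of the momenta; equals (1/2)|v|_V^2.
    """
    s2 = fk.sigma**2
    d, r2, k = _pair_terms(x, fk)
    wrw = w * rho_w  # (n,)

    v = k @ rho_x + np.einsum("ij,ijk->ik", k * wrw[None, :] / s2, d)  # v(x_i)
    div = (-np.einsum("ij,ijk,jk->i", k, d, rho_x) / s2
           + (k * (3.0 / s2 - r2 / s2**2)) @ wrw)

    h = 0.5 * (np.einsum("ik,ik->", rho_x, v) + np.dot(wrw, div))

    d_rho_x = v
    d_rho_w = w * div
    d_w = rho_w * div

    # dH/dx_i = sum_j k_ij [ -d_ij/s2 * T_ij + rx_i (w_j rw_j)/s2
    #                        - rx_j (w_i rw_i)/s2 - 2 d_ij w_i rw_i w_j rw_j/s2^2 ]
    # with T_ij = rx_i.rx_j + (rx_i.d_ij) w_j rw_j/s2 - (rx_j.d_ij) w_i rw_i/s2
    #             + w_i rw_i w_j rw_j (3/s2 - r2_ij/s2^2)
    rxd = np.einsum("ik,ijk->ij", rho_x, d)  # rx_i . d_ij
    rxd_t = np.einsum("jk,ijk->ij", rho_x, d)  # rx_j . d_ij
    t_ij = (rho_x @ rho_x.T
            + rxd * wrw[None, :] / s2
            - rxd_t * wrw[:, None] / s2
            + np.outer(wrw, wrw) * (3.0 / s2 - r2 / s2**2))
    coef = k * (t_ij / s2 + 2.0 * np.outer(wrw, wrw) / s2**2)  # (n, n)
    d_x = (-np.einsum("ij,ijk->ik", coef, d)
           + (k @ wrw)[:, None] * rho_x / s2
           - (k * wrw[:, None]) @ rho_x / s2)
    return h, d_x, d_w, d_rho_x, d_rho_w


def velocity_field(state: GeodesicState, fk: FlowKernel, query) -> np.ndarray:
    """Velocity v(x) generated by the state's momenta, at query points."""
    query = np.atleast_2d(np.asarray(query, float))
    return _velocity_raw(state.x, state.w, state.rho_x, state.rho_w, fk, query)


def velocity_divergence(state: GeodesicState, fk: FlowKernel, query) -> np.ndarray:
    """Analytic div v at query points (drives the mass transport)."""
    query = np.atleast_2d(np.asarray(query, float))
    return _divergence_raw(state.x, state.w, state.rho_x, state.rho_w, fk, query)


def hamiltonian(state: GeodesicState, fk: FlowKernel) -> float:
    """H(q, rho) = (1/2)|v|_V^2; conserved along geodesics."""
    h, *_ = _ham_grads(state.x, state.w, state.rho_x, state.rho_w, fk)
    return float(h.real if np.iscomplexobj(h) else h)


# ---------------------------------------------------------------------------
# Geodesic integration (RK4) and its exact discrete adjoint


def _field(z, fk):
    x, w, rx, rw = z
    _, d_x, d_w, d_rx, d_rw = _ham_grads(x, w, rx, rw, fk)
    return (d_rx, d_rw, -d_x, -d_w)  # (x_dot, w_dot, rho_x_dot, rho_w_dot)


def _zadd(a, b, s=1.0):
    return tuple(ai + s * bi for ai, bi in zip(a, b))


def _grad_vec(z, fk):
    """Full gradient of H in (x, w, rx, rw) layout."""
    _, d_x, d_w, d_rx, d_rw = _ham_grads(*z, fk)
    return (d_x, d_w, d_rx, d_rw)


def _hvp(z, u, fk):
    """Hessian-of-H vector product via complex step on the analytic gradient."""
    zc = tuple(np.asarray(zi, complex) + 1j * _CSTEP * ui for zi, ui in zip(z, u))
    g = _grad_vec(zc, fk)
    return tuple(gi.imag / _CSTEP for gi in g)


def _field_vjp(y, a, fk):
    """DF(y)^T a for the Hamiltonian field F = (H_rho, -H_q).

    Equals Hess(H)(y) . u with u = (-a_rho, a_q) in (q, rho) layout.
    """
    a_x, a_w, a_rx, a_rw = a
    u = (-a_rx, -a_rw, a_x, a_w)
    return _hvp(y, u, fk)


def shoot(initial: GeodesicState, fk: FlowKernel, n_steps: int = 10,
          _cache: list | None = None):
    """Integrate the geodesic equations from t=0 to t=1 with fixed-step RK4.

    Returns (trajectory, diffeo): the list of states at each time node and the
    endpoint ``DiffeoSample`` with |Dphi| recovered from the mass transport
    ratio w_1/w_0 (1 where w_0 = 0).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    h = 1.0 / n_steps
    z = (initial.x.copy(), initial.w.copy(),
         initial.rho_x.copy(), initial.rho_w.copy())
    traj = [initial.copy()]
    for step in range(n_steps):
        with np.errstate(over="ignore", invalid="ignore", under="ignore"):
            k1 = _field(z, fk)
            y2 = _zadd(z, k1, h / 2)
            k2 = _field(y2, fk)
            y3 = _zadd(z, k2, h / 2)
            k3 = _field(y3, fk)
            y4 = _zadd(z, k3, h)
            k4 = _field(y4, fk)
            z_new = tuple(
                zi + h / 6.0 * (a + 2 * b + 2 * c + e)
                for zi, a, b, c, e in zip(z, k1, k2, k3, k4)
            )
        if not all(np.all(np.isfinite(zi)) for zi in z_new):
            raise FloatingPointError(
                f"geodesic integration blew up at step {step + 1}/{n_steps}")
        if _cache is not None:
            _cache.append((z, y2, y3, y4))
        z = z_new
        traj.append(GeodesicState(*(zi.copy() for zi in z), t=(step + 1) * h))
    w0 = initial.w
    jac = np.where(w0 > 0, z[1] / np.where(w0 > 0, w0, 1.0), 1.0)
    diffeo = DiffeoSample(z[0], jac)
    return traj, diffeo


def _shoot_vjp(cache, bar_z1, fk, n_steps):
    """Pull a gradient at the endpoint back to t=0 through the RK4 sweep."""
    h = 1.0 / n_steps
    bar = bar_z1
    for z, y2, y3, y4 in reversed(cache):
        k4b = tuple(h / 6.0 * b for b in bar)
        y4b = _field_vjp(y4, k4b, fk)
        k3b = _zadd(tuple(h / 3.0 * b for b in bar), y4b, h)
        y3b = _field_vjp(y3, k3b, fk)
        k2b = _zadd(tuple(h / 3.0 * b for b in bar), y3b, h / 2)
        y2b = _field_vjp(y2, k2b, fk)
        k1b = _zadd(tuple(h / 6.0 * b for b in bar), y2b, h / 2)
        y1b = _field_vjp(z, k1b, fk)
        bar = tuple(b + p + q + r + s
                    for b, p, q, r, s in zip(bar, y1b, y2b, y3b, y4b))
    return bar


# ---------------------------------------------------------------------------
# KL prior on latent laws


def kl_prior(feature_laws: np.ndarray, deformed_region_masses: np.ndarray,
             target_feature_masses: np.ndarray) -> float:
    """Mass-weighted KL of each region law to the uniform law.

    J = sum_l (M^A_l / sum_f M^T_f) sum_f p_l(f) log(pbar_l(f) |F|),
    nonnegative, zero iff every law is uniform.
    """
    p = np.atleast_2d(np.asarray(feature_laws, float))
    m_a = np.asarray(deformed_region_masses, float).ravel()
    m_t = float(np.sum(target_feature_masses))
    if m_t <= 0:
        raise ValueError("total target feature mass must be positive")
    if np.any(m_a < 0) or np.any(p < 0):
        raise ValueError("masses and laws must be nonnegative")
    nf = p.shape[1]
    sums = p.sum(axis=1, keepdims=True)
    pbar = np.divide(p, sums, out=np.zeros_like(p), where=sums > 0)
    logterm = np.where(p > 0, np.log(np.where(pbar > 0, pbar, 1.0) * nf), 0.0)
    return float(np.sum(m_a / m_t * np.sum(p * logterm, axis=1)))


# ---------------------------------------------------------------------------
# Matching drivers


def _censor_alpha_and_grads(censor, x, lam):
    """alpha(x), d alpha/dx and d alpha/d lambda by vectorized complex step."""
    alpha = censor.evaluate(x, lam=lam)
    grads = np.empty_like(x)
    for k in range(x.shape[1]):
        xc = np.asarray(x, complex).copy()
        xc[:, k] += 1j * _CSTEP
        grads[:, k] = censor.evaluate(xc, lam=lam).imag / _CSTEP
    dlam = censor.evaluate(x, lam=lam + 1j * _CSTEP).imag / _CSTEP
    return alpha, grads, dlam


def _run_lbfgs(objective, theta0, cfg: MappingConfig):
    trace: list[float] = []
    last: dict = {}

    def fun(theta):
        try:
            val, grad = objective(theta)
        except FloatingPointError:
            # blown-up shoot during line search: steep finite penalty makes
            # the line search backtrack toward smaller momenta
            return 1e12 * (1.0 + theta @ theta), 2e12 * theta
        if not np.isfinite(val):
            prev = trace[-1] if trace else float("nan")
            raise FloatingPointError(
                f"optimizer diverged (last finite objective {prev!r})")
        last["key"] = theta.tobytes()
        last["val"] = val
        return val, grad

    def callback(theta):
        if last.get("key") == theta.tobytes():
            trace.append(float(last["val"]))
        else:
            trace.append(float(fun(theta)[0]))

    res = minimize(fun, theta0, jac=True, method="L-BFGS-B",
                   callback=callback,
                   options={"maxiter": cfg.max_iter, "maxcor": 20,
                            "ftol": 1e-12, "gtol": 1e-10})
    return res, trace


def _endpoint_loss_grads(x1, w1, u, target: ParticleMeasure, ks: SpaceKernel,
                         censor=None, lam=None):
    """Data term |alpha . (phi . mu) - target|^2 and grads wrt x1, w1, (lam).

    Returns (E, dx1, dw1, du, dlam, alpha).
    """
    if censor is not None:
        alpha, dalpha_dx, dalpha_dlam = _censor_alpha_and_grads(censor, x1, lam)
    else:
        alpha = np.ones(len(x1))
        dalpha_dx = None
        dalpha_dlam = None
    w_eff = alpha * w1
    e, dx, dweff, du = distance_sq_with_grads(
        x1, w_eff, u, target.positions, target.weights, target.feature_dists, ks)
    dw1 = dweff * alpha
    dlam = 0.0
    if censor is not None:
        dx = dx + (dweff * w1)[:, None] * dalpha_dx
        dlam = float(np.dot(dweff * w1, dalpha_dlam))
    return e, dx, dw1, du, dlam, alpha


def match_single_modality(mu: ParticleMeasure, target: ParticleMeasure,
                          cfg: MappingConfig,
                          censor=None) -> MappingResult:
    """Variational matching of two measures sharing a feature space.

    Minimizes reg * H(q0, rho0) + |phi_1 . mu - mu'|_M^2 over initial
    momenta (plus the censor bandwidth when a censor is supplied).
    """
    if mu.feature_space != target.feature_space:
        raise ValueError("measures live on different feature spaces")
    n = len(mu)
    fk = cfg.flow_kernel
    x0, w0 = mu.positions, mu.weights
    u = mu.feature_dists
    n_mom = 4 * n
    with_censor = censor is not None
    lam0 = float(censor.lam) if with_censor else None

    def objective(theta):
        rx = theta[: 3 * n].reshape(n, 3)
        rw = theta[3 * n: 4 * n]
        lam = np.exp(theta[n_mom]) if with_censor else None
        h0, _, _, dh_rx, dh_rw = _ham_grads(x0, w0, rx, rw, fk)
        cache: list = []
        _, diffeo = shoot(GeodesicState(x0, w0, rx, rw), fk, cfg.n_steps,
                          _cache=cache)
        x1 = diffeo.mapped_positions
        w1 = diffeo.jacobian_dets * w0
        e, dx1, dw1, _, dlam, _ = _endpoint_loss_grads(
            x1, w1, u, target, cfg.space_kernel, censor, lam)
        val = cfg.reg_weight * h0 + cfg.data_weight * e
        bar1 = (cfg.data_weight * dx1, cfg.data_weight * dw1,
                np.zeros_like(dx1), np.zeros(n))
        bar0 = _shoot_vjp(cache, bar1, fk, cfg.n_steps)
        grad = np.concatenate([
            (cfg.reg_weight * dh_rx + bar0[2]).ravel(),
            cfg.reg_weight * dh_rw + bar0[3],
        ])
        if with_censor:
            from .censoring import lambda_penalty, _lambda_penalty_grad
            val += cfg.censor_weight * lambda_penalty(lam)
            g_lam = (cfg.data_weight * dlam
                     + cfg.censor_weight * _lambda_penalty_grad(lam)) * lam
            grad = np.concatenate([grad, [g_lam]])
        return val, grad

    theta0 = np.zeros(n_mom + (1 if with_censor else 0))
    if with_censor:
        theta0[n_mom] = np.log(lam0)
    res, trace = _run_lbfgs(objective, theta0, cfg)
    theta = res.x
    rx = theta[: 3 * n].reshape(n, 3)
    rw = theta[3 * n: 4 * n]
    lam = float(np.exp(theta[n_mom])) if with_censor else None
    _, diffeo = shoot(GeodesicState(x0, w0, rx, rw), fk, cfg.n_steps)
    w1 = diffeo.jacobian_dets * w0
    alpha = censor.evaluate(diffeo.mapped_positions, lam=lam) if with_censor \
        else np.ones(n)
    deformed = ParticleMeasure(diffeo.mapped_positions, alpha * w1,
                               mu.feature_dists, mu.feature_space,
                               normalized=mu.normalized)
    return MappingResult(rx, rw, None, lam, float(res.fun), trace,
                         deformed, diffeo)


def match_cross_modality(atlas: AtlasMeasure, target: ParticleMeasure,
                         censor, cfg: MappingConfig,
                         init_laws: np.ndarray | None = None) -> MappingResult:
    """Joint estimation of the diffeomorphism, per-region feature laws and
    (optionally) the censor bandwidth.

    The deformed atlas carries the mixture law sum_l pi_i(l) p_l; the KL
    prior weights each region law toward uniform by its deformed mass.
    """
    if atlas.target_space is None:
        atlas = AtlasMeasure(atlas.positions, atlas.weights, atlas.region_probs,
                             atlas.region_space, target.feature_space,
                             atlas.feature_laws)
    if atlas.target_space != target.feature_space:
        raise ValueError("atlas target space does not match the target measure")
    n = len(atlas)
    nl = len(atlas.region_space)
    nf = len(target.feature_space)
    fk = cfg.flow_kernel
    x0, w0, pi = atlas.positions, atlas.weights, atlas.region_probs
    m_t = float(np.sum(target.weights[:, None] * target.feature_dists))
    region_mass0 = pi.T @ w0
    empty = region_mass0 <= 1e-12
    if np.any(empty):
        warnings.warn("atlas regions with zero mass: laws pinned to uniform")

    n_mom = 4 * n
    with_censor = censor is not None
    n_theta = n_mom + nl * nf + (1 if with_censor else 0)

    if init_laws is None:
        eta0 = np.zeros((nl, nf))  # p_l = exp(eta) = 1: unnormalized uniform
    else:
        eta0 = np.log(np.maximum(np.atleast_2d(init_laws), 1e-12))

    def objective(theta):
        rx = theta[: 3 * n].reshape(n, 3)
        rw = theta[3 * n: n_mom]
        eta = theta[n_mom: n_mom + nl * nf].reshape(nl, nf)
        eta = np.where(empty[:, None], 0.0, eta)
        laws = np.exp(eta)
        lam = np.exp(theta[-1]) if with_censor else None

        h0, _, _, dh_rx, dh_rw = _ham_grads(x0, w0, rx, rw, fk)
        cache: list = []
        _, diffeo = shoot(GeodesicState(x0, w0, rx, rw), fk, cfg.n_steps,
                          _cache=cache)
        x1 = diffeo.mapped_positions
        w1 = diffeo.jacobian_dets * w0
        u = pi @ laws
        e, dx1, dw1, du, dlam, alpha = _endpoint_loss_grads(
            x1, w1, u, target, cfg.space_kernel, censor, lam)
        d_laws = pi.T @ du  # (nl, nf)

        # KL prior with deformed (censored) region masses
        w_eff = alpha * w1
        m_a = pi.T @ w_eff
        sums = laws.sum(axis=1, keepdims=True)
        pbar = laws / sums
        log_pf = np.log(pbar * nf)
        d_l = np.sum(laws * log_pf, axis=1)  # per-region divergence
        j_kl = float(np.dot(m_a, d_l)) / m_t
        d_laws_kl = (m_a / m_t)[:, None] * log_pf
        # dependence of m_a on the endpoint (and censor)
        c_i = (pi @ d_l) / m_t  # dJ/dW_i
        dw1_kl = c_i * alpha
        dx1_kl = np.zeros_like(x1)
        dlam_kl = 0.0
        if with_censor:
            _, dalpha_dx, dalpha_dlam = _censor_alpha_and_grads(censor, x1, lam)
            dx1_kl = (c_i * w1)[:, None] * dalpha_dx
            dlam_kl = float(np.dot(c_i * w1, dalpha_dlam))

        val = (cfg.reg_weight * h0 + cfg.data_weight * e
               + cfg.kl_weight * j_kl)
        bar1 = (cfg.data_weight * dx1 + cfg.kl_weight * dx1_kl,
                cfg.data_weight * dw1 + cfg.kl_weight * dw1_kl,
                np.zeros_like(dx1), np.zeros(n))
        bar0 = _shoot_vjp(cache, bar1, fk, cfg.n_steps)
        g_laws = (cfg.data_weight * d_laws + cfg.kl_weight * d_laws_kl) * laws
        g_laws = np.where(empty[:, None], 0.0, g_laws)
        grad = np.concatenate([
            (cfg.reg_weight * dh_rx + bar0[2]).ravel(),
            cfg.reg_weight * dh_rw + bar0[3],
            g_laws.ravel(),
        ])
        if with_censor:
            from .censoring import lambda_penalty, _lambda_penalty_grad
            val += cfg.censor_weight * lambda_penalty(lam)
            g_lam = (cfg.data_weight * dlam + cfg.kl_weight * dlam_kl
                     + cfg.censor_weight * _lambda_penalty_grad(lam)) * lam
            grad = np.concatenate([grad, [g_lam]])
        return val, grad

    theta0 = np.zeros(n_theta)
    theta0[n_mom: n_mom + nl * nf] = eta0.ravel()
    if with_censor:
        theta0[-1] = np.log(float(censor.lam))
    res, trace = _run_lbfgs(objective, theta0, cfg)
    theta = res.x
    rx = theta[: 3 * n].reshape(n, 3)
    rw = theta[3 * n: n_mom]
    eta = theta[n_mom: n_mom + nl * nf].reshape(nl, nf)
    eta = np.where(empty[:, None], 0.0, eta)
    laws = np.exp(eta)
    lam = float(np.exp(theta[-1])) if with_censor else None
    _, diffeo = shoot(GeodesicState(x0, w0, rx, rw), fk, cfg.n_steps)
    w1 = diffeo.jacobian_dets * w0
    alpha = censor.evaluate(diffeo.mapped_positions, lam=lam) if with_censor \
        else np.ones(n)
    deformed = ParticleMeasure(diffeo.mapped_positions, alpha * w1,
                               pi @ laws, target.feature_space,
                               normalized=False)
    return MappingResult(rx, rw, laws, lam, float(res.fun), trace,
                         deformed, diffeo)


# ---------------------------------------------------------------------------
# Closed-form law estimation and rigid-rotation sweeps


def estimate_feature_laws(positions, weights, region_probs,
                          target: ParticleMeasure, ks: SpaceKernel):
    """Optimal nonnegative per-region laws for fixed geometry.

    The loss |mu_A^p - mu_T|^2 is quadratic in the laws and separates by
    feature: per feature f, minimize p_f' G p_f - 2 c_f' p_f with
    G_{ll'} = sum_{ij} w_i w_j K(x_i, x_j) pi_i(l) pi_j(l') and
    c_{lf} = sum_{im} pi_i(l) w_i m_m K(x_i, y_m) b_m(f), solved with
    nonnegative least squares.  Returns (laws (|L|, |F|), loss value).
    """
    from scipy.linalg import cholesky, solve_triangular
    from scipy.optimize import nnls

    x = np.atleast_2d(np.asarray(positions, float))
    w = np.asarray(weights, float).ravel()
    pi = np.atleast_2d(np.asarray(region_probs, float))
    y = target.positions
    m = target.weights
    b = target.feature_dists

    k_xx = ks(_vf_sqdist(x, x))
    k_xy = ks(_vf_sqdist(x, y))
    gram = pi.T @ (k_xx * np.outer(w, w)) @ pi  # (L, L)
    c = pi.T @ ((w[:, None] * k_xy) @ (m[:, None] * b))  # (L, F)
    target_term = float(np.einsum(
        "mn,m,n,mn->", ks(_vf_sqdist(y, y)), m, m, b @ b.T))

    nl = gram.shape[0]
    jitter = 1e-10 * np.trace(gram) / nl
    chol = cholesky(gram + jitter * np.eye(nl), lower=True)
    laws = np.empty_like(c)
    for f in range(c.shape[1]):
        rhs = solve_triangular(chol, c[:, f], lower=True)
        laws[:, f], _ = nnls(chol.T, rhs)
    loss = float(np.einsum("lf,lk,kf->", laws, gram, laws)
                 - 2.0 * np.sum(laws * c) + target_term)
    return laws, loss


def _vf_sqdist(a, b):
    d = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


def rotation_sweep(atlas: AtlasMeasure, target: ParticleMeasure,
                   ks: SpaceKernel, angles_deg=None, axis: int = 2):
    """Cross-modality loss over in-plane rigid rotations of the atlas.

    At each angle the atlas is rotated about the origin, the per-region laws
    are re-estimated in closed form, and the varifold loss of the resulting
    mixture measure against the target is recorded.  Returns (angles, losses).
    """
    if angles_deg is None:
        angles_deg = np.arange(0.0, 360.0)
    angles_deg = np.asarray(angles_deg, float)
    losses = np.empty(len(angles_deg))
    x = atlas.positions
    plane = [i for i in range(3) if i != axis]
    for a_i, deg in enumerate(angles_deg):
        th = np.deg2rad(deg)
        rot = x.copy()
        c, s = np.cos(th), np.sin(th)
        rot[:, plane[0]] = c * x[:, plane[0]] - s * x[:, plane[1]]
        rot[:, plane[1]] = s * x[:, plane[0]] + c * x[:, plane[1]]
        _, losses[a_i] = estimate_feature_laws(
            rot, atlas.weights, atlas.region_probs, target, ks)
    return angles_deg, losses
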