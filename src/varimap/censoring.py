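"""Spatial support weights for partial-volume (censored) matching.

Spatial-omics experiments rarely cover the whole organ the reference atlas
describes.  The censoring function alpha^lambda : R^3 -> [0, 1] is defined in
target coordinates; it is ~1 inside the measured subvolume and decays
smoothly to 0 outside, with the bandwidth lambda setting the width of the
transition zone.  During matching the deforming atlas mass is multiplied by
alpha^lambda at its mapped position, so unmeasured regions stop contributing
to the data term and hence attract no deformation.

Two parameterizations are provided: a pair of opposing tanh half-spaces for
slab-shaped supports (stacks of sections with missing rostral/caudal ends),
and a small feed-forward classifier (3->15->5->1, exponential-linear units,
tanh output rescaled to [0, 1]) for irregular boundaries such as hemi-brain
sections, trained on interior particles against dummy boundary particles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .varifold import DiffeoSample, ParticleMeasure, apply_varifold_action

__all__ = [
    "PlanarCensor",
    "LearnedCensor",
    "BoundaryTrainingSet",
    "censor_eval",
    "lambda_penalty",
    "censored_action",
    "fit_boundary_classifier",
]

_CSTEP = 1e-100


def _maybe_clip01(a):
    if np.iscomplexobj(a):  # complex-step path: leave analytic
        return a
    return np.clip(a, 0.0, 1.0)


@dataclass
class PlanarCensor:
    """Slab support: half the sum of two opposing tanh half-space weights.

    alpha(x) = (1/2)(tanh(<x - a0, n0>/lambda) + tanh(<x - a1, n1>/lambda))
    with a0, a1 anchor points on the first/last bounding planes and n0, n1
    the inward unit normals.
    """

    a0: np.ndarray
    a1: np.ndarray
    n0: np.ndarray
    n1: np.ndarray
    lam: float = np.sqrt(0.1)

    def __post_init__(self):
        self.a0 = np.asarray(self.a0, float).ravel()
        self.a1 = np.asarray(self.a1, float).ravel()
        for name in ("n0", "n1"):
            n = np.asarray(getattr(self, name), float).ravel()
            norm = np.linalg.norm(n)
            if norm == 0:
                raise ValueError("censor normals must be nonzero")
            setattr(self, name, n / norm)
        if self.lam <= 0:
            raise ValueError("censor bandwidth lambda must be positive")

    def evaluate(self, x, lam=None):
        lam = self.lam if lam is None else lam
        if np.real(lam) <= 0:
            raise ValueError("censor bandwidth lambda must be positive")
        x = np.atleast_2d(x)
        s0 = (x - self.a0) @ self.n0
        s1 = (x - self.a1) @ self.n1
        return _maybe_clip01(0.5 * (np.tanh(s0 / lam) + np.tanh(s1 / lam)))

    def to_json(self) -> str:
        return json.dumps({
            "kind": "planar",
            "a0": self.a0.tolist(), "a1": self.a1.tolist(),
            "n0": self.n0.tolist(), "n1": self.n1.tolist(),
            "lambda": float(self.lam),
        })

    @classmethod
    def from_json(cls, text: str) -> "PlanarCensor":
        d = json.loads(text)
        if d.get("kind") != "planar":
            raise ValueError("not a planar censor document")
        return cls(d["a0"], d["a1"], d["n0"], d["n1"], d["lambda"])


def _elu(z):
    # branch on the real part so the complex-step path stays analytic
    pos = np.real(z) > 0
    return np.where(pos, z, np.exp(np.where(pos, 0.0, z)) - 1.0)


_LAYERS = ((3, 15), (15, 5), (5, 1))


@dataclass
class LearnedCensor:
    """3-layer censor classifier; tanh output rescaled to [0, 1].

    alpha(x) = (tanh(z(x)/lambda) + 1)/2 where z is the scalar output of the
    3->15->5->1 ELU network; lambda again controls the transition width.
    """

    params: np.ndarray  # flattened weights and biases
    lam: float = np.sqrt(0.1)

    def __post_init__(self):
        self.params = np.asarray(self.params, float).ravel()
        if len(self.params) != self.n_params():
            raise ValueError(f"expected {self.n_params()} parameters")
        if self.lam <= 0:
            raise ValueError("censor bandwidth lambda must be positive")

    @staticmethod
    def n_params() -> int:
        return sum(a * b + b for a, b in _LAYERS)

    @staticmethod
    def _unpack(params):
        out, k = [], 0
        for a, b in _LAYERS:
            w = params[k: k + a * b].reshape(a, b)
            k += a * b
            bias = params[k: k + b]
            k += b
            out.append((w, bias))
        return out

    def logits(self, x, params=None):
        """Raw scalar network output z(x) (before the tanh squashing)."""
        params = self.params if params is None else params
        (w1, b1), (w2, b2), (w3, b3) = self._unpack(params)
        h = _elu(np.atleast_2d(x) @ w1 + b1)
        h = _elu(h @ w2 + b2)
        return (h @ w3 + b3).ravel()

    def evaluate(self, x, lam=None, params=None):
        lam = self.lam if lam is None else lam
        if np.real(lam) <= 0:
            raise ValueError("censor bandwidth lambda must be positive")
        z = self.logits(x, params=params)
        return _maybe_clip01(0.5 * (np.tanh(z / lam) + 1.0))

    def to_json(self) -> str:
        return json.dumps({
            "kind": "learned",
            "layers": [list(shape) for shape in _LAYERS],
            "params": self.params.tolist(),
            "lambda": float(self.lam),
        })

    @classmethod
    def from_json(cls, text: str) -> "LearnedCensor":
        d = json.loads(text)
        if d.get("kind") != "learned":
            raise ValueError("not a learned censor document")
        return cls(np.asarray(d["params"]), d["lambda"])


@dataclass
class BoundaryTrainingSet:
    """Interior particles (label 1) and boundary dummies (label 0)."""

    interior: np.ndarray  # (n, 3)
    boundary: np.ndarray  # (m, 3)
    class_weight_ratio: float = 1000.0  # weight on the sparse label-0 class

    def __post_init__(self):
        self.interior = np.atleast_2d(np.asarray(self.interior, float))
        self.boundary = np.atleast_2d(np.asarray(self.boundary, float))
        if self.interior.size == 0 or self.boundary.size == 0:
            raise ValueError("both classes must be non-empty")
        if self.class_weight_ratio <= 0:
            raise ValueError("class weight ratio must be positive")


def censor_eval(censor, x) -> np.ndarray:
    """Support weight alpha^lambda(x) in [0, 1] at query points."""
    return censor.evaluate(np.atleast_2d(np.asarray(x)))


def lambda_penalty(lam: float) -> float:
    """Bandwidth regularizer J_s(lambda) = u ln u + 1 - u with u = lambda^2/0.1.

    Convex in lambda^2, nonnegative, uniquely zero at lambda^2 = 0.1; the
    limit 1 is returned at lambda = 0.
    """
    u = float(np.real(lam)) ** 2 / 0.1
    if u == 0.0:
        return 1.0
    return float(u * np.log(u) + 1.0 - u)


def _lambda_penalty_grad(lam: float) -> float:
    """dJ_s/dlambda = (2 lambda / 0.1) ln(lambda^2/0.1)."""
    u = lam**2 / 0.1
    if u == 0.0:
        return 0.0
    return float(2.0 * lam / 0.1 * np.log(u))


def censored_action(mu: ParticleMeasure, phi: DiffeoSample, censor) -> ParticleMeasure:
    """Varifold action followed by masking: weights become
    alpha(phi(x_i)) |Dphi| w_i at phi(x_i); laws unchanged."""
    moved = apply_varifold_action(mu, phi)
    alpha = censor.evaluate(moved.positions)
    moved.weights = alpha * moved.weights
    return moved


def _softplus(t):
    """log(1 + exp(t)), overflow-safe and complex-step safe."""
    pos = np.real(t) > 0
    tneg = np.where(pos, -t, t)  # always nonpositive real part
    base = np.log(1.0 + np.exp(tneg))
    return np.where(pos, t + base, base)


def close_stack_ends(interior: np.ndarray, spacing: float, axis: int = 2,
                     tol: float = 1e-9) -> np.ndarray:
    """Dummy boundary sections beyond the first/last sections of a stack.

    Copies the extreme sections along ``axis`` shifted outward by
    ``spacing``; used as label-0 particles so the fitted support closes at
    the stack ends.
    """
    interior = np.atleast_2d(np.asarray(interior, float))
    coord = interior[:, axis]
    lo, hi = coord.min(), coord.max()
    first = interior[np.abs(coord - lo) <= tol].copy()
    last = interior[np.abs(coord - hi) <= tol].copy()
    first[:, axis] -= spacing
    last[:, axis] += spacing
    return np.vstack([first, last])


def fit_boundary_classifier(train: BoundaryTrainingSet, seed: int = 0,
                            lam: float = np.sqrt(0.1),
                            close_ends_spacing: float | None = None,
                            stack_axis: int = 2,
                            max_iter: int = 400) -> LearnedCensor:
    """Train the 3-layer censor on interior (1) vs boundary-dummy (0) points.

    Weighted cross-entropy on the tanh-rescaled output (equivalently a
    logistic loss on 2 z / lambda); deterministic for a fixed seed.  When
    ``close_ends_spacing`` is given, dummy copies of the first and last
    sections are appended beyond the stack ends before training.
    """
    boundary = train.boundary
    if close_ends_spacing is not None:
        boundary = np.vstack([
            boundary,
            close_stack_ends(train.interior, close_ends_spacing, stack_axis),
        ])
    x = np.vstack([train.interior, boundary])
    y = np.concatenate([np.ones(len(train.interior)), np.zeros(len(boundary))])
    sw = np.where(y == 0, train.class_weight_ratio, 1.0)
    sw = sw / sw.sum()

    # normalize inputs for conditioning; fold the transform into the first layer
    center = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    xn = (x - center) / scale

    rng = np.random.default_rng(seed)
    theta0 = 0.5 * rng.standard_normal(LearnedCensor.n_params())
    net = LearnedCensor(theta0, lam)

    def loss(theta):
        logit = 2.0 * net.logits(xn, params=theta) / lam
        # BCE: softplus(-logit) for y=1, softplus(logit) for y=0
        per = np.where(y == 1, _softplus(-logit), _softplus(logit))
        return np.sum(sw * per)

    def loss_and_grad(theta):
        val = loss(theta)
        grad = np.empty_like(theta)
        for k in range(len(theta)):
            tc = theta.astype(complex)
            tc[k] += 1j * _CSTEP
            grad[k] = np.imag(loss(tc)) / _CSTEP
        return float(np.real(val)), grad

    res = minimize(loss_and_grad, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-12})
    if not np.isfinite(res.fun):
        raise FloatingPointError(f"classifier training diverged (loss {res.fun})")
    theta = res.x

    # fold the input normalization into the first layer
    (w1, b1), (w2, b2), (w3, b3) = LearnedCensor._unpack(theta)
    w1_raw = w1 / scale[:, None]
    b1_raw = b1 - (center / scale) @ w1
    params = np.concatenate([w1_raw.ravel(), b1_raw,
                             w2.ravel(), b2, w3.ravel(), b3])
    fitted = LearnedCensor(params, lam)

    acc = _weighted_accuracy(fitted, x, y, sw)
    if acc < 0.95:
        raise RuntimeError(
            f"boundary classifier failed to converge: weighted training "
            f"accuracy {acc:.3f} < 0.95 (final loss {res.fun:.4g})")
    return fitted


def _weighted_accuracy(censor: LearnedCensor, x, y, sw) -> float:
    pred = (censor.evaluate(x) >= 0.5).astype(float)
    return float(np.sum(sw * (pred == y)) / np.sum(sw))
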