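"""Rigid alignment of a stack of 2D sections.

Serial sections from one specimen are imaged with arbitrary in-plane
orientations.  Before any volumetric mapping, each intermediate section of
the stack is given a rotation theta_n and a 2D translation tau_n (the first
and last sections stay fixed) minimizing the summed varifold distance
between adjacent sections.  Sections are centered at their mass centroid on
load; the feature kernel is the identity indicator and the space kernel a
single Gaussian whose default bandwidth is twice the median nearest-neighbor
spacing of the stack.

Rotation-symmetric sections admit multiple optima; the optimizer reports the
local optimum reached from the identity initialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .varifold import ParticleMeasure, SpaceKernel, distance_sq_with_grads

__all__ = ["SectionStack", "RigidParams", "apply_rigid", "align_stack"]


@dataclass
class SectionStack:
    """Ordered 2D sections (particles with z = 0), centered on load."""

    sections: list[ParticleMeasure]
    spacing: float = 0.2  # inter-section spacing, mm (bookkeeping only)

    def __post_init__(self):
        if len(self.sections) == 0:
            raise ValueError("empty stack")
        space = self.sections[0].feature_space
        centered = []
        for sec in self.sections:
            if sec.feature_space != space:
                raise ValueError("sections must share a feature space")
            sec = sec.copy()
            centroid = np.average(sec.positions, axis=0, weights=sec.weights)
            sec.positions = sec.positions - centroid
            sec.positions[:, 2] = 0.0
            centered.append(sec)
        self.sections = centered

    def __len__(self) -> int:
        return len(self.sections)


@dataclass
class RigidParams:
    """Per-section angle (radians, in (-pi, pi]) and 2D translation."""

    thetas: np.ndarray  # (N,)
    taus: np.ndarray  # (N, 2)

    def __post_init__(self):
        self.thetas = np.asarray(self.thetas, float).ravel()
        self.taus = np.atleast_2d(np.asarray(self.taus, float))
        if len(self.taus) != len(self.thetas):
            raise ValueError("thetas and taus must agree in length")
        self.thetas = np.mod(self.thetas + np.pi, 2 * np.pi) - np.pi


def apply_rigid(section: ParticleMeasure, theta: float, tau) -> ParticleMeasure:
    """Rotate the section in-plane by theta, then translate by tau (2D).

    Mass and feature laws are untouched (|D| = 1 for rigid motions).
    """
    tau = np.asarray(tau, float).ravel()
    c, s = np.cos(theta), np.sin(theta)
    out = section.copy()
    xy = out.positions[:, :2].copy()
    out.positions[:, 0] = c * xy[:, 0] - s * xy[:, 1] + tau[0]
    out.positions[:, 1] = s * xy[:, 0] + c * xy[:, 1] + tau[1]
    return out


def _default_bandwidth(stack: SectionStack) -> float:
    dists = []
    for sec in stack.sections:
        if len(sec) < 2:
            continue
        tree = cKDTree(sec.positions)
        d, _ = tree.query(sec.positions, k=2)
        dists.append(d[:, 1])
    if not dists:
        raise ValueError("stack too small to infer a kernel bandwidth")
    return 2.0 * float(np.median(np.concatenate(dists)))


def _transform(x: np.ndarray, theta: float, tau: np.ndarray) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    out = x.copy()
    out[:, 0] = c * x[:, 0] - s * x[:, 1] + tau[0]
    out[:, 1] = s * x[:, 0] + c * x[:, 1] + tau[1]
    return out


def align_stack(stack: SectionStack, bandwidth: float | None = None,
                max_iter: int = 200) -> RigidParams:
    """Estimate (theta_n, tau_n) for interior sections, ends held fixed.

    Minimizes the sum over adjacent pairs of squared varifold distances with
    a quasi-Newton (L-BFGS) descent and analytic gradients; all interior
    sections are optimized simultaneously.
    """
    n_sec = len(stack)
    if n_sec < 3:
        raise ValueError("need at least 3 sections (ends are fixed)")
    ks = SpaceKernel(((bandwidth or _default_bandwidth(stack), 1.0),))
    free = list(range(1, n_sec - 1))
    xs = [sec.positions for sec in stack.sections]
    ws = [sec.weights for sec in stack.sections]
    us = [sec.feature_dists for sec in stack.sections]

    def unpack(theta_vec):
        thetas = np.zeros(n_sec)
        taus = np.zeros((n_sec, 2))
        for idx, sec_i in enumerate(free):
            thetas[sec_i] = theta_vec[3 * idx]
            taus[sec_i] = theta_vec[3 * idx + 1: 3 * idx + 3]
        return thetas, taus

    def fun(theta_vec):
        thetas, taus = unpack(theta_vec)
        moved = [_transform(xs[i], thetas[i], taus[i]) for i in range(n_sec)]
        total = 0.0
        dpos = [np.zeros_like(xs[i]) for i in range(n_sec)]
        for a in range(n_sec - 1):
            b = a + 1
            e, dxa, _, _ = distance_sq_with_grads(
                moved[a], ws[a], us[a], moved[b], ws[b], us[b], ks)
            _, dxb, _, _ = distance_sq_with_grads(
                moved[b], ws[b], us[b], moved[a], ws[a], us[a], ks)
            total += e
            dpos[a] += dxa
            dpos[b] += dxb
        grad = np.zeros_like(theta_vec)
        for idx, sec_i in enumerate(free):
            c, s = np.cos(thetas[sec_i]), np.sin(thetas[sec_i])
            x = xs[sec_i]
            # d(moved)/dtheta = R'_theta x
            dxdt = np.zeros_like(x)
            dxdt[:, 0] = -s * x[:, 0] - c * x[:, 1]
            dxdt[:, 1] = c * x[:, 0] - s * x[:, 1]
            grad[3 * idx] = np.sum(dpos[sec_i] * dxdt)
            grad[3 * idx + 1] = np.sum(dpos[sec_i][:, 0])
            grad[3 * idx + 2] = np.sum(dpos[sec_i][:, 1])
        return total, grad

    theta0 = np.zeros(3 * len(free))
    res = minimize(fun, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-12})
    if not np.isfinite(res.fun):
        raise FloatingPointError(f"stack alignment diverged: {res.message}")
    thetas, taus = unpack(res.x)
    return RigidParams(thetas, taus)
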