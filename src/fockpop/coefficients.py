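"""State-dependent Hamiltonian coefficients.

All four coefficient functions are driven by the per-cell resource/human
density ratio ``K_alpha = n_b(alpha) / n_a(alpha)``:

* ``omega_a`` — inertia of the human population; grows with ``K`` (humans
  are static where resources are plentiful relative to people).
* ``omega_b`` — inertia of the resources; decays with ``K`` (resources are
  static where humans are scarce).
* ``lambda_coeff = omega_a + omega_b + mu`` — strength of the local
  predator-prey exchange; ``mu`` keeps a minimal exchange alive when both
  inertia terms vanish.
* ``gamma_coeff(K_alpha, K_beta) = omega_b(K_alpha) + omega_b(K_beta)`` —
  migration drive between neighboring cells; large when either cell has a
  low resource/human ratio, so people flow out of resource-stressed cells.

The ratio is floored at ``eps_density`` in both numerator and denominator,
making every coefficient finite even at vanishing densities (the blow-up
regime is never reached from the default initial conditions, but the
floor keeps the simulator total).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ModelParams",
    "DensityField",
    "ratio_K",
    "omega_a",
    "omega_b",
    "lambda_coeff",
    "gamma_coeff",
]


@dataclass(frozen=True)
class ModelParams:
    """Scalar model parameters, spatially uniform.

    Defaults are the published fit of the South-American pre-agricultural
    phase: ``sigma=12.5, tau=0.35, mu=0.25, p=1, K_total=0.5``.
    ``p=0`` turns migration off entirely.
    """

    sigma: float = 12.5
    tau: float = 0.35
    mu: float = 0.25
    p: float = 1.0
    K_total: float = 0.5
    jitter: float = 0.10
    eps_density: float = 1e-10

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if self.p < 0:
            raise ValueError(f"p must be >= 0, got {self.p}")
        if not 0 < self.K_total <= 1:
            raise ValueError(f"K_total must be in (0, 1], got {self.K_total}")
        if not 0 <= self.jitter < 1:
            raise ValueError(f"jitter must be in [0, 1), got {self.jitter}")
        if not self.eps_density > 0:
            raise ValueError(f"eps_density must be > 0, got {self.eps_density}")

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class DensityField:
    """Per-cell human (``n_a``) and resource (``n_b``) densities."""

    n_a: np.ndarray
    n_b: np.ndarray

    def __post_init__(self) -> None:
        n_a = np.asarray(self.n_a, dtype=np.float64)
        n_b = np.asarray(self.n_b, dtype=np.float64)
        if n_a.shape != n_b.shape or n_a.ndim != 1:
            raise ValueError("n_a and n_b must be 1-D with equal length")
        if (n_a < 0).any() or (n_b < 0).any():
            raise ValueError("densities must be nonnegative")
        if (n_a > 1 + 1e-9).any() or (n_b > 1 + 1e-9).any():
            raise ValueError("densities must not exceed 1")
        object.__setattr__(self, "n_a", n_a)
        object.__setattr__(self, "n_b", n_b)

    def K_ratio(self, eps: float = 1e-10) -> np.ndarray:
        return ratio_K(self.n_a, self.n_b, eps)


def ratio_K(n_a, n_b, eps: float = 1e-10):
    """Resource/human density ratio ``K = n_b / n_a`` with an ``eps`` floor
    on both densities, so the result is always finite and positive."""
    n_a = np.asarray(n_a, dtype=np.float64)
    n_b = np.asarray(n_b, dtype=np.float64)
    if (n_a < 0).any() or (n_b < 0).any():
        raise ValueError("densities must be nonnegative")
    out = np.maximum(n_b, eps) / np.maximum(n_a, eps)
    return out if out.ndim else float(out)


def _check_positive_ratio(K) -> np.ndarray:
    K = np.asarray(K, dtype=np.float64)
    if (K <= 0).any():
        raise ValueError("ratio K must be strictly positive")
    return K


def omega_a(K, params: ModelParams):
    """Human inertia ``sigma * [exp(-(K - 1/tau)^2) * K]^(1/2)``."""
    K = _check_positive_ratio(K)
    out = params.sigma * np.sqrt(np.exp(-((K - 1.0 / params.tau) ** 2)) * K)
    return out if out.ndim else float(out)


def omega_b(K, params: ModelParams):
    """Resource inertia ``sigma * [exp(-(K/tau)^2) / K]^(1/2)``."""
    K = _check_positive_ratio(K)
    out = params.sigma * np.sqrt(np.exp(-((K / params.tau) ** 2)) / K)
    return out if out.ndim else float(out)


def lambda_coeff(K, params: ModelParams):
    """Predator-prey exchange strength ``omega_a + omega_b + mu``."""
    K = _check_positive_ratio(K)
    out = omega_a(K, params) + omega_b(K, params) + params.mu
    return out if np.ndim(out) else float(out)


def gamma_coeff(K_alpha, K_beta, params: ModelParams):
    """Migration drive ``omega_b(K_alpha) + omega_b(K_beta)``, symmetric in
    its arguments and dominated by whichever cell is resource-stressed."""
    out = omega_b(K_alpha, params) + omega_b(K_beta, params)
    return out if np.ndim(out) else float(out)
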