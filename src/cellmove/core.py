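"""Interaction kernels and movement laws shared by the simulator and moment model.

A motile cell is described by three ingredients:

* a motility rate ``psi = max(0, m + sum_j w(x_j - x_i))`` where the Gaussian
  kernel ``w`` weights the contribution of each neighbour,
* a neighbour-dependent bias vector ``b(x) = sum_j grad v(x_j - x)`` whose
  direction points towards the least (``beta > 0``) or most (``beta < 0``)
  crowded part of the neighbourhood, and whose magnitude acts as the
  concentration of a von Mises law for the movement direction,
* a step length drawn from a normal distribution with mean ``1/lambda_mu`` and
  spread ``sigma_mu``, truncated to non-negative lengths.

All functions here are pure and operate on plain numpy arrays so that both the
event-driven simulator and the moment-dynamics solver can share them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import special, stats

from .errors import ParameterError

__all__ = [
    "ModelParams",
    "BiasVector",
    "gaussian_kernel",
    "grad_bias_kernel",
    "motility_rate",
    "bias_vector",
    "direction_pdf",
    "sample_direction",
    "sample_step_length",
    "step_length_density",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the movement model.

    Units: rates in h^-1, lengths in µm. ``lambda_mu`` is the reciprocal of the
    mean step length (µm^-1), ``sigma_mu`` the spread of the step-length law.
    ``Lx, Ly`` give the periodic rectangle, ``n`` the (constant) cell count.
    """

    m: float
    alpha: float
    sigma_w: float
    beta: float
    sigma_v: float
    lambda_mu: float
    sigma_mu: float
    Lx: float
    Ly: float
    n: int

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ParameterError(f"intrinsic rate m must be >= 0, got {self.m}")
        for name in ("sigma_w", "sigma_v", "lambda_mu", "sigma_mu", "Lx", "Ly"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n < 1:
            raise ParameterError(f"cell count n must be >= 1, got {self.n}")

    @property
    def mean_step(self) -> float:
        """Mean step length 1/lambda_mu in µm."""
        return 1.0 / self.lambda_mu

    @property
    def density(self) -> float:
        """Average density n/(Lx*Ly) in cells µm^-2 (the first moment Z1)."""
        return self.n / (self.Lx * self.Ly)

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class BiasVector:
    """Neighbour-dependent bias b; magnitude = concentration, arg = mean direction."""

    bx: float
    by: float

    @property
    def magnitude(self) -> float:
        return math.hypot(self.bx, self.by)

    @property
    def direction(self) -> float:
        """arg(b) in [0, 2*pi); arbitrary (0.0) when the magnitude vanishes."""
        return math.atan2(self.by, self.bx) % TWO_PI

    def as_array(self) -> np.ndarray:
        return np.array([self.bx, self.by])


def gaussian_kernel(z, strength: float, range_: float):
    """Gaussian interaction kernel ``strength * exp(-|z|^2 / (2 range^2))``.

    ``z`` is a displacement 2-vector or an (..., 2) array of displacements.
    """
    if range_ <= 0:
        raise ParameterError(f"kernel range must be > 0, got {range_}")
    z = np.asarray(z, dtype=float)
    r2 = np.sum(z * z, axis=-1)
    return strength * np.exp(-r2 / (2.0 * range_**2))


def grad_bias_kernel(z, beta: float, sigma_v: float):
    """Gradient of the bias kernel v with respect to its displacement argument.

    ``grad v(z) = -(z / sigma_v^2) * v(z)``; antisymmetric in z. Summing this
    over neighbour displacements ``x_j - x`` yields a vector pointing away from
    crowding for ``beta > 0`` and towards it for ``beta < 0``.
    """
    if sigma_v <= 0:
        raise ParameterError(f"sigma_v must be > 0, got {sigma_v}")
    z = np.asarray(z, dtype=float)
    v = gaussian_kernel(z, beta, sigma_v)
    return -(z / sigma_v**2) * v[..., np.newaxis]


def _default_displacement(a, b):
    return np.asarray(b, dtype=float) - np.asarray(a, dtype=float)


def motility_rate(focal, neighbours, params: ModelParams, displacement_fn=None) -> float:
    """Movement rate ``max(0, m + sum_j w(x_j - x_i))`` of a focal cell.

    ``neighbours`` must not include the focal cell itself. ``displacement_fn``
    computes displacements (e.g. minimum-image in a periodic domain); plain
    Euclidean differences are used when omitted.
    """
    disp_fn = displacement_fn or _default_displacement
    neighbours = np.asarray(neighbours, dtype=float).reshape(-1, 2)
    if neighbours.size == 0:
        return max(0.0, params.m)
    disp = disp_fn(np.asarray(focal, dtype=float), neighbours)
    w = gaussian_kernel(disp, params.alpha, params.sigma_w)
    return max(0.0, params.m + float(np.sum(w)))


def bias_vector(focal, neighbours, params: ModelParams, displacement_fn=None) -> BiasVector:
    """Bias vector ``sum_j grad v(x_j - x)`` over the neighbourhood of ``focal``."""
    disp_fn = displacement_fn or _default_displacement
    neighbours = np.asarray(neighbours, dtype=float).reshape(-1, 2)
    if neighbours.size == 0:
        return BiasVector(0.0, 0.0)
    disp = disp_fn(np.asarray(focal, dtype=float), neighbours)
    g = grad_bias_kernel(disp, params.beta, params.sigma_v)
    total = np.sum(g, axis=0)
    return BiasVector(float(total[0]), float(total[1]))


def direction_pdf(theta, b: BiasVector):
    """von Mises density of the movement direction, per radian.

    ``exp(|b| cos(theta - arg b)) / (2 pi I0(|b|))``; reduces exactly to the
    uniform density ``1/(2 pi)`` when the bias vanishes.
    """
    theta = np.asarray(theta, dtype=float)
    kappa = b.magnitude
    if kappa == 0.0:
        return np.full_like(theta, 1.0 / TWO_PI) if theta.shape else 1.0 / TWO_PI
    val = np.exp(kappa * np.cos(theta - b.direction)) / (TWO_PI * special.i0(kappa))
    return val if theta.shape else float(val)


def sample_direction(b: BiasVector, rng: np.random.Generator, size=None):
    """Draw movement directions in [0, 2*pi) from the von Mises law of ``b``."""
    kappa = b.magnitude
    if kappa == 0.0:
        return rng.uniform(0.0, TWO_PI, size=size)
    return rng.vonmises(b.direction, kappa, size=size) % TWO_PI


def sample_step_length(params: ModelParams, rng: np.random.Generator, size=None):
    """Draw step lengths from the non-negative (truncated) normal step law.

    Rejection from the untruncated normal is used when the acceptance
    probability is high (it is ~1 for typical parameters, where the mean sits
    several sigma above zero); otherwise the inverse-CDF of the truncated
    normal is used directly.
    """
    mu, sigma = params.mean_step, params.sigma_mu
    scalar = size is None
    n = 1 if scalar else int(np.prod(size))
    accept = special.ndtr(mu / sigma)  # P(normal draw >= 0)
    if accept > 0.5:
        out = np.empty(n)
        filled = 0
        while filled < n:
            want = n - filled
            draw = rng.normal(mu, sigma, size=max(want, int(want / accept) + 1))
            good = draw[draw >= 0.0][:want]
            out[filled : filled + good.size] = good
            filled += good.size
    else:
        a = (0.0 - mu) / sigma
        out = stats.truncnorm.ppf(rng.uniform(size=n), a, np.inf, loc=mu, scale=sigma)
    if scalar:
        return float(out[0])
    return out.reshape(size)


def step_length_density(r, params: ModelParams):
    """Density f_L(r) of the non-negative normal step-length law, per µm.

    Normalized so that the integral over [0, inf) is 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("step length r must be >= 0")
    mu, sigma = params.mean_step, params.sigma_mu
    norm = special.ndtr(mu / sigma)  # truncation mass kept above zero
    val = np.exp(-((r - mu) ** 2) / (2.0 * sigma**2)) / (sigma * math.sqrt(TWO_PI) * norm)
    return val if val.shape else float(val)
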