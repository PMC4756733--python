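"""Dynamics of the second spatial moment under movement with directional bias.

For a spatially homogeneous population the first moment Z1 (average density)
is constant, and the second moment — the average density of pairs — depends
only on the pair displacement ``xi``. Closing the moment hierarchy with the
Kirkwood superposition approximation (the third moment expressed as the
product of the three pair moments over the three singleton moments) yields a
closed integro-differential equation on displacement space:

    M2(xi)  = m + (1/Z1^3) INT w(z) Z2(z) Z2(z - xi) dz + w(xi)
    b2(xi)  =     (1/Z1^3) INT grad v(z) Z2(z) Z2(z - xi) dz + grad v(xi)
    dZ2/dt  = -2 M2(xi) Z2(xi)
              + 2 INT f_L(r) g(theta; b2(xi + s)) M2(xi + s) Z2(xi + s) dr dtheta

with ``s = (r cos theta, r sin theta)`` the step taken by the moving member of
a pair at pre-move displacement ``xi + s``; a step ``s`` carries the pair from
displacement ``xi + s`` to ``xi``. ``f_L`` is the non-negative normal
step-length density and ``g`` the von Mises direction density. Evenness of Z2
makes the out/in terms for either pair member coincide, hence the factors 2.
No max(0, .) clamp is applied to M2: the model is solved in regimes where
expected rates stay positive, and a warning flags any violation.

Numerics: the z-integrals are discrete (cross-)correlations on the square
xi-grid, evaluated spectrally (FFT) or by direct summation; the step integral
uses Gauss-Legendre radial nodes spanning the support of f_L (weights
normalized to unit step-law mass) and a uniform angular grid sized to resolve
the largest von Mises concentration present; each quadrature node contributes
a uniformly shifted copy of the pair-flux field, evaluated by bilinear
interpolation inside the grid and by the flat far field (Z2 = Z1^2, b2 = 0)
outside. Time stepping is explicit RK4 from the uncorrelated initial state
Z2 = Z1^2, with dt limited by the fastest out-rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, special

from .core import ModelParams, gaussian_kernel, grad_bias_kernel, step_length_density
from .errors import ConvergenceError, ParameterError
from .pcf import PairCorrelation

logger = logging.getLogger(__name__)

__all__ = [
    "MomentField",
    "MomentParams",
    "kirkwood_triplet",
    "pair_motility_rate_field",
    "pair_bias_field",
    "z2_rhs",
    "solve_to_steady_state",
    "radial_section",
    "steady_state_pcf",
]


@dataclass
class MomentField:
    """Second moment Z2 on a square displacement grid, plus Z1 and grid spec."""

    Z1: float  # cells µm^-2
    Z2: np.ndarray  # (N, N), cells^2 µm^-4, N = 2 * (xi_max / delta) + 1
    delta: float  # grid spacing µm
    xi_max: float  # half-width of the grid µm
    time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Z2 = np.asarray(self.Z2, dtype=float)
        M = int(round(self.xi_max / self.delta))
        if not math.isclose(M * self.delta, self.xi_max, rel_tol=1e-9):
            raise ParameterError("xi_max must be a multiple of delta")
        if self.Z2.shape != (2 * M + 1, 2 * M + 1):
            raise ParameterError(
                f"Z2 must be {(2 * M + 1, 2 * M + 1)} for this grid, got {self.Z2.shape}"
            )

    @property
    def half_points(self) -> int:
        return (self.Z2.shape[0] - 1) // 2

    @property
    def axis(self) -> np.ndarray:
        M = self.half_points
        return (np.arange(-M, M + 1)) * self.delta

    def grid(self):
        x = self.axis
        return np.meshgrid(x, x, indexing="ij")

    def correlation(self) -> np.ndarray:
        """C(xi) = Z2 / Z1^2."""
        return self.Z2 / self.Z1**2


@dataclass(frozen=True)
class MomentParams:
    """Numerical settings for the moment solver.

    ``dt`` of None means auto: ``dt_factor / max M2``. ``tol`` is the
    steady-state criterion max|dZ2/dt| / Z1^2 < tol (per hour). ``n_theta`` is
    a floor; the solver enlarges the angular grid as needed to resolve the
    von Mises concentration actually present.
    """

    delta: float
    xi_max: float
    dt: float | None = None
    tol: float = 1e-6
    n_theta: int = 32
    n_r: int = 20
    dt_factor: float = 0.4
    max_hours: float = 400.0
    newton_polish: bool = True
    switch_res: float = 1e-2

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.xi_max <= 0:
            raise ParameterError("delta and xi_max must be > 0")
        if self.dt is not None and self.dt <= 0:
            raise ParameterError("dt must be > 0 when given")
        if self.tol <= 0:
            raise ParameterError("tol must be > 0")
        if self.n_theta < 16:
            raise ParameterError("n_theta must be >= 16")


def kirkwood_triplet(z2_xy: float, z2_xz: float, z2_yz: float, z1: float) -> float:
    """Kirkwood superposition closure for the third moment of one triplet."""
    return z2_xy * z2_xz * z2_yz / z1**3


def _correlate(A: np.ndarray, B: np.ndarray, delta: float, method: str) -> np.ndarray:
    """T(xi) = integral of A(z) B(z - xi) dz on the grid; B tapering to 0 off-grid.

    ``method`` is 'fft' (spectral, via zero-padded convolution) or 'direct'
    (explicit summation; O(N^4), for cross-checks on small grids only).
    """
    if method == "fft":
        out = signal.fftconvolve(A, B[::-1, ::-1], mode="same")
    elif method == "direct":
        N = A.shape[0]
        M = (N - 1) // 2
        out = np.zeros_like(A)
        for i in range(N):
            for j in range(N):
                # z - xi on the grid: index z=(p,q) maps to B index (p-(i-M), q-(j-M))
                acc = 0.0
                for p in range(N):
                    pi = p - (i - M)
                    if pi < 0 or pi >= N:
                        continue
                    for q in range(N):
                        qj = q - (j - M)
                        if 0 <= qj < N:
                            acc += A[p, q] * B[pi, qj]
                out[i, j] = acc
    else:
        raise ParameterError(f"unknown correlation method {method!r}")
    return out * delta**2


def _kernel_grids(field: MomentField, params: ModelParams):
    X, Y = field.grid()
    disp = np.stack([X, Y], axis=-1)
    w = gaussian_kernel(disp, params.alpha, params.sigma_w)
    gv = grad_bias_kernel(disp, params.beta, params.sigma_v)
    return w, gv


def pair_motility_rate_field(field: MomentField, params: ModelParams,
                             method: str = "fft") -> np.ndarray:
    """Expected movement rate M2(xi) of a cell whose pair partner sits at xi."""
    w, _ = _kernel_grids(field, params)
    if params.alpha == 0.0:
        return np.full_like(field.Z2, params.m)
    Z1 = field.Z1
    A = w * field.Z2
    D = field.Z2 - Z1**2
    integral = Z1**2 * A.sum() * field.delta**2 + _correlate(A, D, field.delta, method)
    M2 = params.m + integral / Z1**3 + w
    if np.any(M2 < 0):
        logger.warning(
            "negative expected movement rates (min %.3g): outside the model's validity",
            float(M2.min()),
        )
    return M2


def pair_bias_field(field: MomentField, params: ModelParams,
                    method: str = "fft") -> np.ndarray:
    """Bias b2(xi) (shape (N, N, 2)) of a cell whose pair partner sits at xi."""
    _, gv = _kernel_grids(field, params)
    if params.beta == 0.0:
        return np.zeros(field.Z2.shape + (2,))
    Z1 = field.Z1
    D = field.Z2 - Z1**2
    out = np.empty(field.Z2.shape + (2,))
    for c in range(2):
        B = gv[..., c] * field.Z2
        integral = Z1**2 * B.sum() * field.delta**2 + _correlate(B, D, field.delta, method)
        out[..., c] = integral / Z1**3 + gv[..., c]
    return out


def _step_influx(Z2, M2, b2, delta, Z1sq, M_far, r_nodes, r_weights,
                 cos_t, sin_t, w_theta):
    """In-flux integral of the pair-density equation at every grid point.

    I(xi) = sum_q sum_k r_weights[q] w_theta G_k(xi + s_qk), where
    G_k(xi') = g(theta_k; b2(xi')) M2(xi') Z2(xi') and s_qk is the step
    r_q (cos theta_k, sin theta_k). Because each quadrature node shifts the
    whole grid by the same offset, each term is a bilinear blend of four
    uniformly shifted copies of G_k — plain vectorized slicing. Off-grid
    values take the flat far field (Z2 = Z1^2, b2 = 0, M2 = M_far).
    """
    N = Z2.shape[0]
    two_pi = 2.0 * math.pi
    base = M2 * Z2 / two_pi
    kappa = np.hypot(b2[..., 0], b2[..., 1])
    biased = np.any(kappa > 0)
    if biased:
        # log I0 via the exponentially scaled Bessel function (overflow-safe)
        log_i0 = np.log(special.i0e(kappa)) + kappa
    far = M_far * Z1sq / two_pi
    pad = int(math.floor(r_nodes.max() / delta)) + 2
    Npad = N + 2 * pad
    Gpad = np.full((Npad, Npad), far)
    out = np.zeros((N, N))
    for k in range(cos_t.shape[0]):
        if biased:
            G = base * np.exp(b2[..., 0] * cos_t[k] + b2[..., 1] * sin_t[k] - log_i0)
        else:
            G = base
        Gpad[pad:pad + N, pad:pad + N] = G
        for q in range(r_nodes.shape[0]):
            dx = r_nodes[q] * cos_t[k] / delta  # offset in grid units
            dy = r_nodes[q] * sin_t[k] / delta
            i0 = math.floor(dx)
            j0 = math.floor(dy)
            fx = dx - i0
            fy = dy - j0
            a = pad + i0
            b = pad + j0
            shifted = ((1 - fx) * (1 - fy) * Gpad[a:a + N, b:b + N]
                       + fx * (1 - fy) * Gpad[a + 1:a + 1 + N, b:b + N]
                       + (1 - fx) * fy * Gpad[a:a + N, b + 1:b + 1 + N]
                       + fx * fy * Gpad[a + 1:a + 1 + N, b + 1:b + 1 + N])
            out += (r_weights[q] * w_theta) * shifted
    return out


def _radial_rule(params: ModelParams, n_r: int):
    """Step-length quadrature: Gauss-Legendre in probability space.

    Nodes are placed by the inverse CDF of the truncated-normal step law, so
    they track the density's peak whatever the parameters; weights are the
    corresponding probability masses (normalized to exactly one, making the
    discrete step law a probability law).
    """
    from scipy import stats

    mu, sigma = params.mean_step, params.sigma_mu
    x, w = np.polynomial.legendre.leggauss(n_r)
    u = 0.5 * (x + 1.0)
    a = (0.0 - mu) / sigma
    nodes = stats.truncnorm.ppf(u, a, np.inf, loc=mu, scale=sigma)
    weights = 0.5 * w
    weights = weights / weights.sum()
    return nodes, weights


def _angular_rule(n_theta_floor: int, kappa_max: float):
    """Uniform angles, enlarged until the trapezoid rule resolves exp(kappa cos)."""
    need = int(8 * math.ceil((6.0 * math.sqrt(max(kappa_max, 0.0)) + 8.0) / 8.0))
    n_t = max(n_theta_floor, need)
    theta = 2.0 * math.pi * np.arange(n_t) / n_t
    return np.cos(theta), np.sin(theta), 2.0 * math.pi / n_t


def _far_field_rate(field: MomentField, params: ModelParams) -> float:
    """M2 far from the partner: m + (1/Z1) * integral of w Z2 (the w(xi) term vanishes)."""
    if params.alpha == 0.0:
        return params.m
    w, _ = _kernel_grids(field, params)
    return params.m + float((w * field.Z2).sum()) * field.delta**2 / field.Z1


def z2_rhs(field: MomentField, params: ModelParams, numerics: MomentParams,
           method: str = "fft") -> np.ndarray:
    """dZ2/dt on the grid."""
    if not np.all(np.isfinite(field.Z2)):
        raise FloatingPointError("non-finite Z2: moment solve diverged")
    M2 = pair_motility_rate_field(field, params, method)
    b2 = pair_bias_field(field, params, method)
    r_nodes, r_weights = _radial_rule(params, numerics.n_r)
    kappa_max = float(np.max(np.hypot(b2[..., 0], b2[..., 1])))
    cos_t, sin_t, w_theta = _angular_rule(numerics.n_theta, kappa_max)
    influx = _step_influx(
        field.Z2, M2, b2, field.delta, field.Z1**2, _far_field_rate(field, params),
        r_nodes, r_weights, cos_t, sin_t, w_theta,
    )
    return -2.0 * M2 * field.Z2 + 2.0 * influx


def _newton_polish(Z2, Z1, params, numerics, method):
    """Finish the steady-state solve with a Jacobian-free Newton-Krylov step.

    Returns the polished field or None if the root finder fails (the caller
    then keeps time-marching).
    """
    from scipy.optimize import newton_krylov
    from scipy.optimize._nonlin import NoConvergence

    def rhs_of(z):
        return z2_rhs(MomentField(Z1, z, numerics.delta, numerics.xi_max),
                      params, numerics, method)

    scale = 2.0 * float(np.max(pair_motility_rate_field(
        MomentField(Z1, Z2, numerics.delta, numerics.xi_max), params, method)))
    try:
        sol = newton_krylov(lambda z: rhs_of(z) / scale, Z2,
                            f_tol=numerics.tol * Z1**2 / scale, method="lgmres",
                            maxiter=50)
    except (NoConvergence, ValueError, FloatingPointError):
        return None
    sol = 0.5 * (sol + sol[::-1, ::-1])
    if sol.min() < -1e-9 * Z1**2:
        return None  # unphysical root; fall back to marching
    return np.maximum(sol, 0.0)


def solve_to_steady_state(params: ModelParams, numerics: MomentParams,
                          method: str = "fft") -> MomentField:
    """Evolve Z2 from the uncorrelated state Z2 = Z1^2 until dZ2/dt vanishes.

    Convergence: max|dZ2/dt| / Z1^2 < numerics.tol (units 1/h). RK4
    time-marching captures the physical transient; once the residual falls
    below ``numerics.switch_res`` the remaining slow relaxation is finished
    by a Newton-Krylov root solve (disable with ``newton_polish=False`` for
    pure marching). Negative Z2 values are clamped to zero and counted;
    persistent clamping indicates closure breakdown and is logged. Raises
    ConvergenceError if the residual has not met the tolerance by
    ``numerics.max_hours`` of model time.
    """
    Z1 = params.density
    M = int(round(numerics.xi_max / numerics.delta))
    N = 2 * M + 1
    field = MomentField(Z1, np.full((N, N), Z1**2), numerics.delta, numerics.xi_max)
    clamped = 0
    t = 0.0
    res = math.inf
    polish = numerics.newton_polish
    while True:
        k1 = z2_rhs(field, params, numerics, method)
        res = float(np.max(np.abs(k1))) / Z1**2
        if res < numerics.tol:
            break
        if polish and res < numerics.switch_res:
            sol = _newton_polish(field.Z2, Z1, params, numerics, method)
            if sol is not None:
                field = MomentField(Z1, sol, numerics.delta, numerics.xi_max, time=t)
                res = float(np.max(np.abs(z2_rhs(field, params, numerics, method)))) / Z1**2
                if res < numerics.tol:
                    break
            polish = False  # fall back to marching
            continue
        if t >= numerics.max_hours:
            raise ConvergenceError(
                f"moment solve not converged by t={t:.1f} h: residual {res:.3e} "
                f"(tol {numerics.tol:.1e})"
            )
        if numerics.dt is not None:
            dt = numerics.dt
        else:
            M2 = pair_motility_rate_field(field, params, method)
            dt = numerics.dt_factor / max(float(np.max(np.abs(M2))), 1e-12)
        dt = min(dt, numerics.max_hours - t + 1e-12)

        def rhs_of(Z2):
            return z2_rhs(MomentField(Z1, Z2, numerics.delta, numerics.xi_max),
                          params, numerics, method)

        Z2 = field.Z2
        k2 = rhs_of(Z2 + 0.5 * dt * k1)
        k3 = rhs_of(Z2 + 0.5 * dt * k2)
        k4 = rhs_of(Z2 + dt * k3)
        Z2 = Z2 + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        neg = Z2 < 0.0
        if np.any(neg):
            clamped += int(neg.sum())
            Z2 = np.where(neg, 0.0, Z2)
        Z2 = 0.5 * (Z2 + Z2[::-1, ::-1])  # enforce pair symmetry against roundoff
        t += dt
        field = MomentField(Z1, Z2, numerics.delta, numerics.xi_max, time=t)
    if clamped:
        logger.warning("clamped %d negative Z2 values during the solve", clamped)
    field.meta.update({"residual": res, "clamped": clamped, "time": t})
    return field


def radial_section(field: MomentField) -> PairCorrelation:
    """C_SM(r): annular average of Z2/Z1^2 in rings of width delta.

    The converged second moment is radially symmetric, so the annular average
    and an axis section agree within discretization error; the average is
    reported. Bins follow the PCF convention ((k-1) delta, k delta].
    """
    C = field.correlation()
    X, Y = field.grid()
    rho = np.hypot(X, Y)
    K = field.half_points
    k = np.ceil(rho / field.delta - 1e-12).astype(int)
    centers = (np.arange(1, K + 1) - 0.5) * field.delta
    values = np.empty(K)
    for b in range(1, K + 1):
        sel = k == b
        values[b - 1] = C[sel].mean()
    return PairCorrelation(centers, values, field.delta, math.nan, math.nan,
                           periodic=True, meta={"source": "SM", "Z1": field.Z1})


def steady_state_pcf(params: ModelParams, numerics: MomentParams,
                     method: str = "fft") -> PairCorrelation:
    """Convenience: solve to steady state and return the radial PCF C_SM(r)."""
    return radial_section(solve_to_steady_state(params, numerics, method))
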