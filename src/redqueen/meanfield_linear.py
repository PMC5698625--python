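"""Linearized self-consistent mean-field solution of the Red Queen.

Under strong selection, deterministic dynamics and a linearization of the
fitness around the population mean activity R, a new allele invades with
probability 2*s0 where s0 = gamma(R)*(1-R)/2 and gamma = f'/f.  Invasions
therefore arrive at rate lambda = mu*s0, i.e. every tau = 1/(mu*s0)
generations.  Between invasions the resident landscape erodes, and averaging
the exponential activity decay over one inter-invasion interval gives
R = (1 - exp(-L))/L with L = rho*tau.  Eliminating tau yields a one-dimensional
self-consistent equation on R whose unique root depends on the parameters only
through eps = vg/u (and the fitness parameter) -- hence R, s0 and the turnover
time are independent of Ne.

The typical-allele trajectory (frequency x, activity theta) follows
dx/dt = gamma(R) * (theta - R)/2 * x,  dtheta/dt = -rho * x * theta,
with closed forms for x(theta) and for the time integrals of x and x^2, from
which the diversity D = tau / int x^2 dt and the turnover time follow by the
tiling (ergodicity) principle.

Both regimes -- succession (one allele at a time, D = 1) and polymorphic
(overlapping invasion waves) -- share the same (R, R_inf, tau); they differ
only in D and T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .model import FitnessSpec, ModelParams

__all__ = [
    "MeanFieldSolution",
    "AlleleTrajectory",
    "linearized_s0",
    "solve_selfconsistent_R",
    "allele_trajectory_linear",
    "closed_form_integrals",
    "diversity_turnover_linear",
]

#: deterministic D below this scaled mutation rate is advisory "succession"
_SUCCESSION_MU = 0.1


@dataclass
class MeanFieldSolution:
    """Equilibrium point of the Red Queen under a mean-field closure.

    Attributes
    ----------
    R, H : float
        Population mean relative recombination rate, and mean fraction of
        active targets (H = R in the uniform hot-spot model).
    R_inf : float
        Residual activity of a dying allele; R = (1 - R_inf)/(-ln R_inf).
    tau : float
        Mean time between successive invasions, 1/(mu*s0), in generations.
    s0, S0 : float
        Invader selection coefficient and its scaled form 4*Ne*s0.
    lam : float
        Invasion rate 1/tau.
    D : float
        Effective number of PRDM9 alleles (>= 1; the raw deterministic value
        is kept in ``diagnostics['D_raw']``).
    T : float
        Turnover time: lag at which cross-homozygosity halves.  Equal to
        D*tau/2 under the mean field; the full-renewal time D*tau is exposed
        as ``T_renew``.
    L : float
        Scaled per-invasion erosion dose rho*tau = eps/s0.
    regime : str
        'succession' or 'polymorphic' (advisory classification).
    """

    R: float
    R_inf: float
    tau: float
    s0: float
    S0: float
    lam: float
    D: float
    T: float
    T_renew: float
    L: float
    regime: str
    H: float = float("nan")
    method: str = "linear"
    diagnostics: dict = field(default_factory=dict)


@dataclass
class AlleleTrajectory:
    """Deterministic (t, x, theta) path of a typical allele.

    theta decreases monotonically from 1 towards R_inf while x rises from x0,
    peaks exactly where theta crosses R (the selection coefficient changes
    sign there) and returns to 0.
    """

    t: np.ndarray
    x: np.ndarray
    theta: np.ndarray
    x0: float
    R: float
    gamma: float
    rho: float

    def x_of_theta(self, theta) -> np.ndarray:
        """Closed form x(theta) = x0 + (gamma/(2*rho)) * [(1-theta) + R*ln theta]."""
        theta = np.asarray(theta, dtype=float)
        return self.x0 + self.gamma / (2.0 * self.rho) * ((1.0 - theta) + self.R * np.log(theta))


def linearized_s0(R: float, spec: FitnessSpec,
                  linearize_at: str = "mean") -> float:
    """Invader selection coefficient at mean activity R, linearized fitness.

    s0 = gamma * (1 - R)/2 with gamma = f'/f evaluated at the mean field R
    (``linearize_at='mean'``, the default, which matches the exact invader
    coefficient to first order in 1-R) or at full activity
    (``linearize_at='fresh'``, for sensitivity checks).
    """
    if not (0.0 < R < 1.0):
        raise ValueError("R must lie in (0, 1)")
    if linearize_at not in ("mean", "fresh"):
        raise ValueError("linearize_at must be 'mean' or 'fresh'")
    at = R if linearize_at == "mean" else 1.0
    return float(spec.log_derivative(at)) * (1.0 - R) / 2.0


def _self_consistency_residual(R: float, eps: float, spec: FitnessSpec,
                               linearize_at: str = "mean") -> float:
    s0 = linearized_s0(R, spec, linearize_at)
    L = eps / s0
    if L > 700.0:  # exp underflow guard: rhs -> 1/L
        rhs = 1.0 / L
    else:
        rhs = (1.0 - math.exp(-L)) / L if L > 1e-12 else 1.0 - L / 2.0
    return R - rhs


def solve_selfconsistent_R(params: ModelParams,
                           spec: FitnessSpec | None = None,
                           bracket: tuple[float, float] = (1e-9, 1.0 - 1e-9),
                           tol: float = 1e-14,
                           linearize_at: str = "mean") -> MeanFieldSolution:
    """Solve R = (1 - e^-L)/L with L = eps/s0(R) by bracketed root-finding.

    The solution depends on (eps, fitness) only; tau, D and T are then filled
    in using Ne through mu and rho.  Raises if the bracket shows no sign
    change (pathological parameters).
    """
    spec = spec if spec is not None else params.fitness
    eps = params.eps
    lo, hi = bracket
    flo = _self_consistency_residual(lo, eps, spec, linearize_at)
    fhi = _self_consistency_residual(hi, eps, spec, linearize_at)
    if flo * fhi > 0:
        raise RuntimeError(
            f"no sign change on bracket {bracket}: f(lo)={flo:g}, f(hi)={fhi:g}")
    R = brentq(_self_consistency_residual, lo, hi,
               args=(eps, spec, linearize_at),
               xtol=tol, rtol=4 * np.finfo(float).eps)
    s0 = linearized_s0(R, spec, linearize_at)
    L = eps / s0
    R_inf = math.exp(-L)
    tau = 1.0 / (params.mu * s0)
    sol = MeanFieldSolution(
        R=R, H=R, R_inf=R_inf, tau=tau, s0=s0, S0=4.0 * params.Ne * s0,
        lam=1.0 / tau, D=1.0, T=tau / 2.0, T_renew=tau, L=L,
        regime="succession", method="linear",
        diagnostics={"residual": abs(_self_consistency_residual(R, eps, spec, linearize_at))},
    )
    return diversity_turnover_linear(sol, params, spec)


def closed_form_integrals(R: float, R_inf: float, gamma: float,
                          rho: float) -> tuple[float, float]:
    """Lifetime integrals of the typical-allele frequency (x0 -> 0 limit).

    int x dt = (-ln R_inf)/rho  (the tiling identity: equals tau when
    R_inf = exp(-rho*tau));
    int x^2 dt = (gamma/(2*rho^2)) * [L - (1-R_inf) - L*(1-R_inf)/2],
    with L = -ln R_inf.
    """
    L = -math.log(R_inf)
    int_x = L / rho
    int_x2 = gamma / (2.0 * rho ** 2) * (L - (1.0 - R_inf) - L * (1.0 - R_inf) / 2.0)
    return int_x, int_x2


def diversity_turnover_linear(solution: MeanFieldSolution, params: ModelParams,
                              spec: FitnessSpec | None = None) -> MeanFieldSolution:
    """Fill D and T from the closed-form trajectory integrals.

    1/D = (1/tau) int x^2 dt (tiling); D is clamped at 1 (succession), and
    T = D*tau/2 (cross-homozygosity half-decorrelation; D*tau is the full
    renewal time).
    """
    spec = spec if spec is not None else params.fitness
    gamma = float(spec.log_derivative(solution.R))
    int_x, int_x2 = closed_form_integrals(solution.R, solution.R_inf, gamma,
                                          params.rho)
    if int_x2 <= 0:
        raise RuntimeError("non-positive int x^2 dt: upstream root is invalid")
    D_raw = solution.tau / int_x2
    D = max(1.0, D_raw)
    regime = "succession" if (D_raw <= 1.0 + 1e-6 or params.mu < _SUCCESSION_MU) \
        else "polymorphic"
    solution.D = D
    solution.T = D * solution.tau / 2.0
    solution.T_renew = D * solution.tau
    solution.regime = regime
    solution.diagnostics.update(D_raw=D_raw, int_x=int_x, int_x2=int_x2,
                                gamma=gamma)
    return solution


def allele_trajectory_linear(R: float, params: ModelParams,
                             spec: FitnessSpec | None = None,
                             x0: float | None = None,
                             n: int = 2000) -> AlleleTrajectory:
    """Integrate the typical-allele path under the linearized mean field.

    Uses theta as the integration variable (it is strictly monotone):
    dt = -dtheta/(rho*x*theta) with the closed-form x(theta).  The path starts
    at (x0 = 1/(2*Ne), theta = 1) and ends where x returns to x0's level near
    the dying activity R_inf.
    """
    spec = spec if spec is not None else params.fitness
    if x0 is None:
        x0 = 1.0 / (2.0 * params.Ne)
    gamma = float(spec.log_derivative(R))
    rho = params.rho
    coef = gamma / (2.0 * rho)

    def x_of_theta(th):
        return x0 + coef * ((1.0 - th) + R * np.log(th))

    # terminal activity: the deterministic path is cut where the frequency
    # returns to its starting level x0 (one copy); x(theta) = 0 would only be
    # reached in infinite time
    lo = 1e-300
    theta_end = brentq(lambda th: x_of_theta(th) - x0, lo, R, xtol=1e-15)
    theta = np.linspace(1.0, theta_end, n)
    x = np.maximum(x_of_theta(theta), x0)
    # time grid by quadrature of dt/dtheta = -1/(rho x theta)
    integrand = 1.0 / (rho * x * theta)
    t = cumulative_trapezoid(-integrand, theta, initial=0.0)
    return AlleleTrajectory(t=t, x=x, theta=theta, x0=x0, R=R, gamma=gamma,
                            rho=rho)
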