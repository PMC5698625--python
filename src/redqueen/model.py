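"""Core domain types for the Red Queen model of recombination hot-spot turnover.

The model tracks the PRDM9 locus of a panmictic diploid Wright-Fisher
population of constant size ``Ne``.  Each PRDM9 allele recognises its own
private set of genomic target motifs (hot spots).  Recombination at a hot spot
triggers DSB-induced biased gene conversion (dBGC) against the hot allele of
the target, so hot spots self-destruct: the fraction of still-active targets
of an allele -- its *activity* -- decays over the allele's lifetime at a rate
proportional to the allele's population frequency.  Fitness increases with an
individual's genome-wide recombination activity, so eroded alleles are
selected against and fresh alleles (full activity) are favoured, yielding a
perpetual intra-genomic arms race.

This module holds the parameter containers, the hot-spot strength models, the
fitness functions and the selection-coefficient machinery shared by the
forward simulator and the mean-field solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FitnessSpec",
    "ModelParams",
    "PopulationState",
    "UniformHotspots",
    "GammaHotspots",
    "hotspot_model",
    "genotype_recombination",
    "fitness_eval",
    "marginal_fitness",
    "marginal_fitness_all",
    "mean_fitness",
    "selection_coefficient",
    "s0_new_allele",
]


# ---------------------------------------------------------------------------
# Hot-spot strength models
# ---------------------------------------------------------------------------


class UniformHotspots:
    """All hot spots of an allele recombine at the same relative rate.

    State variable is the cumulative erosion dose ``y = rho * int x dt``; the
    fraction of still-active targets is ``theta(y) = exp(-y)`` and, with
    uniform strengths, the mean relative recombination rate equals theta.
    """

    a = None

    def theta(self, y):
        return np.exp(-np.asarray(y, dtype=float))

    def rate(self, y):
        return self.theta(y)

    def __repr__(self):  # pragma: no cover
        return "UniformHotspots()"

    def __eq__(self, other):
        return isinstance(other, UniformHotspots)


class GammaHotspots:
    """Hot-spot strengths drawn from a gamma distribution of mean 1, shape a.

    A hot spot of relative strength ``c`` erodes at rate proportional to c,
    so after a cumulative dose y its survival probability is ``exp(-c*y)``.
    Averaging over the gamma density (a Laplace transform) gives the fraction
    of active targets ``theta(y) = (1 + y/a)^-a`` and the mean relative
    recombination rate ``r(y) = (1 + y/a)^-(a+1)`` (strength-weighted
    survival: strong hot spots die first, hence r <= theta).  As a -> inf the
    distribution degenerates to a point mass and the uniform model is
    recovered.
    """

    def __init__(self, a: float):
        if not (a > 0):
            raise ValueError(f"gamma shape a must be > 0, got {a}")
        self.a = float(a)

    def theta(self, y):
        y = np.asarray(y, dtype=float)
        return np.exp(-self.a * np.log1p(y / self.a))

    def rate(self, y):
        y = np.asarray(y, dtype=float)
        return np.exp(-(self.a + 1.0) * np.log1p(y / self.a))

    def __repr__(self):  # pragma: no cover
        return f"GammaHotspots(a={self.a})"

    def __eq__(self, other):
        return isinstance(other, GammaHotspots) and other.a == self.a


def hotspot_model(a: float | None):
    """Return the hot-spot model for shape ``a`` (None means uniform)."""
    return UniformHotspots() if a is None else GammaHotspots(a)


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitnessSpec:
    """Fitness as a function of relative genome-wide recombination activity R.

    Two monotone families, both normalised so f(1) = 1:

    * ``power``:       f(R) = R**alpha
    * ``exponential``: f(R) = exp(beta * (R - 1))

    Larger alpha (or beta) penalises low recombination more strongly.  The
    neutral limit alpha (beta) -> 0 gives f = 1 everywhere.
    """

    kind: str = "power"
    parameter: float = 1e-2

    def __post_init__(self):
        if self.kind not in ("power", "exponential"):
            raise ValueError(f"unknown fitness kind {self.kind!r}")
        if self.parameter < 0:
            raise ValueError("fitness parameter must be >= 0")

    def __call__(self, R):
        """Vectorised evaluation; R = 0 maps to the boundary value."""
        R = np.asarray(R, dtype=float)
        if self.kind == "power":
            with np.errstate(divide="ignore"):
                out = np.where(R > 0, np.exp(self.parameter * np.log(np.maximum(R, 1e-300))), 0.0)
            if self.parameter == 0:
                out = np.ones_like(R)
            return out if out.ndim else float(out)
        out = np.exp(self.parameter * (R - 1.0))
        return out if out.ndim else float(out)

    def log_derivative(self, R):
        """gamma(R) = f'(R)/f(R): alpha/R for power, beta for exponential."""
        R = np.asarray(R, dtype=float)
        if self.kind == "power":
            out = self.parameter / R
        else:
            out = np.full_like(R, self.parameter)
        return out if out.ndim else float(out)


def genotype_recombination(theta_i: float, theta_j: float) -> float:
    """Relative recombination activity of a diploid genotype (additive model).

    R_ij = (theta_i + theta_j) / 2; symmetric, and equal to theta for a
    homozygote.
    """
    ti, tj = np.asarray(theta_i, float), np.asarray(theta_j, float)
    if np.any(ti < 0) or np.any(ti > 1) or np.any(tj < 0) or np.any(tj > 1):
        raise ValueError("activities must lie in [0, 1]")
    out = (ti + tj) / 2.0
    return out if out.ndim else float(out)


def fitness_eval(spec: FitnessSpec, R: float) -> float:
    """Evaluate fitness at relative recombination activity R in (0, 1]."""
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0) or np.any(R > 1):
        raise ValueError("relative recombination activity must lie in (0, 1]")
    out = spec(R)
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParams:
    """All rates and sizes of the Red Queen model.

    Parameters
    ----------
    Ne : int
        Effective population size (diploid individuals).
    u : float
        Functional mutation rate at the PRDM9 locus, per haploid copy per
        generation (each mutation creates an allele with an entirely fresh
        target set, activity 1).
    v : float
        Inactivating mutation rate per target site per generation.
    g : float
        dBGC conversion rate per heterozygous target per generation,
        conditional on homozygosity for the PRDM9 allele recognising it.
    fitness : FitnessSpec
    a : float or None
        Gamma shape of the hot-spot strength distribution; None selects the
        uniform-strength model.

    Derived compound parameters: scaled erosion rate ``rho = 4*Ne*v*g``,
    scaled PRDM9 mutation rate ``mu = 4*Ne*u`` and the erosion-restoration
    balance ``eps = rho/mu = v*g/u``, which is independent of Ne and sets the
    equilibrium erosion level.
    """

    Ne: int
    u: float
    v: float
    g: float
    fitness: FitnessSpec = field(default_factory=FitnessSpec)
    a: float | None = None

    def __post_init__(self):
        if int(self.Ne) < 1:
            raise ValueError("Ne must be a positive integer")
        object.__setattr__(self, "Ne", int(self.Ne))
        for name in ("u", "v", "g"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if self.a is not None and not (self.a > 0):
            raise ValueError("gamma shape a must be > 0 when present")

    @property
    def rho(self) -> float:
        return 4.0 * self.Ne * self.v * self.g

    @property
    def mu(self) -> float:
        return 4.0 * self.Ne * self.u

    @property
    def eps(self) -> float:
        return self.v * self.g / self.u

    @property
    def model(self):
        return hotspot_model(self.a)

    def with_Ne(self, Ne: int) -> "ModelParams":
        """Same rates at a different population size (rescales rho and mu)."""
        return ModelParams(Ne=Ne, u=self.u, v=self.v, g=self.g,
                           fitness=self.fitness, a=self.a)


# ---------------------------------------------------------------------------
# Population state
# ---------------------------------------------------------------------------


@dataclass
class PopulationState:
    """Multiset of PRDM9 alleles with copy counts and erosion doses.

    ``ids`` are unique, never-recycled allele identifiers; ``counts`` are
    haploid copy numbers summing to 2*Ne; ``dose`` is the cumulative dBGC
    erosion dose y of each allele (0 at birth, non-decreasing).  The activity
    theta and mean recombination rate r follow from the hot-spot model.
    """

    Ne: int
    ids: np.ndarray
    counts: np.ndarray
    dose: np.ndarray
    model: UniformHotspots | GammaHotspots = field(default_factory=UniformHotspots)
    t: int = 0

    @classmethod
    def monomorphic(cls, Ne: int, model=None) -> "PopulationState":
        model = model if model is not None else UniformHotspots()
        return cls(Ne=int(Ne),
                   ids=np.array([0], dtype=np.int64),
                   counts=np.array([2 * int(Ne)], dtype=np.int64),
                   dose=np.zeros(1),
                   model=model)

    @property
    def x(self) -> np.ndarray:
        return self.counts / (2.0 * self.Ne)

    @property
    def theta(self) -> np.ndarray:
        return self.model.theta(self.dose)

    @property
    def r(self) -> np.ndarray:
        """Per-allele mean relative recombination rate (equals theta when uniform)."""
        return self.model.rate(self.dose)

    @property
    def K(self) -> int:
        return len(self.ids)

    def validate(self) -> None:
        if self.K == 0:
            raise ValueError("empty population")
        if int(self.counts.sum()) != 2 * self.Ne:
            raise ValueError("copy counts must sum to 2*Ne")
        if np.any(self.counts < 0) or np.any(self.dose < 0):
            raise ValueError("negative counts or erosion doses")

    def copy(self) -> "PopulationState":
        return PopulationState(Ne=self.Ne, ids=self.ids.copy(),
                               counts=self.counts.copy(), dose=self.dose.copy(),
                               model=self.model, t=self.t)


# ---------------------------------------------------------------------------
# Fitness of alleles within a population
# ---------------------------------------------------------------------------


def marginal_fitness_all(pop: PopulationState, spec: FitnessSpec) -> np.ndarray:
    """Mean fitness of each allele over random-mating partners.

    fbar_i = sum_j x_j f((r_i + r_j)/2), including the homozygote term j = i
    at weight x_i.
    """
    pop.validate()
    r = pop.r
    F = spec((r[:, None] + r[None, :]) / 2.0)
    return F @ pop.x


def marginal_fitness(i: int, pop: PopulationState, spec: FitnessSpec) -> float:
    """Mean fitness induced by allele ``i`` (positional index) over the population."""
    return float(marginal_fitness_all(pop, spec)[i])


def mean_fitness(pop: PopulationState, spec: FitnessSpec) -> float:
    """Population mean fitness fbar = sum_i x_i fbar_i."""
    return float(pop.x @ marginal_fitness_all(pop, spec))


def selection_coefficient(i: int, pop: PopulationState, spec: FitnessSpec) -> float:
    """s_i = fbar_i / fbar - 1 (relative marginal fitness minus one).

    The frequency-weighted average of s_i over the population is 0 by
    construction.
    """
    fbar_all = marginal_fitness_all(pop, spec)
    fbar = float(pop.x @ fbar_all)
    if fbar <= 0:
        raise ValueError("non-positive mean fitness")
    return float(fbar_all[i] / fbar - 1.0)


def s0_new_allele(pop: PopulationState, spec: FitnessSpec) -> float:
    """Selection coefficient of a fresh invader (activity 1, vanishing frequency).

    s0 = [sum_j x_j f((1 + r_j)/2)] / fbar - 1.  Non-negative whenever all
    resident activities are <= 1 and f is increasing.
    """
    pop.validate()
    r = pop.r
    fbar_all = marginal_fitness_all(pop, spec)
    fbar = float(pop.x @ fbar_all)
    if fbar <= 0:
        raise ValueError("non-positive mean fitness")
    f_inv = float(pop.x @ spec((1.0 + r) / 2.0))
    return f_inv / fbar - 1.0
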