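"""Discrete-generation Wright-Fisher engine for the Red Queen model.

Each generation applies, in order:

1. mutation  -- Poisson(2*Ne*u) new PRDM9 alleles, each replacing one
   uniformly chosen haploid copy;
2. erosion   -- every segregating allele accrues dBGC dose rho*x_i
   (activity theta_i multiplied by exp(-rho*x_i) in the uniform model);
3. selection and drift -- the next generation's 2*Ne copies are drawn from a
   multinomial with weights proportional to x_i * fbar_i.

A run starts monomorphic, burns in until every starting allele has gone
extinct, then records the stationary phase for ``burnin_multiplier`` times the
burn-in length.  Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import FitnessSpec, ModelParams, PopulationState, marginal_fitness_all

__all__ = [
    "SimulationConfig",
    "TrajectoryRecord",
    "BurninError",
    "mutate_step",
    "erode_step",
    "select_drift_step",
    "run_simulation",
]


class BurninError(RuntimeError):
    """Burn-in (extinction of all starting alleles) not reached in time."""


@dataclass(frozen=True)
class SimulationConfig:
    """Run protocol for one Wright-Fisher simulation."""

    params: ModelParams
    seed: int = 0
    record_stride: int = 1          # generations between recorded samples
    max_generations: int = 5_000_000
    burnin_multiplier: float = 50.0  # stationary span / burn-in span

    def __post_init__(self):
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if not (self.burnin_multiplier > 0):
            raise ValueError("burnin_multiplier must be > 0")


@dataclass
class TrajectoryRecord:
    """Stationary-phase samples of a simulation run.

    ``samples`` holds per-sample allele tables (generation, ids, x, dose);
    ``summaries`` one row per sample with the standard statistics: effective
    allele number D = 1/sum(x^2), population mean recombination activity
    R = sum(x*r), mean fraction of active targets H = sum(x*theta) (equal to R
    in the uniform model), homozygosity and allele count K.
    """

    config: SimulationConfig
    burnin: int
    generations: np.ndarray
    sample_ids: list
    sample_x: list
    sample_dose: list
    summaries: pd.DataFrame

    @property
    def stride(self) -> int:
        return self.config.record_stride

    @property
    def n_samples(self) -> int:
        return len(self.generations)

    def allele_table(self) -> pd.DataFrame:
        """Long-format table: one row per (sample, allele)."""
        frames = []
        model = self.config.params.model
        for t, ids, x, dose in zip(self.generations, self.sample_ids,
                                   self.sample_x, self.sample_dose):
            frames.append(pd.DataFrame({
                "generation": t, "allele": ids, "x": x,
                "theta": model.theta(dose), "dose": dose,
            }))
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Single steps (operate in place on a PopulationState and return it)
# ---------------------------------------------------------------------------


def mutate_step(pop: PopulationState, params: ModelParams, rng,
                next_id: int | None = None, k: int | None = None) -> PopulationState:
    """Create k ~ Poisson(2*Ne*u) fresh alleles, each replacing one haploid copy.

    The donor copy is uniform over the 2*Ne copies (so common alleles are the
    likelier donors); a new allele created earlier in the same generation can
    itself donate.  ``k`` may be forced for testing.
    """
    if k is None:
        k = int(rng.poisson(2.0 * params.Ne * params.u))
    if k == 0:
        return pop
    if next_id is None:
        next_id = int(pop.ids.max()) + 1
    ids = list(pop.ids)
    counts = list(pop.counts)
    dose = list(pop.dose)
    two_ne = 2 * pop.Ne
    for _ in range(k):
        # pick a uniform haploid copy as donor
        c = int(rng.integers(two_ne))
        acc = 0
        for j, n in enumerate(counts):
            acc += n
            if c < acc:
                counts[j] -= 1
                break
        ids.append(next_id)
        counts.append(1)
        dose.append(0.0)
        next_id += 1
    keep = [j for j, n in enumerate(counts) if n > 0]
    pop.ids = np.array([ids[j] for j in keep], dtype=np.int64)
    pop.counts = np.array([counts[j] for j in keep], dtype=np.int64)
    pop.dose = np.array([dose[j] for j in keep])
    return pop


def erode_step(pop: PopulationState, params: ModelParams) -> PopulationState:
    """Deterministic dBGC erosion: dose_i += rho * x_i for every allele.

    In the uniform model this is theta_i <- theta_i * exp(-rho * x_i), the
    exact one-generation solution of dtheta/dt = -rho*x*theta (and it keeps
    theta strictly positive even for large rho*x).
    """
    pop.dose = pop.dose + params.rho * pop.x
    return pop


def select_drift_step(pop: PopulationState, params: ModelParams, rng) -> PopulationState:
    """Multinomial resampling of 2*Ne copies with weights x_i * fbar_i."""
    x = pop.x
    if params.fitness.parameter == 0.0:
        p = x
    else:
        fbar = marginal_fitness_all(pop, params.fitness)
        w = x * fbar
        p = w / w.sum()
    counts = rng.multinomial(2 * pop.Ne, p)
    keep = counts > 0
    pop.ids = pop.ids[keep]
    pop.counts = counts[keep].astype(np.int64)
    pop.dose = pop.dose[keep]
    return pop


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def _summarize(pop: PopulationState) -> dict:
    x = pop.x
    hom = float(x @ x)
    return {
        "generation": pop.t,
        "D": 1.0 / hom,
        "R": float(x @ pop.r),
        "H": float(x @ pop.theta),
        "hom": hom,
        "K": pop.K,
    }


def run_simulation(config: SimulationConfig) -> TrajectoryRecord:
    """Burn in, then record the stationary phase.  Reproducible from seed.

    Raises
    ------
    BurninError
        If some starting allele still segregates after ``max_generations``
        (e.g. u = 0 from a monomorphic start).
    """
    params = config.params
    rng = np.random.default_rng(config.seed)
    pop = PopulationState.monomorphic(params.Ne, params.model)
    initial_ids = set(int(i) for i in pop.ids)
    next_id = int(pop.ids.max()) + 1

    def step():
        nonlocal next_id
        k = int(rng.poisson(2.0 * params.Ne * params.u))
        if k:
            mutate_step(pop, params, rng, next_id=next_id, k=k)
            next_id += k
        erode_step(pop, params)
        select_drift_step(pop, params, rng)
        pop.t += 1

    # burn-in: run until all initial alleles are extinct
    burnin = None
    for gen in range(config.max_generations):
        step()
        if initial_ids and not initial_ids.intersection(pop.ids.tolist()):
            initial_ids = set()
            burnin = pop.t
            break
    if burnin is None:
        raise BurninError(
            f"burn-in not reached within {config.max_generations} generations "
            f"(Ne={params.Ne}, u={params.u:g}; {pop.K} alleles, "
            f"{len(initial_ids)} initial survivors)")

    span = int(np.ceil(config.burnin_multiplier * burnin))
    generations, ids_l, x_l, dose_l, rows = [], [], [], [], []
    for j in range(span):
        if j % config.record_stride == 0:
            generations.append(pop.t)
            ids_l.append(pop.ids.copy())
            x_l.append(pop.x.copy())
            dose_l.append(pop.dose.copy())
            rows.append(_summarize(pop))
        step()

    return TrajectoryRecord(
        config=config, burnin=burnin,
        generations=np.array(generations, dtype=np.int64),
        sample_ids=ids_l, sample_x=x_l, sample_dose=dose_l,
        summaries=pd.DataFrame(rows),
    )
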