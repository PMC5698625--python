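"""Summary statistics of Red Queen trajectories and the phase-diagram scan.

Diversity is measured as the effective number of PRDM9 alleles
D = 1/sum(x_i^2) (inverse homozygosity).  Landscape turnover is measured
through the cross-homozygosity CH(T): the homozygosity of a fictitious 50/50
mixture of the population at time t and at time t+T, averaged over t.  CH(0)
is the instant homozygosity and CH decays to 0 once the allele pool has been
fully renewed; the turnover time is the lag at which CH has dropped to half
of CH(0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParams, PopulationState
from .simulate import SimulationConfig, TrajectoryRecord, run_simulation

__all__ = [
    "diversity",
    "mean_activity",
    "cross_homozygosity",
    "cross_homozygosity_series",
    "turnover_time",
    "SummaryStats",
    "summarize_trajectory",
    "ScanResult",
    "phase_scan",
]


def diversity(x) -> float:
    """Effective allele number D = 1/sum(x^2); D = K iff all weights equal."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or abs(x.sum() - 1.0) > 1e-8:
        raise ValueError("x must be a normalized frequency vector")
    return 1.0 / float(x @ x)


def mean_activity(pop: PopulationState) -> float:
    """Population mean relative recombination rate R = sum_i x_i r_i.

    Under the additive genotype model this equals the double sum
    sum_ij x_i x_j (r_i + r_j)/2.  In the uniform hot-spot model r = theta.
    """
    pop.validate()
    return float(pop.x @ pop.r)


def _pair_ch(ids_a, x_a, ids_b, x_b) -> float:
    """sum over shared allele ids of x_a * x_b."""
    common, ia, ib = np.intersect1d(ids_a, ids_b, assume_unique=True,
                                    return_indices=True)
    if len(common) == 0:
        return 0.0
    return float(x_a[ia] @ x_b[ib])


def cross_homozygosity(traj: TrajectoryRecord, lag: int) -> float:
    """Time-averaged CH(lag) = <sum_i x_{i,t} x_{i,t+lag}> over recorded pairs.

    ``lag`` is in generations and must be a multiple of the recording stride.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    off, rem = divmod(lag, traj.stride)
    if rem:
        raise ValueError(f"lag must be a multiple of the stride {traj.stride}")
    n = traj.n_samples
    if off >= n:
        raise ValueError("lag exceeds the recorded span")
    vals = [
        _pair_ch(traj.sample_ids[t], traj.sample_x[t],
                 traj.sample_ids[t + off], traj.sample_x[t + off])
        for t in range(n - off)
    ]
    return float(np.mean(vals))


def cross_homozygosity_series(traj: TrajectoryRecord,
                              max_lag: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """CH at every recorded lag up to ``max_lag`` generations."""
    n = traj.n_samples
    max_off = n - 1 if max_lag is None else min(n - 1, max_lag // traj.stride)
    lags = np.arange(max_off + 1) * traj.stride
    ch = np.array([cross_homozygosity(traj, int(l)) for l in lags])
    return lags, ch


def turnover_time(traj: TrajectoryRecord) -> float | None:
    """Lag at which CH first drops to half of CH(0), linearly interpolated.

    Returns None (undetermined) if CH never reaches the half-point within the
    recorded span -- e.g. for a frozen population.
    """
    n = traj.n_samples
    if n < 2:
        raise ValueError("trajectory too short for a turnover time")
    ch0 = cross_homozygosity(traj, 0)
    half = ch0 / 2.0
    prev = ch0
    for off in range(1, n):
        cur = cross_homozygosity(traj, off * traj.stride)
        if cur <= half:
            lo, hi = (off - 1) * traj.stride, off * traj.stride
            if cur == prev:
                return float(hi)
            frac = (prev - half) / (prev - cur)
            return float(lo + frac * (hi - lo))
        prev = cur
    return None


@dataclass(frozen=True)
class SummaryStats:
    """Stationary means and variances of the per-sample summary statistics."""

    D: float
    R: float
    H: float
    hom: float
    T: float | None
    var: dict

    @classmethod
    def columns(cls):
        return ("D", "R", "H", "hom")


def summarize_trajectory(traj: TrajectoryRecord) -> SummaryStats:
    """Arithmetic trajectory means/variances plus the CH turnover time."""
    s = traj.summaries
    means = {c: float(s[c].mean()) for c in SummaryStats.columns()}
    var = {c: float(s[c].var(ddof=1)) for c in SummaryStats.columns()}
    return SummaryStats(T=turnover_time(traj), var=var, **means)


# ---------------------------------------------------------------------------
# Phase-diagram scans
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    """One simulation per grid point of a single varied parameter."""

    varied: str
    grid: np.ndarray
    table: pd.DataFrame   # one row per point; NaNs where a run failed
    failures: dict        # grid value -> error message


_SCANNABLE = ("Ne", "u", "vg", "alpha")


def phase_scan(central: ModelParams, varied: str, n_points: int = 64,
               span_decades: float = 4.0, seeds=None,
               record_stride: int = 1, max_generations: int = 5_000_000,
               burnin_multiplier: float = 50.0) -> ScanResult:
    """Scan one parameter over a log-spaced grid centred on its current value.

    The grid spans ``span_decades`` decades in total (half each side).
    ``vg`` is varied through g at fixed v; non-integer Ne values are rounded
    to the nearest integer >= 2.  Failures of individual runs are recorded
    and the scan continues.
    """
    if varied not in _SCANNABLE:
        raise ValueError(f"varied must be one of {_SCANNABLE}")
    if varied == "alpha":
        center = central.fitness.parameter
    elif varied == "vg":
        center = central.v * central.g
    else:
        center = getattr(central, varied)
    grid = center * np.logspace(-span_decades / 2, span_decades / 2, n_points)
    if seeds is None:
        seeds = range(n_points)

    rows, failures = [], {}
    for value, seed in zip(grid, seeds):
        if varied == "Ne":
            p = central.with_Ne(max(2, int(round(value))))
        elif varied == "u":
            p = ModelParams(central.Ne, value, central.v, central.g,
                            central.fitness, central.a)
        elif varied == "vg":
            p = ModelParams(central.Ne, central.u, central.v,
                            value / central.v, central.fitness, central.a)
        else:
            spec = type(central.fitness)(central.fitness.kind, value)
            p = ModelParams(central.Ne, central.u, central.v, central.g,
                            spec, central.a)
        row = {"value": float(value)}
        try:
            traj = run_simulation(SimulationConfig(
                params=p, seed=int(seed), record_stride=record_stride,
                max_generations=max_generations,
                burnin_multiplier=burnin_multiplier))
            stats = summarize_trajectory(traj)
            row.update(D=stats.D, R=stats.R, H=stats.H, hom=stats.hom,
                       T=np.nan if stats.T is None else stats.T)
            row.update({f"var_{c}": stats.var[c] for c in SummaryStats.columns()})
        except Exception as exc:  # record and continue
            failures[float(value)] = str(exc)
            row.update(D=np.nan, R=np.nan, H=np.nan, hom=np.nan, T=np.nan)
        rows.append(row)
    return ScanResult(varied=varied, grid=grid,
                      table=pd.DataFrame(rows), failures=failures)
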