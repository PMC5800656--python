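"""Stochastic lattice simulation of viral spread and trait evolution.

The simulator realises the same process the pair approximation
describes, on a concrete periodic lattice: susceptible target cells are
infected either globally — with hazard ``g_k x_k`` from each strain k,
where ``x_k`` is that strain's current density over all lattice sites —
or locally from each infected orthogonal neighbour with hazard
``beta_L L(G_k) / 4``; infected cells revert to susceptible at rate
``alpha``.  Updates are synchronous over a fixed step ``dt`` with
exponential event probabilities ``1 - exp(-hazard dt)``.

In evolutionary runs every transmission is, with probability ``mu``,
a mutation to a strain of adjacent G value on the strain grid (half
each side, reflecting at the endpoints), so the population explores the
trait axis while competition among co-circulating strains selects on it.

The target / non-target mosaic is frozen: only infection states change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import EpidemicParams, Strain
from .invasion import StrainGrid
from .structures import SpatialStructure

__all__ = [
    "MCConfig",
    "MCState",
    "StepSizeError",
    "step",
    "run_single_strain",
    "run_persistence",
    "run_evolution",
    "summarize_trajectory",
    "PersistenceResult",
    "EvolutionTrajectory",
]


class StepSizeError(RuntimeError):
    """Raised when a per-site event probability exceeds the cap,
    demanding a smaller dt."""


@dataclass
class MCConfig:
    """Simulation settings.

    ``dt=None`` selects the largest step for which the worst-case
    per-site event probability stays at or below ``prob_cap``.
    """

    dt: float | None = None
    prob_cap: float = 0.1
    initial_infected_fraction: float = 0.1
    mutation_rate: float = 0.01
    record_every: float = 1.0
    seed: int | np.random.Generator | None = None

    def resolve_dt(
        self,
        params: EpidemicParams,
        x_C: float,
        strains: list[Strain] | None = None,
    ) -> float:
        if self.dt is not None:
            return self.dt
        # worst-case hazards over the strain registry: global
        # sum_k g_k x_k <= max_k g_k * x_C, local <= max_k beta_L L_k
        # (all 4 neighbours infected)
        if strains:
            g_max = max(params.beta_G * s.G for s in strains)
            l_max = max(params.beta_L * s.local_weight for s in strains)
        else:
            g_max, l_max = params.beta_G, params.beta_L
        h_max = max(g_max * x_C + l_max, params.alpha)
        return self.prob_cap / h_max


@dataclass
class MCState:
    """Per-site state on a concrete lattice.

    ``site_state`` holds -1 for non-target sites, 0 for susceptible
    target cells and ``k + 1`` for a cell infected by strain ``k`` of
    the registry.
    """

    structure: SpatialStructure
    strains: list[Strain]
    site_state: np.ndarray
    time: float = 0.0

    @classmethod
    def initialize(
        cls,
        structure: SpatialStructure,
        strains: list[Strain],
        initial_strain: int,
        infected_fraction: float,
        rng: np.random.Generator,
    ) -> "MCState":
        mask = structure.mask
        site_state = np.where(mask, 0, -1).astype(np.int32)
        targets = np.flatnonzero(mask.ravel())
        n_inf = max(1, int(round(infected_fraction * targets.size)))
        chosen = rng.choice(targets, size=n_inf, replace=False)
        flat = site_state.ravel()
        flat[chosen] = initial_strain + 1
        return cls(structure=structure, strains=strains, site_state=site_state)

    @property
    def n_infected(self) -> int:
        return int((self.site_state > 0).sum())

    def strain_counts(self) -> np.ndarray:
        """Number of cells infected by each strain of the registry."""
        flat = self.site_state[self.site_state > 0]
        return np.bincount(flat - 1, minlength=len(self.strains))

    def mean_G(self) -> float:
        """Population mean proportion of global infection; NaN if extinct."""
        counts = self.strain_counts()
        total = counts.sum()
        if total == 0:
            return float("nan")
        G = np.array([s.G for s in self.strains])
        return float((counts * G).sum() / total)


def _strain_rate_tables(strains: list[Strain], params: EpidemicParams):
    g = np.array([params.beta_G * s.G for s in strains])
    local = np.array([params.beta_L * s.local_weight for s in strains])
    return g, local


def step(
    state: MCState,
    params: EpidemicParams,
    dt: float,
    rng: np.random.Generator,
    mutation_rate: float = 0.0,
    prob_cap: float = 0.1,
) -> MCState:
    """Advance the lattice by one synchronous step of length ``dt``.

    Infection hazards are computed from the state at the start of the
    step; the infecting strain is drawn proportionally to its hazard
    contribution (global pool vs. each of the 4 neighbours).
    """
    ss = state.site_state
    n_strains = len(state.strains)
    g, local = _strain_rate_tables(state.strains, params)

    counts = state.strain_counts()
    x_k = counts / ss.size
    w_global = g * x_k
    W = w_global.sum()

    # local hazard lookup by site value (-1 and 0 map to rate 0)
    lut = np.zeros(n_strains + 2)
    lut[2:] = local * 0.25
    shifts = [(1, 0), (-1, 0), (1, 1), (-1, 1)]
    nb_states = [np.roll(ss, s, axis=ax) for s, ax in shifts]
    lw = [lut[nb + 1] for nb in nb_states]
    H = W + lw[0] + lw[1] + lw[2] + lw[3]

    sus = ss == 0
    if sus.any():
        h_max = float(H[sus].max())
        if max(h_max, params.alpha) * dt > prob_cap + 1e-12:
            raise StepSizeError(
                f"event probability cap exceeded: hazard {h_max:.3g} * dt "
                f"{dt:.3g} > {prob_cap}; reduce dt"
            )
    p_inf = -np.expm1(-H * dt)
    new_inf = sus & (rng.random(ss.shape) < p_inf)
    idx = np.flatnonzero(new_inf.ravel())

    new_strains = np.empty(idx.size, dtype=np.int64)
    if idx.size:
        v = rng.random(idx.size) * H.ravel()[idx]
        is_global = v < W
        if is_global.any():
            cw = np.cumsum(w_global)
            new_strains[is_global] = np.searchsorted(
                cw, rng.random(int(is_global.sum())) * W, side="right"
            ).clip(max=n_strains - 1)
        loc = ~is_global
        if loc.any():
            li = idx[loc]
            v_loc = v[loc] - W
            lw_at = np.stack([a.ravel()[li] for a in lw])  # (4, m)
            cum = np.cumsum(lw_at, axis=0)
            which = (v_loc[None, :] >= cum).sum(axis=0).clip(max=3)
            nb_at = np.stack([a.ravel()[li] for a in nb_states])
            new_strains[loc] = nb_at[which, np.arange(li.size)] - 1
        if mutation_rate > 0.0:
            mut = rng.random(idx.size) < mutation_rate
            if mut.any():
                delta = rng.choice([-1, 1], size=int(mut.sum()))
                cand = new_strains[mut] + delta
                out = (cand < 0) | (cand >= n_strains)
                cand[out] = new_strains[mut][out] - delta[out]  # reflect
                new_strains[mut] = cand.clip(0, n_strains - 1)

    recover = (ss > 0) & (rng.random(ss.shape) < -np.expm1(-params.alpha * dt))

    flat = ss.ravel()
    flat[recover.ravel()] = 0
    flat[idx] = new_strains + 1
    state.time += dt
    return state


@dataclass
class EvolutionTrajectory:
    """Recorded time series of an evolutionary (or single-strain) run."""

    times: np.ndarray
    mean_G: np.ndarray
    infected_density: np.ndarray
    strain_counts: np.ndarray  # (n_records, n_strains)
    extinction_time: float | None = None

    @property
    def extinct(self) -> bool:
        return self.extinction_time is not None


def _run(
    structure: SpatialStructure,
    strains: list[Strain],
    initial_strain: int,
    params: EpidemicParams,
    t_end: float,
    config: MCConfig,
    rng: np.random.Generator,
    mutation_rate: float,
) -> EvolutionTrajectory:
    x_C = structure.moments().x_C
    dt = config.resolve_dt(params, x_C, strains)
    state = MCState.initialize(
        structure, strains, initial_strain, config.initial_infected_fraction, rng
    )
    times, meanG, dens, counts = [], [], [], []
    next_record = 0.0
    extinction = None
    n_steps = int(np.ceil(t_end / dt))
    for _ in range(n_steps + 1):
        if state.time >= next_record - 1e-9:
            times.append(state.time)
            meanG.append(state.mean_G())
            dens.append(state.n_infected / structure.n_sites)
            counts.append(state.strain_counts())
            next_record += config.record_every
        if state.n_infected == 0:
            extinction = state.time
            break
        if state.time >= t_end:
            break
        step(state, params, dt, rng, mutation_rate, config.prob_cap)
    return EvolutionTrajectory(
        times=np.array(times),
        mean_G=np.array(meanG),
        infected_density=np.array(dens),
        strain_counts=np.array(counts),
        extinction_time=extinction,
    )


def run_single_strain(
    structure: SpatialStructure,
    strain: Strain,
    params: EpidemicParams,
    t_end: float,
    config: MCConfig | None = None,
) -> EvolutionTrajectory:
    """Simulate one strain (no mutation) and record its density."""
    config = config or MCConfig()
    rng = np.random.default_rng(config.seed)
    return _run(structure, [strain], 0, params, t_end, config, rng, 0.0)


@dataclass
class PersistenceResult:
    """Outcome of replicated persistence runs."""

    survival_fraction: float
    extinction_times: list[float | None]


def run_persistence(
    structure: SpatialStructure,
    strain_G: float,
    params: EpidemicParams,
    t_end: float = 500.0,
    reps: int = 20,
    config: MCConfig | None = None,
    tradeoff_exponent: float = 1.0,
) -> PersistenceResult:
    """Fraction of replicate runs in which the virus is not extinct at
    ``t_end``, from independent seeded initial infections."""
    config = config or MCConfig()
    rng = np.random.default_rng(config.seed)
    strain = Strain(strain_G, tradeoff_exponent)
    ext: list[float | None] = []
    for _ in range(reps):
        traj = _run(structure, [strain], 0, params, t_end, config, rng, 0.0)
        ext.append(traj.extinction_time)
    surv = sum(e is None for e in ext) / reps
    return PersistenceResult(survival_fraction=surv, extinction_times=ext)


def run_evolution(
    structure: SpatialStructure,
    grid: StrainGrid,
    params: EpidemicParams,
    t_end: float = 5000.0,
    config: MCConfig | None = None,
    initial_G: float = 0.5,
) -> EvolutionTrajectory:
    """Multi-strain run with mutation among adjacent strains on the grid.

    All initial infections carry the grid strain closest to
    ``initial_G``; mutation then lets the population wander along the
    trait axis.  Returns the recorded trajectory; extinction, should it
    happen, is reported through ``extinction_time``.
    """
    config = config or MCConfig()
    rng = np.random.default_rng(config.seed)
    strains = grid.strains()
    init_idx = int(np.argmin(np.abs(grid.values - initial_G)))
    return _run(
        structure,
        strains,
        init_idx,
        params,
        t_end,
        config,
        rng,
        config.mutation_rate,
    )


def summarize_trajectory(
    trajectory: EvolutionTrajectory, tail_fraction: float = 0.5
) -> tuple[float, float]:
    """Mean and standard deviation of the population mean G over the
    trailing ``tail_fraction`` of the recorded trajectory."""
    if not 0.0 < tail_fraction <= 1.0:
        raise ValueError("tail_fraction must lie in (0, 1]")
    n = len(trajectory.times)
    if n == 0:
        raise ValueError("empty trajectory")
    start = int(np.floor(n * (1.0 - tail_fraction)))
    tail = trajectory.mean_G[start:]
    tail = tail[~np.isnan(tail)]
    if tail.size == 0:
        raise ValueError("no surviving records in the requested tail window")
    return float(tail.mean()), float(tail.std())
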