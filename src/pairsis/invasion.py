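"""Adaptive dynamics of the global-infection proportion G.

A rare mutant strain with proportion of global infection ``G'`` is
introduced at the endemic equilibrium of a resident strain with
proportion ``G``.  Its fate is decided by the dominant eigenvalue of
the mutant block ``(x_J, p_SJ, p_IJ, p_JJ)`` of the two-strain pair
dynamics, linearised in the mutant densities with the resident held at
equilibrium.  Scanning residents and mutants over a grid of strains
yields a pairwise invasibility plot (PIP); grid strains that neither
adjacent strain can invade are local ESSs.

For the completely global resident (G = 1) the invasion condition is
available in closed form: a mutant G' < 1 grows if and only if

    (beta_G / beta_L) / (1 - theta + G' theta)  <  p_CC / x_C**2,

so with equal transmission rates the completely global strain remains
uninvadable exactly up to complete spatial randomness (clustering 1),
and in general up to clustering beta_G / beta_L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    EpidemicParams,
    PairState,
    Strain,
    basic_reproduction_number,
    endemic_equilibrium,
    force_of_infection,
)
from .structures import SpatialMoments

__all__ = [
    "StrainGrid",
    "SingularStrategy",
    "PIPResult",
    "mutant_jacobian",
    "invasion_growth_rate",
    "can_invade",
    "build_pip",
    "find_local_ess",
    "invades_global_strain",
    "r0_maximizing_G",
]

#: invasion growth rates within this band of 0 count as neutral
EPS_NEUTRAL = 1e-8


@dataclass(frozen=True)
class StrainGrid:
    """Equally spaced strains on [G_min, G_max] (endpoints included)."""

    n_strains: int = 101
    G_min: float = 0.0
    G_max: float = 1.0
    tradeoff_exponent: float = 1.0

    def __post_init__(self):
        if self.n_strains < 2:
            raise ValueError("need at least two strains")
        if not 0.0 <= self.G_min < self.G_max <= 1.0:
            raise ValueError("need 0 <= G_min < G_max <= 1")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.G_min, self.G_max, self.n_strains)

    def strains(self) -> list[Strain]:
        return [Strain(float(G), self.tradeoff_exponent) for G in self.values]


@dataclass(frozen=True)
class SingularStrategy:
    """A point where the local selection gradient changes sign."""

    G: float
    kind: str  # "ess" | "repeller" | "degenerate"


@dataclass
class PIPResult:
    """Pairwise invasibility plot over a strain grid.

    ``invade[i, j]`` is 1 if mutant ``G_j`` invades resident ``G_i``,
    0 if it cannot, and -1 if resident ``G_i`` is not endemic.  The
    diagonal is 0 (self-invasion is neutral).
    """

    grid: StrainGrid
    invade: np.ndarray
    endemic: np.ndarray
    singular: list[SingularStrategy] = field(default_factory=list)

    @property
    def ess_values(self) -> list[float]:
        return [s.G for s in self.singular if s.kind == "ess"]


def mutant_jacobian(
    resident: Strain,
    mutant: Strain,
    params: EpidemicParams,
    moments: SpatialMoments,
    resident_eq: PairState,
) -> np.ndarray:
    """4x4 Jacobian of the mutant block at the resident equilibrium.

    Rows/columns order: (x_J, p_SJ, p_IJ, p_JJ).  Resident densities are
    frozen at their equilibrium values; the mutant force of infection
    ``phi' = g' x_J + l' p_SJ / x_S`` is linear in the mutant densities.
    """
    r = mutant.rates(params)
    alpha = params.alpha
    rec = resident_eq.reconstruct(moments)
    x_S = rec["x_S"]
    p_SS = rec["p_SS"]
    p_SI = resident_eq.p_SI
    phi = force_of_infection(resident_eq, resident.rates(params), moments)
    if x_S <= 0:
        raise ValueError("resident equilibrium leaves no susceptible cells")
    return np.array(
        [
            [r.g * x_S - alpha, r.l + r.psi, 0.0, 0.0],
            [
                r.g * p_SS,
                r.l * p_SS / x_S - (phi + r.psi + alpha),
                alpha,
                alpha,
            ],
            [r.g * p_SI, phi + r.l * p_SI / x_S, -2.0 * alpha, 0.0],
            [0.0, 2.0 * r.psi, 0.0, -2.0 * alpha],
        ]
    )


def invasion_growth_rate(
    resident: Strain,
    mutant: Strain,
    params: EpidemicParams,
    moments: SpatialMoments,
    resident_eq: PairState | None = None,
) -> float:
    """Invasion fitness: dominant eigenvalue of the mutant block.

    The mutant block is quasi-positive (non-negative off-diagonals), so
    the dominant eigenvalue is real.  ``resident_eq`` may be supplied to
    avoid recomputing the resident equilibrium (as in PIP scans).
    """
    if resident_eq is None:
        resident_eq = endemic_equilibrium(resident, params, moments)
        if resident_eq is None:
            raise ValueError(
                "resident strain is not endemic; mutant establishment in an "
                "empty population is governed by its own R0, not by invasion "
                "fitness"
            )
    J = mutant_jacobian(resident, mutant, params, moments, resident_eq)
    return float(np.max(np.linalg.eigvals(J).real))


def can_invade(
    resident: Strain,
    mutant: Strain,
    params: EpidemicParams,
    moments: SpatialMoments,
    resident_eq: PairState | None = None,
) -> bool:
    """True when the mutant's invasion growth rate clears the neutral band."""
    lam = invasion_growth_rate(resident, mutant, params, moments, resident_eq)
    return bool(lam > EPS_NEUTRAL)


def _gradient_direction(invade_row_up: bool, invade_row_down: bool) -> int:
    """Direction of selection at a grid strain from its two neighbours:
    +1 toward higher G, -1 toward lower G, 0 if neither invades."""
    if invade_row_up and not invade_row_down:
        return 1
    if invade_row_down and not invade_row_up:
        return -1
    if not invade_row_up and not invade_row_down:
        return 0
    return 2  # both neighbours invade: degenerate / near-singular


def build_pip(
    grid: StrainGrid,
    params: EpidemicParams,
    moments: SpatialMoments,
) -> PIPResult:
    """Full pairwise invasibility plot with singular-strategy detection.

    One resident equilibrium is solved per grid strain (cached), then
    every mutant is scored by the 4x4 eigenvalue.  Singular strategies
    are located where the nearest-neighbour selection direction changes
    sign: sign pattern (+, then -) marks an attracting ESS candidate
    (classified "ess" when neither adjacent strain invades), (-, then +)
    marks a repeller.
    """
    strains = grid.strains()
    n = grid.n_strains
    invade = np.zeros((n, n), dtype=np.int8)
    endemic = np.zeros(n, dtype=bool)
    equilibria = [endemic_equilibrium(s, params, moments) for s in strains]
    for i, (res, eq) in enumerate(zip(strains, equilibria)):
        if eq is None:
            invade[i, :] = -1
            continue
        endemic[i] = True
        for j, mut in enumerate(strains):
            if i == j:
                continue
            invade[i, j] = int(
                can_invade(res, mut, params, moments, resident_eq=eq)
            )
    result = PIPResult(grid=grid, invade=invade, endemic=endemic)
    result.singular = _locate_singular(result)
    return result


def _locate_singular(pip: PIPResult) -> list[SingularStrategy]:
    G = pip.grid.values
    n = len(G)
    directions = np.full(n, -9, dtype=int)
    for i in range(n):
        if not pip.endemic[i]:
            continue
        up = bool(pip.invade[i, i + 1] == 1) if i + 1 < n else False
        down = bool(pip.invade[i, i - 1] == 1) if i > 0 else False
        directions[i] = _gradient_direction(up, down)
    singular: list[SingularStrategy] = []
    idx = [i for i in range(n) if directions[i] != -9]
    for k, i in enumerate(idx):
        d = directions[i]
        if d == 0:
            # neither adjacent strain invades: local ESS by definition
            singular.append(SingularStrategy(G=float(G[i]), kind="ess"))
        elif d == 2:
            singular.append(SingularStrategy(G=float(G[i]), kind="degenerate"))
        elif k + 1 < len(idx):
            j = idx[k + 1]
            if d == 1 and directions[j] == -1:
                # selection converges from both sides between i and j
                singular.append(
                    SingularStrategy(G=float(0.5 * (G[i] + G[j])), kind="ess")
                )
            elif d == -1 and directions[j] == 1:
                singular.append(
                    SingularStrategy(G=float(0.5 * (G[i] + G[j])), kind="repeller")
                )
    return singular


def find_local_ess(
    grid: StrainGrid,
    params: EpidemicParams,
    moments: SpatialMoments,
) -> list[Strain]:
    """Grid strains that neither adjacent grid strain can invade.

    Endpoints are judged one-sidedly.  Returns an empty list (with no
    further diagnosis) when no grid strain is endemic.
    """
    strains = grid.strains()
    out: list[Strain] = []
    for i, res in enumerate(strains):
        eq = endemic_equilibrium(res, params, moments)
        if eq is None:
            continue
        invaded = False
        for j in (i - 1, i + 1):
            if 0 <= j < len(strains):
                if can_invade(res, strains[j], params, moments, resident_eq=eq):
                    invaded = True
                    break
        if not invaded:
            out.append(res)
    return out


def invades_global_strain(
    mutant_G: float, params: EpidemicParams, moments: SpatialMoments
) -> bool:
    """Closed-form invasion test against the completely global resident.

    Requires the G = 1 resident to be endemic (beta_G x_C > alpha).
    A mutant with proportion of global infection ``G'`` invades iff

        (beta_G / beta_L) / (1 - theta + G' theta) < p_CC / x_C**2.
    """
    if params.beta_G * moments.x_C <= params.alpha:
        raise ValueError("completely global resident is not endemic")
    lhs = (params.beta_G / params.beta_L) / (
        1.0 - params.theta + mutant_G * params.theta
    )
    return bool(lhs < moments.clustering)


def r0_maximizing_G(
    params: EpidemicParams,
    moments: SpatialMoments,
    grid: StrainGrid | None = None,
) -> Strain:
    """Grid strain maximising the closed-form R0.

    Used to contrast with the ESS: at strong clustering, the ESS
    proportion of global infection falls well below the R0 maximiser.
    """
    grid = grid or StrainGrid()
    strains = grid.strains()
    values = [basic_reproduction_number(s, params, moments) for s in strains]
    return strains[int(np.argmax(values))]
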