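"""Pair-approximation SIS dynamics for a virus with mixed global/local spread.

Target cells on the lattice are susceptible (S) or infected (I);
non-target cells (O) are inert.  A strain is characterised by its
proportion of global infection ``G``: a fraction ``G`` of its
transmission effort goes into cell-free (mass-action, "global") spread
and the remaining weight ``L(G)`` into cell-to-cell ("local") spread to
one of the 4 lattice neighbours.  The default trade-off is linear,
``L(G) = 1 - G``; more generally ``L(G) = 1 - G**s``.

Effective rates for a strain::

    g   = beta_G * G                  (global, mass action)
    l   = beta_L * L(G) * (1 - theta) (local, from outside a focal pair)
    psi = beta_L * L(G) * theta       (local, within a focal pair)

with ``theta = 1/4`` the inverse neighbourhood size.  The per-susceptible
force of infection is ``phi = g x_I + l p_SI / x_S``.

The model state is closed at the pair level: singlet densities ``x_s``
and ordered pair densities ``p_ss'`` evolve with conditional triples
approximated by pairs, ``q_{s/s's''} ~ q_{s/s'}``.  With the constants
(x_C, p_CC) of the frozen target-cell mosaic, three variables
``(x_I, p_SI, p_IO)`` determine the single-strain state and seven
variables the resident+mutant state; all other pair densities follow
from the conservation identities

    p_SS + 2 p_SI + p_II = p_CC
    p_SO + p_IO          = x_C - p_CC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .structures import THETA, SpatialMoments

__all__ = [
    "EpidemicParams",
    "Strain",
    "StrainRates",
    "PairState",
    "TwoStrainState",
    "force_of_infection",
    "deriv_single",
    "deriv_two_strain",
    "integrate",
    "basic_reproduction_number",
    "r0_via_ngm",
    "rho_1",
    "rho_0",
    "is_endemic",
    "endemic_margin_rho_form",
    "endemic_equilibrium",
    "global_strain_equilibrium",
    "proportional_mixing_state",
]

#: densities this close to 0 (or below) are floored to exactly 0
NEGATIVE_FLOOR = 1e-12
#: reconstruction-identity violations beyond this are treated as errors
RECONSTRUCTION_TOL = 1e-8
#: steady-state criterion: max |d/dt| below this value
STEADY_STATE_TOL = 1e-9


@dataclass(frozen=True)
class EpidemicParams:
    """Transmission and recovery rates (per unit time).

    ``theta`` is the inverse neighbourhood size; 1/4 for the square
    lattice with orthogonal neighbours.
    """

    beta_G: float
    beta_L: float
    alpha: float
    theta: float = THETA

    def __post_init__(self):
        if self.beta_G < 0 or self.beta_L < 0 or self.alpha < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 < self.theta <= 1.0:
            raise ValueError("theta must lie in (0, 1]")


@dataclass(frozen=True)
class StrainRates:
    """Effective global / outside-pair / within-pair transmission rates."""

    g: float
    l: float
    psi: float


@dataclass(frozen=True)
class Strain:
    """A viral strain: proportion of global infection plus trade-off shape.

    ``tradeoff_exponent`` is the exponent ``s`` in ``L(G) = 1 - G**s``;
    ``s = 1`` is the linear trade-off, ``s = 0.5`` a concave one under
    which local efficiency drops steeply at small ``G``.
    """

    G: float
    tradeoff_exponent: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.G <= 1.0:
            raise ValueError(f"G must lie in [0, 1], got {self.G}")
        if self.tradeoff_exponent <= 0:
            raise ValueError("tradeoff exponent must be positive")

    @property
    def local_weight(self) -> float:
        """Trade-off weight L(G) of local transmission."""
        return 1.0 - self.G**self.tradeoff_exponent

    def rates(self, params: EpidemicParams) -> StrainRates:
        L = self.local_weight
        return StrainRates(
            g=params.beta_G * self.G,
            l=params.beta_L * L * (1.0 - params.theta),
            psi=params.beta_L * L * params.theta,
        )


@dataclass(frozen=True)
class PairState:
    """Single-strain state: the three independent densities.

    ``x_I`` is the global density of infected cells (measured over all
    lattice sites), ``p_SI`` and ``p_IO`` ordered pair densities.
    """

    x_I: float
    p_SI: float
    p_IO: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x_I, self.p_SI, self.p_IO])

    def reconstruct(self, moments: SpatialMoments) -> dict[str, float]:
        """All dependent densities via the conservation identities."""
        x_S = moments.x_C - self.x_I
        p_II = self.x_I - self.p_SI - self.p_IO
        p_SS = moments.p_CC - 2.0 * self.p_SI - p_II
        p_SO = (moments.x_C - moments.p_CC) - self.p_IO
        return {"x_S": x_S, "p_II": p_II, "p_SS": p_SS, "p_SO": p_SO}

    def validate(self, moments: SpatialMoments, tol: float = RECONSTRUCTION_TOL) -> None:
        dens = {"x_I": self.x_I, "p_SI": self.p_SI, "p_IO": self.p_IO}
        dens.update(self.reconstruct(moments))
        bad = {k: v for k, v in dens.items() if v < -tol}
        if bad:
            raise ValueError(f"inconsistent pair state, negative densities: {bad}")


@dataclass(frozen=True)
class TwoStrainState:
    """Resident + mutant state: the seven independent densities."""

    x_I: float
    p_SI: float
    p_IO: float
    x_J: float
    p_SJ: float
    p_IJ: float
    p_JJ: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.x_I, self.p_SI, self.p_IO, self.x_J, self.p_SJ, self.p_IJ, self.p_JJ]
        )

    def reconstruct(self, moments: SpatialMoments) -> dict[str, float]:
        x_S = moments.x_C - self.x_I - self.x_J
        p_II = self.x_I - self.p_SI - self.p_IJ - self.p_IO
        p_JO = self.x_J - self.p_SJ - self.p_IJ - self.p_JJ
        p_SS = (
            moments.p_CC
            - 2.0 * self.p_SI
            - 2.0 * self.p_SJ
            - p_II
            - 2.0 * self.p_IJ
            - self.p_JJ
        )
        p_SO = (moments.x_C - moments.p_CC) - self.p_IO - p_JO
        return {"x_S": x_S, "p_II": p_II, "p_JO": p_JO, "p_SS": p_SS, "p_SO": p_SO}

    def validate(self, moments: SpatialMoments, tol: float = RECONSTRUCTION_TOL) -> None:
        dens = {
            "x_I": self.x_I,
            "p_SI": self.p_SI,
            "p_IO": self.p_IO,
            "x_J": self.x_J,
            "p_SJ": self.p_SJ,
            "p_IJ": self.p_IJ,
            "p_JJ": self.p_JJ,
        }
        dens.update(self.reconstruct(moments))
        bad = {k: v for k, v in dens.items() if v < -tol}
        if bad:
            raise ValueError(f"inconsistent two-strain state, negative densities: {bad}")


# ---------------------------------------------------------------------------
# forces and derivatives
# ---------------------------------------------------------------------------

def _phi(x_I, p_SI, x_S, g, l):
    """Per-susceptible force of infection phi = g x_I + l p_SI / x_S."""
    if p_SI == 0.0:
        return g * x_I
    if x_S <= 0.0:
        raise ValueError("inconsistent state: p_SI > 0 while x_S = 0")
    return g * x_I + l * p_SI / x_S


def force_of_infection(
    state: PairState, rates: StrainRates, moments: SpatialMoments
) -> float:
    """Hazard experienced by a susceptible cell from outside a focal pair."""
    x_S = moments.x_C - state.x_I
    return _phi(state.x_I, state.p_SI, x_S, rates.g, rates.l)


def _deriv_single_arr(y, rates: StrainRates, alpha: float, moments: SpatialMoments):
    x_I, p_SI, p_IO = y
    x_S = moments.x_C - x_I
    p_II = x_I - p_SI - p_IO
    p_SS = moments.p_CC - 2.0 * p_SI - p_II
    p_SO = (moments.x_C - moments.p_CC) - p_IO
    phi = _phi(x_I, p_SI, x_S, rates.g, rates.l)
    dx_I = rates.g * x_S * x_I + (rates.l + rates.psi) * p_SI - alpha * x_I
    dp_SI = -(phi + rates.psi + alpha) * p_SI + phi * p_SS + alpha * p_II
    dp_IO = phi * p_SO - alpha * p_IO
    return np.array([dx_I, dp_SI, dp_IO])


def deriv_single(
    state: PairState,
    rates: StrainRates,
    params: EpidemicParams,
    moments: SpatialMoments,
    check: bool = True,
) -> np.ndarray:
    """Time derivative of (x_I, p_SI, p_IO) for a single resident strain."""
    if check:
        state.validate(moments)
    return _deriv_single_arr(state.as_array(), rates, params.alpha, moments)


def _deriv_two_arr(
    y,
    res: StrainRates,
    mut: StrainRates,
    alpha: float,
    moments: SpatialMoments,
):
    x_I, p_SI, p_IO, x_J, p_SJ, p_IJ, p_JJ = y
    x_S = moments.x_C - x_I - x_J
    p_II = x_I - p_SI - p_IJ - p_IO
    p_JO = x_J - p_SJ - p_IJ - p_JJ
    p_SS = moments.p_CC - 2.0 * p_SI - 2.0 * p_SJ - p_II - 2.0 * p_IJ - p_JJ
    p_SO = (moments.x_C - moments.p_CC) - p_IO - p_JO

    phi = _phi(x_I, p_SI, x_S, res.g, res.l)
    phi_m = _phi(x_J, p_SJ, x_S, mut.g, mut.l)

    dx_I = res.g * x_S * x_I + (res.l + res.psi) * p_SI - alpha * x_I
    # The susceptible member of an SI pair is also exposed to the mutant
    # force phi'; the matching gain appears in dp_IJ/dt below, so the
    # phi' loss here is required for flux consistency (and exact
    # neutrality when the two strains are identical).
    dp_SI = (
        -(phi + phi_m + res.psi + alpha) * p_SI + phi * p_SS + alpha * (p_II + p_IJ)
    )
    dp_IO = phi * p_SO - alpha * p_IO
    dx_J = mut.g * x_S * x_J + (mut.l + mut.psi) * p_SJ - alpha * x_J
    dp_SJ = (
        -(phi + phi_m + mut.psi + alpha) * p_SJ + phi_m * p_SS + alpha * (p_JJ + p_IJ)
    )
    dp_IJ = phi * p_SJ + phi_m * p_SI - 2.0 * alpha * p_IJ
    dp_JJ = 2.0 * ((phi_m + mut.psi) * p_SJ - alpha * p_JJ)
    return np.array([dx_I, dp_SI, dp_IO, dx_J, dp_SJ, dp_IJ, dp_JJ])


def deriv_two_strain(
    state: TwoStrainState,
    resident: Strain,
    mutant: Strain,
    params: EpidemicParams,
    moments: SpatialMoments,
    check: bool = True,
) -> np.ndarray:
    """Time derivative of the seven resident+mutant densities."""
    if check:
        state.validate(moments)
    return _deriv_two_arr(
        state.as_array(),
        resident.rates(params),
        mutant.rates(params),
        params.alpha,
        moments,
    )


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate(
    deriv: Callable[[np.ndarray], np.ndarray],
    state0: np.ndarray,
    t_span: tuple[float, float],
    rtol: float = 1e-10,
    atol: float = 1e-12,
    t_eval: np.ndarray | None = None,
):
    """Integrate a density system with adaptive stepping.

    Small negative excursions (above ``-NEGATIVE_FLOOR``) in the output
    are clipped to zero; larger ones raise, since they indicate an
    inadmissible initial state or a tolerance problem.
    """
    sol = solve_ivp(
        lambda t, y: deriv(y),
        t_span,
        np.asarray(state0, dtype=float),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    y = sol.y
    if (y < -1e-8).any():
        raise RuntimeError(
            f"integration produced negative densities (min {y.min():.3e})"
        )
    sol.y = np.where((y < 0) & (y > -1e-8), 0.0, y)
    return sol


# ---------------------------------------------------------------------------
# R0, endemic condition, equilibria
# ---------------------------------------------------------------------------

def basic_reproduction_number(
    strain: Strain, params: EpidemicParams, moments: SpatialMoments
) -> float:
    """Closed-form basic reproduction number.

    R0 = (g x_C + l q_{C/C} + sqrt((g x_C + l q_{C/C})^2 + 4 g psi p_CC))
         / (2 alpha)

    reducing to ``rho_1 = beta_G x_C / alpha`` for the completely global
    strain and ``rho_0 = beta_L (1 - theta) q_{C/C} / alpha`` for the
    completely local one.
    """
    if params.alpha <= 0:
        raise ValueError("R0 requires alpha > 0")
    r = strain.rates(params)
    q = moments.q_C_given_C
    b = r.g * moments.x_C + r.l * q
    return (b + np.sqrt(b * b + 4.0 * r.g * r.psi * moments.p_CC)) / (2.0 * params.alpha)


def rho_1(params: EpidemicParams, moments: SpatialMoments) -> float:
    """R0 of the completely global strain, beta_G x_C / alpha."""
    return params.beta_G * moments.x_C / params.alpha


def rho_0(params: EpidemicParams, moments: SpatialMoments) -> float:
    """R0 of the completely local strain, beta_L (1-theta) q_{C/C} / alpha."""
    return params.beta_L * (1.0 - params.theta) * moments.q_C_given_C / params.alpha


def _dfe_jacobian(rates: StrainRates, alpha: float, moments: SpatialMoments,
                  eps: float = 1e-7) -> np.ndarray:
    """Jacobian of the single-strain system at the disease-free state,
    by central finite differences (the vector field is smooth there)."""
    J = np.empty((3, 3))
    for j in range(3):
        e = np.zeros(3)
        e[j] = eps
        f_plus = _deriv_single_arr(e, rates, alpha, moments)
        f_minus = _deriv_single_arr(-e, rates, alpha, moments)
        J[:, j] = (f_plus - f_minus) / (2.0 * eps)
    return J


def r0_via_ngm(
    strain: Strain, params: EpidemicParams, moments: SpatialMoments
) -> float:
    """R0 from a numerically built next-generation matrix.

    The linearised dynamics at the disease-free equilibrium are split
    into a transmission part T (every term carrying a transmission
    rate g, l or psi) and a transition part S (the recovery flows, all
    carrying alpha); T is obtained numerically as the difference between
    the full Jacobian and the Jacobian of the transmission-free system.
    R0 is the spectral radius of ``-T S^{-1}``.  Independent of the
    closed form, and used as its oracle.
    """
    if params.alpha <= 0:
        raise ValueError("R0 requires alpha > 0")
    r = strain.rates(params)
    J_full = _dfe_jacobian(r, params.alpha, moments)
    J_trans = _dfe_jacobian(StrainRates(0.0, 0.0, 0.0), params.alpha, moments)
    T = J_full - J_trans
    V = -J_trans
    if abs(np.linalg.det(V)) < 1e-12:
        raise ValueError("singular transition matrix")
    K = T @ np.linalg.inv(V)
    return float(max(np.abs(np.linalg.eigvals(K))))


def is_endemic(
    strain: Strain, params: EpidemicParams, moments: SpatialMoments
) -> tuple[bool, float]:
    """Endemic-threshold test for a strain.

    Evaluates the quadratic stability margin of the disease-free state,

        m = alpha^2 - alpha (g x_C + l q_{C/C}) - g psi p_CC,

    which is negative exactly when R0 > 1.  Returns ``(m < 0, m)``.
    """
    r = strain.rates(params)
    q = moments.q_C_given_C
    a = params.alpha
    margin = a * a - a * (r.g * moments.x_C + r.l * q) - r.g * r.psi * moments.p_CC
    return bool(margin < 0.0), float(margin)


def endemic_margin_rho_form(
    strain: Strain, params: EpidemicParams, moments: SpatialMoments
) -> bool:
    """The same endemic condition in reproduction-number form,

        (1 - 1/(rho_1 G)) (1 - 1/(rho_0 (1-G))) < 1/(1 - theta),

    defined for strains with both transmission routes active (0 < G < 1)
    and a linear trade-off.
    """
    G = strain.G
    if not 0.0 < G < 1.0:
        raise ValueError("rho-form applies to interior G only")
    r1 = rho_1(params, moments) * G
    r0_ = rho_0(params, moments) * strain.local_weight  # (1 - G) when linear
    lhs = (1.0 - 1.0 / r1) * (1.0 - 1.0 / r0_)
    return bool(lhs < 1.0 / (1.0 - params.theta))


def proportional_mixing_state(
    x_I: float, moments: SpatialMoments
) -> PairState:
    """Seed state with infections distributed as under random labelling
    of target cells: p_SI = p_CC x_S x_I / x_C^2, p_IO = p_CO x_I / x_C."""
    x_C = moments.x_C
    x_S = x_C - x_I
    return PairState(
        x_I=x_I,
        p_SI=moments.p_CC * x_S * x_I / (x_C * x_C),
        p_IO=(x_C - moments.p_CC) * x_I / x_C,
    )


def endemic_equilibrium(
    strain: Strain,
    params: EpidemicParams,
    moments: SpatialMoments,
    t_max: float = 1e4,
    seed_fraction: float = 0.01,
) -> PairState | None:
    """Numerically determined endemic equilibrium, or ``None`` if the
    strain cannot persist.

    Integrates the single-strain system from a small proportional-mixing
    seed until the motion stalls, then polishes with a Newton solve; the
    result satisfies max |d/dt| < ``STEADY_STATE_TOL``.
    """
    endemic, _ = is_endemic(strain, params, moments)
    if not endemic:
        return None
    r = strain.rates(params)
    fun = lambda y: _deriv_single_arr(y, r, params.alpha, moments)
    y = proportional_mixing_state(seed_fraction * moments.x_C, moments).as_array()
    t = 0.0
    chunk = 50.0
    while t < t_max:
        sol = integrate(fun, y, (0.0, chunk), rtol=1e-10, atol=1e-13)
        y = sol.y[:, -1]
        t += chunk
        if np.max(np.abs(fun(y))) < 1e-6:
            break
    res = root(fun, y, method="hybr", tol=1e-13)
    if res.success and np.max(np.abs(fun(res.x))) < STEADY_STATE_TOL:
        y = res.x
    if np.max(np.abs(fun(y))) >= STEADY_STATE_TOL:
        raise RuntimeError(
            f"no steady state reached within t_max={t_max}: "
            f"max|d/dt| = {np.max(np.abs(fun(y))):.3e}"
        )
    if y[0] < 1e-8:  # converged back to the disease-free state
        return None
    y = np.where(np.abs(y) < NEGATIVE_FLOOR, 0.0, y)
    state = PairState(*y)
    state.validate(moments)
    return state


def global_strain_equilibrium(
    params: EpidemicParams, moments: SpatialMoments
) -> PairState | None:
    """Closed-form endemic equilibrium of the completely global strain.

    For G = 1 the pair equations solve exactly:

        x_I  = x_C - alpha / beta_G
        p_SI = (1 - a) a p_CC        with a = alpha / (beta_G x_C)
        p_IO = (1 - a) (x_C - p_CC)

    Returns ``None`` when beta_G x_C < alpha (extinction); at the
    threshold beta_G x_C = alpha the equilibrium degenerates to zero
    infection.
    """
    a = params.alpha / (params.beta_G * moments.x_C)
    if a > 1.0:
        return None
    if a == 1.0:
        return PairState(0.0, 0.0, 0.0)
    return PairState(
        x_I=moments.x_C - params.alpha / params.beta_G,
        p_SI=(1.0 - a) * a * moments.p_CC,
        p_IO=(1.0 - a) * (moments.x_C - moments.p_CC),
    )
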