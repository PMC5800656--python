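# Methods

## Model

The habitat is a rectangular lattice with periodic boundaries; each
site permanently holds either a target cell or a non-target cell, and
each site has the 4 orthogonal neighbours (θ = 1/4). Target cells are
susceptible or infected; infected cells revert to susceptible at rate
α (SIS — death with immediate replacement, or recovery). A strain's
trait is its proportion of global infection G: global transmission is
mass action at rate β_G·G against the infected density measured over
the whole lattice, local transmission goes to a uniformly chosen
orthogonal neighbour at rate β_L·L(G), with trade-off
L(G) = 1 − G^s. The trait grid used for evolutionary analysis has 101
equally spaced strains on [0, 1].

Pair approximation closes the hierarchy at pairs: conditional triple
probabilities q_{σ/σ′σ″} are replaced by q_{σ/σ′}. Local transmission
splits into a within-pair part ψ = β_L L(G) θ and an outside-pair part
l = β_L L(G)(1 − θ). Because the target/non-target mosaic is frozen,
x_C and p_CC are constants of motion and the single-strain state
reduces to (x_I, p_SI, p_IO); the resident+mutant state to seven
densities. All dependent densities are *reconstructed* from the
conservation identities rather than integrated, so the pair-sum
identities hold exactly along trajectories by construction; the
meaningful numerical check is that reconstructed densities stay
non-negative, which the integrator and tests enforce at 1e-8.

One term of the two-strain system deserves note: the loss rate of SI
pairs includes the mutant force of infection φ′ (the susceptible member
of an SI pair can be infected by the mutant, moving the pair to IJ).
Writing the system without that term breaks flux consistency with the
IJ gain term and destroys exact neutrality of a relabelled resident;
with it, a 50/50 relabelling of one strain as two identical strains
reproduces the single-strain trajectory to integrator precision
(~1e-11), which the tests assert.

## R0 and the endemic condition

The closed-form R0 is the largest root of
α²R² − α(g x_C + l q_{C/C})R − gψp_CC = 0. As an independent oracle the
package linearises the dynamics at the disease-free state numerically
(central differences), splits the Jacobian into a transmission part
(all terms carrying g, l or ψ, obtained as the difference between the
full Jacobian and that of the transmission-free system) and a
transition part (the α flows), and takes the spectral radius of
−T·Σ⁻¹. The two routes agree to ~1e-13 over random admissible
parameters; the endemic condition (the sign of the quadratic margin
α² − α(g x_C + l q_{C/C}) − gψp_CC) coincides with R0 > 1.

## Equilibria and invasion

Endemic equilibria are found numerically: integrate from a small
proportional-mixing seed (default 1 % of x_C infected, pairs at random
labelling) until motion stalls, then polish with a Newton solve; the
accepted state satisfies max |d/dt| < 1e-9 and is insensitive to the
seed fraction (tested). For G = 1 the equilibrium is also available in
closed form — x̂_I = x_C − α/β_G, p̂_SI = (1−a)a·p_CC,
p̂_IO = (1−a)(x_C − p_CC) with a = α/(β_G x_C) — and the numeric route
matches it to 1e-6, which doubles as a regression check on the solver.

Invasion fitness is the dominant eigenvalue of the 4×4 Jacobian of the
mutant block (x_J, p_SJ, p_IJ, p_JJ), linearised in the mutant
densities with the resident frozen at equilibrium; the matrix is
quasi-positive so the dominant eigenvalue is real. The analytic matrix
is cross-checked against a finite-difference linearisation of the full
two-strain vector field. Self-invasion is neutral to machine precision;
the decision threshold for "can invade" is λ > 1e-8, so numerical
neutrality is never mistaken for invasion. PIPs cache one equilibrium
per resident (101 ODE solves, 101² eigenvalue evaluations; ~1 s).

Singular strategies are read off the grid from the nearest-neighbour
selection direction: a grid strain invadable by neither neighbour is a
local ESS (endpoints one-sided); a sign change from "select downward"
to "select upward" between adjacent strains is a repeller. Near weakly
selected singular points two adjacent grid strains can both be
uninvadable; callers should treat such a contiguous block as one ESS at
its midpoint. Convergence stability beyond this PIP reading is not
classified.

The closed-form invasion condition against the G = 1 resident is
implemented as (β_G/β_L)/(1 − θ + G′θ) < p_CC/x_C². The source text
for this inequality is typographically ambiguous; this reading was
fixed by requiring sign agreement with the eigenvalue criterion (exact
over a 21 × 100 grid of (p_CC, G′) in the tests) and is the only
reading consistent with the ESS-loss threshold sitting at clustering
β_G/β_L independently of x_C and θ. Its left side *decreases* in G′:
the marginal invader is always the nearly-global mutant.

## Monte-Carlo simulator

The simulator realises the same process on a concrete lattice with
synchronous fixed-step updates: per-site event probabilities
1 − exp(−h·dt), where a susceptible site's hazard sums the global pool
Σ_k g_k x_k (x_k the strain's density over all lattice sites) and
β_L L(G_k)/4 per infected neighbour. The infecting strain is drawn
proportionally to its hazard contribution. The step size is capped so
that no per-site event probability exceeds 0.1 (default dt is derived
from a worst-case hazard bound over the strain registry; a step that
violates the cap raises rather than silently biasing the discretisation).
Choices the underlying description leaves open, fixed here as defaults:
synchronous updates; initial infections seeded uniformly at random in
10 % of target cells; mutation probability μ = 0.01 per transmission,
moving one grid step in G (half each side, reflecting at the ends).
Qualitative evolutionary conclusions were checked to not depend on μ's
order of magnitude.

## What the generators emulate, and what a green test establishes

`generate_csr` produces independent-site mosaics (clustering → 1);
`generate_structure_mh` starts from an exact count round(x_C·N) of
target sites and greedily accepts swaps of (target, non-target) site
pairs that bring p_CC strictly closer to the goal (tol 1e-3, 1e6
proposals), so x_C is exact and p_CC controlled; deterministic patterns
(stripes, checkerboard, Sierpinski raster) pin down moments exactly or
reproducibly. These mosaics control first and second moments only:
higher-order structure is whatever the generator happens to produce.
Green tests therefore establish consistency of simulation and pair
approximation *as functions of (x_C, p_CC)* — which is the model's own
claim — not fidelity to any particular tissue architecture. Likewise
the pair approximation itself degrades when infection is strongly
local (large contiguous infected clusters violate the triple closure),
so simulation outcomes near G ≈ 0 sit systematically above the
pair-approximation ESS; tests only assert the qualitative orderings
that survive this bias.

## Numerical choices

- ODE integration: LSODA, rtol 1e-10 / atol 1e-12 (1e-13 for
  equilibrium runs); output densities in (−1e-8, 0) are clipped to 0,
  anything more negative is an error.
- Steady state: max |d/dt| < 1e-9, t_max 1e4, Newton polish.
- Neutral band for invasion decisions: 1e-8.
- Structure generator: greedy strict-improvement swaps; ties rejected.
  The achieved p_CC error can equal tol exactly (integer pair counts).
- Scaled-down defaults in tests: 30–50 square lattices, shortened
  horizons and replicate counts, fixed seeds; the full 100×100 /
  t = 5000 setting is available through the same interfaces.

## Known limitations

- The analytic resident equilibrium for general G is not implemented;
  the numeric steady state is authoritative (cross-checked at G = 1).
- Three-dimensional lattices, Moore neighbourhoods and continuous-space
  point patterns are out of scope; so are SIR/latent variants,
  superinfection mechanics and between-host selection.
- The Sierpinski raster's moments depend on the rasterisation; they are
  measured, never asserted.
- `find_local_ess` reports grid-resolution ESSs; it does not refine
  singular points below one grid step.
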