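"""Stochastic lattice simulation: single-strain persistence against the
pair approximation, and trait evolution under mutation.

Scaled down (50x50 lattice, short horizon) so the script runs in about
a minute; the qualitative outcomes match the deterministic analysis.
"""

from pairsis import (
    EpidemicParams,
    MCConfig,
    Strain,
    StrainGrid,
    generate_csr,
    generate_structure_mh,
    global_strain_equilibrium,
    run_evolution,
    run_single_strain,
    summarize_trajectory,
)

params = EpidemicParams(beta_G=10, beta_L=10, alpha=1)

# 1. G = 1 on a CSR lattice: density settles at the pair-approximation value
lattice = generate_csr(0.5, (50, 50), seed=2)
expected = global_strain_equilibrium(params, lattice.moments()).x_I
traj = run_single_strain(lattice, Strain(1.0), params, t_end=80, config=MCConfig(seed=3))
tail = traj.infected_density[len(traj.times) // 2 :]
print(
    f"G=1 on CSR: simulated infected density {tail.mean():.3f}, "
    f"pair approximation predicts {expected:.3f}"
)

# 2. evolution of the trait under mutation on three mosaics
print("\np_CC   long-run mean G (from initial 0.5)")
for p_CC, seed in ((0.1, 11), (0.25, 12), (0.4, 13)):
    if p_CC == 0.25:
        lat = generate_csr(0.5, (50, 50), seed=seed)
    else:
        lat = generate_structure_mh(0.5, p_CC, (50, 50), seed=seed)
    ev = run_evolution(
        lat,
        StrainGrid(101),
        params,
        t_end=400,
        config=MCConfig(seed=seed, record_every=5.0),
    )
    mean, sd = summarize_trajectory(ev, 0.25)
    print(f"{p_CC:.2f}   {mean:.3f} (sd {sd:.3f})")

print(
    "\nMean G drifts upward (toward global infection) on over-dispersed\n"
    "mosaics and downward on clustered ones: the ordering of outcomes in\n"
    "p_CC mirrors the deterministic ESS analysis."
)
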