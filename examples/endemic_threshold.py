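"""When can a strain with a given proportion of global infection persist?

R0 is computed two independent ways — the closed form and the spectral
radius of a numerically assembled next-generation matrix — and the
endemic condition is the sign of a quadratic margin in the recovery
rate alpha.
"""

from pairsis import (
    EpidemicParams,
    SpatialMoments,
    Strain,
    basic_reproduction_number,
    endemic_equilibrium,
    is_endemic,
    r0_via_ngm,
)

moments = SpatialMoments(x_C=0.5, p_CC=0.4)  # clustering 1.6

print("alpha  G     R0(closed)  R0(NGM)   endemic  equilibrium x_I")
for alpha in (4.0, 5.5):
    params = EpidemicParams(beta_G=10, beta_L=10, alpha=alpha)
    for G in (0.0, 0.5, 1.0):
        strain = Strain(G)
        r0 = basic_reproduction_number(strain, params, moments)
        r0n = r0_via_ngm(strain, params, moments)
        endemic, _ = is_endemic(strain, params, moments)
        eq = endemic_equilibrium(strain, params, moments)
        x_I = f"{eq.x_I:.4f}" if eq is not None else "extinct"
        print(
            f"{alpha:4.1f}  {G:.2f}  {r0:9.4f}  {r0n:9.4f}   {str(endemic):5s}   {x_I}"
        )

print(
    "\nAt alpha = 5.5 the completely global strain (G = 1) is subcritical\n"
    "(R0 < 1) while the mixed strain G = 0.5 still persists: on clustered\n"
    "target cells, intermediate strategies tolerate higher recovery rates."
)
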