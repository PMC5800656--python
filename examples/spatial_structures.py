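"""Build target-cell mosaics and measure their spatial moments.

The clustering index p_CC / x_C^2 is the quantity the evolutionary
analysis keys on: 1 means complete spatial randomness (CSR), above 1
aggregated target cells, below 1 over-dispersed ones.
"""

from pairsis import (
    checkerboard,
    generate_csr,
    generate_structure_mh,
    measure_moments,
    sierpinski,
    stripes,
)


def show(name, structure):
    m = measure_moments(structure)
    print(
        f"{name:22s} x_C = {m.x_C:.3f}  p_CC = {m.p_CC:.3f}  "
        f"clustering = {m.clustering:.3f}"
    )


show("stripes(width 1)", stripes(1, (100, 100)))
show("checkerboard(5x5)", checkerboard(5, (100, 100)))
show("sierpinski gasket", sierpinski((100, 100)))
show("CSR x_C=0.5", generate_csr(0.5, (100, 100), seed=1))
# swap generator: prescribe (x_C, p_CC) = (0.5, 0.4), i.e. clustering 1.6
show("swap-matched (0.5,0.4)", generate_structure_mh(0.5, 0.4, (100, 100), seed=1))

print(
    "\nThe width-1 stripes and the 5x5 checkerboard reproduce the moments\n"
    "(0.5, 0.25) and (0.5, 0.4) exactly; the swap generator reaches any\n"
    "feasible moment pair on a random lattice, and CSR sits at clustering 1."
)
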