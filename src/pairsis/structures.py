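"""Heterogeneous target/non-target lattices and their spatial moments.

A virus spreading within a host tissue sees a mosaic of cells it can
infect (*target* cells) and cells it cannot (*non-target* cells).  We
represent the tissue as a rectangular lattice with periodic boundaries
in which every site is permanently either target or non-target; only
the infection status of target cells changes over time.

The arrangement of target cells is summarised by two spatial moments:

``x_C``
    the fraction of lattice sites occupied by target cells;
``p_CC``
    the fraction of ordered (site, neighbour) pairs — each site paired
    with each of its 4 orthogonal neighbours — in which both members
    are target cells.

The ratio ``p_CC / x_C**2`` measures clustering: it equals 1 under
complete spatial randomness (CSR), exceeds 1 when target cells are
aggregated and falls below 1 when they are over-dispersed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SpatialMoments",
    "SpatialStructure",
    "MHConvergenceError",
    "measure_moments",
    "generate_csr",
    "generate_structure_mh",
    "generate_deterministic",
    "stripes",
    "checkerboard",
    "sierpinski",
    "read_structure",
    "write_structure",
]

#: number of orthogonal (von Neumann) neighbours of every site
N_NEIGHBORS = 4

#: inverse neighbourhood size, theta = 1/4 on the square lattice
THETA = 1.0 / N_NEIGHBORS


class MHConvergenceError(RuntimeError):
    """Raised when the swap-based structure generator fails to reach the
    requested pair density; carries the best pair density achieved."""

    def __init__(self, message: str, best_p_CC: float, n_iter: int):
        super().__init__(message)
        self.best_p_CC = best_p_CC
        self.n_iter = n_iter


@dataclass(frozen=True)
class SpatialMoments:
    """First and second spatial moments of a target-cell configuration.

    Parameters
    ----------
    x_C
        Global density of target cells, in [0, 1].
    p_CC
        Ordered pair density of target cells, in [0, x_C].
    """

    x_C: float
    p_CC: float

    def __post_init__(self):
        if not 0.0 <= self.x_C <= 1.0:
            raise ValueError(f"x_C must lie in [0, 1], got {self.x_C}")
        # Ordered-pair density can never exceed the singlet density, and
        # p_CO = x_C - p_CC must be non-negative.
        if not -1e-12 <= self.p_CC <= self.x_C + 1e-12:
            raise ValueError(
                f"p_CC must lie in [0, x_C={self.x_C}], got {self.p_CC}"
            )

    @property
    def q_C_given_C(self) -> float:
        """Conditional probability that a neighbour of a target cell is
        itself a target cell, q_{C/C} = p_CC / x_C."""
        if self.x_C == 0.0:
            raise ValueError("q_C_given_C is undefined when x_C = 0")
        return self.p_CC / self.x_C

    @property
    def clustering(self) -> float:
        """Clustering index p_CC / x_C**2 (1 at CSR)."""
        if self.x_C == 0.0:
            raise ValueError("clustering is undefined when x_C = 0")
        return self.p_CC / self.x_C**2

    @property
    def p_CO(self) -> float:
        """Pair density of (target, non-target) ordered pairs."""
        return self.x_C - self.p_CC

    @classmethod
    def csr(cls, x_C: float) -> "SpatialMoments":
        """Moments of a completely spatially random configuration."""
        return cls(x_C=x_C, p_CC=x_C**2)

    @classmethod
    def from_clustering(cls, x_C: float, clustering: float) -> "SpatialMoments":
        """Build moments from density and clustering index."""
        return cls(x_C=x_C, p_CC=clustering * x_C**2)


@dataclass
class SpatialStructure:
    """A concrete periodic lattice of target / non-target sites.

    ``mask`` is a 2-D boolean array, True where the site holds a target
    cell.  Coordinates are row-major ``(row, col)``, 0-based; boundaries
    are periodic and each site has the 4 orthogonal neighbours.
    """

    mask: np.ndarray

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2 or mask.size == 0:
            raise ValueError("mask must be a non-empty 2-D array")
        self.mask = mask

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]

    @property
    def n_sites(self) -> int:
        return self.mask.size

    def moments(self) -> SpatialMoments:
        return measure_moments(self)

    def copy(self) -> "SpatialStructure":
        return SpatialStructure(self.mask.copy())


def _ordered_target_pairs(mask: np.ndarray) -> int:
    """Count ordered (site, neighbour) pairs with both sites target,
    with periodic wrap.  Each unordered adjacency contributes 2."""
    pairs = 0
    for axis in (0, 1):
        adj = mask & np.roll(mask, 1, axis=axis)
        pairs += 2 * int(adj.sum())
    return pairs


def measure_moments(structure: SpatialStructure) -> SpatialMoments:
    """Measure (x_C, p_CC) of a lattice.

    ``p_CC`` is the number of ordered target–target (site, neighbour)
    pairs divided by the total number of such pairs, ``4 N``; counting
    from either endpoint of a pair gives the same result by symmetry.
    """
    mask = structure.mask
    n = mask.size
    x_C = mask.sum() / n
    p_CC = _ordered_target_pairs(mask) / (N_NEIGHBORS * n)
    return SpatialMoments(x_C=float(x_C), p_CC=float(p_CC))


def generate_csr(
    x_C: float,
    dims: tuple[int, int] = (100, 100),
    seed: int | np.random.Generator | None = None,
) -> SpatialStructure:
    """Independent-site (completely spatially random) lattice.

    Each site is target with probability ``x_C`` independently, so the
    expected measured pair density is ``x_C**2``.
    """
    if not 0.0 < x_C < 1.0:
        raise ValueError(
            "generate_csr requires 0 < x_C < 1; use an explicit all-target "
            "or all-non-target mask for the degenerate cases"
        )
    rng = np.random.default_rng(seed)
    mask = rng.random(dims) < x_C
    return SpatialStructure(mask)


# ---------------------------------------------------------------------------
# swap-based generator with prescribed (x_C, p_CC)
# ---------------------------------------------------------------------------

def _neighbor_indices(shape: tuple[int, int]) -> np.ndarray:
    """Flat indices of the 4 orthogonal neighbours of every site."""
    h, w = shape
    rows, cols = np.divmod(np.arange(h * w), w)
    nbrs = np.empty((h * w, 4), dtype=np.int64)
    nbrs[:, 0] = ((rows - 1) % h) * w + cols
    nbrs[:, 1] = ((rows + 1) % h) * w + cols
    nbrs[:, 2] = rows * w + (cols - 1) % w
    nbrs[:, 3] = rows * w + (cols + 1) % w
    return nbrs


def generate_structure_mh(
    x_C: float,
    p_CC_target: float,
    dims: tuple[int, int] = (100, 100),
    seed: int | np.random.Generator | None = None,
    tol: float = 1e-3,
    max_iter: int = 1_000_000,
) -> SpatialStructure:
    """Generate a lattice with prescribed ``x_C`` and ``p_CC`` by swaps.

    Starting from exactly ``round(x_C * N)`` target sites placed at
    random, pairs of (target, non-target) sites are repeatedly proposed
    for exchange and the exchange is accepted when it brings the current
    pair density strictly closer to ``p_CC_target`` (swaps conserve the
    target count, so ``x_C`` is exact throughout).

    Raises
    ------
    MHConvergenceError
        If ``max_iter`` proposals do not bring the measured p_CC within
        ``tol`` of the target; the error carries the best value reached.
    """
    h, w = dims
    n = h * w
    if not 0.0 < x_C < 1.0:
        raise ValueError("x_C must lie strictly between 0 and 1")
    if not 0.0 <= p_CC_target <= x_C:
        raise ValueError(
            f"infeasible pair density: need 0 <= p_CC <= x_C={x_C}, "
            f"got {p_CC_target}"
        )
    rng = np.random.default_rng(seed)

    n_target = int(round(x_C * n))
    if n_target in (0, n):
        raise ValueError("rounded target count is degenerate for these dims")
    flat = np.zeros(n, dtype=bool)
    flat[rng.choice(n, size=n_target, replace=False)] = True

    nbrs = _neighbor_indices((h, w))
    denom = float(N_NEIGHBORS * n)
    # ordered pair count over all 4N (site, neighbour) pairs; maintained
    # incrementally under swaps below
    pairs = int((flat[:, None] & flat[nbrs]).sum())

    best = pairs / denom
    target_pairs = p_CC_target * denom
    achieved_iter = 0
    for it in range(max_iter):
        if abs(pairs - target_pairs) <= tol * denom:
            achieved_iter = it
            break
        a = int(rng.integers(n))
        b = int(rng.integers(n))
        if flat[a] == flat[b]:
            continue
        if not flat[a]:
            a, b = b, a  # a is the target site, b the non-target site
        nb_a = nbrs[a]
        nb_b = nbrs[b]
        m = int(np.count_nonzero(nb_a == b))  # adjacency multiplicity
        nt_a = int(np.count_nonzero(flat[nb_a]))
        nt_b = int(np.count_nonzero(flat[nb_b]))
        # remove target at a, then add target at b (a no longer target)
        new_pairs = pairs - 2 * nt_a + 2 * (nt_b - m)
        if abs(new_pairs - target_pairs) < abs(pairs - target_pairs):
            flat[a] = False
            flat[b] = True
            pairs = new_pairs
            best = pairs / denom
    else:
        raise MHConvergenceError(
            f"did not reach p_CC={p_CC_target} within tol={tol} after "
            f"{max_iter} proposals (best achieved {pairs / denom:.6f})",
            best_p_CC=pairs / denom,
            n_iter=max_iter,
        )

    structure = SpatialStructure(flat.reshape(h, w))
    structure.mh_iterations = achieved_iter  # type: ignore[attr-defined]
    structure.mh_achieved = measure_moments(structure)  # type: ignore[attr-defined]
    return structure


# ---------------------------------------------------------------------------
# deterministic patterns
# ---------------------------------------------------------------------------

def stripes(line_width: int = 1, dims: tuple[int, int] = (100, 100)) -> SpatialStructure:
    """Vertical stripes of target cells of the given line width."""
    h, w = dims
    if line_width < 1 or w % (2 * line_width) != 0:
        raise ValueError(
            f"width {w} must be divisible by the stripe period {2 * line_width}"
        )
    cols = (np.arange(w) // line_width) % 2 == 0
    return SpatialStructure(np.tile(cols, (h, 1)))


def checkerboard(block: int = 5, dims: tuple[int, int] = (100, 100)) -> SpatialStructure:
    """Checkerboard of ``block``-by-``block`` target/non-target squares."""
    h, w = dims
    if block < 1 or h % (2 * block) != 0 or w % (2 * block) != 0:
        raise ValueError(
            f"dims {dims} must be divisible by the checker period {2 * block}"
        )
    rows = np.arange(h) // block
    cols = np.arange(w) // block
    return SpatialStructure((rows[:, None] + cols[None, :]) % 2 == 0)


def sierpinski(dims: tuple[int, int] = (100, 100)) -> SpatialStructure:
    """Sierpinski-gasket raster: site (r, c) is target iff r AND c == 0
    bitwise (Pascal-triangle mod 2), clipped to the lattice.  Moments of
    this pattern are reported as measured, not prescribed."""
    h, w = dims
    rows = np.arange(h)
    cols = np.arange(w)
    return SpatialStructure((rows[:, None] & cols[None, :]) == 0)


_PATTERNS = {"stripes": stripes, "checkerboard": checkerboard, "sierpinski": sierpinski}


def generate_deterministic(kind: str, dims: tuple[int, int] = (100, 100)) -> SpatialStructure:
    """Named deterministic pattern, e.g. ``"stripes:1"``,
    ``"checkerboard:5"`` or ``"sierpinski"``."""
    name, _, arg = kind.partition(":")
    if name not in _PATTERNS:
        raise ValueError(f"unknown pattern {name!r}; choose from {sorted(_PATTERNS)}")
    if name == "sierpinski":
        if arg:
            raise ValueError("sierpinski takes no size argument")
        return sierpinski(dims)
    size = int(arg) if arg else 1 if name == "stripes" else 5
    return _PATTERNS[name](size, dims)


# ---------------------------------------------------------------------------
# plain-text persistence
# ---------------------------------------------------------------------------

def write_structure(structure: SpatialStructure, path: str | Path) -> None:
    """Write the mask as lines of 0/1 characters, one row per line."""
    lines = ["".join("1" if v else "0" for v in row) for row in structure.mask]
    Path(path).write_text("\n".join(lines) + "\n")


def read_structure(path: str | Path) -> SpatialStructure:
    """Read a 0/1 text matrix written by :func:`write_structure`."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if set(line) - {"0", "1"}:
            raise ValueError(f"line {ln}: characters other than 0/1")
        rows.append([c == "1" for c in line])
    if not rows:
        raise ValueError("empty structure file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"ragged rows: widths {sorted(widths)}")
    return SpatialStructure(np.array(rows, dtype=bool))
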