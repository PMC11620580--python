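"""Stochastic off-lattice growth of a filamentous yeast colony.

A colony starts from a single sated cell at the origin and grows by
repeated budding events.  While the colony occupies at most a fraction
``n_star`` of its target size, every mother and daughter is sated and the
colony expands in compact Eden-like fashion.  Past that threshold,
pseudohyphal growth may start, governed by four probabilities:

``p_a``
    probability the proliferating mother is sated (vs pseudohyphal),
``p_sp``
    probability a sated mother produces a pseudohyphal daughter,
``p_ps``
    probability a pseudohyphal mother (that already extended once)
    produces a sated daughter,
``gamma``
    the forking control: probability that a pseudohyphal mother with an
    existing pseudohyphal daughter aborts in favour of a fresh branch tip.

Cells never move, change shape or die.  Partial overlap between cells is
permitted; an event is aborted whenever the centre of the new cell would
fall strictly inside an existing cell, or its boundary would leave the
domain.  Time is not modelled: the simulation runs until a prescribed
cell count ``n_max`` (or, alternatively, a target rasterised area) is
reached.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import (
    DISTAL_SITES,
    PSEUDOHYPHAL,
    SATED,
    Cell,
    CellTypeParams,
    place_daughter,
)

__all__ = [
    "SimParams",
    "Colony",
    "ColonySimulator",
    "ColonyStallError",
    "init_colony",
    "propose_event",
    "attempt_insertion",
    "run_simulation",
    "rasterise_ellipses",
    "colony_to_mask",
]

ALL_SITES = (0, 1, 2, 3)


class ColonyStallError(RuntimeError):
    """Raised when too many consecutive proliferation events abort.

    Carries the partial colony in the ``colony`` attribute so callers can
    inspect the jammed state.
    """

    def __init__(self, message: str, colony: "Colony"):
        super().__init__(message)
        self.colony = colony


@dataclass(frozen=True)
class SimParams:
    """Parameters of one colony growth simulation.

    Exactly one stopping rule is active: by cell count (``n_max``) or by
    rasterised colony area (``target_area`` occupied pixels, matched to a
    relative tolerance ``area_tol``).  In area mode ``n_max`` acts as a
    hard safety cap on cell number.
    """

    n_star: float = 0.67
    p_a: float = 0.14
    p_sp: float = 0.25
    p_ps: float = 0.58
    gamma: float = 0.12
    n_max: int = 1000
    target_area: float | None = None
    area_tol: float = 0.05
    px_per_um: float = 1.0
    domain: tuple[float, float] = (4000.0, 4000.0)
    seed: int = 0
    max_consecutive_aborts: int = 100_000
    sated: CellTypeParams = SATED
    pseudohyphal: CellTypeParams = PSEUDOHYPHAL

    def __post_init__(self) -> None:
        for name in ("n_star", "p_a", "p_sp", "p_ps", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_star == 0.0:
            raise ValueError("n_star must lie in (0, 1]")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.target_area is not None and self.target_area <= 0:
            raise ValueError("target_area must be positive")
        if not (0 < self.area_tol < 1):
            raise ValueError("area_tol must lie in (0, 1)")
        lx, ly = self.domain
        need = 2 * self.sated.half_length
        if lx < need or ly < need:
            raise ValueError("domain too small to hold the founder cell")

    @property
    def theta(self) -> np.ndarray:
        """The inferred parameter vector (n*, p_a, p_sp, p_ps, gamma)."""
        return np.array([self.n_star, self.p_a, self.p_sp, self.p_ps, self.gamma])


class Colony:
    """Ordered collection of cells plus the parallel arrays used for
    fast volume-exclusion queries."""

    def __init__(self, params: SimParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.cells: list[Cell] = []
        cap = params.n_max
        self._cx = np.empty(cap)
        self._cy = np.empty(cap)
        self._ct = np.empty(cap)
        self._st = np.empty(cap)
        self._a = np.empty(cap)
        self._b = np.empty(cap)
        self._ph = np.zeros(cap, dtype=bool)
        self._has_pd = np.zeros(cap, dtype=bool)

    @property
    def n(self) -> int:
        return len(self.cells)

    def append(self, cell: Cell) -> None:
        i = self.n
        self.cells.append(cell)
        self._cx[i], self._cy[i] = cell.centre
        self._ct[i] = math.cos(cell.orientation)
        self._st[i] = math.sin(cell.orientation)
        self._a[i] = cell.type_params.half_length
        self._b[i] = cell.type_params.half_width
        self._ph[i] = cell.is_pseudohyphal

    def centre_inside_any(self, p: np.ndarray) -> bool:
        """Strictly-inside test of point ``p`` against every cell."""
        n = self.n
        dx = p[0] - self._cx[:n]
        dy = p[1] - self._cy[:n]
        xl = dx * self._ct[:n] + dy * self._st[:n]
        yl = -dx * self._st[:n] + dy * self._ct[:n]
        return bool(np.any((xl / self._a[:n]) ** 2 + (yl / self._b[:n]) ** 2 < 1.0))

    def pseudohyphal_count(self) -> int:
        return int(self._ph[: self.n].sum())

    def arrays(self):
        """Views of (cx, cy, cos, sin, a, b, is_pseudohyphal) for all cells."""
        n = self.n
        return (
            self._cx[:n],
            self._cy[:n],
            self._ct[:n],
            self._st[:n],
            self._a[:n],
            self._b[:n],
            self._ph[:n],
        )


def init_colony(params: SimParams) -> Colony:
    """Colony of a single sated cell at the origin with orientation 0."""
    rng = np.random.default_rng(params.seed)
    colony = Colony(params, rng)
    colony.append(Cell(id=0, centre=np.zeros(2), orientation=0.0,
                       type_params=params.sated, mother_id=None))
    return colony


def _choose_free_site(cell: Cell, sites: tuple[int, ...], rng) -> int | None:
    free = cell.free_sites(sites)
    if not free:
        return None
    return free[int(rng.integers(len(free)))]


def propose_event(colony: Colony) -> tuple[int, CellTypeParams, int] | None:
    """Draw the next proliferation proposal from the budding decision tree.

    Returns ``(mother_id, daughter_type, site_index)``, or ``None`` to
    signal an aborted event (no free bud site, or a forking redirect with
    no eligible branch tip), in which case the procedure restarts from
    the top with fresh random draws.

    Random draws are consumed in a fixed, documented order: mother-type
    coin (if applicable), mother index, forking coin / redirect index
    (if applicable), daughter-type coin (if applicable), site index.
    """
    p = colony.params
    rng = colony.rng
    n = colony.n
    ph_mask = colony._ph[:n]

    if n / p.n_max <= p.n_star:
        # Pre-threshold: everything is sated.
        mother = colony.cells[int(rng.integers(n))]
        site = _choose_free_site(mother, ALL_SITES, rng)
        return None if site is None else (mother.id, p.sated, site)

    n_ph = int(ph_mask.sum())
    mother_sated = n_ph == 0 or rng.random() < p.p_a

    if mother_sated:
        sated_ids = np.flatnonzero(~ph_mask)
        mother = colony.cells[int(sated_ids[rng.integers(len(sated_ids))])]
        daughter = p.pseudohyphal if rng.random() < p.p_sp else p.sated
        site = _choose_free_site(mother, ALL_SITES, rng)
        return None if site is None else (mother.id, daughter, site)

    ph_ids = np.flatnonzero(ph_mask)
    mother = colony.cells[int(ph_ids[rng.integers(len(ph_ids))])]
    if not mother.has_pseudohyphal_daughter:
        daughter = p.pseudohyphal
    else:
        if rng.random() < p.gamma:
            # Forking control: redirect to a fresh branch tip.
            tips = np.flatnonzero(ph_mask & ~colony._has_pd[:n])
            if len(tips) == 0:
                return None
            mother = colony.cells[int(tips[rng.integers(len(tips))])]
            daughter = p.pseudohyphal
        else:
            daughter = p.sated if rng.random() < p.p_ps else p.pseudohyphal
    site = _choose_free_site(mother, DISTAL_SITES, rng)
    return None if site is None else (mother.id, daughter, site)


def _boundary_in_domain(centre, orientation, tp: CellTypeParams, domain) -> bool:
    # Tight axis-aligned bounding half-extents of a rotated ellipse.
    a, b = tp.half_length, tp.half_width
    ct, st = math.cos(orientation), math.sin(orientation)
    ex = math.sqrt((a * ct) ** 2 + (b * st) ** 2)
    ey = math.sqrt((a * st) ** 2 + (b * ct) ** 2)
    lx, ly = domain
    return (
        centre[0] - ex >= -lx / 2
        and centre[0] + ex <= lx / 2
        and centre[1] - ey >= -ly / 2
        and centre[1] + ey <= ly / 2
    )


def attempt_insertion(
    colony: Colony, proposal: tuple[int, CellTypeParams, int]
) -> bool:
    """Try to realise a proposed budding event.

    Builds the daughter; if its centre falls strictly inside any existing
    cell, or its boundary leaves the domain, the event is discarded and
    False is returned.  On success the daughter is appended, the mother's
    bud site is marked used, and the mother's pseudohyphal-daughter flag
    is updated.
    """
    mother_id, daughter_type, site = proposal
    mother = colony.cells[mother_id]
    daughter = place_daughter(mother, site, daughter_type, next_id=colony.n)
    if not _boundary_in_domain(
        daughter.centre, daughter.orientation, daughter_type, colony.params.domain
    ):
        return False
    if colony.centre_inside_any(daughter.centre):
        return False
    colony.append(daughter)
    mother.used_sites.add(site)
    if daughter.is_pseudohyphal:
        mother.has_pseudohyphal_daughter = True
        colony._has_pd[mother_id] = True
    return True


def _occupied_area_px(colony: "Colony") -> int:
    return int(colony_to_mask(colony, colony.params.px_per_um).pixels.sum())


def run_simulation(params: SimParams, engine: str = "auto") -> Colony:
    """Grow a colony to its stopping condition.

    ``engine`` selects the implementation: ``"python"`` runs the
    readable propose/attempt loop in this module; ``"numba"`` runs the
    compiled kernel (identical logic, different random stream);
    ``"auto"`` uses the kernel when available.  Both are deterministic
    given ``params.seed``.

    Raises :class:`ColonyStallError` (carrying the partial colony) if
    ``max_consecutive_aborts`` successive events fail.
    """
    if engine == "auto":
        engine = "numba" if _kernel_available() else "python"
    if engine == "numba":
        from . import _kernel

        return _kernel.run_simulation_fast(params)
    if engine != "python":
        raise ValueError(f"unknown engine {engine!r}")

    colony = init_colony(params)
    p = params
    area_mode = p.target_area is not None
    check_every = max(1, p.n_max // 50) if area_mode else 0
    aborts = 0
    while True:
        if not area_mode:
            if colony.n >= p.n_max:
                return colony
        else:
            if colony.n >= p.n_max:
                warnings.warn("area-mode simulation hit the n_max safety cap")
                return colony
            if colony.n % check_every == 0:
                area = _occupied_area_px(colony)
                if area >= p.target_area * (1 - p.area_tol):
                    return colony
        proposal = propose_event(colony)
        ok = proposal is not None and attempt_insertion(colony, proposal)
        if ok:
            aborts = 0
        else:
            aborts += 1
            if aborts >= p.max_consecutive_aborts:
                raise ColonyStallError(
                    f"colony jammed at n={colony.n}: "
                    f"{aborts} consecutive aborted events",
                    colony,
                )


def _kernel_available() -> bool:
    try:
        from . import _kernel  # noqa: F401
    except Exception:  # pragma: no cover - numba genuinely missing
        return False
    return True


def rasterise_ellipses(
    cx, cy, ct, st, a, b, px_per_um: float, engine: str = "auto"
) -> np.ndarray:
    """Boolean mask of the union of ellipses on a pixel grid.

    A pixel is occupied iff its centre lies inside (or on the boundary
    of) any ellipse.  The grid covers the joint bounding box plus a 2-px
    margin; row 0 is the top of the image (largest y).  The compiled and
    numpy engines apply the same per-pixel formula and agree exactly.
    """
    if px_per_um <= 0:
        raise ValueError("px_per_um must be positive")
    n = len(cx)
    if n == 0:
        return np.zeros((1, 1), dtype=bool)
    ex = np.sqrt((a * ct) ** 2 + (b * st) ** 2)
    ey = np.sqrt((a * st) ** 2 + (b * ct) ** 2)
    px = 1.0 / px_per_um
    margin = 2.0 * px
    xmin = (cx - ex).min() - margin
    xmax = (cx + ex).max() + margin
    ymin = (cy - ey).min() - margin
    ymax = (cy + ey).max() + margin
    nx = max(1, int(math.ceil((xmax - xmin) * px_per_um)))
    ny = max(1, int(math.ceil((ymax - ymin) * px_per_um)))
    if engine == "auto" and _kernel_available():
        from ._kernel import raster_kernel

        return raster_kernel(
            np.ascontiguousarray(cx, dtype=float),
            np.ascontiguousarray(cy, dtype=float),
            np.ascontiguousarray(ct, dtype=float),
            np.ascontiguousarray(st, dtype=float),
            np.ascontiguousarray(a, dtype=float),
            np.ascontiguousarray(b, dtype=float),
            px_per_um, xmin, ymax, ny, nx,
        )
    mask = np.zeros((ny, nx), dtype=bool)
    # Paint each ellipse into its local window; pixel centres are at
    # (xmin + (i+0.5)px, ymax - (j+0.5)px) with j the row index (y-down).
    for k in range(n):
        i0 = max(0, int((cx[k] - ex[k] - xmin) * px_per_um) - 1)
        i1 = min(nx, int((cx[k] + ex[k] - xmin) * px_per_um) + 2)
        j0 = max(0, int((ymax - (cy[k] + ey[k])) * px_per_um) - 1)
        j1 = min(ny, int((ymax - (cy[k] - ey[k])) * px_per_um) + 2)
        xs = xmin + (np.arange(i0, i1) + 0.5) * px
        ys = ymax - (np.arange(j0, j1) + 0.5) * px
        dx = xs[None, :] - cx[k]
        dy = ys[:, None] - cy[k]
        xl = dx * ct[k] + dy * st[k]
        yl = -dx * st[k] + dy * ct[k]
        mask[j0:j1, i0:i1] |= (xl / a[k]) ** 2 + (yl / b[k]) ** 2 <= 1.0
    return mask


def colony_to_mask(colony: Colony, px_per_um: float = 1.0):
    """Rasterise the union of all cell ellipses to a :class:`BinaryImage`."""
    from .morphometry import BinaryImage

    cx, cy, ct, st, a, b, _ = colony.arrays()
    mask = rasterise_ellipses(cx, cy, ct, st, a, b, px_per_um)
    return BinaryImage(mask, px_size=1.0 / px_per_um)


class ColonySimulator:
    """Generator of simulated colonies with a scikit-learn parameter API.

    Parameters mirror :class:`SimParams`; :meth:`sample` draws colonies,
    :meth:`sample_masks` additionally rasterises them.

    Examples
    --------
    >>> sim = ColonySimulator(n_star=1.0, n_max=50, random_state=0)
    >>> colony = sim.sample()
    >>> colony.n
    50
    """

    def __init__(
        self,
        n_star: float = 0.67,
        p_a: float = 0.14,
        p_sp: float = 0.25,
        p_ps: float = 0.58,
        gamma: float = 0.12,
        n_max: int = 1000,
        target_area: float | None = None,
        area_tol: float = 0.05,
        px_per_um: float = 1.0,
        domain: tuple[float, float] = (4000.0, 4000.0),
        max_consecutive_aborts: int = 100_000,
        engine: str = "auto",
        random_state: int | None = None,
    ):
        self.n_star = n_star
        self.p_a = p_a
        self.p_sp = p_sp
        self.p_ps = p_ps
        self.gamma = gamma
        self.n_max = n_max
        self.target_area = target_area
        self.area_tol = area_tol
        self.px_per_um = px_per_um
        self.domain = domain
        self.max_consecutive_aborts = max_consecutive_aborts
        self.engine = engine
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "n_star", "p_a", "p_sp", "p_ps", "gamma", "n_max",
                "target_area", "area_tol", "px_per_um", "domain",
                "max_consecutive_aborts", "engine", "random_state",
            )
        }

    def set_params(self, **params) -> "ColonySimulator":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _sim_params(self, seed: int) -> SimParams:
        return SimParams(
            n_star=self.n_star, p_a=self.p_a, p_sp=self.p_sp, p_ps=self.p_ps,
            gamma=self.gamma, n_max=self.n_max, target_area=self.target_area,
            area_tol=self.area_tol, px_per_um=self.px_per_um,
            domain=self.domain,
            max_consecutive_aborts=self.max_consecutive_aborts, seed=seed,
        )

    def set_theta(self, theta) -> "ColonySimulator":
        """Set the five inferred parameters from a vector
        (n*, p_a, p_sp, p_ps, gamma)."""
        n_star, p_a, p_sp, p_ps, gamma = np.asarray(theta, dtype=float)
        return self.set_params(
            n_star=float(n_star), p_a=float(p_a), p_sp=float(p_sp),
            p_ps=float(p_ps), gamma=float(gamma),
        )

    def sample(self, random_state: int | None = None) -> Colony:
        """Run one simulation and return the grown colony."""
        seed = self.random_state if random_state is None else random_state
        if seed is None:
            seed = int(np.random.default_rng().integers(2**31))
        return run_simulation(self._sim_params(int(seed)), engine=self.engine)

    def sample_masks(self, n_colonies: int, random_state: int | None = None):
        """Simulate ``n_colonies`` independent colonies and rasterise each."""
        seed = self.random_state if random_state is None else random_state
        ss = np.random.SeedSequence(seed)
        seeds = [int(s) % (2**31) for s in ss.generate_state(n_colonies)]
        return [
            colony_to_mask(self.sample(random_state=s), self.px_per_um)
            for s in seeds
        ]
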