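"""Compiled growth kernel.

Implements the same budding decision tree, volume exclusion and domain
clipping as the readable propose/attempt loop in :mod:`filacol.simulate`,
as one numba-jitted function over flat arrays.  The random stream differs
from the Python engine (numba's Mersenne Twister vs numpy's Generator)
but each engine is deterministic given the seed.

The kernel is restartable: ``_grow`` continues a colony from ``n`` cells
to ``n_target`` without reseeding, which lets the area-mode stopping rule
rasterise between growth chunks.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .geometry import Cell, bud_angle_parameter
from .simulate import Colony, ColonyStallError, SimParams

__all__ = ["run_simulation_fast", "grow_arrays", "raster_kernel"]


@njit(cache=True)
def raster_kernel(cx, cy, ct, st, aa, bb, px_per_um, xmin, ymax, ny, nx):
    """Paint ellipses onto a pixel grid; same formula as the numpy path."""
    mask = np.zeros((ny, nx), np.bool_)
    px = 1.0 / px_per_um
    n = len(cx)
    for k in range(n):
        ex = math.sqrt((aa[k] * ct[k]) ** 2 + (bb[k] * st[k]) ** 2)
        ey = math.sqrt((aa[k] * st[k]) ** 2 + (bb[k] * ct[k]) ** 2)
        i0 = max(0, int((cx[k] - ex - xmin) * px_per_um) - 1)
        i1 = min(nx, int((cx[k] + ex - xmin) * px_per_um) + 2)
        j0 = max(0, int((ymax - (cy[k] + ey)) * px_per_um) - 1)
        j1 = min(ny, int((ymax - (cy[k] - ey)) * px_per_um) + 2)
        for j in range(j0, j1):
            y = ymax - (j + 0.5) * px
            dy = y - cy[k]
            for i in range(i0, i1):
                x = xmin + (i + 0.5) * px
                dx = x - cx[k]
                xl = dx * ct[k] + dy * st[k]
                yl = -dx * st[k] + dy * ct[k]
                if (xl / aa[k]) ** 2 + (yl / bb[k]) ** 2 <= 1.0:
                    mask[j, i] = True
    return mask

_STALLED = -1


@njit(cache=True)
def _grow(
    cx, cy, th, ct, st, aa, bb, ph, has_pd, mother, used,
    n, n_target, n_max,
    n_star, p_a, p_sp, p_ps, gamma,
    a_s, b_s, phib_s, a_p, b_p, phib_p,
    lx, ly, max_aborts, seed, do_seed,
):
    if do_seed:
        np.random.seed(seed)
    aborts = 0
    cand = np.empty(n_max, np.int64)
    free = np.empty(4, np.int64)
    while n < n_target:
        # --- decision tree ---------------------------------------------
        d_ph = False
        if n / n_max <= n_star:
            m = np.random.randint(n)
            n_sites = 4
        else:
            n_ph = 0
            for j in range(n):
                if ph[j]:
                    n_ph += 1
            mother_sated = n_ph == 0 or np.random.random() < p_a
            if mother_sated:
                k = 0
                for j in range(n):
                    if not ph[j]:
                        cand[k] = j
                        k += 1
                m = cand[np.random.randint(k)]
                d_ph = np.random.random() < p_sp
                n_sites = 4
            else:
                k = 0
                for j in range(n):
                    if ph[j]:
                        cand[k] = j
                        k += 1
                m = cand[np.random.randint(k)]
                n_sites = 2
                if not has_pd[m]:
                    d_ph = True
                elif np.random.random() < gamma:
                    # forking control: redirect to a fresh branch tip
                    k = 0
                    for j in range(n):
                        if ph[j] and not has_pd[j]:
                            cand[k] = j
                            k += 1
                    if k == 0:
                        aborts += 1
                        if aborts >= max_aborts:
                            return _STALLED, n
                        continue
                    m = cand[np.random.randint(k)]
                    d_ph = True
                else:
                    d_ph = not (np.random.random() < p_ps)
        # --- free bud site ---------------------------------------------
        k = 0
        for s in range(n_sites):
            if used[m, s] == 0:
                free[k] = s
                k += 1
        if k == 0:
            aborts += 1
            if aborts >= max_aborts:
                return _STALLED, n
            continue
        site = free[np.random.randint(k)]
        # --- daughter placement ----------------------------------------
        phib = phib_p if ph[m] else phib_s
        if site == 0:
            phi = phib
        elif site == 1:
            phi = -phib
        elif site == 2:
            phi = math.pi - phib
        else:
            phi = math.pi + phib
        cphi = math.cos(phi)
        sphi = math.sin(phi)
        am = aa[m]
        bm = bb[m]
        sx = cx[m] + am * cphi * ct[m] - bm * sphi * st[m]
        sy = cy[m] + am * cphi * st[m] + bm * sphi * ct[m]
        ang = math.atan2(sy - cy[m], sx - cx[m])
        ca = math.cos(ang)
        sa = math.sin(ang)
        if d_ph:
            ad = a_p
            bd = b_p
        else:
            ad = a_s
            bd = b_s
        dx_c = sx + ad * ca
        dy_c = sy + ad * sa
        # --- domain clipping (ellipse bounding box) --------------------
        ex = math.sqrt((ad * ca) ** 2 + (bd * sa) ** 2)
        ey = math.sqrt((ad * sa) ** 2 + (bd * ca) ** 2)
        if (
            dx_c - ex < -lx / 2 or dx_c + ex > lx / 2
            or dy_c - ey < -ly / 2 or dy_c + ey > ly / 2
        ):
            aborts += 1
            if aborts >= max_aborts:
                return _STALLED, n
            continue
        # --- volume exclusion: centre strictly inside any cell? --------
        blocked = False
        for j in range(n):
            dxj = dx_c - cx[j]
            dyj = dy_c - cy[j]
            if dxj * dxj + dyj * dyj < aa[j] * aa[j]:
                xl = dxj * ct[j] + dyj * st[j]
                yl = -dxj * st[j] + dyj * ct[j]
                if (xl / aa[j]) ** 2 + (yl / bb[j]) ** 2 < 1.0:
                    blocked = True
                    break
        if blocked:
            aborts += 1
            if aborts >= max_aborts:
                return _STALLED, n
            continue
        # --- commit ----------------------------------------------------
        cx[n] = dx_c
        cy[n] = dy_c
        th[n] = ang
        ct[n] = ca
        st[n] = sa
        aa[n] = ad
        bb[n] = bd
        ph[n] = 1 if d_ph else 0
        mother[n] = m
        used[m, site] = 1
        if d_ph:
            has_pd[m] = 1
        n += 1
        aborts = 0
    return 0, n


class _State:
    """Flat colony arrays for the kernel, sized to the n_max cap."""

    def __init__(self, params: SimParams):
        cap = params.n_max
        self.cx = np.empty(cap)
        self.cy = np.empty(cap)
        self.th = np.empty(cap)
        self.ct = np.empty(cap)
        self.st = np.empty(cap)
        self.aa = np.empty(cap)
        self.bb = np.empty(cap)
        self.ph = np.zeros(cap, np.uint8)
        self.has_pd = np.zeros(cap, np.uint8)
        self.mother = np.full(cap, -1, np.int64)
        self.used = np.zeros((cap, 4), np.uint8)
        self.cx[0] = 0.0
        self.cy[0] = 0.0
        self.th[0] = 0.0
        self.ct[0] = 1.0
        self.st[0] = 0.0
        self.aa[0] = params.sated.half_length
        self.bb[0] = params.sated.half_width
        self.n = 1

    def grow_to(self, params: SimParams, n_target: int, first: bool) -> int:
        status, self.n = _grow(
            self.cx, self.cy, self.th, self.ct, self.st, self.aa, self.bb,
            self.ph, self.has_pd, self.mother, self.used,
            self.n, n_target, params.n_max,
            params.n_star, params.p_a, params.p_sp, params.p_ps, params.gamma,
            params.sated.half_length, params.sated.half_width,
            bud_angle_parameter(params.sated),
            params.pseudohyphal.half_length, params.pseudohyphal.half_width,
            bud_angle_parameter(params.pseudohyphal),
            params.domain[0], params.domain[1],
            params.max_consecutive_aborts, params.seed, first,
        )
        return status


def grow_arrays(params: SimParams):
    """Run a full simulation, returning flat arrays.

    Returns ``(cx, cy, ct, st, a, b, ph)`` trimmed to the final cell
    count; used by the inference hot loop, which rasterises directly.
    Raises :class:`ColonyStallError` on a jam (partial colony attached).
    """
    state = _State(params)
    if params.target_area is None:
        status = state.grow_to(params, params.n_max, first=True)
        if status == _STALLED:
            raise ColonyStallError(
                f"colony jammed at n={state.n}", _to_colony(state, params)
            )
    else:
        _grow_area_mode(state, params)
    n = state.n
    return (
        state.cx[:n], state.cy[:n], state.ct[:n], state.st[:n],
        state.aa[:n], state.bb[:n], state.ph[:n].astype(bool), state,
    )


def _grow_area_mode(state: _State, params: SimParams) -> None:
    from .simulate import rasterise_ellipses

    target = params.target_area
    first = True
    while True:
        n = state.n
        mask = rasterise_ellipses(
            state.cx[:n], state.cy[:n], state.ct[:n], state.st[:n],
            state.aa[:n], state.bb[:n], params.px_per_um,
        )
        area = int(mask.sum())
        if area >= target * (1 - params.area_tol):
            return
        if n >= params.n_max:
            import warnings

            warnings.warn("area-mode simulation hit the n_max safety cap")
            return
        per_cell = max(area / n, 1.0)
        chunk = max(1, int(0.9 * (target * (1 - params.area_tol / 2) - area) / per_cell))
        n_target = min(params.n_max, n + chunk)
        status = state.grow_to(params, n_target, first=first)
        first = False
        if status == _STALLED:
            raise ColonyStallError(
                f"colony jammed at n={state.n}", _to_colony(state, params)
            )


def _to_colony(state: _State, params: SimParams) -> Colony:
    """Materialise Cell objects from the kernel arrays."""
    colony = Colony(params, np.random.default_rng(params.seed))
    for i in range(state.n):
        tp = params.pseudohyphal if state.ph[i] else params.sated
        cell = Cell(
            id=i,
            centre=np.array([state.cx[i], state.cy[i]]),
            orientation=float(state.th[i]),
            type_params=tp,
            mother_id=int(state.mother[i]) if state.mother[i] >= 0 else None,
            has_pseudohyphal_daughter=bool(state.has_pd[i]),
            used_sites={s for s in range(4) if state.used[i, s]},
        )
        colony.append(cell)
        colony._has_pd[i] = bool(state.has_pd[i])
    return colony


def run_simulation_fast(params: SimParams) -> Colony:
    """Kernel-backed equivalent of :func:`filacol.simulate.run_simulation`."""
    state = _State(params)
    if params.target_area is None:
        status = state.grow_to(params, params.n_max, first=True)
        if status == _STALLED:
            raise ColonyStallError(
                f"colony jammed at n={state.n}", _to_colony(state, params)
            )
    else:
        _grow_area_mode(state, params)
    return _to_colony(state, params)
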