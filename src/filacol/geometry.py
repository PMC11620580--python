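"""Ellipse-cell geometry for the off-lattice colony model.

Every cell is an ellipse with centre ``m``, half-length ``a`` along the
cell axis (major radius), half-width ``b`` perpendicular to it, and
orientation ``theta`` measured anticlockwise from the x-axis.  The distal
pole is ``m + a (cos theta, sin theta)``; the proximal pole is the
opposite end.  Daughters bud from four prescribed sites on the boundary,
two flanking each pole at the budding angle ``beta`` measured from the
cell axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellTypeParams",
    "Cell",
    "SATED",
    "PSEUDOHYPHAL",
    "boundary_point",
    "bud_angle_parameter",
    "bud_sites",
    "contains_point",
    "place_daughter",
    "BudSiteOccupiedError",
]

N_BUD_SITES = 4
DISTAL_SITES = (0, 1)
PROXIMAL_SITES = (2, 3)


class BudSiteOccupiedError(ValueError):
    """Raised when a daughter is requested at an already-used bud site."""


@dataclass(frozen=True)
class CellTypeParams:
    """Fixed per-type dimensions and budding angle.

    Parameters
    ----------
    label : str
        ``"sated"`` or ``"pseudohyphal"``.
    half_length : float
        Radius along the cell axis, in micrometres (major radius).
    half_width : float
        Radius perpendicular to the axis, in micrometres (minor radius).
    beta : float
        Budding angle in radians, measured from the cell axis; must lie
        strictly inside (0, pi/2).
    """

    label: str
    half_length: float
    half_width: float
    beta: float

    def __post_init__(self) -> None:
        if self.half_length <= 0 or self.half_width <= 0:
            raise ValueError("cell radii must be positive")
        if self.half_length < self.half_width:
            raise ValueError("half_length must be >= half_width (aspect ratio >= 1)")
        if not 0.0 < self.beta < math.pi / 2:
            raise ValueError("budding angle beta must lie in (0, pi/2)")

    @property
    def aspect_ratio(self) -> float:
        return self.half_length / self.half_width

    @property
    def area(self) -> float:
        """Ellipse area pi*a*b in square micrometres."""
        return math.pi * self.half_length * self.half_width


#: Sated (bipolar-budding) cell: aspect ratio ~1.5, wide budding angle.
SATED = CellTypeParams("sated", half_length=4.2, half_width=3.0, beta=7 * math.pi / 16)

#: Pseudohyphal (elongated, unipolar) cell: aspect ratio ~3.5, narrow angle.
PSEUDOHYPHAL = CellTypeParams(
    "pseudohyphal", half_length=6.7, half_width=1.9, beta=math.pi / 16
)


@dataclass
class Cell:
    """One ellipse agent in the colony."""

    id: int
    centre: np.ndarray
    orientation: float
    type_params: CellTypeParams
    mother_id: int | None = None
    has_pseudohyphal_daughter: bool = False
    used_sites: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=float)
        if self.centre.shape != (2,):
            raise ValueError("centre must be a 2-vector")

    @property
    def direction_vector(self) -> np.ndarray:
        """Half-length-scaled axis vector a*(cos theta, sin theta)."""
        a = self.type_params.half_length
        return a * np.array(
            [math.cos(self.orientation), math.sin(self.orientation)]
        )

    @property
    def distal_pole(self) -> np.ndarray:
        return self.centre + self.direction_vector

    @property
    def proximal_pole(self) -> np.ndarray:
        return self.centre - self.direction_vector

    @property
    def is_pseudohyphal(self) -> bool:
        return self.type_params.label == "pseudohyphal"

    def free_sites(self, sites: tuple[int, ...] = (0, 1, 2, 3)) -> list[int]:
        return [s for s in sites if s not in self.used_sites]


def boundary_point(cell: Cell, phi: float) -> np.ndarray:
    """Point on the cell boundary at angle parameter ``phi``.

    ``phi = 0`` maps to the distal pole; the parameter increases
    anticlockwise in the cell frame and is wrapped into [0, 2*pi).
    """
    phi = phi % (2 * math.pi)
    a = cell.type_params.half_length
    b = cell.type_params.half_width
    ct, st = math.cos(cell.orientation), math.sin(cell.orientation)
    cp, sp = math.cos(phi), math.sin(phi)
    return cell.centre + np.array(
        [a * cp * ct - b * sp * st, a * cp * st + b * sp * ct]
    )


def bud_angle_parameter(type_params: CellTypeParams) -> float:
    """Boundary-parameter angle ``phi_beta`` of the budding angle ``beta``.

    A ray from the centre at angle ``beta`` to the cell axis meets the
    boundary at parameter ``phi_beta`` satisfying
    ``tan(beta) = (b/a) tan(phi_beta)``.  The closed form used here is

        phi_beta = beta + arctan((a - b) tan(beta) / (b + a tan^2(beta)))

    which is algebraically identical to ``arctan((a/b) tan(beta))`` on the
    principal branch and lies in (0, pi/2).
    """
    a = type_params.half_length
    b = type_params.half_width
    beta = type_params.beta
    if not 0.0 < beta < math.pi / 2:
        raise ValueError("beta must lie in (0, pi/2)")
    t = math.tan(beta)
    return beta + math.atan((a - b) * t / (b + a * t * t))


def bud_sites(cell: Cell) -> list[tuple[int, np.ndarray, float]]:
    """The four bud sites of a cell.

    Returns a list of ``(site_index, point, outward_angle)``: sites 0 and 1
    flank the distal pole at boundary parameters ``+phi_beta`` and
    ``-phi_beta``; sites 2 and 3 flank the proximal pole at
    ``pi - phi_beta`` and ``pi + phi_beta``.  ``outward_angle`` is the
    absolute direction of the ray from the cell centre through the site.
    """
    phi_b = bud_angle_parameter(cell.type_params)
    out = []
    for idx, phi in enumerate([phi_b, -phi_b, math.pi - phi_b, math.pi + phi_b]):
        p = boundary_point(cell, phi)
        d = p - cell.centre
        out.append((idx, p, math.atan2(d[1], d[0])))
    return out


def contains_point(cell: Cell, p) -> bool:
    """True iff ``p`` lies strictly inside the cell's ellipse.

    Boundary contact is permitted overlap, so points exactly on the
    boundary return False.
    """
    p = np.asarray(p, dtype=float)
    a = cell.type_params.half_length
    b = cell.type_params.half_width
    ct, st = math.cos(cell.orientation), math.sin(cell.orientation)
    dx, dy = p[0] - cell.centre[0], p[1] - cell.centre[1]
    xl = dx * ct + dy * st
    yl = -dx * st + dy * ct
    return (xl / a) ** 2 + (yl / b) ** 2 < 1.0


def place_daughter(
    mother: Cell,
    site_index: int,
    daughter_type: CellTypeParams,
    next_id: int,
) -> Cell:
    """Construct the daughter cell budding from ``mother`` at a site.

    The daughter is oriented along the outward ray from the mother's
    centre through the bud site, and translated so that its proximal pole
    touches the site point exactly (tangential contact, no initial
    overlap).  The caller is responsible for volume-exclusion checks.
    """
    if site_index not in range(N_BUD_SITES):
        raise ValueError(f"site_index must be in 0..3, got {site_index}")
    if site_index in mother.used_sites:
        raise BudSiteOccupiedError(
            f"bud site {site_index} of cell {mother.id} already carries a scar"
        )
    _, site_point, out_angle = bud_sites(mother)[site_index]
    a_d = daughter_type.half_length
    centre = site_point + a_d * np.array([math.cos(out_angle), math.sin(out_angle)])
    return Cell(
        id=next_id,
        centre=centre,
        orientation=out_angle,
        type_params=daughter_type,
        mother_id=mother.id,
    )
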