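"""Programmatic test masks and synthetic replicate sets.

Real colony photographs are not bundled with the package; every stage of
the pipeline is instead exercised on masks generated in code with known
morphology: filled disks (compact, branchless colonies), disks with
radial spikes (a controllable number of filament branches per quadrant),
Y-shaped filaments (a known skeleton branch structure) and random blobs
(fuzzing).  ``synthetic_replicate_set`` produces simulated-colony
replicate sets so the full inference pipeline can be tested end to end
without downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .inference import ReplicateStats
from .morphometry import BinaryImage, summarise
from .simulate import ColonySimulator

__all__ = ["FixtureSpec", "make_fixture", "synthetic_replicate_set"]

#: Default angular offset of the first spike.  With 8 evenly spaced
#: spikes this puts exactly two (at 100 and 145 degrees) inside the
#: branch-counting quadrant [90, 180] degrees.
SPIKE_OFFSET = math.pi / 18


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one deterministic fixture mask."""

    kind: str = "disk"
    radius: int = 100
    n_spikes: int = 0
    spike_length: int = 80
    spike_width: int = 5
    spike_taper: float = 0.0
    spike_offset: float = SPIKE_OFFSET
    canvas: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("disk", "disk_spikes", "y_filament", "random_blob"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.n_spikes < 0:
            raise ValueError("n_spikes must be >= 0")
        if self.n_spikes > 0 and (self.spike_length <= 0 or self.spike_width <= 0):
            raise ValueError("spike dimensions must be positive")


def _grid(half: int):
    ax = np.arange(2 * half + 1) - half
    x = ax[None, :].astype(float)
    y = -ax[:, None].astype(float)  # row 0 is the top: y decreases downwards
    return x, y


def _stamp_segment(mask, x, y, x0, y0, x1, y1, width, taper=0.0):
    """Paint a thick line segment (capsule) onto the mask.

    ``taper`` linearly widens the stroke towards its far end: the local
    width is ``width * (1 + taper * t)`` for ``t in [0, 1]`` along the
    segment.
    """
    vx, vy = x1 - x0, y1 - y0
    L2 = vx * vx + vy * vy
    t = ((x - x0) * vx + (y - y0) * vy) / max(L2, 1e-12)
    t = np.clip(t, 0.0, 1.0)
    px, py = x0 + t * vx, y0 + t * vy
    w = width * (1.0 + taper * t)
    mask |= (x - px) ** 2 + (y - py) ** 2 <= (w / 2.0) ** 2


def make_fixture(spec: FixtureSpec) -> BinaryImage:
    """Deterministic binary mask for a fixture recipe."""
    r = spec.radius
    if spec.kind == "disk":
        half = r + 4
        x, y = _grid(half)
        return BinaryImage(x * x + y * y <= r * r)

    if spec.kind == "disk_spikes":
        reach = r + spec.spike_length
        half = reach + 4
        if spec.canvas is not None and spec.canvas < 2 * half + 1:
            raise ValueError("spikes longer than the canvas")
        x, y = _grid(half)
        mask = x * x + y * y <= r * r
        for k in range(spec.n_spikes):
            ang = spec.spike_offset + 2 * math.pi * k / max(spec.n_spikes, 1)
            _stamp_segment(
                mask, x, y,
                0.8 * r * math.cos(ang), 0.8 * r * math.sin(ang),
                reach * math.cos(ang), reach * math.sin(ang),
                spec.spike_width, taper=spec.spike_taper,
            )
        return BinaryImage(mask)

    if spec.kind == "y_filament":
        # Disk core plus a Y-shaped filament in the top-left quadrant:
        # a radial stem that splits into two arms.  The skeleton of the
        # filament region has exactly three segments.
        stem = spec.spike_length
        arm = max(stem // 2, 8)
        half = r + stem + arm + 6
        x, y = _grid(half)
        mask = x * x + y * y <= r * r
        ang = 3 * math.pi / 4  # 135 degrees, well inside [90, 180]
        sx0, sy0 = 0.8 * r * math.cos(ang), 0.8 * r * math.sin(ang)
        sx1, sy1 = (r + stem) * math.cos(ang), (r + stem) * math.sin(ang)
        _stamp_segment(mask, x, y, sx0, sy0, sx1, sy1, spec.spike_width)
        for da in (-math.pi / 5, math.pi / 5):
            ex = sx1 + arm * math.cos(ang + da)
            ey = sy1 + arm * math.sin(ang + da)
            _stamp_segment(mask, x, y, sx1, sy1, ex, ey, spec.spike_width)
        return BinaryImage(mask)

    # random_blob: a solid core, a speckled halo of sub-CSR density (a
    # dense fringe of unresolved filaments), and a few larger blobs for
    # irregularity.  The pixel-level speckle keeps the radial density
    # profile flat but clearly below rho_csr, so most of the occupied
    # area lies beyond r_csr.
    rng = np.random.default_rng(spec.seed)
    half = int(2.5 * r) + 4
    x, y = _grid(half)
    r2 = x * x + y * y
    mask = r2 <= r * r
    halo = (r2 > r * r) & (r2 <= (2.5 * r) ** 2)
    mask |= halo & (rng.random(mask.shape) < 0.3)
    for _ in range(8):
        rad = rng.uniform(0.12 * r, 0.25 * r)
        rho = r * math.sqrt(rng.uniform(0.25, 4.0))
        ang = rng.uniform(0, 2 * math.pi)
        px, py = rho * math.cos(ang), rho * math.sin(ang)
        mask |= (x - px) ** 2 + (y - py) ** 2 <= rad * rad
    return BinaryImage(mask)


def synthetic_replicate_set(
    theta,
    n_rep: int,
    n_max: int = 1000,
    px_per_um: float = 1.0,
    seed: int = 0,
    max_redraws: int = 5,
    **sim_kwargs,
) -> tuple[list[BinaryImage], ReplicateStats]:
    """Simulate ``n_rep`` colonies at ``theta`` and collect their statistics.

    Each replicate uses a distinct seed derived from ``seed``.  If the
    resulting statistics are degenerate (min equals max for any of the
    three, leaving the normalisation undefined) additional replicates are
    drawn, up to ``max_redraws`` rounds.
    """
    if n_rep < 2:
        raise ValueError("need at least 2 replicates")
    sim = ColonySimulator(
        n_max=n_max, px_per_um=px_per_um, **sim_kwargs
    ).set_theta(theta)
    ss = np.random.SeedSequence(seed)
    masks = sim.sample_masks(n_rep, random_state=seed)
    stats = [summarise(m) for m in masks]
    for round_ in range(max_redraws):
        try:
            ref = ReplicateStats.from_summaries(stats)
            return masks, ref
        except ValueError:
            extra_seed = int(ss.generate_state(1)[0] % (2**31)) + round_ + 1
            extra = sim.sample_masks(1, random_state=extra_seed)
            masks.append(extra[0])
            stats.append(summarise(extra[0]))
    raise RuntimeError(
        "replicate statistics remained degenerate after redraws; "
        "increase n_rep or n_max"
    )
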