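"""Monte-Carlo estimate of synaptic loss from slice truncation.

The SPN dendritic field is modelled as a sphere centred on the soma.  A
fraction of synapses (default 80%) lies on dendrites at radii drawn from a
configurable radial density; the remainder sits at the soma and is never
lost.  Directions are isotropic.  Slicing removes a spherical cap: a
dendritic synapse is lost iff its coordinate toward the cut surface
exceeds the soma depth (default 80 um, the shallowest recording depth —
a conservative, worst-case plane; the far slice face is ignored).

For all mass at a single radius r > d, the cap geometry gives the closed
form loss = frac_dendritic * (r - d) / (2 r), used as the cross-check
oracle for the sampler.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TruncationConfig",
    "TruncationResult",
    "estimate_truncation_loss",
    "expected_loss_single_radius",
]

#: Anatomy-inspired radial density of dendritic synapses: rare near the
#: soma, peaking mid-arbor (80 um) and vanishing at the field edge (200 um).
#: Knots are (radius_um, relative density), linearly interpolated.
DEFAULT_RADIAL_DENSITY: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (80.0, 1.0),
    (200.0, 0.0),
)


@dataclass(frozen=True)
class TruncationConfig:
    """Spherical dendritic-field model parameters."""

    dendritic_radius_um: float = 200.0
    frac_dendritic: float = 0.8
    radial_density: tuple[tuple[float, float], ...] = field(
        default_factory=lambda: DEFAULT_RADIAL_DENSITY
    )
    soma_depth_um: float = 80.0
    n_synapses: int = 100_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_dendritic <= 1.0:
            raise ValueError("frac_dendritic must be in [0, 1]")
        if self.soma_depth_um < 0:
            raise ValueError("soma_depth_um must be >= 0")
        if self.dendritic_radius_um <= 0:
            raise ValueError("dendritic_radius_um must be positive")
        if self.n_synapses < 1:
            raise ValueError("n_synapses must be >= 1")
        knots = tuple(self.radial_density)
        if not knots:
            raise ValueError("radial_density table must not be empty")
        radii = [r for r, _ in knots]
        weights = [w for _, w in knots]
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ValueError("radial_density weights must be >= 0, not all zero")
        if min(radii) < 0 or max(radii) > self.dendritic_radius_um:
            raise ValueError("radial_density radii must lie in [0, R]")
        if sorted(radii) != radii:
            raise ValueError("radial_density radii must be increasing")


@dataclass(frozen=True)
class TruncationResult:
    loss_fraction: float
    standard_error: float
    n_synapses: int
    n_lost: int

    @property
    def loss_pct(self) -> float:
        return 100.0 * self.loss_fraction


def _sample_radii(
    config: TruncationConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Inverse-CDF sampling of the (interpolated) radial density."""
    knots = np.asarray(config.radial_density, dtype=float)
    if knots.shape[0] == 1:
        return np.full(n, knots[0, 0])
    grid = np.linspace(knots[0, 0], knots[-1, 0], 4001)
    pdf = np.interp(grid, knots[:, 0], knots[:, 1])
    cdf = np.concatenate(([0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2.0
                                           * np.diff(grid))))
    cdf /= cdf[-1]
    u = rng.random(n)
    return np.interp(u, cdf, grid)


def estimate_truncation_loss(
    config: TruncationConfig | None = None, seed=0
) -> TruncationResult:
    """Monte-Carlo fraction of synapses lost to the truncation cap.

    Somatic synapses (1 - frac_dendritic) are never lost.  Dendritic
    synapses draw a radius from the radial density and an isotropic
    direction; the one lost condition is z > soma_depth, where z is the
    coordinate toward the cut surface (z/r is uniform on [-1, 1] under
    isotropy).  Returns the loss fraction and its binomial standard error.
    """
    config = config or TruncationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n_synapses
    dendritic = rng.random(n) < config.frac_dendritic
    n_dend = int(dendritic.sum())
    lost = 0
    if n_dend:
        r = _sample_radii(config, rng, n_dend)
        z = r * rng.uniform(-1.0, 1.0, size=n_dend)
        lost = int(np.count_nonzero(z > config.soma_depth_um))
    p = lost / n
    se = math.sqrt(p * (1.0 - p) / n)
    return TruncationResult(p, se, n, lost)


def expected_loss_single_radius(
    radius_um: float, soma_depth_um: float, frac_dendritic: float = 1.0
) -> float:
    """Closed-form loss when all dendritic mass sits at one radius.

    Under isotropy z/r is uniform, so P(z > d) = (r - d) / (2 r) for
    r > d and 0 otherwise.
    """
    if radius_um <= soma_depth_um:
        return 0.0
    return frac_dendritic * (radius_um - soma_depth_um) / (2.0 * radius_um)
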