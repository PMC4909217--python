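"""Deterministic generators of synthetic inputs for tests and examples.

Nothing here downloads or reads experimental data: traced-length tables are
drawn from a constant-kernel stochastic coalescence process (the same
merge-anybody-with-anybody statistics that end-to-end annealing produces
when rates are length-independent), calibration curves from the closed-form
worm-like-chain expression plus optional noise, and reaction fixtures are
two ULFs placed with an exact gap and junction angle.

The coalescence generator is a millisecond-scale stand-in for the full
Monte Carlo; its distributional family mimics annealing statistics but is
not a claim about any experimental dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .analysis import LengthDistribution
from .engine import seed_rng_state
from .polymer import PeriodicBox, SimulationParams, SystemState, init_system
from .wlc import CalibrationCurve, wlc_rg2

__all__ = [
    "FixtureSpec",
    "make_traced_lengths",
    "make_calibration_points",
    "make_reactive_pair",
]


def _coalesce_to(n_monomers: int, n_clusters: int, rng: np.random.Generator
                 ) -> np.ndarray:
    """Constant-kernel coalescence: merge uniformly random cluster pairs
    until ``n_clusters`` remain; returns integer cluster sizes."""
    sizes = np.ones(n_monomers, dtype=np.int64)
    k = n_monomers
    while k > n_clusters:
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        sizes[i] += sizes[j]
        sizes[j] = sizes[k - 1]
        k -= 1
    return np.sort(sizes[:k])


def make_traced_lengths(
    n: int,
    target_mean_ulf: float,
    seed: int = 0,
    time_label: Optional[float] = None,
) -> LengthDistribution:
    """Synthetic traced-length table with ``n`` filaments averaging
    ``target_mean_ulf`` ULFs per filament.

    Integer ULF counts come from constant-kernel coalescence started from
    ``round(n * target_mean_ulf)`` monomers and stopped at ``n`` clusters,
    so the sample mean is the target up to monomer-count rounding; lengths
    are the exact ULF-to-nm conversion.  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if target_mean_ulf < 1:
        raise ValueError("target mean must be >= 1 ULF")
    n_monomers = int(round(n * target_mean_ulf))
    if n_monomers < n:
        raise ValueError("infeasible target: fewer monomers than filaments")
    rng = np.random.default_rng(seed)
    sizes = _coalesce_to(n_monomers, n, rng)
    return LengthDistribution.from_ulf_counts(
        sizes, time_label=time_label, source=f"synthetic-coalescence(seed={seed})"
    )


def make_calibration_points(
    lp_nm: float,
    lc_grid: Sequence[float] = (100, 200, 400, 800, 1600, 3200),
    noise: float = 0.0,
    seed: int = 0,
    alpha_deg: float = float("nan"),
) -> CalibrationCurve:
    """Synthetic Rg^2(lc) curve from the closed-form WLC expression with
    multiplicative Gaussian noise of relative size ``noise`` (0 = exact)."""
    if lp_nm <= 0:
        raise ValueError("lp must be positive")
    lc = np.asarray(sorted(lc_grid), dtype=float)
    rg2 = wlc_rg2(lc, lp_nm)
    rng = np.random.default_rng(seed)
    if noise > 0:
        rg2 = rg2 * (1.0 + noise * rng.standard_normal(lc.size))
        se = noise * rg2
    else:
        se = 1e-9 * rg2
    return CalibrationCurve(
        lc=lc, rg2=rg2, rg2_se=se, alpha_deg=alpha_deg,
        sweeps_per_point=np.zeros(lc.size), seed=seed,
        n_ulfs=np.zeros(lc.size),
    )


def make_reactive_pair(
    gap_nm: float,
    junction_angle_deg: float = 0.0,
    params: Optional[SimulationParams] = None,
    box_edge_nm: float = 1000.0,
) -> SystemState:
    """Two straight ULFs whose facing terminal beads are exactly ``gap_nm``
    apart, meeting at the given junction angle.

    Filament A lies along +x ending at the origin; filament B starts at
    ``(gap, 0, 0)`` and continues at ``junction_angle_deg`` to the x axis
    (in the xy plane).  The A-side junction angle is 0.  Useful as a unit
    fixture for reaction detection and annealing.
    """
    if params is None:
        params = SimulationParams()
    if gap_nm <= 0:
        raise ValueError("gap must be positive")
    if not 0.0 <= junction_angle_deg < 180.0:
        raise ValueError("junction angle must be in [0, 180) degrees")
    d = params.bead_diameter
    k = params.beads_per_ulf
    box = PeriodicBox(box_edge_nm)
    state = init_system(2, box, params, seed=0)
    # overwrite the random placement with the exact geometry
    center = box_edge_nm / 2.0
    a_beads = np.zeros((k, 3))
    a_beads[:, 0] = center + d * (np.arange(k) - (k - 1))
    theta = np.radians(junction_angle_deg)
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    start = np.array([center + gap_nm, 0.0, 0.0])
    b_beads = start + direction * (d * np.arange(k))[:, None]
    pos = np.vstack([a_beads, b_beads])
    pos[:, 1] += center
    pos[:, 2] += center
    state.pos[:] = pos
    state.rng_state = seed_rng_state(params.seed)
    return state


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic input; ``build()`` dispatches
    to the matching generator."""

    kind: str                     # traced_lengths | calibration_points | reactive_pair
    n: int = 1000
    target_mean_ulf: float = 7.9
    lp_nm: float = 1000.0
    noise: float = 0.0
    gap_nm: float = 11.0
    junction_angle_deg: float = 0.0
    seed: int = 0

    def build(self):
        if self.kind == "traced_lengths":
            return make_traced_lengths(self.n, self.target_mean_ulf, seed=self.seed)
        if self.kind == "calibration_points":
            return make_calibration_points(self.lp_nm, noise=self.noise, seed=self.seed)
        if self.kind == "reactive_pair":
            return make_reactive_pair(self.gap_nm, self.junction_angle_deg)
        raise ValueError(f"unknown fixture kind {self.kind!r}")
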