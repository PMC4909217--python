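"""Bead-bond filament model: domain types and geometric primitives.

Filaments are chains of spherical beads of diameter ``d`` (11 nm for
intermediate filaments).  A unit-length filament (ULF) is four consecutive
beads; bonds between neighbouring beads may stretch between ``0.8 d`` and
``1.2 d``, and the angle between consecutive bond vectors is capped at a
maximum bond angle ``alpha`` (15 degrees for vimentin/desmin, 25 degrees for
keratin).  There are no energies: conformations are accepted or rejected on
these geometric criteria alone, and the persistence length of the chain is
an emergent property of the angular measure (see :mod:`ifsim.wlc`).

Coordinates are stored *unwrapped*; the periodic box enters only through
minimum-image distance queries used for reaction detection, so contour
lengths and radii of gyration are never corrupted by wrapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Sequence

import numpy as np

__all__ = [
    "UNIFORM_ANGLE",
    "UNIFORM_CONE",
    "SimulationParams",
    "PeriodicBox",
    "Filament",
    "SystemState",
    "ConstraintViolation",
    "minimum_image",
    "bond_angle",
    "validate_filament",
    "contour_length",
    "radius_of_gyration",
    "init_system",
]

# Angular measures for the bond-angle constraint.  ``UNIFORM_ANGLE`` keeps
# the scalar bond angle uniformly distributed on [0, alpha] (the calibration
# that yields lp = 1000 nm at alpha = 15 deg); ``UNIFORM_CONE`` is the flat
# measure over the spherical cap (cos(theta) uniform on [cos alpha, 1]).
UNIFORM_ANGLE = "uniform-angle"
UNIFORM_CONE = "uniform-cone"

#: Mass of one ULF in grams (~32 vimentin monomers of ~53.7 kDa); reproduces
#: the equivalent-concentration bookkeeping of the simulation runs to ~2%.
ULF_MASS_G = 2.85e-18


@dataclass(frozen=True)
class SimulationParams:
    """All geometric and kinetic constants of the bead-bond model.

    Lengths are in nm, angles in degrees, times in seconds.
    """

    bead_diameter: float = 11.0
    max_bond_angle: float = 15.0
    reaction_angle: float | None = None  # defaults to max_bond_angle
    beads_per_ulf: int = 4
    ulf_length_nm: float = 60.0
    ulf_repeat_nm: float = 42.7
    sweep_time_s: float = 1e-9
    ulf_mass_g: float = ULF_MASS_G
    angle_measure: str = UNIFORM_ANGLE
    #: regularisation floor for the uniform-angle acceptance ratio (degrees)
    min_reg_angle: float = 0.5
    seed: int = 0

    # Derived intervals (fractions of the bead diameter).
    bond_min_frac: float = 0.8
    bond_max_frac: float = 1.2
    max_displacement_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.bead_diameter <= 0:
            raise ValueError("bead_diameter must be positive")
        if not 0.0 < self.bond_min_frac < self.bond_max_frac:
            raise ValueError("need 0 < bond_min < bond_max")
        if not 0.0 < self.max_bond_angle < 180.0:
            raise ValueError("max_bond_angle must lie in (0, 180) degrees")
        if self.reaction_angle is not None and not 0.0 < self.reaction_angle < 180.0:
            raise ValueError("reaction_angle must lie in (0, 180) degrees")
        if self.max_displacement_frac <= 0:
            raise ValueError("max_displacement must be positive")
        if self.beads_per_ulf < 2:
            raise ValueError("beads_per_ulf must be >= 2")
        if self.angle_measure not in (UNIFORM_ANGLE, UNIFORM_CONE):
            raise ValueError(f"unknown angle_measure {self.angle_measure!r}")

    # -- derived quantities -------------------------------------------------
    @property
    def bond_min(self) -> float:
        return self.bond_min_frac * self.bead_diameter

    @property
    def bond_max(self) -> float:
        return self.bond_max_frac * self.bead_diameter

    @property
    def max_displacement(self) -> float:
        return self.max_displacement_frac * self.bead_diameter

    @property
    def reaction_distance(self) -> float:
        """Ends closer than the maximum bond length may react."""
        return self.bond_max

    @property
    def effective_reaction_angle(self) -> float:
        return self.max_bond_angle if self.reaction_angle is None else self.reaction_angle

    def with_angle(self, alpha_deg: float) -> "SimulationParams":
        """Copy with both the bond and reaction angle set to ``alpha_deg``."""
        return replace(self, max_bond_angle=alpha_deg, reaction_angle=None)


@dataclass(frozen=True)
class PeriodicBox:
    """Cubic box with fully periodic boundaries; ``edge`` in nm."""

    edge: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.edge) or self.edge <= 0:
            raise ValueError("box edge must be positive and finite")

    @property
    def volume_um3(self) -> float:
        return (self.edge / 1000.0) ** 3

    @classmethod
    def from_volume(cls, volume_um3: float) -> "PeriodicBox":
        if volume_um3 <= 0:
            raise ValueError("volume must be positive")
        return cls(edge=1000.0 * volume_um3 ** (1.0 / 3.0))

    @classmethod
    def from_concentration(
        cls, n_ulfs: int, concentration_gpl: float, params: SimulationParams
    ) -> "PeriodicBox":
        """Size the box so ``n_ulfs`` correspond to a protein mass concentration.

        ``c [g/l] = n * m_ulf [g] / V [l]`` with ``V = (edge/1000)^3 um^3``.
        """
        if concentration_gpl <= 0:
            raise ValueError("concentration must be positive")
        volume_um3 = n_ulfs * params.ulf_mass_g / (concentration_gpl * 1e-15)
        return cls.from_volume(volume_um3)


def minimum_image(p: np.ndarray, q: np.ndarray, box: PeriodicBox) -> np.ndarray:
    """Displacement ``q - p`` folded into the primary image of a periodic cube.

    Each component of the result lies in ``(-edge/2, edge/2]``.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("non-finite coordinates")
    d = q - p
    edge = box.edge
    d -= edge * np.floor(d / edge + 0.5)
    # floor(x+0.5) maps the half-open convention to [-edge/2, edge/2); flip
    # the lower boundary so the interval is (-edge/2, edge/2].
    d[d == -edge / 2.0] = edge / 2.0
    return d


def bond_angle(b1: Sequence[float], b2: Sequence[float]) -> float:
    """Angle in degrees between two successive bond vectors (0 = collinear)."""
    b1 = np.asarray(b1, dtype=float)
    b2 = np.asarray(b2, dtype=float)
    n1 = np.linalg.norm(b1)
    n2 = np.linalg.norm(b2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("zero-length bond vector")
    c = float(np.dot(b1, b2) / (n1 * n2))
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


@dataclass(frozen=True)
class ConstraintViolation:
    """A single geometric constraint violation within a filament."""

    kind: str  # "bond-length" | "bond-angle"
    bead_index: int
    value: float
    limit: tuple

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.kind} at bead {self.bead_index}: {self.value:.3f} not in {self.limit}"


@dataclass
class Filament:
    """An ordered chain of bead positions (nm, unwrapped coordinates)."""

    beads: np.ndarray  # (n, 3)
    beads_per_ulf: int = 4

    def __post_init__(self) -> None:
        self.beads = np.asarray(self.beads, dtype=float)
        if self.beads.ndim != 2 or self.beads.shape[1] != 3:
            raise ValueError("beads must be an (n, 3) array")

    @property
    def n_beads(self) -> int:
        return self.beads.shape[0]

    @property
    def n_ulfs(self) -> int:
        return self.n_beads // self.beads_per_ulf

    def bond_vectors(self) -> np.ndarray:
        return np.diff(self.beads, axis=0)


def validate_filament(f: Filament, params: SimulationParams) -> List[ConstraintViolation]:
    """List every bond-length or bond-angle violation (empty list = valid)."""
    out: List[ConstraintViolation] = []
    b = f.bond_vectors()
    if b.shape[0] == 0:
        return out
    lengths = np.linalg.norm(b, axis=1)
    lo, hi = params.bond_min, params.bond_max
    for i, ell in enumerate(lengths):
        if not lo - 1e-9 <= ell <= hi + 1e-9:
            out.append(ConstraintViolation("bond-length", i, float(ell), (lo, hi)))
    alpha = params.max_bond_angle
    for i in range(b.shape[0] - 1):
        ang = bond_angle(b[i], b[i + 1])
        if ang > alpha + 1e-9:
            out.append(ConstraintViolation("bond-angle", i + 1, ang, (0.0, alpha)))
    return out


def contour_length(f: Filament) -> float:
    """Sum of consecutive bead distances, nm."""
    if f.n_beads < 2:
        raise ValueError("contour length needs at least two beads")
    return float(np.linalg.norm(f.bond_vectors(), axis=1).sum())


def radius_of_gyration(f: Filament) -> float:
    """Root-mean-square bead distance from the centroid (unwrapped), nm."""
    if f.n_beads < 1:
        raise ValueError("empty filament")
    c = f.beads.mean(axis=0)
    return float(np.sqrt(((f.beads - c) ** 2).sum(axis=1).mean()))


@dataclass
class SystemState:
    """Flat-array state of an assembly simulation.

    ``pos`` holds unwrapped bead coordinates; connectivity is an undirected
    adjacency ``nb`` (two neighbour slots per bead, -1 = none), which makes
    end-to-end merges orientation-free (no chain reversal is ever needed).
    ``fil_id`` labels each bead with its filament; ``fil_nbeads`` (indexed by
    filament id) is zero for ids that have been absorbed by a merge.
    """

    params: SimulationParams
    box: PeriodicBox
    pos: np.ndarray            # (n_beads, 3) float64
    nb: np.ndarray             # (n_beads, 2) int64
    fil_id: np.ndarray         # (n_beads,)   int64
    fil_nbeads: np.ndarray     # (n0,)        int64
    ends: np.ndarray           # (m,) bead indices of free filament ends
    n_filaments: int
    n0: int
    sweep_count: int = 0
    rng_state: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=np.uint64))
    seed: int = 0

    @property
    def n_beads(self) -> int:
        return self.pos.shape[0]

    @property
    def total_ulfs(self) -> int:
        return self.n_beads // self.params.beads_per_ulf

    def filament_bead_counts(self) -> np.ndarray:
        """Bead count per live filament."""
        return self.fil_nbeads[self.fil_nbeads > 0]

    def filaments(self) -> List[Filament]:
        """Materialise ordered :class:`Filament` objects by walking ends."""
        out: List[Filament] = []
        seen = np.zeros(self.n_beads, dtype=bool)
        for e in sorted(int(x) for x in self.ends):
            if seen[e]:
                continue
            chain = [e]
            seen[e] = True
            prev, cur = -1, e
            while True:
                a, b = self.nb[cur]
                nxt = int(a) if int(a) != prev and int(a) >= 0 else int(b)
                if nxt == prev or nxt < 0:
                    break
                chain.append(nxt)
                seen[nxt] = True
                prev, cur = cur, nxt
                if self.nb[cur, 0] == -1 or self.nb[cur, 1] == -1:
                    break
            out.append(Filament(self.pos[np.array(chain)], self.params.beads_per_ulf))
        return out

    def copy(self) -> "SystemState":
        return SystemState(
            params=self.params,
            box=self.box,
            pos=self.pos.copy(),
            nb=self.nb.copy(),
            fil_id=self.fil_id.copy(),
            fil_nbeads=self.fil_nbeads.copy(),
            ends=self.ends.copy(),
            n_filaments=self.n_filaments,
            n0=self.n0,
            sweep_count=self.sweep_count,
            rng_state=self.rng_state.copy(),
            seed=self.seed,
        )


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def init_system(
    n0: int,
    box: PeriodicBox,
    params: SimulationParams | None = None,
    seed: int | None = None,
) -> SystemState:
    """Place ``n0`` straight ULFs uniformly at random in a periodic box.

    Each ULF is ``beads_per_ulf`` beads on a line at exactly ``1.0 d``
    spacing, with uniform random position and orientation.  ULFs are ideal
    chains (no pair interactions), so no overlap check is performed.
    Deterministic for a given seed.
    """
    if params is None:
        params = SimulationParams()
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    if seed is None:
        seed = params.seed
    k = params.beads_per_ulf
    n_beads = n0 * k
    if n_beads > 2**31 - 1:
        raise ValueError("system too large to index")
    rng = np.random.default_rng(seed)
    origins = rng.random((n0, 3)) * box.edge
    dirs = _random_unit_vectors(rng, n0)
    offsets = np.arange(k)[None, :, None] * params.bead_diameter  # (1, k, 1)
    pos = (origins[:, None, :] + dirs[:, None, :] * offsets).reshape(n_beads, 3)

    nb = np.full((n_beads, 2), -1, dtype=np.int64)
    idx = np.arange(n_beads).reshape(n0, k)
    nb[idx[:, :-1].ravel(), 1] = idx[:, 1:].ravel()
    nb[idx[:, 1:].ravel(), 0] = idx[:, :-1].ravel()
    # normalise neighbour slots: slot 0 filled first for end beads
    first = idx[:, 0]
    nb[first, 0] = nb[first, 1]
    nb[first, 1] = -1

    fil_id = np.repeat(np.arange(n0, dtype=np.int64), k)
    fil_nbeads = np.full(n0, k, dtype=np.int64)
    ends = np.concatenate([idx[:, 0], idx[:, -1]]).astype(np.int64)

    from .engine import seed_rng_state  # local import to avoid cycle

    return SystemState(
        params=params,
        box=box,
        pos=pos,
        nb=nb,
        fil_id=fil_id,
        fil_nbeads=fil_nbeads,
        ends=ends,
        n_filaments=n0,
        n0=n0,
        sweep_count=0,
        rng_state=seed_rng_state(seed),
        seed=seed,
    )
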