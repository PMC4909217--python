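"""Filament length-distribution analytics.

Converts traced filament lengths (nm) to ULF counts and back, summarises
length distributions (number- and mass-weighted histograms, binning in
multiples of the persistence length), and computes the kinetic summary
quantities used to compare assembly speeds across proteins and conditions:
the elongation constant ``(<l_n> - 1) / (c * t)``, equivalent protein
concentrations of simulated systems, and concentration-normalised sweep
counts.

The ULF conversion accounts for end overlap: a single ULF is 60 nm long,
but each annealing step adds only the 42.7 nm repeat because filament ends
interdigitate by ~17 nm, so a filament of ``i`` ULFs measures
``60 + (i - 1) * 42.7`` nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .polymer import SimulationParams

__all__ = [
    "LengthDistribution",
    "KineticsRecord",
    "length_to_ulfs",
    "ulfs_to_length",
    "summarize",
    "DistributionSummary",
    "number_histogram",
    "mass_weighted_histogram",
    "lp_normalized_fractions",
    "elongation_constant",
    "mass_concentration",
    "ulfs_for_concentration",
    "normalized_sweeps",
    "fold_reduction",
]

ULF_LENGTH_NM = 60.0
ULF_REPEAT_NM = 42.7


def length_to_ulfs(length_nm, ulf_length: float = ULF_LENGTH_NM,
                   ulf_repeat: float = ULF_REPEAT_NM):
    """Number of ULF segments in a filament of traced length ``L`` nm:
    ``i = (L - 60) / 42.7 + 1``.  Returns a real number; rounding is the
    caller's choice."""
    L = np.asarray(length_nm, dtype=float)
    if np.any(L < ulf_length - 1e-9):
        raise ValueError(f"length below a single ULF ({ulf_length} nm)")
    i = (L - ulf_length) / ulf_repeat + 1.0
    return float(i) if i.ndim == 0 else i


def ulfs_to_length(i, ulf_length: float = ULF_LENGTH_NM,
                   ulf_repeat: float = ULF_REPEAT_NM):
    """Traced length in nm of a filament of ``i`` ULFs (inverse conversion)."""
    i = np.asarray(i, dtype=float)
    if np.any(i < 1.0 - 1e-12):
        raise ValueError("ULF count must be >= 1")
    L = ulf_length + (i - 1.0) * ulf_repeat
    return float(L) if L.ndim == 0 else L


@dataclass
class LengthDistribution:
    """A set of traced filament lengths at one assembly time point."""

    lengths_nm: np.ndarray
    time_label: Optional[float] = None   # assembly time, s
    source: str = "simulation"           # EM / AFM / TIRFM / simulation

    def __post_init__(self) -> None:
        self.lengths_nm = np.asarray(self.lengths_nm, dtype=float).ravel()
        if self.lengths_nm.size == 0:
            raise ValueError("empty length distribution")
        if not np.all(np.isfinite(self.lengths_nm)):
            raise ValueError("lengths must be finite")
        if np.any(self.lengths_nm < ULF_LENGTH_NM - 1e-9):
            raise ValueError("lengths below one ULF (60 nm)")

    @classmethod
    def from_ulf_counts(cls, counts, time_label=None, source="simulation"):
        return cls(ulfs_to_length(np.asarray(counts, dtype=float)),
                   time_label=time_label, source=source)

    @property
    def n(self) -> int:
        return int(self.lengths_nm.size)

    @property
    def ulfs(self) -> np.ndarray:
        return length_to_ulfs(self.lengths_nm)


@dataclass
class DistributionSummary:
    n: int
    mean_length_nm: float
    mean_ulf: float
    sd_ulf: float


def summarize(dist: LengthDistribution) -> DistributionSummary:
    """Count, mean traced length, and mean/SD of the per-filament ULF number."""
    u = dist.ulfs
    return DistributionSummary(
        n=dist.n,
        mean_length_nm=float(dist.lengths_nm.mean()),
        mean_ulf=float(u.mean()),
        sd_ulf=float(u.std(ddof=0)) if dist.n > 1 else 0.0,
    )


def _ulf_bin_edges(u: np.ndarray, bin_width: float) -> np.ndarray:
    # left-closed right-open bins with edges at multiples of the width,
    # starting at i = 1 (one ULF)
    if bin_width < 1:
        raise ValueError("bin width must be >= 1 ULF")
    top = np.floor((u.max() - 1.0) / bin_width) + 1.0
    return 1.0 + bin_width * np.arange(top + 1)


def number_histogram(dist: LengthDistribution, bin_width: float = 1.0
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Fraction of filaments per ULF-unit bin; fractions sum to 1.

    Returns (edges, fractions); bin k covers [edges[k], edges[k+1]) in ULF
    units.
    """
    u = dist.ulfs
    edges = _ulf_bin_edges(u, bin_width)
    counts, _ = np.histogram(u, bins=edges)
    # np.histogram closes the last bin on the right; our convention is
    # right-open, which the edge construction already guarantees (the last
    # edge is strictly above the maximum except for exact integer hits,
    # which belong to the last bin either way).
    return edges, counts / u.size


def mass_weighted_histogram(dist: LengthDistribution, bin_width: float = 1.0
                            ) -> Tuple[np.ndarray, np.ndarray]:
    """Fraction of *total filament length* per ULF-unit bin (sums to 1)."""
    u = dist.ulfs
    edges = _ulf_bin_edges(u, bin_width)
    total, _ = np.histogram(u, bins=edges, weights=dist.lengths_nm)
    return edges, total / dist.lengths_nm.sum()


def lp_normalized_fractions(dist: LengthDistribution, lp_nm: float
                            ) -> np.ndarray:
    """Length-weighted fractions per persistence-length bin.

    Bin ``k`` collects filaments with length in ``[k*lp, (k+1)*lp)``; the
    value is that bin's share of the total traced length.  Sums to 1.
    """
    if lp_nm <= 0:
        raise ValueError("lp must be positive")
    L = dist.lengths_nm
    k = np.floor(L / lp_nm).astype(int)
    out = np.zeros(k.max() + 1)
    np.add.at(out, k, L)
    return out / L.sum()


@dataclass
class KineticsRecord:
    """One row of an assembly-kinetics comparison table."""

    protein: str
    concentration_gpl: float
    time_s: float
    mean_ulf: float
    n_filaments: Optional[int] = None
    assembly_mode: Optional[str] = None
    elongation: float = field(init=False)

    def __post_init__(self) -> None:
        if self.concentration_gpl <= 0 or self.time_s <= 0:
            raise ValueError("concentration and time must be positive")
        if self.mean_ulf < 1:
            raise ValueError("mean ULF number must be >= 1")
        self.elongation = elongation_constant(
            self.mean_ulf, self.concentration_gpl, self.time_s
        )


def elongation_constant(mean_ulf: float, c_gpl: float, t_s: float) -> float:
    """Assembly speed normalised to 1 g/l and 1 s: ``(<l_n> - 1)/(c t)``,
    in ULF/(g/l)/s."""
    if c_gpl <= 0 or t_s <= 0:
        raise ValueError("concentration and time must be positive")
    if mean_ulf < 1:
        raise ValueError("mean ULF number must be >= 1")
    return (mean_ulf - 1.0) / (c_gpl * t_s)


def mass_concentration(n_ulfs: int, volume_um3: float,
                       params: Optional[SimulationParams] = None) -> float:
    """Equivalent protein concentration (g/l) of ``n_ulfs`` ULFs in a box."""
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    m = (params.ulf_mass_g if params is not None else SimulationParams().ulf_mass_g)
    return n_ulfs * m / (volume_um3 * 1e-15)


def ulfs_for_concentration(c_gpl: float, volume_um3: float,
                           params: Optional[SimulationParams] = None) -> int:
    """ULF count whose mass matches concentration ``c`` in the given box."""
    if c_gpl <= 0 or volume_um3 <= 0:
        raise ValueError("concentration and volume must be positive")
    m = (params.ulf_mass_g if params is not None else SimulationParams().ulf_mass_g)
    return int(round(c_gpl * volume_um3 * 1e-15 / m))


def normalized_sweeps(c_gpl: float, sweeps: float) -> float:
    """Sweep count normalised to 1 g/l: ``c * sweeps``.  Constancy of this
    product across concentrations shows the annealing kinetics are purely
    concentration-limited."""
    if c_gpl <= 0:
        raise ValueError("concentration must be positive")
    return c_gpl * sweeps


def fold_reduction(total_ulfs: float, n_filaments: float) -> float:
    """How many-fold the filament number has dropped since the all-ULF
    start: total ULFs / current filament count (= <l_n>)."""
    if n_filaments < 1:
        raise ValueError("need at least one filament")
    return total_ulfs / n_filaments
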