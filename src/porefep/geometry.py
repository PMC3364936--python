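"""Pore geometry, restraint design and axial ligand density.

Operates on pentameric channel structures (five subunits around a
central ion-conduction pore lined by the M2 helices).  Conventions:

* The pore center is the centroid of the Calpha atoms of the two
  tyrosine anchors (residues 226 and 244) over all five chains.
* The pore axis is the principal axis of those ten anchor atoms,
  oriented so the extracellular end (residue 244 ring) is positive;
  axial coordinates ("z") are measured along this axis from the pore
  center.
* Prime notation indexes M2 positions from the intracellular end:
  ``prime = residue - 223`` (232 -> 9', 239 -> 16').
* Pore collapse is monitored through the five distances between the
  Calpha geometric centers (residues 232-245, the extracellular half of
  M2) of non-adjacent subunit pairs of the pentagon: 1-3, 1-4, 2-4,
  2-5, 3-5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .exceptions import DesignError, DomainError, MissingAtomsError, ValidationError
from .thermo import ThermoContext

PORE_ANCHOR_RESIDUES = (226, 244)      # Tyr pair defining the pore center
M2_EXTRACELLULAR_SPAN = (232, 245)     # Ile232..Leu245
M2_SPAN = (223, 246)                   # 0' .. 23'
_PRIME_OFFSET = 223
#: 1-based index pairs of non-adjacent subunits of a pentagon.
NON_ADJACENT_PAIRS = ((1, 3), (1, 4), (2, 4), (2, 5), (3, 5))


def read_pdb(path) -> struc.AtomArray:
    """First model of a PDB file as a biotite ``AtomArray``."""
    return PDBFile.read(str(path)).get_structure(model=1)


def write_pdb(atoms: struc.AtomArray, path) -> None:
    f = PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


def _ca_coords(atoms: struc.AtomArray, chain: str, res_id: int) -> np.ndarray:
    mask = (
        (atoms.chain_id == chain)
        & (atoms.res_id == res_id)
        & (atoms.atom_name == "CA")
    )
    coords = atoms.coord[mask]
    if coords.shape[0] == 0:
        raise MissingAtomsError(f"no CA atom for chain {chain} residue {res_id}")
    return coords[0]


def _chains(atoms: struc.AtomArray) -> list:
    # preserve file order, not lexicographic
    seen = dict.fromkeys(atoms.chain_id.tolist())
    return list(seen)


def pore_center(atoms: struc.AtomArray) -> np.ndarray:
    """Centroid of the ten Tyr226/Tyr244 Calpha atoms (unweighted)."""
    chains = _chains(atoms)
    if len(chains) != 5:
        raise ValidationError(f"pentamer expected (5 chains), found {len(chains)}")
    coords = [
        _ca_coords(atoms, c, r) for c in chains for r in PORE_ANCHOR_RESIDUES
    ]
    return np.mean(coords, axis=0)


def pore_axis(atoms: struc.AtomArray) -> np.ndarray:
    """Unit vector along the pore, extracellular side positive.

    The principal axis (largest-variance eigenvector) of the ten
    Tyr226/Tyr244 Calpha atoms, with its sign fixed so that the
    centroid of the residue-244 ring projects above the residue-226
    ring.
    """
    chains = _chains(atoms)
    lower = np.array([_ca_coords(atoms, c, PORE_ANCHOR_RESIDUES[0]) for c in chains])
    upper = np.array([_ca_coords(atoms, c, PORE_ANCHOR_RESIDUES[1]) for c in chains])
    pts = np.vstack([lower, upper])
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, upper.mean(axis=0) - lower.mean(axis=0)) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def chain_order(atoms: struc.AtomArray) -> list:
    """Chain ids ordered consecutively around the pore.

    Chains are sorted by azimuthal angle of their M2 extracellular-half
    center about the pore axis, starting from the first chain in file
    order so the labelling is stable.
    """
    chains = _chains(atoms)
    center = pore_center(atoms)
    axis = pore_axis(atoms)
    # orthonormal in-plane basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    angles = {}
    for c in chains:
        m2c = _m2_center(atoms, c) - center
        angles[c] = math.atan2(np.dot(m2c, e2), np.dot(m2c, e1))
    start = chains[0]
    ordered = sorted(chains, key=lambda c: (angles[c] - angles[start]) % (2 * math.pi))
    return ordered


def _m2_center(atoms: struc.AtomArray, chain: str) -> np.ndarray:
    lo, hi = M2_EXTRACELLULAR_SPAN
    mask = (
        (atoms.chain_id == chain)
        & (atoms.res_id >= lo)
        & (atoms.res_id <= hi)
        & (atoms.atom_name == "CA")
    )
    coords = atoms.coord[mask]
    if coords.shape[0] < hi - lo + 1:
        raise MissingAtomsError(
            f"chain {chain}: need CA atoms for residues {lo}-{hi}, found {coords.shape[0]}"
        )
    return coords.mean(axis=0)


@dataclass
class DistanceSeries:
    """Per-frame distances for the five non-adjacent subunit pairs."""

    pair_labels: tuple
    values: np.ndarray  # shape (n_frames, 5), Angstrom
    chains: tuple = ()

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.pair_labels) != 5 or self.values.shape[1] != 5:
            raise ValidationError("exactly five non-adjacent pairs expected")
        if np.any(self.values <= 0):
            raise ValidationError("distances must be positive")

    def pooled(self) -> np.ndarray:
        """All five distance series concatenated into one sample set."""
        return self.values.ravel()


def m2_pair_distances(
    frames: Union[struc.AtomArray, Sequence[struc.AtomArray]],
) -> DistanceSeries:
    """Distances between M2 extracellular-half centers, non-adjacent pairs.

    Accepts a single structure or a sequence of frames; pair labels are
    1-based positions around the pentagon ("1-3", ..., "3-5").
    """
    if isinstance(frames, struc.AtomArray):
        frames = [frames]
    frames = list(frames)
    if not frames:
        raise ValidationError("no frames supplied")
    order = chain_order(frames[0])
    if len(order) != 5:
        raise ValidationError("pentamer expected")
    values = np.empty((len(frames), 5))
    for t, frame in enumerate(frames):
        centers = np.array([_m2_center(frame, c) for c in order])
        for j, (a, b) in enumerate(NON_ADJACENT_PAIRS):
            values[t, j] = np.linalg.norm(centers[a - 1] - centers[b - 1])
    labels = tuple(f"{a}-{b}" for a, b in NON_ADJACENT_PAIRS)
    return DistanceSeries(pair_labels=labels, values=values, chains=tuple(order))


@dataclass
class FreeEnergyProfile1D:
    """Boltzmann-transformed histogram: minimum shifted to zero.

    Bins never visited are NaN (flagged undefined, not zero).
    """

    centers: np.ndarray
    values: np.ndarray  # kcal/mol, NaN where undefined
    bin_width: float

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.centers.shape != self.values.shape:
            raise ValidationError("centers and values must align")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


def boltzmann_profile(
    samples: np.ndarray,
    bin_width: float = 0.5,
    ctx: ThermoContext = ThermoContext(),
    bounds: Optional[tuple] = None,
) -> FreeEnergyProfile1D:
    """Free-energy profile ``-kT ln rho(d)`` from a 1-d sample set."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValidationError("no samples")
    if not bin_width > 0:
        raise ValidationError("bin_width must be positive")
    lo, hi = bounds if bounds is not None else (samples.min(), samples.max())
    n_bins = max(1, int(math.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(samples, bins=edges)
    density = counts / (samples.size * bin_width)
    values = np.full(n_bins, np.nan)
    occupied = counts > 0
    values[occupied] = -ctx.kt * np.log(density[occupied])
    values -= np.nanmin(values)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return FreeEnergyProfile1D(centers=centers, values=values, bin_width=bin_width)


@dataclass(frozen=True)
class RestraintSpec:
    """One-sided flat-bottom harmonic wall on a distance coordinate.

    Zero for ``d >= d0``; ``(k/2)(d - d0)^2`` for ``d < d0``.  The
    potential and its first derivative are continuous at the wall.
    """

    d0: float
    k: float
    target: str = "M2 non-adjacent pair distance"

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValidationError("force constant must be positive")

    def energy(self, d):
        d = np.asarray(d, dtype=float)
        out = np.where(d >= self.d0, 0.0, 0.5 * self.k * (d - self.d0) ** 2)
        return float(out) if out.ndim == 0 else out

    def force(self, d):
        """-dU/dd: pushes the coordinate back above the wall."""
        d = np.asarray(d, dtype=float)
        out = np.where(d >= self.d0, 0.0, self.k * (self.d0 - d))
        return float(out) if out.ndim == 0 else out


def design_flat_bottom_restraint(
    profile: FreeEnergyProfile1D,
    open_basin_center: float,
    k: float = 10.0,
    margin_kt: float = 1.0,
    ctx: ThermoContext = ThermoContext(),
) -> RestraintSpec:
    """Place a flat-bottom wall at the barrier-side edge of the open basin.

    The wall position ``d0`` is the largest distance below
    ``open_basin_center`` at which the profile rises ``margin_kt`` kT
    above the basin minimum, so the wall amplifies the existing barrier
    without biasing the interior of the basin.  Raises
    :class:`DesignError` (carrying the profile) when no such barrier
    exists below the basin.
    """
    defined = profile.defined
    if not defined.any():
        raise DesignError("empty profile", profile=profile)
    centers, values = profile.centers, profile.values
    i0 = int(np.nanargmin(np.where(defined, np.abs(centers - open_basin_center), np.inf)))
    if not defined[i0]:
        raise DesignError("no sampling near the open basin center", profile=profile)
    # discrete descent to the local minimum of the basin
    i_min = i0
    while i_min + 1 < len(values) and defined[i_min + 1] and values[i_min + 1] < values[i_min]:
        i_min += 1
    while i_min - 1 >= 0 and defined[i_min - 1] and values[i_min - 1] < values[i_min]:
        i_min -= 1
    threshold = values[i_min] + margin_kt * ctx.kt
    for i in range(i_min - 1, -1, -1):
        if not defined[i]:
            continue
        if values[i] >= threshold:
            # a true barrier descends again further down; a monotonic
            # rise is just the wall of a single well
            descends = any(
                defined[j] and values[j] < values[i] for j in range(i - 1, -1, -1)
            )
            if descends:
                return RestraintSpec(d0=float(centers[i]), k=k)
            break
    raise DesignError(
        f"no barrier rising {margin_kt} kT above the open basin was found "
        f"below {open_basin_center}",
        profile=profile,
    )


@dataclass
class DensityProfile:
    """Ligand number density along the pore axis.

    ``rho`` integrates to ``n_ligands`` over the sampled span, both in
    its raw form and after the three-bin running-average smoothing
    (``rho_raw`` keeps the unsmoothed histogram).
    """

    centers: np.ndarray
    rho: np.ndarray
    n_ligands: int
    bin_width: float
    rho_raw: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho_raw is None:
            self.rho_raw = self.rho.copy()
        self.rho_raw = np.asarray(self.rho_raw, dtype=float)


def smooth_three_bin(rho: np.ndarray) -> np.ndarray:
    """Mass-preserving three-bin running average.

    Each bin spreads its content equally over itself and its two
    neighbours; thirds that would leave the grid at the two edges stay
    in the edge bin, so the integral is conserved exactly.
    """
    rho = np.asarray(rho, dtype=float)
    if rho.size < 3:
        return rho.copy()
    out = np.convolve(rho, np.ones(3) / 3.0, mode="same")
    out[0] += rho[0] / 3.0
    out[-1] += rho[-1] / 3.0
    return out


def axial_density(
    ligand_z: np.ndarray,
    n_ligands: int,
    bin_width: float = 0.5,
    bounds: Optional[tuple] = None,
    smooth: bool = True,
) -> DensityProfile:
    """Number density of ligand centers of mass along the pore axis.

    ``rho(z) = n_ligands * P(z) / dz`` where ``P(z)`` is the pooled
    probability of observing a ligand center of mass in the bin at
    ``z``; optionally smoothed by the three-bin running average.
    """
    z = np.asarray(ligand_z, dtype=float).ravel()
    z = z[~np.isnan(z)]
    if z.size == 0:
        raise ValidationError("no ligand positions supplied")
    if n_ligands not in (1, 2):
        raise ValidationError(f"n_ligands must be 1 or 2, got {n_ligands}")
    if not bin_width > 0:
        raise ValidationError("bin_width must be positive")
    lo, hi = bounds if bounds is not None else (z.min(), z.max())
    n_bins = max(1, int(math.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    rho_raw = n_ligands * counts / (z.size * bin_width)
    rho = smooth_three_bin(rho_raw) if smooth else rho_raw.copy()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(
        centers=centers, rho=rho, n_ligands=n_ligands,
        bin_width=bin_width, rho_raw=rho_raw,
    )


def prime_index(residue: int) -> int:
    """M2 prime-notation index of a residue (232 -> 9', 239 -> 16')."""
    lo, hi = M2_SPAN
    if not lo <= residue <= hi:
        raise DomainError(f"residue {residue} outside the M2 span {lo}-{hi}")
    return residue - _PRIME_OFFSET


def residue_for_prime(prime: int) -> int:
    """Inverse of :func:`prime_index`."""
    residue = prime + _PRIME_OFFSET
    lo, hi = M2_SPAN
    if not lo <= residue <= hi:
        raise DomainError(f"prime index {prime}' outside the M2 span")
    return residue


@dataclass(frozen=True)
class SiteDefinition:
    """Axial interval of a pore binding site.

    ``prime_interval`` records the M2 prime positions bounding the
    site; ``z_interval`` is the corresponding axial range (Angstrom)
    derived from a particular structure.
    """

    label: str
    prime_interval: tuple
    z_interval: tuple

    def __post_init__(self) -> None:
        if not self.z_interval[0] < self.z_interval[1]:
            raise ValidationError("z_interval must be ordered (low, high)")


#: Prime-notation bounds of the pore binding sites.
PORE_SITE_PRIMES = {
    "secondary_lower": (6, 9),
    "primary": (9, 16),
    "secondary_upper": (16, 20),
}


def sites_from_structure(atoms: struc.AtomArray) -> list:
    """Site z-intervals derived from the anchor residues of a structure.

    For each prime bound, the axial coordinate is the chain-averaged
    Calpha position of the corresponding residue, projected on the pore
    axis with the pore center as origin.
    """
    center = pore_center(atoms)
    axis = pore_axis(atoms)
    chains = _chains(atoms)

    def z_of(prime: int) -> float:
        res = residue_for_prime(prime)
        coords = np.array([_ca_coords(atoms, c, res) for c in chains])
        return float(np.dot(coords.mean(axis=0) - center, axis))

    sites = []
    for label, (p_lo, p_hi) in PORE_SITE_PRIMES.items():
        z_lo, z_hi = sorted((z_of(p_lo), z_of(p_hi)))
        sites.append(SiteDefinition(label, (p_lo, p_hi), (z_lo, z_hi)))
    return sites


def _check_disjoint(sites: Sequence[SiteDefinition]) -> None:
    intervals = sorted(s.z_interval for s in sites)
    for (a_lo, a_hi), (b_lo, b_hi) in zip(intervals[:-1], intervals[1:]):
        if b_lo < a_hi - 1e-9:
            raise ValidationError("site z-intervals overlap")


def site_occupancy(
    data: Union[np.ndarray, DensityProfile],
    sites: Sequence[SiteDefinition],
    n_ligands: Optional[int] = None,
) -> dict:
    """Expected ligand count per site.

    From raw axial samples: sample fraction inside each interval times
    ``n_ligands``.  From a :class:`DensityProfile`: integral of the raw
    (unsmoothed) density over the interval, with fractional bin overlap
    at the interval edges.
    """
    _check_disjoint(sites)
    if isinstance(data, DensityProfile):
        dz = data.bin_width
        lo_edges = data.centers - dz / 2
        hi_edges = data.centers + dz / 2
        out = {}
        for s in sites:
            overlap = np.clip(
                np.minimum(hi_edges, s.z_interval[1]) - np.maximum(lo_edges, s.z_interval[0]),
                0.0, dz,
            )
            out[s.label] = float(np.sum(data.rho_raw * overlap))
        return out
    z = np.asarray(data, dtype=float).ravel()
    if n_ligands is None:
        raise ValidationError("n_ligands required for raw-sample occupancy")
    out = {}
    for s in sites:
        frac = np.mean((z >= s.z_interval[0]) & (z < s.z_interval[1]))
        out[s.label] = float(n_ligands * frac)
    return out


def project_on_axis(
    coords: np.ndarray, origin: np.ndarray, axis: np.ndarray
) -> np.ndarray:
    """Axial coordinates of points relative to an origin."""
    coords = np.asarray(coords, dtype=float)
    return (coords - np.asarray(origin)) @ np.asarray(axis)


def ligand_axial_positions(
    com_xyz: np.ndarray, atoms: struc.AtomArray
) -> np.ndarray:
    """Project ligand center-of-mass coordinates onto a structure's pore axis."""
    return project_on_axis(com_xyz, pore_center(atoms), pore_axis(atoms))
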