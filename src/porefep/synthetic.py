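"""Seeded generators for every input class the analysis consumes.

Each generator has a known ground truth so the estimators can be
validated by recovery:

* FEP window samples are Gaussian work distributions obeying the
  Crooks fluctuation relation, the condition under which forward and
  backward exponential averages (and hence BAR) converge to the same
  window free energy;
* pore trajectories are Metropolis samples of a 1-d multi-well
  potential between hard walls, emulating an anesthetic hopping among
  axial binding sites;
* M2 pair-distance series are Gaussian mixtures emulating the bimodal
  open/collapsed pore statistics;
* dose-response curves are exact pore-block model curves plus clipped
  Gaussian noise;
* a geometric pentamer of Calpha-only M2 helices supports the
  structural operations with hand-computable coordinates.

All generators draw from ``numpy.random.default_rng(seed)`` and are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import biotite.structure as struc

from .exceptions import ValidationError
from .fep import LambdaSchedule, WindowSamples, make_lambda_schedule
from .poreblock import DoseResponse, PoreBlockParams, ic50_exact, inhibition
from .thermo import ThermoContext


# ---------------------------------------------------------------------------
# FEP work samples

@dataclass
class FepGroundTruth:
    """True per-window free energies behind a synthetic FEP data set."""

    window_delta_g: np.ndarray     # kcal/mol, one entry per window
    sigma: float                   # work stddev per window, kcal/mol
    n_samples: int                 # per direction per window
    seed: int = 0
    schedule: Optional[LambdaSchedule] = None

    def __post_init__(self) -> None:
        self.window_delta_g = np.asarray(self.window_delta_g, dtype=float)
        if not self.sigma > 0:
            raise ValidationError("sigma must be positive")
        if self.schedule is not None and self.schedule.n_windows != self.window_delta_g.size:
            raise ValidationError("window_delta_g must align with the schedule")

    @property
    def total_delta_g(self) -> float:
        return float(self.window_delta_g.sum())

    @classmethod
    def from_total(
        cls,
        total_delta_g: float,
        schedule: Optional[LambdaSchedule] = None,
        sigma: float = 1.0,
        n_samples: int = 5000,
        seed: int = 0,
    ) -> "FepGroundTruth":
        """Distribute a total dG over a schedule, linearly in lambda."""
        if schedule is None:
            schedule = make_lambda_schedule()
        widths = np.diff(np.asarray(schedule.values))
        return cls(
            window_delta_g=total_delta_g * widths / widths.sum(),
            sigma=sigma,
            n_samples=n_samples,
            seed=seed,
            schedule=schedule,
        )


def gen_fep_samples(
    truth: FepGroundTruth, ctx: ThermoContext = ThermoContext()
) -> list:
    """Crooks-consistent Gaussian work samples for every window.

    For a window with free energy dG and work stddev sigma, forward
    samples are N(dG + sigma^2/2kT, sigma^2) and backward samples
    N(dG - sigma^2/2kT, sigma^2): the two Gaussians satisfy the Crooks
    relation, and each direction's exponential average converges to dG.
    """
    rng = np.random.default_rng(truth.seed)
    dissipation = truth.sigma**2 / (2.0 * ctx.kt)
    schedule = truth.schedule if truth.schedule is not None else make_lambda_schedule()
    if schedule.n_windows != truth.window_delta_g.size:
        raise ValidationError("truth does not align with its schedule")
    windows = []
    for (lam_lo, lam_hi), dg in zip(schedule.windows(), truth.window_delta_g):
        fwd = rng.normal(dg + dissipation, truth.sigma, truth.n_samples)
        bwd = rng.normal(dg - dissipation, truth.sigma, truth.n_samples)
        windows.append(
            WindowSamples(
                lambda_low=lam_lo, lambda_high=lam_hi,
                forward_du=fwd, backward_du=bwd,
            )
        )
    return windows


# ---------------------------------------------------------------------------
# Pore toy model

@dataclass
class PoreToyModel:
    """1-d multi-well potential emulating axial anesthetic binding sites.

    ``U(z) = -sum_i depth_i exp(-(z - center_i)^2 / (2 width_i^2))``
    between hard walls at ``z_bounds``; two ligands may repel through a
    soft Gaussian core of height ``repulsion_strength`` and range
    ``repulsion_range``.
    """

    site_centers: Sequence[float]
    well_depths: Sequence[float]          # kcal/mol, positive = attractive
    well_widths: Sequence[float]          # Angstrom
    n_ligands: int = 1
    n_frames: int = 20000
    seed: int = 0
    z_bounds: tuple = (-15.0, 15.0)
    repulsion_strength: float = 0.0       # kcal/mol
    repulsion_range: float = 2.0          # Angstrom

    def __post_init__(self) -> None:
        if self.n_ligands not in (1, 2):
            raise ValidationError("n_ligands must be 1 or 2")
        lo, hi = self.z_bounds
        for c in self.site_centers:
            if not lo < c < hi:
                raise ValidationError("well centers must lie inside the pore span")

    def potential(self, z):
        z = np.asarray(z, dtype=float)
        u = np.zeros_like(z)
        for c, d, w in zip(self.site_centers, self.well_depths, self.well_widths):
            u -= d * np.exp(-((z - c) ** 2) / (2.0 * w * w))
        return u


def gen_pore_trajectory(
    model: PoreToyModel, ctx: ThermoContext = ThermoContext()
) -> np.ndarray:
    """Metropolis samples of the toy-pore Boltzmann distribution.

    Returns an array of shape ``(n_frames, n_ligands)`` of axial
    positions.  Proposals mix local displacements (80%) with global
    uniform jumps (20%) so hopping between wells mixes quickly; the
    local step is auto-tuned to 30-50% acceptance during a burn-in of
    10% of ``n_frames``, which is discarded.
    """
    rng = np.random.default_rng(model.seed)
    kt = ctx.kt
    lo, hi = model.z_bounds
    n_lig = model.n_ligands

    def energy(z: np.ndarray) -> float:
        u = float(model.potential(z).sum())
        if n_lig == 2 and model.repulsion_strength > 0:
            dz = z[0] - z[1]
            u += model.repulsion_strength * math.exp(
                -(dz * dz) / (2.0 * model.repulsion_range**2)
            )
        return u

    z = rng.uniform(lo, hi, n_lig)
    u = energy(z)
    step = 1.0
    n_burn = max(100, model.n_frames // 10)
    accepted = attempted = 0
    frames = np.empty((model.n_frames, n_lig))
    for it in range(n_burn + model.n_frames):
        for i in range(n_lig):
            if rng.random() < 0.2:
                z_new = rng.uniform(lo, hi)
            else:
                z_new = z[i] + rng.uniform(-step, step)
                if not lo <= z_new <= hi:
                    attempted += 1
                    continue
            trial = z.copy()
            trial[i] = z_new
            u_new = energy(trial)
            attempted += 1
            if u_new <= u or rng.random() < math.exp(-(u_new - u) / kt):
                z, u = trial, u_new
                accepted += 1
        if it < n_burn:
            if attempted >= 100:
                rate = accepted / attempted
                if rate > 0.5:
                    step *= 1.1
                elif rate < 0.3:
                    step *= 0.9
                accepted = attempted = 0
        else:
            frames[it - n_burn] = z
    return frames


# ---------------------------------------------------------------------------
# M2 distance series

def gen_distance_series(
    open_center: float = 20.0,
    collapsed_center: float = 18.5,
    weights: Sequence[float] = (0.3, 0.7),
    sigmas: Sequence[float] = (0.3, 0.3),
    n: int = 100000,
    seed: int = 0,
) -> np.ndarray:
    """Gaussian-mixture samples of an M2 pair distance.

    Emulates the bimodal statistics of an unrestrained pore: a
    metastable open basin (default 20 A) and a collapsed state below
    19 A, with the collapsed state the larger population.
    """
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9 or np.any(weights < 0):
        raise ValidationError("weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    centers = np.array([open_center, collapsed_center])
    sigmas = np.asarray(sigmas, dtype=float)
    component = rng.choice(len(weights), size=n, p=weights)
    return rng.normal(centers[component], sigmas[component])


# ---------------------------------------------------------------------------
# Dose-response curves

def gen_dose_response(
    params: PoreBlockParams,
    n_points: int = 12,
    conc_range: Optional[tuple] = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DoseResponse:
    """Pore-block model curve on a log-spaced grid with clipped noise.

    The default concentration span covers two decades either side of
    the model IC50 (which must lie inside any explicit span).  Additive
    Gaussian noise of width ``noise_sigma`` is clipped to [0, 1].
    """
    ic50 = ic50_exact(params)
    if conc_range is None:
        conc_range = (ic50 / 100.0, ic50 * 100.0)
    lo, hi = conc_range
    if not lo < ic50 < hi:
        raise ValidationError("concentration span must cover the model IC50")
    conc = np.geomspace(lo, hi, n_points)
    y = inhibition(params, conc)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0.0, noise_sigma, n_points), 0.0, 1.0)
    return DoseResponse(concentrations=conc, inhibition=y)


# ---------------------------------------------------------------------------
# Pentameric Calpha structure

def gen_pentamer_structure(
    radius: float = 15.0,
    rise: float = 1.5,
    res_range: tuple = (222, 246),
    collapse_chain: Optional[str] = None,
    collapse_by: float = 0.0,
) -> struc.AtomArray:
    """Calpha-only pentamer of straight M2-like helices.

    Five chains A-E sit at the vertices of a regular pentagon of
    circumradius ``radius`` (A), each carrying one Calpha per residue
    of ``res_range`` stacked vertically with ``rise`` A per residue
    (residue 234 at z = 0).  With exact C5 symmetry the pore center
    falls on the axis, giving hand-computable oracles.  Optionally one
    chain is displaced radially inward by ``collapse_by`` A to emulate
    asymmetric pore collapse.
    """
    chains = ["A", "B", "C", "D", "E"]
    res_ids = list(range(res_range[0], res_range[1] + 1))
    n = len(chains) * len(res_ids)
    atoms = struc.AtomArray(n)
    names = {226: "TYR", 244: "TYR", 232: "ILE", 239: "ILE", 245: "LEU"}
    coords = np.empty((n, 3))
    chain_id = []
    res_id = []
    res_name = []
    idx = 0
    for k, ch in enumerate(chains):
        angle = math.pi / 2 + 2.0 * math.pi * k / 5.0
        r = radius
        if ch == collapse_chain:
            r -= collapse_by
        x, y = r * math.cos(angle), r * math.sin(angle)
        for res in res_ids:
            coords[idx] = (x, y, (res - 234) * rise)
            chain_id.append(ch)
            res_id.append(res)
            res_name.append(names.get(res, "ALA"))
            idx += 1
    atoms.coord = coords
    atoms.chain_id = np.array(chain_id)
    atoms.res_id = np.array(res_id)
    atoms.res_name = np.array(res_name)
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    return atoms
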