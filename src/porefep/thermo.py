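"""Standard-state bookkeeping for absolute binding free energies.

Alchemical decoupling simulations yield the free energy of inserting a
ligand from vacuum into a restrained binding site.  Turning that number
into a binding free energy (and hence a dissociation constant) requires
three corrections:

* the solvation free energy of the ligand (vacuum -> bulk solution),
  which must be subtracted because binding proceeds from solution;
* the entropic cost of confining the ligand to the restraint volume
  relative to the free volume it would have in a 1 M standard-state
  solution (1661 A^3 per molecule);
* a symmetry penalty ``+kT ln(sigma)`` for a ligand whose symmetry
  number ``sigma`` exceeds one, reflecting the loss of indistinguishable
  orientations upon binding.

The resulting total, ``dG_bind = dG_insert - dG_solv + dG_V + dG_sym``,
maps to a dissociation constant through ``Kd = (1 M) exp(dG_bind / kT)``.

Double occupancy is handled identically: ``dG_bind,2`` uses the
insertion free energy into a singly occupied site and yields the
stepwise constant ``Kd2`` for binding of the second ligand.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

from .exceptions import DomainError, ValidationError

#: Boltzmann constant in kcal/(mol K).
KB_KCAL = 1.9872e-3

#: Free volume per molecule of a 1 M ideal solution, in A^3.
STANDARD_STATE_VOLUME = 1661.0


@dataclass(frozen=True)
class ThermoContext:
    """Thermodynamic constants shared across the package.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin.  Defaults to 300 K, the
        thermostat temperature of the simulations the analysis targets.
    boltzmann_constant : float
        In kcal/(mol K).
    standard_volume : float
        Volume per molecule of a 1 M solution, in A^3.
    """

    temperature: float = 300.0
    boltzmann_constant: float = KB_KCAL
    standard_volume: float = STANDARD_STATE_VOLUME

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise DomainError(f"temperature must be > 0 K, got {self.temperature}")
        if not self.boltzmann_constant > 0:
            raise DomainError("boltzmann_constant must be positive")
        if not self.standard_volume > 0:
            raise DomainError("standard_volume must be positive")

    @property
    def kt(self) -> float:
        """Thermal energy kT in kcal/mol."""
        return self.boltzmann_constant * self.temperature


@dataclass(frozen=True)
class FreeEnergyComponents:
    """Per-ligand, per-site terms entering a binding free energy.

    All values in kcal/mol.  ``site_insertion_1`` is the free energy of
    moving the ligand from vacuum into the unoccupied, restrained site;
    ``site_insertion_2`` (optional) into a site already holding one
    ligand.  Correction terms carry no printed uncertainty and are
    treated as exact.
    """

    solvation: float
    symmetry: float
    restraint_volume: float
    site_insertion_1: float
    site_insertion_1_err: float = 0.0
    site_insertion_2: Optional[float] = None
    site_insertion_2_err: Optional[float] = None

    def __post_init__(self) -> None:
        if self.site_insertion_1_err < 0:
            raise ValidationError("site_insertion_1_err must be >= 0")
        if self.site_insertion_2_err is not None and self.site_insertion_2_err < 0:
            raise ValidationError("site_insertion_2_err must be >= 0")
        if self.site_insertion_2_err is not None and self.site_insertion_2 is None:
            raise ValidationError("site_insertion_2_err given without site_insertion_2")


@dataclass(frozen=True)
class BindingResult:
    """Binding free energies and the dissociation constants they imply.

    Free energies in kcal/mol; dissociation constants in molar.
    Second-occupancy fields are ``None`` for single-occupancy results.
    """

    delta_g_bind_1: float
    stderr_1: float
    kd1: float
    delta_g_bind_2: Optional[float] = None
    stderr_2: Optional[float] = None
    kd2: Optional[float] = None
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.kd1 > 0:
            raise ValidationError("kd1 must be positive")
        if self.kd2 is not None and not self.kd2 > 0:
            raise ValidationError("kd2 must be positive")

    def to_json(self, **extra_provenance) -> str:
        """Serialize to JSON, including component provenance."""
        payload = {
            "delta_g_bind_1_kcal_mol": self.delta_g_bind_1,
            "stderr_1_kcal_mol": self.stderr_1,
            "kd1_M": self.kd1,
            "kd1_display": format_concentration(self.kd1),
        }
        if self.delta_g_bind_2 is not None:
            payload.update(
                {
                    "delta_g_bind_2_kcal_mol": self.delta_g_bind_2,
                    "stderr_2_kcal_mol": self.stderr_2,
                    "kd2_M": self.kd2,
                    "kd2_display": format_concentration(self.kd2),
                }
            )
        prov = dict(self.provenance)
        prov.update(extra_provenance)
        if prov:
            payload["provenance"] = prov
        return json.dumps(payload, indent=2)


def restraint_volume_term(site_volume: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Entropic cost of confinement relative to the standard state.

    ``-kT ln(V_site / V_0)`` with ``V_0`` = 1661 A^3 (1 M).  Negative
    (favourable bookkeeping term) when the restraint volume exceeds the
    standard-state free volume, as for a pore-spanning cylinder.

    Parameters
    ----------
    site_volume : float
        Volume enclosed by the flat-bottom restraint, in A^3.
    """
    if not site_volume > 0:
        raise DomainError(f"site_volume must be > 0 A^3, got {site_volume}")
    return -ctx.kt * math.log(site_volume / ctx.standard_volume)


def symmetry_term(sigma_ligand: int, ctx: ThermoContext = ThermoContext()) -> float:
    """Penalty ``+kT ln(sigma)`` for loss of ligand symmetry upon binding.

    ``sigma`` is the symmetry number of the free ligand: 1 for
    isoflurane, 2 for propofol or ethanol (C2-symmetric frameworks).
    At 300 K, sigma = 2 contributes 0.41 kcal/mol, i.e. a factor of two
    in affinity.
    """
    if not float(sigma_ligand).is_integer() or sigma_ligand < 1:
        raise DomainError(f"symmetry number must be an integer >= 1, got {sigma_ligand}")
    return ctx.kt * math.log(sigma_ligand)


def kd_from_free_energy(delta_g: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Dissociation constant (molar) for a binding free energy.

    ``Kd = (1 M) exp(dG_bind / kT)``; strictly increasing in ``delta_g``.
    """
    if not math.isfinite(delta_g):
        raise DomainError("delta_g must be finite")
    return math.exp(delta_g / ctx.kt)


def free_energy_from_kd(kd: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Inverse of :func:`kd_from_free_energy`; ``kd`` in molar."""
    if not kd > 0:
        raise DomainError(f"kd must be > 0 M, got {kd}")
    return ctx.kt * math.log(kd)


def combine_binding_free_energy(
    components: FreeEnergyComponents, ctx: ThermoContext = ThermoContext()
) -> BindingResult:
    """Assemble total binding free energies and dissociation constants.

    ``dG_bind,n = dG_insert,n - dG_solv + dG_V + dG_sym`` (insertion
    measured from vacuum).  Uncertainties of the correction terms are
    not propagated (treated as exact); the stderr of each total equals
    the stderr of its insertion term.
    """
    corrections = (
        -components.solvation + components.restraint_volume + components.symmetry
    )
    dg1 = components.site_insertion_1 + corrections
    result = {
        "delta_g_bind_1": dg1,
        "stderr_1": components.site_insertion_1_err,
        "kd1": kd_from_free_energy(dg1, ctx),
    }
    if components.site_insertion_2 is not None:
        dg2 = components.site_insertion_2 + corrections
        result.update(
            delta_g_bind_2=dg2,
            stderr_2=components.site_insertion_2_err or 0.0,
            kd2=kd_from_free_energy(dg2, ctx),
        )
    provenance = {
        "solvation_kcal_mol": components.solvation,
        "symmetry_kcal_mol": components.symmetry,
        "restraint_volume_kcal_mol": components.restraint_volume,
        "site_insertion_1_kcal_mol": components.site_insertion_1,
        "site_insertion_2_kcal_mol": components.site_insertion_2,
        "temperature_K": ctx.temperature,
        "sign_convention": "dG_bind = dG_insert - dG_solv + dG_V + dG_sym",
    }
    return BindingResult(provenance=provenance, **result)


def cooperativity(kd1: float, kd2: float, tolerance: float = 0.5) -> str:
    """Classify stepwise binding as negative/positive/non-cooperative.

    ``kd2 > kd1 (1 + tolerance)`` -> "negative" (second ligand binds
    more weakly); ``kd2 < kd1 / (1 + tolerance)`` -> "positive";
    otherwise "non-cooperative".  ``tolerance`` is a relative dead band.
    """
    if not (kd1 > 0 and kd2 > 0):
        raise DomainError("dissociation constants must be positive")
    if kd2 > kd1 * (1.0 + tolerance):
        return "negative"
    if kd2 < kd1 / (1.0 + tolerance):
        return "positive"
    return "non-cooperative"


def format_concentration(molar: float) -> str:
    """Render a molar concentration with an auto-scaled unit.

    Chooses among M, mM, uM, nM so the mantissa lies in [1, 1000) where
    possible; values are stored in molar throughout the package.
    """
    if not molar > 0:
        raise DomainError("concentration must be positive")
    for factor, unit in ((1.0, "M"), (1e-3, "mM"), (1e-6, "uM"), (1e-9, "nM")):
        if molar >= factor:
            return f"{molar / factor:.3g} {unit}"
    return f"{molar / 1e-9:.3g} nM"
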