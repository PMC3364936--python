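"""Two-site Adair model of ion-channel pore block.

A channel pore can hold up to two anesthetic molecules, binding
sequentially with stepwise dissociation constants ``Kd1`` (first
ligand, empty pore) and ``Kd2`` (second ligand, singly occupied pore).
At free anesthetic concentration ``x`` the occupancy probabilities are

    Z  = 1 + x/Kd1 + x^2/(Kd1 Kd2)
    p0 = 1/Z,  p1 = (x/Kd1)/Z,  p2 = (x^2/(Kd1 Kd2))/Z.

A doubly occupied pore is always blocked; a single bound molecule may
be too mobile or too small to occlude the pore, so it blocks with
probability ``alpha`` in [0, 1].  Fractional inhibition is then

    I(x) = alpha * p1 + p2,

a modified Adair form.  The half-inhibition concentration (IC50) has
closed-form radicals at the extremes of ``alpha``:

    alpha = 1:  positive root of x^2 + Kd2 x - Kd1 Kd2 = 0
    alpha = 0:  positive root of x^2 - Kd2 x - Kd1 Kd2 = 0

and the pair (alpha=1 root, alpha=0 root) brackets the predicted IC50
range.  The model is scale-invariant: concentrations and both constants
may be carried in any single unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DomainError, FitError, ValidationError


@dataclass(frozen=True)
class PoreBlockParams:
    """Microscopic parameters of the pore-block model.

    ``kd1``/``kd2`` are stepwise dissociation constants in the unit of
    the dose axis; ``alpha`` is the monomer block probability.
    """

    kd1: float
    kd2: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (self.kd1 > 0 and self.kd2 > 0):
            raise DomainError("dissociation constants must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise DomainError(f"alpha must lie in [0, 1], got {self.alpha}")


@dataclass(frozen=True)
class OccupancyDistribution:
    """Probabilities of 0, 1 and 2 ligands bound."""

    p0: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        for p in (self.p0, self.p1, self.p2):
            if not -1e-12 <= p <= 1.0 + 1e-12:
                raise ValidationError("occupancy probabilities must lie in [0, 1]")
        if abs(self.p0 + self.p1 + self.p2 - 1.0) > 1e-12:
            raise ValidationError("occupancy probabilities must sum to 1")


@dataclass
class DoseResponse:
    """Concentration / fractional-inhibition pairs (one curve)."""

    concentrations: np.ndarray
    inhibition: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        if self.concentrations.shape != self.inhibition.shape:
            raise ValidationError("concentrations and inhibition must have equal length")
        if self.concentrations.ndim != 1:
            raise ValidationError("dose-response data must be one-dimensional")
        if np.any(self.concentrations <= 0) or np.any(np.diff(self.concentrations) <= 0):
            raise ValidationError("concentrations must be positive and strictly increasing")
        if np.any(self.inhibition < 0) or np.any(self.inhibition > 1):
            raise ValidationError("inhibition values must lie in [0, 1]")


def _species_fractions(params: PoreBlockParams, conc):
    x = np.asarray(conc, dtype=float)
    if np.any(x < 0):
        raise DomainError("concentration must be >= 0")
    a = x / params.kd1
    b = x * x / (params.kd1 * params.kd2)
    z = 1.0 + a + b
    return 1.0 / z, a / z, b / z


def occupancy(params: PoreBlockParams, conc: float) -> OccupancyDistribution:
    """Occupancy probabilities (p0, p1, p2) at one concentration."""
    p0, p1, p2 = _species_fractions(params, conc)
    return OccupancyDistribution(float(p0), float(p1), float(p2))


def inhibition(params: PoreBlockParams, conc):
    """Fractional inhibition ``alpha p1 + p2``; scalar or array ``conc``."""
    _, p1, p2 = _species_fractions(params, conc)
    out = params.alpha * p1 + p2
    return float(out) if np.isscalar(conc) else out


def ic50_closed_form(params: PoreBlockParams) -> float:
    """Closed-form IC50 at the ``alpha`` extremes.

    Valid only for ``alpha`` exactly 0 or 1; other values require
    :func:`ic50_exact`.
    """
    k1, k2 = params.kd1, params.kd2
    disc = math.sqrt(k2 * k2 + 4.0 * k1 * k2)
    if params.alpha == 1.0:
        return 0.5 * (-k2 + disc)
    if params.alpha == 0.0:
        return 0.5 * (k2 + disc)
    raise ValidationError(
        f"closed form requires alpha in {{0, 1}}, got {params.alpha}; use ic50_exact"
    )


def ic50_exact(params: PoreBlockParams, tol: float = 1e-12) -> float:
    """IC50 for any ``alpha``: the unique root of ``I(x) = 1/2``.

    Inhibition rises continuously from 0 to 1, so a root always exists;
    it is bracketed by geometric growth (factor 10) from a tiny lower
    bound and refined with Brent's method to relative tolerance ``tol``.
    """
    lo = 1e-12 * params.kd1
    hi = params.kd1
    while inhibition(params, hi) <= 0.5:
        hi *= 10.0
        if hi > 1e30 * params.kd1:  # pragma: no cover - unreachable for valid params
            raise DomainError("failed to bracket the half-inhibition point")
    return brentq(lambda x: inhibition(params, x) - 0.5, lo, hi, rtol=tol)


def ic50_range(kd1: float, kd2: float) -> Tuple[float, float]:
    """Predicted IC50 range over ``alpha`` in [0, 1].

    Returns ``(low, high)`` = (IC50 at alpha=1, IC50 at alpha=0);
    inhibition increases with ``alpha``, so the alpha=1 bound is the
    lower one.
    """
    low = ic50_closed_form(PoreBlockParams(kd1, kd2, alpha=1.0))
    high = ic50_closed_form(PoreBlockParams(kd1, kd2, alpha=0.0))
    return low, high


class PoreBlockModel(BaseEstimator, RegressorMixin):
    """Least-squares fit of the two-site pore-block model to a curve.

    scikit-learn style estimator: ``X`` is the concentration axis
    (1-d array or single-column 2-d), ``y`` the observed fractional
    inhibition.  The fit minimizes the unweighted sum of squared
    residuals over ``(log10 Kd1, log10 Kd2, alpha)`` from a
    deterministic multistart grid anchored at the observed
    half-inhibition concentration.

    Parameters
    ----------
    fix_alpha : float or None
        Pin the monomer block probability instead of fitting it.
    kd_bounds : (float, float) or None
        Absolute bounds on both dissociation constants; by default
        six decades either side of the observed half-inhibition point.
    random_state : int
        Kept for API symmetry; the start grid is deterministic.

    Attributes
    ----------
    kd1_, kd2_, alpha_ : float
        Fitted parameters.
    params_ : PoreBlockParams
    residual_norm_ : float
        Euclidean norm of the residual vector at the solution.
    converged_ : bool
    """

    def __init__(self, fix_alpha: Optional[float] = None,
                 kd_bounds: Optional[Tuple[float, float]] = None,
                 random_state: int = 0):
        self.fix_alpha = fix_alpha
        self.kd_bounds = kd_bounds
        self.random_state = random_state

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        y = np.asarray(y, dtype=float)
        data = DoseResponse(x, y)  # validates
        x, y = data.concentrations, data.inhibition
        if x.size < 4:
            raise FitError("need at least 4 dose-response points")
        if np.all(y < 0.05) or np.all(y > 0.95):
            raise FitError("degenerate curve: inhibition never crosses its dynamic range")
        if self.fix_alpha is not None and not 0.0 <= self.fix_alpha <= 1.0:
            raise ValidationError("fix_alpha must lie in [0, 1]")

        x50 = self._half_point(x, y)
        if self.kd_bounds is not None:
            kd_lo, kd_hi = self.kd_bounds
            if not 0 < kd_lo < kd_hi:
                raise ValidationError("kd_bounds must be positive and ordered")
        else:
            kd_lo, kd_hi = x50 * 1e-6, x50 * 1e6
        log_lo, log_hi = math.log10(kd_lo), math.log10(kd_hi)

        free_alpha = self.fix_alpha is None

        def residuals(theta):
            kd1, kd2 = 10.0 ** theta[0], 10.0 ** theta[1]
            alpha = theta[2] if free_alpha else self.fix_alpha
            p = PoreBlockParams(kd1, kd2, min(max(alpha, 0.0), 1.0))
            return inhibition(p, x) - y

        starts = []
        for f1, f2, a0 in [
            (1.0, 2.0, 0.9), (1.0 / 3.0, 3.0, 0.95), (3.0, 30.0, 0.5),
            (1.0, 100.0, 0.99), (0.1, 1.0, 0.2), (1.0, 10.0, 0.05),
        ]:
            k1 = min(max(x50 * f1, kd_lo * 1.01), kd_hi * 0.99)
            k2 = min(max(x50 * f2, kd_lo * 1.01), kd_hi * 0.99)
            theta0 = [math.log10(k1), math.log10(k2)]
            if free_alpha:
                theta0.append(a0)
            starts.append(theta0)

        bounds_lo = [log_lo, log_lo] + ([0.0] if free_alpha else [])
        bounds_hi = [log_hi, log_hi] + ([1.0] if free_alpha else [])

        best = None
        for theta0 in starts:
            res = least_squares(residuals, theta0, bounds=(bounds_lo, bounds_hi),
                                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
            if best is None or res.cost < best.cost:
                best = res
        if best is None:  # pragma: no cover
            raise FitError("all fit starts failed")

        self.kd1_ = 10.0 ** best.x[0]
        self.kd2_ = 10.0 ** best.x[1]
        self.alpha_ = float(best.x[2]) if free_alpha else float(self.fix_alpha)
        self.params_ = PoreBlockParams(self.kd1_, self.kd2_, self.alpha_)
        self.residual_norm_ = float(np.linalg.norm(best.fun))
        self.converged_ = bool(best.status > 0)
        self.n_features_in_ = 1
        return self

    @staticmethod
    def _half_point(x: np.ndarray, y: np.ndarray) -> float:
        """Log-interpolated concentration where the curve crosses 1/2."""
        above = np.nonzero(y >= 0.5)[0]
        if above.size == 0 or above[0] == 0:
            return float(x[len(x) // 2])
        j = above[0]
        x0, x1 = math.log(x[j - 1]), math.log(x[j])
        y0, y1 = y[j - 1], y[j]
        t = (0.5 - y0) / (y1 - y0) if y1 != y0 else 0.5
        return math.exp(x0 + t * (x1 - x0))

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        return inhibition(self.params_, x)


def fit_dose_response(
    data: DoseResponse,
    fix_alpha: Optional[float] = None,
    bounds: Optional[Tuple[float, float]] = None,
    seed: int = 0,
):
    """Functional wrapper around :class:`PoreBlockModel`.

    Returns ``(PoreBlockParams, diagnostics)`` where the diagnostics
    dict carries ``residual_norm`` and ``converged``.
    """
    model = PoreBlockModel(fix_alpha=fix_alpha, kd_bounds=bounds, random_state=seed)
    model.fit(data.concentrations, data.inhibition)
    return model.params_, {
        "residual_norm": model.residual_norm_,
        "converged": model.converged_,
    }
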