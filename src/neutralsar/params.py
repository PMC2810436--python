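"""Parameter set and unit conventions for the spatial neutral community model.

The model describes individuals that die at per-capita rate ``d``, give birth
at per-capita rate ``b`` (offspring displaced by a dispersal kernel), and new
species that appear as single founding individuals -- "point speciation" -- as
a spatial Poisson process.  The stationary community is controlled by three
parameters:

``alpha``
    ``d/b - 1 > 0``, the small excess of death over birth.  It plays the role
    of a per-capita speciation rate: each lineage is subcritical and its loss
    is balanced by the appearance of new species.
``sigma``
    The dispersal length scale.  Convention used throughout this package:
    ``sigma**2`` is the diffusion coefficient of the dispersal process, i.e.
    an isotropic Gaussian kernel has per-axis variance ``2 * sigma**2``.  With
    this convention the conspecific correlation length is ``sigma/sqrt(alpha)``
    and the species-area curve becomes exactly linear for areas beyond
    ``sigma**2/alpha``.
``theta_s``
    The fundamental diversity parameter *per unit area*: new species arise at
    areal rate ``theta_s * b``.  The stationary density of individuals is
    ``theta_s / alpha``.

Time units default to ``b = 1``; every equilibrium quantity depends on ``b``
and ``d`` only through ``alpha``.

The discrete (lattice) formulation carries three more bookkeeping quantities
(per-birth speciation probability ``nu``, landscape species pool ``S_tot`` and
the dimensionless diversity number ``theta = S_tot * nu * P0 / b``); they are
stored for documentation of the lattice-to-continuum story but the continuum
operations are parametrized by ``theta_s`` alone.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "NeutralParams",
    "SampleRegion",
    "TransformPoint",
    "make_params",
    "read_config",
    "write_config",
]

_REL_TOL = 1e-12


class ParameterError(ValueError):
    """A parameter violates its domain (named field in the message)."""


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise ParameterError(f"{name} must be strictly positive and finite, got {value!r}")
    return value


@dataclass(frozen=True)
class NeutralParams:
    """Validated parameter set of the neutral birth-death-dispersal model.

    Construct via :func:`make_params`, or directly; invariants are enforced in
    ``__post_init__``.
    """

    alpha: float
    sigma: float
    theta_s: float
    b: float = 1.0
    d: Optional[float] = None
    # Discrete/lattice narrative fields (not used by continuum operations).
    nu: Optional[float] = None
    S_tot: Optional[float] = None
    theta: Optional[float] = None

    def __post_init__(self) -> None:
        _require_positive("alpha", self.alpha)
        _require_positive("sigma", self.sigma)
        _require_positive("theta_s", self.theta_s)
        _require_positive("b", self.b)
        if self.d is None:
            object.__setattr__(self, "d", self.b * (1.0 + self.alpha))
        else:
            _require_positive("d", self.d)
            implied = self.d / self.b - 1.0
            if not math.isclose(implied, self.alpha, rel_tol=_REL_TOL, abs_tol=0.0):
                raise ParameterError(
                    f"alpha={self.alpha!r} inconsistent with d/b-1={implied!r} "
                    "(they must agree to 1e-12 relative)"
                )

    @property
    def density(self) -> float:
        """Stationary expected individuals per unit area, theta_s/alpha."""
        return self.theta_s / self.alpha

    @property
    def correlation_length(self) -> float:
        """Conspecific correlation length sigma/sqrt(alpha)."""
        return self.sigma / math.sqrt(self.alpha)

    def rescaled(self, c: float) -> "NeutralParams":
        """Return the same community with lengths multiplied by ``c``.

        sigma -> c*sigma, theta_s -> theta_s/c**2; all dimensionless outputs
        of the theory are invariant when radii are rescaled accordingly.
        """
        c = _require_positive("c", c)
        return NeutralParams(self.alpha, c * self.sigma, self.theta_s / c**2, self.b)


def make_params(
    alpha: float,
    sigma: float,
    theta_s: float,
    b: float = 1.0,
) -> NeutralParams:
    """Validate and assemble a :class:`NeutralParams`; ``d = b*(1+alpha)``."""
    return NeutralParams(alpha=alpha, sigma=sigma, theta_s=theta_s, b=b)


@dataclass(frozen=True)
class SampleRegion:
    """Circular sample region of radius ``R`` (area ``pi R^2``)."""

    R: float
    A: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ParameterError(f"R must be nonnegative, got {self.R!r}")
        area = math.pi * self.R * self.R
        if self.A is None:
            object.__setattr__(self, "A", area)
        elif not math.isclose(self.A, area, rel_tol=_REL_TOL, abs_tol=1e-300):
            raise ParameterError(f"A={self.A!r} != pi*R^2={area!r}")

    @classmethod
    def from_area(cls, A: float) -> "SampleRegion":
        if A < 0:
            raise ParameterError(f"A must be nonnegative, got {A!r}")
        return cls(R=math.sqrt(A / math.pi))


@dataclass(frozen=True)
class TransformPoint:
    """A point of the generating-function transform variable ``h``.

    ``alpha_h = (d/b) e^{-h} - 1`` is the tilted demographic parameter: inside
    a sample window weighted by ``e^{h n}``, the community behaves as if its
    demographic parameter were ``alpha_h``.  For ``h <= 0``, ``alpha_h >= alpha``.
    """

    h: float
    alpha: float
    alpha_h: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _require_positive("alpha", self.alpha)
        # (1+alpha) e^{-h} - 1, written for accuracy near h = 0
        val = (1.0 + self.alpha) * math.expm1(-self.h) + self.alpha
        if self.alpha_h is None:
            object.__setattr__(self, "alpha_h", val)
        elif self.alpha_h != val:
            raise ParameterError("alpha_h must equal (1+alpha)*exp(-h) - 1 exactly")


# ---------------------------------------------------------------------------
# Flat key=value config files
# ---------------------------------------------------------------------------

_FLOAT_KEYS = ("alpha", "sigma", "theta_s", "b", "side", "time", "cap")
_INT_KEYS = ("seed", "n_centers", "max_pairs")


def read_config(path: str) -> dict:
    """Read a flat ``key = value`` config file (``#`` comments allowed)."""
    out: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw.rstrip()!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key in _INT_KEYS:
                out[key] = int(val)
            elif key in _FLOAT_KEYS:
                out[key] = float(val)
            else:
                out[key] = val
    return out


def write_config(path: str, values: dict) -> None:
    tmp = path + ".tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        for key, val in values.items():
            if isinstance(val, float):
                fh.write(f"{key} = {val!r}\n")
            else:
                fh.write(f"{key} = {val}\n")
    os.replace(tmp, path)
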