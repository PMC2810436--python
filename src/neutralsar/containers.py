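"""Curve containers (species-area, distance decay) and their TSV round-trips.

All files are plain tab-separated text with a single header line and values
formatted to 12 significant digits, so that write/read round-trips are exact
at the declared precision.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["SARCurve", "BetaDiversityCurve", "PhaseReport"]

_FMT = "%.12g"


def _atomic_write(path: str, text: str) -> None:
    tmp = f"{path}.tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        fh.write(text)
    os.replace(tmp, path)


@dataclass
class SARCurve:
    """Paired (area, expected or observed species count).

    ``method`` records provenance: ``closed_form``, ``quadrature``,
    ``linear_phase`` or ``measured``.  Measured curves may carry standard
    errors over sampling centres.
    """

    areas: np.ndarray
    species: np.ndarray
    method: str
    params: Optional[object] = None
    se: Optional[np.ndarray] = None

    _ANALYTIC = ("closed_form", "quadrature", "linear_phase")

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        self.species = np.asarray(self.species, dtype=float)
        if self.areas.shape != self.species.shape:
            raise ValueError("areas and species must have equal length")
        if self.areas.size > 1 and not np.all(np.diff(self.areas) > 0):
            raise ValueError("areas must be strictly increasing")
        if np.any(self.species < 0):
            raise ValueError("species counts must be nonnegative")
        if self.method in self._ANALYTIC and self.species.size > 1:
            if np.any(np.diff(self.species) < -1e-9 * np.maximum(self.species[:-1], 1e-300)):
                raise ValueError("analytic species-area curves must be nondecreasing")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.sqrt(self.areas / math.pi)

    def to_tsv(self, path: str) -> None:
        cols = ["area", "species"] + (["se"] if self.se is not None else [])
        lines = ["\t".join(cols)]
        for i in range(self.areas.size):
            row = [_FMT % self.areas[i], _FMT % self.species[i]]
            if self.se is not None:
                row.append(_FMT % self.se[i])
            lines.append("\t".join(row))
        _atomic_write(path, "\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str, method: str = "measured") -> "SARCurve":
        data = _read_tsv(path, required=("area", "species"))
        return cls(
            areas=data["area"],
            species=data["species"],
            method=method,
            se=data.get("se"),
        )


@dataclass
class BetaDiversityCurve:
    """Distance decay of community similarity: F(r), the probability that two
    individuals separated by distance r are conspecific.

    Measured curves carry the number of sampled pairs per distance bin;
    bins with no pairs hold ``nan``.
    """

    r: np.ndarray
    F: np.ndarray
    method: str
    n_pairs: Optional[np.ndarray] = None
    params: Optional[object] = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.r.shape != self.F.shape:
            raise ValueError("r and F must have equal length")
        if self.r.size > 1 and not np.all(np.diff(self.r) > 0):
            raise ValueError("r must be strictly increasing")
        finite = np.isfinite(self.F)
        if np.any((self.F[finite] < 0) | (self.F[finite] > 1)):
            raise ValueError("F must lie in [0, 1]")
        if self.method == "analytic" and self.F.size > 1 and not np.all(np.diff(self.F) < 0):
            raise ValueError("analytic F(r) must be strictly decreasing")
        if self.n_pairs is not None:
            self.n_pairs = np.asarray(self.n_pairs, dtype=float)

    def to_tsv(self, path: str) -> None:
        cols = ["r", "F"] + (["n_pairs"] if self.n_pairs is not None else [])
        lines = ["\t".join(cols)]
        for i in range(self.r.size):
            row = [_FMT % self.r[i], _FMT % self.F[i]]
            if self.n_pairs is not None:
                row.append(_FMT % self.n_pairs[i])
            lines.append("\t".join(row))
        _atomic_write(path, "\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str, method: str = "measured") -> "BetaDiversityCurve":
        data = _read_tsv(path, required=("r", "F"))
        return cls(r=data["r"], F=data["F"], method=method, n_pairs=data.get("n_pairs"))


@dataclass(frozen=True)
class PhaseReport:
    """The three phases of the species-area curve for one parameter set.

    ``A_small = sigma**2`` ends the steep 'sampling' phase; ``A_large =
    sigma**2/alpha`` starts the exactly linear phase; between them the curve is
    approximately a power law ``S ~ A**z`` whose exponent ``z`` is evaluated at
    radius ``R_eval = sigma * alpha**(-1/4)``, the log-scale centre of the
    power-law window.
    """

    A_small: float
    A_large: float
    z: float
    R_eval: float

    def __post_init__(self) -> None:
        if not (0.0 < self.z < 1.0):
            raise ValueError(f"power-law exponent z out of (0,1): {self.z!r}")


def _read_tsv(path: str, required: Sequence[str]) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        names = header.split("\t")
        for col in required:
            if col not in names:
                raise ValueError(f"{path}: missing required column {col!r} in header {header!r}")
        rows = []
        for lineno, raw in enumerate(fh, 2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != len(names):
                raise ValueError(f"{path}:{lineno}: expected {len(names)} fields, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
    arr = np.asarray(rows, dtype=float).reshape(-1, len(names))
    return {name: arr[:, j] for j, name in enumerate(names)}
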