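"""Individual-based simulation of the neutral community on a 2-D torus.

Implements the exact stochastic process whose equilibrium the analytic module
solves: every individual dies at rate ``d`` and gives birth at rate ``b`` with
the offspring displaced by a dispersal kernel draw (wrapped periodically), and
new species appear as single founding individuals at uniformly random
locations as a Poisson process with areal rate ``theta_s * b``.  That areal
rate is the unique choice for which the stationary density matches the
equilibrium prediction ``theta_s/alpha``: each founding lineage contributes an
expected time-integrated abundance of ``1/(alpha b)``.

Estimators for species-area curves, distance decay and density operate on the
resulting point patterns; measurement seeds are independent of simulation
seeds so measuring never perturbs reproducibility.
"""
from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import _engine
from .containers import BetaDiversityCurve, SARCurve
from .params import NeutralParams
from .theory import expected_density

__all__ = [
    "DispersalKernel",
    "PointCommunity",
    "EventCounts",
    "simulate",
    "equilibrate",
    "measure_sar",
    "measure_F",
    "measure_density",
    "EquilibrationError",
]

DEFAULT_CAP = 2_000_000


class EquilibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class DispersalKernel:
    """Radially symmetric dispersal kernel.

    ``gaussian``: isotropic displacement with per-axis standard deviation
    ``sqrt(2) * sigma`` so that the kernel's diffusion coefficient equals
    ``sigma**2`` (the package-wide convention).

    ``lattice_nearest_neighbour``: dispersal to one of the 4 neighbours at
    spacing ``lattice_spacing`` with total probability ``1 - self_prob``, or
    no displacement; mirrors the discrete-world formulation and is used for
    the lattice-to-continuum story only.  Its diffusion coefficient is
    ``(1 - self_prob) * lattice_spacing**2 / 4``.
    """

    kind: str = "gaussian"
    sigma: float = 1.0
    lattice_spacing: float = 1.0
    self_prob: float = 0.2

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "lattice_nearest_neighbour"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.sigma <= 0:
            raise ValueError("kernel sigma must be positive")
        if self.kind == "lattice_nearest_neighbour":
            if self.lattice_spacing <= 0:
                raise ValueError("lattice_spacing must be positive")
            if not (0.0 <= self.self_prob < 1.0):
                raise ValueError("self_prob must lie in [0, 1)")

    @classmethod
    def for_params(cls, params: NeutralParams) -> "DispersalKernel":
        return cls(kind="gaussian", sigma=params.sigma)

    @property
    def diffusion_sigma(self) -> float:
        """The sigma of the diffusion approximation this kernel realizes."""
        if self.kind == "gaussian":
            return self.sigma
        return math.sqrt((1.0 - self.self_prob) * self.lattice_spacing**2 / 4.0)


@dataclass(frozen=True)
class EventCounts:
    births: int = 0
    deaths: int = 0
    speciations: int = 0


@dataclass
class PointCommunity:
    """A snapshot of the community: individuals with coordinates and species.

    Coordinates are continuous in ``[0, L)`` on a torus of side ``L``.
    Species labels are opaque integers; estimators only compare them for
    equality, never inspect their values.
    """

    x: np.ndarray
    y: np.ndarray
    species: np.ndarray
    L: float
    t: float = 0.0
    params: Optional[NeutralParams] = None
    seed: Optional[int] = None
    initial_n: int = 0
    event_counts: EventCounts = field(default_factory=EventCounts)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.species = np.asarray(self.species, dtype=np.int64)
        if not (self.x.shape == self.y.shape == self.species.shape):
            raise ValueError("x, y, species must have equal length")
        if self.L <= 0:
            raise ValueError("torus side L must be positive")
        if self.x.size and (self.x.min() < 0 or self.x.max() >= self.L
                            or self.y.min() < 0 or self.y.max() >= self.L):
            raise ValueError("coordinates must lie in [0, L)")
        ec = self.event_counts
        expect = self.initial_n + ec.births + ec.speciations - ec.deaths
        if expect != self.n:
            raise ValueError(
                f"event bookkeeping inconsistent: initial {self.initial_n} + births "
                f"{ec.births} + speciations {ec.speciations} - deaths {ec.deaths} "
                f"!= N = {self.n}"
            )

    @property
    def n(self) -> int:
        return int(self.x.size)

    @property
    def n_species(self) -> int:
        return int(np.unique(self.species).size) if self.n else 0

    @classmethod
    def empty(cls, L: float, params: Optional[NeutralParams] = None) -> "PointCommunity":
        return cls(
            x=np.empty(0), y=np.empty(0), species=np.empty(0, dtype=np.int64), L=L,
            params=params,
        )

    # -- CSV round-trip ----------------------------------------------------
    def to_csv(self, path: str) -> None:
        """Write ``x,y,species`` CSV plus a JSON sidecar ``<path>.meta``.

        Header comment documents the conventions: continuous real-valued
        coordinates in [0, L), Euclidean distances with toroidal wrapping.
        """
        lines = [
            "# point community: continuous coordinates in [0, L), toroidal distances",
            "x,y,species",
        ]
        for i in range(self.n):
            lines.append(f"{self.x[i]:.12g},{self.y[i]:.12g},{int(self.species[i])}")
        tmp = path + ".tmp"
        with open(tmp, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
        os.replace(tmp, path)
        meta = {
            "L": self.L,
            "t": self.t,
            "seed": self.seed,
            "initial_n": self.initial_n,
            "births": self.event_counts.births,
            "deaths": self.event_counts.deaths,
            "speciations": self.event_counts.speciations,
        }
        if self.params is not None:
            meta.update(
                alpha=self.params.alpha, sigma=self.params.sigma,
                theta_s=self.params.theta_s, b=self.params.b,
            )
        tmp = path + ".meta.tmp"
        with open(tmp, "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, path + ".meta")

    @classmethod
    def from_csv(cls, path: str) -> "PointCommunity":
        xs, ys, sps = [], [], []
        with open(path, "r", encoding="utf-8") as fh:
            header_seen = False
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if not header_seen:
                    if line != "x,y,species":
                        raise ValueError(f"{path}:{lineno}: expected header 'x,y,species', got {line!r}")
                    header_seen = True
                    continue
                parts = line.split(",")
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
                try:
                    xs.append(float(parts[0]))
                    ys.append(float(parts[1]))
                    sps.append(int(parts[2]))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad field ({exc})") from None
        meta_path = path + ".meta"
        meta: dict = {}
        if os.path.exists(meta_path):
            with open(meta_path, "r", encoding="utf-8") as fh:
                meta = json.load(fh)
        else:
            # bare CSV: treat the whole pattern as the initial condition
            meta["initial_n"] = len(xs)
        params = None
        if "alpha" in meta:
            params = NeutralParams(meta["alpha"], meta["sigma"], meta["theta_s"], meta.get("b", 1.0))
        return cls(
            x=np.asarray(xs), y=np.asarray(ys), species=np.asarray(sps, dtype=np.int64),
            L=float(meta.get("L", (max(xs + [1.0]) if xs else 1.0) + 1.0)),
            t=float(meta.get("t", 0.0)),
            params=params,
            seed=meta.get("seed"),
            initial_n=int(meta.get("initial_n", 0)),
            event_counts=EventCounts(
                births=int(meta.get("births", 0)),
                deaths=int(meta.get("deaths", 0)),
                speciations=int(meta.get("speciations", 0)),
            ),
        )


def _kernel_args(kernel: DispersalKernel):
    if kernel.kind == "gaussian":
        return 0, math.sqrt(2.0) * kernel.sigma, 0.0, 0.0
    return 1, 0.0, kernel.lattice_spacing, kernel.self_prob


def simulate(
    params: NeutralParams,
    kernel: Optional[DispersalKernel],
    L: float,
    T: float,
    seed: int,
    initial: Optional[PointCommunity] = None,
    cap: int = DEFAULT_CAP,
) -> PointCommunity:
    """Run the exact event-driven process for duration ``T``.

    Starts from ``initial`` (or empty).  Deterministic: the same seed and
    inputs give a bit-identical community.  If the population would exceed
    ``cap`` (a safety device against near-critical configurations) the run is
    aborted with a diagnostic; a capped run is never truncated-and-returned.
    """
    if kernel is None:
        kernel = DispersalKernel.for_params(params)
    if L <= 10.0 * kernel.diffusion_sigma:
        raise ValueError(
            f"torus side L={L!r} must exceed 10 dispersal lengths "
            f"({10.0 * kernel.diffusion_sigma!r}) so the kernel does not wrap trivially"
        )
    if T < 0:
        raise ValueError("duration T must be nonnegative")
    if seed is None or int(seed) < 0:
        raise ValueError("a nonnegative integer seed is required")

    x = np.empty(cap)
    y = np.empty(cap)
    species = np.empty(cap, dtype=np.int64)
    if initial is not None and initial.n:
        n0 = initial.n
        if n0 > cap:
            raise ValueError("initial community exceeds the population cap")
        x[:n0] = initial.x
        y[:n0] = initial.y
        species[:n0] = initial.species
        next_sp = int(initial.species.max()) + 1
    else:
        n0, next_sp = 0, 0

    kind, s_axis, dx, self_p = _kernel_args(kernel)
    state = _engine.seed_state(int(seed))
    n, t, births, deaths, specs, next_sp, hit = _engine.run_events(
        state, x, y, species, n0, next_sp, float(L),
        params.b, params.d, params.theta_s * params.b * L * L,
        0.0, float(T), cap, kind, s_axis, dx, self_p,
    )
    if hit:
        raise RuntimeError(
            f"population cap {cap} reached at t={t:.4g} (N={n}); "
            "the run is discarded -- check alpha is not too close to 0"
        )
    return PointCommunity(
        x=x[:n].copy(), y=y[:n].copy(), species=species[:n].copy(), L=float(L),
        t=(initial.t if initial is not None else 0.0) + t,
        params=params, seed=int(seed),
        initial_n=n0,
        event_counts=EventCounts(births=births, deaths=deaths, speciations=specs),
    )


def equilibrate(
    params: NeutralParams,
    kernel: Optional[DispersalKernel],
    L: float,
    seed: int,
    turnover_times: float = 10.0,
    n_checkpoints: int = 50,
    trend_tstat: float = 3.0,
    max_extensions: int = 2,
    cap: int = DEFAULT_CAP,
) -> PointCommunity:
    """Run from empty until stationary.

    Default horizon is ``turnover_times`` lineage turnover times
    (``T = 10/(alpha b)``), recording the density at checkpoints; stationarity
    requires the regression slope of the density series over the last 20% of
    checkpoints to be statistically indistinguishable from flat
    (|t| < ``trend_tstat``).  On failure the run is extended by 50% up to
    ``max_extensions`` times before raising.
    """
    if kernel is None:
        kernel = DispersalKernel.for_params(params)
    T = turnover_times / (params.alpha * params.b)
    dt = T / n_checkpoints

    x = np.empty(cap)
    y = np.empty(cap)
    species = np.empty(cap, dtype=np.int64)
    kind, s_axis, dxl, self_p = _kernel_args(kernel)
    if L <= 10.0 * kernel.diffusion_sigma:
        raise ValueError("torus side too small relative to dispersal length")
    state = _engine.seed_state(int(seed))
    n, t_now, births, deaths, specs, next_sp = 0, 0.0, 0, 0, 0, 0
    dens_series: list = []

    extensions = 0
    target = T
    while True:
        while t_now < target - 1e-12:
            n, t_now, b_, d_, s_, next_sp, hit = _engine.run_events(
                state, x, y, species, n, next_sp, float(L),
                params.b, params.d, params.theta_s * params.b * L * L,
                t_now, min(t_now + dt, target), cap, kind, s_axis, dxl, self_p,
            )
            births += b_
            deaths += d_
            specs += s_
            if hit:
                raise RuntimeError(f"population cap {cap} reached during equilibration")
            dens_series.append(n / (L * L))
        tail = np.asarray(dens_series[int(0.8 * len(dens_series)):])
        if _trend_ok(tail, trend_tstat):
            break
        if extensions >= max_extensions:
            raise EquilibrationError(
                f"density trend still significant after T={t_now:.4g} "
                f"({extensions} extension(s)); densities tail mean "
                f"{tail.mean():.4g}, expected {expected_density(params):.4g}"
            )
        extensions += 1
        target += 0.5 * T
    return PointCommunity(
        x=x[:n].copy(), y=y[:n].copy(), species=species[:n].copy(), L=float(L),
        t=t_now, params=params, seed=int(seed), initial_n=0,
        event_counts=EventCounts(births=births, deaths=deaths, speciations=specs),
    )


def _trend_ok(series: np.ndarray, tcrit: float) -> bool:
    """True if the OLS slope of the series is within tcrit SEs of zero.

    The checkpoint densities are serially correlated (the community relaxes
    over a lineage turnover time), so the slope SE is inflated by the AR(1)
    effective-sample-size factor (1+rho)/(1-rho) before the t-test.
    """
    m = series.size
    if m < 4:
        return True
    tt = np.arange(m, dtype=float)
    tt -= tt.mean()
    yy = series - series.mean()
    sxx = float(tt @ tt)
    slope = float(tt @ yy) / sxx
    resid = yy - slope * tt
    s2 = float(resid @ resid) / (m - 2)
    if s2 <= 0:
        return True
    rho = float(resid[:-1] @ resid[1:]) / float(resid @ resid)
    rho = min(max(rho, 0.0), 0.99)
    inflate = (1.0 + rho) / (1.0 - rho)
    se = math.sqrt(s2 * inflate / sxx)
    return abs(slope) <= tcrit * se


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def measure_sar(
    community: PointCommunity,
    R_values: Sequence[float],
    n_centers: int = 200,
    seed: int = 0,
) -> SARCurve:
    """Observed species-area curve: mean distinct-species count over uniformly
    random circle centres (toroidal distance), with standard errors."""
    R = np.asarray(R_values, dtype=float)
    if R.size > 1 and not np.all(np.diff(R) > 0):
        raise ValueError("radii must be sorted strictly increasing")
    if np.any(R >= community.L / 2.0):
        raise ValueError("max radius must be below L/2 on the torus")
    if n_centers < 1:
        raise ValueError("n_centers must be >= 1")
    state = _engine.seed_state(int(seed) ^ 0x5A17)
    counts = np.zeros((n_centers, R.size))
    r2 = R * R
    for k in range(n_centers):
        cx = _u01(state) * community.L
        cy = _u01(state) * community.L
        d2 = _engine.torus_dist2(cx, cy, community.x, community.y, community.L)
        order = np.argsort(d2)
        sorted_d2 = d2[order]
        sorted_sp = community.species[order]
        for j in range(R.size):
            m = np.searchsorted(sorted_d2, r2[j], side="right")
            counts[k, j] = np.unique(sorted_sp[:m]).size
    mean = counts.mean(axis=0)
    se = counts.std(axis=0, ddof=1) / math.sqrt(n_centers) if n_centers > 1 else np.zeros(R.size)
    return SARCurve(areas=math.pi * R**2, species=mean, method="measured",
                    params=community.params, se=se)


def _u01(state) -> float:
    return float(_engine._next_double(state))


def measure_F(
    community: PointCommunity,
    r_edges: Sequence[float],
    max_pairs: int = 20_000,
    seed: int = 0,
) -> BetaDiversityCurve:
    """Observed distance decay: per distance bin, the fraction of sampled
    unordered pairs (toroidal separation inside the bin) that are conspecific.

    Pairs are subsampled to at most ``max_pairs`` per bin; self-pairs are
    excluded; empty bins are recorded as missing (nan), never as zero.
    """
    edges = np.asarray(r_edges, dtype=float)
    if edges.size < 2:
        raise ValueError("need at least two bin edges")
    if np.any(edges <= 0) or not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be positive and strictly increasing")
    if community.n < 2:
        raise ValueError("community must hold at least two individuals")
    state = _engine.seed_state(int(seed) ^ 0xBE7A)
    nbins = edges.size - 1
    attempts = int(min(60 * max_pairs * nbins, 60_000_000))
    same, tot = _engine.sample_pairs(
        state, community.x, community.y, community.species, community.L,
        edges * edges, int(max_pairs), attempts,
    )
    mid = np.sqrt(edges[:-1] * edges[1:])
    with np.errstate(invalid="ignore"):
        F = np.where(tot > 0, same / np.maximum(tot, 1), np.nan)
    return BetaDiversityCurve(r=mid, F=F, method="measured",
                              n_pairs=tot.astype(float), params=community.params)


def measure_density(community: PointCommunity) -> float:
    """Individuals per unit area, N / L^2."""
    return community.n / (community.L * community.L)


def relabel(community: PointCommunity, permutation_seed: int) -> PointCommunity:
    """Apply a random permutation to species labels (neutrality check aid)."""
    rng = np.random.default_rng(permutation_seed)
    unique = np.unique(community.species)
    perm = rng.permutation(unique.size)
    mapping = dict(zip(unique.tolist(), unique[perm].tolist()))
    new = np.asarray([mapping[s] for s in community.species.tolist()], dtype=np.int64)
    return replace(community, species=new)
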