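"""Simulator-versus-theory consistency report.

Runs a small equilibrated community and compares its density, distance decay
and species-area curve against the analytic predictions.  Used by the
``validate`` command line entry point and convenient for quick interactive
sanity checks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List

import numpy as np

from .community import equilibrate, measure_density, measure_F, measure_sar
from .model import fit_beta_diversity
from .params import NeutralParams, make_params
from .theory import beta_diversity_F, expected_density, sar_closed_form

__all__ = ["ValidationReport", "run_validation"]


@dataclass
class Check:
    name: str
    passed: bool
    detail: str


@dataclass
class ValidationReport:
    params: NeutralParams
    checks: List[Check] = field(default_factory=list)

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def render(self) -> str:
        lines = [
            "simulator vs theory validation",
            f"alpha={self.params.alpha:g} sigma={self.params.sigma:g} "
            f"theta_s={self.params.theta_s:g}",
            "-" * 60,
        ]
        for c in self.checks:
            lines.append(f"[{'ok' if c.passed else 'FAIL'}] {c.name}: {c.detail}")
        lines.append("-" * 60)
        lines.append("ALL OK" if self.all_passed else "SOME CHECKS FAILED")
        return "\n".join(lines)


def run_validation(
    alpha: float = 0.2,
    sigma: float = 1.0,
    theta_s: float = 0.5,
    L: float = 40.0,
    n_replicates: int = 4,
    seed: int = 0,
) -> ValidationReport:
    """Equilibrate a few replicates and compare estimators with theory.

    Checks: stationary density within 3 SE of theta_s/alpha; measured F(r)
    within binomial 95% CIs of the analytic curve in at least 80% of bins at
    separations beyond ~1.25 dispersal lengths; measured richness within 10%
    of the closed form at radii beyond 1.5 correlation lengths; recovered
    alpha within a factor 2.
    """
    params = make_params(alpha, sigma, theta_s)
    report = ValidationReport(params=params)

    densities = []
    comms = []
    for k in range(n_replicates):
        comm = equilibrate(params, None, L, seed=seed * 1000 + k)
        comms.append(comm)
        densities.append(measure_density(comm))
    dens = np.asarray(densities)
    rho = expected_density(params)
    se = dens.std(ddof=1) / math.sqrt(len(dens)) if len(dens) > 1 else float("inf")
    ok = abs(dens.mean() - rho) <= 3.0 * se
    report.checks.append(Check(
        "stationary density", ok,
        f"sim {dens.mean():.4g} +- {se:.2g} vs theory {rho:.4g}"))

    # distance decay on the first replicate; a coarse health check (the
    # CI-level comparison lives in the test suite at smaller alpha, where the
    # diffusion approximation of the kernel is tighter)
    comm = comms[0]
    corr = params.correlation_length
    edges = np.geomspace(1.0 * sigma, min(4.0 * corr, L / 2.5), 11)
    meas = measure_F(comm, edges, max_pairs=30_000, seed=seed + 17)
    good = np.isfinite(meas.F) & (meas.F > 0) & (meas.r >= 2.0 * sigma)
    pred = beta_diversity_F(params, meas.r[good])
    rel = np.abs(meas.F[good] / pred.F - 1.0)
    ok = bool(np.mean(rel < 0.20) >= 0.8)
    report.checks.append(Check(
        "distance decay F(r)", ok,
        f"{int((rel < 0.20).sum())}/{rel.size} bins within 20% of theory"))

    # species-area at radii where the equilibrium solution is accurate
    R = np.geomspace(1.5 * corr, min(2.8 * corr, L / 2.2), 4)
    sar = measure_sar(comm, R, n_centers=150, seed=seed + 29)
    pred_sar = sar_closed_form(params, R)
    rel = np.abs(pred_sar.species / sar.species - 1.0)
    ok = bool(np.all(rel < 0.10))
    report.checks.append(Check(
        "species-area (R >= 1.5 corr. lengths)", ok,
        f"max |rel| = {rel.max():.2%}"))

    # parameter recovery
    try:
        fit = fit_beta_diversity(meas, measure_density(comm))
        ratio = fit.alpha_hat / alpha
        ok = 0.5 <= ratio <= 2.0
        detail = f"alpha_hat/alpha = {ratio:.2f}, sigma_hat = {fit.sigma_hat:.3g}"
    except Exception as exc:  # pragma: no cover - diagnostic path
        ok, detail = False, f"fit failed: {exc}"
    report.checks.append(Check("parameter recovery", ok, detail))
    return report
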