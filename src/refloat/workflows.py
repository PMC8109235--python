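"""High-level recovery workflows.

These glue the generator and the co-refinement together for the standard
self-consistency exercise: simulate the three-contrast measurement of a
known structure, refine the organic-layer parameters against it with the
substrate and SAM block held common across the contrasts, and compare the
recovered bilayer-to-SAM distance with the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import (
    FitProblem,
    assemble_problem,
    dram_sample,
    optimize,
    summarize_posterior,
)
from .model import Parameter, ffb_structure
from .synthetic import (
    NoiseModel,
    default_qgrid,
    simulate_condition,
    measured_scenario,
)

__all__ = [
    "RecoveryResult",
    "recovery_problem",
    "recover_distance",
    "quick_distance_fit",
]

#: Broad refinement bounds for the organic layers (angstrom / angstrom^2).
DEFAULT_BOUNDS = {
    "distance": (1.0, 650.0),
    "roughness": (0.5, 150.0),
    "apm": (50.0, 85.0),
    "coverage": (0.6, 1.0),
}


@dataclass
class RecoveryResult:
    """Outcome of one simulate-and-refit exercise."""

    composition: str
    condition: str
    truth_distance: float
    truth_roughness: float
    map_distance: float
    ci_distance: tuple
    map_roughness: float
    ci_roughness: tuple
    chi_squared: float
    n_points: int
    summary: object = None

    @property
    def truth_in_ci(self) -> bool:
        lo, hi = self.ci_distance
        return lo <= self.truth_distance <= hi


def recovery_problem(composition: str, condition: str, seed: int, *,
                     grid=None, noise: NoiseModel = None,
                     free=("distance", "roughness", "apm", "coverage"),
                     bounds=None, start=None, n_quad: int = 17) -> tuple:
    """Simulated three-contrast datasets plus the refinement problem.

    The generating structure takes the resolved distance/roughness of the
    given fixture cell; the fit structure frees the requested organic
    parameters (within ``bounds``) while substrate and SAM stay at their
    configured values, common to all three contrasts.

    Returns ``(problem, scenario)``.
    """
    scen = measured_scenario(composition, condition)
    truth = scen.structure()
    if grid is None:
        grid = default_qgrid()
    data = simulate_condition(truth, grid=grid, noise=noise, seed=seed,
                              n_quad=n_quad)

    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    s = dict(start or {})
    mid = {k: 0.5 * (lo + hi) for k, (lo, hi) in b.items()}

    def par(key, default_fixed):
        if key in free:
            return Parameter(s.get(key, mid[key]), key, b[key], vary=True)
        return default_fixed

    fit_structure = ffb_structure(
        composition, condition,
        par("distance", scen.distance),
        par("roughness", scen.roughness),
        area_per_molecule=par("apm", scen.area_per_molecule),
        coverage=par("coverage", scen.coverage),
        sam_area_per_molecule=scen.sam_area_per_molecule,
        sam_coverage=scen.sam_coverage,
    )
    problem = assemble_problem(data, {condition: fit_structure}, n_quad=n_quad)
    return problem, scen


def recover_distance(composition: str, condition: str, seed: int, *,
                     grid=None, noise=None, free=("distance", "roughness",
                                                  "apm", "coverage"),
                     bounds=None, n_steps: int = 2000,
                     burn_fraction: float = 0.3, n_quad: int = 17,
                     optimizer_options=None) -> RecoveryResult:
    """Full recovery: global optimisation, DRAM sampling, shortest-CI summary."""
    problem, scen = recovery_problem(composition, condition, seed, grid=grid,
                                     noise=noise, free=free, bounds=bounds,
                                     n_quad=n_quad)
    opts = dict(maxiter=25, popsize=10, tol=0.005)
    opts.update(optimizer_options or {})
    res = optimize(problem, seed=seed + 1, **opts)
    chains, info = dram_sample(problem, res.x, n_steps=n_steps, seed=seed + 2)
    burn = int(burn_fraction * n_steps)
    summary = summarize_posterior(chains[burn:], names=problem.names,
                                  acceptance_rate=info["acceptance_rate"])
    problem.set_vector(summary.map_estimate)

    def grab(key):
        if key in problem.names:
            m, lo, hi = summary.parameter(key)
            return m, (lo, hi)
        v = {"distance": scen.distance, "roughness": scen.roughness}[key]
        return v, (v, v)

    md, cid = grab("distance")
    mr, cir = grab("roughness")
    return RecoveryResult(
        composition=scen.composition, condition=condition,
        truth_distance=scen.distance, truth_roughness=scen.roughness,
        map_distance=md, ci_distance=cid, map_roughness=mr, ci_roughness=cir,
        chi_squared=problem.chi_squared(), n_points=problem.n_points,
        summary=summary,
    )


def quick_distance_fit(composition: str, condition: str, seed: int, *,
                       grid=None, free=("distance", "roughness"),
                       n_quad: int = 17, optimizer_options=None) -> RecoveryResult:
    """Point estimate only (differential evolution, no MCMC).

    The distance likelihood is fringe-multimodal over broad bounds, so the
    default search budget favours robustness over speed.
    """
    problem, scen = recovery_problem(composition, condition, seed, grid=grid,
                                     free=free, n_quad=n_quad)
    opts = dict(maxiter=25, popsize=15, tol=0.01)
    opts.update(optimizer_options or {})
    res = optimize(problem, seed=seed + 1, **opts)
    problem.set_vector(res.x)
    vals = dict(zip(problem.names, res.x))
    md = vals.get("distance", scen.distance)
    mr = vals.get("roughness", scen.roughness)
    return RecoveryResult(
        composition=scen.composition, condition=condition,
        truth_distance=scen.distance, truth_roughness=scen.roughness,
        map_distance=md, ci_distance=(md, md), map_roughness=mr,
        ci_roughness=(mr, mr), chi_squared=float(res.fun),
        n_points=problem.n_points,
    )
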