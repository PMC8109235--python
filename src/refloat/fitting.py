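"""Simultaneous refinement of reflectivity datasets.

Many datasets (isotopic contrasts x salt conditions, plus SAM-only
controls) are fitted against one parameter vector.  Sharing is by object
identity: structures that hold the same :class:`~refloat.model.Parameter`
instance are constrained to a common value, which is how the substrate and
SAM block is tied across every condition of a sample while only the
presence and position of the membrane varies.

The likelihood is Gaussian with the reported point uncertainties,
log L = -chi^2 / 2.  Point estimation uses bounded differential evolution
with a local polish; uncertainties come from a Delayed Rejection Adaptive
Metropolis (DRAM) chain started at the optimum, summarised by the
per-parameter distribution maximum and the shortest interval holding 95%
of the marginal posterior mass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sciopt
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigurationError, ConvergenceWarning
from .model import (
    FFBStructure,
    IsotopicContrast,
    Parameter,
    model_reflectivity,
    value_of,
)
from .reflectivity import QGrid

__all__ = [
    "ReflectivityDataset",
    "FitProblem",
    "PosteriorSummary",
    "assemble_problem",
    "chi_squared",
    "optimize",
    "dram_sample",
    "summarize_posterior",
    "fit",
    "distance_report",
]


@dataclass
class ReflectivityDataset:
    """One measured (or simulated) reflectivity curve.

    ``scale`` and ``background`` are per-dataset nuisance parameters: the
    model curve compared with the data is ``scale * R + background``.
    """

    grid: QGrid
    r: np.ndarray
    dr: np.ndarray
    contrast: IsotopicContrast
    condition: str = "custom"
    scale: Parameter | float = 1.0
    background: Parameter | float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.dr = np.asarray(self.dr, dtype=float)
        if isinstance(self.contrast, str):
            self.contrast = IsotopicContrast.from_name(self.contrast)
        n = self.grid.values.size
        if self.r.shape != (n,) or self.dr.shape != (n,):
            raise ConfigurationError("Q, R and dR columns must have equal length")
        if np.any(self.dr <= 0):
            raise ConfigurationError("dR must be strictly positive")

    @property
    def name(self) -> str:
        return f"{self.condition}/{self.contrast.name}"


class FitProblem:
    """Datasets + structures + the shared/free parameter map."""

    def __init__(self, datasets, structures, *, slab_width=0.5, adaptive=True,
                 quality=12.0, n_quad=17):
        self.datasets = list(datasets)
        self.structures = dict(structures)
        self.slab_width = slab_width
        self.adaptive = adaptive
        self.quality = quality
        self.n_quad = n_quad
        for ds in self.datasets:
            if ds.condition not in self.structures:
                raise ConfigurationError(
                    f"dataset {ds.name!r} has no structure for condition "
                    f"{ds.condition!r}"
                )
        self.parameters = self._collect()
        for p in self.parameters:
            if p.bounds is None:
                raise ConfigurationError(
                    f"varying parameter {p.name!r} needs bounds"
                )

    def _collect(self):
        seen, out = set(), []

        def visit(p):
            if isinstance(p, Parameter) and p.vary and id(p) not in seen:
                seen.add(id(p))
                out.append(p)

        for s in self.structures.values():
            for p in s.parameters():
                visit(p)
        for ds in self.datasets:
            visit(ds.scale)
            visit(ds.background)
        return out

    # -- parameter vector ------------------------------------------------
    @property
    def bounds(self) -> np.ndarray:
        return np.array([p.bounds for p in self.parameters], dtype=float)

    @property
    def names(self):
        return [p.name for p in self.parameters]

    def get_vector(self) -> np.ndarray:
        return np.array([p.value for p in self.parameters], dtype=float)

    def set_vector(self, x) -> None:
        for p, v in zip(self.parameters, x):
            p.value = float(v)

    def in_bounds(self, x) -> bool:
        b = self.bounds
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= b[:, 0]) and np.all(x <= b[:, 1]))

    # -- model and likelihood -------------------------------------------
    def model_curve(self, dataset: ReflectivityDataset) -> np.ndarray:
        """scale * R_model + background for one dataset at current values."""
        structure = self.structures[dataset.condition]
        r = model_reflectivity(
            structure, dataset.contrast, dataset.grid,
            slab_width=self.slab_width, adaptive=self.adaptive,
            quality=self.quality, n_quad=self.n_quad,
        )
        return value_of(dataset.scale) * r + value_of(dataset.background)

    def chi_squared(self, x=None) -> float:
        if x is not None:
            if not self.in_bounds(x):
                return math.inf
            self.set_vector(x)
        total = 0.0
        for ds in self.datasets:
            res = (self.model_curve(ds) - ds.r) / ds.dr
            total += float(res @ res)
        return total

    def log_likelihood(self, x=None) -> float:
        return -0.5 * self.chi_squared(x)

    @property
    def n_points(self) -> int:
        return sum(ds.r.size for ds in self.datasets)


def assemble_problem(datasets, structures, **options) -> FitProblem:
    """Build a :class:`FitProblem` from datasets and per-condition structures.

    ``structures`` maps condition labels to :class:`FFBStructure`; a
    SAM-only condition maps to a bilayer-free structure.  Which parameters
    are shared is decided upstream by handing the same Parameter objects
    to several structures (the standard layout shares the whole
    substrate + SAM block and frees the membrane position per condition).
    """
    return FitProblem(datasets, structures, **options)


def chi_squared(problem: FitProblem, params=None) -> float:
    """Sum over datasets and points of ((scale*R+bg - R_obs)/dR)^2.

    Out-of-bounds parameter vectors give +inf (rejected point).
    """
    return problem.chi_squared(params)


def optimize(problem: FitProblem, seed: int = 0, *, maxiter: int = 100,
             popsize: int = 15, tol: float = 0.01, polish: bool = True,
             init: str = "sobol", workers: int = 1):
    """Bounded global optimisation (differential evolution + local polish).

    Deterministic for a given seed.  The best vector is written back into
    the problem's parameters and returned with its chi-squared.
    """
    res = sciopt.differential_evolution(
        problem.chi_squared, problem.bounds, seed=seed, maxiter=maxiter,
        popsize=popsize, tol=tol, polish=polish, init=init, workers=workers,
    )
    if not res.success and not math.isfinite(res.fun):
        warnings.warn("optimiser did not converge; returning best-so-far",
                      ConvergenceWarning, stacklevel=2)
    problem.set_vector(res.x)
    return res


def dram_sample(problem, start, n_steps: int = 5000, seed: int = 0, *,
                gamma: float = 0.2, adapt_start: int = 200,
                adapt_interval: int = 10, initial_scale: float = 0.01,
                delayed_rejection: bool = True, log_post=None, bounds=None):
    """Delayed Rejection Adaptive Metropolis sampling of exp(-chi^2/2).

    One delayed-rejection stage retries a rejected move with the proposal
    shrunk by ``gamma``; the proposal covariance adapts to the running
    chain covariance (Haario scaling 2.38^2/d) from ``adapt_start`` on.
    Samples never leave the parameter bounds.

    Returns ``(chains, info)`` where ``chains`` has shape
    ``(n_steps, n_params)`` and ``info`` carries log-posteriors and the
    acceptance rate.
    """
    if log_post is None:
        log_post = problem.log_likelihood
        bounds = problem.bounds
    bounds = np.asarray(bounds, dtype=float)
    rng = np.random.default_rng(seed)
    x = np.array(start, dtype=float)
    d = x.size
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.any(x < lo) or np.any(x > hi):
        raise ConfigurationError("start point violates bounds")

    def lp(v):
        if np.any(v < lo) or np.any(v > hi):
            return -math.inf
        return float(log_post(v))

    lpx = lp(x)
    sd = 2.38 ** 2 / d
    cov = np.diag((initial_scale * (hi - lo)) ** 2)
    eps = 1e-12 * float(np.max(hi - lo)) ** 2

    def chol(c):
        try:
            return np.linalg.cholesky(c)
        except np.linalg.LinAlgError:
            warnings.warn("degenerate proposal covariance; adding jitter",
                          ConvergenceWarning, stacklevel=2)
            return np.linalg.cholesky(c + (eps + 1e-10) * np.eye(d))

    cho = chol(cov)
    chains = np.empty((n_steps, d))
    logps = np.empty(n_steps)
    accepted = 0
    mean = x.copy()
    m2 = np.zeros((d, d))  # sum of outer products of deviations

    for i in range(n_steps):
        y1 = x + cho @ rng.standard_normal(d)
        lp1 = lp(y1)
        log_a1 = min(0.0, lp1 - lpx)
        if math.log(rng.random()) < log_a1:
            x, lpx = y1, lp1
            accepted += 1
        elif delayed_rejection:
            # delayed-rejection stage with a shrunk proposal
            y2 = x + gamma * (cho @ rng.standard_normal(d))
            lp2 = lp(y2)
            if math.isfinite(lp2):
                # alpha1 for the hypothetical move y2 -> y1
                log_a1_rev = min(0.0, lp1 - lp2)
                num_reject = 1.0 - math.exp(log_a1_rev)
                den_reject = 1.0 - math.exp(log_a1)
                if num_reject > 0.0 and den_reject > 0.0:
                    dy2 = np.linalg.solve(cho, y1 - y2)
                    dx = np.linalg.solve(cho, y1 - x)
                    logq_num = -0.5 * float(dy2 @ dy2)
                    logq_den = -0.5 * float(dx @ dx)
                    log_a2 = (lp2 + logq_num + math.log(num_reject)
                              - lpx - logq_den - math.log(den_reject))
                    if math.log(rng.random()) < min(0.0, log_a2):
                        x, lpx = y2, lp2
                        accepted += 1
        chains[i] = x
        logps[i] = lpx

        # running mean / covariance (Welford) and periodic re-scaling
        delta = x - mean
        mean += delta / (i + 2)
        m2 += np.outer(delta, x - mean)
        if i + 1 >= adapt_start and (i + 1) % adapt_interval == 0:
            cov = sd * (m2 / (i + 1)) + sd * eps * np.eye(d)
            cho = chol(cov)

    info = {
        "log_posterior": logps,
        "acceptance_rate": accepted / n_steps,
        "seed": seed,
        "n_steps": n_steps,
    }
    return chains, info


@dataclass
class PosteriorSummary:
    """Marginal posterior summary: mode, shortest 95% CI, diagnostics."""

    map_estimate: np.ndarray
    ci95: np.ndarray  # (n_params, 2)
    chains: np.ndarray
    names: list
    diagnostics: dict = field(default_factory=dict)

    def parameter(self, name: str):
        """(map, lo, hi) for a named parameter."""
        i = self.names.index(name)
        return float(self.map_estimate[i]), float(self.ci95[i, 0]), float(self.ci95[i, 1])


def _shortest_interval(samples: np.ndarray, level: float):
    s = np.sort(samples)
    n = s.size
    m = max(1, int(math.ceil(level * n)))
    if m >= n:
        return float(s[0]), float(s[-1])
    widths = s[m:] - s[: n - m]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + m])


def _histogram_mode(samples: np.ndarray, bins: int = 128, smooth: float = 2.0):
    lo, hi = samples.min(), samples.max()
    if hi == lo:
        return float(lo)
    counts, edges = np.histogram(samples, bins=bins, range=(lo, hi))
    counts = gaussian_filter1d(counts.astype(float), smooth, mode="nearest")
    centers = 0.5 * (edges[:-1] + edges[1:])
    best = np.flatnonzero(counts == counts.max())
    if best.size > 1:  # break ties toward the sample median
        med = np.median(samples)
        best = best[[int(np.argmin(np.abs(centers[best] - med)))]]
    return float(centers[best[0]])


def _ess(x: np.ndarray) -> float:
    """Effective sample size from the initial-positive-sequence autocorrelation."""
    n = x.size
    if n < 4 or np.all(x == x[0]):
        return float(n)
    xc = x - x.mean()
    f = np.fft.rfft(xc, 2 * n)
    acf = np.fft.irfft(f * np.conj(f))[:n].real
    if acf[0] <= 0:
        return float(n)
    acf /= acf[0]
    tau = 1.0
    for k in range(1, n):
        if acf[k] <= 0.05:
            break
        tau += 2.0 * acf[k]
    return float(n / tau)


def summarize_posterior(chains: np.ndarray, level: float = 0.95, *,
                        names=None, acceptance_rate=None) -> PosteriorSummary:
    """Per-parameter distribution maxima and shortest credible intervals.

    ``chains`` must already exclude burn-in.  The mode comes from a
    smoothed 128-bin histogram; the interval is the narrowest window over
    the sorted samples containing the requested mass.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 1:
        chains = chains[:, None]
    n, d = chains.shape
    if n < 1000:
        warnings.warn(f"only {n} posterior samples; summaries may be noisy",
                      ConvergenceWarning, stacklevel=2)
    maps = np.empty(d)
    ci = np.empty((d, 2))
    ess = np.empty(d)
    for j in range(d):
        col = chains[:, j]
        ci[j] = _shortest_interval(col, level)
        maps[j] = min(max(_histogram_mode(col), ci[j, 0]), ci[j, 1])
        ess[j] = _ess(col)
    diag = {"ess": ess, "n_samples": n}
    if acceptance_rate is not None:
        diag["acceptance_rate"] = acceptance_rate
    return PosteriorSummary(maps, ci, chains, list(names) if names else [f"p{j}" for j in range(d)],
                            diag)


def fit(problem: FitProblem, seed: int = 0, *, n_steps: int = 5000,
        burn_fraction: float = 0.3, optimizer_options=None,
        sampler_options=None) -> PosteriorSummary:
    """Optimise, then sample, then summarise — the standard workflow.

    The MCMC chain starts at the optimum; the first ``burn_fraction`` of
    the chain is discarded before summarising.  The problem's parameters
    are left at the MAP estimate.
    """
    res = optimize(problem, seed=seed, **(optimizer_options or {}))
    chains, info = dram_sample(problem, res.x, n_steps=n_steps, seed=seed + 1,
                               **(sampler_options or {}))
    burn = int(burn_fraction * chains.shape[0])
    summary = summarize_posterior(chains[burn:], names=problem.names,
                                  acceptance_rate=info["acceptance_rate"])
    problem.set_vector(summary.map_estimate)
    return summary


def distance_report(problem: FitProblem, summary: PosteriorSummary) -> dict:
    """Per-condition bilayer-to-SAM distance and bilayer roughness table.

    Returns ``{condition: {"distance": (map, lo, hi), "roughness": ...}}``
    for every condition whose structure carries a varying distance or
    roughness parameter; fixed values are reported as zero-width entries.
    """
    out = {}
    idx = {id(p): j for j, p in enumerate(problem.parameters)}
    for cond, s in problem.structures.items():
        if not s.has_bilayer:
            continue
        entry = {}
        for key, par in (("distance", s.interlayer_thickness),
                         ("roughness", s.bilayer_roughness)):
            if isinstance(par, Parameter) and id(par) in idx:
                j = idx[id(par)]
                entry[key] = (float(summary.map_estimate[j]),
                              float(summary.ci95[j, 0]), float(summary.ci95[j, 1]))
            else:
                v = value_of(par)
                entry[key] = (v, v, v)
        out[cond] = entry
    return out
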