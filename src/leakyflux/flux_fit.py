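"""Flux estimation by constrained weighted least squares.

Free parameters are (i) designated free net fluxes — the null-space
coordinates of the stoichiometric matrix, so every candidate satisfies
S·v = 0 by construction, never by penalty — (ii) exchange fluxes of
reversible reactions in the bounded transform u = r/(1+r) of the
reversibility ratio, and (iii) initial pool concentrations.  Parameters
can be shared across datasets (the FM/EM analysis shares all fluxes
except the lactate exchange) through a per-parameter flag.

The objective is the weighted sum of squared residuals over enrichment
fractions (sigma = 0.01 uniformly) and metabolite abundances (sigma
from the calibration curve).  Uncertainty comes from chi-square SSR
profiling (threshold 3.84 = chi2(1 DoF, 95 %)) and from Monte Carlo
re-estimation on corrupted data (50 replicates by default).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .fluxes import U_CAP, FluxState, ratio_to_u, u_to_ratio
from .hybrid_dynamics import HybridSimulator, SimulationConfig, StepInstabilityError
from .label_simulation import LabelInput, LabellingError
from .measurement_model import MeasurementSet
from .network_model import NetworkModel, free_flux_basis

__all__ = [
    "Parameter",
    "DatasetSpec",
    "FitProblem",
    "FitResult",
    "ProfileCI",
    "SharedRatioTest",
    "MonteCarloResult",
    "CHI2_95_1DOF",
    "REVERSIBILITY_PRESETS",
    "weighted_ssr",
    "estimate",
    "profile_ci",
    "joint_fit_shared",
    "monte_carlo_errors",
    "classify_reversibility",
]

#: 95 % quantile of chi-square with 1 degree of freedom, the profiling
#: threshold used to delimit single-parameter confidence intervals.
CHI2_95_1DOF = 3.84

#: named cut-off presets for calling a reaction fully reversible: the
#: running text uses >= 20, the figure caption >= 25.  Irreversible
#: cut-off is <= 0.05 in both.
REVERSIBILITY_PRESETS = {"text": 20.0, "figure_caption": 25.0}

_PENALTY = 1e3


@dataclass
class Parameter:
    """One (potentially) free parameter of a fit.

    kind: "free_flux" (net flux of a designated free reaction),
    "exchange_u" (bounded exchange transform of a reversible reaction),
    or "init_conc" (initial mM of a pool or tracked source).
    ``shared=False`` gives every dataset its own copy.  ``value`` fixes
    the parameter everywhere (it is then not optimised);
    ``fixed_per_dataset`` fixes individual per-dataset copies (used by
    profiling of non-shared parameters).
    """

    name: str
    kind: str
    target: str
    bounds: tuple[float, float]
    shared: bool = True
    value: float | None = None
    fixed_per_dataset: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("free_flux", "exchange_u", "init_conc"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.kind == "exchange_u":
            lo, hi = self.bounds
            self.bounds = (max(lo, 0.0), min(hi, U_CAP))


@dataclass
class DatasetSpec:
    """One experiment: measurements plus everything needed to simulate it."""

    name: str
    measurements: MeasurementSet
    config: SimulationConfig
    label_input: LabelInput
    initial_conc: dict[str, float]
    analyte_map: dict[str, str] = field(default_factory=dict)
    initial_pool_labelling: dict | None = None


@dataclass
class FitResult:
    names: list[str]
    x: np.ndarray
    ssr: float
    per_dataset_ssr: dict[str, float]
    n_starts: int
    start_ssrs: list[float]
    nfev: int
    success: bool
    weakly_identified: list[str] = field(default_factory=list)

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(self.names, self.x))

    def __getitem__(self, name: str) -> float:
        return self.params[name]


class FitProblem:
    """A (multi-)dataset flux-fitting problem with parameter sharing."""

    def __init__(self, model: NetworkModel, datasets: list[DatasetSpec],
                 parameters: list[Parameter], base_fluxes: FluxState,
                 record_intracellular: tuple[str, ...] = ()):
        self.model = model
        self.datasets = datasets
        self.parameters = parameters
        self.base_fluxes = base_fluxes
        self.basis = free_flux_basis(model)
        for p in parameters:
            if p.kind == "free_flux" and p.target not in self.basis.free_reactions:
                raise ValueError(
                    f"{p.name}: {p.target} is not a designated free flux "
                    f"(free set: {self.basis.free_reactions})"
                )
            if p.kind == "exchange_u" and p.target not in model.reversible_reactions:
                raise ValueError(f"{p.name}: {p.target} is not reversible")
        self.simulator = HybridSimulator(model, record_intracellular)
        self._build_packing()
        self._build_alignment()

    # -- parameter packing -------------------------------------------------

    def _build_packing(self):
        entries = []  # (parameter, dataset_name or None)
        for p in self.parameters:
            if p.value is not None:
                continue
            if p.shared:
                entries.append((p, None))
            else:
                for ds in self.datasets:
                    if ds.name not in p.fixed_per_dataset:
                        entries.append((p, ds.name))
        self.entries = entries
        self.param_names = [
            p.name if dsn is None else f"{p.name}[{dsn}]" for p, dsn in entries
        ]
        self.bounds = (
            np.array([p.bounds[0] for p, _ in entries]),
            np.array([p.bounds[1] for p, _ in entries]),
        )

    def default_x(self) -> np.ndarray:
        x = np.zeros(len(self.entries))
        base_free = {
            r: self.base_fluxes.net[r] for r in self.basis.free_reactions
        }
        for i, (p, dsn) in enumerate(self.entries):
            if p.kind == "free_flux":
                x[i] = base_free[p.target]
            elif p.kind == "exchange_u":
                x[i] = ratio_to_u(
                    min(self.base_fluxes.reversibility_ratio(p.target), 1e3)
                )
            else:
                ds = self.datasets[0] if dsn is None else self._dataset(dsn)
                x[i] = ds.initial_conc[p.target]
            x[i] = float(np.clip(x[i], *(b[i] for b in self.bounds)))
        return x

    def _dataset(self, name: str) -> DatasetSpec:
        for ds in self.datasets:
            if ds.name == name:
                return ds
        raise KeyError(name)

    def _value(self, x, param: Parameter, ds_name: str):
        if param.value is not None:
            return param.value
        if not param.shared and ds_name in param.fixed_per_dataset:
            return param.fixed_per_dataset[ds_name]
        key = (param, None if param.shared else ds_name)
        for i, entry in enumerate(self.entries):
            if entry == key:
                return x[i]
        raise KeyError(param.name)

    def fluxes_for(self, ds: DatasetSpec, x: np.ndarray) -> FluxState:
        free = {r: self.base_fluxes.net[r] for r in self.basis.free_reactions}
        for p in self.parameters:
            if p.kind == "free_flux":
                free[p.target] = self._value(x, p, ds.name)
        net = self.basis.expand(free)
        exchange = dict(self.base_fluxes.exchange)
        for p in self.parameters:
            if p.kind == "exchange_u":
                r = u_to_ratio(float(np.clip(self._value(x, p, ds.name), 0, U_CAP)))
                exchange[p.target] = r * abs(net[p.target])
        return FluxState(net, exchange)

    def initial_conc_for(self, ds: DatasetSpec, x: np.ndarray) -> dict[str, float]:
        conc = dict(ds.initial_conc)
        for p in self.parameters:
            if p.kind == "init_conc":
                conc[p.target] = self._value(x, p, ds.name)
        return conc

    # -- measurement alignment --------------------------------------------

    def _build_alignment(self):
        self._align = []
        for ds in self.datasets:
            rows = []
            times = np.asarray(ds.config.record_times)
            for rec in ds.measurements.data.itertuples():
                t_idx = int(np.argmin(np.abs(times - rec.time_min)))
                if abs(times[t_idx] - rec.time_min) > 1e-9:
                    raise ValueError(
                        f"{ds.name}: measurement time {rec.time_min} not on grid"
                    )
                met = ds.analyte_map.get(rec.metabolite, rec.metabolite)
                q = rec.quantity
                if q == "conc":
                    kind, k = "conc", 0
                elif q.startswith("M"):
                    kind, k = "mid", int(q[1:])
                else:
                    raise ValueError(f"unknown quantity {q!r}")
                rows.append((t_idx, met, kind, k, float(rec.value), float(rec.sigma)))
            self._align.append(rows)

    # -- residuals ---------------------------------------------------------

    def residuals(self, x: np.ndarray) -> np.ndarray:
        out = []
        for ds, rows in zip(self.datasets, self._align):
            try:
                traj = self.simulator.run(
                    self.fluxes_for(ds, x),
                    self.initial_conc_for(ds, x),
                    ds.label_input,
                    ds.config,
                    ds.initial_pool_labelling,
                )
            except (StepInstabilityError, LabellingError, ValueError):
                out.append(np.full(len(rows), _PENALTY))
                continue
            res = np.empty(len(rows))
            for j, (t_idx, met, kind, k, value, sigma) in enumerate(rows):
                if kind == "conc":
                    if met in traj.pool_conc:
                        pred = traj.pool_conc[met][t_idx]
                    else:
                        pred = traj.source_conc[met][t_idx]
                else:
                    pred = traj.pool_mid[met][t_idx, k]
                res[j] = (pred - value) / sigma
            out.append(res)
        return np.concatenate(out) if out else np.zeros(0)

    def dataset_ssrs(self, x: np.ndarray) -> dict[str, float]:
        res = self.residuals(x)
        out = {}
        pos = 0
        for ds, rows in zip(self.datasets, self._align):
            out[ds.name] = float(np.sum(res[pos:pos + len(rows)] ** 2))
            pos += len(rows)
        return out

    # -- problem surgery -----------------------------------------------------

    def with_sharing(self, names: list[str], shared: bool) -> "FitProblem":
        params = [
            replace(p, shared=shared) if p.name in names else copy.copy(p)
            for p in self.parameters
        ]
        return self._rebuild(parameters=params)

    def with_fixed(self, name: str, value: float) -> "FitProblem":
        """Fix one parameter at `value`; used by profiling.

        ``name`` may be a bare parameter name (fixes it everywhere) or
        ``"name[dataset]"`` (fixes that dataset's copy only).
        """
        base, _, dsn = name.partition("[")
        dsn = dsn.rstrip("]") if dsn else None
        params = []
        for p in self.parameters:
            if p.name != base:
                params.append(copy.copy(p))
            elif dsn is None:
                params.append(replace(p, value=float(value)))
            else:
                params.append(replace(
                    p, fixed_per_dataset={**p.fixed_per_dataset, dsn: float(value)},
                ))
        return self._rebuild(parameters=params)

    def with_measurements(self, new: dict[str, MeasurementSet]) -> "FitProblem":
        datasets = [
            replace(ds, measurements=new.get(ds.name, ds.measurements))
            for ds in self.datasets
        ]
        return self._rebuild(datasets=datasets)

    def _rebuild(self, parameters=None, datasets=None) -> "FitProblem":
        clone = object.__new__(FitProblem)
        clone.model = self.model
        clone.datasets = datasets if datasets is not None else self.datasets
        clone.parameters = parameters if parameters is not None else self.parameters
        clone.base_fluxes = self.base_fluxes
        clone.basis = self.basis
        clone.simulator = self.simulator  # compiled EMU machinery is reusable
        clone._build_packing()
        clone._build_alignment()
        return clone


def weighted_ssr(x, problem: FitProblem) -> float:
    """Weighted residual sum of squares at parameter vector (or dict) `x`."""
    if isinstance(x, dict):
        vec = np.array([x[name] for name in problem.param_names])
    else:
        vec = np.asarray(x, dtype=float)
    return float(np.sum(problem.residuals(vec) ** 2))


def estimate(problem: FitProblem, n_starts: int = 10, seed: int = 0,
             x0: np.ndarray | None = None, xtol: float = 1e-10,
             ftol: float = 1e-12, identifiability_check: bool = True) -> FitResult:
    """Bound-constrained nonlinear least squares with seeded multi-start.

    Starts are the problem defaults (plus ``x0`` if given) and a Latin
    hypercube over the bounds; the best of all converged starts is
    returned.  Deterministic given ``seed``.
    """
    lo, hi = problem.bounds
    starts = [problem.default_x()]
    if x0 is not None:
        starts.insert(0, np.asarray(x0, dtype=float))
    n_lhs = max(0, n_starts - len(starts))
    if n_lhs:
        sampler = qmc.LatinHypercube(d=len(lo), seed=seed)
        span_hi = np.where(np.isfinite(hi), hi, np.maximum(10 * np.abs(lo), 10.0))
        starts.extend(lo + sampler.random(n_lhs) * (span_hi - lo))

    best = None
    start_ssrs = []
    nfev = 0
    for s in starts:
        s = np.clip(s, lo, hi)
        try:
            res = least_squares(
                problem.residuals, s, bounds=(lo, hi), method="trf",
                xtol=xtol, ftol=ftol, gtol=1e-12,
            )
        except Exception:
            start_ssrs.append(np.inf)
            continue
        ssr = float(2 * res.cost)
        start_ssrs.append(ssr)
        nfev += res.nfev
        if best is None or ssr < float(2 * best.cost):
            best = res
    if best is None:
        raise RuntimeError("all optimisation starts failed")

    weak = []
    if identifiability_check and best.jac is not None and best.jac.size:
        try:
            _, sv, vt = np.linalg.svd(best.jac, full_matrices=False)
            for k in range(len(sv)):
                if sv[k] < 1e-6 * max(sv[0], 1e-30):
                    weak.append(problem.param_names[int(np.argmax(np.abs(vt[k])))])
        except np.linalg.LinAlgError:
            pass
        if weak:
            warnings.warn(
                f"weakly identified parameter directions: {sorted(set(weak))}",
                stacklevel=2,
            )

    x = best.x
    return FitResult(
        names=list(problem.param_names),
        x=x,
        ssr=float(2 * best.cost),
        per_dataset_ssr=problem.dataset_ssrs(x),
        n_starts=len(starts),
        start_ssrs=start_ssrs,
        nfev=nfev,
        success=bool(best.success),
        weakly_identified=sorted(set(weak)),
    )


@dataclass
class ProfileCI:
    parameter: str
    estimate: float
    lower: float
    upper: float
    threshold: float
    lower_at_bound: bool = False
    upper_unbounded: bool = False

    def to_ratio(self) -> "ProfileCI":
        """Transform a CI on the exchange transform u to the ratio r = u/(1-u)."""
        conv = lambda u: u_to_ratio(min(u, U_CAP))
        return ProfileCI(
            self.parameter, conv(self.estimate), conv(self.lower), conv(self.upper),
            self.threshold, self.lower_at_bound, self.upper_unbounded,
        )


def _profile_ssr(problem: FitProblem, result: FitResult, name: str,
                 value: float, warm: np.ndarray | None, refit_kwargs) -> tuple[float, np.ndarray]:
    fixed = problem.with_fixed(name, value)
    if not fixed.entries:  # nothing left to optimise
        return weighted_ssr(np.zeros(0), fixed), np.zeros(0)
    x0 = warm
    if x0 is None:
        x0 = np.array([
            result.x[result.names.index(n)] for n in fixed.param_names
        ])
    r = estimate(fixed, n_starts=1, x0=x0, identifiability_check=False,
                 **refit_kwargs)
    return r.ssr, r.x


def profile_ci(problem: FitProblem, result: FitResult, parameter: str,
               threshold: float = CHI2_95_1DOF, tol_rel: float = 1e-3,
               refit_kwargs: dict | None = None) -> ProfileCI:
    """Chi-square profile confidence interval for one shared parameter.

    All other parameters are re-optimised at each fixed value; the bound
    is where the profiled SSR exceeds SSR_min + threshold, located by
    geometric bracketing and bisection (tolerance ``tol_rel`` of the
    parameter scale).  An upper bound that runs into the exchange
    transform cap (r ~ 1e4) is flagged unbounded; a lower bound resting
    on the parameter's lower bound is flagged ``lower_at_bound``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    refit_kwargs = refit_kwargs or {}
    try:
        idx = problem.param_names.index(parameter)
    except ValueError:
        raise KeyError(f"{parameter} is not an optimised parameter") from None
    theta = float(result.x[idx])
    if threshold == 0:
        return ProfileCI(parameter, theta, theta, theta, 0.0)
    p = next(pp for pp in problem.parameters if pp.name == parameter.split("[")[0])
    lo, hi = p.bounds
    target = result.ssr + threshold
    scale = max(abs(theta), (hi - lo) / 20 if np.isfinite(hi - lo) else 1.0, 1e-6)
    tol = tol_rel * scale

    def crossing(direction: int):
        bound = hi if direction > 0 else lo
        step = 0.2 * scale
        inside, warm = theta, None
        while True:
            candidate = inside + direction * step
            hit_bound = (candidate >= bound) if direction > 0 else (candidate <= bound)
            if hit_bound:
                candidate = bound
            ssr, warm = _profile_ssr(problem, result, parameter, candidate, warm,
                                     refit_kwargs)
            if ssr > target:
                outside = candidate
                break
            inside = candidate
            if hit_bound:
                return bound, True  # SSR never exceeds the threshold: bound hit
            step *= 1.8
        # bisect between inside and outside
        while abs(outside - inside) > tol:
            mid = 0.5 * (inside + outside)
            ssr, warm = _profile_ssr(problem, result, parameter, mid, warm, refit_kwargs)
            if ssr > target:
                outside = mid
            else:
                inside = mid
        return 0.5 * (inside + outside), False

    lower, lower_hit = crossing(-1)
    upper, upper_hit = crossing(+1)
    upper_unbounded = upper_hit and p.kind == "exchange_u" and upper >= U_CAP - 1e-9
    return ProfileCI(
        parameter, theta, lower, upper, threshold,
        lower_at_bound=lower_hit, upper_unbounded=upper_unbounded or upper_hit,
    )


@dataclass
class SharedRatioTest:
    shared: FitResult
    separate: FitResult
    delta_ssr: float
    threshold: float

    @property
    def different_required(self) -> bool:
        """True when forcing the parameters equal degrades the fit by more
        than the chi-square criterion — separate values are required."""
        return self.delta_ssr > self.threshold


def joint_fit_shared(problem: FitProblem, shared_parameters: list[str],
                     threshold: float = CHI2_95_1DOF, n_starts: int = 6,
                     seed: int = 0, **fit_kwargs) -> SharedRatioTest:
    """Compare a joint fit sharing `shared_parameters` against per-dataset copies.

    Fits the pooled residuals twice — once with the named parameters
    shared across datasets, once with independent per-dataset copies —
    and reports ΔSSR = SSR_shared − SSR_separate.
    """
    for name in shared_parameters:
        if not any(p.name == name for p in problem.parameters):
            raise KeyError(f"unknown parameter {name}")
    prob_sep = problem.with_sharing(shared_parameters, shared=False)
    prob_sha = problem.with_sharing(shared_parameters, shared=True)
    res_sep = estimate(prob_sep, n_starts=n_starts, seed=seed, **fit_kwargs)
    # warm-start the shared fit from the separate optimum (averaging copies)
    x0 = []
    sep = res_sep.params
    for name in prob_sha.param_names:
        if name in sep:
            x0.append(sep[name])
        else:
            copies = [v for k, v in sep.items() if k.split("[")[0] == name]
            x0.append(float(np.mean(copies)))
    res_sha = estimate(prob_sha, n_starts=n_starts, seed=seed,
                       x0=np.array(x0), **fit_kwargs)
    delta = res_sha.ssr - res_sep.ssr
    return SharedRatioTest(res_sha, res_sep, float(delta), threshold)


@dataclass
class MonteCarloResult:
    standard_errors: dict[str, float]
    replicates: pd.DataFrame
    n_requested: int
    n_failed: int


def monte_carlo_errors(problem: FitProblem, result: FitResult, n: int = 50,
                       seed: int = 0, max_failure_fraction: float = 0.2,
                       **fit_kwargs) -> MonteCarloResult:
    """Parameter standard errors by in-silico replication.

    Each replicate corrupts every measured value with a Gaussian draw
    at its own sigma, re-estimates from the optimum as the start, and
    the standard errors are the standard deviations over replicates.
    Deterministic given ``seed``; aborts if more than
    ``max_failure_fraction`` of replicates fail.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for rep in range(n):
        perturbed = {
            ds.name: _corrupt(ds.measurements, rng) for ds in problem.datasets
        }
        prob = problem.with_measurements(perturbed)
        try:
            r = estimate(prob, n_starts=1, x0=result.x,
                         identifiability_check=False, **fit_kwargs)
            rows.append({"replicate": rep, "ssr": r.ssr, **r.params})
        except Exception:
            n_failed += 1
    if n_failed > max_failure_fraction * n:
        raise RuntimeError(
            f"{n_failed}/{n} Monte Carlo replicates failed to converge"
        )
    df = pd.DataFrame(rows)
    ses = {
        name: float(df[name].std(ddof=1)) for name in problem.param_names
    }
    return MonteCarloResult(ses, df, n, n_failed)


def _corrupt(ms: MeasurementSet, rng: np.random.Generator) -> MeasurementSet:
    # plain Gaussian corruption per measured value, each with its own
    # sigma; no renormalisation, so the corruption matches the error
    # model the objective weights assume
    df = ms.data.copy()
    df["value"] = df["value"] + rng.normal(0.0, df["sigma"].to_numpy())
    return MeasurementSet(ms.label, df, dict(ms.meta))


def classify_reversibility(r: float, lower: float, upper: float,
                           irreversible_max: float = 0.05,
                           reversible_min: float = REVERSIBILITY_PRESETS["text"],
                           upper_unbounded: bool = False) -> str:
    """Label a reaction from its reversibility ratio and profile CI.

    A reaction is irreversible when the whole CI sits at or below
    ``irreversible_max`` (0.05), fully reversible when the whole CI sits
    at or above ``reversible_min`` (20 in the text, 25 in the figure
    preset), partially reversible when the CI lies strictly between, and
    indeterminate when the CI straddles a cut-off.
    """
    hi = np.inf if upper_unbounded else upper
    if not (lower <= r <= hi):
        raise ValueError("CI must contain the estimate")
    if hi <= irreversible_max:
        return "irreversible"
    if lower >= reversible_min:
        return "fully reversible"
    if lower > irreversible_max and hi < reversible_min:
        return "partially reversible"
    return "indeterminate"
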