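"""In-silico tracer experiments with the statistical structure the fit assumes.

The generator reproduces the study designs end to end: a flux state on
the central-carbon fixture network, a hybrid time-course simulation,
sampling at the experimental cadence, and Gaussian measurement noise —
sigma 0.01 on every enrichment fraction and a calibration-curve-derived
sigma on every concentration.  Presets:

* ``FM`` / ``EM`` — HEK293 fresh-medium vs existing-medium designs:
  initial extracellular lactate ~1 vs ~10 mM, labelled-glucose
  fractions 46.9 % vs 71.7 %, samples every 30 min for 3 h, 1-min
  Euler steps.
* ``PANC_control`` / ``PANC_TNF`` — PANC-1 designs: high-glucose medium
  with essentially pure [U-13C6]-glucose, hourly samples for 5 h,
  2-min steps.

Default true fluxes are physiologically shaped scenario parameters
(glycolysis at pyruvate kinase ~1.2, malic-enzyme entry ~0.4, net
lactate efflux ~0.8 µM/h/µg protein) — an order-of-magnitude choice,
not a reproduction of any fitted value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .fluxes import FluxState
from .hybrid_dynamics import HybridSimulator, SimulationConfig
from .label_simulation import LabelInput
from .measurement_model import (
    ENRICHMENT_SIGMA,
    CalibrationCurve,
    MeasurementSet,
    correction_matrix,
    MAB_FRAGMENTS,
    fit_calibration,
)
from .network_model import NetworkModel, free_flux_basis, parse_model

__all__ = [
    "ExperimentDesign",
    "GroundTruth",
    "Fixture",
    "PRESETS",
    "ANALYTE_TO_POOL",
    "load_fixture_model",
    "fixture_model_text",
    "central_true_fluxes",
    "central_label_input",
    "make_calibration",
    "generate",
    "make_fixture_suite",
    "draw_random_fluxes",
]

#: measurement-table analyte names -> central-model metabolites
ANALYTE_TO_POOL = {"lactate": "LAC_x", "pyruvate": "PYR_x", "glucose": "GLC_x"}
POOL_TO_ANALYTE = {v: k for k, v in ANALYTE_TO_POOL.items()}


def fixture_model_text(name: str) -> str:
    ref = resources.files("leakyflux.fixtures").joinpath(f"{name}.tsv")
    return ref.read_text()


def load_fixture_model(name: str) -> NetworkModel:
    """Load a bundled fixture network: chain, condensation, diamond, central_carbon."""
    return parse_model(fixture_model_text(name))


@dataclass
class ExperimentDesign:
    """Conditions of one tracer experiment."""

    preset: str
    initial_conc: dict[str, float]  # mM per pool/tracked source
    glucose_labelled_fraction: float
    sample_times: tuple[float, ...]  # minutes
    step_min: float = 1.0
    protein_ug: float = 150.0
    enrichment_sigma: float = ENRICHMENT_SIGMA
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.glucose_labelled_fraction <= 1.0:
            raise ValueError("glucose labelled fraction must lie in [0, 1]")

    @property
    def horizon_min(self) -> float:
        return max(self.sample_times)

    def sim_config(self, step_min: float | None = None) -> SimulationConfig:
        return SimulationConfig.for_culture(
            horizon_min=self.horizon_min,
            step_min=step_min or self.step_min,
            protein_ug=self.protein_ug,
            record_times=self.sample_times,
        )


_HEK_TIMES = tuple(float(t) for t in range(0, 181, 30))
_PANC_TIMES = tuple(float(t) for t in range(0, 301, 60))

PRESETS: dict[str, ExperimentDesign] = {
    # fresh medium: residual lactate low, glucose spike dilutes into fresh
    # DMEM glucose -> 46.9 % labelled
    "FM": ExperimentDesign(
        "FM",
        {"LAC_x": 1.0, "PYR_x": 0.10, "GLC_x": 11.1},
        0.469,
        _HEK_TIMES,
        step_min=1.0,
    ),
    # existing medium: accumulated lactate ~10 mM, partially depleted
    # glucose topped up with tracer -> 71.7 % labelled
    "EM": ExperimentDesign(
        "EM",
        {"LAC_x": 10.0, "PYR_x": 0.15, "GLC_x": 7.7},
        0.717,
        _HEK_TIMES,
        step_min=1.0,
    ),
    "PANC_control": ExperimentDesign(
        "PANC_control",
        {"LAC_x": 2.0, "PYR_x": 0.10, "GLC_x": 25.0},
        0.99,
        _PANC_TIMES,
        step_min=2.0,
        protein_ug=100.0,
    ),
    "PANC_TNF": ExperimentDesign(
        "PANC_TNF",
        {"LAC_x": 2.0, "PYR_x": 0.10, "GLC_x": 25.0},
        0.99,
        _PANC_TIMES,
        step_min=2.0,
        protein_ug=100.0,
    ),
}


def central_true_fluxes(hk: float = 0.65, ppp: float = 0.05, gls: float = 0.4,
                        net_lactate: float = 0.8, net_pyruvate: float = 0.05,
                        lactate_exchange_ratio: float = 4.0,
                        pyruvate_exchange_ratio: float = 4.0,
                        ldh_exchange: float = 10.0) -> FluxState:
    """Steady-state-consistent flux scenario for the central fixture.

    Units µM/h/µg protein.  Glycolysis at PK = 2*(hk - ppp); mitochondrial
    uptake PT closes the pyruvate balance; ME1 = GLS by TCA bookkeeping.
    """
    pk = 2.0 * (hk - ppp)
    pt = pk + gls - net_lactate - net_pyruvate
    if min(hk, ppp, gls, pt) < 0 or pk <= 0:
        raise ValueError("infeasible scenario: a net flux would be negative")
    cs = pt
    net = {
        "HK": hk, "PPP": ppp, "P5PX": ppp, "EMP": hk - ppp, "PK": pk,
        "LDH": net_lactate, "LACX": net_lactate, "PYRX": net_pyruvate,
        "PT": pt, "PDH": pt, "CS": cs, "IDH": cs, "AKGDH": cs + gls,
        "SDH": cs + gls, "FH": cs + gls, "MDH": cs, "ME1": gls, "GLS": gls,
    }
    exchange = {
        "LDH": ldh_exchange,
        "LACX": lactate_exchange_ratio * abs(net_lactate),
        "PYRX": pyruvate_exchange_ratio * abs(net_pyruvate),
    }
    return FluxState(net, exchange)


def central_label_input(glucose_labelled_fraction: float,
                        natural_p: float = 0.0) -> LabelInput:
    """Boundary labelling for the central fixture: glucose mixture of
    [U-13C6] tracer and unlabelled glucose; glutamine and CO2 unlabelled."""
    model = load_fixture_model("central_carbon")
    f = glucose_labelled_fraction
    return LabelInput.from_patterns(
        model,
        {
            "GLC_x": [(f, "U"), (1.0 - f, "0")],
            "GLN_x": [(1.0, "0")],
            "CO2": [(1.0, "0")],
        },
        natural_p=natural_p,
    )


# synthetic calibration designs per analyte: (range mM, slope per mM,
# response noise sd).  Ranges follow the cell-culture standard series;
# the noise levels keep pyruvate/lactate tightly linear (r² > 0.985) and
# glucose visibly noisier, as in the real chromatography.
_CALIBRATION_DESIGNS = {
    "pyruvate": (np.array([0.25, 0.5, 1.0, 1.5, 2.0]), 0.55, 0.008),
    "lactate": (np.array([1.25, 2.5, 5.0, 7.5, 10.0]), 0.50, 0.030),
    "glucose": (np.array([2.5, 5.0, 10.0, 15.0, 20.0]), 0.20, 0.060),
}


def make_calibration(metabolite: str, seed: int = 0,
                     duplicates: int = 2) -> tuple[pd.DataFrame, CalibrationCurve]:
    """Synthetic calibration standards and their fitted curve."""
    conc, slope, sd = _CALIBRATION_DESIGNS[metabolite]
    rng = np.random.default_rng(seed)
    rows = []
    for c in np.repeat(conc, duplicates):
        rows.append(
            {"metabolite": metabolite, "mM": c,
             "response": slope * c + rng.normal(0.0, sd)}
        )
    df = pd.DataFrame(rows)
    curve = fit_calibration(df[["mM", "response"]].to_numpy(), metabolite)
    return df, curve


@dataclass
class GroundTruth:
    """Everything needed to reproduce a synthetic dataset bit-for-bit."""

    design: ExperimentDesign
    fluxes: FluxState
    seed: int
    model_name: str = "central_carbon"
    conc_sigma: dict[str, float] = field(default_factory=dict)
    raw_spectra: bool = False

    @property
    def lactate_reversibility_ratio(self) -> float:
        return self.fluxes.reversibility_ratio("LACX")


def generate(design: ExperimentDesign, true_fluxes: FluxState,
             seed: int | None = None, model: NetworkModel | None = None,
             step_min: float | None = None, raw_spectra: bool = False,
             simulator: HybridSimulator | None = None, add_noise: bool = True,
             ) -> tuple[MeasurementSet, GroundTruth]:
    """Simulate one experiment and corrupt it with the design's noise model.

    Enrichment fractions get independent Gaussian noise (sigma 0.01);
    concentrations get noise with the sigma of the analyte's synthetic
    calibration curve.  ``raw_spectra=True``
    additionally pushes each MID through the fragment correction matrix
    so the measurement-correction stage is exercised downstream (rows
    then carry quantity "rawM<i>").  ``add_noise=False`` keeps the error
    model (sigma columns) but emits exact simulated values.
    Deterministic given ``seed``.
    """
    seed = design.seed if seed is None else seed
    if seed is None:
        raise ValueError("a seed is required (no wall-clock seeding)")
    rng = np.random.default_rng(seed)

    def noise(sd, size=None):
        draw = rng.normal(0.0, sd, size)
        return draw if add_noise else np.zeros_like(np.asarray(draw, dtype=float))

    model = model or load_fixture_model("central_carbon")
    label_input = central_label_input(design.glucose_labelled_fraction)
    config = design.sim_config(step_min)
    sim = simulator or HybridSimulator(model)
    traj = sim.run(true_fluxes, dict(design.initial_conc), label_input, config)

    conc_sigma = {
        analyte: make_calibration(analyte, seed=0)[1].concentration_sigma
        for analyte in ANALYTE_TO_POOL
    }

    rows = []
    for pool in model.pools:
        analyte = POOL_TO_ANALYTE.get(pool, pool)
        mids = traj.pool_mid[pool]
        conc = traj.pool_conc[pool]
        n = model.metabolites[pool].carbon_count
        for k, t in enumerate(traj.times):
            mid = mids[k].copy()
            if raw_spectra:
                mat = correction_matrix(MAB_FRAGMENTS[analyte])
                # observed window of the derivatized fragment spectrum
                obs = mat @ mid
                vals = obs + noise(design.enrichment_sigma, n + 1)
                for i in range(n + 1):
                    rows.append({"time_min": t, "metabolite": analyte,
                                 "quantity": f"rawM{i}", "value": vals[i],
                                 "sigma": design.enrichment_sigma})
            else:
                # independent Gaussian per fraction, matching the uniform
                # 0.01 weighting the objective assumes; no clipping or
                # renormalisation — either would correlate the errors and
                # bias near-zero fractions
                noisy = mid + noise(design.enrichment_sigma, n + 1)
                for i in range(n + 1):
                    rows.append({"time_min": t, "metabolite": analyte,
                                 "quantity": f"M{i}", "value": noisy[i],
                                 "sigma": design.enrichment_sigma})
            sigma_c = conc_sigma.get(analyte, 0.05)
            rows.append({"time_min": t, "metabolite": analyte, "quantity": "conc",
                         "value": conc[k] + noise(sigma_c),
                         "sigma": sigma_c})
    for src, conc in traj.source_conc.items():
        analyte = POOL_TO_ANALYTE.get(src, src)
        sigma_c = conc_sigma.get(analyte, 0.05)
        for k, t in enumerate(traj.times):
            rows.append({"time_min": t, "metabolite": analyte, "quantity": "conc",
                         "value": conc[k] + noise(sigma_c),
                         "sigma": sigma_c})

    ms = MeasurementSet(
        design.preset,
        pd.DataFrame(rows),
        meta={"seed": seed, "preset": design.preset},
    )
    truth = GroundTruth(replace(design, seed=seed), true_fluxes, seed,
                        conc_sigma=conc_sigma, raw_spectra=raw_spectra)
    return ms, truth


# ---------------------------------------------------------------------------
# fixture suite


@dataclass
class Fixture:
    name: str
    model: NetworkModel
    model_text: str
    true_fluxes: FluxState
    label_input: LabelInput
    designs: dict[str, ExperimentDesign] = field(default_factory=dict)


def make_fixture_suite() -> dict[str, Fixture]:
    """Bundled toy networks and designs with documented ground truth."""
    suite = {}

    chain = load_fixture_model("chain")
    suite["chain"] = Fixture(
        "chain", chain, fixture_model_text("chain"),
        FluxState({"upt": 1.0, "conv": 1.0, "exp": 1.0}),
        LabelInput.from_patterns(chain, {"S": [(0.5, "U"), (0.5, "0")]}),
    )

    cond = load_fixture_model("condensation")
    suite["condensation"] = Fixture(
        "condensation", cond, fixture_model_text("condensation"),
        FluxState({"f1": 1.0, "f2": 1.0, "cond": 1.0, "cleave": 0.6,
                   "expC": 0.4, "expD": 0.6, "expE": 0.6}),
        LabelInput.from_patterns(
            cond, {"X": [(0.5, "U"), (0.5, "0")], "Y": [(0.3, "U"), (0.7, "0")]}
        ),
    )

    diamond = load_fixture_model("diamond")
    suite["diamond"] = Fixture(
        "diamond", diamond, fixture_model_text("diamond"),
        FluxState({"in": 1.0, "b1": 0.7, "b2": 0.3, "c1": 0.7, "c2": 0.3,
                   "out": 1.0}),
        LabelInput.from_patterns(diamond, {"S": [(0.6, "10"), (0.4, "0")]}),
    )

    central = load_fixture_model("central_carbon")
    suite["central_carbon"] = Fixture(
        "central_carbon", central, fixture_model_text("central_carbon"),
        central_true_fluxes(),
        central_label_input(PRESETS["FM"].glucose_labelled_fraction),
        designs=dict(PRESETS),
    )
    return suite


def neutral_base_fluxes() -> FluxState:
    """Starting/fixed flux values for fitting the central model.

    Carries the known fixed quantities (PPP flux, fast LDH exchange) at
    their scenario values and deliberately generic values for everything
    the fit estimates.
    """
    return central_true_fluxes(
        hk=0.5, ppp=0.05, gls=0.2, net_lactate=0.4, net_pyruvate=0.08,
        lactate_exchange_ratio=1.0, pyruvate_exchange_ratio=1.0,
        ldh_exchange=10.0,
    )


def build_fit_problem(measurements: dict[str, MeasurementSet],
                      model: NetworkModel | None = None,
                      step_min: float = 6.0,
                      free_fluxes: tuple[str, ...] = ("LACX", "PYRX", "MDH", "GLS"),
                      exchange_params: tuple[str, ...] = ("LACX", "PYRX"),
                      per_dataset_exchange: tuple[str, ...] = ("LACX",),
                      init_conc_params: tuple[str, ...] = ("LAC_x", "PYR_x", "GLC_x"),
                      base_fluxes: FluxState | None = None,
                      flux_bounds: tuple[float, float] = (0.01, 5.0),
                      conc_bounds: tuple[float, float] = (0.005, 40.0)):
    """Standard FM/EM-style fit problem on the central fixture network.

    ``measurements`` maps preset names (keys of :data:`PRESETS`) to
    measurement sets.  All fluxes are shared across datasets except the
    exchanges named in ``per_dataset_exchange`` (the lactate exchange,
    by default), mirroring the assumption of identical pyruvate
    producing/consuming fluxes between parallel experiments.  The PPP
    flux and the (series) LDH exchange are fixed at their base values:
    neither is identifiable from extracellular lactate, pyruvate and
    glucose alone.
    """
    from .flux_fit import DatasetSpec, FitProblem, Parameter

    model = model or load_fixture_model("central_carbon")
    base = base_fluxes or neutral_base_fluxes()
    datasets = []
    for preset, ms in measurements.items():
        design = PRESETS[preset]
        datasets.append(DatasetSpec(
            name=preset,
            measurements=ms,
            config=design.sim_config(step_min),
            label_input=central_label_input(design.glucose_labelled_fraction),
            initial_conc=dict(design.initial_conc),
            analyte_map=dict(ANALYTE_TO_POOL),
        ))
    params = [
        Parameter(f"v_{r}", "free_flux", r, flux_bounds) for r in free_fluxes
    ]
    params += [
        Parameter(f"u_{r}", "exchange_u", r, (0.0, 1.0),
                  shared=(r not in per_dataset_exchange))
        for r in exchange_params
    ]
    params += [
        Parameter(f"c0_{met}", "init_conc", met, conc_bounds, shared=False)
        for met in init_conc_params
    ]
    return FitProblem(model, datasets, params, base)


def draw_random_fluxes(model: NetworkModel, rng: np.random.Generator,
                       lo: float = 0.2, hi: float = 2.0,
                       exchange_max_ratio: float = 3.0,
                       min_net: float = 0.02, max_tries: int = 2000) -> FluxState:
    """Draw a random feasible flux state (rejection sampling on free fluxes).

    Net fluxes of irreversible reactions must stay >= ``min_net`` so the
    labelling system is well-posed; reversible reactions get a random
    exchange up to ``exchange_max_ratio`` times their net flux.
    """
    basis = free_flux_basis(model)
    irreversible = {r.id for r in model.reactions if not r.reversible}
    for _ in range(max_tries):
        free = {r: rng.uniform(lo, hi) for r in basis.free_reactions}
        net = basis.expand(free)
        if all(v >= min_net for rid, v in net.items() if rid in irreversible):
            exchange = {
                rid: rng.uniform(0.0, exchange_max_ratio) * abs(net[rid])
                for rid in model.reversible_reactions
            }
            return FluxState(net, exchange)
    raise RuntimeError("could not draw a feasible flux state")
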