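"""Pseudo-experimental datasets for the tailings-dissolution culture.

The validation experiment measured microbial density, dissolved Ca2+ and
Mg2+, and pH over time in a static 200 mL culture.  This module samples the
simulated culture at a measurement cadence and corrupts it with a simple
noise model — multiplicative lognormal for the positive observables
(median-parameterised, so the median trajectory is unbiased) and additive
Gaussian for pH — giving datasets with the statistical shape of the real
measurements so that calibration and parameter-recovery experiments are
fully testable offline.  It deliberately does not emulate instrument
artifacts (drift, detection limits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .microbes import calibrate_mu_max
from .params import deep_merge, load_organism, load_scenario
from .reactors import SolverSettings, run_validation_scenario

OBSERVABLE_COLUMNS = {
    "biomass": "biomass_mg_L",
    "ca": "ca_mol_L",
    "mg": "mg_mol_L",
    "ph": "ph",
}


@dataclass
class NoiseModel:
    """Measurement-noise description for the synthetic datasets.

    ``sigma`` is the lognormal shape parameter for concentrations/biomass
    (so sigma = 0.05 is ~5 % multiplicative noise) and the absolute standard
    deviation for pH.  ``missingness`` is the fraction of scheduled samples
    dropped at random.
    """

    sigma: dict = field(default_factory=lambda: {
        "biomass": 0.05, "ca": 0.05, "mg": 0.05, "ph": 0.05})
    sampling_times_h: np.ndarray = field(
        default_factory=lambda: np.arange(24.0, 504.0, 24.0))
    seed: int = 0
    missingness: float = 0.0

    def __post_init__(self):
        times = np.asarray(self.sampling_times_h, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if any(s < 0 for s in self.sigma.values()):
            raise ValueError("noise sigmas must be non-negative")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must be in [0, 1)")
        self.sampling_times_h = times


@dataclass
class SyntheticDataset:
    """Tidy synthetic measurements plus the generating truth."""

    data: pd.DataFrame            # time_h, observable, value, replicate
    true_params: dict             # e.g. {"mu_max": ...}
    noise: NoiseModel
    config: dict                  # scenario configuration used


def _simulate_trajectory(config, mu_max, radius_m, solver=None):
    scenario = load_scenario("validation", config)
    oxidizer = load_organism(scenario.get("organism", "validation_oxidizer"),
                             {"validation_oxidizer": {"mu_max": mu_max},
                              "oxidizer": {"mu_max": mu_max}})
    horizon = scenario["culture"]["horizon_h"]
    results = run_validation_scenario(
        scenario, oxidizer=oxidizer, radii_m=[radius_m],
        horizon_h=horizon, solver=solver)
    return results[radius_m].series


def generate(config=None, true_params=None, noise=None, *,
             radius_m=50e-6, n_replicates=1, solver=None):
    """Run the validation culture at the true parameters and sample it.

    Lognormal multiplicative noise on biomass/Ca/Mg, additive Gaussian on
    pH, then random missingness; reproducible from ``noise.seed``.
    """
    config = config or {}
    true_params = dict(true_params or {})
    noise = noise or NoiseModel()
    mu_max = true_params.setdefault(
        "mu_max", load_organism("validation_oxidizer").mu_max)
    series = _simulate_trajectory(config, mu_max, radius_m, solver)
    rng = np.random.default_rng(noise.seed)

    times = noise.sampling_times_h
    rows = []
    for rep in range(n_replicates):
        for obs, column in OBSERVABLE_COLUMNS.items():
            truth = np.interp(times, series["time_h"], series[column])
            sigma = noise.sigma.get(obs, 0.0)
            if sigma > 0:
                if obs == "ph":
                    values = truth + rng.normal(0.0, sigma, truth.size)
                else:
                    values = truth * rng.lognormal(0.0, sigma, truth.size)
            else:
                values = truth.copy()
            keep = np.ones(truth.size, dtype=bool)
            if noise.missingness > 0:
                keep = rng.random(truth.size) >= noise.missingness
            for t, v in zip(times[keep], values[keep]):
                rows.append({"time_h": t, "observable": obs,
                             "value": float(np.clip(v, 0.0, None)
                                            if obs != "ph" else v),
                             "replicate": rep})
    data = pd.DataFrame(rows)
    return SyntheticDataset(data=data, true_params=true_params, noise=noise,
                            config=config)


def write_dataset(dataset, csv_path):
    """CSV with a YAML provenance header sidecar (.yaml next to the CSV)."""
    import yaml

    dataset.data.to_csv(csv_path, index=False)
    sidecar = str(csv_path) + ".yaml"
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"true_params": dataset.true_params,
                        "seed": dataset.noise.seed,
                        "sigma": dataset.noise.sigma,
                        "missingness": dataset.noise.missingness,
                        "config_overrides": dataset.config}, fh)


def fit_mu_max(dataset, *, radius_m=50e-6, solver=None, bounds=(1e-3, 0.1),
               **kwargs):
    """Calibrate mu_max against a dataset's biomass observations."""
    biomass = dataset.data.query("observable == 'biomass'")
    grouped = biomass.groupby("time_h")["value"].mean()
    times = grouped.index.to_numpy()
    observed = grouped.to_numpy()

    def model(mu):
        series = _simulate_trajectory(dataset.config, mu, radius_m, solver)
        return np.interp(times, series["time_h"], series["biomass_mg_L"])

    return calibrate_mu_max(times, observed, model, bounds=bounds, **kwargs)


def recovery_experiment(true_mu_max, noise=None, n_replicates=5, seed=0, *,
                        config=None, radius_m=50e-6, solver=None,
                        bounds=(1e-3, 0.1)):
    """generate -> calibrate round trip; reports bias, RMSE and coverage.

    Each replicate gets an independent noise seed derived from ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    base_noise = noise or NoiseModel()
    estimates, covered = [], 0
    for rep in range(n_replicates):
        rep_noise = NoiseModel(
            sigma=dict(base_noise.sigma),
            sampling_times_h=base_noise.sampling_times_h.copy(),
            seed=int(np.random.default_rng([seed, rep]).integers(2 ** 31)),
            missingness=base_noise.missingness)
        dataset = generate(config, {"mu_max": true_mu_max}, rep_noise,
                           radius_m=radius_m, solver=solver)
        fit = fit_mu_max(dataset, radius_m=radius_m, solver=solver,
                         bounds=bounds)
        estimates.append(fit.mu_max)
        if fit.interval[0] <= true_mu_max <= fit.interval[1]:
            covered += 1
    estimates = np.asarray(estimates)
    return {
        "true_mu_max": true_mu_max,
        "estimates": estimates,
        "bias": float(estimates.mean() - true_mu_max),
        "rmse": float(np.sqrt(np.mean((estimates - true_mu_max) ** 2))),
        "coverage": covered / n_replicates,
    }


__all__ = ["NoiseModel", "SyntheticDataset", "generate", "write_dataset",
           "fit_mu_max", "recovery_experiment", "OBSERVABLE_COLUMNS"]
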