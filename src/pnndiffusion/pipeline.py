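"""High-level estimation pipeline and benchmark harness.

`estimate_dataset` is the one-call path from a point-table Dataset to an
EstimateReport: build frame pairs, extract nearest-neighbour records, attach
local densities, and run the chosen estimator.  `run_benchmark` repeats
simulation + estimation over a grid of conditions, emulating the box-plot
comparisons used to characterise the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import Dataset, EstimateReport, Rect, make_frame_pairs, \
    pairwise_frame_pairs
from .density import attach_density
from .estimators import PNNEstimator
from .baselines import estimate_D_spt, pics_estimate
from .model import build_records
from .simulate import SimScenario, make_pairwise_dataset, theoretical_density

__all__ = ["estimate_dataset", "BenchmarkGrid", "run_benchmark"]

ESTIMATOR_NAMES = ("pnn", "pnn_multi", "pics", "local_spt", "global_spt")


def _pairs_from(dataset: Dataset, pairing: str, lag: int):
    if pairing == "pairwise":
        return pairwise_frame_pairs(dataset)
    if pairing == "consecutive":
        return make_frame_pairs(dataset, lag)
    raise ValueError("pairing must be 'pairwise' or 'consecutive'")


def build_record_table(dataset: Dataset, *, pairing: str = "pairwise",
                       lag: int = 1, density_mode: str = "uniform",
                       margin: float | None = None, density_fn=None,
                       knn_correction: str = "unbiased") -> pd.DataFrame:
    """Nearest-neighbour records with densities for a whole dataset."""
    pairs = _pairs_from(dataset, pairing, lag)
    if not pairs:
        raise ValueError("dataset yields no frame pairs")
    aoi = dataset.area_of_interest
    if margin is None:
        margin = dataset.margin
    records = build_records(pairs, aoi, margin, dt=pairs[0].dt)
    records = attach_density(records, pairs, mode=density_mode,
                             area_of_interest=aoi, density_fn=density_fn,
                             correction=knn_correction)
    return records


def estimate_dataset(dataset: Dataset, method: str = "pnn", *,
                     pairing: str = "pairwise", lag: int = 1,
                     density_mode: str = "uniform", density_fn=None,
                     n_states: int = 2, noise_state: bool = False,
                     margin: float | None = None,
                     max_distance: float | None = None,
                     bin_size: float = 0.02, fit_range: float | None = None,
                     knn_correction: str = "unbiased",
                     random_state=None, **em_settings) -> EstimateReport:
    """Estimate diffusion constants from a Dataset with any of the methods.

    ``method`` is one of 'pnn' (single state), 'pnn_multi' (``n_states``
    finite states, plus a disappearing-particle state when ``noise_state``),
    'pics', 'local_spt' or 'global_spt'.
    """
    pairs = _pairs_from(dataset, pairing, lag)
    if not pairs:
        raise ValueError("dataset yields no frame pairs")
    dt = pairs[0].dt
    aoi = dataset.area_of_interest

    if method in ("pnn", "pnn_multi"):
        records = build_record_table(
            dataset, pairing=pairing, lag=lag, density_mode=density_mode,
            margin=margin, density_fn=density_fn, knn_correction=knn_correction)
        X = records[["delta_r", "rho"]].to_numpy()
        if method == "pnn":
            est = PNNEstimator(n_states=1, dt=dt, random_state=random_state,
                               **em_settings)
        else:
            est = PNNEstimator(n_states=n_states, noise_state=noise_state,
                               dt=dt, random_state=random_state, **em_settings)
        est.fit(X)
        report = est.report(X)
        if report.posteriors is not None:
            report.posteriors.insert(0, "pair_index",
                                     records["pair_index"].to_numpy())
            report.posteriors.insert(1, "pre_index",
                                     records["pre_index"].to_numpy())
            for col in ("x", "y"):
                report.posteriors[col] = records[col].to_numpy()
        return report
    if method in ("local_spt", "global_spt"):
        return estimate_D_spt(pairs, mode=method.split("_")[0], dt=dt,
                              max_distance=max_distance,
                              area_of_interest=aoi, margin=margin)
    if method == "pics":
        return pics_estimate(pairs, dt=dt, bin_size=bin_size,
                             fit_range=fit_range, area_of_interest=aoi,
                             margin=margin)
    raise ValueError(f"unknown method {method!r}; choose from {ESTIMATOR_NAMES}")


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkGrid:
    """Grid of simulation conditions × estimators for replicate comparison."""

    densities: Sequence[float] = (0.1, 1.0, 10.0)
    estimators: Sequence[str] = ("pnn", "local_spt", "global_spt", "pics")
    distribution: object | None = None          # None -> uniform scenario
    n_per_frame: int | None = None              # used with an explicit distribution
    D: float = 1.0
    replicates: int = 20
    n_pairs: int = 10
    dt: float = 0.02
    density_mode: str = "uniform"
    seed: int = 0
    area_of_interest: Rect = field(default_factory=lambda: Rect(0, 0, 10, 10))

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        bad = [e for e in self.estimators if e not in ESTIMATOR_NAMES]
        if bad:
            raise ValueError(f"unknown estimators {bad}; valid: {ESTIMATOR_NAMES}")


def run_benchmark(grid: BenchmarkGrid, progress=None) -> pd.DataFrame:
    """Replicate simulation + estimation over the grid.

    Returns one row per (density × estimator × replicate) with the estimated
    D (the slowest finite state for multi-state fits) and the replicate seed,
    so any single run can be replayed.
    """
    ss = np.random.SeedSequence(grid.seed)
    rows = []
    for density in grid.densities:
        rep_seeds = ss.spawn(grid.replicates)
        for rep, rep_seed in enumerate(rep_seeds):
            rng = np.random.default_rng(rep_seed)
            seed_id = int(rep_seed.generate_state(1)[0] % (2 ** 31))
            if grid.distribution is None:
                scenario = SimScenario.uniform(
                    density, states=((grid.D, 1.0),), n_pairs=grid.n_pairs,
                    dt=grid.dt, area_of_interest=grid.area_of_interest)
            else:
                n = grid.n_per_frame or int(round(
                    density * grid.area_of_interest.area))
                scenario = SimScenario(
                    distribution=grid.distribution, n_particles_per_frame=n,
                    states=((grid.D, 1.0),), n_pairs=grid.n_pairs, dt=grid.dt,
                    area_of_interest=grid.area_of_interest)
            dataset, _ = make_pairwise_dataset(scenario, rng)
            density_fn = None
            if grid.density_mode == "theoretical":
                density_fn = theoretical_density(scenario.distribution,
                                                 scenario.n_particles_per_frame)
            for name in grid.estimators:
                try:
                    report = estimate_dataset(
                        dataset, method=name, pairing="pairwise",
                        density_mode=grid.density_mode, density_fn=density_fn,
                        random_state=seed_id)
                    d_est = float(np.min([d for d in report.diffusion_constants
                                          if np.isfinite(d)]))
                    err = ""
                except (ValueError, RuntimeError) as exc:
                    d_est, err = np.nan, str(exc)
                rows.append({"density": density, "estimator": name,
                             "replicate": rep, "seed": seed_id,
                             "D_true": grid.D, "D_est": d_est, "error": err})
                if progress is not None:
                    progress(rows[-1])
    return pd.DataFrame(rows)
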