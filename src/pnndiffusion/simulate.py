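"""Pairwise Monte-Carlo generator of synthetic single-molecule detections.

The generator mirrors the benchmark protocol used throughout the package:
each "experiment" is a set of independent frame *pairs* rather than one long
movie.  For every pair, particle positions are drawn afresh from a spatial
distribution; the subsequent frame displaces each particle by an isotropic
Gaussian step with per-axis variance 2DΔt (free Brownian motion — no drift
or confinement).  A configurable fraction of the detections in each frame
are false detections: points drawn independently from the same spatial
distribution that have no counterpart in the other frame, emulating spurious
peaks in low-SNR images.

Defaults reflect typical single-molecule TIRF benchmarking conditions:
Δt = 20 ms, 10 frame pairs per experiment, a 10×10 μm area of interest, and
for uniform scenarios a sampling window padded well beyond the area of
interest so the density stays uniform after the diffusion step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import DEFAULT_DT, Dataset, ParticleFrame, Rect

__all__ = [
    "UniformRect", "Gaussian", "Annulus", "GaussianMixture",
    "make_distribution", "SimScenario", "sample_positions", "diffuse",
    "make_pairwise_dataset", "simulate_trajectories", "theoretical_density",
]


# ---------------------------------------------------------------------------
# Spatial distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UniformRect:
    """Uniform distribution over a rectangle."""

    rect: Rect

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        r = self.rect
        return np.column_stack([rng.uniform(r.xmin, r.xmax, n),
                                rng.uniform(r.ymin, r.ymax, n)])

    def pdf(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float).reshape(-1, 2)
        return np.where(self.rect.contains(p), 1.0 / self.rect.area, 0.0)


@dataclass(frozen=True)
class Gaussian:
    """Isotropic 2D Gaussian with mean (μm) and standard deviation σ (μm)."""

    mean: tuple[float, float]
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mean, self.sigma, size=(n, 2))

    def pdf(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float).reshape(-1, 2)
        r2 = np.sum((p - np.asarray(self.mean)) ** 2, axis=1)
        return np.exp(-r2 / (2 * self.sigma ** 2)) / (2 * np.pi * self.sigma ** 2)


@dataclass(frozen=True)
class Annulus:
    """Uniform distribution on an annulus (circular band)."""

    center: tuple[float, float]
    r_inner: float
    r_outer: float

    def __post_init__(self):
        if not 0 <= self.r_inner < self.r_outer:
            raise ValueError("need 0 <= r_inner < r_outer")

    @property
    def area(self) -> float:
        return np.pi * (self.r_outer ** 2 - self.r_inner ** 2)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.uniform(size=n)
        r = np.sqrt(self.r_inner ** 2 + u * (self.r_outer ** 2 - self.r_inner ** 2))
        theta = rng.uniform(0, 2 * np.pi, n)
        return np.asarray(self.center) + np.column_stack(
            [r * np.cos(theta), r * np.sin(theta)])

    def pdf(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float).reshape(-1, 2)
        r = np.linalg.norm(p - np.asarray(self.center), axis=1)
        inside = (r >= self.r_inner) & (r <= self.r_outer)
        return np.where(inside, 1.0 / self.area, 0.0)


@dataclass(frozen=True)
class GaussianMixture:
    """Mixture of isotropic Gaussian components."""

    means: tuple
    sigmas: tuple
    weights: tuple

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if len(self.means) != len(self.sigmas) or len(self.means) != len(w):
            raise ValueError("means, sigmas, weights must have equal length")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must sum to 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights))
        means = np.asarray(self.means, dtype=float)[comp]
        sig = np.asarray(self.sigmas, dtype=float)[comp][:, None]
        return means + rng.normal(size=(n, 2)) * sig

    def pdf(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float).reshape(-1, 2)
        out = np.zeros(p.shape[0])
        for m, s, w in zip(self.means, self.sigmas, self.weights):
            r2 = np.sum((p - np.asarray(m)) ** 2, axis=1)
            out += w * np.exp(-r2 / (2 * s ** 2)) / (2 * np.pi * s ** 2)
        return out


def make_distribution(kind: str, **params):
    """Build a spatial distribution from a config-friendly description."""
    kind = kind.lower()
    if kind == "uniform":
        return UniformRect(Rect(*params["bounds"]))
    if kind == "gaussian":
        return Gaussian(tuple(params["mean"]), float(params["sigma"]))
    if kind == "annulus":
        return Annulus(tuple(params["center"]), float(params["r_inner"]),
                       float(params["r_outer"]))
    if kind == "gaussian_mixture":
        return GaussianMixture(tuple(map(tuple, params["means"])),
                               tuple(params["sigmas"]), tuple(params["weights"]))
    raise ValueError(f"unknown distribution kind {kind!r}")


# ---------------------------------------------------------------------------
# Scenario
# ---------------------------------------------------------------------------

#: Padding multiple of the diffusion length sqrt(4 D Δt) used around the
#: area of interest when sampling uniform scenarios; generous enough that
#: boundary flux during one diffusion step is negligible.
WINDOW_PAD_SIGMAS = 5.0


@dataclass
class SimScenario:
    """Full description of one pairwise Monte-Carlo experiment.

    ``states`` lists (D in μm²/s, weight) for the true particle population;
    weights must sum to 1.  ``false_detection_fraction`` f is the fraction of
    *all* detected points in a frame that are false, so each frame carries
    round(f/(1-f) · n_true) false detections alongside the true particles.
    """

    distribution: object
    n_particles_per_frame: int
    states: Sequence[tuple[float, float]] = ((1.0, 1.0),)
    false_detection_fraction: float = 0.0
    n_pairs: int = 10
    dt: float = DEFAULT_DT
    area_of_interest: Rect = field(default_factory=lambda: Rect(0, 0, 10, 10))
    seed: int | None = None

    def __post_init__(self):
        w = np.asarray([w for _, w in self.states], dtype=float)
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("state weights must sum to 1")
        if any(not np.isfinite(d) or d < 0 for d, _ in self.states):
            raise ValueError("state diffusion constants must be finite and >= 0")
        if not 0 <= self.false_detection_fraction < 1:
            raise ValueError("false_detection_fraction must be in [0, 1)")
        if self.n_pairs < 1 or self.n_particles_per_frame < 0:
            raise ValueError("n_pairs >= 1 and n_particles_per_frame >= 0 required")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_false_per_frame(self) -> int:
        f = self.false_detection_fraction
        return int(round(f / (1.0 - f) * self.n_particles_per_frame))

    @classmethod
    def uniform(cls, density: float, states=((1.0, 1.0),),
                area_of_interest: Rect | None = None, **kw) -> "SimScenario":
        """Uniform scenario at a target density (particles/μm², counting true
        particles and false detections together).

        The sampling window pads the area of interest by several diffusion
        lengths so that the density stays uniform after the diffusion step;
        the per-frame particle count follows from density × window area.
        """
        aoi = area_of_interest or Rect(0, 0, 10, 10)
        dt = kw.get("dt", DEFAULT_DT)
        d_max = max(d for d, _ in states)
        pad = WINDOW_PAD_SIGMAS * np.sqrt(4.0 * max(d_max, 1e-12) * dt)
        window = aoi.expand(pad)
        f = kw.get("false_detection_fraction", 0.0)
        n_total = density * window.area
        n_true = int(round(n_total * (1.0 - f)))
        return cls(distribution=UniformRect(window), n_particles_per_frame=n_true,
                   states=states, area_of_interest=aoi, **kw)


def sample_positions(distribution, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` independent positions from a spatial distribution."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return np.empty((0, 2))
    return distribution.sample(n, rng)


def diffuse(positions, D: float, dt: float, rng: np.random.Generator) -> np.ndarray:
    """One Brownian step: independent normal increments, per-axis variance 2DΔt."""
    if D < 0 or dt <= 0:
        raise ValueError("D must be >= 0 and dt > 0")
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        return positions.reshape(0, 2)
    return positions + rng.normal(0.0, np.sqrt(2.0 * D * dt), size=positions.shape)


def make_pairwise_dataset(scenario: SimScenario,
                          rng: np.random.Generator | None = None):
    """Generate the frame pairs of a scenario.

    Returns ``(dataset, ground_truth)``: a Dataset of ``2 * n_pairs`` frames
    (pair k occupies frames 2k and 2k+1) and a ground-truth table with one
    row per preceding-frame particle (``pair_index``, ``pre_index``,
    ``state`` — 0-based into ``scenario.states``, -1 for a false detection —
    and ``D_true``, infinite for false detections).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    d_values = np.asarray([d for d, _ in scenario.states], dtype=float)
    weights = np.asarray([w for _, w in scenario.states], dtype=float)
    n_true = scenario.n_particles_per_frame
    n_false = scenario.n_false_per_frame

    frames, truth = [], []
    for k in range(scenario.n_pairs):
        pos = sample_positions(scenario.distribution, n_true, rng)
        labels = rng.choice(len(d_values), size=n_true, p=weights)
        moved = np.empty_like(pos)
        for s, d in enumerate(d_values):
            sel = labels == s
            moved[sel] = diffuse(pos[sel], d, scenario.dt, rng)
        false_pre = sample_positions(scenario.distribution, n_false, rng)
        false_post = sample_positions(scenario.distribution, n_false, rng)

        pre = np.vstack([pos, false_pre])
        post = np.vstack([moved, false_post])
        frames.append(ParticleFrame(2 * k, pre, time=2 * k * scenario.dt))
        frames.append(ParticleFrame(2 * k + 1, post, time=(2 * k + 1) * scenario.dt))
        truth.append(pd.DataFrame({
            "pair_index": k,
            "pre_index": np.arange(pre.shape[0]),
            "state": np.concatenate([labels, np.full(n_false, -1, dtype=int)]),
            "D_true": np.concatenate([d_values[labels], np.full(n_false, np.inf)]),
            "x": pre[:, 0],
            "y": pre[:, 1],
        }))

    dataset = Dataset(frames=frames, dt=scenario.dt,
                      area_of_interest=scenario.area_of_interest)
    return dataset, pd.concat(truth, ignore_index=True)


def simulate_trajectories(n_frames: int, scenario: SimScenario,
                          rng: np.random.Generator | None = None) -> Dataset:
    """A continuous time course: positions persist and accumulate Brownian
    steps frame to frame (used for multi-lag MSDN checks; the pairwise
    protocol instead regenerates positions per pair)."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    d_values = np.asarray([d for d, _ in scenario.states], dtype=float)
    weights = np.asarray([w for _, w in scenario.states], dtype=float)
    n = scenario.n_particles_per_frame
    pos = sample_positions(scenario.distribution, n, rng)
    labels = rng.choice(len(d_values), size=n, p=weights)
    sigma = np.sqrt(2.0 * d_values[labels] * scenario.dt)[:, None]
    frames = [ParticleFrame(0, pos.copy(), time=0.0)]
    for k in range(1, n_frames):
        pos = pos + rng.normal(size=pos.shape) * sigma
        frames.append(ParticleFrame(k, pos.copy(), time=k * scenario.dt))
    return Dataset(frames=frames, dt=scenario.dt,
                   area_of_interest=scenario.area_of_interest)


def theoretical_density(distribution, n_per_frame: int):
    """The generator's own density field: position -> particles/μm²."""
    def rho(points):
        return n_per_frame * distribution.pdf(points)
    return rho
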