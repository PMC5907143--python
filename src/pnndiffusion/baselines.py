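"""Comparator estimators: tracking-based (local/global SPT) and PICS.

These implement the standard alternatives against which the probabilistic
nearest-neighbour estimator is benchmarked:

* **local SPT** links every preceding-frame particle to its nearest
  subsequent-frame particle with no global consistency — a subsequent
  particle may be claimed by several preceding ones.  At high density this
  systematically picks nearby impostors and biases D low.
* **global SPT** enforces a conflict-free one-to-one association.  The
  linker here minimises the total squared displacement over all one-to-one
  assignments (solved exactly as a min-cost bipartite matching), with an
  optional cap on the allowed displacement; unmatched particles stay
  unlinked.
* **PICS** (particle image correlation spectroscopy) avoids linking
  altogether: the empirical cumulative cross-frame correlation — the mean
  number of subsequent-frame particles within distance l of a preceding
  particle — is fitted with A·(1 − exp(−l²/(4DΔt))) + ρπl², assuming a
  homogeneous background density ρ.

Step lengths from either linker feed the 2D Brownian maximum-likelihood
estimator D = ΣΔr²/(4NΔt).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, linear_sum_assignment
from scipy.spatial import cKDTree

from .datamodel import DEFAULT_DT, EstimateReport, FramePair, Rect
from .model import default_margin, nearest_neighbor_distances

__all__ = [
    "local_spt_link", "global_spt_link", "mle_D_from_steps",
    "estimate_D_spt", "pics_estimate", "pics_curve", "fit_pics_curve",
]


def _clip_frames(pair: FramePair, area_of_interest, margin):
    """Pre positions restricted to the area of interest, post to the
    margin-expanded region; returns (pre, pre_idx, post, post_idx)."""
    pre, post = pair.pre.positions, pair.post.positions
    pre_idx = np.arange(pre.shape[0])
    post_idx = np.arange(post.shape[0])
    if area_of_interest is not None:
        m = area_of_interest.contains(pre)
        pre, pre_idx = pre[m], pre_idx[m]
        region = area_of_interest.expand(margin) if margin else area_of_interest
        m = region.contains(post)
        post, post_idx = post[m], post_idx[m]
    return pre, pre_idx, post, post_idx


def local_spt_link(pair: FramePair, area_of_interest: Rect | None = None,
                   margin: float | None = None) -> pd.DataFrame:
    """Nearest-neighbour linking without global consistency.

    Every preceding-frame particle links to its nearest subsequent-frame
    particle; several links may share a target. Identical to the record
    extraction kernel of the probabilistic model.
    """
    rec = nearest_neighbor_distances(pair, area_of_interest, margin)
    return rec[["pre_index", "post_index", "delta_r"]].rename(
        columns={"delta_r": "distance"})


def global_spt_link(pair: FramePair, max_distance: float | None = None,
                    area_of_interest: Rect | None = None,
                    margin: float | None = None) -> pd.DataFrame:
    """Conflict-free linking minimising total squared displacement.

    Solved exactly as a min-cost bipartite matching; links longer than
    ``max_distance`` are forbidden and the corresponding particles stay
    unlinked.
    """
    if max_distance is not None and max_distance <= 0:
        raise ValueError("max_distance must be positive")
    pre, pre_idx, post, post_idx = _clip_frames(pair, area_of_interest, margin)
    if pre.shape[0] == 0 or post.shape[0] == 0:
        return pd.DataFrame(columns=["pre_index", "post_index", "distance"])
    diff = pre[:, None, :] - post[None, :, :]
    dist = np.sqrt(np.sum(diff ** 2, axis=2))
    cost = dist ** 2
    if max_distance is not None:
        forbidden = dist > max_distance
        if forbidden.all():
            return pd.DataFrame(columns=["pre_index", "post_index", "distance"])
        # big-M keeps the matrix feasible; capped links are dropped afterwards
        cost = np.where(forbidden, cost.max() * 1e6 + 1.0, cost)
    rows, cols = linear_sum_assignment(cost)
    d = dist[rows, cols]
    if max_distance is not None:
        keep = d <= max_distance
        rows, cols, d = rows[keep], cols[keep], d[keep]
    return pd.DataFrame({"pre_index": pre_idx[rows],
                         "post_index": post_idx[cols],
                         "distance": d})


def mle_D_from_steps(step_lengths, dt: float = DEFAULT_DT) -> float:
    """2D Brownian MLE from linked step lengths: D = ΣΔr² / (4NΔt)."""
    steps = np.asarray(step_lengths, dtype=float)
    if steps.size == 0:
        raise ValueError("no steps")
    if np.any(steps < 0):
        raise ValueError("step lengths must be non-negative")
    return float(np.sum(steps ** 2) / (4.0 * steps.size * dt))


def estimate_D_spt(pairs, mode: str = "global", dt: float | None = None,
                   max_distance: float | None = None,
                   area_of_interest: Rect | None = None,
                   margin: float | None = None) -> EstimateReport:
    """Link every pair per ``mode`` ('local' or 'global'), pool the step
    lengths, and apply the Brownian MLE."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no frame pairs")
    if dt is None:
        dt = pairs[0].dt
    if margin is None and area_of_interest is not None:
        # same data-driven margin as the record extraction: without it, edge
        # particles lose their true partner and forced long links inflate D
        margin = default_margin(pairs, area_of_interest, dt)
    steps = []
    for pair in pairs:
        if mode == "local":
            links = local_spt_link(pair, area_of_interest, margin)
        elif mode == "global":
            links = global_spt_link(pair, max_distance, area_of_interest, margin)
        else:
            raise ValueError("mode must be 'local' or 'global'")
        steps.append(links["distance"].to_numpy())
    steps = np.concatenate(steps)
    if steps.size == 0:
        raise ValueError("linking produced zero links; "
                         "increase max_distance or check the data")
    D = mle_D_from_steps(steps, dt)
    return EstimateReport(method=f"{mode}_spt", diffusion_constants=[D],
                          weights=[1.0], log_likelihood=None, aic=None,
                          n_obs=steps.size, dt=dt)


# ---------------------------------------------------------------------------
# PICS
# ---------------------------------------------------------------------------

def pics_curve(l, A, D, rho, dt):
    """Expected cumulative cross-frame correlation:
    A·(1 − exp(−l²/(4DΔt))) + ρπl²."""
    l = np.asarray(l, dtype=float)
    return A * (1.0 - np.exp(-l ** 2 / (4.0 * D * dt))) + rho * np.pi * l ** 2


def empirical_pics_curve(pairs, grid, area_of_interest: Rect | None = None,
                         margin: float | None = None) -> np.ndarray:
    """Mean number of subsequent-frame particles within each distance in
    ``grid`` of a preceding-frame particle, pooled over pairs."""
    grid = np.asarray(grid, dtype=float)
    counts = np.zeros_like(grid)
    n_pre_total = 0
    for pair in pairs:
        pre, _, post, _ = _clip_frames(pair, area_of_interest, margin)
        if pre.shape[0] == 0 or post.shape[0] == 0:
            continue
        tree_pre, tree_post = cKDTree(pre), cKDTree(post)
        counts += tree_pre.count_neighbors(tree_post, grid)
        n_pre_total += pre.shape[0]
    if n_pre_total == 0:
        raise ValueError("no preceding-frame particles in the area of interest")
    return counts / n_pre_total


def fit_pics_curve(grid, values, dt: float, d0: float | None = None):
    """Least-squares fit of A·(1 − exp(−l²/(4DΔt))) + ρπl² to a cumulative
    correlation curve; returns (A, D, rho). Unweighted residuals."""
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if d0 is None:
        d0 = max((0.3 * grid[-1]) ** 2 / (4.0 * dt), 1e-6)
    rho0 = max(values[-1] / (np.pi * grid[-1] ** 2), 1e-12)

    def f(l, A, D, rho):
        return pics_curve(l, A, D, rho, dt)

    try:
        popt, _ = curve_fit(f, grid, values, p0=(1.0, d0, rho0),
                            bounds=([0.0, 1e-12, 0.0], [np.inf] * 3),
                            maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"PICS fit did not converge (grid of {grid.size} bins up to "
            f"{grid[-1]:.3g} um): {exc}") from exc
    return tuple(map(float, popt))


def pics_estimate(pairs, dt: float | None = None, bin_size: float = 0.02,
                  fit_range: float | None = None,
                  area_of_interest: Rect | None = None,
                  margin: float | None = None) -> EstimateReport:
    """Fit the whole cumulative correlation function at once.

    The distance grid runs from ``bin_size`` to ``fit_range`` in steps of
    ``bin_size``; ``fit_range`` defaults to 3/sqrt(ρπ) with ρ taken from the
    subsequent-frame counts (three background nearest-neighbour length
    scales), capped by the halo of subsequent-frame data actually available
    around the area of interest — counts beyond that halo would be
    truncated and bias the quadratic background term. Returns a report
    whose single state holds the fitted D, with the fitted amplitude A and
    background density ρ in ``extra``.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no frame pairs")
    if dt is None:
        dt = pairs[0].dt

    pooled = np.vstack([p.post.positions for p in pairs])
    if area_of_interest is not None:
        rho_rough = float(np.mean([
            area_of_interest.contains(p.post.positions).sum() for p in pairs
        ])) / area_of_interest.area
        a = area_of_interest
        halo = min(a.xmin - pooled[:, 0].min(), a.ymin - pooled[:, 1].min(),
                   pooled[:, 0].max() - a.xmax, pooled[:, 1].max() - a.ymax)
        halo = max(halo, 0.0)
    else:
        box = Rect(pooled[:, 0].min(), pooled[:, 1].min(),
                   pooled[:, 0].max(), pooled[:, 1].max())
        rho_rough = pooled.shape[0] / len(pairs) / box.area
        halo = np.inf
    if margin is not None:
        halo = min(halo, margin)
    if fit_range is None:
        fit_range = 3.0 / np.sqrt(rho_rough * np.pi)
        if halo > 10 * bin_size:
            fit_range = min(fit_range, halo)
    grid = np.arange(bin_size, fit_range + 0.5 * bin_size, bin_size)
    if grid.size < 4:
        raise ValueError("fit range too short for the bin size")

    # every subsequent-frame particle within fit_range of the area of
    # interest can contribute to a count, so that is the natural margin
    emp = empirical_pics_curve(pairs, grid, area_of_interest,
                               float(fit_range) if margin is None else margin)
    A_fit, D_fit, rho_fit = fit_pics_curve(grid, emp, dt)
    return EstimateReport(method="pics", diffusion_constants=[D_fit],
                          weights=[1.0], log_likelihood=None, aic=None,
                          n_obs=grid.size, dt=dt,
                          extra={"amplitude": A_fit, "rho": rho_fit,
                                 "bin_size": bin_size, "fit_range": float(fit_range)})
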