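"""Local particle density estimation.

Every nearest-neighbour record carries a local density ρ_i (particles/μm²)
describing the background against which the nearest neighbour competes.  For
homogeneous data a single frame-wide density suffices; for inhomogeneous
distributions the density is estimated per particle with a k-nearest-
neighbour estimator on the pooled subsequent frames of all *other* pairs,
which trades no spatial resolution for a k-fold variance reduction (the
pooled k corresponds to a length scale of k = 1 within a single frame).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .datamodel import ParticleFrame, Rect

__all__ = ["uniform_density", "knn_local_density", "attach_density"]


def uniform_density(frame: ParticleFrame, area: Rect) -> float:
    """Particles per μm²: count inside the area of interest / its area."""
    n = int(area.contains(frame.positions).sum())
    if n == 0:
        raise ValueError("no particles in the area of interest; "
                         "density is zero and the model is undefined "
                         "(use the rho->0 MSD closed form instead)")
    return n / area.area


def knn_local_density(pairs, pair_index: int, query_points,
                      correction: str = "unbiased") -> np.ndarray:
    """k-NN local density at ``query_points`` for the pair ``pair_index``.

    The subsequent frames of all pairs except ``pair_index`` are merged into
    one cloud of ``N_merged`` points; k is the number of merged frames.  The
    probabilistic density at x is estimated from the distance d_k(x) to the
    k-th nearest merged point,

        p̂(x) = (k - 1) / (N_merged · π · d_k(x)²),

    and converted to a particle density by weighting with the particle count
    of the pair's own subsequent frame: ρ(x) = p̂(x) · N_target.

    The (k-1) numerator makes the estimator exactly unbiased for a Poisson
    point background (λπd_k² is Gamma(k, 1)-distributed, and
    E[1/Gamma(k,1)] = 1/(k-1)); ``correction='plugin'`` uses the plain k
    numerator instead, which overshoots by a factor k/(k-1).

    Duplicated points can make d_k(x) = 0; such queries fall back to the
    smallest positive neighbour distance, with a warning.
    """
    pairs = list(pairs)
    if not 0 <= pair_index < len(pairs):
        raise IndexError("pair_index out of range")
    others = [p.post.positions for i, p in enumerate(pairs) if i != pair_index]
    others = [p for p in others if p.shape[0] > 0]
    k = len(others)
    if k < 1:
        raise ValueError("k-NN density needs at least two frame pairs")
    if correction not in ("unbiased", "plugin"):
        raise ValueError("correction must be 'unbiased' or 'plugin'")
    numerator = k - 1 if correction == "unbiased" else k
    if numerator < 1:
        raise ValueError("unbiased k-NN density needs k >= 2 merged frames "
                         "(at least three pairs)")
    merged = np.vstack(others)
    n_merged = merged.shape[0]
    if n_merged < k:
        raise ValueError(f"merged cloud has {n_merged} points, fewer than k={k}")
    query = np.asarray(query_points, dtype=float).reshape(-1, 2)
    tree = cKDTree(merged)
    dist, _ = tree.query(query, k=k)
    dist = np.atleast_2d(dist)
    d_k = dist[:, -1].astype(float)
    zero = d_k == 0.0
    if np.any(zero):
        warnings.warn("duplicate points: d_k = 0 for some queries; using the "
                      "smallest positive neighbour distance", RuntimeWarning)
        for i in np.flatnonzero(zero):
            all_d = np.linalg.norm(merged - query[i], axis=1)
            positive = all_d[all_d > 0]
            if positive.size == 0:
                raise ValueError("every merged point coincides with the "
                                 "query; cannot estimate a density")
            d_k[i] = positive.min()
    p_hat = numerator / (n_merged * np.pi * d_k ** 2)
    n_target = pairs[pair_index].post.n_particles
    return p_hat * n_target


def attach_density(records, pairs, mode: str = "uniform",
                   area_of_interest: Rect | None = None,
                   density_fn=None,
                   correction: str = "unbiased"):
    """Fill the ``rho`` column of a record table built by ``build_records``.

    mode='uniform'      : per-pair frame-wide density (needs area_of_interest).
    mode='knn'          : per-record k-NN density from the pooled other pairs.
    mode='theoretical'  : evaluate ``density_fn(positions)`` (a known density
                          field, e.g. the generator's own) at each record.
    """
    records = records.copy()
    rho = np.empty(len(records), dtype=float)
    pairs = list(pairs)
    if mode == "uniform":
        if area_of_interest is None:
            raise ValueError("uniform mode requires an area_of_interest")
        for k, pair in enumerate(pairs):
            sel = records["pair_index"].to_numpy() == k
            if sel.any():
                rho[sel] = uniform_density(pair.post, area_of_interest)
    elif mode == "knn":
        for k in range(len(pairs)):
            sel = records["pair_index"].to_numpy() == k
            if sel.any():
                q = records.loc[sel, ["x", "y"]].to_numpy()
                rho[sel] = knn_local_density(pairs, k, q, correction=correction)
    elif mode == "theoretical":
        if density_fn is None:
            raise ValueError("theoretical mode requires density_fn")
        rho[:] = np.asarray(density_fn(records[["x", "y"]].to_numpy()), dtype=float)
    else:
        raise ValueError(f"unknown density mode {mode!r}")
    if np.any(rho <= 0) or not np.all(np.isfinite(rho)):
        raise ValueError("estimated densities must be positive and finite")
    records["rho"] = rho
    return records
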