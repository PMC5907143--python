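"""Probabilistic model of the distance to the nearest detected particle.

A Brownian particle observed at the origin at time t is surrounded by
indistinguishable particles, approximated as a locally uniform background of
density ρ (a mean-field view of the neighbourhood).  After a lag Δt, the
nearest detected point in the subsequent frame is either the particle itself,
diffused with per-axis displacement variance 2DΔt, or a background particle.
The two survival functions multiply:

    P_dif(r > Δr | D)  = exp(-Δr² / (4 D Δt))          (free 2D diffusion)
    P_bg(r > Δr | ρ)   = exp(-ρ π Δr²)                  (spatial Poisson)
    P_nn               = P_dif · P_bg

The second moment of the resulting nearest-neighbour distance, the mean
square displacement to the nearest particle (MSDN), is

    MSDN = 4DΔt / (1 + 4ρπDΔt)  ≤  MSD = 4DΔt,

which inverts in closed form to D = MSDN / (4Δt (1 - ρπ·MSDN)).  These
closed-form relations underlie the uniform-density estimator; the EM
machinery in :mod:`pnndiffusion.estimators` generalises them to local
densities and to mixtures of diffusive states.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .datamodel import FramePair, Rect

logger = logging.getLogger(__name__)

__all__ = [
    "survival_dif", "survival_bg", "survival_nn", "pdf_nn", "log_pdf_nn",
    "msdn_expected", "msdn_empirical", "estimate_D_closed_form",
    "nearest_neighbor_distances", "build_records", "default_margin",
]


def survival_dif(delta_r, D, dt):
    """P(displacement of a free Brownian particle exceeds ``delta_r``)."""
    delta_r = np.asarray(delta_r, dtype=float)
    if np.any(delta_r < 0):
        raise ValueError("delta_r must be non-negative")
    if not D > 0 or not dt > 0:
        raise ValueError("D and dt must be positive")
    return np.exp(-delta_r ** 2 / (4.0 * D * dt))


def survival_bg(delta_r, rho):
    """P(nearest background particle farther than ``delta_r``) for a uniform
    background of density ``rho`` (particles/μm²)."""
    delta_r = np.asarray(delta_r, dtype=float)
    if np.any(delta_r < 0):
        raise ValueError("delta_r must be non-negative")
    if np.any(np.asarray(rho) < 0):
        raise ValueError("rho must be non-negative")
    return np.exp(-np.asarray(rho, dtype=float) * np.pi * delta_r ** 2)


def survival_nn(delta_r, rho, D, dt):
    """P(nearest detected point in the subsequent frame farther than Δr)."""
    return survival_dif(delta_r, D, dt) * survival_bg(delta_r, rho)


def log_pdf_nn(delta_r, rho, D, dt):
    """Log-density of the nearest-neighbour distance; -inf at Δr = 0.

    Evaluated directly in log space so that large exponents (Δr far in the
    tail) underflow gracefully instead of returning 0/0 artefacts.
    """
    delta_r = np.asarray(delta_r, dtype=float)
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore"):
        return (np.log(2.0 * rho * np.pi + 1.0 / (2.0 * D * dt))
                + np.log(delta_r)
                - rho * np.pi * delta_r ** 2
                - delta_r ** 2 / (4.0 * D * dt))


def pdf_nn(delta_r, rho, D, dt):
    """Density of the nearest-neighbour distance (per μm); the negative
    derivative of :func:`survival_nn` with respect to Δr."""
    return np.exp(log_pdf_nn(delta_r, rho, D, dt))


def msdn_expected(rho, D, dt):
    """Expected mean square displacement to the nearest particle (μm²)."""
    rho = np.asarray(rho, dtype=float)
    return 4.0 * D * dt / (1.0 + 4.0 * rho * np.pi * D * dt)


def msdn_empirical(delta_r) -> float:
    """Mean of Δr² over observed nearest-neighbour distances."""
    delta_r = np.asarray(delta_r, dtype=float)
    if delta_r.size == 0:
        raise ValueError("no records: cannot compute empirical MSDN")
    return float(np.mean(delta_r ** 2))


def estimate_D_closed_form(msdn: float, rho: float, dt: float) -> float:
    """Invert the MSDN relation: D = MSDN / (4Δt (1 - ρπ·MSDN)).

    At ρ = 0 this reduces to the plain MSD estimator MSDN/(4Δt).  The MSDN
    saturates at 1/(ρπ) as Δt grows, so values at or beyond that asymptote
    carry no information about D and are rejected.
    """
    if msdn <= 0:
        raise ValueError("msdn must be positive")
    denom = 1.0 - rho * np.pi * msdn
    if denom <= 0:
        raise ValueError(
            f"msdn={msdn:g} is at or beyond its asymptote 1/(rho*pi)="
            f"{1.0 / (rho * np.pi):g}; the closed form is infeasible")
    return float(msdn / (4.0 * dt * denom))


# ---------------------------------------------------------------------------
# Nearest-neighbour record extraction
# ---------------------------------------------------------------------------

def nearest_neighbor_distances(pair: FramePair,
                               area_of_interest: Rect | None = None,
                               margin: float | None = None) -> pd.DataFrame:
    """Distance from each preceding-frame particle to its nearest
    subsequent-frame particle.

    Preceding-frame particles are restricted to ``area_of_interest`` (when
    given); the search among subsequent-frame particles uses the rectangle
    expanded by ``margin`` so edge particles can reach their true nearest
    neighbour.  Several preceding particles may claim the same subsequent
    particle — there is deliberately no exclusivity.  Exact neighbours only
    (k-d tree); ties at identical distance resolve to the lowest
    subsequent-frame index.

    Returns a DataFrame with columns ``pre_index``, ``post_index``,
    ``delta_r``, ``x``, ``y`` (query-particle position).
    """
    pre_pos = pair.pre.positions
    if pre_pos.shape[0] == 0:
        raise ValueError("preceding frame is empty")
    pre_idx = np.arange(pre_pos.shape[0])
    if area_of_interest is not None:
        mask = area_of_interest.contains(pre_pos)
        pre_pos, pre_idx = pre_pos[mask], pre_idx[mask]

    post_pos = pair.post.positions
    post_idx = np.arange(post_pos.shape[0])
    if area_of_interest is not None and margin is not None:
        region = area_of_interest.expand(margin)
        mask = region.contains(post_pos)
        post_pos, post_idx = post_pos[mask], post_idx[mask]

    empty = pd.DataFrame(columns=["pre_index", "post_index", "delta_r", "x", "y"])
    if pre_pos.shape[0] == 0:
        return empty
    if post_pos.shape[0] == 0:
        logger.warning("no subsequent-frame particles in search region; "
                       "%d preceding particles yield no records", pre_pos.shape[0])
        return empty

    tree = cKDTree(post_pos)
    dist, j = tree.query(pre_pos, k=1)
    return pd.DataFrame({
        "pre_index": pre_idx,
        "post_index": post_idx[j],
        "delta_r": dist,
        "x": pre_pos[:, 0],
        "y": pre_pos[:, 1],
    })


def default_margin(pairs, area_of_interest: Rect, dt: float) -> float:
    """Data-driven default search margin: 3·sqrt(4·D_guess·Δt).

    ``D_guess`` comes from the closed-form MSDN estimator on a provisional,
    unrestricted nearest-neighbour pass with the uniform density of the
    subsequent frames.  The margin only needs the right order of magnitude;
    the estimate depends on it very weakly.
    """
    dr, n_post = [], []
    for pair in pairs:
        rec = nearest_neighbor_distances(pair, area_of_interest, margin=None)
        dr.append(rec["delta_r"].to_numpy())
        n_post.append(int(area_of_interest.contains(pair.post.positions).sum()))
    dr = np.concatenate(dr) if dr else np.array([])
    if dr.size == 0:
        raise ValueError("no records available to set a default margin")
    rho = float(np.mean(n_post)) / area_of_interest.area
    msdn = msdn_empirical(dr)
    try:
        d_guess = estimate_D_closed_form(msdn, rho, dt)
    except ValueError:
        d_guess = msdn / (4.0 * dt)  # MSDN at its asymptote: fall back to MSD
    return 3.0 * float(np.sqrt(4.0 * d_guess * dt))


def build_records(pairs, area_of_interest: Rect | None = None,
                  margin: float | None = None,
                  dt: float | None = None) -> pd.DataFrame:
    """Concatenate nearest-neighbour records over frame pairs.

    With an area of interest and ``margin=None`` the margin defaults to
    :func:`default_margin`.  Returns a DataFrame with an added ``pair_index``
    column; densities are attached separately (see
    :mod:`pnndiffusion.density`).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no frame pairs given")
    if margin is None and area_of_interest is not None:
        if dt is None:
            dt = pairs[0].dt
        margin = default_margin(pairs, area_of_interest, dt)
    out = []
    for k, pair in enumerate(pairs):
        rec = nearest_neighbor_distances(pair, area_of_interest, margin)
        rec.insert(0, "pair_index", k)
        out.append(rec)
    return pd.concat(out, ignore_index=True)
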