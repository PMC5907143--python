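"""Maximum-likelihood diffusion-constant estimation by expectation-maximization.

The observed data are per-particle records (Δr_i, ρ_i): the distance from a
preceding-frame particle to its nearest subsequent-frame neighbour, and the
local particle density around it.  Two latent variables are marginalised:

* q_i ∈ {0, 1} — whether the nearest neighbour is a background particle
  (q = 0) or the original particle diffused from the origin (q = 1);
* s_i ∈ {1..M} — which diffusive state the particle is in, with diffusion
  constant D_s and mixture weight α_s (Σα_s = 1).

The joint density of one record is

    p(Δr, q=0, s) = 2ρπ α_s Δr exp(-ρπΔr² - Δr²/(4 D_s Δt))
    p(Δr, q=1, s) = α_s Δr / (2 D_s Δt) exp(-ρπΔr² - Δr²/(4 D_s Δt))

A state with D = ∞ models particles that disappear between frames (false
detections, bleaching, internalisation): its diffusion factor is identically
1 and its q = 1 branch vanishes.  It is implemented as the analytic limit,
never as a large finite D, and its (fixed) D does not count as a free
parameter in the AIC.

The M-step updates are

    α_s  <-  (1/N) Σ_i Σ_q p(q, s | Δr_i, ρ_i, θ)
    D_s  <-  Σ_i Σ_q Δr_i² p(q, s | ·) / (4Δt Σ_i p(q=1, s | ·))

and for M = 1 they collapse to D <- <Δr²> / (4Δt <p(q=1)>), whose fixed
point is exactly the closed-form MSDN estimator when ρ_i is constant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted, check_random_state

from .datamodel import DEFAULT_DT, EstimateReport
from .model import log_pdf_nn

__all__ = [
    "PNNEstimator", "loglik_single", "posterior_q_single", "em_fit_single",
    "joint_multi", "posterior_multi", "em_fit_multi", "assign_states",
    "select_by_aic",
]

_LOG_EPS = -745.0  # below this, exp underflows to 0 in double precision


def _validate_records(delta_r, rho):
    delta_r = np.asarray(delta_r, dtype=float).ravel()
    rho = np.asarray(rho, dtype=float).ravel()
    if delta_r.size == 0:
        raise ValueError("no records")
    if rho.shape != delta_r.shape:
        rho = np.broadcast_to(rho, delta_r.shape).copy()
    if np.any(delta_r == 0):
        raise ValueError(
            "records with delta_r = 0 (exactly coincident points) are not "
            "supported: log(delta_r) enters the likelihood. Remove duplicate "
            "detections before fitting.")
    if np.any(delta_r < 0) or np.any(rho <= 0):
        raise ValueError("delta_r must be positive and rho strictly positive")
    if not (np.all(np.isfinite(delta_r)) and np.all(np.isfinite(rho))):
        raise ValueError("records must be finite")
    return delta_r, rho


# ---------------------------------------------------------------------------
# Single-state pieces (kept as plain functions; also exercised by the class)
# ---------------------------------------------------------------------------

def loglik_single(delta_r, rho, D: float, dt: float = DEFAULT_DT) -> float:
    """Total log-likelihood of the records under a single diffusive state."""
    delta_r, rho = _validate_records(delta_r, rho)
    if not D > 0:
        raise ValueError("D must be positive")
    return float(np.sum(log_pdf_nn(delta_r, rho, D, dt)))


def posterior_q_single(rho, D: float, dt: float = DEFAULT_DT):
    """(p(q=0), p(q=1)) for a single state.

    Independent of Δr: the state-specific exponentials cancel between the
    two branches, leaving p(q=0) = 4ρπDΔt / (4ρπDΔt + 1).
    """
    rho = np.asarray(rho, dtype=float)
    a = 4.0 * rho * np.pi * D * dt
    p0 = a / (a + 1.0)
    return p0, 1.0 - p0


# ---------------------------------------------------------------------------
# Multi-state pieces
# ---------------------------------------------------------------------------

def _log_joint(delta_r, rho, D, alpha, dt):
    """Log joint p(Δr, q, s | ρ, θ) as an (n, 2, M) array (q indexes axis 1)."""
    delta_r = np.asarray(delta_r, dtype=float)[:, None]
    rho = np.asarray(rho, dtype=float)[:, None]
    D = np.asarray(D, dtype=float)[None, :]
    log_alpha = np.log(np.asarray(alpha, dtype=float))[None, :]
    finite = np.isfinite(D)

    common = np.log(delta_r) - rho * np.pi * delta_r ** 2 + log_alpha
    with np.errstate(divide="ignore", over="ignore"):
        diff_exp = np.where(finite, -delta_r ** 2 / (4.0 * D * dt), 0.0)
        lj0 = np.log(2.0 * rho * np.pi) + common + diff_exp
        lj1 = np.where(finite, -np.log(2.0 * D * dt), -np.inf) + common + diff_exp
    return np.stack([lj0, lj1], axis=1)


def joint_multi(delta_r, rho, q: int, s: int, D, alpha, dt: float = DEFAULT_DT):
    """Joint density p(Δr, q, s | ρ, θ) for given latent values (s is 0-based)."""
    lj = _log_joint(np.atleast_1d(delta_r), np.broadcast_to(
        np.asarray(rho, dtype=float), np.atleast_1d(delta_r).shape), D, alpha, dt)
    out = np.exp(lj[:, q, s])
    return out if out.size > 1 else float(out[0])


def posterior_multi(delta_r, rho, D, alpha, dt: float = DEFAULT_DT):
    """Normalized posterior p(q, s | Δr, ρ, θ) as an (n, 2, M) array.

    Computed in log space; unlike the single-state q-posterior it depends on
    Δr through the state-specific exponentials.
    """
    delta_r, rho = _validate_records(delta_r, rho)
    lj = _log_joint(delta_r, rho, D, alpha, dt)
    norm = logsumexp(lj.reshape(len(delta_r), -1), axis=1)
    if np.any(~np.isfinite(norm)):
        raise FloatingPointError("all joint densities underflowed for some record")
    return np.exp(lj - norm[:, None, None])


class PNNEstimator(BaseEstimator):
    """Probabilistic nearest-neighbour estimator of 2D diffusion constants.

    Fits a mixture of ``n_states`` diffusive states (plus an optional
    infinite-D "disappearing particle" state capturing false detections) to
    nearest-neighbour records by EM, without linking particles into
    trajectories.

    Parameters
    ----------
    n_states : int, default=1
        Number of finite diffusive states M.
    noise_state : bool, default=False
        Add a state with D = ∞ for particles absent from the subsequent
        frame (false detections, bleaching).
    dt : float, default=0.02
        Acquisition lag Δt between the paired frames, seconds.
    max_iter : int, default=500
        Maximum EM iterations per restart.
    tol : float, default=1e-8
        Relative log-likelihood change declaring convergence.
    n_restarts : int, default=5
        EM restarts with jittered initial diffusion constants; the highest
        final log-likelihood wins.  The first restart is unjittered.
    init_D : sequence of float, optional
        Explicit initial finite diffusion constants (length ``n_states``).
        Default: the MSD guess <Δr²>/(4Δt) spread geometrically over one
        decade up and down.
    random_state : int, RandomState or None
        Seeds the restart jitter.

    Attributes
    ----------
    diffusion_constants_ : ndarray of shape (M_total,)
        Fitted D per state, μm²/s, sorted ascending; the infinite-D state,
        if present, is last.
    weights_ : ndarray of shape (M_total,)
        Fitted mixture weights α, summing to 1.
    log_likelihood_ : float
    aic_ : float
        2k - 2·log L with k = (M_total - 1) free weights + number of finite
        diffusion constants.
    n_iter_ : int
        EM iterations used by the winning restart.
    converged_ : bool
    degenerate_ : bool
        True if some state emptied out during fitting (its D update was
        skipped).

    Examples
    --------
    >>> import numpy as np
    >>> from pnndiffusion import PNNEstimator
    >>> rng = np.random.default_rng(0)
    >>> # records at uniform density rho=1 from a D=1 um^2/s population
    >>> X = np.column_stack([rng.rayleigh(np.sqrt(2 * 1.0 * 0.02), 500),
    ...                      np.ones(500)])
    >>> est = PNNEstimator(dt=0.02).fit(X)
    >>> float(est.diffusion_constants_[0])  # doctest: +SKIP
    1.02...
    """

    def __init__(self, n_states: int = 1, noise_state: bool = False,
                 dt: float = DEFAULT_DT, max_iter: int = 500, tol: float = 1e-8,
                 n_restarts: int = 5, init_D=None, random_state=None):
        self.n_states = n_states
        self.noise_state = noise_state
        self.dt = dt
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.init_D = init_D
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _check_X(self, X):
        X = check_array(X, ensure_min_features=2)
        if X.shape[1] != 2:
            raise ValueError("X must have two columns: (delta_r, rho)")
        return _validate_records(X[:, 0], X[:, 1])

    def _initial_D(self, delta_r):
        if self.init_D is not None:
            D0 = np.asarray(self.init_D, dtype=float)
            if D0.shape != (self.n_states,) or np.any(D0 <= 0):
                raise ValueError("init_D must hold n_states positive values")
            return D0
        d_msd = float(np.mean(delta_r ** 2)) / (4.0 * self.dt)
        if self.n_states == 1:
            return np.array([d_msd])
        # geometric spread one decade either side of the MSD guess
        return d_msd * 10.0 ** np.linspace(-1.0, 1.0, self.n_states)

    def _em_once(self, delta_r, rho, D_init):
        m_total = self.n_states + (1 if self.noise_state else 0)
        D = np.concatenate([D_init, [np.inf]]) if self.noise_state else D_init.copy()
        alpha = np.full(m_total, 1.0 / m_total)
        n = delta_r.size
        dr2 = delta_r ** 2
        loglik = -np.inf
        degenerate = False
        converged = False
        trace = []
        for it in range(1, self.max_iter + 1):
            lj = _log_joint(delta_r, rho, D, alpha, self.dt)
            norm = logsumexp(lj.reshape(n, -1), axis=1)
            new_loglik = float(np.sum(norm))      # likelihood of current θ
            trace.append(new_loglik)
            post = np.exp(lj - norm[:, None, None])          # (n, 2, M)
            # M-step
            resp = post.sum(axis=1)                          # Σ_q, (n, M)
            alpha = resp.mean(axis=0)
            alpha = alpha / alpha.sum()
            w1 = post[:, 1, :].sum(axis=0)                   # Σ_i p(q=1, s)
            num = (dr2[:, None] * resp).sum(axis=0)
            for s in range(self.n_states):
                if w1[s] > n * 1e-12:
                    D[s] = num[s] / (4.0 * self.dt * w1[s])
                else:
                    degenerate = True
            rel = abs(new_loglik - loglik) / max(1.0, abs(loglik))
            loglik = new_loglik
            if rel < self.tol:
                converged = True
                break
        # likelihood of the parameters actually returned (post-final-M-step)
        lj = _log_joint(delta_r, rho, D, alpha, self.dt)
        loglik = float(np.sum(logsumexp(lj.reshape(n, -1), axis=1)))
        trace.append(loglik)
        return D, alpha, loglik, it, converged, degenerate, trace

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        """Fit on records ``X`` of shape (n, 2): columns (delta_r, rho)."""
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter must be >= 1 and tol > 0")
        delta_r, rho = self._check_X(X)
        rng = check_random_state(self.random_state)
        base_D = self._initial_D(delta_r)

        best = None
        for r in range(max(1, self.n_restarts)):
            if r == 0:
                D_init = base_D
            else:
                D_init = base_D * np.exp(rng.normal(0.0, 0.5, size=base_D.shape))
            result = self._em_once(delta_r, rho, D_init)
            if best is None or result[2] > best[2]:
                best = result
        D, alpha, loglik, n_iter, converged, degenerate, trace = best
        self.loglik_trace_ = np.asarray(trace)

        order = np.argsort(D, kind="stable")  # inf sorts last
        self.diffusion_constants_ = D[order]
        self.weights_ = alpha[order]
        self.log_likelihood_ = loglik
        k = (len(D) - 1) + int(np.sum(np.isfinite(D)))
        self.aic_ = 2.0 * k - 2.0 * loglik
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.degenerate_ = degenerate
        self.n_features_in_ = 2
        return self

    def posterior(self, X):
        """Full posterior p(q, s | Δr, ρ, θ̂) as an (n, 2, M_total) array."""
        check_is_fitted(self)
        delta_r, rho = self._check_X(X)
        return posterior_multi(delta_r, rho, self.diffusion_constants_,
                               self.weights_, self.dt)

    def predict_proba(self, X):
        """State membership p(s | Δr, ρ, θ̂), shape (n, M_total)."""
        return self.posterior(X).sum(axis=1)

    def predict(self, X):
        """Most probable state per record (0-based; ties to the lower,
        slower-diffusing index; the infinite-D state is the last index)."""
        return np.argmax(self.predict_proba(X), axis=1)

    def score(self, X, y=None):
        """Mean per-record log-likelihood under the fitted model."""
        check_is_fitted(self)
        delta_r, rho = self._check_X(X)
        lj = _log_joint(delta_r, rho, self.diffusion_constants_, self.weights_,
                        self.dt)
        return float(np.mean(logsumexp(lj.reshape(len(delta_r), -1), axis=1)))

    def report(self, X=None) -> EstimateReport:
        """Bundle the fitted parameters as an :class:`EstimateReport`;
        with ``X`` given, includes the per-record state posteriors."""
        check_is_fitted(self)
        posteriors = None
        n_obs = 0
        if X is not None:
            proba = self.predict_proba(X)
            n_obs = proba.shape[0]
            posteriors = pd.DataFrame(
                proba, columns=[f"p_state_{s + 1}" for s in range(proba.shape[1])])
            posteriors.insert(0, "state", self.predict(X) + 1)
        name = "pnn" if len(self.diffusion_constants_) == 1 else "pnn_multi"
        return EstimateReport(
            method=name,
            diffusion_constants=list(self.diffusion_constants_),
            weights=list(self.weights_),
            log_likelihood=self.log_likelihood_,
            aic=self.aic_,
            n_obs=n_obs,
            iterations=self.n_iter_,
            converged=self.converged_,
            dt=self.dt,
            posteriors=posteriors,
            extra={"degenerate": self.degenerate_} if self.degenerate_ else {},
        )


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def _records_to_X(records) -> np.ndarray:
    if isinstance(records, pd.DataFrame):
        return records[["delta_r", "rho"]].to_numpy(dtype=float)
    return np.asarray(records, dtype=float)


def em_fit_single(records, dt: float = DEFAULT_DT, **settings) -> EstimateReport:
    """Single-state EM fit; ``records`` is a DataFrame with columns
    ``delta_r``/``rho`` or an (n, 2) array."""
    X = _records_to_X(records)
    est = PNNEstimator(n_states=1, dt=dt, **settings).fit(X)
    return est.report(X)


def em_fit_multi(records, dt: float = DEFAULT_DT, n_states: int = 2,
                 noise_state: bool = False, **settings) -> EstimateReport:
    """Multi-state EM fit with an optional infinite-D (disappearing) state."""
    X = _records_to_X(records)
    est = PNNEstimator(n_states=n_states, noise_state=noise_state, dt=dt,
                       **settings).fit(X)
    return est.report(X)


def assign_states(records, D, alpha, dt: float = DEFAULT_DT) -> np.ndarray:
    """Most probable state per record under a fitted model (0-based)."""
    X = _records_to_X(records)
    post = posterior_multi(X[:, 0], X[:, 1], D, alpha, dt).sum(axis=1)
    return np.argmax(post, axis=1)


def select_by_aic(reports) -> EstimateReport:
    """Pick the fit with the smallest AIC among candidate model reports."""
    reports = list(reports)
    if not reports:
        raise ValueError("no candidate reports")
    return min(reports, key=lambda r: r.aic)
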