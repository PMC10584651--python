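"""Stage 2: element-wise selection under a group-indexed Dirichlet-Laplace prior.

After the group stage has fixed the Q surviving blocks and imputed the
censored log-times as their posterior mean w~, the model reduces to an
ordinary Gaussian linear regression on the retained columns,

    w~_i = x_i0' b0 + x_i*' theta + eps_i,   eps_i ~ N(0, sigma^2),

with the Dirichlet-Laplace hierarchy on theta, indexed per group g:

    theta_gj | . ~ N(0, sigma^2 psi_gj phi_gj^2 tau_g^2)
    psi_gj ~ Exp(1/2),  phi_g ~ Dir(a_g, ..., a_g),
    tau_g ~ Gamma(q_g a_g, 1/2),  a_g ~ uniform on a 50-point grid
                                        from 1/q_g to 1/2.

The Gibbs sweep below draws b0, the per-group theta blocks, sigma^2, and
then the scale block in its only valid order — the simplex weights phi
(normalised giG variates, psi and tau marginalised), the global scales
tau (generalized inverse Gaussian, psi marginalised), the local
exponential scales psi (reciprocal inverse-Gaussian conditionals), and
the concentration a_g (discrete grid).
Because Dirichlet-Laplace shrinkage never zeroes a coefficient exactly, the
number of signals H is read off by two-means clustering of the |theta|
draws at every stored iteration; the H largest posterior medians |theta|
are reported as the selected variables.

Note on the psi step: the conditional of a local exponential scale in this
hierarchy is giG(1/2, 1, theta^2/(sigma phi tau)^2), i.e. the RECIPROCAL
1/psi follows the (two-parameter, mean/shape) inverse-Gaussian distribution
with mean phi_gj tau_g sigma / |theta_gj| and shape 1 — not the
inverse-gamma, whose notation it shares, and not the inverse-Gaussian of
psi itself.  A joint-distribution (Geweke-style) test pins this down: only
the reciprocal form leaves the Exp(1/2) prior marginal invariant.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import linalg, stats
from scipy.special import gammaln

from ._gig import gig_rvs

logger = logging.getLogger(__name__)

__all__ = [
    "DLState",
    "ElementSelection",
    "ReducedDesign",
    "sample_beta0",
    "sample_theta_g",
    "sample_sigma_sq",
    "sample_psi",
    "sample_tau_g",
    "sample_phi_g",
    "sample_ag",
    "sample_gig",
    "run_stage2",
    "kmeans_select",
    "two_means_1d",
]

_THETA_FLOOR = 1e-10   # |theta| floor guarding giG/inverse-Gaussian parameters
_PSI_MEAN_CAP = 1e8    # cap on the inverse-Gaussian mean when theta underflows
_AG_GRID = 50


@dataclass
class ReducedDesign:
    """Design of the reduced regression: unpenalised X0 plus the Q kept groups."""

    X0: NDArray[np.float64]
    group_X: list[NDArray[np.float64]]       # X*_g, n x q_g each
    group_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X0 = np.atleast_2d(np.asarray(self.X0, dtype=np.float64))
        self.group_X = [np.asarray(X, dtype=np.float64) for X in self.group_X]
        if not self.group_ids:
            self.group_ids = [f"g{j}" for j in range(len(self.group_X))]

    @property
    def n(self) -> int:
        return self.X0.shape[0]

    @property
    def p0(self) -> int:
        return self.X0.shape[1]

    @property
    def Q(self) -> int:
        return len(self.group_X)

    @property
    def group_sizes(self) -> NDArray[np.intp]:
        return np.array([X.shape[1] for X in self.group_X], dtype=np.intp)

    @property
    def q_total(self) -> int:
        return int(self.group_sizes.sum())

    def stacked(self) -> NDArray[np.float64]:
        return np.concatenate(self.group_X, axis=1)

    def slices(self) -> list[slice]:
        sizes = self.group_sizes
        offs = np.concatenate([[0], np.cumsum(sizes)])
        return [slice(int(offs[j]), int(offs[j + 1])) for j in range(len(sizes))]


@dataclass
class DLState:
    """Chain state of the Dirichlet-Laplace sampler."""

    beta0: NDArray[np.float64]
    theta: list[NDArray[np.float64]]         # per group
    sigma_sq: float
    psi: list[NDArray[np.float64]]
    phi: list[NDArray[np.float64]]
    tau: NDArray[np.float64]
    a_g: NDArray[np.float64]

    def prior_var(self, g: int) -> NDArray[np.float64]:
        """Diagonal of Sigma*_g = diag(psi phi^2 tau^2)."""
        return self.psi[g] * self.phi[g] ** 2 * self.tau[g] ** 2


def _ag_grid(q_g: int) -> NDArray[np.float64]:
    return np.linspace(1.0 / q_g, 0.5, _AG_GRID)


def initial_state(design: ReducedDesign, rng: np.random.Generator,
                  sigma_sq: float = 1.0) -> DLState:
    sizes = design.group_sizes
    return DLState(
        beta0=np.zeros(design.p0),
        theta=[np.zeros(k) for k in sizes],
        sigma_sq=sigma_sq,
        psi=[np.ones(k) for k in sizes],
        phi=[np.full(k, 1.0 / k) for k in sizes],
        tau=np.ones(len(sizes)),
        a_g=np.array([_ag_grid(int(k))[0] for k in sizes]),
    )


# ---------------------------------------------------------------- step 1
def sample_beta0(state: DLState, design: ReducedDesign,
                 w_tilde: NDArray[np.float64], rng: np.random.Generator,
                 h0: float = 100.0) -> NDArray[np.float64]:
    """b0 | . ~ N((X0'X0 + I/h0)^{-1} X0'(w~ - X* theta), sigma^2 (X0'X0 + I/h0)^{-1})."""
    X0 = design.X0
    resid = w_tilde - _eta_theta(state, design)
    A = X0.T @ X0 + np.eye(design.p0) / h0
    L = np.linalg.cholesky(A)
    mean = linalg.cho_solve((L, True), X0.T @ resid)
    z = rng.standard_normal(design.p0)
    draw = mean + np.sqrt(state.sigma_sq) * linalg.solve_triangular(
        L, z, lower=True, trans="T")
    state.beta0 = draw
    return draw


def _eta_theta(state: DLState, design: ReducedDesign) -> NDArray[np.float64]:
    out = np.zeros(design.n)
    for X, th in zip(design.group_X, state.theta):
        out += X @ th
    return out


# ---------------------------------------------------------------- step 2
def sample_theta_g(g: int, state: DLState, design: ReducedDesign,
                   w_tilde: NDArray[np.float64],
                   rng: np.random.Generator) -> NDArray[np.float64]:
    """theta_g | . ~ N(mu_g, sigma^2 (X_g'X_g + inv(Sigma*_g))^{-1}).

    mu_g is the ridge-type estimate of the group's partial residual; the
    prior precision is the inverse of the diagonal Dirichlet-Laplace
    covariance, floored to keep the system well posed when a scale
    collapses numerically.
    """
    X = design.group_X[g]
    resid = w_tilde - design.X0 @ state.beta0 - _eta_theta(state, design) \
        + X @ state.theta[g]
    pv = state.prior_var(g)
    floored = np.maximum(pv, 1e-12)
    if np.any(pv < 1e-12):
        logger.debug("floored %d collapsed prior variances in group %d",
                     int(np.sum(pv < 1e-12)), g)
    A = X.T @ X + np.diag(1.0 / floored)
    L = np.linalg.cholesky(A)
    mean = linalg.cho_solve((L, True), X.T @ resid)
    z = rng.standard_normal(X.shape[1])
    draw = mean + np.sqrt(state.sigma_sq) * linalg.solve_triangular(
        L, z, lower=True, trans="T")
    state.theta[g] = draw
    return draw


# ---------------------------------------------------------------- step 3
def sample_sigma_sq(state: DLState, design: ReducedDesign,
                    w_tilde: NDArray[np.float64], rng: np.random.Generator,
                    h0: float = 100.0, nu0: float = 3.0,
                    sigma0_sq: float = 1.0) -> float:
    """sigma^2 | . ~ IG(N/2, {nu0 s0^2 + ||w~-eta||^2 + b0'b0/h0 + theta'inv(S*)theta}/2)."""
    n, p0 = design.n, design.p0
    q = design.q_total
    eta = design.X0 @ state.beta0 + _eta_theta(state, design)
    rss = float(np.sum((w_tilde - eta) ** 2))
    quad = float(state.beta0 @ state.beta0) / h0
    for g in range(design.Q):
        quad += float(np.sum(state.theta[g] ** 2
                             / np.maximum(state.prior_var(g), 1e-12)))
    shape = 0.5 * (n + q + p0 + nu0)
    rate = 0.5 * (nu0 * sigma0_sq + rss + quad)
    draw = float(stats.invgamma.rvs(shape, scale=rate, random_state=rng))
    state.sigma_sq = draw
    return draw


# ---------------------------------------------------------------- step 4
def sample_psi(state: DLState, rng: np.random.Generator) -> list[NDArray[np.float64]]:
    """Local scales: 1/psi_gj ~ inverse-Gaussian(phi tau sigma / |theta|, shape 1)."""
    sigma = np.sqrt(state.sigma_sq)
    sizes = [t.shape[0] for t in state.theta]
    denom = np.concatenate([np.abs(t) for t in state.theta])
    scale = np.concatenate([ph * tg for ph, tg in zip(state.phi, state.tau)])
    mean = np.where(denom > _THETA_FLOOR,
                    scale * sigma / np.maximum(denom, _THETA_FLOOR),
                    _PSI_MEAN_CAP)
    mean = np.minimum(mean, _PSI_MEAN_CAP)
    # The conditional of psi is giG(1/2, 1, theta^2/(sigma phi tau)^2),
    # equivalently 1/psi ~ inverse-Gaussian(mean, shape 1); scipy
    # invgauss(mu) has mean mu and shape 1, so draw the reciprocal.
    recip = np.atleast_1d(stats.invgauss.rvs(mean, random_state=rng))
    draw = 1.0 / np.maximum(recip.astype(np.float64), 1e-300)
    draw = np.maximum(draw, 1e-300)
    out = []
    off = 0
    for g, k in enumerate(sizes):
        state.psi[g] = draw[off:off + k]
        out.append(state.psi[g])
        off += k
    return out


# -------------------------------------------------------- giG sampling
def sample_gig(order, chi, psi_par, rng: np.random.Generator,
               size: int | None = None):
    """Generalized inverse Gaussian with density ∝ x^{order-1} e^{-(chi x + psi/x)/2}.

    Thin wrapper over the vectorised rejection sampler in :mod:`bbvs._gig`;
    the boundary psi -> 0 with positive order degenerates to Gamma(order,
    rate chi/2) and chi -> 0 with negative order to the inverse-gamma, both
    handled there.
    """
    return gig_rvs(order, chi, psi_par, rng, size=size)


# ---------------------------------------------------------------- step 5
def sample_tau_g(g: int, state: DLState, rng: np.random.Generator) -> float:
    """tau_g | . ~ giG(q_g a_g - q_g, 1, 2 sum_j |theta_gj| / (phi_gj sigma))."""
    sigma = np.sqrt(state.sigma_sq)
    q_g = state.theta[g].shape[0]
    order = q_g * state.a_g[g] - q_g
    psi_par = 2.0 * float(np.sum(
        np.maximum(np.abs(state.theta[g]), _THETA_FLOOR)
        / (np.maximum(state.phi[g], _THETA_FLOOR) * sigma)))
    draw = float(sample_gig(order, 1.0, psi_par, rng))
    draw = max(draw, 1e-300)
    state.tau[g] = draw
    return draw


# ---------------------------------------------------------------- step 6
def sample_phi_g(g: int, state: DLState,
                 rng: np.random.Generator) -> NDArray[np.float64]:
    """phi_g as normalised giG(a_g - 1, 1, 2|theta_gj|/sigma) variates."""
    sigma = np.sqrt(state.sigma_sq)
    th = np.maximum(np.abs(state.theta[g]), _THETA_FLOOR)
    q_g = th.shape[0]
    if q_g == 1:
        state.phi[g] = np.ones(1)
        return state.phi[g]
    T = np.asarray(gig_rvs(state.a_g[g] - 1.0, 1.0, 2.0 * th / sigma, rng))
    total = T.sum()
    if not np.isfinite(total) or total <= 0.0:
        logger.warning("phi draws underflowed in group %d; renormalising "
                       "to uniform", g)
        phi = np.full(q_g, 1.0 / q_g)
    else:
        phi = T / total
        phi = np.maximum(phi, 1e-300)
        phi = phi / phi.sum()
    state.phi[g] = phi
    return phi


# ---------------------------------------------------------------- step 7
def ag_log_weights(q_g: int, phi_g: NDArray[np.float64], tau_g: float,
                   variant: str = "full") -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Unnormalised log-weights of a_g on its grid, for a single grid draw.

    ``variant="full"`` scores each grid point u by the full conditional
    density pi(phi_g | u) * pi(tau_g | u): the Dirichlet(u,...,u) density of
    phi_g including its normalising constant and the Gamma(q_g u, 1/2)
    density of tau_g including its constant.  ``variant="paper"`` keeps only
    the kernel terms (u-1) sum log phi + (q_g u - 1) log tau.
    """
    grid = _ag_grid(q_g)
    slog_phi = float(np.sum(np.log(phi_g)))
    log_tau = float(np.log(tau_g))
    lw = (grid - 1.0) * slog_phi + (q_g * grid - 1.0) * log_tau
    if variant == "full":
        # Dirichlet const: log Gamma(q u) - q log Gamma(u);
        # Gamma(q u, rate 1/2) const: -q u log 2 - log Gamma(q u)
        # (the two Gamma(q u) terms cancel)
        lw = lw - q_g * gammaln(grid) - q_g * grid * np.log(2.0)
    elif variant != "paper":
        raise ValueError("variant must be 'full' or 'paper'")
    return grid, lw


def sample_ag(g: int, state: DLState, rng: np.random.Generator,
              variant: str = "full") -> float:
    """Single multinomial draw of a_g over its 50-point grid."""
    q_g = state.theta[g].shape[0]
    grid, lw = ag_log_weights(q_g, state.phi[g], state.tau[g], variant)
    lw = lw - np.max(lw)  # log-sum-exp shift guards underflow
    wgt = np.exp(lw)
    wgt = wgt / wgt.sum()
    idx = int(rng.choice(len(grid), p=wgt))
    state.a_g[g] = grid[idx]
    return float(grid[idx])


def _sample_scales_all(state: DLState, rng: np.random.Generator,
                       ag_variant: str) -> None:
    """Batched phi/tau/psi/a_g refresh across groups.

    Statistically identical to looping :func:`sample_phi_g`,
    :func:`sample_tau_g`, :func:`sample_psi` and :func:`sample_ag` in that
    order; batching just amortises the sampler overhead over all
    coefficients.  The order matters: the phi and tau conditionals are
    derived with the local exponential scales psi integrated out
    (phi additionally with tau integrated out), so this is a partially
    collapsed Gibbs step and is only valid as a joint draw of
    (phi, tau, psi) given (theta, sigma, a) when phi comes first, tau is
    drawn given the fresh phi, and psi is redrawn last given both.
    """
    sigma = np.sqrt(state.sigma_sq)
    Q = len(state.theta)
    sizes = np.array([t.shape[0] for t in state.theta])
    th_abs = [np.maximum(np.abs(t), _THETA_FLOOR) for t in state.theta]
    # phi | theta, sigma, a (psi and tau marginalised):
    # one giG draw per coefficient, grouped normalisation
    flat_th = np.concatenate(th_abs)
    flat_order = np.repeat(state.a_g - 1.0, sizes)
    T = np.asarray(gig_rvs(flat_order, 1.0, 2.0 * flat_th / sigma, rng))
    off = 0
    for g in range(Q):
        k = int(sizes[g])
        Tg = T[off:off + k]
        off += k
        if k == 1:
            state.phi[g] = np.ones(1)
            continue
        total = Tg.sum()
        if not np.isfinite(total) or total <= 0.0:
            logger.warning("phi draws underflowed in group %d; renormalising "
                           "to uniform", g)
            state.phi[g] = np.full(k, 1.0 / k)
        else:
            phi = np.maximum(Tg / total, 1e-300)
            state.phi[g] = phi / phi.sum()
    # tau | phi, theta, sigma, a (psi marginalised): one giG draw per group
    orders = sizes * state.a_g - sizes
    psis = np.array([
        2.0 * float(np.sum(th / (np.maximum(ph, _THETA_FLOOR) * sigma)))
        for th, ph in zip(th_abs, state.phi)
    ])
    tau = np.asarray(gig_rvs(orders, 1.0, psis, rng))
    state.tau = np.maximum(tau, 1e-300)
    # psi | phi, tau, theta, sigma completes the joint scale draw
    sample_psi(state, rng)
    for g in range(Q):
        sample_ag(g, state, rng, variant=ag_variant)


# ---------------------------------------------------------------- driver
@dataclass
class ElementSelection:
    """Outcome of the element-wise selection."""

    theta_median: NDArray[np.float64]
    H: int
    selected_snps: NDArray[np.intp]
    h_trace: NDArray[np.intp]


def two_means_1d(values: NDArray[np.float64], max_iter: int = 100
                 ) -> tuple[float, float, NDArray[np.bool_]]:
    """Deterministic Lloyd 2-means on a 1-D array.

    Centroids start at the min and max of the data (reproducible, no random
    restarts).  Returns (low centroid, high centroid, mask of points in the
    high-centroid cluster).
    """
    v = np.asarray(values, dtype=np.float64)
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return lo, hi, np.zeros(v.shape, dtype=bool)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        high = v > mid
        new_lo = float(v[~high].mean()) if np.any(~high) else lo
        new_hi = float(v[high].mean()) if np.any(high) else hi
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    return lo, hi, v > 0.5 * (lo + hi)


def kmeans_select(theta_draws: NDArray[np.float64],
                  theta_median: NDArray[np.float64]) -> ElementSelection:
    """Signal count by per-iteration 2-means on |theta|, then top-|median| pick.

    At every stored iteration the absolute coefficients are clustered into
    two groups; h_i is the size of the cluster with the larger centroid (the
    signal cluster — with sparse signals this is also the smaller cluster).
    An exact centroid tie yields h_i = 0 (no separation means no signal).
    H is the mode of the h_i (smallest modal value on ties), and the H
    largest absolute posterior medians are selected.
    """
    draws = np.atleast_2d(np.abs(np.asarray(theta_draws, dtype=np.float64)))
    med = np.abs(np.asarray(theta_median, dtype=np.float64))
    q = med.shape[0]
    if q < 2:
        raise ValueError("element-wise selection needs at least 2 coefficients")
    h_trace = np.empty(draws.shape[0], dtype=np.intp)
    for i, row in enumerate(draws):
        lo, hi, high_mask = two_means_1d(row)
        h_trace[i] = int(high_mask.sum()) if hi > lo else 0
    counts = Counter(h_trace.tolist())
    top = max(counts.values())
    H = min(h for h, c in counts.items() if c == top)
    order = np.argsort(med)[::-1]
    selected = np.sort(order[:H]).astype(np.intp)
    return ElementSelection(theta_median=theta_median, H=int(H),
                            selected_snps=selected, h_trace=h_trace)


def run_stage2(
    design: ReducedDesign,
    w_tilde: NDArray[np.float64],
    n_iter: int = 5000,
    burn_in: int = 2500,
    seed: int | np.random.Generator = 0,
    h0: float = 100.0,
    nu0: float = 3.0,
    sigma0_sq: float = 1.0,
    ag_weights: str = "full",
    log_every: int = 0,
) -> tuple[NDArray[np.float64], ElementSelection]:
    """Run the seven-step Dirichlet-Laplace Gibbs sampler.

    Returns the post-burn-in theta draws (iterations x q, groups stacked in
    design order) and the k-means based :class:`ElementSelection`.
    """
    if not (n_iter > burn_in >= 0):
        raise ValueError("need n_iter > burn_in >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w_tilde = np.asarray(w_tilde, dtype=np.float64)
    state = initial_state(design, rng)
    n_keep = n_iter - burn_in
    draws = np.empty((n_keep, design.q_total))
    sl = design.slices()
    for it in range(n_iter):
        sample_beta0(state, design, w_tilde, rng, h0=h0)
        for g in range(design.Q):
            sample_theta_g(g, state, design, w_tilde, rng)
        sample_sigma_sq(state, design, w_tilde, rng, h0=h0, nu0=nu0,
                        sigma0_sq=sigma0_sq)
        _sample_scales_all(state, rng, ag_weights)
        if it >= burn_in:
            for g, s in enumerate(sl):
                draws[it - burn_in, s] = state.theta[g]
        if log_every and (it + 1) % log_every == 0:
            logger.info("stage2 iteration %d/%d, sigma^2=%.3g",
                        it + 1, n_iter, state.sigma_sq)
    theta_median = np.median(draws, axis=0)
    selection = kmeans_select(draws, theta_median)
    return draws, selection
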