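"""Vectorised generalized-inverse-Gaussian sampling.

The GIG(lam, chi, psi) density is proportional to
``x^{lam-1} exp(-(chi*x + psi/x)/2)`` on x > 0.  In log-space
(y = log x) the standardised two-parameter form

    f_y(y) = exp(lam*y - omega*cosh(y)) / (2 K_lam(omega)),
    omega = sqrt(chi*psi),

is log-concave with mode y* = asinh(lam/omega), so Devroye's universal
rejection method for normalised log-concave densities applies: with
s = f_y(y*), the rescaled density g(u) = f_y(y* + u/s)/s is bounded by
min(1, e^{1-|u|}), an envelope of total area 4 that is trivial to sample.
Acceptance is at least 1/4 uniformly over the whole parameter range, and
everything vectorises, which matters because the element-wise Gibbs sweep
draws one GIG variate per coefficient per iteration.

Negative orders use the reciprocal identity 1/GIG(lam, a, b) = GIG(-lam,
b, a); the boundary cases psi -> 0 (Gamma) and chi -> 0 (inverse-Gamma)
are dispatched explicitly.  The Bessel normaliser is evaluated in log
space, falling back to the small-argument asymptotic when K_lam(omega)
overflows.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import NDArray
from scipy.special import gammaln, kv

_EULER_GAMMA = 0.5772156649015329


def _log_kv(lam: NDArray[np.float64], omega: NDArray[np.float64]) -> NDArray[np.float64]:
    """log K_lam(omega), elementwise, robust to overflow at small omega."""
    lam = np.abs(lam)  # K_{-v} = K_v
    with np.errstate(over="ignore", invalid="ignore"):
        k = kv(lam, omega)
    out = np.where((k > 0) & np.isfinite(k), np.log(np.where(k > 0, k, 1.0)), np.nan)
    bad = ~np.isfinite(out)
    if np.any(bad):
        lam_b, om_b = lam[bad], omega[bad]
        # omega -> 0 asymptotics
        asym = np.where(
            lam_b > 1e-10,
            np.log(0.5) + gammaln(lam_b) + lam_b * np.log(2.0 / om_b),
            -np.log(om_b / 2.0) - _EULER_GAMMA,
        )
        out[bad] = asym
    return out


def _gig_standard(lam: NDArray[np.float64], omega: NDArray[np.float64],
                  rng: np.random.Generator) -> NDArray[np.float64]:
    """Draws from f(x) ∝ x^{lam-1} exp(-omega (x + 1/x)/2), lam >= 0."""
    lam = np.asarray(lam, dtype=np.float64)
    omega = np.asarray(omega, dtype=np.float64)
    y_star = np.arcsinh(lam / omega)
    log_norm = np.log(2.0) + _log_kv(lam, omega)
    # log density height at the mode, for the rescaling step
    log_s = lam * y_star - omega * np.cosh(y_star) - log_norm
    s = np.exp(log_s)

    n = lam.shape[0]
    y = np.empty(n)
    todo = np.ones(n, dtype=bool)
    while np.any(todo):
        m = int(todo.sum())
        # envelope min(1, e^{1-|u|}): half the mass uniform on [-1,1],
        # half in the two exponential tails
        pick_tail = rng.random(m) < 0.5
        u = np.where(
            pick_tail,
            np.sign(rng.random(m) - 0.5) * (1.0 + rng.exponential(size=m)),
            rng.uniform(-1.0, 1.0, size=m),
        )
        log_env = np.minimum(0.0, 1.0 - np.abs(u))
        yy = y_star[todo] + u / s[todo]
        with np.errstate(over="ignore"):
            log_g = (lam[todo] * yy - omega[todo] * np.cosh(yy)
                     - log_norm[todo] - log_s[todo])
        accept = np.log(rng.random(m)) + log_env <= log_g
        idx = np.flatnonzero(todo)[accept]
        y[idx] = yy[accept]
        todo[idx] = False
    return np.exp(y)


def gig_rvs(order, chi, psi, rng: np.random.Generator,
            size: int | None = None):
    """Sample GIG(order, chi, psi) with density ∝ x^{order-1} e^{-(chi x + psi/x)/2}.

    Parameters broadcast against each other; a scalar is returned when all
    inputs are scalar and ``size`` is None.
    """
    scalar_in = np.isscalar(order) and np.isscalar(chi) and np.isscalar(psi) \
        and size is None
    order, chi, psi = np.broadcast_arrays(
        np.asarray(order, dtype=np.float64),
        np.asarray(chi, dtype=np.float64),
        np.asarray(psi, dtype=np.float64),
    )
    shape = order.shape if size is None else (size,)
    order = np.broadcast_to(order, shape).ravel()
    chi = np.broadcast_to(chi, shape).ravel()
    psi = np.broadcast_to(psi, shape).ravel()
    if np.any(chi < 0) or np.any(psi < 0):
        raise ValueError("chi and psi must be non-negative")

    out = np.empty(order.shape)
    tiny = 1e-300
    gamma_case = psi <= tiny
    invgamma_case = (~gamma_case) & (chi <= tiny)
    general = ~(gamma_case | invgamma_case)

    if np.any(gamma_case):
        if np.any(order[gamma_case] <= 0):
            raise ValueError(
                f"giG with psi=0 requires positive order "
                f"(order={order[gamma_case].min()}, chi=?, psi=0)")
        out[gamma_case] = rng.gamma(order[gamma_case], 2.0 / chi[gamma_case])
    if np.any(invgamma_case):
        if np.any(order[invgamma_case] >= 0):
            raise ValueError(
                f"giG with chi=0 requires negative order "
                f"(order={order[invgamma_case].max()}, chi=0)")
        out[invgamma_case] = psi[invgamma_case] / 2.0 / rng.gamma(
            -order[invgamma_case], 1.0)
    if np.any(general):
        lam = order[general]
        a, b = chi[general], psi[general]
        omega = np.sqrt(a * b)
        alpha = np.sqrt(b / a)
        neg = lam < 0
        x = _gig_standard(np.abs(lam), omega, rng)
        x[neg] = 1.0 / x[neg]
        out[general] = alpha * x

    out = out.reshape(shape)
    return float(out[()]) if scalar_in and out.ndim == 0 else (
        float(out.ravel()[0]) if scalar_in else out)
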