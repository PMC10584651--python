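"""Core data model for bi-level selection in the log-normal AFT regression.

The survival outcome enters on the log scale, ``log Y = X0' b0 + sum_g
gamma_g X_g' b_g + eps``, with ``eps ~ N(0, sigma^2)``.  Group coefficients
carry an information-matrix (Zellner-g style) prior ``b_g ~ N(0, c0 sigma^2
Sigma_g)`` with ``Sigma_g = (X_g'X_g)^{-1}`` (ridge-stabilised when the group
is wider than the sample).  Integrating out all regression coefficients and
sigma^2 leaves the augmented log-times with an n-dimensional multivariate-t
marginal whose scale matrix is

    H_gamma = I + h0 X0 X0' + c0 * sum_{g: gamma_g = 1} X_g Sigma_g X_g'.

This module holds the grouped design container, the per-group Gram inverses,
a factorised ``H_gamma`` supporting cheap single-group flips, and the
multivariate-t log-density those pieces feed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import linalg
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "Block",
    "GroupedDesign",
    "SurvivalData",
    "Stage1Hyper",
    "build_gram_inverse",
    "MarginalKernel",
    "marginal_kernel",
    "log_marginal_t",
]


class RankDeficiencyError(np.linalg.LinAlgError):
    """Gram matrix of a group is singular and no ridge was requested."""


@dataclass
class Block:
    """One predictor group: an LD block of SNPs (or any column group)."""

    group_id: str
    member_index: NDArray[np.intp]   # column indices into the full genotype matrix
    X: NDArray[np.float64]           # n x k_g design slice

    @property
    def size(self) -> int:
        return self.X.shape[1]


def build_gram_inverse(
    X_g: NDArray[np.float64], ridge: float, n: int | None = None,
    group_id: str = "?",
) -> NDArray[np.float64]:
    """Per-group prior covariance kernel Sigma_g.

    Returns ``(X_g'X_g)^{-1}`` when the group has at most ``n`` columns, and
    the ridge-stabilised ``(X_g'X_g + ridge*I)^{-1}`` when it is wider than
    the sample.  Raises :class:`RankDeficiencyError` when the plain Gram is
    singular.
    """
    X_g = np.asarray(X_g, dtype=np.float64)
    if n is None:
        n = X_g.shape[0]
    k = X_g.shape[1]
    gram = X_g.T @ X_g
    if k > n:
        if ridge <= 0:
            raise ValueError(
                f"group {group_id!r} has more columns ({k}) than rows ({n}); "
                "a positive ridge is required"
            )
        gram = gram + ridge * np.eye(k)
    try:
        c, low = linalg.cho_factor(gram)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - message path below
        raise RankDeficiencyError(
            f"Gram matrix of group {group_id!r} is singular; columns are "
            "collinear and no ridge applies (k_g <= n)"
        ) from exc
    # cho_factor does not always raise on (numerically) singular input; the
    # pivot ratio is a scale-free rank check
    d = np.abs(np.diag(c))
    if not np.all(np.isfinite(d)) or np.min(d) < 1e-7 * np.max(d):
        raise RankDeficiencyError(
            f"Gram matrix of group {group_id!r} is singular; columns are "
            "collinear and no ridge applies (k_g <= n)"
        )
    inv = linalg.cho_solve((c, low), np.eye(k))
    return (inv + inv.T) / 2.0


@dataclass
class GroupedDesign:
    """Genotypes split into groups plus always-in covariates.

    ``X0`` holds the unpenalised covariates with a leading all-ones column
    (intercept).  Every SNP belongs to exactly one block.  ``gram_inv[g]`` is
    the prior covariance kernel Sigma_g for block g.
    """

    X0: NDArray[np.float64]
    blocks: list[Block]
    ridge: float = 1.0
    gram_inv: list[NDArray[np.float64]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X0 = np.atleast_2d(np.asarray(self.X0, dtype=np.float64))
        n = self.X0.shape[0]
        if not np.allclose(self.X0[:, 0], 1.0):
            raise ValueError("first column of X0 must be the all-ones intercept")
        seen: set[int] = set()
        for b in self.blocks:
            if b.X.shape[0] != n:
                raise ValueError(f"block {b.group_id!r} row count mismatch")
            idx = set(int(i) for i in np.asarray(b.member_index).ravel())
            if seen & idx:
                raise ValueError(f"block {b.group_id!r} shares SNPs with another block")
            seen |= idx
        if not self.gram_inv:
            self.gram_inv = [
                build_gram_inverse(b.X, self.ridge, n, b.group_id) for b in self.blocks
            ]

    @property
    def n(self) -> int:
        return self.X0.shape[0]

    @property
    def n_groups(self) -> int:
        return len(self.blocks)

    @property
    def p0(self) -> int:
        return self.X0.shape[1]

    @property
    def group_sizes(self) -> NDArray[np.intp]:
        return np.array([b.size for b in self.blocks], dtype=np.intp)

    def group_half_kernels(self) -> list[NDArray[np.float64]]:
        """Z_g with Z_g Z_g' = X_g Sigma_g X_g' (n x k_g each)."""
        out = []
        for b, S in zip(self.blocks, self.gram_inv):
            L = np.linalg.cholesky(S)
            out.append(b.X @ L)
        return out


@dataclass
class SurvivalData:
    """Observed times with right censoring and the augmented log-times.

    ``w`` equals ``log t`` exactly on events (nu == 1) and sits strictly
    above ``log t`` on censored entries, where ``log t`` is only a lower
    bound for the latent log event time.
    """

    t: NDArray[np.float64]
    nu: NDArray[np.intp]
    w: NDArray[np.float64] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.nu = np.asarray(self.nu, dtype=np.intp)
        if np.any(self.t <= 0):
            raise ValueError("all observed times must be strictly positive")
        if not np.all(np.isin(self.nu, (0, 1))):
            raise ValueError("event indicators must be 0 or 1")
        if self.w is None:
            # strictly feasible start for censored latent log-times
            self.w = self.censor_lb + 0.1 * (1 - self.nu)
        self.w = np.asarray(self.w, dtype=np.float64)
        ev = self.nu == 1
        if not np.allclose(self.w[ev], np.log(self.t[ev])):
            raise ValueError("w must equal log t on uncensored entries")
        if np.any(self.w[~ev] <= np.log(self.t[~ev])):
            raise ValueError("censored w entries must exceed their bound log t")

    @property
    def censor_lb(self) -> NDArray[np.float64]:
        return np.log(self.t)

    @property
    def n(self) -> int:
        return self.t.shape[0]

    @property
    def censored_index(self) -> NDArray[np.intp]:
        return np.flatnonzero(self.nu == 0)


@dataclass
class Stage1Hyper:
    """Hyperparameters of the marginalised group-selection model.

    h0        prior scale of the unpenalised coefficients b0 ~ N(0, h0 sigma^2 I)
    c0        prior scale of the group coefficients (g-prior multiplier);
              None (default) resolves to the sample size n, the
              unit-information scaling under which one prior pseudo-
              observation is worth one data point.  A fixed O(1) value
              shrinks each group's explained signal by c0/(1+c0) while
              paying the full log-determinant complexity penalty, which
              drains the selection power of the marginal Bayes factors.
    nu0       prior degrees of freedom of sigma^2 ~ IG(nu0/2, nu0 sigma0^2/2)
    sigma0_sq prior scale of sigma^2
    a, b      Beta(a, b) prior on each group inclusion probability
    ridge     stabiliser for wide groups (k_g > n)
    """

    h0: float = 100.0
    c0: float | None = None
    nu0: float = 3.0
    sigma0_sq: float = 1.0
    a: float = 10.0
    b: float = 190.0
    ridge: float = 1.0

    def __post_init__(self) -> None:
        for name in ("h0", "nu0", "sigma0_sq", "a", "b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.c0 is not None and self.c0 <= 0:
            raise ValueError("c0 must be strictly positive (or None for n)")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")

    def c0_value(self, n: int) -> float:
        """Effective g-prior multiplier: explicit c0, or n (unit information)."""
        return float(self.c0) if self.c0 is not None else float(n)


class MarginalKernel:
    """Factorised H_gamma = I + h0 X0 X0' + c0 sum_{active} X_g Sigma_g X_g'.

    Holds the dense n x n kernel together with its Cholesky factor.  The
    effect of flipping a single group indicator is probed through the
    low-rank Woodbury/determinant-lemma identities on the group's
    half-kernel Z_g = X_g chol(Sigma_g) (H +/- c0 Z_g Z_g'), so a candidate
    evaluation costs one n x k triangular solve instead of an n x n
    factorisation; committing a flip updates the dense kernel in place and
    refactorises once.
    """

    def __init__(self, design: GroupedDesign, gamma: NDArray[np.intp],
                 hyper: Stage1Hyper):
        self.design = design
        self.hyper = hyper
        self.gamma = np.asarray(gamma, dtype=np.intp).copy()
        if self.gamma.shape[0] != design.n_groups:
            raise ValueError("gamma length must match the number of groups")
        self._Z = design.group_half_kernels()
        n = design.n
        self.c0 = hyper.c0_value(n)
        X0 = design.X0
        H = np.eye(n) + hyper.h0 * (X0 @ X0.T)
        if not np.all(np.isfinite(H)) or any(
                not np.all(np.isfinite(Z)) for Z in self._Z):
            raise ValueError("non-finite entries in the marginal kernel inputs")
        for g in np.flatnonzero(self.gamma == 1):
            Z = self._Z[g]
            H += self.c0 * (Z @ Z.T)
        self._H = H
        self._refactor()

    def _refactor(self) -> None:
        self._L = np.linalg.cholesky(self._H)
        self.logdet = 2.0 * np.sum(np.log(np.diag(self._L)))

    @property
    def matrix(self) -> NDArray[np.float64]:
        return self._H

    @property
    def chol(self) -> NDArray[np.float64]:
        """Lower-triangular L with H = L L'."""
        return self._L

    # -- queries ------------------------------------------------------
    def whiten(self, w: NDArray[np.float64]) -> NDArray[np.float64]:
        """u = L^{-1} w, so that w' H^{-1} w = u'u."""
        return linalg.solve_triangular(self._L, w, lower=True,
                                       check_finite=False)

    def quad_form(self, w: NDArray[np.float64]) -> float:
        u = self.whiten(w)
        return float(u @ u)

    def inverse(self) -> NDArray[np.float64]:
        K = linalg.cho_solve((self._L, True), np.eye(self.design.n),
                             check_finite=False)
        return (K + K.T) / 2.0

    def flip_stats(self, g: int, w: NDArray[np.float64] | None = None,
                   u: NDArray[np.float64] | None = None) -> tuple[float, float]:
        """(logdet, quad form) of the kernel with group g's indicator flipped.

        Pass either the outcome ``w`` or its whitened image ``u = L^{-1}w``
        under the current factor.  Uses the determinant lemma
        log|H ± c0 Z_g Z_g'| = log|H| + log|I ± c0 T'T| and the Woodbury
        correction to the quadratic form, with T = L^{-1} Z_g.
        """
        if u is None:
            if w is None:
                raise ValueError("need w or its whitened image u")
            u = self.whiten(w)
        c0 = self.c0
        sgn = -1.0 if self.gamma[g] else 1.0  # +: add the group, -: remove it
        T = linalg.solve_triangular(self._L, self._Z[g], lower=True,
                                    check_finite=False)
        k = T.shape[1]
        C = np.eye(k) + sgn * c0 * (T.T @ T)
        try:
            Lc = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            Lc = np.linalg.cholesky(C + 1e-10 * np.eye(k))
        logdet = self.logdet + 2.0 * np.sum(np.log(np.diag(Lc)))
        r = T.T @ u
        y = linalg.solve_triangular(Lc, r, lower=True, check_finite=False)
        quad = float(u @ u) - sgn * c0 * float(y @ y)
        return logdet, quad

    def flip(self, g: int) -> None:
        """Commit a flip of gamma_g: rank-k update of H, one refactorisation."""
        Z = self._Z[g]
        if self.gamma[g]:
            self._H -= self.c0 * (Z @ Z.T)
        else:
            self._H += self.c0 * (Z @ Z.T)
        self.gamma[g] = 1 - self.gamma[g]
        self._refactor()



def marginal_kernel(design: GroupedDesign, gamma: NDArray[np.intp],
                    hyper: Stage1Hyper) -> MarginalKernel:
    """Build the factorised marginal covariance kernel H_gamma."""
    return MarginalKernel(design, gamma, hyper)


def log_marginal_t(
    w: NDArray[np.float64],
    H: MarginalKernel | NDArray[np.float64],
    nu0: float,
    sigma0_sq: float,
) -> float:
    """Log-density of w under the n-dim multivariate t_n(nu0, 0, sigma0^2 H).

    This is the marginal of the augmented log-times after integrating the
    regression coefficients and sigma^2 out of the hierarchical model.  The
    normalising constant is included: inclusion-probability ratios compare
    densities under kernels of different effective rank, so dropping
    constants would bias them.
    """
    w = np.asarray(w, dtype=np.float64)
    n = w.shape[0]
    if isinstance(H, MarginalKernel):
        logdet = H.logdet
        quad = H.quad_form(w)
    else:
        H = np.asarray(H, dtype=np.float64)
        try:
            L = np.linalg.cholesky(H)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "marginal kernel is not positive definite"
            ) from exc
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        u = linalg.solve_triangular(L, w, lower=True)
        quad = float(u @ u)
    return _log_mvt(n, nu0, sigma0_sq, logdet, quad)


def _log_mvt(n: int, nu0: float, sigma0_sq: float, logdet_H: float,
             quad: float) -> float:
    """Multivariate-t log-density from a precomputed determinant/quadratic."""
    half = 0.5
    return float(
        gammaln(half * (nu0 + n))
        - gammaln(half * nu0)
        - half * n * np.log(nu0 * np.pi * sigma0_sq)
        - half * logdet_H
        - half * (nu0 + n) * np.log1p(quad / (nu0 * sigma0_sq))
    )
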