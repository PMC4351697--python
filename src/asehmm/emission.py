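"""State-conditional emission probabilities for allele-specific read counts.

Given a hidden genotype/ASE state, the four observed base counts of a site
are multinomial with probability vector ``p(delta, e)`` where ``delta`` is the
ASE ratio (probability a read carries allele A) and ``e`` the mapping-error
rate, a third of which lands on each wrong base.  Point-mass states (AA,
balanced AT, TT) give a plain multinomial; the two ASE heterozygote states
marginalise the multinomial over a beta density rescaled onto (0.5, 1) or
(0, 0.5), computed here by Gauss-Legendre quadrature in log space.

The multinomial coefficient is included throughout, so emission values are
true log-probabilities (it cancels in posteriors but keeps per-individual
log-likelihoods interpretable).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import betaln, gammaln, logsumexp, xlogy

from .core_model import AlleleCountMatrix, DeltaSpec, ModelParameters, StateSpace

__all__ = [
    "DeltaSpec",
    "EmissionTable",
    "allele_probability_vector",
    "rescaled_beta_logpdf",
    "emission_logprob",
    "build_emission_table",
]

DEFAULT_QUAD_NODES = 64


def allele_probability_vector(delta, e: float) -> np.ndarray:
    """Probability of observing a read as A, C, G or T.

    ``((1 - 4e/3) delta + e/3, e/3, e/3, (4e/3 - 1) delta + 1 - e)``; the
    components sum to one identically.  ``delta`` is the ASE ratio in [0, 1]
    (scalar or array; an array yields a stacked (..., 4) matrix), ``e`` the
    mapping-error rate in [0, 0.75] (in practice far below 0.5).
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0) or np.any(delta > 1):
        raise ValueError("delta outside [0, 1]")
    if not 0.0 <= e <= 0.75:
        raise ValueError(f"e={e} outside [0, 0.75]")
    pa = (1.0 - 4.0 * e / 3.0) * delta + e / 3.0
    pt = (4.0 * e / 3.0 - 1.0) * delta + 1.0 - e
    err = np.broadcast_to(e / 3.0, delta.shape)
    return np.stack([pa, err, err, pt], axis=-1)


def rescaled_beta_logpdf(x, S: float, U: float, alpha: float, beta: float):
    """Log-density of a beta distribution rescaled onto the open interval (S, U).

    ``f(x) = (x-S)^(alpha-1) (U-x)^(beta-1) / ((U-S)^(alpha+beta-1) B(alpha, beta))``
    for ``S < x < U``; ``-inf`` outside (open support).
    """
    if not S < U:
        raise ValueError(f"need S < U, got S={S}, U={U}")
    if alpha <= 0 or beta <= 0:
        raise ValueError(f"shapes must be positive, got alpha={alpha}, beta={beta}")
    x = np.asarray(x, dtype=float)
    inside = (x > S) & (x < U)
    out = np.full(x.shape, -np.inf)
    xs = x[inside]
    out[inside] = (
        (alpha - 1.0) * np.log(xs - S)
        + (beta - 1.0) * np.log(U - xs)
        - (alpha + beta - 1.0) * np.log(U - S)
        - betaln(alpha, beta)
    )
    return out if out.ndim else float(out)


def _multinomial_logcoef(x: np.ndarray) -> np.ndarray:
    """log n! / (x1! x2! x3! x4!) along the last axis."""
    n = x.sum(axis=-1)
    return gammaln(n + 1.0) - gammaln(np.asarray(x) + 1.0).sum(axis=-1)


@lru_cache(maxsize=8)
def _leggauss(nodes: int):
    z, w = np.polynomial.legendre.leggauss(nodes)
    return z, w


def _quad_points(S: float, U: float, nodes: int):
    """Gauss-Legendre abscissae and log-weights mapped onto (S, U)."""
    z, w = _leggauss(nodes)
    half = 0.5 * (U - S)
    return S + half * (z + 1.0), np.log(w * half)


def emission_logprob(
    x, state: DeltaSpec, e: float, quad_nodes: int = DEFAULT_QUAD_NODES
) -> float:
    """Log-probability of one 4-vector of base counts under one state.

    Point-mass states evaluate the multinomial at the fixed ASE ratio; beta
    states integrate the multinomial kernel against the rescaled-beta density
    by ``quad_nodes``-point Gauss-Legendre quadrature, combined with
    log-sum-exp.  Zero-probability outcomes (possible only at ``e = 0``)
    return ``-inf``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (4,):
        raise ValueError("x must be a 4-vector of counts")
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    logcoef = _multinomial_logcoef(x)
    if state.kind == "point":
        p = allele_probability_vector(state.value, e)
        return float(logcoef + xlogy(x, p).sum())
    if state.alpha is None or state.beta is None:
        raise ValueError("rescaled_beta spec must be resolved (concrete shapes)")
    S, U = state.support
    if quad_nodes < 2:
        raise ValueError("quad_nodes must be >= 2")
    d, logw = _quad_points(S, U, quad_nodes)
    logf = rescaled_beta_logpdf(d, S, U, state.alpha, state.beta)
    # multinomial log-kernel at every node
    P = allele_probability_vector(d, e)  # (T, 4)
    logkern = xlogy(x[None, :], P).sum(axis=1)
    return float(logcoef + logsumexp(logw + logf + logkern))


def _beta_state_logprob_batch(
    counts2d: np.ndarray,
    logcoef: np.ndarray,
    spec: DeltaSpec,
    e: float,
    quad_nodes: int,
) -> np.ndarray:
    """Vectorized marginal emission for one rescaled-beta state.

    ``counts2d`` has shape (N, 4).  Uses a matmul fast path when every node
    probability is strictly positive (always true for e > 0).
    """
    S, U = spec.support
    d, logw = _quad_points(S, U, quad_nodes)
    logf = rescaled_beta_logpdf(d, S, U, spec.alpha, spec.beta)
    P = allele_probability_vector(d, e)  # (T, 4)
    if np.all(P > 0):
        logkern = counts2d @ np.log(P).T  # (N, T)
    else:
        logkern = xlogy(counts2d[:, None, :], P[None, :, :]).sum(axis=2)
    return logcoef + logsumexp(logkern + (logw + logf)[None, :], axis=1)


def _point_state_logprob_batch(
    counts2d: np.ndarray, logcoef: np.ndarray, a: float, e: float
) -> np.ndarray:
    p = allele_probability_vector(a, e)
    if np.all(p > 0):
        return logcoef + counts2d @ np.log(p)
    return logcoef + xlogy(counts2d, p[None, :]).sum(axis=1)


@dataclass
class EmissionTable:
    """Per-site, per-state emission log-probabilities.

    ``logb[i, l, k]`` is the log-probability of the counts of individual
    ``i`` at SNP ``l`` under hidden state ``k`` (state order of the space).
    Sites with zero coverage have ``logb = 0`` for every state: they carry no
    emission information and are imputed purely from the chain.
    """

    logb: np.ndarray
    quadrature_nodes: int


def build_emission_table(
    counts: AlleleCountMatrix,
    space: StateSpace,
    theta: ModelParameters,
    quad_nodes: int = DEFAULT_QUAD_NODES,
) -> EmissionTable:
    """Emission log-probabilities for every (individual, SNP, state)."""
    logb = _emission_logb(counts.counts, space, theta, quad_nodes)
    return EmissionTable(logb=logb, quadrature_nodes=quad_nodes)


def _emission_logb(
    counts3d: np.ndarray,
    space: StateSpace,
    theta: ModelParameters,
    quad_nodes: int = DEFAULT_QUAD_NODES,
) -> np.ndarray:
    n, L, _ = counts3d.shape
    flat = counts3d.reshape(n * L, 4).astype(float)
    logcoef = _multinomial_logcoef(flat)
    cols = []
    for st in space.states:
        spec = st.delta.resolve(theta)
        if spec.kind == "point":
            col = _point_state_logprob_batch(flat, logcoef, spec.value, theta.e)
        else:
            col = _beta_state_logprob_batch(flat, logcoef, spec, theta.e, quad_nodes)
        cols.append(col)
    logb = np.stack(cols, axis=1).reshape(n, L, space.M)
    logb[counts3d.sum(axis=2) == 0] = 0.0  # zero coverage: no information
    return logb
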