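"""Forward-backward recursions, EM fitting, and genotype/ASE calling.

The hidden genotype/ASE state of each SNP in a block forms a homogeneous
Markov chain shared by all individuals; individuals are independent chains
with common parameters.  Posterior state probabilities come from scaled
forward-backward recursions.  Parameters are estimated by EM: the transition
matrix and initial distribution have closed-form updates from expected
counts, while the mapping-error rate (and optionally, for the ASE-aware
variant, the two pairs of beta shapes) is improved by bounded numerical
maximisation of the posterior-weighted emission log-likelihood — an
ECM-style step that preserves the generalised-EM ascent property.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from .core_model import (
    HET,
    NO_CALL,
    AlleleCountMatrix,
    ModelParameters,
    StateSpace,
    make_state_space,
    validate_parameters,
)
from .emission import (
    DEFAULT_QUAD_NODES,
    _emission_logb,
    _quad_points,
    allele_probability_vector,
    rescaled_beta_logpdf,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PosteriorResult",
    "FitResult",
    "GenotypeCallSet",
    "default_initial_parameters",
    "forward_backward",
    "em_fit",
    "call_genotypes",
    "estimate_ase_ratio",
]


@dataclass
class PosteriorResult:
    """Posterior state probabilities and likelihood of a fitted block.

    ``gamma[i, l, k] = P(G_il = k | X)``; ``xi_sums[k, k']`` is the expected
    number of k -> k' transitions summed over individuals and positions;
    ``loglik_per_individual`` the observed-data log-likelihood of each
    individual's chain, ``loglik`` their sum.
    """

    gamma: np.ndarray
    xi_sums: np.ndarray
    loglik_per_individual: np.ndarray

    @property
    def loglik(self) -> float:
        return float(self.loglik_per_individual.sum())


@dataclass
class FitResult:
    theta_hat: ModelParameters
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    posterior: PosteriorResult


@dataclass
class GenotypeCallSet:
    """Hard genotype + ASE calls for every (individual, SNP).

    ``calls`` holds genotype codes (HOM_A/HET/HOM_T/NO_CALL); ``ase_status``
    is defined (>= 0) only for heterozygous calls under the ASE variant;
    ``map_state`` is the MAP hidden-state index (1-based);
    ``ase_ratio_hat`` the posterior-mean ASE ratio (ASE variant only).
    """

    calls: np.ndarray
    ase_status: np.ndarray
    map_state: np.ndarray
    posterior_max: np.ndarray
    ase_ratio_hat: np.ndarray | None
    variant: str


def default_initial_parameters(
    space: StateSpace,
    diag: float = 0.7,
    e0: float = 0.01,
    rng: np.random.Generator | None = None,
) -> ModelParameters:
    """Diagonal-heavy starting point for EM.

    The diagonal-dominant transition matrix reflects linkage disequilibrium
    (adjacent SNPs tend to share their state); the beta shapes start at
    (30, 10) / (10, 30), concentrating the A-/T-biased ASE ratios around
    0.75 and 0.25.  With ``rng``, the start is jittered for random restarts.
    """
    M = space.M
    A = np.full((M, M), (1.0 - diag) / (M - 1))
    np.fill_diagonal(A, diag)
    pi = np.full(M, 1.0 / M)
    if space.variant == "ASE":
        theta = ModelParameters(A=A, pi=pi, e=e0, alpha1=30.0, beta1=10.0,
                                alpha2=10.0, beta2=30.0)
    else:
        theta = ModelParameters(A=A, pi=pi, e=e0)
    if rng is not None:
        A = A * np.exp(rng.uniform(-0.3, 0.3, size=A.shape))
        theta.A = A / A.sum(axis=1, keepdims=True)
        pi = pi * np.exp(rng.uniform(-0.3, 0.3, size=M))
        theta.pi = pi / pi.sum()
        theta.e = float(np.clip(e0 * np.exp(rng.uniform(-1, 1)), *theta.e_bounds))
        if space.variant == "ASE":
            for name in ("alpha1", "beta1", "alpha2", "beta2"):
                setattr(theta, name,
                        float(getattr(theta, name) * np.exp(rng.uniform(-0.3, 0.3))))
    return validate_parameters(theta, space)


def _forward_backward_batch(logb: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward for a batch of independent chains.

    ``logb`` has shape (n, L, M).  Returns gamma (n, L, M), xi_sums (M, M)
    accumulated over all chains and positions, and loglik (n,).
    """
    n, L, M = logb.shape
    m = logb.max(axis=2)
    bad = ~np.isfinite(m)
    if np.any(bad):
        i, l = np.argwhere(bad)[0]
        raise ValueError(
            f"observation at individual {i}, SNP {l} has zero probability "
            "under every hidden state"
        )
    b = np.exp(logb - m[:, :, None])  # (n, L, M), max 1 per site
    alpha_hat = np.empty((n, L, M))
    c = np.empty((n, L))
    a = pi[None, :] * b[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    if np.any(c[:, 0] <= 0):
        i = int(np.argwhere(c[:, 0] <= 0)[0][0])
        raise ValueError(f"zero forward mass at individual {i}, SNP 0")
    alpha_hat[:, 0] = a / c[:, 0, None]
    for l in range(1, L):
        a = (alpha_hat[:, l - 1] @ A) * b[:, l]
        c[:, l] = a.sum(axis=1)
        if np.any(c[:, l] <= 0):
            i = int(np.argwhere(c[:, l] <= 0)[0][0])
            raise ValueError(f"zero forward mass at individual {i}, SNP {l}")
        alpha_hat[:, l] = a / c[:, l, None]
    beta_hat = np.empty((n, L, M))
    beta_hat[:, L - 1] = 1.0
    xi_sums = np.zeros((M, M))
    for l in range(L - 2, -1, -1):
        w = b[:, l + 1] * beta_hat[:, l + 1] / c[:, l + 1, None]  # (n, M)
        beta_hat[:, l] = w @ A.T
        xi_sums += (alpha_hat[:, l].T @ w) * A
    gamma = alpha_hat * beta_hat
    gamma /= gamma.sum(axis=2, keepdims=True)
    loglik = np.log(c).sum(axis=1) + m.sum(axis=1)
    return gamma, xi_sums, loglik


def forward_backward(logb_i: np.ndarray, theta: ModelParameters, space: StateSpace):
    """Posteriors and log-likelihood for a single individual's chain.

    Parameters
    ----------
    logb_i
        Emission log-probabilities, shape (L, M).

    Returns
    -------
    gamma : (L, M) posterior state probabilities
    xi : (M, M) expected transition counts summed over positions
    loglik : float, log P(X_i | theta)
    """
    logb_i = np.asarray(logb_i, dtype=float)
    if logb_i.ndim != 2 or logb_i.shape[1] != space.M:
        raise ValueError(f"logb must have shape (L, {space.M})")
    gamma, xi, ll = _forward_backward_batch(logb_i[None], theta.A, theta.pi)
    return gamma[0], xi, float(ll[0])


def _unique_counts(counts3d: np.ndarray):
    flat = counts3d.reshape(-1, 4)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    return uniq.astype(np.int64), inverse


def _logb_from_unique(uniq_logb: np.ndarray, inverse: np.ndarray, n: int, L: int):
    return uniq_logb[inverse].reshape(n, L, uniq_logb.shape[1])


def _emission_q(W_nz, uniq_nz, space, theta, quad_nodes):
    """Posterior-weighted emission log-likelihood over unique count vectors.

    The multinomial coefficient is omitted: it is constant in the parameters
    and cancels when comparing candidate values.
    """
    logb = np.empty((uniq_nz.shape[0], space.M))
    flat = uniq_nz.astype(float)
    from scipy.special import xlogy

    for k, st in enumerate(space.states):
        spec = st.delta.resolve(theta)
        if spec.kind == "point":
            p = allele_probability_vector(spec.value, theta.e)
            logb[:, k] = xlogy(flat, p[None, :]).sum(axis=1)
        else:
            S, U = spec.support
            d, logw = _quad_points(S, U, quad_nodes)
            logf = rescaled_beta_logpdf(d, S, U, spec.alpha, spec.beta)
            P = allele_probability_vector(d, theta.e)
            if np.all(P > 0):
                logkern = flat @ np.log(P).T
            else:
                logkern = xlogy(flat[:, None, :], P[None, :, :]).sum(axis=2)
            logb[:, k] = logsumexp(logkern + (logw + logf)[None, :], axis=1)
    val = float((W_nz * logb).sum())
    return val if np.isfinite(val) else -np.inf


_SHAPE_BOUNDS = (1e-2, 1e4)


def _update_continuous(theta, space, W_nz, uniq_nz, quad_nodes,
                       estimate_shapes=False):
    """ECM step: improve e (and optionally the beta shapes) numerically.

    Beta shapes are optimised on the log scale; the step is accepted only if
    it does not decrease the weighted emission log-likelihood, so the EM
    ascent property is preserved.
    """
    ase = space.variant == "ASE" and estimate_shapes

    def unpack(x):
        t = theta.copy()
        t.e = float(x[0])
        if ase:
            t.alpha1, t.beta1, t.alpha2, t.beta2 = np.exp(x[1:5])
        return t

    q_old = _emission_q(W_nz, uniq_nz, space, theta, quad_nodes)
    try:
        if ase:
            x0 = np.array([theta.e, np.log(theta.alpha1), np.log(theta.beta1),
                           np.log(theta.alpha2), np.log(theta.beta2)])
            bounds = [theta.e_bounds] + [tuple(np.log(_SHAPE_BOUNDS))] * 4
            res = minimize(
                lambda x: -_emission_q(W_nz, uniq_nz, space, unpack(x),
                                       quad_nodes),
                x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 25, "maxfun": 100})
            q_new, x_new = -res.fun, res.x
        else:
            res = minimize_scalar(
                lambda e: -_emission_q(W_nz, uniq_nz, space,
                                       unpack(np.array([e])), quad_nodes),
                bounds=theta.e_bounds, method="bounded",
                options={"xatol": 1e-10})
            q_new, x_new = -res.fun, np.array([res.x])
    except Exception as exc:  # pragma: no cover - optimizer failure fallback
        logger.warning("continuous M-step optimizer failed (%s); keeping "
                       "previous values", exc)
        return theta
    if np.isfinite(q_new) and q_new >= q_old:
        return unpack(x_new)
    logger.debug("continuous M-step did not improve (%.6g -> %.6g); keeping "
                 "previous values", q_old, q_new)
    return theta


def em_fit(
    counts: AlleleCountMatrix,
    space: StateSpace,
    init_theta: ModelParameters | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    quad_nodes: int = DEFAULT_QUAD_NODES,
    n_restarts: int = 1,
    rng: np.random.Generator | None = None,
    estimate_shapes: bool = False,
) -> FitResult:
    """Fit the chain parameters to one block of counts by (generalised) EM.

    The E-step runs scaled forward-backward over all individuals; the M-step
    updates the transition matrix and initial distribution in closed form
    from expected counts and improves the mapping-error rate numerically
    (one-dimensional bounded search).  By default the beta shapes of the two
    ASE states are held fixed at their initial values: they act as
    hyperparameters of the ASE-ratio laws, because their unpenalised MLE is
    ill-posed at typical block sizes (a flattened A-biased beta can absorb
    homozygous sites with higher likelihood, wrecking the calls);
    ``estimate_shapes=True`` enables the full joint maximisation.  Iteration
    stops when the observed-data log-likelihood improves by less than
    ``tol`` or after ``max_iter`` iterations.  With ``n_restarts > 1``
    additional jittered initialisations are tried (seeded via ``rng``) and
    the fit with the highest log-likelihood is returned.
    """
    if counts.n_individuals < 1 or counts.n_snps < 1:
        raise ValueError("need at least one individual and one SNP")
    best: FitResult | None = None
    if n_restarts > 1 and rng is None:
        rng = np.random.default_rng(0)
    for r in range(max(1, n_restarts)):
        if r == 0 and init_theta is not None:
            theta0 = validate_parameters(init_theta, space)
        elif r == 0:
            theta0 = default_initial_parameters(space)
        else:
            theta0 = default_initial_parameters(space, rng=rng)
        fit = _em_fit_single(counts, space, theta0, tol, max_iter, quad_nodes,
                             estimate_shapes)
        if best is None or fit.posterior.loglik > best.posterior.loglik:
            best = fit
    return best


def _em_fit_single(counts, space, theta, tol, max_iter, quad_nodes,
                   estimate_shapes=False) -> FitResult:
    n, L = counts.n_individuals, counts.n_snps
    uniq, inverse = _unique_counts(counts.counts)
    nz_mask = uniq.sum(axis=1) > 0
    uniq_nz = uniq[nz_mask]
    # map flat site index -> row of uniq_nz (-1 for zero-coverage sites)
    nz_row = np.full(uniq.shape[0], -1, dtype=np.int64)
    nz_row[nz_mask] = np.arange(nz_mask.sum())
    site_row = nz_row[inverse]

    trace = []
    converged = False
    gamma = xi_sums = logliks = None
    for it in range(max_iter):
        uniq_logb = _emission_logb(uniq.reshape(1, -1, 4), space, theta, quad_nodes)[0]
        logb = _logb_from_unique(uniq_logb, inverse, n, L)
        gamma, xi_sums, logliks = _forward_backward_batch(logb, theta.A, theta.pi)
        ll = float(logliks.sum())
        trace.append(ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            converged = True
            break
        # M-step: closed-form chain updates
        new = theta.copy()
        row = xi_sums.sum(axis=1)
        A_new = theta.A.copy()
        pos = row > 0
        A_new[pos] = xi_sums[pos] / row[pos, None]
        new.A = A_new
        new.pi = gamma[:, 0, :].mean(axis=0)
        new.pi /= new.pi.sum()
        # M-step: posterior-weighted emission improvement for e (and shapes)
        gflat = gamma.reshape(-1, space.M)
        keep = site_row >= 0
        W_nz = np.zeros((uniq_nz.shape[0], space.M))
        np.add.at(W_nz, site_row[keep], gflat[keep])
        new = _update_continuous(new, space, W_nz, uniq_nz, quad_nodes,
                                 estimate_shapes)
        theta = validate_parameters(new, space)
    posterior = PosteriorResult(gamma=gamma, xi_sums=xi_sums,
                                loglik_per_individual=logliks)
    logger.info("EM finished after %d iterations (converged=%s, loglik=%.4f)",
                len(trace), converged, trace[-1])
    return FitResult(theta_hat=theta, loglik_trace=np.array(trace),
                     n_iter=len(trace), converged=converged, posterior=posterior)


def call_genotypes(
    posterior: PosteriorResult,
    counts: AlleleCountMatrix,
    space: StateSpace,
    noncall_on_zero: bool = False,
    min_posterior: float = 0.0,
    theta: ModelParameters | None = None,
    quad_nodes: int = DEFAULT_QUAD_NODES,
) -> GenotypeCallSet:
    """MAP genotype + ASE-status calls from posterior state probabilities.

    The MAP state of each site determines the genotype (states 2-4 project to
    heterozygous) and, under the ASE variant, the ASE status of heterozygous
    calls.  Sites become NO_CALL when ``noncall_on_zero`` is set and they
    have zero reads, or when the MAP posterior mass falls below
    ``min_posterior`` (default 0: pure MAP calling).  Exact posterior ties
    resolve to the lowest state index.  When ``theta`` is supplied under the
    ASE variant, posterior-mean ASE ratios are attached.
    """
    gamma = posterior.gamma
    n, L, M = gamma.shape
    if (n, L) != counts.counts.shape[:2] or M != space.M:
        raise ValueError("posterior, counts and state space are not aligned")
    kstar = gamma.argmax(axis=2)  # ties -> lowest index
    tie = (gamma == gamma.max(axis=2, keepdims=True)).sum(axis=2) > 1
    if np.any(tie):
        logger.info("%d sites had exact posterior ties; called the lowest "
                    "state index", int(tie.sum()))
    posterior_max = np.take_along_axis(gamma, kstar[:, :, None], axis=2)[:, :, 0]
    proj = space.genotype_projection()
    calls = proj[kstar]
    status_by_state = np.array(
        [s.ase_status if s.ase_status is not None else -1 for s in space.states]
    )
    ase_status = np.where(calls == HET, status_by_state[kstar], -1)
    no_call = posterior_max < min_posterior
    if noncall_on_zero:
        no_call |= counts.totals == 0
    calls = np.where(no_call, NO_CALL, calls)
    ase_status = np.where(no_call, -1, ase_status)
    ratio = None
    if space.variant == "ASE" and theta is not None:
        ratio = _posterior_mean_delta(counts.counts, gamma, space, theta, quad_nodes)
    state_index = np.array([s.index for s in space.states])
    return GenotypeCallSet(
        calls=calls,
        ase_status=ase_status,
        map_state=state_index[kstar],
        posterior_max=posterior_max,
        ase_ratio_hat=ratio,
        variant=space.variant,
    )


def _beta_state_mean_delta(flat_counts, spec, e, quad_nodes):
    """E[delta | X, G=k] for one rescaled-beta state, all sites at once."""
    from scipy.special import xlogy

    S, U = spec.support
    d, logw = _quad_points(S, U, quad_nodes)
    logf = rescaled_beta_logpdf(d, S, U, spec.alpha, spec.beta)
    P = allele_probability_vector(d, e)
    if np.all(P > 0):
        logkern = flat_counts @ np.log(P).T
    else:
        logkern = xlogy(flat_counts[:, None, :], P[None, :, :]).sum(axis=2)
    base = logkern + (logw + logf)[None, :]
    log_den = logsumexp(base, axis=1)
    log_num = logsumexp(base + np.log(d)[None, :], axis=1)
    return np.exp(log_num - log_den)


def _posterior_mean_delta(counts3d, gamma, space, theta, quad_nodes):
    n, L, _ = counts3d.shape
    flat = counts3d.reshape(-1, 4).astype(float)
    mean_by_state = np.empty((n * L, space.M))
    for k, st in enumerate(space.states):
        spec = st.delta.resolve(theta)
        if spec.kind == "point":
            mean_by_state[:, k] = spec.value
        else:
            mean_by_state[:, k] = _beta_state_mean_delta(flat, spec, theta.e,
                                                         quad_nodes)
    return (gamma.reshape(-1, space.M) * mean_by_state).sum(axis=1).reshape(n, L)


def estimate_ase_ratio(
    x,
    gamma_row: np.ndarray,
    theta: ModelParameters,
    space: StateSpace | None = None,
    quad_nodes: int = DEFAULT_QUAD_NODES,
) -> float:
    """Posterior-mean ASE ratio E[delta | X] at one site.

    Mixes the per-state conditional means with the posterior state weights:
    point states contribute their fixed ratio, beta states the quadrature
    ratio of first to zeroth posterior moments of delta.  Only meaningful
    under the ASE variant; the NASE variant has no ASE ratios to estimate.
    """
    if space is None:
        space = make_state_space("ASE")
    if space.variant != "ASE":
        raise ValueError("ASE-ratio estimation requires the ASE model variant")
    x = np.asarray(x, dtype=float).reshape(1, 4)
    gamma_row = np.asarray(gamma_row, dtype=float)
    if gamma_row.shape != (space.M,):
        raise ValueError(f"gamma row must have length {space.M}")
    means = np.empty(space.M)
    for k, st in enumerate(space.states):
        spec = st.delta.resolve(theta)
        if spec.kind == "point":
            means[k] = spec.value
        else:
            means[k] = _beta_state_mean_delta(x, spec, theta.e, quad_nodes)[0]
    return float((gamma_row * means).sum())
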