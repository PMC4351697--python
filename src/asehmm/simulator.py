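"""Synthetic data generator: LD-constrained haplotypes and read counts.

The generator mirrors the benchmarking design the model is built for.  Each
individual's genotype at a block of biallelic SNPs is the combination of two
independent haplotypes.  A haplotype is a first-order Markov chain over
alleles {A, T}: the first allele is Bernoulli(p_A) and each subsequent allele
is drawn from the conditional of the pairwise joint implied by a constant
linkage-disequilibrium level, measured by the squared-correlation statistic

    LD = (p_AA - p_A. p_.A)^2 / (p_A. p_T. p_.A p_.T).

Heterozygotes are split between a balanced state and an A-biased ASE state
whose ratio is drawn from a standard Beta(30, 10) (mode 29/38 ~ 0.763, so
expression is concentrated around 75% allele A); the T-biased ASE state is
excluded from generation by default, while fitted models may still carry it.
Per-site read totals are negative-binomial NB(lambda, 0.4) in the size /
success-probability convention (mean 1.5*lambda); allele-specific counts are
multinomial given the site's ASE ratio and the mapping-error rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    AlleleCountMatrix,
    ModelParameters,
    StateSpace,
    make_state_space,
)
from .emission import allele_probability_vector

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationScenario",
    "SimulatedDataset",
    "pairwise_joint_from_ld",
    "simulate_haplotype",
    "simulate_dataset",
    "simulate_from_hmm",
    "run_scenario_grid",
]

#: hidden-state codes used for generated truth (1-based, matching the model)
_STATE_AA, _STATE_NASE, _STATE_HIGH, _STATE_LOW, _STATE_TT = 1, 2, 3, 4, 5
_GENO_OF_STATE = {1: 0, 2: 1, 3: 1, 4: 1, 5: 2}


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulation design.

    ``lambda_`` and ``nb_second`` parameterise the negative-binomial read
    totals (size/prob convention by default: mean ``1.5 * lambda_`` at
    ``nb_second = 0.4``); ``ld`` is the constant pairwise LD between adjacent
    SNPs; ``phi_ase`` the probability that a heterozygote is A-biased ASE
    rather than balanced; ``ase_high_shape`` the (alpha, beta) of the
    generating beta for the ASE ratio of A-biased heterozygotes (standard
    support (0, 1)); ``e_sim`` the mapping-error rate used in generation.
    """

    n: int
    L: int
    lambda_: float
    ld: float
    nb_second: float = 0.4
    nb_parameterization: str = "size_prob"  # or "mean_size"
    p_A: float = 0.5
    ase_states: tuple[int, ...] = (_STATE_AA, _STATE_NASE, _STATE_HIGH, _STATE_TT)
    ase_high_shape: tuple[float, float] = (30.0, 10.0)
    phi_ase: float = 0.5
    e_sim: float = 0.01
    reps: int = 10
    seed: int = 0
    position_spacing: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.p_A < 1):
            raise ValueError("p_A must be in (0, 1)")
        if not (0 <= self.ld <= 1):
            raise ValueError("ld must be in [0, 1]")
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if not (0 <= self.phi_ase <= 1):
            raise ValueError("phi_ase must be in [0, 1]")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.nb_parameterization not in ("size_prob", "mean_size"):
            raise ValueError("nb_parameterization must be size_prob or mean_size")


@dataclass
class SimulatedDataset:
    counts: AlleleCountMatrix
    true_states: np.ndarray     # (n, L), 1-based state codes
    true_genotypes: np.ndarray  # (n, L), genotype codes
    true_delta: np.ndarray      # (n, L)


def pairwise_joint_from_ld(p_A: float, ld: float) -> tuple[float, float, float, float]:
    """Joint allele probabilities (p_AA, p_AT, p_TA, p_TT) of adjacent SNPs.

    Inverts the squared-correlation LD statistic under symmetric marginals
    ``p_A. = p_.A = p_A``, taking the positive root (positive allelic
    association); the statistic itself is sign-invariant.
    """
    if not 0 < p_A < 1:
        raise ValueError("p_A must be in (0, 1)")
    if not 0 <= ld <= 1:
        raise ValueError("ld must be in [0, 1]")
    q = 1.0 - p_A
    p_aa = p_A * p_A + np.sqrt(ld * (p_A * q) * (p_A * q))
    p_at = p_A - p_aa
    p_ta = p_A - p_aa
    p_tt = 1.0 - p_aa - p_at - p_ta
    cells = (p_aa, p_at, p_ta, p_tt)
    if any(c < -1e-12 or c > 1 + 1e-12 for c in cells):
        raise ValueError(f"ld={ld} incompatible with p_A={p_A}: joint {cells}")
    return tuple(float(np.clip(c, 0.0, 1.0)) for c in cells)


def simulate_haplotype(
    L: int, p_A: float, ld: float, rng: np.random.Generator
) -> np.ndarray:
    """One haplotype of ``L`` alleles coded 0 (A) / 1 (T).

    The chain is stationary: the marginal allele-A probability is ``p_A`` at
    every position, and adjacent positions have the target pairwise LD.
    """
    hap = _simulate_haplotypes(1, L, p_A, ld, rng)
    return hap[0]


def _simulate_haplotypes(m, L, p_A, ld, rng):
    p_aa, p_at, p_ta, p_tt = pairwise_joint_from_ld(p_A, ld)
    # conditional P(next = A | current)
    p_a_given_a = p_aa / p_A
    p_a_given_t = p_ta / (1.0 - p_A)
    hap = np.empty((m, L), dtype=np.int8)
    hap[:, 0] = rng.random(m) >= p_A  # 0 = A with prob p_A
    for l in range(1, L):
        p_next_a = np.where(hap[:, l - 1] == 0, p_a_given_a, p_a_given_t)
        hap[:, l] = rng.random(m) >= p_next_a
    return hap


def _draw_totals(scn: SimulationScenario, size, rng) -> np.ndarray:
    if scn.nb_parameterization == "size_prob":
        return rng.negative_binomial(scn.lambda_, scn.nb_second, size=size)
    # mean_size: lambda_ is the mean, nb_second the size (dispersion)
    size_p = scn.nb_second / (scn.nb_second + scn.lambda_)
    return rng.negative_binomial(scn.nb_second, size_p, size=size)


def simulate_dataset(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> SimulatedDataset:
    """Generate one replicate dataset from the scenario.

    Genotypes combine two independent haplotypes; heterozygotes become
    A-biased ASE with probability ``phi_ase`` (when the A-biased state is in
    ``ase_states``), otherwise balanced; the ASE ratio of each site follows
    its state's generating law; totals are negative-binomial and counts
    multinomial given the ratio and the mapping error.  Reproducible from
    ``scenario.seed`` when no ``rng`` is passed.
    """
    scn = scenario
    if rng is None:
        rng = np.random.default_rng(scn.seed)
    hap1 = _simulate_haplotypes(scn.n, scn.L, scn.p_A, scn.ld, rng)
    hap2 = _simulate_haplotypes(scn.n, scn.L, scn.p_A, scn.ld, rng)
    geno_sum = hap1 + hap2  # 0 = AA, 1 = AT, 2 = TT
    states = np.where(geno_sum == 0, _STATE_AA,
                      np.where(geno_sum == 2, _STATE_TT, _STATE_NASE))
    het = geno_sum == 1
    high_ok = _STATE_HIGH in scn.ase_states
    low_ok = _STATE_LOW in scn.ase_states
    if het.any() and (high_ok or low_ok):
        u = rng.random(states.shape)
        if high_ok and low_ok:
            states[het & (u < scn.phi_ase / 2)] = _STATE_HIGH
            states[het & (u >= scn.phi_ase / 2) & (u < scn.phi_ase)] = _STATE_LOW
        elif high_ok:
            states[het & (u < scn.phi_ase)] = _STATE_HIGH
        else:
            states[het & (u < scn.phi_ase)] = _STATE_LOW
    a, b = scn.ase_high_shape
    delta = np.where(states == _STATE_AA, 1.0,
                     np.where(states == _STATE_TT, 0.0, 0.5))
    n_high = int((states == _STATE_HIGH).sum())
    if n_high:
        delta[states == _STATE_HIGH] = rng.beta(a, b, size=n_high)
    n_low = int((states == _STATE_LOW).sum())
    if n_low:
        delta[states == _STATE_LOW] = rng.beta(b, a, size=n_low)
    totals = _draw_totals(scn, states.shape, rng)
    pvecs = allele_probability_vector(delta.ravel(), scn.e_sim)
    counts = rng.multinomial(totals.ravel(), pvecs).reshape(scn.n, scn.L, 4)
    acm = AlleleCountMatrix(
        counts=counts,
        positions=1 + scn.position_spacing * np.arange(scn.L),
        snp_ids=[f"snp{l + 1}" for l in range(scn.L)],
        individual_ids=[f"ind{i + 1}" for i in range(scn.n)],
        chroms=["chr1"] * scn.L,
        ref_alleles=["A"] * scn.L,
        alt_alleles=["T"] * scn.L,
    )
    genotypes = np.vectorize(_GENO_OF_STATE.get)(states)
    return SimulatedDataset(counts=acm, true_states=states,
                            true_genotypes=genotypes, true_delta=delta)


def simulate_from_hmm(
    theta: ModelParameters,
    space: StateSpace,
    n: int,
    L: int,
    lambda_: float,
    nb_second: float = 0.4,
    e_sim: float | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Generate data directly from the fitted model's own generative process.

    Hidden states follow the chain (``theta.pi``, ``theta.A``); ASE ratios
    follow each state's conditional law, including the rescaled-beta
    supports; counts are multinomial with mapping error ``e_sim`` (default
    ``theta.e``).  Used for parameter-recovery checks where the generator and
    the model coincide.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if e_sim is None:
        e_sim = theta.e
    M = space.M
    states_idx = np.empty((n, L), dtype=np.int64)  # 0-based positions in space
    states_idx[:, 0] = rng.choice(M, size=n, p=theta.pi)
    cum = theta.A.cumsum(axis=1)
    for l in range(1, L):
        u = rng.random(n)
        states_idx[:, l] = (u[:, None] > cum[states_idx[:, l - 1]]).sum(axis=1)
    delta = np.empty((n, L))
    for k, st in enumerate(space.states):
        mask = states_idx == k
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        spec = st.delta.resolve(theta)
        if spec.kind == "point":
            delta[mask] = spec.value
        else:
            S, U = spec.support
            delta[mask] = S + (U - S) * rng.beta(spec.alpha, spec.beta, size=cnt)
    totals = rng.negative_binomial(lambda_, nb_second, size=(n, L))
    pvecs = allele_probability_vector(delta.ravel(), e_sim)
    counts = rng.multinomial(totals.ravel(), pvecs).reshape(n, L, 4)
    acm = AlleleCountMatrix(
        counts=counts,
        positions=1 + 100 * np.arange(L),
        snp_ids=[f"snp{l + 1}" for l in range(L)],
        individual_ids=[f"ind{i + 1}" for i in range(n)],
        ref_alleles=["A"] * L,
        alt_alleles=["T"] * L,
    )
    state_codes = np.array([s.index for s in space.states])[states_idx]
    genotypes = np.vectorize(_GENO_OF_STATE.get)(state_codes)
    return SimulatedDataset(counts=acm, true_states=state_codes,
                            true_genotypes=genotypes, true_delta=delta)


def run_scenario_grid(
    scenarios: Sequence[SimulationScenario] | SimulationScenario,
    variants: Iterable[str] = ("ASE", "NASE"),
    master_seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    quad_nodes: int = 64,
    noncall_on_zero: bool = False,
    min_posterior: float = 0.0,
) -> pd.DataFrame:
    """Run the simulate -> fit -> call -> score loop over a scenario grid.

    For each scenario, replicate and model variant: simulate a dataset with a
    seed derived deterministically from ``master_seed`` and the (scenario,
    replicate) index, fit the variant by EM, MAP-call genotypes, and score
    EFDR/EFNR against the generating truth.  Returns a tidy table with one
    row per (scenario, variant, replicate); per-replicate failures are logged
    and recorded as missing rather than aborting the grid.
    """
    from .inference import call_genotypes, em_fit
    from .metrics import score_calls

    if isinstance(scenarios, SimulationScenario):
        scenarios = [scenarios]
    variants = list(variants)
    spaces = {v: make_state_space(v) for v in variants}
    rows = []
    for s_idx, scn in enumerate(scenarios):
        for rep in range(scn.reps):
            ss = np.random.SeedSequence([master_seed, s_idx, rep])
            rep_seed = int(ss.generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(ss)
            data = simulate_dataset(scn, rng=rng)
            for v in variants:
                row = {
                    "lambda": scn.lambda_, "ld": scn.ld, "n": scn.n,
                    "L": scn.L, "variant": v, "rep": rep, "seed": rep_seed,
                    "efdr": np.nan, "efnr": np.nan, "sensitivity": np.nan,
                }
                try:
                    fit = em_fit(data.counts, spaces[v], tol=tol,
                                 max_iter=max_iter, quad_nodes=quad_nodes)
                    calls = call_genotypes(fit.posterior, data.counts,
                                           spaces[v],
                                           noncall_on_zero=noncall_on_zero,
                                           min_posterior=min_posterior)
                    rep_report = score_calls(calls, data.true_genotypes)
                    row.update(efdr=rep_report.efdr, efnr=rep_report.efnr,
                               sensitivity=rep_report.sensitivity)
                except Exception as exc:
                    logger.warning(
                        "replicate failed (scenario %d, rep %d, %s): %s",
                        s_idx, rep, v, exc,
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def summarize_grid(results: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) of EFDR/EFNR per scenario cell and variant."""
    g = results.groupby(["lambda", "ld", "n", "L", "variant"], as_index=False)
    out = g.agg(
        efdr_mean=("efdr", "mean"), efdr_sd=("efdr", "std"),
        efnr_mean=("efnr", "mean"), efnr_sd=("efnr", "std"),
        reps=("rep", "count"),
    )
    return out
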