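"""Data model shared by the whole package.

Holds the allele-count container, the hidden-state catalogue for the two model
variants, and the full parameter vector of the chain.

Hidden states couple the genotype of a biallelic site (alleles A and T, or
ref/alt mapped onto those slots) with its allele-specific-expression (ASE)
status.  The ASE ratio ``delta`` is the probability that a read carries allele
A: homozygous AA pins ``delta`` at 1, a balanced heterozygote at 0.5,
homozygous TT at 0, and the two ASE heterozygote states draw ``delta`` from a
beta distribution rescaled onto (0.5, 1) (A-biased) or (0, 0.5) (T-biased).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

# Genotype codes used throughout (calls, truth tables, metrics).
HOM_A = 0
HET = 1
HOM_T = 2
NO_CALL = -1

GENOTYPE_LABELS = {HOM_A: "hom_a", HET: "het", HOM_T: "hom_t", NO_CALL: "no_call"}

# ASE-status codes for heterozygous calls under the 5-state variant.
NASE = 0
ASE_HIGH = 1
ASE_LOW = 2
ASE_STATUS_LABELS = {NASE: "nase", ASE_HIGH: "ase_high", ASE_LOW: "ase_low"}

_ALLELE_SLOTS = ("A", "C", "G", "T")


@dataclass(frozen=True)
class DeltaSpec:
    """Conditional law of the ASE ratio delta given a hidden state.

    ``kind`` is ``"point"`` (mass one at ``value``) or ``"rescaled_beta"``
    (beta density rescaled onto the open interval ``support``).  States of a
    :class:`StateSpace` carry *unresolved* beta specs whose shapes are looked
    up in the fitted parameters via ``shape_index`` (1 for the A-biased pair
    ``(alpha1, beta1)``, 2 for the T-biased pair); :meth:`resolve` substitutes
    concrete shapes.
    """

    kind: str
    value: float | None = None
    support: tuple[float, float] | None = None
    alpha: float | None = None
    beta: float | None = None
    shape_index: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("point", "rescaled_beta"):
            raise ValueError(f"unknown DeltaSpec kind {self.kind!r}")
        if self.kind == "point":
            if self.value is None or not 0.0 <= self.value <= 1.0:
                raise ValueError("point DeltaSpec needs a value in [0, 1]")
        else:
            if self.support is None:
                raise ValueError("rescaled_beta DeltaSpec needs a support")
            s, u = self.support
            if not (0.0 <= s < u <= 1.0):
                raise ValueError(f"invalid support ({s}, {u}); need 0 <= S < U <= 1")
            for name, v in (("alpha", self.alpha), ("beta", self.beta)):
                if v is not None and v <= 0:
                    raise ValueError(f"{name} must be > 0, got {v}")

    def resolve(self, theta: "ModelParameters") -> "DeltaSpec":
        """Return a concrete spec with shapes filled in from ``theta``."""
        if self.kind == "point":
            return self
        if self.alpha is not None and self.beta is not None:
            return self
        if self.shape_index == 1:
            return replace(self, alpha=theta.alpha1, beta=theta.beta1)
        if self.shape_index == 2:
            return replace(self, alpha=theta.alpha2, beta=theta.beta2)
        raise ValueError("rescaled_beta spec has neither shapes nor a shape_index")


@dataclass(frozen=True)
class HiddenState:
    index: int            # 1-based state code (1..5)
    label: str            # AA / AT-NASE / AT-ASE-HIGH / AT-ASE-LOW / TT
    genotype: int         # HOM_A / HET / HOM_T
    ase_status: int | None  # for HET states only
    delta: DeltaSpec


_ASE_STATES = (
    HiddenState(1, "AA", HOM_A, None, DeltaSpec("point", value=1.0)),
    HiddenState(2, "AT-NASE", HET, NASE, DeltaSpec("point", value=0.5)),
    HiddenState(3, "AT-ASE-HIGH", HET, ASE_HIGH,
                DeltaSpec("rescaled_beta", support=(0.5, 1.0), shape_index=1)),
    HiddenState(4, "AT-ASE-LOW", HET, ASE_LOW,
                DeltaSpec("rescaled_beta", support=(0.0, 0.5), shape_index=2)),
    HiddenState(5, "TT", HOM_T, None, DeltaSpec("point", value=0.0)),
)


@dataclass(frozen=True)
class StateSpace:
    """Ordered catalogue of hidden states for one model variant.

    ``variant`` is ``"ASE"`` (five states) or ``"NASE"`` (three states: the
    heterozygote is always balanced, ASE is not modelled).  State order is by
    ascending index so transition-matrix coordinates are unambiguous.
    """

    variant: str
    states: tuple[HiddenState, ...]

    @property
    def M(self) -> int:
        return len(self.states)

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(s.index for s in self.states)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.states)

    def genotype_projection(self) -> np.ndarray:
        """Genotype code of each state, in state order."""
        return np.array([s.genotype for s in self.states], dtype=int)


def make_state_space(variant: str) -> StateSpace:
    """Build the canonical hidden-state catalogue for a model variant.

    Parameters
    ----------
    variant
        ``"ASE"`` for the five-state ASE-aware chain (AA, AT-NASE,
        AT-ASE-HIGH, AT-ASE-LOW, TT) or ``"NASE"`` for the three-state
        restriction (AA, AT-NASE, TT) that does not model ASE.
    """
    v = variant.upper()
    if v == "ASE":
        return StateSpace("ASE", _ASE_STATES)
    if v == "NASE":
        return StateSpace("NASE", tuple(s for s in _ASE_STATES if s.index in (1, 2, 5)))
    raise ValueError(f"unknown variant {variant!r}; valid variants are 'ASE' and 'NASE'")


@dataclass
class ModelParameters:
    """Full parameter vector theta of one chain.

    ``A`` is the MxM row-stochastic transition matrix between hidden states
    of adjacent SNPs, ``pi`` the length-M initial distribution (shared across
    individuals), ``e`` the per-read mapping-error rate, and
    ``(alpha1, beta1)`` / ``(alpha2, beta2)`` the shapes of the rescaled betas
    of the A-biased / T-biased ASE heterozygote states.  The NASE variant
    carries no beta shapes (they are ``None``).
    """

    A: np.ndarray
    pi: np.ndarray
    e: float
    alpha1: float | None = None
    beta1: float | None = None
    alpha2: float | None = None
    beta2: float | None = None
    e_bounds: tuple[float, float] = (1e-8, 0.5)

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            A=self.A.copy(), pi=self.pi.copy(), e=self.e,
            alpha1=self.alpha1, beta1=self.beta1,
            alpha2=self.alpha2, beta2=self.beta2,
            e_bounds=self.e_bounds,
        )


def validate_parameters(theta: ModelParameters, space: StateSpace) -> ModelParameters:
    """Check ``theta`` against ``space`` and return a normalized copy.

    Rows of ``A`` and the vector ``pi`` are renormalized when within 1e-6 of
    summing to one; anything further off, negative entries, non-positive beta
    shapes or an out-of-bounds ``e`` raise ``ValueError`` naming the field.
    """
    M = space.M
    A = np.asarray(theta.A, dtype=float)
    pi = np.asarray(theta.pi, dtype=float)
    if A.shape != (M, M):
        raise ValueError(f"A has shape {A.shape}, expected ({M}, {M})")
    if pi.shape != (M,):
        raise ValueError(f"pi has shape {pi.shape}, expected ({M},)")
    if np.any(A < 0) or np.any(A > 1 + 1e-6):
        raise ValueError("A has entries outside [0, 1]")
    if np.any(pi < 0) or np.any(pi > 1 + 1e-6):
        raise ValueError("pi has entries outside [0, 1]")
    row_sums = A.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-6):
        raise ValueError(f"A rows sum to {row_sums}, not 1 within 1e-6")
    pi_sum = pi.sum()
    if abs(pi_sum - 1.0) > 1e-6:
        raise ValueError(f"pi sums to {pi_sum}, not 1 within 1e-6")
    A = np.clip(A / row_sums[:, None], 0.0, 1.0)
    pi = np.clip(pi / pi_sum, 0.0, 1.0)
    lo, hi = theta.e_bounds
    if not lo <= theta.e <= hi:
        raise ValueError(f"e={theta.e} outside bounds [{lo}, {hi}]")
    needs_shapes = space.variant == "ASE"
    for name in ("alpha1", "beta1", "alpha2", "beta2"):
        v = getattr(theta, name)
        if needs_shapes:
            if v is None or v <= 0:
                raise ValueError(f"{name} must be a positive real, got {v}")
        elif v is not None and v <= 0:
            raise ValueError(f"{name} must be positive when given, got {v}")
    out = theta.copy()
    out.A = A
    out.pi = pi
    return out


@dataclass
class AlleleCountMatrix:
    """Observed allele-specific read counts for n individuals x L SNPs.

    ``counts[i, l, j]`` is the read count of individual ``i`` at SNP ``l``
    supporting allele slot ``j`` in A, C, G, T order.  Biallelic ref/alt input
    occupies slots A (ref) and T (alt) with C and G zero; the original allele
    labels are kept in ``ref_alleles``/``alt_alleles`` so calls can be
    reported in terms of the input alleles.
    """

    counts: np.ndarray
    positions: np.ndarray | None = None
    snp_ids: list[str] | None = None
    individual_ids: list[str] | None = None
    chroms: list[str] | None = None
    ref_alleles: list[str] | None = None
    alt_alleles: list[str] | None = None
    totals: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 3 or c.shape[2] != 4:
            raise ValueError(f"counts must have shape (n, L, 4), got {c.shape}")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValueError("counts must be integers")
            c = np.round(c).astype(np.int64)
        self.counts = c
        self.totals = c.sum(axis=2)
        n, L, _ = c.shape
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if self.positions.shape != (L,):
                raise ValueError("positions must have one entry per SNP")
        for name in ("snp_ids", "chroms", "ref_alleles", "alt_alleles"):
            v = getattr(self, name)
            if v is not None and len(v) != L:
                raise ValueError(f"{name} must have one entry per SNP")
        if self.individual_ids is not None and len(self.individual_ids) != n:
            raise ValueError("individual_ids must have one entry per individual")

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    def subset_snps(self, idx: Sequence[int]) -> "AlleleCountMatrix":
        """Return a new matrix restricted to the SNPs in ``idx`` (order kept)."""
        idx = list(idx)
        pick = lambda v: [v[j] for j in idx] if v is not None else None
        return AlleleCountMatrix(
            counts=self.counts[:, idx, :],
            positions=None if self.positions is None else self.positions[idx],
            snp_ids=pick(self.snp_ids),
            individual_ids=self.individual_ids,
            chroms=pick(self.chroms),
            ref_alleles=pick(self.ref_alleles),
            alt_alleles=pick(self.alt_alleles),
        )


def ingest_biallelic(
    ref_counts: np.ndarray,
    alt_counts: np.ndarray,
    ref_allele: str | Sequence[str] = "A",
    alt_allele: str | Sequence[str] = "T",
    **metadata,
) -> AlleleCountMatrix:
    """Build an :class:`AlleleCountMatrix` from biallelic ref/alt counts.

    Reference counts occupy the A slot and alternative counts the T slot, so
    the A/T roles of the emission model map directly onto ref/alt; the C and G
    slots are zero.  ``ref_allele``/``alt_allele`` may be single bases or
    per-SNP sequences and are recorded for reporting.  All-zero rows (sites
    without any read) are retained; downstream calling decides whether they
    become non-calls.
    """
    ref = np.asarray(ref_counts)
    alt = np.asarray(alt_counts)
    if ref.shape != alt.shape:
        raise ValueError(f"ref shape {ref.shape} != alt shape {alt.shape}")
    if ref.ndim != 2:
        raise ValueError("ref/alt counts must be 2-D (individuals x SNPs)")
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("counts must be non-negative")
    n, L = ref.shape
    counts = np.zeros((n, L, 4), dtype=np.int64)
    counts[:, :, 0] = ref
    counts[:, :, 3] = alt
    as_list = lambda a: list(a) if not isinstance(a, str) else [a] * L
    return AlleleCountMatrix(
        counts=counts,
        ref_alleles=as_list(ref_allele),
        alt_alleles=as_list(alt_allele),
        **metadata,
    )
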