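"""Scoring called genotypes against a gold standard.

Error rates follow the genotype-calling benchmarking convention with
called-class denominators:

    EFDR        = # homozygotes called heterozygous / # called heterozygous
    EFNR        = # heterozygotes called homozygous / # called homozygous
    Sensitivity = # heterozygotes called heterozygous / # true heterozygotes

Note the EFNR denominator is the number of *called homozygotes*, not the
number of true heterozygotes; the conventional miss rate (true-heterozygote
denominator) is also reported, under ``fnr_conventional``.  Non-calls are
excluded from the EFDR/EFNR denominators but appear in the contingency table
and count against sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import HET, HOM_A, HOM_T, NO_CALL
from .inference import GenotypeCallSet

__all__ = ["EvaluationReport", "score_calls", "noncall_rate"]


@dataclass
class EvaluationReport:
    """Contingency table and summary rates for one comparison.

    Rates with a zero denominator are ``nan`` and flagged in ``undefined``.
    """

    contingency: pd.DataFrame
    efdr: float
    efnr: float
    sensitivity: float
    fnr_conventional: float
    noncall_rate_het: float
    n_eval: int
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "efdr": self.efdr,
            "efnr": self.efnr,
            "sensitivity": self.sensitivity,
            "fnr_conventional": self.fnr_conventional,
            "noncall_rate_het": self.noncall_rate_het,
            "n_eval": self.n_eval,
            "undefined": list(self.undefined),
            "contingency": {
                str(r): {str(c): int(v) for c, v in row.items()}
                for r, row in self.contingency.iterrows()
            },
        }


def _call_array(calls) -> np.ndarray:
    if isinstance(calls, GenotypeCallSet):
        return calls.calls
    return np.asarray(calls)


def score_calls(calls, truth) -> EvaluationReport:
    """Score genotype calls against true genotypes.

    ``truth`` uses the genotype codes (HOM_A/HET/HOM_T); the homozygote
    classes are kept apart in the contingency table but collapsed for the
    rates.  ``calls`` may be a :class:`GenotypeCallSet` or a plain code
    array of the same shape.
    """
    called = _call_array(calls)
    truth = np.asarray(truth)
    if called.shape != truth.shape:
        raise ValueError(f"calls shape {called.shape} != truth shape {truth.shape}")
    if called.size == 0:
        raise ValueError("empty input")
    true_het = truth == HET
    true_hom = (truth == HOM_A) | (truth == HOM_T)
    called_het = called == HET
    called_hom = (called == HOM_A) | (called == HOM_T)
    no_call = called == NO_CALL

    rows = []
    for code, label in ((HOM_A, "hom_a"), (HET, "het"), (HOM_T, "hom_t")):
        t = truth == code
        rows.append({
            "true": label,
            "called_het": int((t & called_het).sum()),
            "called_hom": int((t & called_hom).sum()),
            "no_call": int((t & no_call).sum()),
        })
    contingency = pd.DataFrame(rows).set_index("true")

    undefined = []

    def rate(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    n_called_het = int(called_het.sum())
    n_called_hom = int(called_hom.sum())
    n_true_het = int(true_het.sum())
    efdr = rate(int((true_hom & called_het).sum()), n_called_het, "efdr")
    efnr = rate(int((true_het & called_hom).sum()), n_called_hom, "efnr")
    sens = rate(int((true_het & called_het).sum()), n_true_het, "sensitivity")
    fnr = rate(int((true_het & called_hom).sum()), n_true_het, "fnr_conventional")
    nc = rate(int((true_het & no_call).sum()), n_true_het, "noncall_rate_het")
    return EvaluationReport(
        contingency=contingency,
        efdr=efdr,
        efnr=efnr,
        sensitivity=sens,
        fnr_conventional=fnr,
        noncall_rate_het=nc,
        n_eval=int(truth.size),
        undefined=tuple(undefined),
    )


def noncall_rate(calls, truth) -> float:
    """Fraction of true heterozygotes left uncalled."""
    called = _call_array(calls)
    truth = np.asarray(truth)
    het = truth == HET
    n_het = int(het.sum())
    if n_het == 0:
        return float("nan")
    return float(((called == NO_CALL) & het).sum() / n_het)
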