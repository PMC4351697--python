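"""Count-table and VCF input, parameter serialization, block segmentation.

Count tables are TSV with columns ``snp_id, chrom, pos, ref, alt`` followed
by per-individual count columns: either four columns ``<id>.A <id>.C <id>.G
<id>.T`` (4-base mode) or two columns ``<id>.ref <id>.alt`` (biallelic mode).
Coordinates are 1-based inclusive (VCF convention).  VCF input uses the
per-sample AD (allele depth) field of biallelic records.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import (
    AlleleCountMatrix,
    ModelParameters,
    StateSpace,
    ingest_biallelic,
    make_state_space,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BlockSpec",
    "read_count_table",
    "write_count_table",
    "extract_counts_from_vcf",
    "segment_blocks",
    "save_parameters",
    "load_parameters",
]

_META_COLS = ["snp_id", "chrom", "pos", "ref", "alt"]
PARAMS_FORMAT_VERSION = 1


def write_count_table(acm: AlleleCountMatrix, path) -> None:
    """Write an allele-count matrix as a TSV count table.

    Biallelic matrices (ref/alt alleles recorded, C and G slots empty) are
    written with two columns per individual, otherwise four.
    """
    n, L = acm.n_individuals, acm.n_snps
    ids = acm.individual_ids or [f"ind{i + 1}" for i in range(n)]
    df = pd.DataFrame({
        "snp_id": acm.snp_ids or [f"snp{l + 1}" for l in range(L)],
        "chrom": acm.chroms or ["chr1"] * L,
        "pos": acm.positions if acm.positions is not None else np.arange(1, L + 1),
        "ref": acm.ref_alleles or ["A"] * L,
        "alt": acm.alt_alleles or ["T"] * L,
    })
    biallelic = (
        acm.ref_alleles is not None
        and acm.counts[:, :, 1].sum() == 0
        and acm.counts[:, :, 2].sum() == 0
    )
    if biallelic:
        for i, ind in enumerate(ids):
            df[f"{ind}.ref"] = acm.counts[i, :, 0]
            df[f"{ind}.alt"] = acm.counts[i, :, 3]
    else:
        for i, ind in enumerate(ids):
            for j, base in enumerate("ACGT"):
                df[f"{ind}.{base}"] = acm.counts[i, :, j]
    df.to_csv(path, sep="\t", index=False)


def read_count_table(path) -> AlleleCountMatrix:
    """Read a TSV count table into an :class:`AlleleCountMatrix`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"count table {path} missing columns {missing}")
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate snp_id {dup!r}")
    for chrom, grp in df.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
            raise ValueError(f"positions not strictly increasing on {chrom}")
    count_cols = [c for c in df.columns if c not in _META_COLS]
    by_ind: dict[str, dict[str, str]] = {}
    for c in count_cols:
        if "." not in c:
            raise ValueError(f"malformed count column {c!r}; expected <id>.<slot>")
        ind, slot = c.rsplit(".", 1)
        by_ind.setdefault(ind, {})[slot] = c
    four = {"A", "C", "G", "T"}
    two = {"ref", "alt"}
    modes = {ind: (
        "four" if set(slots) == four else "two" if set(slots) == two else "bad")
        for ind, slots in by_ind.items()}
    if "bad" in modes.values() or len(set(modes.values())) > 1:
        bad = [i for i, m in modes.items() if m != list(modes.values())[0]]
        raise ValueError(f"inconsistent count columns for individual(s) {bad}")
    ids = list(by_ind)
    vals = df[count_cols].to_numpy()
    if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
        raise ValueError("counts must be non-negative integers")
    meta = dict(
        positions=df["pos"].to_numpy(),
        snp_ids=df["snp_id"].astype(str).tolist(),
        individual_ids=ids,
        chroms=df["chrom"].astype(str).tolist(),
    )
    if next(iter(modes.values())) == "two":
        ref = np.stack([df[by_ind[i]["ref"]].to_numpy() for i in ids])
        alt = np.stack([df[by_ind[i]["alt"]].to_numpy() for i in ids])
        return ingest_biallelic(ref, alt, df["ref"].astype(str).tolist(),
                                df["alt"].astype(str).tolist(), **meta)
    counts = np.stack([
        np.stack([df[by_ind[i][b]].to_numpy() for b in "ACGT"], axis=1)
        for i in ids
    ])
    return AlleleCountMatrix(
        counts=counts,
        ref_alleles=df["ref"].astype(str).tolist(),
        alt_alleles=df["alt"].astype(str).tolist(),
        **meta,
    )


def extract_counts_from_vcf(path, samples: Sequence[str] | None = None) -> AlleleCountMatrix:
    """Extract per-sample ref/alt allele depths (AD) from a VCF.

    Only biallelic records are used; multi-allelic records are skipped with a
    logged count.  A missing AD entry for one genotype loads as zero counts
    for that sample with a warning.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    if "AD" not in vf.header.formats:
        raise ValueError(f"VCF {path} has no AD FORMAT field")
    vcf_samples = list(vf.header.samples)
    if samples is None:
        samples = vcf_samples
    else:
        missing = [s for s in samples if s not in vcf_samples]
        if missing:
            raise ValueError(f"samples not in VCF: {missing}")
    rows = []
    skipped = 0
    missing_ad = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            skipped += 1
            continue
        ref_c, alt_c = [], []
        for s in samples:
            ad = rec.samples[s].get("AD")
            if ad is None or len(ad) < 2 or ad[0] is None:
                missing_ad += 1
                ref_c.append(0)
                alt_c.append(0)
            else:
                ref_c.append(int(ad[0]))
                alt_c.append(int(ad[1]))
        rows.append((rec.id or f"{rec.chrom}:{rec.pos}", rec.chrom, rec.pos,
                     rec.ref, rec.alts[0], ref_c, alt_c))
    vf.close()
    if skipped:
        logger.info("skipped %d multi-allelic VCF records", skipped)
    if missing_ad:
        logger.warning("%d genotype entries had no AD; loaded as zero counts",
                       missing_ad)
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    ref = np.array([r[5] for r in rows]).T
    alt = np.array([r[6] for r in rows]).T
    return ingest_biallelic(
        ref, alt,
        [r[3] for r in rows], [r[4] for r in rows],
        positions=np.array([r[2] for r in rows]),
        snp_ids=[r[0] for r in rows],
        individual_ids=list(samples),
        chroms=[r[1] for r in rows],
    )


@dataclass(frozen=True)
class BlockSpec:
    """Segmentation rule for splitting SNPs into HMM blocks.

    Greedy mode caps each block at ``max_snps`` SNPs spanning at most
    ``max_span`` base pairs; anchored mode builds one block per anchor
    position containing the SNPs within ``max_span / 2`` on each side.
    """

    max_snps: int = 25
    max_span: int = 2000
    anchors: tuple[int, ...] | None = None


def segment_blocks(
    positions: np.ndarray,
    spec: BlockSpec = BlockSpec(),
    chroms: Sequence[str] | None = None,
) -> list[np.ndarray]:
    """Partition SNP indices into blocks of closely linked sites.

    Positions must be sorted (strictly increasing within each chromosome);
    blocks never cross chromosome boundaries.  In greedy mode every SNP lands
    in exactly one block; anchored blocks may overlap and need not cover all
    SNPs.
    """
    positions = np.asarray(positions)
    L = len(positions)
    if chroms is None:
        chroms = ["chr1"] * L
    chrom_arr = np.asarray(chroms)
    for ch in pd.unique(chrom_arr):
        p = positions[chrom_arr == ch]
        if np.any(np.diff(p) <= 0):
            raise ValueError(f"positions not strictly increasing on {ch}")
    if spec.anchors is not None:
        blocks = []
        half = spec.max_span / 2
        for a in spec.anchors:
            j = int(np.argmin(np.abs(positions - a)))
            on_chrom = chrom_arr == chrom_arr[j]
            near = np.abs(positions - positions[j]) <= half
            blocks.append(np.flatnonzero(on_chrom & near))
        return blocks
    blocks = []
    start = 0
    for l in range(1, L + 1):
        boundary = l == L
        if not boundary:
            boundary = (
                chrom_arr[l] != chrom_arr[start]
                or l - start >= spec.max_snps
                or positions[l] - positions[start] > spec.max_span
            )
        if boundary:
            blocks.append(np.arange(start, l))
            start = l
    return blocks


def save_parameters(theta: ModelParameters, space: StateSpace, path) -> None:
    """Serialize fitted parameters as JSON with explicit state order."""
    obj = {
        "format_version": PARAMS_FORMAT_VERSION,
        "variant": space.variant,
        "state_order": list(space.indices),
        "A": theta.A.tolist(),
        "pi": theta.pi.tolist(),
        "e": theta.e,
        "alpha1": theta.alpha1,
        "beta1": theta.beta1,
        "alpha2": theta.alpha2,
        "beta2": theta.beta2,
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def load_parameters(path) -> tuple[ModelParameters, StateSpace]:
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("format_version") != PARAMS_FORMAT_VERSION:
        raise ValueError(f"unsupported parameter file version in {path}")
    space = make_state_space(obj["variant"])
    theta = ModelParameters(
        A=np.array(obj["A"]), pi=np.array(obj["pi"]), e=obj["e"],
        alpha1=obj.get("alpha1"), beta1=obj.get("beta1"),
        alpha2=obj.get("alpha2"), beta2=obj.get("beta2"),
    )
    return theta, space
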