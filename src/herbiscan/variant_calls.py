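"""Called genotype matrix: VCF I/O, NP filtering, allelic-status calling.

The analysis unit is the *sample* (genotype/line), and a locus is a nucleotide
polymorphism (NP) — a SNP or small indel.  Two site-level filters are applied
before any association testing:

* multi-allelic sites (three or more alleles, counting the reference) are
  removed;
* sites with quality-by-depth (QD) strictly below 8 are removed (QD = 8.0 is
  retained).

Per-sample calls are coded with a four-letter allelic status:

====== =========================================
A      homozygous reference
B      homozygous alternate
H      heterozygous
C      ambiguous — read support too thin or skewed to decide ("potentially
       either"); distinct from a missing call
====== =========================================

Status can be taken from the VCF genotype field or re-derived from allele
depths (AD) with :func:`call_allelic_status`, whose thresholds are exposed
because the upstream calling recipe varies between published pipelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

__all__ = [
    "AllelicStatus",
    "NucleotidePolymorphism",
    "GenotypeMatrix",
    "StatusCallConfig",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "filter_nps",
    "call_allelic_status",
]

MAX_ALLELES = 2        # sites with >= 3 alleles are dropped
MIN_QD = 8.0           # strict: qd < 8 dropped, qd == 8 kept


class AllelicStatus(str, Enum):
    A = "A"
    B = "B"
    H = "H"
    C = "C"
    missing = "."


@dataclass(frozen=True)
class NucleotidePolymorphism:
    """One called site: SNP or indel, with site-level QC annotations."""

    chrom: str
    position: int          # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    qd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alt_alleles)

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and all(len(a) == 1 for a in self.alt_alleles)

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.position}"


@dataclass(frozen=True)
class StatusCallConfig:
    """Thresholds for AD-based status calling.

    Defaults: a call needs at least 4 reads; >= 90 % of reads on one allele is
    a homozygous call; an alternate-read fraction within [0.25, 0.75] is
    heterozygous; anything between those bands is ambiguous (C).
    """

    min_depth: int = 4
    hom_frac: float = 0.9
    het_low: float = 0.25
    het_high: float = 0.75


def call_allelic_status(
    ref_reads: int,
    alt_reads: int,
    min_depth: int = 4,
    hom_frac: float = 0.9,
    het_low: float = 0.25,
    het_high: float = 0.75,
) -> AllelicStatus:
    """Deterministically map (ref, alt) read counts to an allelic status."""
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_reads + alt_reads
    if total < min_depth:
        return AllelicStatus.C
    frac = alt_reads / total
    if frac >= hom_frac:
        return AllelicStatus.B
    if frac <= 1.0 - hom_frac:
        return AllelicStatus.A
    if het_low <= frac <= het_high:
        return AllelicStatus.H
    return AllelicStatus.C


@dataclass
class GenotypeMatrix:
    """samples x loci grid of allelic statuses with optional read support."""

    samples: list[str]
    loci: list[NucleotidePolymorphism]
    calls: np.ndarray                     # dtype '<U1', shape (n_samples, n_loci)
    support: Optional[np.ndarray] = None  # int, shape (n_samples, n_loci, 2)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U1")
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        if self.support is not None:
            self.support = np.asarray(self.support, dtype=int)
            if self.support.shape != (len(self.samples), len(self.loci), 2):
                raise ValueError("support shape must be (n_samples, n_loci, 2)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def status(self, sample: str, locus_index: int) -> AllelicStatus:
        return AllelicStatus(self.calls[self.samples.index(sample), locus_index])

    def subset_loci(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=[self.loci[i] for i in keep],
            calls=self.calls[:, keep].copy(),
            support=None if self.support is None else self.support[:, keep].copy(),
        )

    def recall_from_support(self, config: StatusCallConfig = StatusCallConfig()) -> None:
        """Overwrite statuses from AD counts (missing calls stay missing)."""
        if self.support is None:
            raise ValueError("no AD support stored; cannot re-call statuses")
        for i in range(self.n_samples):
            for j in range(self.n_loci):
                if self.calls[i, j] == AllelicStatus.missing.value:
                    continue
                r, a = self.support[i, j]
                self.calls[i, j] = call_allelic_status(
                    int(r), int(a), config.min_depth, config.hom_frac,
                    config.het_low, config.het_high,
                ).value


def filter_nps(matrix: GenotypeMatrix, min_qd: float = MIN_QD,
               max_alleles: int = MAX_ALLELES) -> GenotypeMatrix:
    """Drop multi-allelic loci and loci with QD below the cutoff.

    Order-preserving, idempotent, and never removes samples.  Loci without a
    QD value fail the QD rule only if a cutoff is in force; a matrix read from
    a VCF lacking QD raises, because the filter cannot be evaluated.
    """
    keep = []
    for j, np_ in enumerate(matrix.loci):
        if np_.n_alleles > max_alleles:
            continue
        if min_qd is not None:
            if np_.qd is None:
                raise ValueError(
                    f"locus {np_.locus_id} has no QD value; cannot apply the QD filter "
                    "(pass min_qd=None to skip it)"
                )
            if np_.qd < min_qd:
                continue
        keep.append(j)
    return matrix.subset_loci(keep)


# ---------------------------------------------------------------------------
# VCF dialect I/O
#
# Subset of VCF 4.2: CHROM/POS/REF/ALT/QUAL, INFO QD, FORMAT GT:AD.
# Encoding of statuses:  A = 0/0, B = 1/1, H = 0/1, C = ./. with total AD > 0,
# missing = ./. with AD 0,0 (or absent).

_GT_TO_STATUS = {
    (0, 0): AllelicStatus.A,
    (1, 1): AllelicStatus.B,
    (0, 1): AllelicStatus.H,
    (1, 0): AllelicStatus.H,
}
_STATUS_TO_GT = {
    AllelicStatus.A: "0/0",
    AllelicStatus.B: "1/1",
    AllelicStatus.H: "0/1",
    AllelicStatus.C: "./.",
    AllelicStatus.missing: "./.",
}


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    """Read a genotype matrix from an (uncompressed or bgzipped) VCF."""
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        loci: list[NucleotidePolymorphism] = []
        call_rows: list[list[str]] = []
        support_rows: list[list[tuple[int, int]]] = []
        has_ad = "AD" in vf.header.formats
        for rec in vf:
            qd = rec.info.get("QD")
            if isinstance(qd, tuple):
                qd = qd[0]
            loci.append(
                NucleotidePolymorphism(
                    chrom=rec.chrom,
                    position=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=tuple(rec.alts or ()),
                    qd=None if qd is None else float(qd),
                )
            )
            row: list[str] = []
            srow: list[tuple[int, int]] = []
            for s in samples:
                sam = rec.samples[s]
                gt = sam.get("GT")
                ad = sam.get("AD") if has_ad else None
                if ad is None or ad[0] is None:
                    ad = (0, 0)
                ad = (int(ad[0] or 0), int(ad[1] or 0) if len(ad) > 1 else 0)
                if gt is None or any(a is None for a in gt):
                    status = AllelicStatus.C if sum(ad) > 0 else AllelicStatus.missing
                else:
                    status = _GT_TO_STATUS.get(tuple(gt), AllelicStatus.C)
                row.append(status.value)
                srow.append(ad)
            call_rows.append(row)
            support_rows.append(srow)
    n_s, n_l = len(samples), len(loci)
    calls = np.full((n_s, n_l), AllelicStatus.missing.value, dtype="<U1")
    support = np.zeros((n_s, n_l, 2), dtype=int)
    for j in range(n_l):
        for i in range(n_s):
            calls[i, j] = call_rows[j][i]
            support[i, j] = support_rows[j][i]
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls,
                          support=support if has_ad else None)


def write_genotype_matrix(matrix: GenotypeMatrix, path: str | Path,
                          removed: Optional[dict[str, str]] = None) -> None:
    """Write the VCF dialect back out.

    ``removed`` maps locus_id -> filter name for an optional audit trail:
    removed loci are emitted with their filter name in the FILTER column.
    """
    contigs = sorted({np_.chrom for np_ in matrix.loci})
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FILTER=<ID=multiallelic,Description="Three or more alleles">',
        '##FILTER=<ID=low_qd,Description="Quality by depth below 8">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
        + "FORMAT\t" + "\t".join(matrix.samples),
    ]
    removed = removed or {}
    for j, np_ in enumerate(matrix.loci):
        alt = ",".join(np_.alt_alleles) if np_.alt_alleles else "."
        info = "." if np_.qd is None else f"QD={np_.qd:g}"
        filt = removed.get(np_.locus_id, "PASS")
        cols = [np_.chrom, str(np_.position), ".", np_.ref_allele, alt, ".",
                filt, info, "GT:AD"]
        for i in range(matrix.n_samples):
            status = AllelicStatus(matrix.calls[i, j])
            gt = _STATUS_TO_GT[status]
            if matrix.support is not None:
                r, a = matrix.support[i, j]
            else:
                # synthesize depths consistent with the status encoding
                r, a = {
                    AllelicStatus.A: (10, 0),
                    AllelicStatus.B: (0, 10),
                    AllelicStatus.H: (5, 5),
                    AllelicStatus.C: (1, 1),
                    AllelicStatus.missing: (0, 0),
                }[status]
            ad = ",".join(map(str, (r, a) + (0,) * (len(np_.alt_alleles) - 1)))
            cols.append(f"{gt}:{ad}")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")
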