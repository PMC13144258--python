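"""Codon-level consequence annotation and known-mutation catalog matching.

Exonic SNPs are mapped onto their codon, the reference and alternate codons
are translated with the standard genetic code, and the substitution is
labelled synonymous or missense.  Missense substitutions are then compared
against a catalog of published herbicide-resistance alleles (e.g. the ACCase
Asp2078Gly and Gly2096Ala substitutions for HRAC-1 herbicides, or the
promiscuous ALS Pro197 position for HRAC 2).

Published resistance positions use standardized cross-species protein
numbering, which need not coincide with the local numbering of a particular
gene model; :func:`match_catalog` therefore takes an explicit per-gene
``numbering_offset`` (local codon + offset = catalog codon).

Indels and non-exonic SNPs are annotated by region only (effect
``non_coding``); splice, frameshift and regulatory effects are out of scope.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .gene_models import (
    GeneModel,
    GeneModelError,
    RegionLabel,
    Strand,
    classify_site,
    codon_genomic_positions,
    genomic_to_protein,
)
from .variant_calls import NucleotidePolymorphism

__all__ = [
    "Effect",
    "SubstitutionAnnotation",
    "CatalogEntry",
    "annotate_consequence",
    "match_catalog",
    "load_catalog",
    "write_catalog",
    "load_bundled_catalog",
    "ReferenceMismatchError",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class ReferenceMismatchError(ValueError):
    """The VCF reference allele disagrees with the supplied gene sequence."""


class Effect(str, Enum):
    synonymous = "synonymous"
    missense = "missense"
    non_coding = "non_coding"


@dataclass(frozen=True)
class SubstitutionAnnotation:
    """Consequence of one NP within one gene model."""

    locus_id: str
    gene_id: str
    gene_acronym: str
    region: RegionLabel
    effect: Effect
    codon_index: Optional[int] = None
    ref_aa: Optional[str] = None        # one-letter
    alt_aa: Optional[str] = None

    def __post_init__(self) -> None:
        if self.effect in (Effect.synonymous, Effect.missense):
            if self.region is not RegionLabel.exon or self.codon_index is None:
                raise ValueError("coding effects require exonic region and codon fields")

    @property
    def label(self) -> str:
        """Human-readable substitution label, e.g. ``Asp2078Gly``."""
        if self.effect is Effect.non_coding or self.codon_index is None:
            return f"{self.gene_acronym}:{self.region.value}"
        from Bio.SeqUtils import seq3
        return f"{seq3(self.ref_aa)}{self.codon_index}{seq3(self.alt_aa)}"


def annotate_consequence(
    np_: NucleotidePolymorphism,
    model: GeneModel,
    ref_seq: str,
    window_start: Optional[int] = None,
) -> SubstitutionAnnotation:
    """Annotate one NP against a gene model and its reference sequence.

    ``ref_seq`` is the forward-strand genomic sequence of the gene window
    starting at genomic coordinate ``window_start`` (defaults to the model's
    flanked window start).  Indels are annotated by region only.
    """
    if window_start is None:
        window_start = model.window[0]
    region = classify_site(model, np_.position)
    base = SubstitutionAnnotation(
        locus_id=np_.locus_id, gene_id=model.gene_id, gene_acronym=model.acronym,
        region=region, effect=Effect.non_coding,
    )
    if not np_.is_snp:
        logger.info("indel %s annotated by region only (%s)", np_.locus_id, region.value)
        return base
    if region is not RegionLabel.exon:
        return base
    if len(np_.alt_alleles) != 1:
        raise ValueError(f"{np_.locus_id}: exactly one alternate allele expected")
    alt = np_.alt_alleles[0]

    idx = np_.position - window_start
    if not 0 <= idx < len(ref_seq):
        raise GeneModelError(f"{np_.locus_id}: position outside supplied sequence window")
    if ref_seq[idx].upper() != np_.ref_allele.upper():
        raise ReferenceMismatchError(
            f"{np_.locus_id}: VCF ref {np_.ref_allele!r} != sequence "
            f"{ref_seq[idx]!r} at that position"
        )
    try:
        pc = genomic_to_protein(model, np_.position)
    except GeneModelError:
        # exonic but untranslated (e.g. UTR not explicitly declared)
        return base

    positions = codon_genomic_positions(model, pc.codon_index)
    bases = [ref_seq[p - window_start].upper() for p in positions]
    if model.strand is Strand.reverse:
        bases = [b.translate(_COMPLEMENT) for b in bases]
        alt_base = alt.upper().translate(_COMPLEMENT)
    else:
        alt_base = alt.upper()
    ref_codon = "".join(bases)
    alt_codon_list = list(bases)
    alt_codon_list[pc.codon_offset] = alt_base
    alt_codon = "".join(alt_codon_list)

    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    effect = Effect.synonymous if ref_aa == alt_aa else Effect.missense
    return SubstitutionAnnotation(
        locus_id=np_.locus_id, gene_id=model.gene_id, gene_acronym=model.acronym,
        region=region, effect=effect, codon_index=pc.codon_index,
        ref_aa=ref_aa, alt_aa=alt_aa,
    )


def annotate_codon_haplotype(
    nps: Sequence[NucleotidePolymorphism],
    model: GeneModel,
    ref_seq: str,
    window_start: Optional[int] = None,
) -> SubstitutionAnnotation:
    """Combined annotation of several SNPs hitting the *same* codon.

    Each SNP is normally annotated independently against the reference
    background; when a line carries several alternate bases in one codon the
    joint haplotype can encode a different residue, so this emits the
    all-alternate codon's consequence in addition.
    """
    if window_start is None:
        window_start = model.window[0]
    coords = [genomic_to_protein(model, n.position) for n in nps]
    codons = {pc.codon_index for pc in coords}
    if len(codons) != 1:
        raise ValueError(f"SNPs span codons {sorted(codons)}; expected one codon")
    codon_index = codons.pop()
    positions = codon_genomic_positions(model, codon_index)
    bases = [ref_seq[p - window_start].upper() for p in positions]
    if model.strand is Strand.reverse:
        bases = [b.translate(_COMPLEMENT) for b in bases]
    alt_bases = list(bases)
    for n, pc in zip(nps, coords):
        if not n.is_snp or len(n.alt_alleles) != 1:
            raise ValueError(f"{n.locus_id}: haplotype annotation needs biallelic SNPs")
        alt = n.alt_alleles[0].upper()
        if model.strand is Strand.reverse:
            alt = alt.translate(_COMPLEMENT)
        alt_bases[pc.codon_offset] = alt
    ref_aa = str(Seq("".join(bases)).translate())
    alt_aa = str(Seq("".join(alt_bases)).translate())
    return SubstitutionAnnotation(
        locus_id="+".join(n.locus_id for n in nps),
        gene_id=model.gene_id, gene_acronym=model.acronym,
        region=RegionLabel.exon,
        effect=Effect.synonymous if ref_aa == alt_aa else Effect.missense,
        codon_index=codon_index, ref_aa=ref_aa, alt_aa=alt_aa,
    )


# ---------------------------------------------------------------------------
# catalog

WILDCARD = "*"


@dataclass(frozen=True)
class CatalogEntry:
    """One published resistance substitution (catalog protein numbering)."""

    gene: str                 # enzyme acronym; matches gene acronyms by prefix
    codon: int
    ref_aa: str
    alt_aa: frozenset         # one-letter codes, or {"*"} for any substitution
    hrac_group: int
    source: str = ""

    def __post_init__(self) -> None:
        if WILDCARD not in self.alt_aa and self.ref_aa in self.alt_aa:
            raise ValueError(f"{self.gene} {self.codon}: ref_aa within alt_aa set")

    def matches(self, gene_acronym: str, codon: int, ref_aa: str, alt_aa: str) -> bool:
        if not gene_acronym.startswith(self.gene):
            return False
        if codon != self.codon or ref_aa != self.ref_aa:
            return False
        return WILDCARD in self.alt_aa or alt_aa in self.alt_aa


def load_catalog(path: str | Path) -> list[CatalogEntry]:
    with open(path) as fh:
        return _parse_catalog(fh)


def _parse_catalog(lines: Iterable[str]) -> list[CatalogEntry]:
    reader = csv.DictReader(lines, delimiter="\t")
    out = []
    for row in reader:
        out.append(
            CatalogEntry(
                gene=row["gene"].strip(),
                codon=int(row["codon"]),
                ref_aa=row["ref_aa"].strip(),
                alt_aa=frozenset(a.strip() for a in row["alt_aa"].split(",")),
                hrac_group=int(row["hrac_group"]),
                source=row.get("source", "").strip(),
            )
        )
    return out


def write_catalog(entries: Sequence[CatalogEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "codon", "ref_aa", "alt_aa", "hrac_group", "source"])
        for e in entries:
            w.writerow([e.gene, e.codon, e.ref_aa, ",".join(sorted(e.alt_aa)),
                        e.hrac_group, e.source])


def load_bundled_catalog() -> list[CatalogEntry]:
    """The shipped catalog of published target-site resistance substitutions."""
    text = resources.files("herbiscan.data").joinpath("resistance_catalog.tsv") \
        .read_text().splitlines()
    return _parse_catalog(text)


def match_catalog(
    annotations: Iterable[SubstitutionAnnotation],
    catalog: Sequence[CatalogEntry],
    numbering_offset: Optional[Mapping[str, int]] = None,
) -> list[tuple[SubstitutionAnnotation, CatalogEntry]]:
    """Match missense annotations against catalog entries.

    ``numbering_offset`` maps gene acronym -> integer added to the local codon
    index to obtain the catalog's cross-species numbering (0 when the local
    protein numbering already matches the published one).
    """
    numbering_offset = numbering_offset or {}
    matched = []
    for ann in annotations:
        if ann.effect is not Effect.missense:
            continue
        codon = ann.codon_index + numbering_offset.get(ann.gene_acronym, 0)
        for entry in catalog:
            if entry.matches(ann.gene_acronym, codon, ann.ref_aa, ann.alt_aa):
                matched.append((ann, entry))
    return matched
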