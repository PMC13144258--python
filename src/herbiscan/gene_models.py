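"""Target-gene structures: loading, validation and coordinate mapping.

Coordinate convention
---------------------
All intervals are stored 1-based, half-open ``[start, end)``, so the span of a
feature is simply ``end - start``.  This matches the printed gene sizes of the
bundled target-gene table (e.g. ACCase on scaffold 7: 8,726,543 - 8,711,297 =
15,246 bp).  GFF3 input, which is 1-based *inclusive*, is converted on read by
adding 1 to every end coordinate.

A gene model carries exon, CDS and UTR interval lists plus a flanking window
(default 5 kb up- and downstream) inside which candidate-gene polymorphisms
are considered.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Strand",
    "RegionLabel",
    "GeneModel",
    "ProteinCoordinate",
    "GeneModelError",
    "load_gene_models",
    "load_bundled_gene_table",
    "gene_span_length",
    "classify_site",
    "genomic_to_protein",
]

DEFAULT_FLANK_BP = 5000


class GeneModelError(ValueError):
    """Raised for malformed or invariant-violating gene models."""


class Strand(str, Enum):
    forward = "forward"
    reverse = "reverse"

    @classmethod
    def parse(cls, token: str) -> "Strand":
        token = token.strip().lower()
        if token in ("+", "forward", "fwd", "1"):
            return cls.forward
        if token in ("-", "reverse", "rev", "-1"):
            return cls.reverse
        raise GeneModelError(f"unrecognized strand token: {token!r}")


class RegionLabel(str, Enum):
    utr = "utr"
    intron = "intron"
    exon = "exon"
    flank = "flank"


@dataclass(frozen=True)
class ProteinCoordinate:
    """Position of a genomic base within the encoded protein.

    ``codon_index`` is 1-based; ``codon_offset`` is the 0-based position of the
    base inside its codon, counted in transcription order (so for a
    reverse-strand gene offset 0 is the *highest* genomic coordinate of the
    codon).
    """

    gene_id: str
    codon_index: int
    codon_offset: int

    def __post_init__(self) -> None:
        if self.codon_index < 1:
            raise GeneModelError("codon_index must be >= 1")
        if self.codon_offset not in (0, 1, 2):
            raise GeneModelError("codon_offset must be in {0, 1, 2}")


Interval = tuple[int, int]


def _check_intervals(name: str, ivs: Sequence[Interval]) -> list[Interval]:
    ivs = sorted((int(a), int(b)) for a, b in ivs)
    for a, b in ivs:
        if b <= a:
            raise GeneModelError(f"{name} interval [{a}, {b}) is empty or inverted")
        if a < 1:
            raise GeneModelError(f"{name} interval start {a} is not a positive coordinate")
    for (_, b1), (a2, _) in zip(ivs, ivs[1:]):
        if a2 < b1:
            raise GeneModelError(f"{name} intervals overlap near coordinate {a2}")
    return ivs


@dataclass
class GeneModel:
    """Strand-aware exon/intron/UTR structure of one candidate gene."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: Strand
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    acronym: str = ""
    name: str = ""
    flank_bp: int = DEFAULT_FLANK_BP

    def __post_init__(self) -> None:
        self.start = int(self.start)
        self.end = int(self.end)
        if isinstance(self.strand, str):
            self.strand = Strand.parse(self.strand)
        if self.end <= self.start:
            raise GeneModelError(
                f"{self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        self.exons = _check_intervals(f"{self.gene_id} exon", self.exons)
        self.cds = _check_intervals(f"{self.gene_id} CDS", self.cds)
        self.utr5 = _check_intervals(f"{self.gene_id} 5'UTR", self.utr5)
        self.utr3 = _check_intervals(f"{self.gene_id} 3'UTR", self.utr3)
        for a, b in self.exons:
            if a < self.start or b > self.end:
                raise GeneModelError(
                    f"{self.gene_id}: exon [{a}, {b}) outside gene span "
                    f"[{self.start}, {self.end})"
                )
        for a, b in self.cds:
            if not any(ea <= a and b <= eb for ea, eb in self.exons):
                raise GeneModelError(
                    f"{self.gene_id}: CDS [{a}, {b}) not contained in any exon"
                )
        if self.cds_length % 3 != 0:
            raise GeneModelError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )
        if not self.acronym:
            self.acronym = self.gene_id

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds)

    @property
    def window(self) -> Interval:
        """Flanked half-open window analyzed for this gene."""
        return (self.start - self.flank_bp, self.end + self.flank_bp)

    def contains(self, position: int) -> bool:
        lo, hi = self.window
        return lo <= position < hi


def gene_span_length(model: GeneModel) -> int:
    """Gene size in bp under the half-open convention (``end - start``)."""
    return model.end - model.start


def classify_site(model: GeneModel, position: int) -> RegionLabel:
    """Label a genomic position as utr / intron / exon / flank.

    UTR intervals take precedence over the bare exon label (UTRs sit inside
    terminal exons); any other exonic base is ``exon``; bases inside the gene
    body but in no exon are ``intron``; bases outside ``[start, end)`` but
    inside the 5 kb flank are ``flank``.
    """
    lo, hi = model.window
    if not lo <= position < hi:
        raise GeneModelError(
            f"position {position} outside flanked window [{lo}, {hi}) of {model.gene_id}"
        )
    if not model.start <= position < model.end:
        return RegionLabel.flank
    for a, b in (*model.utr5, *model.utr3):
        if a <= position < b:
            return RegionLabel.utr
    for a, b in model.exons:
        if a <= position < b:
            return RegionLabel.exon
    return RegionLabel.intron


def _cds_in_transcription_order(model: GeneModel) -> list[Interval]:
    return model.cds if model.strand is Strand.forward else list(reversed(model.cds))


def genomic_to_protein(model: GeneModel, position: int) -> ProteinCoordinate:
    """Map a genomic base inside the CDS onto (codon_index, codon_offset).

    CDS intervals are concatenated in transcription order; reverse-strand
    genes are walked from the highest genomic coordinate downwards.
    """
    offset = 0
    for a, b in _cds_in_transcription_order(model):
        if a <= position < b:
            if model.strand is Strand.forward:
                idx = offset + (position - a)
            else:
                idx = offset + (b - 1 - position)
            return ProteinCoordinate(model.gene_id, idx // 3 + 1, idx % 3)
        offset += b - a
    raise GeneModelError(
        f"position {position} is not coding in {model.gene_id} (intronic/UTR/flank)"
    )


def codon_genomic_positions(model: GeneModel, codon_index: int) -> list[int]:
    """Genomic coordinates of a codon's three bases, in transcription order."""
    wanted = {(codon_index - 1) * 3 + k: k for k in range(3)}
    out: dict[int, int] = {}
    offset = 0
    for a, b in _cds_in_transcription_order(model):
        length = b - a
        for idx, k in wanted.items():
            if offset <= idx < offset + length:
                if model.strand is Strand.forward:
                    out[k] = a + (idx - offset)
                else:
                    out[k] = b - 1 - (idx - offset)
        offset += length
    if len(out) != 3:
        raise GeneModelError(f"codon {codon_index} outside CDS of {model.gene_id}")
    return [out[k] for k in range(3)]


# ---------------------------------------------------------------------------
# readers


def _load_gene_table(lines: Iterable[str], source: str, flank_bp: int) -> list[GeneModel]:
    reader = csv.DictReader(lines, delimiter="\t")
    models = []
    for i, row in enumerate(reader, start=2):
        try:
            models.append(
                GeneModel(
                    gene_id=row["gene_id"].strip(),
                    chrom=row["chrom"].strip(),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=Strand.parse(row["strand"]),
                    acronym=row.get("acronym", "").strip(),
                    name=row.get("name", "").strip(),
                    flank_bp=flank_bp,
                )
            )
        except (KeyError, ValueError) as exc:
            if isinstance(exc, GeneModelError):
                raise
            raise GeneModelError(f"{source}:{i}: malformed gene-table row: {exc}") from exc
    return models


def _load_gff(lines: Iterable[str], source: str, flank_bp: int) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise GeneModelError(f"{source}:{lineno}: expected 9 GFF columns, got {len(parts)}")
        chrom, _, ftype, start_s, end_s, _, strand_s, _, attrs = parts
        try:
            start, end = int(start_s), int(end_s) + 1  # inclusive -> half-open
        except ValueError as exc:
            raise GeneModelError(f"{source}:{lineno}: malformed interval: {exc}") from exc
        fields = dict(
            kv.split("=", 1) for kv in attrs.rstrip(";").split(";") if "=" in kv
        )
        ftype = ftype.lower()
        if ftype == "gene":
            gid = fields.get("ID", fields.get("Name", ""))
            genes.setdefault(gid, {"exons": [], "cds": [], "utr5": [], "utr3": []}).update(
                chrom=chrom, start=start, end=end, strand=strand_s,
                acronym=fields.get("Name", ""),
            )
        else:
            # dialect: structural features carry Parent = gene ID directly
            parent = fields.get("Parent", "")
            key = {
                "exon": "exons",
                "cds": "cds",
                "five_prime_utr": "utr5",
                "three_prime_utr": "utr3",
            }.get(ftype)
            if key is None:
                continue
            # attach to the gene whose span will contain this feature
            genes.setdefault(parent, {"exons": [], "cds": [], "utr5": [], "utr3": []})
            genes[parent][key].append((start, end))
    models = []
    for gid, g in genes.items():
        if "chrom" not in g:
            raise GeneModelError(f"{source}: feature Parent={gid!r} has no gene record")
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=g["chrom"],
                start=g["start"],
                end=g["end"],
                strand=Strand.parse(g["strand"]),
                exons=g["exons"],
                cds=g["cds"],
                utr5=g["utr5"],
                utr3=g["utr3"],
                acronym=g.get("acronym", ""),
                flank_bp=flank_bp,
            )
        )
    return models


def load_gene_models(path: str | Path, flank_bp: int = DEFAULT_FLANK_BP) -> list[GeneModel]:
    """Load gene models from GFF3 (``.gff``/``.gff3``) or the 8-column table.

    Both readers run the same invariant validation; GFF coordinates are
    converted from 1-based inclusive to half-open on read.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    if not any(line.strip() and not line.startswith("#") for line in text):
        return []
    if path.suffix.lower() in (".gff", ".gff3") or text[0].startswith("##gff"):
        return _load_gff(text, str(path), flank_bp)
    return _load_gene_table(text, str(path), flank_bp)


def load_bundled_gene_table(flank_bp: int = DEFAULT_FLANK_BP) -> list[GeneModel]:
    """The eight bundled candidate-gene models (span/strand only, no exon
    structure — the reference annotation is supplied separately via GFF when
    codon-level annotation is needed)."""
    text = (
        resources.files("herbiscan.data").joinpath("target_genes.tsv").read_text()
    ).splitlines()
    return _load_gene_table(text, "target_genes.tsv", flank_bp)
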