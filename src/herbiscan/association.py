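"""Dual screening of loci against resistance calls, plus heterozygosity tests.

Two complementary screens are run per locus x herbicide over the herbicide's
mechanistic target gene(s):

1. a one-sided Fisher exact test for enrichment of alternate-allele carriers
   among resistant lines, computed by direct hypergeometric enumeration — the
   panel's resistant groups are small, so the exact tail is both feasible and
   necessary;
2. a blanket carrier-frequency-difference screen flagging any locus where the
   resistant and susceptible carrier frequencies differ by at least 15
   percentage points (inclusive).  The exact test is conservative at these
   group sizes; the frequency screen deliberately casts a wider net.

A *carrier* is a called sample whose status is B, H or C (``carrier_mode
"bhc"``, the default — ambiguous calls are counted as potential carriers); a
strict mode ("bh") excludes C.  An allele-dosage variant (B = 2, H = 1,
halved) is also available since "allelic frequency difference" can be read
either way.

No multiple-testing correction gates the screens; a Benjamini–Hochberg column
is emitted for information only.

Gene-wide heterozygosity (het versus homozygous calls pooled over the gene's
loci) is compared between resistant and susceptible lines with a 2x2 Pearson
chi-square; when any expected count falls below 5 the result is flagged
degenerate and a two-sided Fisher exact p is substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .gene_models import GeneModel, RegionLabel, classify_site
from .phenotypes import HERBICIDE_BY_NAME, Herbicide, ResistanceCall
from .variant_calls import AllelicStatus, GenotypeMatrix

__all__ = [
    "CarrierTable",
    "AssociationResult",
    "HetTestResult",
    "fisher_one_sided",
    "fisher_two_sided",
    "frequency_screen",
    "screen_all",
    "heterozygosity_test",
    "candidate_report",
    "default_gene_pairs",
    "benjamini_hochberg",
    "load_bundled_screen_tallies",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_FREQ_DIFF = 0.15

CARRIER_STATUSES = {
    "bhc": frozenset({"B", "H", "C"}),
    "bh": frozenset({"B", "H"}),
}


@dataclass(frozen=True)
class CarrierTable:
    """2x2 carrier counts over *called* (non-missing) samples."""

    r_carrier: int
    r_noncarrier: int
    s_carrier: int
    s_noncarrier: int

    def __post_init__(self) -> None:
        if min(self.r_carrier, self.r_noncarrier,
               self.s_carrier, self.s_noncarrier) < 0:
            raise ValueError("carrier-table counts must be non-negative")

    @property
    def n_resistant(self) -> int:
        return self.r_carrier + self.r_noncarrier

    @property
    def n_susceptible(self) -> int:
        return self.s_carrier + self.s_noncarrier

    @property
    def carrier_freq_resistant(self) -> float:
        return self.r_carrier / self.n_resistant

    @property
    def carrier_freq_susceptible(self) -> float:
        return self.s_carrier / self.n_susceptible


def _hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    return comb(K, k) * comb(N - K, n - k) / comb(N, n)


def fisher_one_sided(table: CarrierTable) -> float:
    """Exact upper-tail probability of carrier enrichment among resistant lines.

    Direct hypergeometric enumeration: with ``N`` called samples, ``K``
    carriers and ``n`` resistant lines, returns ``P(X >= r_carrier)`` for
    ``X ~ Hypergeometric(N, K, n)``.  Degenerate margins return 1.
    """
    a = table.r_carrier
    N = table.n_resistant + table.n_susceptible
    K = table.r_carrier + table.s_carrier
    n = table.n_resistant
    if N == 0 or K == 0 or n == 0:
        return 1.0
    hi = min(K, n)
    p = sum(_hypergeom_pmf(k, N, K, n) for k in range(a, hi + 1))
    return min(p, 1.0)


def fisher_two_sided(table: CarrierTable) -> float:
    """Two-sided exact p: total probability of tables no more likely than
    the observed one (the usual point-probability rule)."""
    a = table.r_carrier
    N = table.n_resistant + table.n_susceptible
    K = table.r_carrier + table.s_carrier
    n = table.n_resistant
    if N == 0 or K == 0 or n == 0:
        return 1.0
    lo, hi = max(0, n - (N - K)), min(K, n)
    p_obs = _hypergeom_pmf(a, N, K, n)
    total = sum(
        p for k in range(lo, hi + 1)
        if (p := _hypergeom_pmf(k, N, K, n)) <= p_obs * (1 + 1e-12)
    )
    return min(total, 1.0)


def frequency_screen(table: CarrierTable, threshold: float = DEFAULT_FREQ_DIFF) -> bool:
    """Flag a carrier-frequency gap of at least ``threshold`` (inclusive)."""
    if table.n_resistant == 0 or table.n_susceptible == 0:
        raise ValueError("both groups need at least one called sample")
    gap = abs(table.carrier_freq_resistant - table.carrier_freq_susceptible)
    # tolerate representation error at the inclusive boundary
    return gap >= threshold - 1e-12


@dataclass
class AssociationResult:
    locus_id: str
    herbicide: str
    gene_acronym: str
    region: Optional[RegionLabel]
    table: CarrierTable
    fisher_p: float
    fisher_flag: bool
    freq_diff_flag: bool
    bh_q: Optional[float] = None

    @property
    def carrier_freq_resistant(self) -> float:
        return self.table.carrier_freq_resistant

    @property
    def carrier_freq_susceptible(self) -> float:
        return self.table.carrier_freq_susceptible


def default_gene_pairs() -> dict[str, tuple[str, ...]]:
    """Herbicide -> target-gene acronyms: each herbicide is screened only
    against the gene(s) encoding its inhibited enzyme (10 pairs in all)."""
    return {
        "fluazifop-butyl": ("ACCase7", "ACCase9"),
        "sethoxydim": ("ACCase7", "ACCase9"),
        "nicosulfuron": ("ALS",),
        "glyphosate": ("EPSP",),
        "glufosinate-ammonium": ("GlutSynth1", "GlutSynth3",
                                 "GlutSynth9_1", "GlutSynth9_2"),
    }


def loci_in_gene(matrix: GenotypeMatrix, model: GeneModel,
                 include_flank: bool = True) -> list[int]:
    """Indices of matrix loci inside the gene's (optionally flanked) window."""
    lo, hi = model.window if include_flank else (model.start, model.end)
    return [
        j for j, np_ in enumerate(matrix.loci)
        if np_.chrom == model.chrom and lo <= np_.position < hi
    ]


def carrier_table(
    matrix: GenotypeMatrix,
    locus_index: int,
    resistant: Mapping[str, bool],
    carrier_mode: str = "bhc",
) -> Optional[CarrierTable]:
    """Build the 2x2 carrier table at one locus; None if a group has no
    called samples."""
    carriers = CARRIER_STATUSES[carrier_mode]
    rc = rn = sc = sn = 0
    for i, sample in enumerate(matrix.samples):
        if sample not in resistant:
            continue
        status = matrix.calls[i, locus_index]
        if status == AllelicStatus.missing.value:
            continue
        is_carrier = status in carriers
        if resistant[sample]:
            rc, rn = rc + is_carrier, rn + (not is_carrier)
        else:
            sc, sn = sc + is_carrier, sn + (not is_carrier)
    if rc + rn == 0 or sc + sn == 0:
        return None
    return CarrierTable(rc, rn, sc, sn)


def allele_dosage_freqs(
    matrix: GenotypeMatrix, locus_index: int, resistant: Mapping[str, bool]
) -> tuple[Optional[float], Optional[float]]:
    """Alternate-allele frequency per group under dosage coding (B=2, H=1,
    per two chromosomes); C and missing excluded."""
    dose = {"A": 0, "H": 1, "B": 2}
    sums = {True: [0, 0], False: [0, 0]}  # group -> [dosage, n_called]
    for i, sample in enumerate(matrix.samples):
        if sample not in resistant:
            continue
        status = matrix.calls[i, locus_index]
        if status not in dose:
            continue
        g = sums[resistant[sample]]
        g[0] += dose[status]
        g[1] += 1
    fr = sums[True][0] / (2 * sums[True][1]) if sums[True][1] else None
    fs = sums[False][0] / (2 * sums[False][1]) if sums[False][1] else None
    return fr, fs


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up q-values (informational column; never gates the screens)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return p
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def screen_all(
    matrix: GenotypeMatrix,
    calls: Sequence[ResistanceCall],
    models: Sequence[GeneModel],
    pairs: Optional[Mapping[str, Sequence[str]]] = None,
    alpha: float = DEFAULT_ALPHA,
    freq_diff: float = DEFAULT_FREQ_DIFF,
    carrier_mode: str = "bhc",
    two_sided: bool = False,
    include_flank: bool = True,
) -> list[AssociationResult]:
    """Run both screens at every locus of every herbicide's target gene(s).

    Loci where either phenotype group has no called sample are skipped with a
    logged reason.  Results carry a BH q-value computed within herbicide.
    """
    if pairs is None:
        pairs = default_gene_pairs()
    model_by_acronym = {m.acronym: m for m in models}
    resistant_by_herb: dict[str, dict[str, bool]] = {}
    for c in calls:
        resistant_by_herb.setdefault(c.herbicide, {})[c.genotype_id] = c.resistant

    results: list[AssociationResult] = []
    for herb, phenos in resistant_by_herb.items():
        if herb not in pairs:
            raise ValueError(f"no target gene mapped for herbicide {herb!r}")
        herb_results: list[AssociationResult] = []
        for acr in pairs[herb]:
            if acr not in model_by_acronym:
                raise ValueError(f"gene {acr!r} mapped to {herb!r} but no model loaded")
            model = model_by_acronym[acr]
            for j in loci_in_gene(matrix, model, include_flank):
                tab = carrier_table(matrix, j, phenos, carrier_mode)
                if tab is None:
                    logger.info(
                        "skipping %s x %s: a phenotype group has no called sample",
                        matrix.loci[j].locus_id, herb,
                    )
                    continue
                p = fisher_two_sided(tab) if two_sided else fisher_one_sided(tab)
                herb_results.append(
                    AssociationResult(
                        locus_id=matrix.loci[j].locus_id,
                        herbicide=herb,
                        gene_acronym=acr,
                        region=classify_site(model, matrix.loci[j].position),
                        table=tab,
                        fisher_p=p,
                        fisher_flag=p <= alpha,
                        freq_diff_flag=frequency_screen(tab, freq_diff),
                    )
                )
        qs = benjamini_hochberg([r.fisher_p for r in herb_results])
        for r, q in zip(herb_results, qs):
            r.bh_q = float(q)
        results.extend(herb_results)
    results.sort(key=lambda r: (r.herbicide, r.fisher_p, r.locus_id))
    return results


# ---------------------------------------------------------------------------
# heterozygosity


@dataclass
class HetTestResult:
    gene_acronym: str
    herbicide: str
    het_resistant: int
    hom_resistant: int
    het_susceptible: int
    hom_susceptible: int
    chi_sq: Optional[float]
    p_value: Optional[float]
    degenerate: bool

    @property
    def het_rate_resistant(self) -> float:
        n = self.het_resistant + self.hom_resistant
        return self.het_resistant / n if n else float("nan")

    @property
    def het_rate_susceptible(self) -> float:
        n = self.het_susceptible + self.hom_susceptible
        return self.het_susceptible / n if n else float("nan")


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for [[a, b], [c, d]]."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / denom
    return stat, float(chi2.sf(stat, df=1))


def heterozygosity_test(
    matrix: GenotypeMatrix,
    calls: Sequence[ResistanceCall],
    gene: GeneModel,
    herbicide: str,
    include_flank: bool = False,
) -> HetTestResult:
    """Gene-wide het-vs-hom 2x2 chi-square between phenotype groups.

    Calls are pooled over every sample x locus cell at the gene's loci
    (gene body by default); C and missing calls are excluded.  Any expected
    count < 5 flags the result degenerate and substitutes a two-sided Fisher
    exact p.
    """
    phenos = {c.genotype_id: c.resistant for c in calls if c.herbicide == herbicide}
    idx = loci_in_gene(matrix, gene, include_flank)
    het = {True: 0, False: 0}
    hom = {True: 0, False: 0}
    for i, sample in enumerate(matrix.samples):
        if sample not in phenos:
            continue
        grp = phenos[sample]
        for j in idx:
            s = matrix.calls[i, j]
            if s == "H":
                het[grp] += 1
            elif s in ("A", "B"):
                hom[grp] += 1
    a, b = het[True], hom[True]
    c, d = het[False], hom[False]
    n = a + b + c + d
    if n == 0 or not idx:
        return HetTestResult(gene.acronym, herbicide, a, b, c, d,
                             None, None, True)
    stat, p = chi_square_2x2(a, b, c, d)
    expected_min = min(
        (a + b) * (a + c), (a + b) * (b + d), (c + d) * (a + c), (c + d) * (b + d)
    ) / n
    degenerate = expected_min < 5
    if degenerate:
        p = fisher_two_sided(CarrierTable(a, b, c, d))
    return HetTestResult(gene.acronym, herbicide, a, b, c, d, stat, p, degenerate)


# ---------------------------------------------------------------------------
# candidate report


def candidate_report(
    results: Sequence[AssociationResult],
    annotations: Mapping[str, "SubstitutionAnnotation"],
    matrix: GenotypeMatrix,
    calls: Sequence[ResistanceCall],
    carrier_mode: str = "bhc",
) -> pd.DataFrame:
    """Candidate-substitution report: one row per flagged exonic missense
    locus x herbicide, with carrier accession lists and zygosity suffixes.

    Percentages are recomputed from the per-locus called denominators that the
    row itself prints, so every number in the table is reproducible from its
    own columns.
    """
    from .consequence import Effect  # local import avoids a cycle

    carriers_set = CARRIER_STATUSES[carrier_mode]
    locus_index = {np_.locus_id: j for j, np_ in enumerate(matrix.loci)}
    resistant_by_herb: dict[str, dict[str, bool]] = {}
    for c in calls:
        resistant_by_herb.setdefault(c.herbicide, {})[c.genotype_id] = c.resistant

    rows = []
    for r in results:
        if not (r.fisher_flag or r.freq_diff_flag):
            continue
        ann = annotations.get(r.locus_id)
        if ann is None or ann.effect is not Effect.missense:
            continue
        j = locus_index[r.locus_id]
        phenos = resistant_by_herb[r.herbicide]
        carriers = {True: [], False: []}
        for i, sample in enumerate(matrix.samples):
            if sample not in phenos:
                continue
            s = matrix.calls[i, j]
            if s in carriers_set:
                carriers[phenos[sample]].append(f"{sample}({s})")
        herb = HERBICIDE_BY_NAME.get(r.herbicide)
        rows.append({
            "herbicide": r.herbicide,
            "hrac_group": herb.hrac_group if herb else None,
            "gene": r.gene_acronym,
            "n_resistant_called": r.table.n_resistant,
            "n_susceptible_called": r.table.n_susceptible,
            "substitution": ann.label,
            "locus_id": r.locus_id,
            "resistant_carriers": ";".join(sorted(carriers[True])),
            "susceptible_carriers": ";".join(sorted(carriers[False])),
            "pct_resistant_with_snp": 100.0 * r.table.r_carrier / r.table.n_resistant,
            "pct_susceptible_with_snp": 100.0 * r.table.s_carrier / r.table.n_susceptible,
            "fisher_p": r.fisher_p,
            "fisher_flag": r.fisher_flag,
            "freq_diff_flag": r.freq_diff_flag,
        })
    return pd.DataFrame(rows)


def load_bundled_screen_tallies() -> pd.DataFrame:
    """Published per-gene/herbicide/region tallies of Fisher-significant NPs
    at the study scale (gene, herbicide, region, n_significant)."""
    from importlib import resources

    path = resources.files("herbiscan.data").joinpath("reported_fisher_hits.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")
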