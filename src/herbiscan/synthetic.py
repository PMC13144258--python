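"""Synthetic panel generator: gene models, genotypes, trials, SSRs, truth.

Emulates the data shapes of a candidate-gene herbicide-resistance study — a
panel of mostly-inbred genotypes, eight target genes with UTR/intron/exon
structure on both strands, per-call read support with site-level missingness,
replicated single-dose herbicide trials, and SSR profiles with clade
structure — entirely in memory, with optional writers for every file dialect
the other modules read.

Two resistance architectures can be planted:

* *target-site*: a causal missense SNP in a target gene, carried at a higher
  frequency among resistant than susceptible lines, with configurable
  penetrance (carriers express resistance with probability ``penetrance``;
  sub-penetrant carriers are demoted to the susceptible group);
* *non-target-site*: resistant lines with no causal carrier status at all —
  the default when a herbicide has no causal plan, so an unplanned herbicide
  doubles as a null panel for the screens.

The same seed yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .gene_models import GeneModel, Strand, codon_genomic_positions
from .phenotypes import HERBICIDES, Herbicide, TrialRecord
from .variant_calls import (
    AllelicStatus,
    GenotypeMatrix,
    NucleotidePolymorphism,
    call_allelic_status,
    write_genotype_matrix,
)

__all__ = [
    "CausalPlan",
    "SimulationConfig",
    "PanelData",
    "simulate_panel",
    "write_panel",
    "snp_codon_pair",
    "default_synthetic_pairs",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = np.array(list("ACGT"))

# region weights at the study scale (lines per world region)
_REGION_WEIGHTS = {
    "USA": 96, "Canada": 37, "East Asia": 27,
    "South Asia": 15, "Middle East": 20, "Europe": 19,
}
_SPECIES_WEIGHTS = {
    "Setaria faberi": 12, "Setaria italica": 10, "Setaria viridis": 192,
}


def snp_codon_pair(ref_aa: str, alt_aa: str) -> tuple[str, str, int]:
    """Find codons (ref, alt) encoding the two residues that differ at exactly
    one base; returns (ref_codon, alt_codon, offset).  Deterministic (first
    pair in lexicographic order)."""
    bases = "ACGT"
    codons = ["".join((a, b, c)) for a in bases for b in bases for c in bases]
    for rc in codons:
        if str(Seq(rc).translate()) != ref_aa:
            continue
        for pos in range(3):
            for nb in bases:
                if nb == rc[pos]:
                    continue
                ac = rc[:pos] + nb + rc[pos + 1:]
                if str(Seq(ac).translate()) == alt_aa:
                    return rc, ac, pos
    raise ValueError(f"no single-base codon change encodes {ref_aa} -> {alt_aa}")


@dataclass(frozen=True)
class CausalPlan:
    """One planted target-site causal variant."""

    gene_acronym: str
    herbicide: str
    codon: int
    ref_aa: str
    alt_aa: str
    carrier_freq_resistant: float = 0.6
    carrier_freq_susceptible: float = 0.1
    penetrance: float = 0.9

    def __post_init__(self) -> None:
        for name in ("carrier_freq_resistant", "carrier_freq_susceptible", "penetrance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic panel.

    Defaults mirror the emulated study: 214 genotypes, 8 candidate genes on
    mixed strands, 3 replicate plants per genotype x herbicide, five
    herbicides in four HRAC classes, a minority-resistant phenotype per
    herbicide, and low gene-level heterozygosity typical of an inbreeding
    panel.
    """

    seed: int
    n_genotypes: int = 214
    n_genes: int = 8
    cds_codons: tuple[int, ...] = ()      # per-gene; default derived in builder
    strands: tuple[str, ...] = ()         # per-gene; default alternating
    n_neutral_snps: int = 400             # across all gene windows
    causal_plans: tuple[CausalPlan, ...] = ()
    non_target_resistance_fraction: float = 0.0
    resistant_fraction: float = 0.15      # per herbicide, before penetrance
    reproduction_given_resistant: float = 0.6
    missing_rate: float = 0.03
    het_rate: float = 0.04                # inbred panel: a few percent
    mean_depth: float = 20.0              # Poisson read-depth model
    low_qd_fraction: float = 0.05         # raw loci failing the QD < 8 filter
    multiallelic_fraction: float = 0.02   # raw loci failing the allele-count filter
    replicates: int = 3
    herbicides: tuple[Herbicide, ...] = HERBICIDES
    n_ssr_loci: int = 12
    ssr_divergence: float = 0.3           # allele-pool divergence of the two clades
    ssr_missing_rate: float = 0.02
    include_controls: bool = False
    flank_bp: int = 5000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        for name in ("non_target_resistance_fraction", "resistant_fraction",
                     "missing_rate", "het_rate", "low_qd_fraction",
                     "multiallelic_fraction", "ssr_divergence", "ssr_missing_rate",
                     "reproduction_given_resistant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class PanelData:
    """All simulated inputs plus ground truth, in memory."""

    config: SimulationConfig
    models: list[GeneModel]
    ref_seqs: dict[str, str]              # gene acronym -> window sequence
    matrix: GenotypeMatrix
    trials: list[TrialRecord]
    metadata: pd.DataFrame
    ssr: list
    truth_loci: pd.DataFrame
    truth_genotypes: pd.DataFrame
    resistant: dict[str, dict[str, bool]]  # herbicide -> genotype -> resistant


def _build_gene(index: int, strand: Strand, cds_codons: int, rng: np.random.Generator,
                flank_bp: int) -> GeneModel:
    """One synthetic gene with UTRs, 2-5 exons and introns."""
    start = 10001
    utr_left = int(rng.integers(80, 200))
    utr_right = int(rng.integers(120, 300))
    n_exons = int(rng.integers(2, 6))
    cds_len = 3 * cds_codons
    # split CDS into n_exons chunks of at least 30 bp
    cuts = np.sort(rng.choice(np.arange(30, cds_len - 30, 3), size=n_exons - 1,
                              replace=False)) if n_exons > 1 else np.array([], dtype=int)
    chunks = np.diff(np.concatenate(([0], cuts, [cds_len]))).astype(int)
    introns = rng.integers(80, 300, size=n_exons - 1)

    exons, cds = [], []
    pos = start
    first_exon_start = pos
    pos += utr_left
    for k, chunk in enumerate(chunks):
        cds.append((pos, pos + int(chunk)))
        pos += int(chunk)
        if k < n_exons - 1:
            exons.append((cds[-1][0] if k > 0 else first_exon_start, pos))
            pos += int(introns[k])
        else:
            exons.append((cds[-1][0] if k > 0 else first_exon_start, pos + utr_right))
            pos += utr_right
    end = pos
    utr_l_iv = [(start, start + utr_left)]
    utr_r_iv = [(end - utr_right, end)]
    utr5, utr3 = (utr_l_iv, utr_r_iv) if strand is Strand.forward else (utr_r_iv, utr_l_iv)
    return GeneModel(
        gene_id=f"SYN.{index + 1}G{cds_codons:04d}",
        chrom=f"chr{index + 1}",
        start=start, end=end, strand=strand,
        exons=exons, cds=cds, utr5=utr5, utr3=utr3,
        acronym=f"Gene{index + 1}",
        flank_bp=flank_bp,
    )


def _random_seq(length: int, rng: np.random.Generator) -> list[str]:
    return list(_BASES[rng.integers(0, 4, size=length)])


def _plant_codon(seq: list[str], model: GeneModel, codon_index: int,
                 codon: str, window_start: int) -> None:
    """Write a codon (transcript orientation) into the window sequence."""
    positions = codon_genomic_positions(model, codon_index)
    for k, p in enumerate(positions):
        base = codon[k]
        if model.strand is Strand.reverse:
            base = base.translate(_COMPLEMENT)
        seq[p - window_start] = base


def simulate_panel(config: SimulationConfig) -> PanelData:
    rng = np.random.default_rng(config.seed)
    n = config.n_genotypes
    samples = [f"G{k + 1:04d}" for k in range(n)]

    # --- gene models and reference windows -------------------------------
    strands = list(config.strands) or [
        "reverse" if g % 2 == 0 else "forward" for g in range(config.n_genes)
    ]
    default_codons = [700, 550, 640, 420, 360, 380, 340, 330]
    codons = list(config.cds_codons) or [
        default_codons[g % len(default_codons)] for g in range(config.n_genes)
    ]
    for plan in config.causal_plans:
        g = _gene_index(plan.gene_acronym, config.n_genes)
        if plan.codon > codons[g]:
            codons[g] = plan.codon + 10
    models = [
        _build_gene(g, Strand.parse(strands[g]), codons[g], rng, config.flank_bp)
        for g in range(config.n_genes)
    ]
    by_acronym = {m.acronym: m for m in models}
    seqs: dict[str, list[str]] = {
        m.acronym: _random_seq(m.window[1] - m.window[0], rng) for m in models
    }

    # --- phenotypes (planned groups), then causal carriers ----------------
    herb_names = [h.name for h in config.herbicides]
    plan_by_herb = {p.herbicide: p for p in config.causal_plans}
    unknown = set(plan_by_herb) - set(herb_names)
    if unknown:
        raise ValueError(f"causal plan for unscreened herbicide(s): {sorted(unknown)}")

    resistant: dict[str, dict[str, bool]] = {}
    carrier_status: dict[str, dict[str, str]] = {}   # herbicide -> sample -> A/B/H
    truth_geno_rows = []
    n_res_planned = int(round(config.resistant_fraction * n))
    for herb in herb_names:
        order = rng.permutation(n)
        res_set = {samples[i] for i in order[:n_res_planned]}
        plan = plan_by_herb.get(herb)
        res_flags = {s: (s in res_set) for s in samples}
        statuses = {s: "A" for s in samples}
        if plan is not None:
            res_list = sorted(res_set)
            sus_list = sorted(set(samples) - res_set)
            max_carriers_r = int(round((1.0 - config.non_target_resistance_fraction)
                                       * len(res_list)))
            k_r = int(round(plan.carrier_freq_resistant * len(res_list)))
            if k_r > len(res_list):
                raise ValueError("carrier frequency incompatible with group size")
            k_r = min(k_r, max_carriers_r)
            k_s = int(round(plan.carrier_freq_susceptible * len(sus_list)))
            carriers = set(
                s for s in np.array(res_list)[rng.permutation(len(res_list))[:k_r]]
            ) | set(
                s for s in np.array(sus_list)[rng.permutation(len(sus_list))[:k_s]]
            )
            for s in carriers:
                statuses[s] = "H" if rng.random() < config.het_rate else "B"
            # sub-penetrant resistant carriers are demoted to susceptible
            for s in sorted(res_set & carriers):
                if rng.random() > plan.penetrance:
                    res_flags[s] = False
        resistant[herb] = res_flags
        carrier_status[herb] = statuses
        for s in samples:
            mech = "susceptible"
            if res_flags[s]:
                mech = ("target_site" if plan is not None and statuses[s] != "A"
                        else "non_target_site")
            truth_geno_rows.append({
                "genotype_id": s, "herbicide": herb, "resistant": res_flags[s],
                "causal_carrier": statuses[s] != "A", "mechanism": mech,
            })

    # --- loci: causal first, then neutral --------------------------------
    loci_raw: list[tuple[NucleotidePolymorphism, dict[str, str], bool, str]] = []
    truth_loci_rows = []
    for herb, plan in plan_by_herb.items():
        model = by_acronym[f"Gene{_gene_index(plan.gene_acronym, config.n_genes) + 1}"]
        ref_codon, alt_codon, offset = snp_codon_pair(plan.ref_aa, plan.alt_aa)
        _plant_codon(seqs[model.acronym], model, plan.codon, ref_codon, model.window[0])
        positions = codon_genomic_positions(model, plan.codon)
        pos = positions[offset]
        wstart = model.window[0]
        ref_base = seqs[model.acronym][pos - wstart]
        alt_base = alt_codon[offset]
        if model.strand is Strand.reverse:
            alt_base = alt_base.translate(_COMPLEMENT)
        np_ = NucleotidePolymorphism(
            chrom=model.chrom, position=pos, ref_allele=ref_base,
            alt_alleles=(alt_base,), qd=float(np.round(rng.uniform(15, 35), 2)),
        )
        loci_raw.append((np_, carrier_status[herb], False, model.acronym))
        truth_loci_rows.append({
            "locus_id": np_.locus_id, "gene": plan.gene_acronym,
            "model_acronym": model.acronym, "herbicide": herb,
            "codon": plan.codon, "ref_aa": plan.ref_aa, "alt_aa": plan.alt_aa,
            "carrier_freq_resistant": plan.carrier_freq_resistant,
            "carrier_freq_susceptible": plan.carrier_freq_susceptible,
            "penetrance": plan.penetrance,
        })
    causal_positions = {(np_.chrom, np_.position) for np_, *_ in loci_raw}

    per_gene = np.full(config.n_genes, config.n_neutral_snps // config.n_genes)
    per_gene[: config.n_neutral_snps % config.n_genes] += 1
    for g, model in enumerate(models):
        wstart, wend = model.window
        k = 0
        while k < per_gene[g]:
            pos = int(rng.integers(wstart, wend))
            if (model.chrom, pos) in causal_positions:
                continue
            causal_positions.add((model.chrom, pos))
            ref_base = seqs[model.acronym][pos - wstart]
            alts = [b for b in "ACGT" if b != ref_base]
            multi = rng.random() < config.multiallelic_fraction
            alt = tuple(rng.choice(alts, size=2 if multi else 1, replace=False))
            qd = (float(np.round(rng.uniform(1, 7.99), 2))
                  if rng.random() < config.low_qd_fraction
                  else float(np.round(rng.uniform(8, 35), 2)))
            p_alt = float(rng.uniform(0.05, 0.5))
            statuses = {}
            for s in samples:
                if rng.random() < p_alt:
                    statuses[s] = "H" if rng.random() < config.het_rate else "B"
                else:
                    statuses[s] = "A"
            np_ = NucleotidePolymorphism(model.chrom, pos, ref_base, alt, qd=qd)
            loci_raw.append((np_, statuses, multi, model.acronym))
            k += 1

    loci_raw.sort(key=lambda t: (t[0].chrom, t[0].position))
    loci = [t[0] for t in loci_raw]

    # --- read-depth model -> AD support and final statuses ----------------
    n_loci = len(loci)
    calls = np.full((n, n_loci), AllelicStatus.missing.value, dtype="<U1")
    support = np.zeros((n, n_loci, 2), dtype=int)
    err = 0.01
    p_read = {"A": err, "B": 1 - err, "H": 0.5}
    for j, (np_, statuses, _multi, _acr) in enumerate(loci_raw):
        depth = rng.poisson(config.mean_depth, size=n)
        miss = rng.random(n) < config.missing_rate
        p_vec = np.array([p_read[statuses[s]] for s in samples])
        alt_reads = rng.binomial(depth, p_vec)
        for i in range(n):
            d = int(depth[i])
            if miss[i] or d == 0:
                continue
            a = int(alt_reads[i])
            support[i, j] = (d - a, a)
            calls[i, j] = call_allelic_status(d - a, a).value
    matrix = GenotypeMatrix(samples=samples, loci=loci, calls=calls, support=support)

    # --- trials ------------------------------------------------------------
    trials: list[TrialRecord] = []
    for herb in herb_names:
        for s in samples:
            is_res = resistant[herb][s]
            reproduces = is_res and rng.random() < config.reproduction_given_resistant
            for rep in range(1, config.replicates + 1):
                if is_res:
                    if rep == 1:
                        surv, grow = True, True
                        rep3 = bool(reproduces and rng.random() < 0.7)
                        rep6 = bool(reproduces and not rep3)
                    else:
                        surv = bool(rng.random() < 0.6)
                        grow = bool(surv and rng.random() < 0.5)
                        rep3 = rep6 = False
                else:
                    surv = bool(rng.random() < 0.1)   # 3-wk survival without recovery
                    grow = rep3 = rep6 = False
                trials.append(TrialRecord(
                    genotype_id=s, herbicide=herb, replicate=rep,
                    survived_3wk=surv, reproduced_3wk=rep3,
                    active_growth_6wk=grow, reproduced_6wk=rep6,
                ))
        if config.include_controls:
            for s in samples:
                for rep in range(1, config.replicates + 1):
                    trials.append(TrialRecord(
                        genotype_id=s, herbicide=herb, replicate=rep,
                        survived_3wk=True, reproduced_3wk=True,
                        active_growth_6wk=True, reproduced_6wk=False,
                        treated=False,
                    ))

    # --- metadata ----------------------------------------------------------
    regions = list(_REGION_WEIGHTS)
    rw = np.array(list(_REGION_WEIGHTS.values()), dtype=float)
    species = list(_SPECIES_WEIGHTS)
    sw = np.array(list(_SPECIES_WEIGHTS.values()), dtype=float)
    metadata = pd.DataFrame({
        "genotype_id": samples,
        "accession": [f"ACC{1 + k // 2:04d}" for k in range(n)],
        "species": rng.choice(species, size=n, p=sw / sw.sum()),
        "region": rng.choice(regions, size=n, p=rw / rw.sum()),
    })

    # --- SSR profiles along a two-clade genealogy --------------------------
    from .phylo import SSRProfile
    clade = np.array([0] * (n // 2) + [1] * (n - n // 2))
    profiles = []
    pool_a = [[f"{100 + 2 * a}" for a in rng.choice(10, size=4, replace=False)]
              for _ in range(config.n_ssr_loci)]
    pool_b = []
    for lidx in range(config.n_ssr_loci):
        if rng.random() < config.ssr_divergence:
            pool_b.append([f"{121 + 2 * a}" for a in rng.choice(10, size=4, replace=False)])
        else:
            pool_b.append(pool_a[lidx])
    for i, s in enumerate(samples):
        pools = pool_a if clade[i] == 0 else pool_b
        loci_map = {}
        for lidx in range(config.n_ssr_loci):
            if rng.random() < config.ssr_missing_rate:
                continue
            allele = str(rng.choice(pools[lidx]))
            if rng.random() < config.het_rate:
                other = str(rng.choice(pools[lidx]))
                loci_map[f"SSR{lidx + 1:02d}"] = tuple(sorted((allele, other)))
            else:
                loci_map[f"SSR{lidx + 1:02d}"] = (allele, allele)
        profiles.append(SSRProfile(genotype_id=s, loci=loci_map))
    metadata["clade"] = clade

    return PanelData(
        config=config,
        models=models,
        ref_seqs={acr: "".join(seq) for acr, seq in seqs.items()},
        matrix=matrix,
        trials=trials,
        metadata=metadata,
        ssr=profiles,
        truth_loci=pd.DataFrame(truth_loci_rows),
        truth_genotypes=pd.DataFrame(truth_geno_rows),
        resistant=resistant,
    )


def _gene_index(acronym: str, n_genes: int) -> int:
    """Map a plan's gene acronym (``Gene3`` or an index-like name) to 0-based
    gene index."""
    digits = "".join(ch for ch in acronym if ch.isdigit())
    if not digits:
        raise ValueError(f"cannot infer gene index from acronym {acronym!r}")
    idx = int(digits) - 1
    if not 0 <= idx < n_genes:
        raise ValueError(f"gene {acronym!r} outside the simulated {n_genes} genes")
    return idx


def default_synthetic_pairs(n_genes: int = 8,
                            herbicides: Sequence[Herbicide] = HERBICIDES) -> dict:
    """Herbicide -> simulated-gene mapping mirroring the real target mapping:
    the two HRAC-1 herbicides share the first two genes, the HRAC-2 and
    HRAC-9 herbicides get one gene each, and the HRAC-10 herbicide gets the
    remaining homolog block."""
    if n_genes < 5:
        raise ValueError("the default mapping needs at least 5 simulated genes")
    names = [h.name for h in herbicides]
    return {
        names[0]: ("Gene1", "Gene2"),
        names[1]: ("Gene1", "Gene2"),
        names[2]: ("Gene3",),
        names[3]: ("Gene4",),
        names[4]: tuple(f"Gene{g}" for g in range(5, n_genes + 1)),
    }


# ---------------------------------------------------------------------------
# writers


def write_panel(panel: PanelData, outdir: str | Path) -> dict[str, Path]:
    """Write every simulated input in the dialect its consumer module reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.gff3",
        "reference": outdir / "reference.fasta",
        "vcf": outdir / "genotypes.vcf",
        "trials": outdir / "trials.tsv",
        "metadata": outdir / "metadata.tsv",
        "ssr": outdir / "ssr.tsv",
        "truth_loci": outdir / "truth_loci.tsv",
        "truth_genotypes": outdir / "truth_genotypes.tsv",
    }

    gff = ["##gff-version 3"]
    for m in panel.models:
        s = "+" if m.strand is Strand.forward else "-"
        gff.append("\t".join([m.chrom, "herbiscan_sim", "gene", str(m.start),
                              str(m.end - 1), ".", s, ".",
                              f"ID={m.gene_id};Name={m.acronym}"]))
        for ftype, ivs in (("exon", m.exons), ("CDS", m.cds),
                           ("five_prime_UTR", m.utr5), ("three_prime_UTR", m.utr3)):
            for a, b in ivs:
                gff.append("\t".join([m.chrom, "herbiscan_sim", ftype, str(a),
                                      str(b - 1), ".", s, ".", f"Parent={m.gene_id}"]))
    paths["genes"].write_text("\n".join(gff) + "\n")

    fasta = []
    for m in panel.models:
        fasta.append(f">{m.acronym} {m.chrom}:{m.window[0]}-{m.window[1]}")
        seq = panel.ref_seqs[m.acronym]
        fasta.extend(seq[k:k + 80] for k in range(0, len(seq), 80))
    paths["reference"].write_text("\n".join(fasta) + "\n")

    write_genotype_matrix(panel.matrix, paths["vcf"])

    trial_rows = [asdict(t) for t in panel.trials]
    pd.DataFrame(trial_rows).to_csv(paths["trials"], sep="\t", index=False)
    panel.metadata.to_csv(paths["metadata"], sep="\t", index=False)

    ssr_rows = []
    for p in panel.ssr:
        for locus in sorted(p.loci):
            for allele in p.loci[locus]:
                ssr_rows.append({"genotype_id": p.genotype_id,
                                 "locus": locus, "allele": allele})
    pd.DataFrame(ssr_rows).to_csv(paths["ssr"], sep="\t", index=False)

    panel.truth_loci.to_csv(paths["truth_loci"], sep="\t", index=False)
    panel.truth_genotypes.to_csv(paths["truth_genotypes"], sep="\t", index=False)
    return paths
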