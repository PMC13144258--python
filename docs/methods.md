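# Methods

This note records the statistical model, procedures, parameter defaults and
numerical choices implemented in `herbiscan`, and the design decisions behind
them.

## 1. Data model

**Coordinates.** All genomic intervals are 1-based half-open `[start, end)`,
so a printed gene size equals `end − start` (`gene_span_length`). GFF3 input
(1-based inclusive) is converted on read. Each gene carries exons, CDS
chunks, UTRs and a flanking window of `flank_bp = 5000` bp on each side;
every position in the flanked window receives exactly one region label with
precedence UTR > exon; intron between exons; flank outside the gene span.

**Gene panel.** The bundled table holds eight target genes on both strands:
two ACCase homologs (HRAC group 1), ALS (group 2), EPSP synthase (group 9)
and four glutamine-synthetase homologs (group 10). Five herbicides map to
them as 10 herbicide × gene screening pairs (the two group-1 herbicides are
each screened against both ACCase homologs; the group-10 herbicide against
all four GS homologs).

**Phenotypes.** Trial records are per genotype × herbicide × replicate with
four boolean scores (3-week survival, 3-week seed set, 6-week active growth,
6-week seed set) and a treated flag; untreated controls are ignored by the
coder. Record-level invariants (seed set implies survival or growth) are
enforced at construction. A genotype is *resistant* if any treated replicate
set seed at either census or grew actively at 6 weeks; *reproduced* if any
replicate set seed; *survived_3wk* is kept as a looser stringency.
Prevalence tables are reported at both stringencies by world region, and
multi-class resistance counts distinct HRAC groups resisted (two herbicides
in the same group count once).

## 2. Variant processing

**Filters.** Loci with ≥ 3 alleles or `QD < 8` (strict: `QD = 8.0` is
retained) are removed. A locus lacking a QD value is a hard error unless the
QD rule is disabled (`min_qd=None`), so silent retention is impossible. The
pipeline writes a filter-audit VCF with per-locus removal reasons and a
manifest tallying raw/kept/removed counts.

**Allelic status.** With `ref`/`alt` read counts and depth `d`: missing if
`d < min_depth` (default 4) — except truly zero-depth entries, which are
missing outright; `A` if `ref/d ≥ hom_frac` (default 0.9); `B` if
`alt/d ≥ hom_frac`; `H` if `0.25 ≤ alt/d ≤ 0.75` (both ends inclusive);
otherwise `C` (conflicting). Every count pair maps to exactly one status.
Statuses round-trip bit-exactly through the VCF writer/reader (`C` is
encoded as `./.` with nonzero AD).

**Consequence annotation.** For each SNP in a gene window with a reference
sequence available, the CDS is concatenated in transcription order (reverse
strand walks high→low coordinates with complemented bases), the codon
containing the site is translated (Biopython) for reference and alternate
alleles, and the substitution is labeled (e.g. `Asp2078Gly`). A mismatch
between the declared reference allele and the reference sequence raises
(never silently repairs). Indels receive a region label only. Catalog
matching compares gene (prefix match on the acronym, so homolog families
match family-level entries), codon (with optional per-gene numbering
offsets), reference residue and alternate set; `*` matches any alternate.

## 3. Statistics

**Dual association screen.** For each screening pair and each kept locus in
the gene window (flanks included by default): carriers are samples with
status in `{B, H, C}` (`carrier_mode="bhc"`; `"bh"` available), missing
calls excluded per locus, so every percentage has an explicit per-locus
denominator. The one-sided Fisher exact p is computed by direct
hypergeometric enumeration (`math.comb`, exact rationals until the final
division): with N called, K carriers, n resistant and a resistant carriers,
p = Σ_{k≥a} C(K,k)·C(N−K,n−k)/C(N,n). Degenerate margins give p = 1. The
frequency screen flags |f_res − f_sus| ≥ 0.15 with an inclusive boundary
(tolerance 1e-12 for representation error). Flags use raw α = 0.05;
Benjamini–Hochberg q-values are attached for context only, since the
historical screen this reproduces thresholds raw p. The candidate report
keeps loci that are flagged by either screen *and* are missense, and lists
carriers by name with percentages recomputed from the emitted counts.

**Heterozygosity.** Per gene (gene body only, flanks excluded) and
herbicide, `H` calls vs `A`/`B` calls (C and missing excluded) are
cross-tabulated against resistance and tested with the closed-form 2×2
Pearson chi-square; if any expected count is < 5 the two-sided Fisher exact
p (point-probability rule, tolerance 1+1e-12) is substituted and marked
`degenerate`.

**Dps / neighbor joining.** Dps(a,b) = 1 − mean over co-scored loci of
(multiset intersection)/max(|a|,|b|); a pooled variant divides total shared
by total comparable alleles. Dps is symmetric, zero on identity, one on
disjoint profiles, but not a metric (no triangle inequality), which NJ does
not require. NJ is the standard Saitou–Nei agglomeration re-implemented
directly (the distance input is not a metric, and deterministic tie-breaking
was needed): Q(i,j) = (m−2)d(i,j) − Σd(i,·) − Σd(j,·), branch lengths
l_i = d(i,j)/2 + (r_i − r_j)/(2(m−2)), update
d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2 clamped at 0. Q-ties break toward the
lexicographically smallest tip-label pair; negative branch lengths are
clamped to zero with the deficit moved to the sibling so the split length is
preserved. On additive matrices the tree's path distances reproduce the
input to < 1e-9 (verified against an independent NJ implementation in the
test suite). The final two clusters are joined at half their distance.

## 4. Synthetic generator

The generator emulates: a mostly-inbred panel (default 214 genotypes, 12/10/
192 across three *Setaria* species; six world regions with fixed weights);
eight genes with alternating strands, 2–5 exons, UTRs and realistic sizes;
per-locus read support via a Poisson(`mean_depth=20`) depth model with
binomial alternate-read sampling (sequencing error 1 %) feeding the *same*
status caller used on real data; site-level missingness (3 %); filter fodder
(5 % low-QD, 2 % multiallelic loci); replicated trials (3 replicates)
consistent with the declared resistance coding; and SSR profiles drawn from
two clade-specific allele pools (divergence 0.3, i.e. 30 % of loci have
disjoint pools).

Causal architecture: phenotype groups are drawn first (resistant fraction
0.15 per herbicide); for a planted `CausalPlan`, carriers are sampled without
replacement at group-specific frequencies (defaults 0.6 resistant / 0.1
susceptible) and the planted codon is written into the reference so the
ref→alt change encodes the requested substitution on either strand.
Penetrance is implemented as demotion: each resistant carrier stays
resistant with probability `penetrance`, otherwise moves to the susceptible
group (so susceptible carriers exist for two reasons, standing variation and
incomplete penetrance). Herbicides without a plan have resistance unlinked
to any locus and double as null panels. Ground truth (per-locus plans,
per-genotype mechanisms) is emitted alongside the data.

Not emulated: linkage disequilibrium between loci (statuses are independent
across loci), population structure in the SNPs (only the SSRs carry clade
structure), dose–response curves, maternal seed effects, genotyping batch
effects, and indel consequences.

All randomness flows from a single mandatory seed through
`numpy.random.default_rng`; the same seed yields byte-identical output
files.

## 5. Numerical choices

- Fisher p-values by exact integer enumeration (`math.comb`), not normal or
  chi-square approximations; the test oracle is the independent
  `scipy.stats.hypergeom` survival function (agreement ≤ 4.5e-16 over all
  28,560 tables with cells ≤ 12).
- Inclusive thresholds carry a 1e-12 absolute tolerance so that values like
  0.15 computed as a float ratio are not dropped by representation error.
- Distance matrices are symmetrized `(D + Dᵀ)/2` and clipped at 0 on
  construction; asymmetry beyond 1e-9 is rejected rather than repaired.
- The NJ implementation keeps the full distance matrix and pads it per
  merge; panels of a few hundred tips run in well under a second, so no
  O(n²)-memory optimization was attempted.

## 6. Design decisions and resolutions

- **Pipeline, not estimator.** The workflow is a multi-stage screen over
  heterogeneous inputs with many outputs, not a fit/predict mapping, so it
  is shaped as composable functions plus a `run_pipeline` orchestrator and
  CLI rather than an sklearn-style estimator class.
- **10 screening pairs.** Homologous targets are screened per-homolog (each
  GS homolog separately), not collapsed per enzyme: per-homolog tables keep
  denominators and consequences unambiguous.
- **Carriers include `C`.** Conflicting calls carry alternate-allele reads,
  so the default carrier set is `{B, H, C}`; a strict `{B, H}` mode is one
  flag away, and the choice is recorded in the manifest.
- **One-sided Fisher.** The screen asks specifically for carrier enrichment
  among resistant lines; depletion is not evidence of target-site
  resistance. The two-sided test is available and used by the
  heterozygosity fallback.
- **Raw-α flags, BH for context.** The screen is a candidate generator, not
  a confirmatory test; q-values are emitted so readers can apply their own
  multiplicity standard.
- **Errors over repair.** Missing QD with the QD rule active, reference
  mismatches, conflicting duplicate trial records and malformed gene models
  all raise with named errors rather than being silently patched.

## 7. Limitations

- Candidate-gene only: the screen cannot see resistance loci outside the
  configured gene windows, and non-target-site resistance is detectable only
  as resistant lines with no flagged locus.
- The frequency-gap screen is anti-conservative at small per-locus
  denominators (a handful of called resistant lines make 15 % gaps cheap);
  it is a recall-oriented filter and should be read jointly with the Fisher
  flag and the consequence annotation.
- Fisher exact tests are conservative on discrete 2×2 tables; the null flag
  rate on synthetic panels runs below the nominal α.
- Dps/NJ describe relatedness; they are not a phylogeny in the inferential
  sense (no branch support, no model of SSR evolution).
- Consequence annotation handles SNPs within single codons (plus an explicit
  multi-SNP codon-haplotype helper); indels and splice-site disruptions get
  region labels only.
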