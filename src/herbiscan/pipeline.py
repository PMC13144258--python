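"""End-to-end orchestration of the screening stages, with a run manifest.

``run_pipeline`` chains the stages — gene loading, NP filtering, phenotype
coding, consequence annotation, dual association screening, heterozygosity
testing and the Dps/NJ tree — writing each stage's output as a delimited
file so that every number in the rendered summary tables can be recomputed
from stage outputs.  A JSON manifest records the seed, thresholds, gene
mapping and the locus tally at every filter stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from . import __version__
from .association import (
    candidate_report,
    default_gene_pairs,
    heterozygosity_test,
    screen_all,
)
from .consequence import (
    Effect,
    annotate_consequence,
    load_bundled_catalog,
    load_catalog,
    match_catalog,
)
from .gene_models import GeneModel, RegionLabel, load_gene_models
from .phenotypes import (
    code_resistance,
    multi_class_summary,
    prevalence_table,
    read_metadata_table,
    read_trial_table,
)
from .phylo import (
    annotate_tree,
    distance_matrix,
    neighbor_joining,
    read_ssr_table,
    write_phylip,
)
from .synthetic import default_synthetic_pairs
from .variant_calls import filter_nps, read_genotype_matrix, write_genotype_matrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genes: Path
    vcf: Path
    trials: Path
    metadata: Optional[Path] = None
    reference: Optional[Path] = None
    ssr: Optional[Path] = None
    catalog: Optional[Path] = None
    pairs: Optional[Path] = None
    alpha: float = 0.05
    freq_diff: float = 0.15
    carrier_mode: str = "bhc"
    min_qd: float = 8.0
    seed: int = 0
    render_figure: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml
            raw = yaml.safe_load(path.read_text())
        else:
            raw = json.loads(path.read_text())
        missing = {"genes", "vcf", "trials"} - set(raw)
        if missing:
            raise ValueError(f"pipeline config missing required inputs: {sorted(missing)}")
        paths = {k: Path(v) for k, v in raw.items()
                 if k in ("genes", "vcf", "trials", "metadata", "reference",
                          "ssr", "catalog", "pairs") and v is not None}
        rest = {k: v for k, v in raw.items() if k not in paths}
        return cls(**paths, **rest)


def _resolve_pairs(models: Sequence[GeneModel], pairs_path: Optional[Path]) -> dict:
    if pairs_path is not None:
        return {k: tuple(v) for k, v in json.loads(Path(pairs_path).read_text()).items()}
    acronyms = {m.acronym for m in models}
    if "ACCase7" in acronyms:
        return default_gene_pairs()
    if "Gene1" in acronyms:
        return default_synthetic_pairs(len(models))
    raise ValueError(
        "cannot infer a herbicide->gene mapping from gene acronyms; "
        "supply a pairs JSON file"
    )


def _read_reference(path: Path, models: Sequence[GeneModel]) -> dict[str, str]:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    out = {}
    for m in models:
        if m.acronym in seqs:
            out[m.acronym] = seqs[m.acronym]
        elif m.gene_id in seqs:
            out[m.acronym] = seqs[m.gene_id]
    return out


def np_accounting(annotation_df: pd.DataFrame, models: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-gene NP counts by region with candidate-substitution counts —
    the gene-level bookkeeping table."""
    rows = []
    for m in models:
        sub = annotation_df[annotation_df.gene == m.acronym]
        rows.append({
            "gene": m.acronym,
            "gene_id": m.gene_id,
            "location": f"{m.chrom}:{m.start}..{m.end} {m.strand.value}",
            "size_bp": m.end - m.start,
            "n_utr_nps": int((sub.region == "utr").sum()),
            "n_intronic_nps": int((sub.region == "intron").sum()),
            "n_exonic_nps": int((sub.region == "exon").sum()),
            "n_flank_nps": int((sub.region == "flank").sum()),
            "n_candidate_substitutions": int(
                ((sub.effect == "missense") & sub.flagged).sum()
            ),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig | str | Path, outdir: str | Path) -> Path:
    """Run every stage; returns the output directory.

    Raises on any stage error (the CLI converts that to a nonzero exit).
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "alpha": config.alpha, "freq_diff": config.freq_diff,
            "carrier_mode": config.carrier_mode, "min_qd": config.min_qd,
        },
        "inputs": {k: str(getattr(config, k)) for k in
                   ("genes", "vcf", "trials", "metadata", "reference", "ssr",
                    "catalog", "pairs") if getattr(config, k) is not None},
    }

    # stage 1: gene models ------------------------------------------------
    models = load_gene_models(config.genes)
    if not models:
        raise ValueError(f"no gene models loaded from {config.genes}")
    pairs = _resolve_pairs(models, config.pairs)
    manifest["pairs"] = {k: list(v) for k, v in pairs.items()}

    # stage 2: genotype matrix + NP filters --------------------------------
    raw = read_genotype_matrix(config.vcf)
    filtered = filter_nps(raw, min_qd=config.min_qd)
    kept = {np_.locus_id for np_ in filtered.loci}
    removed = {}
    for np_ in raw.loci:
        if np_.locus_id in kept:
            continue
        removed[np_.locus_id] = "multiallelic" if np_.n_alleles > 2 else "low_qd"
    write_genotype_matrix(raw, outdir / "filter_audit.vcf", removed=removed)
    manifest["filters"] = {
        "n_loci_raw": raw.n_loci,
        "n_loci_filtered": filtered.n_loci,
        "n_removed_multiallelic": sum(v == "multiallelic" for v in removed.values()),
        "n_removed_low_qd": sum(v == "low_qd" for v in removed.values()),
        "n_samples": raw.n_samples,
    }

    # stage 3: phenotypes ---------------------------------------------------
    trials = read_trial_table(config.trials)
    calls = code_resistance(trials)
    calls_df = pd.DataFrame([vars(c) for c in calls])
    calls_df.to_csv(outdir / "resistance_calls.tsv", sep="\t", index=False)
    mc = multi_class_summary(calls)
    mc.to_csv(outdir / "multi_class.tsv", sep="\t", index=False)
    manifest["phenotypes"] = {
        "n_genotypes": calls_df.genotype_id.nunique(),
        "n_calls": len(calls_df),
        "n_multi_class": mc.attrs["n_multi"],
        "frac_multi_class": mc.attrs["frac_multi"],
    }
    if config.metadata is not None:
        meta = read_metadata_table(config.metadata)
        regions = dict(zip(meta.genotype_id, meta.region))
        prevalence_table(calls, regions).to_csv(
            outdir / "prevalence.tsv", sep="\t", index=False
        )

    # stage 4: consequence annotation --------------------------------------
    ann_rows = []
    annotations = {}
    if config.reference is not None:
        ref = _read_reference(Path(config.reference), models)
        for m in models:
            if m.acronym not in ref:
                logger.warning("no reference sequence for %s; skipping annotation",
                               m.acronym)
                continue
            lo, hi = m.window
            for np_ in filtered.loci:
                if np_.chrom != m.chrom or not lo <= np_.position < hi:
                    continue
                ann = annotate_consequence(np_, m, ref[m.acronym])
                annotations[np_.locus_id] = ann
                ann_rows.append({
                    "locus_id": np_.locus_id, "gene": m.acronym,
                    "region": ann.region.value, "effect": ann.effect.value,
                    "codon": ann.codon_index, "ref_aa": ann.ref_aa,
                    "alt_aa": ann.alt_aa, "label": ann.label,
                })

    # stage 5: association screens ------------------------------------------
    results = screen_all(
        filtered, calls, models, pairs=pairs, alpha=config.alpha,
        freq_diff=config.freq_diff, carrier_mode=config.carrier_mode,
    )
    assoc_df = pd.DataFrame([{
        "locus_id": r.locus_id, "herbicide": r.herbicide, "gene": r.gene_acronym,
        "region": r.region.value,
        "carrier_freq_resistant": r.carrier_freq_resistant,
        "carrier_freq_susceptible": r.carrier_freq_susceptible,
        "n_resistant_called": r.table.n_resistant,
        "n_susceptible_called": r.table.n_susceptible,
        "fisher_p": r.fisher_p, "bh_q": r.bh_q,
        "fisher_flag": r.fisher_flag, "freq_diff_flag": r.freq_diff_flag,
    } for r in results])
    assoc_df.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    manifest["associations"] = {
        "n_tests": len(assoc_df),
        "n_fisher_flagged": int(assoc_df.fisher_flag.sum()) if len(assoc_df) else 0,
        "n_freq_diff_flagged": int(assoc_df.freq_diff_flag.sum()) if len(assoc_df) else 0,
    }

    flagged_loci = set(assoc_df.loc[
        assoc_df.fisher_flag | assoc_df.freq_diff_flag, "locus_id"
    ]) if len(assoc_df) else set()
    if ann_rows:
        ann_df = pd.DataFrame(ann_rows)
        ann_df["flagged"] = ann_df.locus_id.isin(flagged_loci)
        ann_df.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        np_accounting(ann_df, models).to_csv(
            outdir / "np_accounting.tsv", sep="\t", index=False
        )
        catalog = (load_catalog(config.catalog) if config.catalog is not None
                   else load_bundled_catalog())
        matches = match_catalog(annotations.values(), catalog)
        pd.DataFrame([{
            "locus_id": a.locus_id, "gene": a.gene_acronym, "label": a.label,
            "catalog_gene": e.gene, "catalog_codon": e.codon,
            "hrac_group": e.hrac_group, "source": e.source,
        } for a, e in matches]).to_csv(outdir / "catalog_matches.tsv",
                                       sep="\t", index=False)
        report = candidate_report(results, annotations, filtered, calls,
                                  carrier_mode=config.carrier_mode)
        report.to_csv(outdir / "candidate_report.tsv", sep="\t", index=False)
        manifest["candidates"] = {"n_rows": len(report),
                                  "n_catalog_matches": len(matches)}

    # stage 6: heterozygosity ------------------------------------------------
    model_by_acr = {m.acronym: m for m in models}
    het_rows = []
    for herb, acrs in pairs.items():
        for acr in acrs:
            h = heterozygosity_test(filtered, calls, model_by_acr[acr], herb)
            het_rows.append({
                "gene": h.gene_acronym, "herbicide": h.herbicide,
                "het_rate_resistant": h.het_rate_resistant,
                "het_rate_susceptible": h.het_rate_susceptible,
                "chi_sq": h.chi_sq, "p_value": h.p_value,
                "degenerate": h.degenerate,
            })
    pd.DataFrame(het_rows).to_csv(outdir / "heterozygosity.tsv", sep="\t", index=False)

    # stage 7: phylogeny ------------------------------------------------------
    if config.ssr is not None:
        profiles = read_ssr_table(config.ssr)
        if len(profiles) >= 2:
            D = distance_matrix(profiles)
            write_phylip(D, outdir / "dps_distances.phylip")
            tree = neighbor_joining(D)
            tip_table = annotate_tree(tree, calls)
            (outdir / "tree.nwk").write_text(tree.to_newick())
            tip_table.to_csv(outdir / "tree_tips.tsv", sep="\t", index=False)
            if config.render_figure:
                from .phylo import plot_tree
                plot_tree(tree, outdir / "tree.png",
                          title="Dps neighbor-joining tree")
            manifest["tree"] = {"n_tips": len(tip_table)}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
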