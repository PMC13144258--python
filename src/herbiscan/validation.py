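"""Stochastic validation of the screens against the synthetic generator.

``recovery_rates`` simulates many independent panels with one planted
target-site variant, runs the dual association screen on each, and tallies
how often the planted locus is recovered and how often loci for herbicides
*without* a planted variant are flagged (the empirical false-positive rate
of the Fisher screen on null panels).
"""

from __future__ import annotations

from dataclasses import dataclass

from .association import screen_all
from .phenotypes import code_resistance
from .synthetic import (
    CausalPlan,
    SimulationConfig,
    default_synthetic_pairs,
    simulate_panel,
)
from .variant_calls import filter_nps

__all__ = ["RecoveryRates", "recovery_rates", "DEFAULT_PLAN"]

DEFAULT_PLAN = CausalPlan(
    gene_acronym="Gene3", herbicide="nicosulfuron", codon=197,
    ref_aa="P", alt_aa="S",
    carrier_freq_resistant=0.6, carrier_freq_susceptible=0.1, penetrance=0.9,
)


@dataclass(frozen=True)
class RecoveryRates:
    n_seeds: int
    n_causal_found: int          # seeds where the planted locus was screened
    n_causal_both_flags: int     # ... and flagged by Fisher AND frequency gap
    n_causal_top5: int           # ... and in the top 5 by fisher_p for its herbicide
    n_null_tests: int            # tests for herbicides with no planted variant
    n_null_fisher_flags: int

    @property
    def causal_both_flag_rate(self) -> float:
        return self.n_causal_both_flags / self.n_seeds

    @property
    def causal_top5_rate(self) -> float:
        return self.n_causal_top5 / self.n_seeds

    @property
    def null_fisher_flag_rate(self) -> float:
        return self.n_null_fisher_flags / self.n_null_tests


def recovery_rates(
    n_seeds: int = 50,
    base_seed: int = 0,
    n_genotypes: int = 100,
    n_genes: int = 5,
    n_neutral_snps: int = 500,
    plan: CausalPlan = DEFAULT_PLAN,
    alpha: float = 0.05,
    freq_diff: float = 0.15,
) -> RecoveryRates:
    pairs = default_synthetic_pairs(n_genes)
    found = both = top5 = null_tests = null_flags = 0
    for k in range(n_seeds):
        cfg = SimulationConfig(
            seed=base_seed + k, n_genotypes=n_genotypes, n_genes=n_genes,
            n_neutral_snps=n_neutral_snps, causal_plans=(plan,),
        )
        panel = simulate_panel(cfg)
        filtered = filter_nps(panel.matrix)
        calls = code_resistance(panel.trials)
        results = screen_all(filtered, calls, panel.models, pairs=pairs,
                             alpha=alpha, freq_diff=freq_diff)
        causal_locus = panel.truth_loci.locus_id.iloc[0]
        herb_results = [r for r in results if r.herbicide == plan.herbicide]
        causal = [r for r in herb_results if r.locus_id == causal_locus]
        if causal:
            found += 1
            (r,) = causal
            if r.fisher_flag and r.freq_diff_flag:
                both += 1
            ranked = sorted(herb_results, key=lambda x: x.fisher_p)
            if r in ranked[:5]:
                top5 += 1
        null_herbs = {h for h in pairs} - {plan.herbicide}
        for r in results:
            if r.herbicide in null_herbs:
                null_tests += 1
                null_flags += r.fisher_flag
    return RecoveryRates(
        n_seeds=n_seeds, n_causal_found=found, n_causal_both_flags=both,
        n_causal_top5=top5, n_null_tests=null_tests,
        n_null_fisher_flags=null_flags,
    )
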