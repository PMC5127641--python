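#!/usr/bin/env python
"""Simulate an SSM selection and derive the enrichment landscape.

A single-mutant library of a 20-residue designed binding interface is
sequenced before and after a fitness-dependent sort (depth 1e5 reads per
pool). The script computes the enrichment-ratio matrix, masks low-coverage
cells, centers each position on its 20-amino-acid mean, reports how far
the designed residues sit from the per-position optimum, picks
specificity mutations against two competitor sorts, and scans for
destabilizing proline/stop enrichment.
"""

from pathlib import Path

import numpy as np
from scipy.stats import spearmanr

from specprofiler import ssm, synth

OUT = Path(__file__).resolve().parent.parent / "results"
REFERENCE = "MKLVDESTARGLWQNHPCFY"
SEED = 20260930


def sorted_pool_for(fitness, seed):
    return synth.generate_ssm_experiment(REFERENCE, fitness=fitness,
                                         depth=100_000, selection_strength=1.0,
                                         seed=seed)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    target_fitness = synth.default_fitness(REFERENCE, rng)

    naive, sorted_pool, ledger = sorted_pool_for(target_fitness, SEED)
    table = ssm.mask_low_coverage(
        ssm.enrichment_ratio(naive, sorted_pool, 0.5), naive, min_reads=10)
    normalized = ssm.positionwise_normalize(table)
    ssm.write_enrichment_tsv(normalized, OUT / "ssm_landscape.tsv")

    est = [table.eratio.loc[p, a] for (p, a) in target_fitness]
    rho = spearmanr(est, list(target_fitness.values())).statistic
    print(f"planted-fitness recovery: Spearman rho = {rho:.3f} "
          f"over {len(target_fitness)} variants at depth 1e5")

    stats = ssm.deviation_stats(normalized)
    stats.frame.drop(columns="argmax_set").to_csv(OUT / "ssm_deviation_stats.tsv",
                                                  sep="\t")
    print(f"designed residues deviate from the per-position maximum by "
          f"{stats.frame['deviation_from_max'].mean():.2f} on average "
          f"(mean deviation from the position average "
          f"{stats.frame['deviation_from_mean'].mean():.2f})")

    # competitor sorts share the library but select on independent landscapes
    competitors = []
    for i in range(2):
        comp_fitness = synth.default_fitness(REFERENCE, rng)
        n, s, _ = sorted_pool_for(comp_fitness, SEED + 1 + i)
        competitors.append(ssm.enrichment_ratio(n, s, 0.5))
    picks = ssm.select_specificity_mutations(table, competitors,
                                             enrich_min=1.0, deplete_max=0.0)
    print(f"{len(picks)} mutations enriched on-target (e >= 1) and depleted "
          f"in both competitor sorts (e <= 0); top 5: {picks[:5]}")

    flagged = ssm.detect_destabilizing_enrichment(table, threshold=1.0)
    print(f"destabilizing proline/stop enrichment at {len(flagged)} positions "
          f"{flagged if flagged else '(library selects the folded bundle)'}")
    print(f"wrote {OUT/'ssm_landscape.tsv'} and {OUT/'ssm_deviation_stats.tsv'}")


if __name__ == "__main__":
    main()
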