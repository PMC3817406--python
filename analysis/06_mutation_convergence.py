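#!/usr/bin/env python
"""Convergence statistics of the synthetic resequencing panel.

14 aminoglycoside-adapted clones (12 dose-escalation, 2 fixed-dose) carrying
100 mutations over 44 genes: per-group mutation loads, coding/non-synonymous
fraction, site- and gene-level convergence, the chemogenomic overlap test
against a synthetic susceptibility-hit set, and a toy gene-set enrichment.
"""

import argparse
import json
from pathlib import Path

from colsen.mutations import (
    DEFAULT_GENE_UNIVERSE,
    chemogenomic_overlap_test,
    convergence_stats,
    geneset_enrichment,
    simulate_resequencing_panel,
    synthetic_chemogenomic_hits,
    write_mutation_table,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int) -> None:
    records, roster = simulate_resequencing_panel(seed=seed)
    s = convergence_stats(records, roster)
    print(
        f"{s.total_mutations} mutations in {len(roster)} clones "
        f"(means: {s.group_means['gradient']:.0f} escalation, {s.group_means['fixed']:.0f} fixed)"
    )
    print(f"coding non-synonymous: {100 * s.fraction_coding_nonsynonymous:.0f}%")
    print(
        f"identical sites in >=2 clones: {s.n_shared_sites} of {s.n_sites} sites "
        f"({100 * s.shared_mutation_fraction:.1f}% of mutations)"
    )
    print(
        f"genes mutated in >=2 clones: {s.n_repeated_genes} of {s.n_genes} "
        f"({100 * s.repeated_gene_fraction:.1f}%)"
    )
    mutated = {r.gene for r in records}
    hits = synthetic_chemogenomic_hits(mutated, seed=seed + 1)
    overlap = chemogenomic_overlap_test(mutated, hits, DEFAULT_GENE_UNIVERSE)
    print(
        f"mutated genes overlapping susceptibility hits: {100 * overlap.overlap_fraction:.0f}% "
        f"(Fisher's exact P = {overlap.pvalue:.3f})"
    )
    # toy pathway collection: PMF/respiration genes vs translation vs random
    collection = {
        "membrane_potential": {"trkH", "cyoB", "cyoC", "hemA", "ispA", "nuoE", "nuoF", "atpA", "atpG", "ndh", "cydB"},
        "translation": {"fusA", "rpsL", "rpoB", "rpoC"},
        "unrelated": {f"x{i}" for i in range(12)},
    }
    enrich = geneset_enrichment(mutated, collection, DEFAULT_GENE_UNIVERSE)
    print(enrich.to_string(index=False))

    RESULTS.mkdir(exist_ok=True)
    write_mutation_table(records, RESULTS / "mutation_table.tsv")
    enrich.to_csv(RESULTS / "geneset_enrichment.tsv", sep="\t", index=False)
    (RESULTS / "convergence_summary.json").write_text(
        json.dumps(
            {
                "total_mutations": s.total_mutations,
                "group_means": s.group_means.to_dict(),
                "fraction_coding_nonsynonymous": s.fraction_coding_nonsynonymous,
                "shared_mutation_fraction": s.shared_mutation_fraction,
                "repeated_gene_fraction": s.repeated_gene_fraction,
                "chemogenomic_overlap_fraction": overlap.overlap_fraction,
                "chemogenomic_overlap_p": overlap.pvalue,
            },
            indent=1,
        )
    )
    print(f"tables -> {RESULTS}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
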