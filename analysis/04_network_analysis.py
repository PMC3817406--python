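#!/usr/bin/env python
"""Network-level analysis of the inferred collateral-sensitivity map.

Builds the directed network from the matrix written by 03, computes the
fraction of interacting pairs, per-class weighted out-degrees, the edge
overlap between two independently simulated screens of the same ground truth
(randomization test), same-class depletion (Fisher's exact test), and the
chemogenomic-distance comparison against synthetic profiles.
"""

import argparse
import importlib
import json
import sys
from pathlib import Path

import colsen as cs
from colsen.inference import TestConfig, read_matrix
from colsen.network import (
    build_network,
    class_degree,
    compare_distance_distributions,
    interacting_pair_fraction,
    network_overlap_pvalue,
    same_target_depletion,
    synthetic_profiles,
    write_edges,
)
from colsen.pipeline import infer_from_screen, run_screen

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "analysis"))
screen_mod = importlib.import_module("02_simulate_screen")
RESULTS = ROOT / "results"


def main(seed: int) -> None:
    design, truth, assay = screen_mod.build_screen(seed)
    classes = cs.class_map(design.antibiotics)
    matrix_path = RESULTS / "interaction_matrix.tsv"
    if matrix_path.exists():
        calls = read_matrix(matrix_path)
    else:
        screen = run_screen(design, truth, assay, seed=seed + 3)
        calls = infer_from_screen(screen, design, TestConfig(n_bootstrap=10_000, seed=seed + 4))
    net = build_network(calls, classes=classes)
    frac = interacting_pair_fraction(calls)
    print(f"network: {net.number_of_edges()} directed edges over {net.number_of_nodes()} antibiotics")
    print(f"fraction of unordered pairs interacting in >=1 direction: {frac:.2f}")
    degrees = class_degree(net)
    print("per-class weighted out-degree:")
    print(degrees.to_string())

    # replicate screen of the same truth: edge-set concordance
    screen2 = run_screen(design, truth, assay, seed=seed + 50)
    calls2 = infer_from_screen(screen2, design, TestConfig(n_bootstrap=10_000, seed=seed + 51))
    net2 = build_network(calls2, classes=classes)
    ov = network_overlap_pvalue(net, net2, n_randomizations=20_000, seed=seed + 52)
    print(f"replicate-screen edge overlap: {100 * ov.overlap:.0f}% (randomization P = {ov.pvalue:.2g})")

    dep = same_target_depletion(calls, classes)
    print(f"same-class depletion table {dep.table.tolist()}, Fisher P = {dep.pvalue:.3g}")

    profiles = synthetic_profiles(design.antibiotics, seed=seed + 60)
    cmp_res = compare_distance_distributions(net, profiles)
    print(
        "chemogenomic distance, interacting vs other pairs: medians "
        f"{cmp_res.median_interacting:.2f} vs {cmp_res.median_other:.2f} "
        f"(rank-sum P = {cmp_res.result.pvalue:.2g}, N = {cmp_res.n_interacting + cmp_res.n_other})"
    )

    RESULTS.mkdir(exist_ok=True)
    write_edges(net, RESULTS / "network_edges.tsv")
    degrees.to_csv(RESULTS / "class_degrees.tsv", sep="\t")
    (RESULTS / "network_summary.json").write_text(
        json.dumps(
            {
                "n_edges": net.number_of_edges(),
                "interacting_pair_fraction": frac,
                "replicate_overlap": ov.overlap,
                "replicate_overlap_p": ov.pvalue,
                "same_class_depletion_p": dep.pvalue,
                "chemogenomic_rank_p": cmp_res.result.pvalue,
            },
            indent=1,
        )
    )
    print(f"edges -> {RESULTS / 'network_edges.tsv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
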