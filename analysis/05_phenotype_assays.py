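#!/usr/bin/env python
"""Phenotype-assay computations on synthetic assay inputs.

MIC calling and fold change on 12-step broth dilutions, IC50 interpolation
from dose-response series, Hoechst accumulation (ratio-curve AUC relative to
wild type) for an efflux-impaired vs an efflux-enhanced population, and the
membrane-potential red/green comparison between aminoglycoside- and
other-adapted groups.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from colsen.assays import (
    call_mic,
    fold_mic,
    hoechst_relative_accumulation,
    ic50,
    potential_ratio_comparison,
    simulate_dose_series,
    simulate_kinetic_curve,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int) -> None:
    rng = np.random.default_rng(seed)
    rows = []
    # evolved lines with 8-64x shifted dose-response vs the ancestor; each
    # strain gets a 12-step linear ladder spanning its own response range,
    # as broth-dilution practice requires
    def ladder(center):
        return np.linspace(center / 4, center * 4, 12)

    anc_ic50 = 2.0
    ancestor = simulate_dose_series(anc_ic50, concentrations=ladder(anc_ic50), hill=4.0, noise_sd=0.01, seed=seed)
    mic_anc = call_mic(ancestor)
    for i, shift in enumerate((8, 16, 32, 64)):
        true = anc_ic50 * shift
        evolved = simulate_dose_series(true, concentrations=ladder(true), hill=4.0, noise_sd=0.01, seed=seed + i)
        mic_ev = call_mic(evolved)
        fold = fold_mic(mic_ev, mic_anc)
        half = ic50(evolved)
        rows.append((f"evolved_{shift}x", mic_ev.value, fold.value, fold.lower_bound, half.value, half.flag))
    assay_table = pd.DataFrame(
        rows, columns=["line", "mic", "fold_mic_vs_ancestor", "censored", "ic50", "ic50_flag"]
    )
    print(f"ancestor MIC: {mic_anc.value:.1f}")
    print(assay_table.to_string(index=False))

    # Hoechst accumulation: impaired efflux accumulates more dye than wild type
    wt = [simulate_kinetic_curve(lambda t: 5.0 + 0.001 * t, seed=seed + k, noise_sd=0.002) for k in range(8)]
    impaired = [
        simulate_kinetic_curve(lambda t: 7.5 + 0.0015 * t, seed=seed + 10 + k, noise_sd=0.002) for k in range(8)
    ]
    enhanced = [
        simulate_kinetic_curve(lambda t: 3.5 + 0.0007 * t, seed=seed + 20 + k, noise_sd=0.002) for k in range(8)
    ]
    rel_imp = hoechst_relative_accumulation(impaired, wt)
    rel_enh = hoechst_relative_accumulation(enhanced, wt)
    print(
        f"Hoechst relative accumulation: impaired-efflux {rel_imp.mean():.2f}, "
        f"enhanced-efflux {rel_enh.mean():.2f} (wild type = 1)"
    )

    # membrane potential: aminoglycoside-adapted lines run depolarized
    pops = []
    for i in range(10):
        pops.append((f"agly_{i}", "aminoglycoside", 0.55 * 50 * (1 + 0.08 * rng.standard_normal()), 50.0))
    for i in range(22):
        pops.append((f"other_{i}", "other", 1.0 * 50 * (1 + 0.08 * rng.standard_normal()), 50.0))
    for i in range(3):
        pops.append((f"wt_{i}", "wild_type", 1.0 * 50 * (1 + 0.03 * rng.standard_normal()), 50.0))
    res = potential_ratio_comparison(pd.DataFrame(pops, columns=["population", "group", "red", "green"]))
    med = res.ratios.groupby("group")["relative_ratio"].median()
    print(
        f"membrane potential (red/green vs wild type): aminoglycoside median {med['aminoglycoside']:.2f}, "
        f"other {med['other']:.2f}; rank-sum P = {res.test.pvalue:.2g} ({res.test.method})"
    )

    RESULTS.mkdir(exist_ok=True)
    assay_table.to_csv(RESULTS / "assay_mic_ic50.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "group": ["impaired_efflux", "enhanced_efflux"],
            "relative_hoechst_auc": [rel_imp.mean(), rel_enh.mean()],
        }
    ).to_csv(RESULTS / "assay_hoechst.tsv", sep="\t", index=False)
    res.ratios.to_csv(RESULTS / "assay_potential.tsv", sep="\t", index=False)
    print(f"assay tables -> {RESULTS}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
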