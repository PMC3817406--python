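"""Bootstrap inference of collateral-sensitivity / cross-resistance calls.

For each ordered antibiotic pair (A, B), the growth of the 10 A-adapted lines
in condition B is compared, as a group, against the 10 adapted control lines
under the same condition.  Each line is summarized by the median of its
technical replicates; the group effect is

    D = (mean(control) - mean(evolved)) / mean(control)

(positive D = sensitivity).  Significance is assessed by a non-parametric
bootstrap: lines are resampled with replacement independently within each
group, and the one-sided p-value for sensitivity is the (add-one corrected)
fraction of resamples whose deficit falls below the 10% effect threshold.
Run-level p-values are combined with Fisher's method.  Finally a cost control
repeats the test on the excess deficit (deficit under drug minus the
drug-free deficit of the same lines), so that calls cannot be driven by
general fitness costs of resistance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import ExperimentDesign
from .normalization import RelativeFitnessTable
from .plates import DRUG_FREE
from .qc import QcReport
from .stats import bh_adjust

EXHAUSTIVE_MAX_N = 4

CLASSIFICATIONS = ("collateral_sensitivity", "cross_resistance", "none", "untestable")


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class TestConfig:
    """Settings of the bootstrap group test.

    effect_threshold
        Minimal relative group difference (10% by default) referenced by the
        bootstrap statistic.
    n_bootstrap
        Monte-Carlo resamples per test (>= 1000 for reported results).
    mtc
        Multiple-testing correction across pairs: "none" or "bh_fdr".
    group_stat
        Group summary used in the deficit: "mean" (default) or "median".
    """

    __test__ = False  # not a pytest class, despite the name

    effect_threshold: float = 0.10
    n_bootstrap: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    mtc: str = "none"
    group_stat: str = "mean"

    def __post_init__(self) -> None:
        if not 0 < self.effect_threshold < 1:
            raise InferenceError("effect_threshold must lie in (0, 1)")
        if self.n_bootstrap < 1:
            raise InferenceError("n_bootstrap must be >= 1")
        if self.mtc not in ("none", "bh_fdr"):
            raise InferenceError(f"unknown mtc {self.mtc!r}")
        if self.group_stat not in ("mean", "median"):
            raise InferenceError(f"unknown group_stat {self.group_stat!r}")


def _summ(values: np.ndarray, stat: str, axis=None):
    return np.mean(values, axis=axis) if stat == "mean" else np.median(values, axis=axis)


def group_effect(evolved, control, stat: str = "mean") -> float:
    """Relative growth deficit of the evolved group: (C - E) / C."""
    evolved = np.asarray(evolved, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(evolved) == 0 or len(control) == 0:
        raise InferenceError("both groups must be non-empty")
    c = float(_summ(control, stat))
    if c <= 0:
        return float("nan")
    return (c - float(_summ(evolved, stat))) / c


def _resample_summaries(
    values: np.ndarray, n_bootstrap: int, rng: np.random.Generator, stat: str
) -> np.ndarray:
    idx = rng.integers(0, len(values), size=(n_bootstrap, len(values)))
    return _summ(values[idx], stat, axis=1)


def _exhaustive_summaries(values: np.ndarray, stat: str) -> np.ndarray:
    n = len(values)
    idx = np.array(list(product(range(n), repeat=n)), dtype=int)
    return _summ(values[idx], stat, axis=1)


@dataclass(frozen=True)
class BootstrapResult:
    pvalue: float
    effect: float
    direction: str
    method: str  # "monte_carlo" or "exhaustive"
    n_resamples: int


def bootstrap_group_test(
    evolved,
    control,
    cfg: TestConfig | None = None,
    direction: str = "sensitivity",
    rng: np.random.Generator | None = None,
    method: str = "monte_carlo",
) -> BootstrapResult:
    """One-sided threshold-referenced bootstrap test on per-line summaries.

    ``direction="sensitivity"`` counts resampled deficits D below the effect
    threshold (add-one corrected); ``"resistance"`` symmetrically counts
    D above minus the threshold.  ``method="exhaustive"`` enumerates all
    joint index resamples (no add-one correction), available for both group
    sizes at most 4.
    """
    cfg = cfg or TestConfig()
    evolved = np.asarray(evolved, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(evolved) < 2 or len(control) < 2:
        raise InferenceError("group size must be >= 2 for the bootstrap test")
    if direction not in ("sensitivity", "resistance"):
        raise InferenceError(f"unknown direction {direction!r}")
    effect = group_effect(evolved, control, cfg.group_stat)
    if method == "exhaustive":
        if len(evolved) > EXHAUSTIVE_MAX_N or len(control) > EXHAUSTIVE_MAX_N:
            raise InferenceError(f"exhaustive mode limited to groups of size <= {EXHAUSTIVE_MAX_N}")
        e = _exhaustive_summaries(evolved, cfg.group_stat)
        c = _exhaustive_summaries(control, cfg.group_stat)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (c[:, None] - e[None, :]) / c[:, None]
        n_total = d.size
        if direction == "sensitivity":
            hits = int(np.count_nonzero(d < cfg.effect_threshold))
        else:
            hits = int(np.count_nonzero(d > -cfg.effect_threshold))
        return BootstrapResult(hits / n_total, effect, direction, "exhaustive", n_total)
    if method != "monte_carlo":
        raise InferenceError(f"unknown method {method!r}")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    e = _resample_summaries(evolved, cfg.n_bootstrap, rng, cfg.group_stat)
    c = _resample_summaries(control, cfg.n_bootstrap, rng, cfg.group_stat)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (c - e) / c
    if direction == "sensitivity":
        hits = int(np.count_nonzero(d < cfg.effect_threshold))
    else:
        hits = int(np.count_nonzero(d > -cfg.effect_threshold))
    p = (1 + hits) / (cfg.n_bootstrap + 1)
    return BootstrapResult(p, effect, direction, "monte_carlo", cfg.n_bootstrap)


def fisher_combine(pvalues, zero_floor: float | None = None) -> float:
    """Fisher's combined probability: chi2 = -2 sum(ln p) on 2k d.f.

    Exact zeros (possible for exhaustive bootstrap p-values) must be floored
    explicitly, conventionally at 1/(n_bootstrap + 1).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise InferenceError("no p-values to combine")
    if np.any((p < 0) | (p > 1)):
        raise InferenceError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        if zero_floor is None:
            raise InferenceError("p=0 requires an explicit zero_floor")
        p = np.maximum(p, zero_floor)
    stat, combined = sps.combine_pvalues(p, method="fisher")
    return float(combined)


def bootstrap_excess_deficit(
    evolved_drug,
    control_drug,
    evolved_free,
    control_free,
    cfg: TestConfig | None = None,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Bootstrap p-value for the cost-controlled excess deficit.

    Delta = deficit under drug - drug-free deficit, with lines resampled
    jointly across the two conditions (a line's drug and drug-free values
    travel together), so general fitness costs cancel.
    """
    cfg = cfg or TestConfig()
    ed = np.asarray(evolved_drug, dtype=float)
    cd = np.asarray(control_drug, dtype=float)
    ef = np.asarray(evolved_free, dtype=float)
    cf = np.asarray(control_free, dtype=float)
    if len(ed) != len(ef) or len(cd) != len(cf):
        raise InferenceError("drug and drug-free summaries must align line-by-line")
    if len(ed) < 2 or len(cd) < 2:
        raise InferenceError("group size must be >= 2 for the bootstrap test")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    delta_obs = group_effect(ed, cd, cfg.group_stat) - group_effect(ef, cf, cfg.group_stat)
    ei = rng.integers(0, len(ed), size=(cfg.n_bootstrap, len(ed)))
    ci = rng.integers(0, len(cd), size=(cfg.n_bootstrap, len(cd)))
    with np.errstate(divide="ignore", invalid="ignore"):
        d_drug = (
            _summ(cd[ci], cfg.group_stat, axis=1) - _summ(ed[ei], cfg.group_stat, axis=1)
        ) / _summ(cd[ci], cfg.group_stat, axis=1)
        d_free = (
            _summ(cf[ci], cfg.group_stat, axis=1) - _summ(ef[ei], cfg.group_stat, axis=1)
        ) / _summ(cf[ci], cfg.group_stat, axis=1)
    delta = d_drug - d_free
    hits = int(np.count_nonzero(delta < cfg.effect_threshold))
    p = (1 + hits) / (cfg.n_bootstrap + 1)
    return BootstrapResult(p, delta_obs, "sensitivity", "monte_carlo", cfg.n_bootstrap)


def infer_matrix(
    fitness: RelativeFitnessTable,
    qc_report: QcReport,
    design: ExperimentDesign,
    cfg: TestConfig | None = None,
) -> pd.DataFrame:
    """Classify every ordered (selection A, test B) pair with retained data.

    Per retained run: one-sided bootstrap p-values for sensitivity and
    resistance plus the cost-controlled excess-deficit p.  Run p-values are
    Fisher-combined (exact zeros floored at 1/(n_bootstrap+1)).  A pair is
    called collateral_sensitivity when mean deficit and mean excess deficit
    both reach the effect threshold and both combined p-values fall below
    alpha; cross_resistance symmetrically on the raw test alone.  Pairs with
    no retained run (or with run sets lacking drug-free references) are
    reported untestable.
    """
    cfg = cfg or TestConfig()
    retained = qc_report.retained()
    summary = fitness.summary
    data: dict[tuple[int, str], dict[str, float]] = {}
    for (run, cond), sub in summary.groupby(["run", "condition"]):
        data[(int(run), cond)] = dict(zip(sub["line_id"], sub["fitness"]))
    evolved_ids = {
        a: sorted(l.line_id for l in design.evolved if l.selection_antibiotic == a)
        for a in design.selection_antibiotics
    }
    control_ids = sorted(l.line_id for l in design.controls)
    runs = sorted(summary["run"].unique())
    pairs = [
        (a, b)
        for a in design.selection_antibiotics
        for b in design.antibiotics["abbreviation"]
        if a != b
    ]
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(pairs))
    floor = 1.0 / (cfg.n_bootstrap + 1)
    rows = []
    for (a, b), ss in zip(pairs, seeds):
        rng = np.random.default_rng(ss)
        p_sens, p_res, p_cost, effects, deltas = [], [], [], [], []
        for run in runs:
            if (run, b) not in retained or (run, DRUG_FREE) not in retained:
                continue
            drug = data.get((run, b), {})
            free = data.get((run, DRUG_FREE), {})
            e_ids = [l for l in evolved_ids[a] if l in drug and l in free]
            c_ids = [l for l in control_ids if l in drug and l in free]
            if len(e_ids) < 2 or len(c_ids) < 2:
                continue
            ed = np.array([drug[l] for l in e_ids])
            cd = np.array([drug[l] for l in c_ids])
            ef = np.array([free[l] for l in e_ids])
            cf = np.array([free[l] for l in c_ids])
            if _summ(cd, cfg.group_stat) <= 0:
                continue
            rs = bootstrap_group_test(ed, cd, cfg, "sensitivity", rng=rng)
            rr = bootstrap_group_test(ed, cd, cfg, "resistance", rng=rng)
            rc = bootstrap_excess_deficit(ed, cd, ef, cf, cfg, rng=rng)
            p_sens.append(rs.pvalue)
            p_res.append(rr.pvalue)
            p_cost.append(rc.pvalue)
            effects.append(rs.effect)
            deltas.append(rc.effect)
        if not effects:
            rows.append((a, b, 0, np.nan, np.nan, np.nan, np.nan, np.nan, "untestable"))
            continue
        eff = float(np.mean(effects))
        delta = float(np.mean(deltas))
        pc = fisher_combine(p_sens, zero_floor=floor)
        pr = fisher_combine(p_res, zero_floor=floor)
        pk = fisher_combine(p_cost, zero_floor=floor)
        rows.append((a, b, len(effects), eff, delta, pc, pr, pk, ""))
    calls = pd.DataFrame(
        rows,
        columns=[
            "A",
            "B",
            "n_runs",
            "effect",
            "delta",
            "p_combined",
            "p_resistance",
            "p_cost_adjusted",
            "classification",
        ],
    )
    testable = calls["classification"] != "untestable"
    p_sens_eff = calls["p_combined"].copy()
    p_cost_eff = calls["p_cost_adjusted"].copy()
    p_res_eff = calls["p_resistance"].copy()
    if cfg.mtc == "bh_fdr":
        p_sens_eff.loc[testable] = bh_adjust(calls.loc[testable, "p_combined"])
        p_cost_eff.loc[testable] = bh_adjust(calls.loc[testable, "p_cost_adjusted"])
        p_res_eff.loc[testable] = bh_adjust(calls.loc[testable, "p_resistance"])
    cls = []
    for i, r in calls.iterrows():
        if r["classification"] == "untestable":
            cls.append("untestable")
        elif (
            r["effect"] >= cfg.effect_threshold
            and r["delta"] >= cfg.effect_threshold
            and p_sens_eff[i] < cfg.alpha
            and p_cost_eff[i] < cfg.alpha
        ):
            cls.append("collateral_sensitivity")
        elif r["effect"] <= -cfg.effect_threshold and p_res_eff[i] < cfg.alpha:
            cls.append("cross_resistance")
        else:
            cls.append("none")
    calls["classification"] = cls
    return calls


def write_matrix(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
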