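"""Directed interaction network and its summary statistics.

An edge A -> B of type collateral_sensitivity means adaptation to A increased
sensitivity to B.  Network-level analyses: per-class weighted out-degrees,
edge-overlap randomization test between two regimes' networks, chemogenomic
Jaccard-distance comparison between interacting and non-interacting pairs,
and depletion of interactions among same-class pairs (Fisher's exact test).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .stats import RankSumResult, fisher_exact_2x2, rank_sum_test


class NetworkError(ValueError):
    pass


def build_network(
    matrix: pd.DataFrame,
    kind: str = "collateral_sensitivity",
    classes: dict[str, str] | None = None,
) -> nx.DiGraph:
    """Build the directed network of called pairs of the requested type.

    Nodes are every antibiotic appearing in a testable pair (so isolated,
    tested-but-uncalled antibiotics are kept); untestable pairs contribute
    nothing.  Edge weights carry the effect sizes.
    """
    if "classification" not in matrix.columns:
        raise NetworkError("matrix is not classified")
    g = nx.DiGraph()
    testable = matrix[matrix["classification"] != "untestable"]
    for n in pd.unique(testable[["A", "B"]].to_numpy().ravel()):
        g.add_node(n, moa_class=(classes or {}).get(n))
    called = testable[testable["classification"] == kind]
    for _, r in called.iterrows():
        if r["A"] == r["B"]:
            raise NetworkError(f"self-edge {r['A']}")
        g.add_edge(r["A"], r["B"], weight=float(r["effect"]), kind=kind)
    return g


def interacting_pair_fraction(matrix: pd.DataFrame, kind: str = "collateral_sensitivity") -> float:
    """Fraction of testable unordered pairs interacting in >= 1 direction."""
    testable = matrix[matrix["classification"] != "untestable"]
    pairs: dict[frozenset, bool] = {}
    for _, r in testable.iterrows():
        key = frozenset((r["A"], r["B"]))
        pairs[key] = pairs.get(key, False) or (r["classification"] == kind)
    if not pairs:
        return float("nan")
    return sum(pairs.values()) / len(pairs)


def class_degree(network: nx.DiGraph, classes: dict[str, str] | None = None) -> pd.Series:
    """Weighted out-degree per antibiotic class.

    For each source class, the mean over its member antibiotics of the number
    of distinct target classes reached by the member's outgoing edges.
    """
    cmap = {n: (classes or {}).get(n, network.nodes[n].get("moa_class")) for n in network}
    if any(c is None for c in cmap.values()):
        missing = sorted(n for n, c in cmap.items() if c is None)
        raise NetworkError(f"nodes without a class: {missing}")
    per_class: dict[str, list[int]] = {}
    for n in network:
        targets = {cmap[t] for t in network.successors(n)}
        per_class.setdefault(cmap[n], []).append(len(targets))
    return pd.Series(
        {c: float(np.mean(v)) for c, v in sorted(per_class.items())}, name="weighted_degree"
    )


@dataclass(frozen=True)
class OverlapResult:
    overlap: float
    pvalue: float
    n_randomizations: int
    method: str


def _overlap(ea: set, eb: set, method: str) -> float:
    if not ea and not eb:
        return float("nan")
    inter = len(ea & eb)
    if method == "jaccard":
        return inter / len(ea | eb)
    if method == "min":
        denom = min(len(ea), len(eb))
        return inter / denom if denom else float("nan")
    raise NetworkError(f"unknown overlap method {method!r}")


def network_overlap_pvalue(
    net_a: nx.DiGraph,
    net_b: nx.DiGraph,
    n_randomizations: int = 10_000,
    seed: int = 0,
    method: str = "jaccard",
) -> OverlapResult:
    """Edge-set overlap between two networks with a randomization p-value.

    Overlap is intersection-over-union of the directed edge sets
    (``method="min"``: intersection over the smaller set).  The null
    redraws each network's edge count uniformly among all ordered non-self
    node pairs; p = (1 + #{null >= observed}) / (R + 1).
    """
    nodes = sorted(net_a.nodes)
    if nodes != sorted(net_b.nodes):
        raise NetworkError("networks must share the same node set")
    ea, eb = set(net_a.edges), set(net_b.edges)
    obs = _overlap(ea, eb, method)
    all_pairs = [(u, v) for u in nodes for v in nodes if u != v]
    rng = np.random.default_rng(seed)
    m = len(all_pairs)
    hits = 0
    for _ in range(n_randomizations):
        ia = rng.choice(m, size=len(ea), replace=False)
        ib = rng.choice(m, size=len(eb), replace=False)
        ra = {all_pairs[i] for i in ia}
        rb = {all_pairs[i] for i in ib}
        if _overlap(ra, rb, method) >= obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_randomizations + 1)
    return OverlapResult(obs, p, n_randomizations, method)


def chemogenomic_distance(profile_a: set, profile_b: set) -> float:
    """Jaccard distance between two susceptibility gene sets.

    Both sets empty is degenerate: the distance is defined as 0 (identical
    empty profiles); callers comparing distributions should exclude
    unprofiled antibiotics.
    """
    a, b = set(profile_a), set(profile_b)
    if not a and not b:
        return 0.0
    return 1.0 - len(a & b) / len(a | b)


@dataclass(frozen=True)
class DistanceComparison:
    result: RankSumResult
    n_interacting: int
    n_other: int
    median_interacting: float
    median_other: float
    excluded: tuple[str, ...]


def compare_distance_distributions(
    network: nx.DiGraph, profiles: dict[str, set]
) -> DistanceComparison:
    """Chemogenomic distance of interacting vs non-interacting pairs.

    Unordered pairs of profiled antibiotics are split by whether the network
    links them in at least one direction; distances are compared with a
    two-sided rank-sum test (exact enumeration for small samples).
    Antibiotics without a profile are excluded and reported.
    """
    nodes = sorted(network.nodes)
    excluded = tuple(n for n in nodes if n not in profiles)
    usable = [n for n in nodes if n in profiles]
    inter, other = [], []
    for i, u in enumerate(usable):
        for v in usable[i + 1 :]:
            d = chemogenomic_distance(profiles[u], profiles[v])
            if network.has_edge(u, v) or network.has_edge(v, u):
                inter.append(d)
            else:
                other.append(d)
    if len(inter) < 2 or len(other) < 2:
        raise NetworkError("need >= 2 pairs per group for the rank test")
    res = rank_sum_test(inter, other, alternative="two-sided")
    return DistanceComparison(
        result=res,
        n_interacting=len(inter),
        n_other=len(other),
        median_interacting=float(np.median(inter)),
        median_other=float(np.median(other)),
        excluded=excluded,
    )


@dataclass(frozen=True)
class DepletionResult:
    table: np.ndarray  # rows: same-class / different-class; cols: interacting / not
    pvalue: float


def same_target_depletion(
    matrix: pd.DataFrame,
    classes: dict[str, str],
    kind: str = "collateral_sensitivity",
) -> DepletionResult:
    """Fisher's exact test for depletion of interactions among same-class pairs.

    Over testable unordered pairs, cross-tabulates same-class membership
    against interaction in at least one direction.
    """
    testable = matrix[matrix["classification"] != "untestable"]
    pairs: dict[frozenset, bool] = {}
    for _, r in testable.iterrows():
        key = frozenset((r["A"], r["B"]))
        pairs[key] = pairs.get(key, False) or (r["classification"] == kind)
    counts = np.zeros((2, 2), dtype=int)
    for key, interacting in pairs.items():
        u, v = sorted(key)
        if u not in classes or v not in classes:
            raise NetworkError(f"pair ({u}, {v}) lacks class assignment")
        same = classes[u] == classes[v]
        counts[0 if same else 1, 0 if interacting else 1] += 1
    return DepletionResult(counts, fisher_exact_2x2(counts))


def synthetic_profiles(
    antibiotics: pd.DataFrame,
    class_core: int = 30,
    specific: int = 20,
    shared_background: int = 10,
    seed: int = 0,
) -> dict[str, set]:
    """Synthetic chemogenomic profiles (stand-in for a published screen).

    Antibiotics of the same mode-of-action class share a class-core gene set
    plus a common background, and each carries private genes, so within-class
    Jaccard distances are small and between-class distances large — the
    structure real chemogenomic screens show.
    """
    rng = np.random.default_rng(seed)
    gene_counter = [0]

    def fresh(n: int) -> set:
        start = gene_counter[0]
        gene_counter[0] += n
        return {f"g{start + i:05d}" for i in range(n)}

    background = fresh(shared_background)
    cores = {c: fresh(class_core) for c in antibiotics["moa_class"].unique()}
    profiles = {}
    for _, row in antibiotics.iterrows():
        profiles[row["abbreviation"]] = background | cores[row["moa_class"]] | fresh(specific)
    return profiles


def read_profiles(path) -> dict[str, set]:
    """Two-column TSV (antibiotic, gene) -> profile sets."""
    df = pd.read_csv(path, sep="\t", header=None, names=["antibiotic", "gene"], comment="#")
    out: dict[str, set] = {}
    for ab, sub in df.groupby("antibiotic"):
        out[str(ab)] = set(map(str, sub["gene"]))
    return out


def write_edges(network: nx.DiGraph, path) -> None:
    rows = [
        (u, v, d.get("kind", ""), d.get("weight", float("nan")))
        for u, v, d in network.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "type", "effect"]).to_csv(
        path, sep="\t", index=False
    )
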