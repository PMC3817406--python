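"""Mutation tables and parallel-evolution convergence statistics.

Sequenced resistant clones yield per-clone mutation lists (SNPs, MNPs,
indels).  Convergence is quantified at two levels: identical sites mutated in
two or more clones, and genes mutated in two or more clones.  A chemogenomic
overlap test asks whether mutated genes are enriched among genes whose
inactivation changes susceptibility to the selecting drug class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import bh_adjust, fisher_exact_2x2, hypergeom_upper_tail

MTYPES = ("SNP", "MNP", "insertion", "deletion")
TSV_COLUMNS = ("clone_id", "gene", "position", "ref", "alt", "mtype", "coding", "synonymous")

# K-12 MG1655 protein-coding gene count, the conventional universe for
# gene-level exact tests against chemogenomic screens.
DEFAULT_GENE_UNIVERSE = 4146


class MutationTableError(ValueError):
    pass


@dataclass(frozen=True)
class MutationRecord:
    clone_id: str
    gene: str  # gene name, or an intergenic marker like "intergenic:1234"
    position: int  # 1-based genomic coordinate
    ref: str
    alt: str
    mtype: str
    coding: bool
    synonymous: bool | None  # defined only for coding records

    def __post_init__(self) -> None:
        if self.position < 1:
            raise MutationTableError(f"position must be >= 1, got {self.position}")
        if self.mtype not in MTYPES:
            raise MutationTableError(f"unknown mutation type {self.mtype!r}")
        if not self.coding and self.synonymous is not None:
            raise MutationTableError("synonymous is defined only for coding records")


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in ("1", "true", "yes")


def read_mutation_table(path, format: str = "tsv") -> list[MutationRecord]:
    """Read mutation records from TSV or (minimal) VCF.

    TSV columns: clone_id, gene, position, ref, alt, mtype, coding,
    synonymous.  VCF: fixed v4 columns with INFO keys GENE, TYPE, CODING,
    SYN and one sample column per clone; a clone carries the variant when its
    genotype includes the alternate allele.  Malformed rows are rejected with
    their line numbers.
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise MutationTableError(f"unknown format {format!r}")


def _read_tsv(path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise MutationTableError(f"mutation TSV missing columns: {missing}")
    records = []
    errors = []
    for i, row in df.iterrows():
        try:
            coding = _parse_bool(row["coding"])
            syn_raw = row["synonymous"].strip()
            synonymous = None if (not coding or syn_raw in ("", "NA")) else _parse_bool(syn_raw)
            records.append(
                MutationRecord(
                    clone_id=row["clone_id"],
                    gene=row["gene"],
                    position=int(row["position"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    mtype=row["mtype"],
                    coding=coding,
                    synonymous=synonymous,
                )
            )
        except (ValueError, MutationTableError) as exc:
            errors.append(f"line {i + 2}: {exc}")
    if errors:
        raise MutationTableError("rejected rows:\n" + "\n".join(errors))
    return records


def _classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "SNP" if len(ref) == 1 else "MNP"
    return "insertion" if len(alt) > len(ref) else "deletion"


def _read_vcf(path) -> list[MutationRecord]:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise MutationTableError("VCF has no sample columns to map to clones")
        for var in vcf:
            gene = var.info.get("GENE", None)
            if gene is None:
                raise MutationTableError(f"record at pos {var.pos} lacks INFO/GENE")
            if isinstance(gene, tuple):
                gene = gene[0]
            coding = bool(var.info.get("CODING", False))
            syn = bool(var.info.get("SYN", False)) if coding else None
            for alt_i, alt in enumerate(var.alts or (), start=1):
                mtype = _classify_alleles(var.ref, alt)
                for clone in samples:
                    gt = var.samples[clone].get("GT", ())
                    if gt and alt_i in [g for g in gt if g is not None]:
                        records.append(
                            MutationRecord(
                                clone_id=clone,
                                gene=str(gene),
                                position=int(var.pos),
                                ref=var.ref,
                                alt=alt,
                                mtype=mtype,
                                coding=coding,
                                synonymous=syn,
                            )
                        )
    return records


def write_mutation_table(records: list[MutationRecord], path) -> None:
    rows = [
        (
            r.clone_id,
            r.gene,
            r.position,
            r.ref,
            r.alt,
            r.mtype,
            str(r.coding).lower(),
            "NA" if r.synonymous is None else str(r.synonymous).lower(),
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=list(TSV_COLUMNS)).to_csv(path, sep="\t", index=False)


@dataclass
class ConvergenceSummary:
    """Convergence bookkeeping over a clone roster.

    Shared-site statistics are reported both allele-aware (identical
    gene/position/alt) and position-only, and both as a fraction of distinct
    sites and of all mutation records, since either denominator is defensible.
    """

    per_clone: pd.Series
    total_mutations: int
    group_means: pd.Series
    fraction_coding_nonsynonymous: float
    n_sites: int
    n_shared_sites: int
    shared_site_fraction: float
    shared_mutation_fraction: float
    n_shared_sites_position_only: int
    n_genes: int
    n_repeated_genes: int
    repeated_gene_fraction: float


def convergence_stats(
    records: list[MutationRecord], roster: pd.DataFrame
) -> ConvergenceSummary:
    """Compute per-clone counts and site/gene-level convergence fractions.

    ``roster`` needs columns clone_id and group; every record's clone must
    appear on the roster (clones without mutations count as zero).
    """
    if not {"clone_id", "group"}.issubset(roster.columns):
        raise MutationTableError("roster needs columns clone_id, group")
    roster_ids = list(roster["clone_id"])
    unknown = sorted({r.clone_id for r in records} - set(roster_ids))
    if unknown:
        raise MutationTableError(f"records from clones missing on roster: {unknown}")
    df = pd.DataFrame(
        {
            "clone_id": [r.clone_id for r in records],
            "gene": [r.gene for r in records],
            "position": [r.position for r in records],
            "alt": [r.alt for r in records],
            "coding": [r.coding for r in records],
            "synonymous": [r.synonymous for r in records],
        }
    )
    per_clone = (
        df.groupby("clone_id").size().reindex(roster_ids, fill_value=0).rename("n_mutations")
    )
    total = int(per_clone.sum())
    groups = roster.set_index("clone_id")["group"]
    group_means = per_clone.groupby(groups).mean().rename("mean_mutations")
    if total:
        coding_nonsyn = int(((df["coding"]) & (df["synonymous"] == False)).sum())  # noqa: E712
        frac_cn = coding_nonsyn / total
    else:
        frac_cn = float("nan")
    # allele-aware sites: distinct (gene, position, alt)
    site_clones = df.groupby(["gene", "position", "alt"])["clone_id"].nunique() if total else pd.Series(dtype=int)
    n_sites = int(len(site_clones))
    shared = site_clones[site_clones >= 2]
    n_shared = int(len(shared))
    pos_clones = df.groupby(["gene", "position"])["clone_id"].nunique() if total else pd.Series(dtype=int)
    n_shared_pos = int((pos_clones >= 2).sum())
    shared_keys = set(shared.index)
    shared_mutations = (
        int(
            df.set_index(["gene", "position", "alt"]).index.isin(shared_keys).sum()
        )
        if n_shared
        else 0
    )
    gene_clones = df.groupby("gene")["clone_id"].nunique() if total else pd.Series(dtype=int)
    n_genes = int(len(gene_clones))
    n_repeated = int((gene_clones >= 2).sum())
    return ConvergenceSummary(
        per_clone=per_clone,
        total_mutations=total,
        group_means=group_means,
        fraction_coding_nonsynonymous=frac_cn,
        n_sites=n_sites,
        n_shared_sites=n_shared,
        shared_site_fraction=(n_shared / n_sites) if n_sites else 0.0,
        shared_mutation_fraction=(shared_mutations / total) if total else 0.0,
        n_shared_sites_position_only=n_shared_pos,
        n_genes=n_genes,
        n_repeated_genes=n_repeated,
        repeated_gene_fraction=(n_repeated / n_genes) if n_genes else 0.0,
    )


@dataclass(frozen=True)
class OverlapTest:
    overlap_fraction: float
    pvalue: float
    table: tuple[tuple[int, int], tuple[int, int]]


def chemogenomic_overlap_test(
    mutated_genes: set, hit_genes: set, universe_size: int
) -> OverlapTest:
    """Fisher's exact test for overlap of mutated genes with susceptibility hits.

    Cross-tabulates membership in the mutated set against the hit set over a
    gene universe of ``universe_size``; overlap fraction is |intersection| /
    |mutated|.
    """
    mutated, hits = set(mutated_genes), set(hit_genes)
    if universe_size <= max(len(mutated), len(hits)):
        raise MutationTableError("universe must exceed both set sizes")
    both = len(mutated & hits)
    only_m = len(mutated) - both
    only_h = len(hits) - both
    neither = universe_size - both - only_m - only_h
    table = ((both, only_m), (only_h, neither))
    p = fisher_exact_2x2(table)
    frac = both / len(mutated) if mutated else float("nan")
    return OverlapTest(frac, p, table)


def geneset_enrichment(
    mutated_genes: set, collection: dict[str, set], universe_size: int
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per gene set with BH q-values."""
    if not collection:
        raise MutationTableError("gene-set collection is empty")
    mutated = set(mutated_genes)
    rows = []
    for name, genes in sorted(collection.items()):
        genes = set(genes)
        k = len(mutated & genes)
        p = hypergeom_upper_tail(k, len(mutated), len(genes), universe_size)
        rows.append((name, len(genes), k, p))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "pvalue"])
    out["qvalue"] = bh_adjust(out["pvalue"])
    return out


# ---------------------------------------------------------------------------
# Synthetic resequencing panel

_CORE_GENES = [
    "trkH", "cyoB", "cyoC", "fusA", "rpsL", "hemA", "ispA", "nuoE", "nuoF",
    "oppF", "cpxA", "sbmA", "arnC", "atpA", "atpG", "ubiF", "sucB", "speA",
    "potD", "glnE", "rpoB", "rpoC", "proQ", "yhjE", "ompF", "marR", "acrR",
    "envZ", "phoQ", "lpxM", "waaP", "pssA", "cls", "fabF", "plsB", "gltA",
    "icd", "mdh", "ndh", "cydB", "menA", "hemH", "trkA", "kdpD",
]


def simulate_resequencing_panel(
    n_gradient_clones: int = 12,
    n_fixed_clones: int = 2,
    mutations_per_gradient_clone: int = 8,
    mutations_per_fixed_clone: int = 2,
    n_genes: int = 44,
    n_repeated_genes: int = 13,
    shared_site_multiplicities: tuple[int, ...] = (3, 2, 2),
    n_coding_nonsynonymous: int = 89,
    seed: int = 0,
) -> tuple[list[MutationRecord], pd.DataFrame]:
    """Synthetic whole-genome resequencing panel of aminoglycoside-adapted clones.

    Emulates the study conditions: 12 clones from the dose-escalation regime
    with 8 mutations each and 2 fixed-dose clones with 2 each (100 records in
    total over 44 coding genes), with planted identical-site sharing
    (multiplicities ``shared_site_multiplicities`` across clones), exactly
    ``n_repeated_genes`` genes hit in >= 2 clones, and
    ``n_coding_nonsynonymous`` non-synonymous records (the remainder are
    synonymous).  Returns (records, roster); the roster's group column is
    ``gradient`` / ``fixed``.
    """
    rng = np.random.default_rng(seed)
    clones = [(f"G{i + 1:02d}", "gradient", mutations_per_gradient_clone) for i in range(n_gradient_clones)]
    clones += [(f"F{i + 1:02d}", "fixed", mutations_per_fixed_clone) for i in range(n_fixed_clones)]
    total = sum(c[2] for c in clones)
    genes = list(_CORE_GENES[:n_genes])
    if len(genes) < n_genes:
        genes += [f"y{chr(97 + i // 26)}{chr(97 + i % 26)}X" for i in range(n_genes - len(genes))]
    base_pos = {
        g: int(p)
        for g, p in zip(genes, sorted(rng.choice(np.arange(10_000, 4_600_000, 1051), len(genes), replace=False)))
    }

    capacity = {cid: k for cid, _, k in clones}
    order = [cid for cid, _, _ in clones]
    gradient_ids = [cid for cid, grp, _ in clones if grp == "gradient"]
    # each site: (gene, position, ref, alt, mtype, [clone_ids])
    sites: list[dict] = []

    def most_capacity(pool: list[str], k: int) -> list[str]:
        return sorted(pool, key=lambda c: -capacity[c])[:k]

    n_shared_slots = sum(shared_site_multiplicities)
    n_more_repeated = n_repeated_genes - len(shared_site_multiplicities)
    if n_more_repeated < 0:
        raise MutationTableError("more shared sites than repeated genes")
    n_singleton_slots = total - n_shared_slots - 2 * n_more_repeated
    n_singleton_genes = n_genes - n_repeated_genes
    if n_singleton_slots < n_singleton_genes:
        raise MutationTableError("not enough mutations to cover every gene")

    # identical sites shared by several clones (planted in the first genes)
    for j, mult in enumerate(shared_site_multiplicities):
        g = genes[j]
        takers = most_capacity(gradient_ids, mult)
        for cid in takers:
            capacity[cid] -= 1
        sites.append(dict(gene=g, position=base_pos[g], ref="C", alt="T", mtype="SNP", clones=takers))
    # further repeated genes: two clones, two distinct sites each
    for j in range(len(shared_site_multiplicities), n_repeated_genes):
        g = genes[j]
        takers = most_capacity(order, 2)
        for k, cid in enumerate(takers):
            capacity[cid] -= 1
            sites.append(
                dict(gene=g, position=base_pos[g] + 3 * (k + 1), ref="C", alt="A", mtype="SNP", clones=[cid])
            )
    # singleton genes: each owned by exactly one clone (possibly several
    # sites within the gene), so the gene never counts as repeated.
    # Ownership is assigned round-robin so every clone with remaining
    # capacity owns at least one gene.
    singleton_genes = genes[n_repeated_genes:]
    owners: dict[str, str] = {}
    remaining = dict(capacity)
    gi = 0
    while gi < len(singleton_genes):
        progress = False
        for cid in order:
            if gi >= len(singleton_genes):
                break
            if remaining[cid] > 0:
                owners[singleton_genes[gi]] = cid
                remaining[cid] -= 1
                gi += 1
                progress = True
        if not progress:
            raise MutationTableError("clone capacities exhausted before covering all genes")
    for g in singleton_genes:
        capacity[owners[g]] -= 1
        sites.append(dict(gene=g, position=base_pos[g], ref="C", alt="G", mtype="SNP", clones=[owners[g]]))
    # leftover capacity: extra distinct sites within genes the clone owns
    owned_by = {cid: [g for g in singleton_genes if owners[g] == cid] for cid in order}
    extra_count = {g: 0 for g in singleton_genes}
    for cid in order:
        j = 0
        while capacity[cid] > 0:
            glist = owned_by[cid]
            g = glist[j % len(glist)]
            extra_count[g] += 1
            capacity[cid] -= 1
            j += 1
            sites.append(
                dict(
                    gene=g,
                    position=base_pos[g] + 100 + 7 * extra_count[g],
                    ref="C",
                    alt="G",
                    mtype="SNP",
                    clones=[cid],
                )
            )

    # a few singleton sites become MNPs / indels
    singleton_idx = [i for i, s in enumerate(sites) if len(s["clones"]) == 1]
    special = rng.choice(singleton_idx, size=min(6, len(singleton_idx)), replace=False)
    for k, i in enumerate(special):
        if k < 2:
            sites[i].update(ref="CA", alt="AT", mtype="MNP")
        elif k < 4:
            sites[i].update(ref="C", alt="CTT", mtype="insertion")
        else:
            sites[i].update(ref="CTT", alt="C", mtype="deletion")
    # synonymous labelling on singleton sites only (shared sites are the
    # adaptive, non-synonymous ones)
    n_records = sum(len(s["clones"]) for s in sites)
    assert n_records == total
    n_syn = total - n_coding_nonsynonymous
    syn_pool = [i for i in singleton_idx if i not in set(special)]
    syn_idx = set(rng.choice(syn_pool, size=n_syn, replace=False).tolist())

    records: list[MutationRecord] = []
    for i, s in enumerate(sites):
        for cid in s["clones"]:
            records.append(
                MutationRecord(
                    clone_id=cid,
                    gene=s["gene"],
                    position=s["position"],
                    ref=s["ref"],
                    alt=s["alt"],
                    mtype=s["mtype"],
                    coding=True,
                    synonymous=i in syn_idx,
                )
            )
    records.sort(key=lambda r: (r.clone_id, r.position))
    roster = pd.DataFrame(
        {"clone_id": [c for c, _, _ in clones], "group": [g for _, g, _ in clones]}
    )
    return records, roster


def synthetic_chemogenomic_hits(
    mutated_genes: set,
    n_overlap: int = 16,
    n_hits: int = 850,
    seed: int = 0,
) -> set:
    """Synthetic chemogenomic hit set (stand-in for a published screen).

    Builds a hit set of ``n_hits`` genes containing ``n_overlap`` of the
    supplied mutated genes, the configuration in which roughly a third of
    mutated genes are susceptibility hits; the remaining hits are filler
    gene names outside the mutated set.
    """
    rng = np.random.default_rng(seed)
    mutated = sorted(set(mutated_genes))
    if n_overlap > len(mutated):
        raise MutationTableError("n_overlap exceeds the mutated set size")
    chosen = set(rng.choice(mutated, size=n_overlap, replace=False).tolist())
    fillers = (f"b{i:04d}" for i in range(10_000))
    hits = set(chosen)
    for g in fillers:
        if len(hits) >= n_hits:
            break
        if g not in mutated:
            hits.add(g)
    return hits
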