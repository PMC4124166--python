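"""Human-branch acceleration screen.

A gene is called accelerated when the human branch shows a significant
excess of non-synonymous over synonymous substitutions relative to the
hominoid-ancestor branch (one-sided Fisher's exact test), the chimpanzee
branch shows no such excess against the same reference, and a
neighbor-joining tree built from the family supports the expected species
topology (human and chimp as sisters).  A rate-matched control set of
non-accelerated genes can be sampled on the human-branch dN/dS distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact, mannwhitneyu
from skbio import DistanceMatrix
from skbio.tree import nj

from .core_io import SPECIES, AnalysisConfig, GeneFamily, logger
from .divergence import BranchCounts


@dataclass(frozen=True)
class AccelerationResult:
    gene_id: str
    p_human: float
    p_chimp: float
    topology_ok: bool
    accelerated: bool


def fisher_branch_excess(focal: BranchCounts, reference: BranchCounts) -> float:
    """One-sided Fisher's exact p for non-synonymous excess in ``focal``.

    The 2x2 table has rows (focal Dn, focal Ds) and (reference Dn,
    reference Ds); fractional parsimony counts are rounded half-to-even
    first.  An all-zero table gives p = 1.
    """
    table = [
        [round(focal.Dn), round(focal.Ds)],
        [round(reference.Dn), round(reference.Ds)],
    ]
    if sum(table[0]) + sum(table[1]) == 0:
        return 1.0
    return float(fisher_exact(table, alternative="greater")[1])


def classify_accelerated(
    gene_counts: Mapping[str, BranchCounts],
    config: AnalysisConfig = AnalysisConfig(),
    topology_ok: bool = True,
) -> AccelerationResult:
    """Dual-Fisher acceleration call for one gene.

    ``gene_counts`` maps branch label to counts and must contain the human,
    chimp and hominoid_ancestor branches.  Accelerated means: human excess
    significant, chimp excess not significant, topology confirmed.
    """
    missing = {"human", "chimp", "hominoid_ancestor"} - set(gene_counts)
    if missing:
        raise KeyError(f"missing branches for acceleration test: {sorted(missing)}")
    ancestor = gene_counts["hominoid_ancestor"]
    p_human = fisher_branch_excess(gene_counts["human"], ancestor)
    p_chimp = fisher_branch_excess(gene_counts["chimp"], ancestor)
    alpha = config.significance_level
    return AccelerationResult(
        gene_id=gene_counts["human"].gene_id,
        p_human=p_human,
        p_chimp=p_chimp,
        topology_ok=topology_ok,
        accelerated=(p_human < alpha) and (p_chimp >= alpha) and topology_ok,
    )


def screen_accelerated(
    counts: Iterable[BranchCounts],
    config: AnalysisConfig = AnalysisConfig(),
    topology_ok: Mapping[str, bool] | None = None,
) -> list[AccelerationResult]:
    """Run the dual-Fisher screen over all genes in a count table."""
    by_gene: dict[str, dict[str, BranchCounts]] = {}
    for bc in counts:
        by_gene.setdefault(bc.gene_id, {})[bc.branch] = bc
    out = []
    for gene_id in sorted(by_gene):
        branches = by_gene[gene_id]
        if {"human", "chimp", "hominoid_ancestor"} - set(branches):
            logger.warning("gene %s: missing branches, skipped in screen", gene_id)
            continue
        ok = True if topology_ok is None else topology_ok.get(gene_id, True)
        out.append(classify_accelerated(branches, config, topology_ok=ok))
    return out


def _jc_distance(a: str, b: str) -> float:
    diff = total = 0
    for x, y in zip(a, b):
        total += 1
        if x != y:
            diff += 1
    if total == 0:
        return 0.0
    p = diff / total
    if p >= 0.75:
        logger.warning("saturated distance (p=%.3f); using uncorrected p", p)
        return p
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nj_topology_check(family: GeneFamily) -> bool:
    """True when a neighbor-joining tree groups human and chimp as sisters.

    Distances are Jukes-Cantor-corrected proportions over the concatenated
    gap-free codon columns (uncorrected when saturated).  Families with no
    divergence at all carry no topological signal and pass by convention.
    """
    idx = family.gap_free_column_indices()
    if not idx:
        raise ValueError(f"family {family.gene_id}: no gap-free codon columns")
    concat = {
        sp: "".join(family.sequences[sp][3 * i : 3 * i + 3] for i in idx)
        for sp in SPECIES
    }
    mat = np.zeros((4, 4))
    for i, a in enumerate(SPECIES):
        for j, b in enumerate(SPECIES):
            if i < j:
                mat[i, j] = mat[j, i] = _jc_distance(concat[a], concat[b])
    if not mat.any():
        return True
    tree = nj(DistanceMatrix(mat, ids=list(SPECIES)))
    target = {frozenset(("human", "chimp")), frozenset(("macaque", "mouse"))}
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        tips = frozenset(t.name for t in node.tips())
        if tips in target:
            return True
    return False


def _dnds_bin(value: float, width: float = 0.1, n_bins: int = 11) -> int:
    """Fixed-width dN/dS bin index; the last bin is open-ended."""
    return min(int(value / width), n_bins - 1)


def sample_matched_controls(
    pool: Mapping[str, float],
    accelerated: Mapping[str, float],
    n: int | None = None,
    seed: int = 0,
    max_retries: int = 20,
) -> set[str]:
    """Sample non-accelerated genes matching the accelerated dN/dS profile.

    ``pool`` and ``accelerated`` map gene id to human-branch dN/dS; the pool
    must exclude accelerated genes.  Genes are drawn without replacement per
    0.1-wide dN/dS bin to mirror the accelerated set's bin counts (borrowing
    from the nearest non-empty bin when a bin is exhausted, with a log
    line).  The draw is accepted when a two-sided rank-sum test of the two
    dN/dS distributions gives p > 0.05, retrying up to ``max_retries`` times.
    """
    overlap = set(pool) & set(accelerated)
    if overlap:
        raise ValueError(f"pool contains accelerated genes: {sorted(overlap)[:5]}")
    if n is None:
        n = len(accelerated)
    if n > len(pool):
        raise ValueError("control size exceeds pool size")
    rng = np.random.default_rng(seed)
    accel_values = np.asarray(list(accelerated.values()))
    target_bins: dict[int, int] = {}
    for v in accelerated.values():
        b = _dnds_bin(v)
        target_bins[b] = target_bins.get(b, 0) + 1
    if n != len(accelerated):
        scale = n / len(accelerated)
        target_bins = {
            b: max(0, int(round(k * scale))) for b, k in target_bins.items()
        }
    pool_bins: dict[int, list[str]] = {}
    for g, v in pool.items():
        pool_bins.setdefault(_dnds_bin(v), []).append(g)
    for b in pool_bins:
        pool_bins[b].sort()

    best: set[str] = set()
    for _attempt in range(max_retries):
        chosen: list[str] = []
        taken: set[str] = set()
        for b, k in sorted(target_bins.items()):
            candidates = [g for g in pool_bins.get(b, []) if g not in taken]
            if len(candidates) < k:
                # borrow the shortfall from the nearest bins
                shortfall = k - len(candidates)
                logger.warning(
                    "dN/dS bin %d short by %d; borrowing from neighbours", b, shortfall
                )
                for dist in range(1, 12):
                    for nb in (b - dist, b + dist):
                        extra = [
                            g
                            for g in pool_bins.get(nb, [])
                            if g not in taken and g not in candidates
                        ]
                        candidates.extend(extra[:shortfall])
                        shortfall = k - len(candidates)
                        if shortfall <= 0:
                            break
                    if shortfall <= 0:
                        break
            pick = list(rng.choice(candidates, size=min(k, len(candidates)), replace=False))
            chosen.extend(pick)
            taken.update(pick)
        best = set(chosen)
        control_values = np.asarray([pool[g] for g in chosen])
        if len(control_values) < 2 or len(accel_values) < 2:
            return best
        p = mannwhitneyu(control_values, accel_values, alternative="two-sided")[1]
        if p > 0.05:
            return best
    logger.warning("matched-control sampling never reached rank-sum p > 0.05")
    return best
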