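"""Gene-set comparisons of fixation-index distributions and category counts.

Per-gene FI values are only stable for informative genes (all four MK counts
non-zero and at least four polymorphic sites), so every distribution
comparison is restricted to that subset.  GO-term groups of at least 40
informative genes, plus the reserved group of genes with no GO annotation
("unknown"), are compared against the full informative background with
rank-sum tests; count-based enrichment of a category inside a gene set uses
an exact binomial proportion test against the background category frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest, mannwhitneyu
from statsmodels.stats.proportion import proportions_ztest

from .mkstats import MKCounts, MKResult

UNKNOWN_GROUP = "unknown"


@dataclass(frozen=True)
class GOGroup:
    term_label: str
    gene_ids: frozenset[str]

    @property
    def n(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class GroupComparison:
    term_label: str
    n: int
    median_group: float
    median_background: float
    p_two_sided: float
    p_one_sided: float | None
    one_sided_suppressed: bool


@dataclass(frozen=True)
class CategoryCountResult:
    observed: int
    expected: float
    p: float
    p_normal: float | None


def filter_informative(gene_results: Mapping[str, MKResult | MKCounts]) -> set[str]:
    """Genes with Dn, Ds, Pn, Ps all non-zero and Pn + Ps >= 4."""
    out = set()
    for gene_id, r in gene_results.items():
        c = r.counts if isinstance(r, MKResult) else r
        if min(c.Dn, c.Ds, c.Pn, c.Ps) > 0 and c.Pn + c.Ps >= 4:
            out.add(gene_id)
    return out


def build_go_groups(
    annotations: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    min_size: int = 40,
) -> list[GOGroup]:
    """GO-term groups restricted to a gene universe.

    Groups with fewer than ``min_size`` universe genes are dropped; genes of
    the universe without any annotation form the reserved group
    ``unknown`` (kept regardless of size).
    """
    universe = set(universe)
    by_term: dict[str, set[str]] = {}
    annotated: set[str] = set()
    for gene, terms in annotations.items():
        if gene not in universe:
            continue
        terms = list(terms)
        if terms:
            annotated.add(gene)
        for t in terms:
            by_term.setdefault(t, set()).add(gene)
    groups = [
        GOGroup(term_label=t, gene_ids=frozenset(genes))
        for t, genes in sorted(by_term.items())
        if len(genes) >= min_size
    ]
    groups.append(
        GOGroup(term_label=UNKNOWN_GROUP, gene_ids=frozenset(universe - annotated))
    )
    return groups


def group_fi_comparison(
    group: GOGroup,
    background: Iterable[str],
    gene_fi: Mapping[str, float],
    include_group_in_background: bool = True,
) -> GroupComparison:
    """Rank-sum comparison of a group's FI distribution with the background.

    The one-sided (greater) p-value is reported only when the group median
    exceeds the background median, otherwise it is suppressed; the two-sided
    p-value is always available.
    """
    bg_ids = set(background)
    if not include_group_in_background:
        bg_ids -= group.gene_ids
    group_vals = np.asarray([gene_fi[g] for g in group.gene_ids if g in gene_fi])
    bg_vals = np.asarray([gene_fi[g] for g in bg_ids if g in gene_fi])
    if len(group_vals) < 2 or len(bg_vals) < 2:
        raise ValueError(f"group {group.term_label}: too few FI values to compare")
    med_g = float(np.median(group_vals))
    med_b = float(np.median(bg_vals))
    p_two = float(mannwhitneyu(group_vals, bg_vals, alternative="two-sided")[1])
    suppressed = not med_g > med_b
    p_one = (
        None
        if suppressed
        else float(mannwhitneyu(group_vals, bg_vals, alternative="greater")[1])
    )
    return GroupComparison(
        term_label=group.term_label,
        n=len(group_vals),
        median_group=med_g,
        median_background=med_b,
        p_two_sided=p_two,
        p_one_sided=p_one,
        one_sided_suppressed=suppressed,
    )


def category_count_test(
    set_genes: Iterable[str],
    category_genes: Iterable[str],
    background: Iterable[str],
) -> CategoryCountResult:
    """Is a category over-represented in a gene set, given its background rate?

    Observed is the category count inside the set; the expectation is the
    set size times the background category frequency.  The default p-value
    is the exact one-sided binomial upper tail; a normal-approximation
    proportion test is reported alongside when computable.
    """
    set_genes = set(set_genes)
    category_genes = set(category_genes)
    background = set(background)
    if not background:
        raise ValueError("empty background")
    if not set_genes <= background or not category_genes <= background:
        raise ValueError("set and category must be subsets of the background")
    p0 = len(category_genes) / len(background)
    k = len(set_genes & category_genes)
    n = len(set_genes)
    expected = n * p0
    if p0 == 0.0:
        return CategoryCountResult(observed=k, expected=0.0, p=1.0, p_normal=None)
    p_exact = float(binomtest(k, n, p0, alternative="greater").pvalue)
    p_norm = None
    if 0 < k < n:
        p_norm = float(
            proportions_ztest(k, n, value=p0, alternative="larger")[1]
        )
    return CategoryCountResult(observed=k, expected=expected, p=p_exact, p_normal=p_norm)


def group_summary_frame(
    groups: Sequence[GOGroup],
    background: Iterable[str],
    gene_fi: Mapping[str, float],
    gene_counts: Mapping[str, MKCounts] | None = None,
) -> pd.DataFrame:
    """Per-group summary table: size, median FI, pooled counts, p-values."""
    bg = set(background)
    rows = []
    for grp in groups:
        try:
            cmp = group_fi_comparison(grp, bg, gene_fi)
        except ValueError:
            continue  # group too small to compare (e.g. empty "unknown")
        row = {
            "term": grp.term_label,
            "n": cmp.n,
            "median_FI": cmp.median_group,
            "p_two_sided": cmp.p_two_sided,
            "p_one_sided": cmp.p_one_sided,
        }
        if gene_counts is not None:
            members = [g for g in grp.gene_ids if g in gene_counts]
            row["Dn"] = sum(gene_counts[g].Dn for g in members)
            row["Ds"] = sum(gene_counts[g].Ds for g in members)
            row["Pn"] = sum(gene_counts[g].Pn for g in members)
            row["Ps"] = sum(gene_counts[g].Ps for g in members)
        rows.append(row)
    return pd.DataFrame(rows)
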