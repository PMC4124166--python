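"""McDonald-Kreitman statistics: FI, NI, NI_TG, DoS, alpha and the G-test.

The MK 2x2 table contrasts fixed differences on the human branch (Dn, Ds)
with segregating human polymorphisms (Pn, Ps):

* fixation index        FI  = (Dn/Ds) / (Pn/Ps)
* neutrality index      NI  = 1/FI
* direction of selection DoS = Dn/(Dn+Ds) - Pn/(Pn+Ps)
* adaptive proportion   alpha = 1 - (Ds*Pn)/(Dn*Ps) = 1 - 1/FI

Significance uses the G-test of independence with the Williams continuity
correction.  Gene-set values pool the four counts over member genes before
computing any ratio (equivalent to concatenating alignments), and NI_TG is
the heterogeneity-robust pooled neutrality index
``sum(Ds_i*Pn_i/(Ps_i+Ds_i)) / sum(Dn_i*Ps_i/(Ps_i+Ds_i))``.

Ratios with a zero count anywhere are reported as undefined with a reason
code rather than as infinities; per-gene analyses exclude such genes via
:func:`lineagemk.functional_groups.filter_informative`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .polymorphism import GenePolymorphism, polymorphic_gene_subset


@dataclass(frozen=True)
class MKCounts:
    """The four MK cell counts (fractional Dn/Ds allowed from parsimony)."""

    Dn: float
    Ds: float
    Pn: float
    Ps: float

    def __post_init__(self) -> None:
        if min(self.Dn, self.Ds, self.Pn, self.Ps) < 0:
            raise ValueError("MK counts must be non-negative")

    def __add__(self, other: "MKCounts") -> "MKCounts":
        return MKCounts(
            self.Dn + other.Dn,
            self.Ds + other.Ds,
            self.Pn + other.Pn,
            self.Ps + other.Ps,
        )


@dataclass(frozen=True)
class MKResult:
    counts: MKCounts
    FI: float | None
    NI: float | None
    DoS: float | None
    alpha: float | None
    G_adj: float | None
    p: float | None
    undefined_reason: str | None = None


@dataclass(frozen=True)
class GeneSetSummary:
    set_label: str
    stratum: str
    n_genes: int
    pooled: MKCounts
    stats: MKResult
    NI_TG: float | None


def _zero_reason(c: MKCounts) -> str | None:
    zeros = [
        name
        for name, v in (("Dn", c.Dn), ("Ds", c.Ds), ("Pn", c.Pn), ("Ps", c.Ps))
        if v == 0
    ]
    return "zero_" + "_".join(zeros) if zeros else None


def fixation_index(c: MKCounts) -> float | None:
    """(Dn/Ds)/(Pn/Ps); None when any of the four counts is zero."""
    if 0 in (c.Dn, c.Ds, c.Pn, c.Ps):
        return None
    return (c.Dn / c.Ds) / (c.Pn / c.Ps)


def neutrality_index(c: MKCounts) -> float | None:
    """NI = 1/FI = (Pn/Ps)/(Dn/Ds)."""
    fi = fixation_index(c)
    return None if fi is None else 1.0 / fi


def direction_of_selection(c: MKCounts) -> float | None:
    """DoS = Dn/(Dn+Ds) - Pn/(Pn+Ps); defined when both margins are positive."""
    if c.Dn + c.Ds == 0 or c.Pn + c.Ps == 0:
        return None
    return c.Dn / (c.Dn + c.Ds) - c.Pn / (c.Pn + c.Ps)


def alpha_adaptive(c: MKCounts) -> float | None:
    """alpha = 1 - (Ds*Pn)/(Dn*Ps); defined when Dn > 0 and Ps > 0."""
    if c.Dn == 0 or c.Ps == 0:
        return None
    return 1.0 - (c.Ds * c.Pn) / (c.Dn * c.Ps)


def mk_gtest_williams(c: MKCounts) -> tuple[float | None, float | None]:
    """Williams-corrected G-test of independence on the MK 2x2 table.

    Zero cells contribute nothing to G (the x*ln(x) -> 0 limit); a zero row
    or column margin makes the test undefined and returns (None, None).
    The Williams factor is
    ``q = 1 + (N/r1 + N/r2 - 1)(N/c1 + N/c2 - 1)/(6N)`` and the p-value is
    the upper chi-squared(1) tail of G/q.
    """
    table = ((c.Dn, c.Ds), (c.Pn, c.Ps))
    r = (c.Dn + c.Ds, c.Pn + c.Ps)
    col = (c.Dn + c.Pn, c.Ds + c.Ps)
    n = r[0] + r[1]
    if 0 in r or 0 in col:
        return None, None
    g = 0.0
    for i in range(2):
        for j in range(2):
            obs = table[i][j]
            if obs > 0:
                g += obs * math.log(obs / (r[i] * col[j] / n))
    g *= 2.0
    q = 1.0 + (n / r[0] + n / r[1] - 1.0) * (n / col[0] + n / col[1] - 1.0) / (6.0 * n)
    g_adj = g / q
    return g_adj, float(chi2.sf(g_adj, df=1))


def mk_test(c: MKCounts) -> MKResult:
    """All MK statistics for one table, with an undefined-reason code."""
    g_adj, p = mk_gtest_williams(c)
    return MKResult(
        counts=c,
        FI=fixation_index(c),
        NI=neutrality_index(c),
        DoS=direction_of_selection(c),
        alpha=alpha_adaptive(c),
        G_adj=g_adj,
        p=p,
        undefined_reason=_zero_reason(c),
    )


def pool_counts(genes: Iterable[MKCounts]) -> MKCounts:
    """Component-wise sum of the four counts over genes."""
    total = MKCounts(0, 0, 0, 0)
    for g in genes:
        total = total + g
    return total


def neutrality_index_tg(genes: Iterable[MKCounts]) -> float | None:
    """Heterogeneity-robust pooled neutrality index.

    Genes with Ps + Ds == 0 carry no information for the ratio and are
    skipped; a zero denominator sum leaves the index undefined.
    """
    num = den = 0.0
    for c in genes:
        w = c.Ps + c.Ds
        if w == 0:
            continue
        num += c.Ds * c.Pn / w
        den += c.Dn * c.Ps / w
    if den == 0:
        return None
    return num / den


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (explicit, never applied silently)."""
    pvals = np.asarray(list(pvalues), dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def stratum_summary(
    gene_counts: Mapping[str, tuple[float, float]],
    gene_polys: Iterable[GenePolymorphism],
    strata: Sequence[str] | None = None,
    set_labels: Mapping[str, Iterable[str]] | None = None,
) -> list[GeneSetSummary]:
    """Pooled MK statistics per gene set and frequency stratum.

    ``gene_counts`` maps gene id to human-branch (Dn, Ds).  Within each
    stratum only genes with at least one polymorphic site there enter the
    pool (and the reported n), matching how per-stratum set summaries are
    tabulated.
    """
    polys = list(gene_polys)
    if strata is None:
        strata = sorted({r.stratum for r in polys})
    if set_labels is None:
        set_labels = {"all": sorted(gene_counts)}
    poly_by = {}
    for r in polys:
        poly_by[(r.gene_id, r.stratum)] = (r.Pn, r.Ps)
    out = []
    for label, members in set_labels.items():
        member_set = set(members)
        for stratum in strata:
            poly_genes = polymorphic_gene_subset(polys, stratum)
            used = sorted(member_set & poly_genes & set(gene_counts))
            per_gene = [
                MKCounts(*gene_counts[g], *poly_by[(g, stratum)]) for g in used
            ]
            pooled = pool_counts(per_gene)
            out.append(
                GeneSetSummary(
                    set_label=label,
                    stratum=stratum,
                    n_genes=len(used),
                    pooled=pooled,
                    stats=mk_test(pooled),
                    NI_TG=neutrality_index_tg(per_gene),
                )
            )
    return out


def summary_frame(summaries: Iterable[GeneSetSummary]) -> pd.DataFrame:
    """Flat table of per-set per-stratum pooled statistics."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "set": s.set_label,
                "stratum": s.stratum,
                "n_genes": s.n_genes,
                "Dn": s.pooled.Dn,
                "Ds": s.pooled.Ds,
                "Pn": s.pooled.Pn,
                "Ps": s.pooled.Ps,
                "FI": s.stats.FI,
                "DoS": s.stats.DoS,
                "alpha": s.stats.alpha,
                "NI_TG": s.NI_TG,
                "G_adj": s.stats.G_adj,
                "p": s.stats.p,
            }
        )
    return pd.DataFrame(rows)


def mk_result_frame(results: Mapping[str, MKResult]) -> pd.DataFrame:
    """Per-gene MK result table (one row per gene)."""
    rows = []
    for gene_id, r in results.items():
        rows.append(
            {
                "gene_id": gene_id,
                "Dn": r.counts.Dn,
                "Ds": r.counts.Ds,
                "Pn": r.counts.Pn,
                "Ps": r.counts.Ps,
                "FI": r.FI,
                "NI": r.NI,
                "DoS": r.DoS,
                "alpha": r.alpha,
                "G_adj": r.G_adj,
                "p": r.p,
                "undefined_reason": r.undefined_reason,
            }
        )
    return pd.DataFrame(rows)
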