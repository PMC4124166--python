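"""Branch-specific substitution counting on the ((human,chimp),macaque,mouse) quartet.

Substitutions are placed on the five edges of the unrooted species quartet by
small parsimony (Fitch) applied per nucleotide position and composed per
codon; every equally parsimonious ancestral assignment is enumerated and the
per-edge counts are averaged uniformly over them, so Dn/Ds may be fractional.
Each edge's codon difference is decomposed into synonymous and
non-synonymous changes by NG86 pathway averaging.  Site totals N and S are
computed from the human sequence.

This is a deterministic substitute for a maximum-likelihood free-ratio codon
model; externally computed ML counts can be supplied instead through
:func:`lineagemk.core_io.read_count_table` and flow through all downstream
statistics unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Iterable, Mapping, NamedTuple, Sequence

from .codons import is_sense, ng86_path_counts, ng86_site_counts
from .core_io import BRANCHES, AnalysisConfig, GeneFamily, RejectionLog, logger

#: the three branches subject to the dN/dS sanity filter
FILTERED_BRANCHES = ("human", "chimp", "hominoid_ancestor")


@dataclass
class BranchCounts:
    """Substitution and site counts for one gene on one branch.

    ``Dn``/``Ds`` may be fractional (parsimony tie averaging, NG86 pathway
    averaging).  ``N``/``S`` are NG86 fractional site counts from the human
    sequence; ``N + S`` equals three times the number of gap-free codon
    columns.
    """

    gene_id: str
    branch: str
    Dn: float
    Ds: float
    N: float | None = None
    S: float | None = None

    @property
    def dN(self) -> float | None:
        if self.N is None or self.N == 0:
            return None
        return self.Dn / self.N

    @property
    def dS(self) -> float | None:
        if self.S is None or self.S == 0:
            return None
        return self.Ds / self.S

    @property
    def omega(self) -> float | None:
        """dN/dS; None when dS is zero or site counts are unavailable."""
        dn, ds = self.dN, self.dS
        if dn is None or ds is None or ds == 0:
            return None
        return dn / ds


@dataclass
class FamilyQC:
    gene_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)


class ColumnAncestors(NamedTuple):
    column: int
    hominoid_codons: frozenset[str]
    root_codons: frozenset[str]
    min_changes: int


@dataclass
class CountResult:
    """Per-gene output of :func:`count_branch_substitutions`."""

    branch_counts: list[BranchCounts]
    human_change_columns: list[int]
    skipped_columns: list[int]

    def by_branch(self) -> dict[str, BranchCounts]:
        return {bc.branch: bc for bc in self.branch_counts}


@lru_cache(maxsize=None)
def _min_pairs_nt(
    h: str, c: str, m: str, o: str
) -> tuple[tuple[tuple[str, str], ...], int]:
    """Minimal-cost (hominoid-ancestor, root) base pairs for one position.

    Internal states are drawn from the observed bases; for a quartet this
    loses no minimal assignment.
    """
    observed = sorted({h, c, m, o})
    best = 10
    pairs: list[tuple[str, str]] = []
    for x in observed:
        for y in observed:
            cost = (x != h) + (x != c) + (y != x) + (y != m) + (y != o)
            if cost < best:
                best = cost
                pairs = [(x, y)]
            elif cost == best:
                pairs.append((x, y))
    return tuple(pairs), best


@lru_cache(maxsize=None)
def _column_solutions(
    h: str, c: str, m: str, o: str
) -> tuple[tuple[tuple[str, str], ...], int, bool]:
    """All minimal codon-level ancestral assignments for one column.

    Returns (assignments, minimal change count, sense_ok).  The parsimony
    cost decomposes over nucleotide positions, so the minimal codon
    assignments are the Cartesian product of the per-position minimal pairs.
    Assignments whose ancestors are both sense codons are preferred; when
    none exist ``sense_ok`` is False.
    """
    per_pos = [_min_pairs_nt(h[p], c[p], m[p], o[p]) for p in range(3)]
    total = sum(best for _, best in per_pos)
    assignments = []
    for combo in product(*(pairs for pairs, _ in per_pos)):
        x = "".join(p[0] for p in combo)
        y = "".join(p[1] for p in combo)
        assignments.append((x, y))
    sense = [(x, y) for x, y in assignments if is_sense(x) and is_sense(y)]
    if sense:
        return tuple(sense), total, True
    return tuple(assignments), total, False


@lru_cache(maxsize=None)
def _column_branch_changes(
    h: str, c: str, m: str, o: str
) -> tuple[tuple[tuple[float, float], ...], bool, bool] | None:
    """Tie-averaged per-branch (nonsyn, syn) changes for one codon column.

    Returns None when no minimal assignment has sense ancestors (the column
    is skipped and flagged by the caller).  The boolean flags are
    (human_branch_changed, all_paths_stop_free).
    """
    assignments, _, sense_ok = _column_solutions(h, c, m, o)
    if not sense_ok:
        return None
    acc = {br: [0.0, 0.0] for br in BRANCHES}
    human_changed = False
    stop_free = True
    for x, y in assignments:
        for parent, child, br in (
            (x, h, "human"),
            (x, c, "chimp"),
            (y, x, "hominoid_ancestor"),
            (y, m, "macaque"),
            (y, o, "mouse"),
        ):
            n, s, sf = ng86_path_counts(parent, child)
            stop_free = stop_free and sf
            acc[br][0] += n
            acc[br][1] += s
            if br == "human" and parent != child:
                human_changed = True
    k = len(assignments)
    rows = tuple((acc[br][0] / k, acc[br][1] / k) for br in BRANCHES)
    return rows, human_changed, stop_free


def fitch_ancestral_codons(family: GeneFamily) -> list[ColumnAncestors]:
    """Minimal-parsimony ancestral codon sets for every gap-free column.

    ``hominoid_codons`` is the set of codons attainable at the human-chimp
    ancestor node over all minimal assignments; ``root_codons`` the same for
    the deeper (primate-ancestor) node.
    """
    out = []
    for i in family.gap_free_column_indices():
        h, c, m, o = family.codon_column(i)
        assignments, total, _ = _column_solutions(h, c, m, o)
        out.append(
            ColumnAncestors(
                column=i,
                hominoid_codons=frozenset(x for x, _ in assignments),
                root_codons=frozenset(y for _, y in assignments),
                min_changes=total,
            )
        )
    return out


def count_branch_substitutions(family: GeneFamily) -> CountResult:
    """Per-branch Dn/Ds for one family under minimal parsimony + NG86.

    Columns whose only minimal reconstructions require a stop-codon ancestor
    are skipped and reported in ``skipped_columns``.
    """
    indices = family.gap_free_column_indices()
    if not indices:
        raise ValueError(f"family {family.gene_id}: no gap-free codon columns")
    totals = {br: [0.0, 0.0] for br in BRANCHES}
    human_cols: list[int] = []
    skipped: list[int] = []
    n_sites = s_sites = 0.0
    human_seq = family.sequences["human"]
    for i in indices:
        h, c, m, o = family.codon_column(i)
        res = _column_branch_changes(h, c, m, o)
        if res is None:
            skipped.append(i)
            logger.warning(
                "gene %s column %d: no stop-free ancestral assignment; skipped",
                family.gene_id,
                i,
            )
            continue
        rows, human_changed, _ = res
        for br, (dn, ds) in zip(BRANCHES, rows):
            totals[br][0] += dn
            totals[br][1] += ds
        if human_changed:
            human_cols.append(i)
        n, s = ng86_site_counts(human_seq[3 * i : 3 * i + 3])
        n_sites += n
        s_sites += s
    counts = [
        BranchCounts(
            gene_id=family.gene_id,
            branch=br,
            Dn=totals[br][0],
            Ds=totals[br][1],
            N=n_sites,
            S=s_sites,
        )
        for br in BRANCHES
    ]
    return CountResult(
        branch_counts=counts, human_change_columns=human_cols, skipped_columns=skipped
    )


def misalignment_fraction(
    family: GeneFamily, human_change_columns: Sequence[int], window: int = 5
) -> float:
    """Fraction of human-branch changes within ``window`` codons of a gap.

    A high value suggests the changes cluster around indels, the typical
    footprint of misalignment; reported as a heuristic, never used to exclude
    genes automatically.
    """
    if not human_change_columns:
        return 0.0
    gaps = family.gap_column_indices()
    if not gaps:
        return 0.0
    near = sum(
        1
        for col in human_change_columns
        if any(abs(col - g) <= window for g in gaps)
    )
    return near / len(human_change_columns)


def apply_quality_filters(
    families: Iterable[GeneFamily] | Mapping[str, GeneFamily],
    counts: Iterable[BranchCounts],
    config: AnalysisConfig = AnalysisConfig(),
    high_dn_threshold: float = 10.0,
    topology_ok: Mapping[str, bool] | None = None,
) -> list[FamilyQC]:
    """Apply the family-level quality filters.

    * ``short_protein`` (excluding): some ungapped protein is not longer
      than ``config.min_protein_len`` amino acids.
    * ``dnds_gt_max`` (excluding): omega exceeds ``config.max_dnds`` on the
      human, chimp or hominoid-ancestor branch; an undefined omega with
      ``Dn > 0`` (no synonymous substitutions) counts as exceeding, while
      ``Dn == 0`` with ``Ds == 0`` passes.
    * ``high_dn_flag`` (non-excluding): human-branch Dn above
      ``high_dn_threshold``, the trigger for a misalignment check.
    * ``topology_fail`` (non-excluding): recorded when ``topology_ok`` marks
      the gene False.
    """
    fam_map: dict[str, GeneFamily]
    if isinstance(families, Mapping):
        fam_map = dict(families)
    else:
        fam_map = {f.gene_id: f for f in families}
    by_gene: dict[str, dict[str, BranchCounts]] = {}
    for bc in counts:
        by_gene.setdefault(bc.gene_id, {})[bc.branch] = bc

    out = []
    for gene_id in sorted(set(fam_map) | set(by_gene)):
        reasons: list[str] = []
        fam = fam_map.get(gene_id)
        if fam is not None and any(
            fam.protein_length(sp) <= config.min_protein_len for sp in fam.sequences
        ):
            reasons.append("short_protein")
        branches = by_gene.get(gene_id, {})
        for br in FILTERED_BRANCHES:
            bc = branches.get(br)
            if bc is None:
                continue
            omega = bc.omega
            if omega is None:
                if bc.Ds == 0:
                    # undefined ratio: an excess with no synonymous signal is
                    # treated as exceeding the cap; 0/0 passes
                    if bc.Dn > 0:
                        reasons.append("dnds_gt_max")
                        break
                    continue
                # site counts unavailable: use the raw count ratio as proxy
                omega = bc.Dn / bc.Ds
            if omega > config.max_dnds:
                reasons.append("dnds_gt_max")
                break
        human = branches.get("human")
        if human is not None and human.Dn > high_dn_threshold:
            reasons.append("high_dn_flag")
        if topology_ok is not None and topology_ok.get(gene_id) is False:
            reasons.append("topology_fail")
        passed = not ({"short_protein", "dnds_gt_max"} & set(reasons))
        out.append(FamilyQC(gene_id=gene_id, passed=passed, reasons=reasons))
    return out
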