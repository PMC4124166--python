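"""Genetic-code utilities and Nei-Gojobori (NG86) site/pathway counting.

The NG86 machinery provides the synonymous/non-synonymous decomposition used
throughout the package: fractional site counts per codon (how many of the
three positions are "synonymous opportunity") and pathway-averaged change
counts between two codons that differ at one or more positions.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations
from typing import NamedTuple

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"

#: amino acid (one letter) per sense codon of the standard code
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TABLE))

TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}

GAP_CODON = "---"


def is_sense(codon: str) -> bool:
    return codon in CODON_TABLE


def is_transition(a: str, b: str) -> bool:
    """True when a->b is a purine<->purine or pyrimidine<->pyrimidine change."""
    return TRANSITIONS.get(a) == b


def translate(codon: str) -> str:
    """Amino acid of a sense codon; raises for stop/ambiguous codons."""
    try:
        return CODON_TABLE[codon]
    except KeyError:
        raise ValueError(f"not a sense codon: {codon!r}") from None


class SiteCounts(NamedTuple):
    n_sites: float
    s_sites: float


class PathCounts(NamedTuple):
    nonsyn: float
    syn: float
    stop_free: bool


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> SiteCounts:
    """Fractional non-synonymous and synonymous site counts of a sense codon.

    Each codon position contributes ``(# synonymous single-nucleotide
    mutants)/3`` to the synonymous total and the remainder to the
    non-synonymous total, so ``n + s == 3`` for every sense codon.  Mutants
    that create a stop codon count on the non-synonymous side.
    """
    aa = translate(codon)
    s = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if CODON_TABLE.get(mutant) == aa:
                s += 1.0 / 3.0
    return SiteCounts(3.0 - s, s)


def _step_is_syn(a: str, b: str) -> bool:
    """Classify a single-nucleotide codon step; stop involvement -> nonsyn."""
    if a in STOP_CODONS or b in STOP_CODONS:
        return False
    return CODON_TABLE[a] == CODON_TABLE[b]


@lru_cache(maxsize=None)
def ng86_path_counts(codon_a: str, codon_b: str) -> PathCounts:
    """Pathway-averaged (non-synonymous, synonymous) changes between codons.

    All minimal mutational pathways (orders of the differing positions) that
    avoid intermediate stop codons are enumerated and the per-step syn/nonsyn
    decomposition is averaged over them.  If every minimal pathway passes
    through a stop codon, all pathways are used instead and ``stop_free`` is
    False.  The two counts always sum to the Hamming distance of the codons.
    """
    if not is_sense(codon_a) or not is_sense(codon_b):
        raise ValueError(f"path counting requires sense codons: {codon_a!r}, {codon_b!r}")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return PathCounts(0.0, 0.0, True)

    paths: list[tuple[float, float]] = []
    stop_free_paths: list[tuple[float, float]] = []
    for order in permutations(diff):
        cur = codon_a
        n = s = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon_b:
                through_stop = True
            if _step_is_syn(cur, nxt):
                s += 1.0
            else:
                n += 1.0
            cur = nxt
        paths.append((n, s))
        if not through_stop:
            stop_free_paths.append((n, s))

    use = stop_free_paths if stop_free_paths else paths
    n_mean = sum(p[0] for p in use) / len(use)
    s_mean = sum(p[1] for p in use) / len(use)
    return PathCounts(n_mean, s_mean, bool(stop_free_paths))
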