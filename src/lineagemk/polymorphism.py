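"""Coding-SNP classification and derived-allele-frequency stratification.

Segregating slightly deleterious amino-acid variants concentrate at low
derived allele frequency (DAF) and inflate Pn relative to the neutral
expectation, biasing MK-type statistics downwards.  Restricting the
polymorphism side of the MK table to SNPs above increasing DAF thresholds
progressively removes that bias, which is the central filtering device of
this package.

Strata come in two families: nested threshold sets (DAF >= t, closed below)
and a half-open interval partition ([lo, hi)).  A derived allele frequency
of exactly 1.0 is not a polymorphism and is excluded everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .codons import CODON_TABLE, STOP_CODONS
from .core_io import AnalysisConfig, RejectionLog, logger

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
OTHER = "other"


@dataclass(frozen=True)
class SNPRecord:
    """One coding polymorphism.

    ``cds_pos`` is 0-based within the coding sequence.  ``daf`` is defined
    only when the ancestral allele matches ref or alt; ``maf`` is always
    defined.  ``func_class`` is filled by :func:`classify_coding_snp`.
    """

    gene_id: str
    cds_pos: int
    ref: str
    alt: str
    ancestral: str | None
    alt_freq: float
    func_class: str | None = None

    @property
    def maf(self) -> float:
        return min(self.alt_freq, 1.0 - self.alt_freq)

    @property
    def daf(self) -> float | None:
        if self.ancestral == self.ref:
            return self.alt_freq
        if self.ancestral == self.alt:
            return 1.0 - self.alt_freq
        return None

    @property
    def daf_undefined(self) -> bool:
        return self.daf is None


@dataclass(frozen=True)
class GenePolymorphism:
    """Pn/Ps totals for one gene in one frequency stratum."""

    gene_id: str
    stratum: str
    Pn: int
    Ps: int


def threshold_label(t: float) -> str:
    return f"ge_{t:g}"

def interval_label(lo: float, hi: float) -> str:
    return f"int_{lo:g}_{hi:g}"


def classify_coding_snp(cds: str, snp: SNPRecord) -> str:
    """Synonymous/non-synonymous/other call for a SNP against its CDS.

    ``other`` covers changes that create or destroy a stop codon; these are
    excluded from Pn/Ps because the MK framework concerns amino-acid
    replacements.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"gene {snp.gene_id}: CDS length not a multiple of 3")
    if snp.cds_pos >= len(cds):
        raise ValueError(
            f"gene {snp.gene_id}: SNP position {snp.cds_pos} beyond CDS"
        )
    codon_i, within = divmod(snp.cds_pos, 3)
    codon = cds[3 * codon_i : 3 * codon_i + 3].upper()
    if codon[within] != snp.ref:
        raise ValueError(
            f"gene {snp.gene_id} position {snp.cds_pos}: reference allele "
            f"{snp.ref} does not match CDS base {codon[within]}"
        )
    alt_codon = codon[:within] + snp.alt + codon[within + 1 :]
    if codon in STOP_CODONS or alt_codon in STOP_CODONS:
        return OTHER
    if CODON_TABLE[codon] == CODON_TABLE[alt_codon]:
        return SYNONYMOUS
    return NONSYNONYMOUS


def classify_snps(
    snps: Iterable[SNPRecord], cds_by_gene: dict[str, str]
) -> list[SNPRecord]:
    """Return copies of the records with ``func_class`` filled in."""
    return [
        replace(s, func_class=classify_coding_snp(cds_by_gene[s.gene_id], s))
        for s in snps
    ]


def _frequency(snp: SNPRecord, mode: str) -> float | None:
    if mode == "MAF":
        return snp.maf
    return snp.daf


def stratify_by_frequency(
    snps: Iterable[SNPRecord],
    config: AnalysisConfig = AnalysisConfig(),
    log: RejectionLog | None = None,
) -> list[GenePolymorphism]:
    """Per-gene Pn/Ps counts for every threshold and interval stratum.

    In DAF mode records lacking a resolvable ancestral allele are excluded
    (and tallied in ``log``); in MAF mode they are retained.  SNPs of class
    ``other`` never count; unclassified records raise.  A frequency of
    exactly 1.0 (fixed in the sample) is excluded from all strata.
    """
    log = log if log is not None else RejectionLog()
    strata = [threshold_label(t) for t in config.daf_thresholds] + [
        interval_label(lo, hi) for lo, hi in config.daf_intervals
    ]
    counts: dict[str, dict[str, list[int]]] = {}
    genes_seen: set[str] = set()
    for snp in snps:
        genes_seen.add(snp.gene_id)
        if snp.func_class is None:
            raise ValueError(
                f"gene {snp.gene_id}: SNP at {snp.cds_pos} has no functional class"
            )
        if snp.func_class == OTHER:
            continue
        freq = _frequency(snp, config.frequency_mode)
        if freq is None:
            log.record("daf_undefined", f"{snp.gene_id}:{snp.cds_pos + 1}")
            continue
        if freq >= 1.0:
            log.record("fixed_allele", f"{snp.gene_id}:{snp.cds_pos + 1}")
            continue
        gene = counts.setdefault(snp.gene_id, {s: [0, 0] for s in strata})
        slot = 0 if snp.func_class == NONSYNONYMOUS else 1
        for t in config.daf_thresholds:
            if freq >= t:
                gene[threshold_label(t)][slot] += 1
        for lo, hi in config.daf_intervals:
            if lo <= freq < hi:
                gene[interval_label(lo, hi)][slot] += 1
    out = []
    for gene_id in sorted(genes_seen):
        gene = counts.get(gene_id, {s: [0, 0] for s in strata})
        for s in strata:
            pn, ps = gene[s]
            out.append(GenePolymorphism(gene_id=gene_id, stratum=s, Pn=pn, Ps=ps))
    return out


def polymorphism_matrix(records: Iterable[GenePolymorphism]) -> pd.DataFrame:
    """Long-format gene x stratum Pn/Ps table."""
    return pd.DataFrame(
        [
            {"gene_id": r.gene_id, "stratum": r.stratum, "Pn": r.Pn, "Ps": r.Ps}
            for r in records
        ]
    )


def polymorphic_gene_subset(
    gene_polys: Iterable[GenePolymorphism], stratum: str
) -> set[str]:
    """Genes with at least one polymorphic site (Pn + Ps >= 1) in a stratum."""
    return {
        r.gene_id for r in gene_polys if r.stratum == stratum and r.Pn + r.Ps >= 1
    }
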