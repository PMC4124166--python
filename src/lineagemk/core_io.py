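"""Input/output for codon alignments, count tables and SNP tables.

The package analyses one-to-one ortholog families from four species
(human, chimpanzee, macaque, mouse) given as in-frame codon alignments,
per-branch substitution count tables (either produced by
:mod:`lineagemk.divergence` or imported from an external maximum-likelihood
run), and coding-SNP tables with derived-allele information.

Coordinate convention: CDS positions are 0-based half-open in memory and
1-based in every file read or written (VCF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .codons import GAP_CODON, STOP_CODONS

logger = logging.getLogger("lineagemk")

#: species labels, fixed order (tree ((human,chimp),macaque,mouse))
SPECIES: tuple[str, ...] = ("human", "chimp", "macaque", "mouse")

#: the five edges of the unrooted quartet, plus labels accepted on import
BRANCHES: tuple[str, ...] = ("human", "chimp", "hominoid_ancestor", "macaque", "mouse")
_BRANCH_ALIASES = {"mouse_side": "mouse"}
ACCEPTED_BRANCHES = frozenset(BRANCHES) | frozenset(_BRANCH_ALIASES) | {"ancestral_other"}


class FrameError(ValueError):
    """A sequence record whose length is not a multiple of three."""


@dataclass
class RejectionLog:
    """Structured record of every rejected gene/row, one entry per rejection."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def record(self, code: str, item: str, detail: str = "") -> None:
        self.entries.append((code, item, detail))
        logger.warning("rejected %s [%s] %s", item, code, detail)

    def tally(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for code, _, _ in self.entries:
            out[code] = out.get(code, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["reason", "item", "detail"])


@dataclass(frozen=True)
class GeneFamily:
    """A four-species in-frame codon alignment for one gene.

    ``sequences`` maps species label to the aligned coding sequence; gaps are
    whole codons (``---``) and all sequences have equal length divisible by 3.
    """

    gene_id: str
    sequences: Mapping[str, str]

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.sequences.values()))) // 3

    def codon_column(self, i: int) -> tuple[str, ...]:
        return tuple(self.sequences[sp][3 * i : 3 * i + 3] for sp in SPECIES)

    def codon_columns(self) -> Iterator[tuple[str, ...]]:
        for i in range(self.n_codons):
            yield self.codon_column(i)

    def gap_free_column_indices(self) -> list[int]:
        return [
            i for i in range(self.n_codons) if GAP_CODON not in self.codon_column(i)
        ]

    def gap_column_indices(self) -> list[int]:
        gapfree = set(self.gap_free_column_indices())
        return [i for i in range(self.n_codons) if i not in gapfree]

    def protein_length(self, species: str) -> int:
        """Number of non-gap codons in one species' row."""
        seq = self.sequences[species]
        return sum(
            1 for i in range(len(seq) // 3) if seq[3 * i : 3 * i + 3] != GAP_CODON
        )


@dataclass(frozen=True)
class AnalysisConfig:
    """Run-wide thresholds and switches.

    Defaults reproduce the study conditions: DAF thresholds 1/15/30/60%,
    the four half-open DAF interval classes, a >100-aa protein-length filter,
    a dN/dS <= 10 sanity cap and a 0.05 significance level.
    """

    daf_thresholds: tuple[float, ...] = (0.01, 0.15, 0.30, 0.60)
    daf_intervals: tuple[tuple[float, float], ...] = (
        (0.01, 0.15),
        (0.15, 0.30),
        (0.30, 0.60),
        (0.60, 1.00),
    )
    min_protein_len: int = 100
    max_dnds: float = 10.0
    significance_level: float = 0.05
    random_seed: int = 0
    frequency_mode: str = "DAF"

    def __post_init__(self) -> None:
        if self.frequency_mode not in ("DAF", "MAF"):
            raise ValueError("frequency_mode must be 'DAF' or 'MAF'")
        if list(self.daf_thresholds) != sorted(set(self.daf_thresholds)):
            raise ValueError("daf_thresholds must be strictly increasing")
        if any(not 0 < t <= 1 for t in self.daf_thresholds):
            raise ValueError("daf_thresholds must lie in (0, 1]")
        prev_hi = 0.0
        for lo, hi in self.daf_intervals:
            if not (0 <= lo < hi <= 1) or lo < prev_hi:
                raise ValueError("daf_intervals must be ordered and non-overlapping")
            prev_hi = hi


def _validate_family(
    gene_id: str, seqs: dict[str, str], log: RejectionLog
) -> GeneFamily | None:
    missing = [sp for sp in SPECIES if sp not in seqs]
    if missing:
        log.record("missing_species", gene_id, ",".join(missing))
        return None
    lengths = {len(s) for s in seqs.values()}
    for sp, s in seqs.items():
        if len(s) % 3 != 0:
            raise FrameError(
                f"record {gene_id}|{sp}: length {len(s)} is not a multiple of 3"
            )
    if len(lengths) != 1:
        log.record("unequal_lengths", gene_id, str(sorted(lengths)))
        return None
    n_codons = lengths.pop() // 3
    seqs = {sp: s.upper() for sp, s in seqs.items()}
    # whole-codon gap convention: any partially gapped codon indicates a
    # frame problem in the back-translated alignment
    for sp, s in seqs.items():
        for i in range(n_codons):
            codon = s[3 * i : 3 * i + 3]
            if "-" in codon and codon != GAP_CODON:
                log.record("partial_codon_gap", gene_id, f"{sp} codon {i}")
                return None
    # drop a terminal stop column if present, then reject internal stops
    last = n_codons - 1
    if last >= 0 and any(
        seqs[sp][3 * last : 3 * last + 3] in STOP_CODONS for sp in SPECIES
    ):
        seqs = {sp: s[: 3 * last] for sp, s in seqs.items()}
        n_codons = last
    fam = GeneFamily(gene_id=gene_id, sequences=seqs)
    for i in fam.gap_free_column_indices():
        if any(c in STOP_CODONS for c in fam.codon_column(i)):
            log.record("internal_stop", gene_id, f"codon column {i}")
            return None
    return fam


def read_codon_alignments(
    path: str | Path,
    family_manifest: pd.DataFrame | None = None,
    log: RejectionLog | None = None,
) -> list[GeneFamily]:
    """Read gene families from a multi-FASTA of codon alignments.

    Record ids are ``<gene_id>|<species>`` unless ``family_manifest`` (columns
    ``record_id, gene_id, species``) maps them.  Families violating the
    alignment invariants are skipped and logged; a sequence whose length is
    not a multiple of three raises :class:`FrameError`.
    """
    log = log if log is not None else RejectionLog()
    mapping = None
    if family_manifest is not None:
        mapping = {
            str(r.record_id): (str(r.gene_id), str(r.species))
            for r in family_manifest.itertuples()
        }
    by_gene: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if mapping is not None:
            if rec.id not in mapping:
                log.record("unmapped_record", rec.id)
                continue
            gene_id, species = mapping[rec.id]
        else:
            gene_id, _, species = rec.id.partition("|")
        if species not in SPECIES:
            log.record("unknown_species", rec.id, species)
            continue
        by_gene.setdefault(gene_id, {})[species] = str(rec.seq)
    families = []
    for gene_id in by_gene:
        fam = _validate_family(gene_id, by_gene[gene_id], log)
        if fam is not None:
            families.append(fam)
    return families


def write_codon_alignments(families: Iterable[GeneFamily], path: str | Path) -> None:
    with open(path, "w") as fh:
        for fam in families:
            for sp in SPECIES:
                fh.write(f">{fam.gene_id}|{sp}\n{fam.sequences[sp]}\n")


# ---------------------------------------------------------------- count tables


def read_count_table(path: str | Path, log: RejectionLog | None = None) -> list:
    """Read a per-gene per-branch substitution count table (TSV).

    Required columns: ``gene_id, branch, Dn, Ds``; optional ``N, S`` (``.``
    for absent).  Rows with negative counts or unknown branch labels are
    rejected and logged.  This is also the import path for externally
    computed (e.g. codon-model maximum-likelihood) branch counts.
    """
    from .divergence import BranchCounts

    log = log if log is not None else RejectionLog()
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    if df.empty:
        logger.warning("empty count table: %s", path)
        return []
    out = []
    for row in df.itertuples(index=False):
        branch = str(row.branch)
        branch = _BRANCH_ALIASES.get(branch, branch)
        if branch not in ACCEPTED_BRANCHES:
            log.record("unknown_branch", str(row.gene_id), branch)
            continue

        def _num(value, default=None):
            if value is None or (isinstance(value, str) and value.strip() == "."):
                return default
            v = float(value)
            if pd.isna(v):
                return default
            return v

        dn, ds = _num(row.Dn), _num(row.Ds)
        n = _num(getattr(row, "N", "."))
        s = _num(getattr(row, "S", "."))
        if dn is None or ds is None or dn < 0 or ds < 0:
            log.record("negative_or_missing_count", str(row.gene_id), branch)
            continue
        if (n is not None and n < 0) or (s is not None and s < 0):
            log.record("negative_site_count", str(row.gene_id), branch)
            continue
        out.append(
            BranchCounts(gene_id=str(row.gene_id), branch=branch, Dn=dn, Ds=ds, N=n, S=s)
        )
    return out


def write_count_table(counts: Iterable, path: str | Path) -> None:
    rows = []
    for c in counts:
        rows.append(
            {
                "gene_id": c.gene_id,
                "branch": c.branch,
                "Dn": c.Dn,
                "Ds": c.Ds,
                "N": "." if c.N is None else c.N,
                "S": "." if c.S is None else c.S,
                "dN": "." if c.dN is None else c.dN,
                "dS": "." if c.dS is None else c.dS,
                "omega": "." if c.omega is None else c.omega,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ SNP tables


def read_snp_table(path: str | Path, log: RejectionLog | None = None) -> list:
    """Read coding SNPs from a TSV with 1-based CDS positions.

    Columns: ``gene_id, cds_pos, ref, alt, ancestral, alt_freq`` (``.`` for a
    missing ancestral allele).  Positions are converted to the internal
    0-based convention; rows with ``alt_freq`` outside [0, 1] or ``ref ==
    alt`` are rejected and logged.
    """
    from .polymorphism import SNPRecord

    log = log if log is not None else RejectionLog()
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"gene_id": str, "ref": str, "alt": str}
    )
    return _snp_rows_to_records(df.itertuples(index=False), log, SNPRecord)


def _snp_rows_to_records(rows, log: RejectionLog, SNPRecord) -> list:
    out = []
    for row in rows:
        gene = str(row.gene_id)
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        anc = str(getattr(row, "ancestral", ".")).upper()
        freq = float(row.alt_freq)
        pos1 = int(row.cds_pos)
        label = f"{gene}:{pos1}"
        if not 0.0 <= freq <= 1.0:
            log.record("freq_out_of_range", label, f"{freq}")
            continue
        if ref == alt:
            log.record("ref_equals_alt", label, ref)
            continue
        if pos1 < 1:
            log.record("bad_position", label)
            continue
        func = str(getattr(row, "func_class", ".")).strip()
        out.append(
            SNPRecord(
                gene_id=gene,
                cds_pos=pos1 - 1,
                ref=ref,
                alt=alt,
                ancestral=None if anc in (".", "", "NAN", "N") else anc,
                alt_freq=freq,
                func_class=None if func in (".", "", "nan", "None") else func,
            )
        )
    return out


def read_snp_vcf(path: str | Path, log: RejectionLog | None = None) -> list:
    """Minimal VCF reader: CHROM = gene id, POS = 1-based CDS position,
    INFO keys ``AA`` (ancestral allele) and ``AF`` (alternate frequency).

    Multi-allelic records become one SNP per alternate allele.
    """
    from .polymorphism import SNPRecord

    log = log if log is not None else RejectionLog()
    rows = []

    class _Row:
        __slots__ = ("gene_id", "cds_pos", "ref", "alt", "ancestral", "alt_freq")

        def __init__(self, **kw):
            for k, v in kw.items():
                setattr(self, k, v)

    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos, _id, ref, alts, _qual, _filt = f[:7]
            info = f[7] if len(f) > 7 else ""
            kv = dict(
                item.split("=", 1) for item in info.split(";") if "=" in item
            )
            aa = kv.get("AA", ".")
            afs = kv.get("AF", "").split(",")
            alt_list = alts.split(",")
            for i, alt in enumerate(alt_list):
                af = afs[i] if i < len(afs) and afs[i] != "" else None
                if af is None:
                    log.record("missing_AF", f"{chrom}:{pos}")
                    continue
                rows.append(
                    _Row(
                        gene_id=chrom,
                        cds_pos=pos,
                        ref=ref,
                        alt=alt,
                        ancestral=aa,
                        alt_freq=af,
                    )
                )
    for r in rows:
        r.alt_freq = float(r.alt_freq)
        r.cds_pos = int(r.cds_pos)
    return _snp_rows_to_records(rows, log, SNPRecord)


def write_snp_table(snps: Iterable, path: str | Path) -> None:
    rows = [
        {
            "gene_id": s.gene_id,
            "cds_pos": s.cds_pos + 1,
            "ref": s.ref,
            "alt": s.alt,
            "ancestral": "." if s.ancestral is None else s.ancestral,
            "alt_freq": s.alt_freq,
            "func_class": "." if s.func_class is None else s.func_class,
        }
        for s in snps
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
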