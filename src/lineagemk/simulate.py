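"""Synthetic codon families and coding polymorphism with known ground truth.

The generator emulates the statistical structure the analysis consumes:

* divergence — codon sequences evolved on the fixed quartet
  ((human, chimp), macaque, mouse) with per-branch mutation rates
  (expected mutations per nucleotide site) and per-branch omega acting as an
  acceptance probability on non-synonymous changes; adaptive substitutions
  are injected on the human branch as forced non-synonymous changes;
* polymorphism — per-gene SNP records drawn directly with class-specific
  derived-allele-frequency distributions: synonymous and neutral
  non-synonymous SNPs share one Beta DAF law, slightly deleterious
  non-synonymous SNPs a second Beta concentrated at low frequency.

Mutations pick a uniform nucleotide site and a kappa-weighted alternative
base, redrawing entirely on stop-creating changes; the SNP generator
computes its synonymous/non-synonymous opportunity from the same weighting,
so under neutrality the expected Pn/Ps ratio equals the expected
non-adaptive Dn/Ds ratio and the pooled MK statistics are centred on their
true values.  Every realized substitution and every SNP class label is
recorded in :class:`SimTruth`, the oracle for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .codons import (
    BASES,
    CODON_TABLE,
    SENSE_CODONS,
    STOP_CODONS,
    is_transition,
)
from .core_io import (
    BRANCHES,
    SPECIES,
    GeneFamily,
    write_codon_alignments,
    write_count_table,
    write_snp_table,
)
from .divergence import BranchCounts
from .polymorphism import NONSYNONYMOUS, SYNONYMOUS, SNPRecord

#: guide-tree branch lengths (expected substitutions per nucleotide site)
DEFAULT_BRANCH_LENGTHS: Mapping[str, float] = {
    "human": 0.01,
    "chimp": 0.01,
    "hominoid_ancestor": 0.03,
    "macaque": 0.04,
    "mouse": 0.32,
}


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults give the study-scale preset.

    ``frac_substitutions_adaptive`` is the target fraction of human-branch
    non-synonymous substitutions that are adaptive (injected as forced
    non-synonymous changes on top of the omega-thinned background).
    ``frac_nonsyn_deleterious`` is the fraction of non-synonymous SNPs drawn
    from the low-frequency (slightly deleterious) DAF law; it and
    ``frac_nonsyn_neutral`` must sum to one.  ``theta_syn`` is the expected
    number of synonymous SNPs per gene.
    """

    n_genes: int = 500
    codons_per_gene: int = 400
    branch_lengths: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BRANCH_LENGTHS)
    )
    branch_omega: Mapping[str, float] = field(
        default_factory=lambda: {br: 0.25 for br in BRANCHES}
    )
    kappa: float = 2.0
    theta_syn: float = 2.0
    frac_nonsyn_neutral: float = 0.7
    frac_nonsyn_deleterious: float = 0.3
    frac_substitutions_adaptive: float = 0.0
    daf_neutral: tuple[float, float] = (0.5, 0.7)
    daf_deleterious: tuple[float, float] = (0.5, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.frac_nonsyn_neutral + self.frac_nonsyn_deleterious - 1.0) > 1e-9:
            raise ValueError("nonsyn SNP class fractions must sum to 1")
        if not 0.0 <= self.frac_substitutions_adaptive < 1.0:
            raise ValueError("frac_substitutions_adaptive must lie in [0, 1)")
        for br in BRANCHES:
            if self.branch_lengths.get(br, 0.0) < 0:
                raise ValueError(f"negative branch length for {br}")
        if any(w < 0 for w in self.branch_omega.values()):
            raise ValueError("branch omegas must be non-negative")


@dataclass
class GeneTruth:
    """Realized per-branch substitution counts and SNP classes for one gene."""

    gene_id: str
    branch_dn: dict[str, int]
    branch_ds: dict[str, int]
    n_adaptive: int
    snp_classes: list[tuple[int, str, str]] = field(default_factory=list)
    # (cds_pos, functional class, selection class)


@dataclass
class SimTruth:
    genes: list[GeneTruth] = field(default_factory=list)

    def true_alpha(self) -> float | None:
        """Adaptive fraction of realized human-branch non-synonymous changes."""
        dn = sum(g.branch_dn["human"] for g in self.genes)
        if dn == 0:
            return None
        return sum(g.n_adaptive for g in self.genes) / dn

    def branch_counts(self) -> list[BranchCounts]:
        out = []
        for g in self.genes:
            for br in BRANCHES:
                out.append(
                    BranchCounts(
                        gene_id=g.gene_id,
                        branch=br,
                        Dn=g.branch_dn[br],
                        Ds=g.branch_ds[br],
                    )
                )
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            for br in BRANCHES:
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "branch": br,
                        "Dn": g.branch_dn[br],
                        "Ds": g.branch_ds[br],
                        "n_adaptive": g.n_adaptive if br == "human" else 0,
                    }
                )
        return pd.DataFrame(rows)


def _base_weights(kappa: float, ref: str) -> tuple[list[str], np.ndarray]:
    alts = [b for b in BASES if b != ref]
    w = np.array([kappa if is_transition(ref, b) else 1.0 for b in alts])
    return alts, w / w.sum()


def _mutate_once(
    codons: list[str], rng: np.random.Generator, kappa: float
) -> tuple[int, str, bool]:
    """Draw one non-stop candidate mutation: (codon index, new codon, is_syn).

    The site is uniform over nucleotides and the base kappa-weighted;
    stop-creating draws are redrawn entirely, so the realized candidate law
    is the kappa-weighted distribution over all non-stop single-nucleotide
    changes of the current sequence.
    """
    n_nt = 3 * len(codons)
    while True:
        site = int(rng.integers(n_nt))
        ci, within = divmod(site, 3)
        codon = codons[ci]
        alts, probs = _base_weights(kappa, codon[within])
        alt = alts[int(rng.choice(3, p=probs))]
        new_codon = codon[:within] + alt + codon[within + 1 :]
        if new_codon in STOP_CODONS:
            continue
        return ci, new_codon, CODON_TABLE[codon] == CODON_TABLE[new_codon]


def _evolve_branch(
    codons: list[str],
    branch_len: float,
    omega: float,
    rng: np.random.Generator,
    kappa: float,
) -> tuple[list[str], int, int]:
    """Evolve a codon sequence along one branch; returns (seq, Dn, Ds)."""
    codons = list(codons)
    dn = ds = 0
    n_events = int(rng.poisson(branch_len * 3 * len(codons)))
    for _ in range(n_events):
        ci, new_codon, is_syn = _mutate_once(codons, rng, kappa)
        if is_syn:
            codons[ci] = new_codon
            ds += 1
        elif rng.random() < min(1.0, omega):
            codons[ci] = new_codon
            dn += 1
    return codons, dn, ds


def _inject_adaptive(
    codons: list[str],
    n_regular_nonsyn: int,
    frac_adaptive: float,
    rng: np.random.Generator,
    kappa: float,
) -> tuple[list[str], int]:
    """Force adaptive non-synonymous changes onto the human sequence.

    The number injected is Poisson with mean ``Dn_regular * f/(1-f)`` so the
    adaptive fraction of all human-branch non-synonymous substitutions is
    centred on ``f``.
    """
    if frac_adaptive <= 0.0 or n_regular_nonsyn == 0:
        return codons, 0
    lam = n_regular_nonsyn * frac_adaptive / (1.0 - frac_adaptive)
    n_adaptive = int(rng.poisson(lam))
    codons = list(codons)
    for _ in range(n_adaptive):
        while True:
            ci, new_codon, is_syn = _mutate_once(codons, rng, kappa)
            if not is_syn:
                codons[ci] = new_codon
                break
    return codons, n_adaptive


def simulate_codon_evolution(
    config: SimConfig, gene_index: int
) -> tuple[GeneFamily, GeneTruth]:
    """Evolve one gene family on the fixed quartet with full bookkeeping."""
    rng = np.random.default_rng((config.seed, gene_index))
    gene_id = f"g{gene_index:05d}"
    root = [
        SENSE_CODONS[i]
        for i in rng.integers(len(SENSE_CODONS), size=config.codons_per_gene)
    ]
    bl, om = config.branch_lengths, config.branch_omega
    dn: dict[str, int] = {}
    ds: dict[str, int] = {}
    hc, dn["hominoid_ancestor"], ds["hominoid_ancestor"] = _evolve_branch(
        root, bl["hominoid_ancestor"], om["hominoid_ancestor"], rng, config.kappa
    )
    human, dn["human"], ds["human"] = _evolve_branch(
        hc, bl["human"], om["human"], rng, config.kappa
    )
    human, n_adaptive = _inject_adaptive(
        human, dn["human"], config.frac_substitutions_adaptive, rng, config.kappa
    )
    dn["human"] += n_adaptive
    chimp, dn["chimp"], ds["chimp"] = _evolve_branch(
        hc, bl["chimp"], om["chimp"], rng, config.kappa
    )
    macaque, dn["macaque"], ds["macaque"] = _evolve_branch(
        root, bl["macaque"], om["macaque"], rng, config.kappa
    )
    mouse, dn["mouse"], ds["mouse"] = _evolve_branch(
        root, bl["mouse"], om["mouse"], rng, config.kappa
    )
    family = GeneFamily(
        gene_id=gene_id,
        sequences={
            "human": "".join(human),
            "chimp": "".join(chimp),
            "macaque": "".join(macaque),
            "mouse": "".join(mouse),
        },
    )
    truth = GeneTruth(gene_id=gene_id, branch_dn=dn, branch_ds=ds, n_adaptive=n_adaptive)
    return family, truth


def _snp_candidates(cds: str, kappa: float):
    """Kappa-weighted non-stop single-nucleotide candidates of a CDS.

    Returns (positions, alt bases, weights, is_synonymous) arrays covering
    every site of every codon; the aggregate synonymous / non-synonymous
    weight ratio is exactly the opportunity ratio of the mutation process
    used for divergence.
    """
    pos_l: list[int] = []
    alt_l: list[str] = []
    w_l: list[float] = []
    syn_l: list[bool] = []
    for ci in range(len(cds) // 3):
        codon = cds[3 * ci : 3 * ci + 3]
        for within in range(3):
            ref = codon[within]
            for b in BASES:
                if b == ref:
                    continue
                new_codon = codon[:within] + b + codon[within + 1 :]
                if new_codon in STOP_CODONS:
                    continue
                pos_l.append(3 * ci + within)
                alt_l.append(b)
                w_l.append(kappa if is_transition(ref, b) else 1.0)
                syn_l.append(CODON_TABLE[codon] == CODON_TABLE[new_codon])
    return (
        np.array(pos_l),
        np.array(alt_l),
        np.array(w_l),
        np.array(syn_l, dtype=bool),
    )


def simulate_polymorphism(
    config: SimConfig, gene_index: int, human_cds: str
) -> tuple[list[SNPRecord], list[tuple[int, str, str]]]:
    """Draw coding SNPs for one gene on its (evolved) human CDS.

    Synonymous SNP counts are Poisson(``theta_syn``); neutral non-synonymous
    SNPs arrive at rate ``theta_syn * (w_n/w_s) * omega_human`` — the same
    opportunity-times-constraint law as the divergence process — and the
    slightly deleterious class tops the non-synonymous count up to its
    configured share.  The ancestral allele is the reference base, so DAF is
    exactly recoverable from each record.
    """
    rng = np.random.default_rng((config.seed, gene_index, 104729))
    pos, alt, w, syn = _snp_candidates(human_cds, config.kappa)
    w_s = float(w[syn].sum())
    w_n = float(w[~syn].sum())
    omega_h = config.branch_omega["human"]
    lam_syn = config.theta_syn
    lam_nn = config.theta_syn * (w_n / w_s) * omega_h if w_s > 0 else 0.0
    f_del = config.frac_nonsyn_deleterious
    lam_nd = lam_nn * f_del / (1.0 - f_del) if f_del < 1.0 else 0.0

    records: list[SNPRecord] = []
    truth: list[tuple[int, str, str]] = []

    def _draw(n: int, mask: np.ndarray, func_class: str, sel_class: str, beta) -> None:
        if n == 0 or not mask.any():
            return
        probs = w[mask] / w[mask].sum()
        idx = rng.choice(mask.sum(), size=n, p=probs)
        cand_pos = pos[mask][idx]
        cand_alt = alt[mask][idx]
        dafs = rng.beta(beta[0], beta[1], size=n)
        for p_i, a_i, daf in zip(cand_pos, cand_alt, dafs):
            p_i = int(p_i)
            records.append(
                SNPRecord(
                    gene_id=f"g{gene_index:05d}",
                    cds_pos=p_i,
                    ref=human_cds[p_i],
                    alt=str(a_i),
                    ancestral=human_cds[p_i],
                    alt_freq=float(daf),
                    func_class=func_class,
                )
            )
            truth.append((p_i, func_class, sel_class))

    _draw(int(rng.poisson(lam_syn)), syn, SYNONYMOUS, "neutral", config.daf_neutral)
    _draw(
        int(rng.poisson(lam_nn)), ~syn, NONSYNONYMOUS, "neutral", config.daf_neutral
    )
    _draw(
        int(rng.poisson(lam_nd)),
        ~syn,
        NONSYNONYMOUS,
        "deleterious",
        config.daf_deleterious,
    )
    return records, truth


def simulate_gene(
    config: SimConfig, gene_index: int
) -> tuple[GeneFamily, list[SNPRecord], GeneTruth]:
    family, truth = simulate_codon_evolution(config, gene_index)
    snps, snp_truth = simulate_polymorphism(
        config, gene_index, family.sequences["human"]
    )
    truth.snp_classes = snp_truth
    return family, snps, truth


def simulate_dataset(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[list[GeneFamily], list[SNPRecord], SimTruth]:
    """Generate a full dataset; optionally write all pipeline input files.

    When ``out_dir`` is given, writes ``alignments.fasta``, ``snps.tsv``,
    ``truth_counts.tsv`` (the true per-branch counts in count-table format),
    ``truth_genes.tsv`` and a ``manifest.txt`` recording the configuration.
    Reruns with the same configuration are byte-identical.
    """
    families: list[GeneFamily] = []
    all_snps: list[SNPRecord] = []
    truth = SimTruth()
    for i in range(config.n_genes):
        fam, snps, gt = simulate_gene(config, i)
        families.append(fam)
        all_snps.extend(snps)
        truth.genes.append(gt)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_codon_alignments(families, out / "alignments.fasta")
        write_snp_table(all_snps, out / "snps.tsv")
        write_count_table(truth.branch_counts(), out / "truth_counts.tsv")
        truth.to_frame().to_csv(out / "truth_genes.tsv", sep="\t", index=False)
        with open(out / "manifest.txt", "w") as fh:
            for key, value in sorted(vars(config).items()):
                fh.write(f"{key}={value}\n")
    return families, all_snps, truth


def paper_like_config(seed: int = 0, n_genes: int = 500, **overrides) -> SimConfig:
    """Study-scale preset: guide-tree branch lengths with gene length and
    human omega set so the mean human-branch Dn and Ds per gene are about
    2 and 3.5."""
    base = dict(
        n_genes=n_genes,
        codons_per_gene=400,
        theta_syn=2.0,
        frac_nonsyn_neutral=0.7,
        frac_nonsyn_deleterious=0.3,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def neutral_config(seed: int = 0, n_genes: int = 500, **overrides) -> SimConfig:
    """Fully neutral polymorphism structure: no deleterious class, no
    adaptive injection; pooled FI is centred on 1."""
    base = dict(
        n_genes=n_genes,
        frac_nonsyn_neutral=1.0,
        frac_nonsyn_deleterious=0.0,
        frac_substitutions_adaptive=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)
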