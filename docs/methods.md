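# Methods

## The MK framework as implemented

For each gene the unit of inference is the 2×2 contingency table with rows
(divergence, polymorphism) and columns (non-synonymous, synonymous):
human-branch substitution counts Dn, Ds against human polymorphism counts
Pn, Ps. The derived statistics are

* FI = (Dn/Ds)/(Pn/Ps), NI = 1/FI,
* DoS = Dn/(Dn+Ds) − Pn/(Pn+Ps),
* α = 1 − (Ds·Pn)/(Dn·Ps) = 1 − 1/FI,

with the identities α = 1 − 1/FI and sign(DoS) = sign(FI − 1) holding
exactly wherever all quantities are defined. Ratios involving a zero count
are reported as *undefined* with a reason code (`zero_Pn`, `zero_Ds`, …)
rather than as infinities; per-gene distribution analyses therefore
restrict to *informative* genes (Dn, Ds, Pn, Ps all non-zero and
Pn + Ps ≥ 4), while gene-set statistics avoid the issue by summing the four
counts over member genes before forming any ratio (equivalent to a
concatenated alignment). The heterogeneity-robust pooled neutrality index
is NI_TG = Σᵢ Dsᵢ·Pnᵢ/(Psᵢ+Dsᵢ) / Σᵢ Dnᵢ·Psᵢ/(Psᵢ+Dsᵢ), skipping genes with
Psᵢ + Dsᵢ = 0.

Significance uses the G-test of independence with the Williams continuity
correction: G = 2·Σ O·ln(O/E) with zero cells contributing nothing (the
x·ln x → 0 limit; no pseudocounts), divided by
q = 1 + (N/r₁ + N/r₂ − 1)(N/c₁ + N/c₂ − 1)/(6N), with the p-value from the
upper χ²(1) tail. A zero row or column margin leaves the test undefined.
Benjamini–Hochberg adjustment is available as an explicit operation
(`bh_fdr`) and is never applied silently.

## Frequency stratification

SNP records carry an alternate-allele frequency and an ancestral allele;
DAF is the frequency of the non-ancestral allele and is defined only when
the ancestral allele equals ref or alt. Records without a resolvable
ancestral allele are excluded from DAF strata (and tallied in the run log)
but retained in MAF mode — exclusion is the only option that does not guess
a polarity. Threshold strata are closed below (DAF ≥ t, defaults 1%, 15%,
30%, 60%); interval strata are half-open [lo, hi) and partition the ≥ 1%
set. DAF = 1.0 is not a polymorphism and is excluded everywhere. Stop-gain
and stop-loss changes are class `other` and never enter Pn: the MK table
concerns amino-acid replacements, and nonsense variants obey very different
selective dynamics. Multi-allelic sites contribute one record per alternate
allele.

Per-stratum gene-set summaries count and pool only genes with at least one
polymorphic site in that stratum, so n varies across strata.

## Branch-specific substitution counting

The species topology is fixed: an unrooted quartet with human and chimp
joined at the hominoid-ancestor node, which connects through the
hominoid-ancestor edge to the node bearing macaque and mouse. Changes are
placed on the five edges by small parsimony. Because the nucleotide-level
cost decomposes over the three codon positions, the minimal codon
assignments of the two internal nodes are the Cartesian product of the
per-position minimal base pairs (internal states drawn from observed bases,
which loses nothing on a quartet). All equally parsimonious assignments are
enumerated and per-edge counts averaged uniformly — Dn and Ds may therefore
be fractional. Assignments requiring a stop-codon ancestor are discarded
when sense alternatives exist; a column with no sense reconstruction is
skipped and flagged. Each edge's codon difference is decomposed into
synonymous/non-synonymous steps by NG86 pathway averaging over minimal
stop-free mutational orders. Per gene, the summed Dn + Ds over edges equals
the minimal parsimony change total over counted columns (tie-averaging
preserves it; an invariant test asserts this to 1e-9).

Site totals use the NG86 convention: each codon position contributes the
fraction of its three single-nucleotide mutants that are synonymous to S,
the remainder (including stop-creating mutants) to N, so N + S = 3 per
codon. N and S are computed from the human sequence only — the human branch
is the object of inference and this keeps ω values interpretable — over
gap-free columns. Gaps must be whole codons; any column containing a gap is
excluded from counting, and a partially gapped codon invalidates the family
(it indicates a frame error in a back-translated alignment).

Parsimony is a deliberate, deterministic substitute for codon-model
maximum-likelihood branch estimation. It is accurate at primate
divergences (on simulations with all branch lengths 0.003 subst/site it
recovers the exact true per-branch counts in > 95% of families) and is
auditable against brute-force enumeration; it undercounts multiple hits on
the long mouse branch, which downstream analyses do not use. Externally
computed ML count tables can be imported and flow through every statistic
unchanged.

### Quality filters

Families pass only if every ungapped protein is longer than 100 aa
(exactly 100 fails) and no branch among human, chimp, hominoid-ancestor has
ω > 10 (an undefined ω with Dn > 0 and Ds = 0 counts as exceeding; 0/0
passes; without site counts the raw Dn/Ds ratio is the proxy). A human
branch with more than 10 non-synonymous substitutions earns a non-excluding
`high_dn_flag`, and `misalignment_fraction` reports how many human-branch
changes fall within 5 codons of an alignment gap — an automated stand-in
for manual inspection of suspicious alignments; exclusion is left to the
user.

## Acceleration screen

Human-branch acceleration is called when (i) the one-sided Fisher's exact
test on rows (human Dn, human Ds) / (ancestor Dn, ancestor Ds) gives
p < 0.05, (ii) the same contrast for chimp does not, and (iii) a
neighbor-joining tree on Jukes–Cantor distances (uncorrected when
saturated) over the gap-free concatenate recovers human and chimp as
sisters. One-sidedness is used for both contrasts: the hypothesis is an
*excess* of amino-acid substitutions, and a two-sided chimp veto would also
trigger on chimp deficits. Fractional parsimony counts are rounded
half-to-even before the exact test. Fully divergence-free families pass the
topology check by convention (no signal). On fully neutral simulations the
dual screen flags well below the nominal 5% (the chimp veto and the
discreteness of the exact test make it conservative).

Rate-matched controls are drawn per 0.1-wide human dN/dS bin (last bin
open-ended) to mirror the accelerated set's bin profile, without
replacement, borrowing from the nearest bins when one is exhausted (logged),
and accepted when a two-sided rank-sum test between the two dN/dS
distributions gives p > 0.05 (bounded retries).

## Functional groups

Group comparisons are rank-based (Mann–Whitney–Wilcoxon) on per-gene FI over
informative genes; the one-sided (greater) p-value is reported only when
the group median exceeds the background median, otherwise suppressed. The
background includes group members by default (configurable): this matches
the reporting design of comparing each group against "all genes", and can
only make the test conservative — the null calibration test in the suite
verifies nominal rejection rates on disjoint samples and conservativeness
under overlap. Groups need ≥ 40 informative genes (configurable); genes
with no annotation form the reserved `unknown` group at any size. Category
enrichment uses the exact one-sided binomial tail against the background
category frequency, with a normal-approximation companion value; the GO
graph is not propagated (annotations are taken as a flat export).

## The synthetic-data generator

The generator produces exactly the statistical structure the analysis
consumes, with full truth bookkeeping, and nothing more.

**Divergence.** Root codons are uniform over the 61 sense codons. On each
branch the number of mutation events is Poisson(branch length × 3 × codons),
with guide-tree defaults 0.01 (human), 0.01 (chimp), 0.03
(hominoid-ancestor), 0.04 (macaque), 0.32 (mouse) mutations per site. An
event picks a uniform nucleotide site and a κ-weighted alternative base
(κ = 2 transition:transversion by default), redrawing entirely on
stop-creating changes; synonymous changes always fix, non-synonymous
changes fix with probability min(1, ω_branch) (default ω = 0.25 on all
branches). Adaptive evolution is injected on the human branch only — never
as polymorphism, since positively selected mutations fix too quickly to be
sampled as SNPs: after the regular pass, Poisson(Dn_regular · f/(1−f))
forced non-synonymous changes are added, so the adaptive share of human
non-synonymous substitutions is centred on `frac_substitutions_adaptive`
and the bookkept true α matches the dial.

**Polymorphism.** SNP records are drawn directly rather than from a
coalescent — the analysis consumes only (position, class, DAF) triples, so
a coalescent would add cost without testable structure. Synonymous SNPs per
gene are Poisson(θ_syn) (default 2); neutral non-synonymous SNPs arrive at
rate θ_syn · (w_n/w_s) · ω_human, where w_n/w_s is the κ-weighted non-stop
mutational opportunity ratio of the gene's actual human CDS — the same law
as the divergence process, so under neutrality E[Pn/Ps] equals the
non-adaptive E[Dn/Ds] and pooled FI is centred on 1. The slightly
deleterious class tops up non-synonymous SNPs to its configured share
(default 30%). DAF laws are explicit Betas: neutral Beta(0.5, 0.7)
(decreasing density with appreciable high-frequency mass, ~33% above 0.6);
deleterious Beta(0.5, 8) (89% of mass below 0.15, ~2% above 0.3,
essentially none above 0.6). The ancestral allele is recorded as the
reference base, so DAF is exactly recoverable. One seeded generator per
gene index makes datasets reproducible and gene streams independent of
`n_genes`.

**Calibration.** The study-scale preset (400 codons/gene, ω = 0.25, κ = 2,
guide-tree lengths) yields mean human-branch Dn ≈ 2.1 and Ds ≈ 3.6 per
gene, matching the target per-gene means of 2 and 3.5 within tolerance.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: indels and alignment error, codon-usage
and CpG mutation bias, site-rate heterogeneity, linkage and demography
(DAF spectra are phenomenological Betas, not coalescent outputs),
ascertainment of SNP panels, and gene-length variation. The recovery tests
certify the estimators against the generative model, not the generative
model against biology.

## Problem sizes and numerical choices

Simulation-backed tests use 500-gene datasets (the study-scale preset has
~20× fewer genes than a genome-wide set, so the per-gene SNP density is
raised to θ_syn = 4 in those runs to keep pooled per-stratum counts
informative), 200-family recovery runs at uniform 0.003 branch lengths,
and exhaustive oracle sweeps (all 2×2 tables with total ≤ 40 for Fisher;
1,000 random tables for G vs mutual information; all single-change columns
of 40 low-divergence families for parsimony attribution). The
FI-vs-threshold monotonicity check allows a 5% tolerance between
neighbouring thresholds — the deleterious DAF law leaves almost no mass
above 0.3, so the expected FI difference between the 30% and 60% thresholds
is smaller than counting noise — while requiring a > 10% overall rise.

Tie-breaks and degenerate inputs: equally parsimonious reconstructions are
averaged with uniform weight; identical sequences give zero counts
everywhere, pass the topology check, and produce G = 0/p = 1 only where
margins allow the test at all; empty gene sets yield n = 0 rows with
undefined statistics; an empty input table is an empty result plus a
warning, never an exception.

## Known limitations

* Parsimony counts are biased low on long branches (mouse); only the three
  short branches feed the screens and filters.
* The Williams-corrected G-test is asymptotic; for the very small tables
  typical of primate MK data it is anti-conservative relative to exact
  tests in some corners, which is why the acceleration screen uses Fisher's
  exact test instead.
* α estimates remain downward-biased if deleterious variants persist above
  the chosen DAF threshold; the 60% threshold reduces but cannot eliminate
  this.
* The NJ topology check uses whole-gene distances and will pass genes whose
  misalignment is local; the gap-proximity heuristic is the complementary
  signal.
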