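"""Shared fixtures: simulated datasets run once per session through the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from lineagemk import (
    AnalysisConfig,
    count_branch_substitutions,
    neutral_config,
    paper_like_config,
    simulate_dataset,
    stratify_by_frequency,
    stratum_summary,
)


@dataclass
class PipelineRun:
    """A simulated dataset pushed through counting and stratification."""

    families: list
    snps: list
    truth: object
    gene_counts: dict          # gene -> human-branch (Dn, Ds) from the pipeline
    all_counts: list           # every BranchCounts from the pipeline
    polys: list                # GenePolymorphism records, default strata
    summaries: dict            # stratum label -> pooled GeneSetSummary ("all" set)


def _run_pipeline(config) -> PipelineRun:
    families, snps, truth = simulate_dataset(config)
    gene_counts = {}
    all_counts = []
    for fam in families:
        res = count_branch_substitutions(fam)
        by = res.by_branch()
        gene_counts[fam.gene_id] = (by["human"].Dn, by["human"].Ds)
        all_counts.extend(res.branch_counts)
    polys = stratify_by_frequency(snps, AnalysisConfig())
    summaries = {
        s.stratum: s for s in stratum_summary(gene_counts, polys)
    }
    return PipelineRun(
        families=families,
        snps=snps,
        truth=truth,
        gene_counts=gene_counts,
        all_counts=all_counts,
        polys=polys,
        summaries=summaries,
    )


@pytest.fixture(scope="session")
def mixture_run() -> PipelineRun:
    """500 genes with 30% deleterious non-synonymous SNPs and a 40% adaptive
    share of human-branch non-synonymous substitutions; SNP density scaled
    up (theta_syn=4) to keep pooled stratum counts informative at this
    gene count."""
    cfg = paper_like_config(
        seed=0, n_genes=500, theta_syn=4.0, frac_substitutions_adaptive=0.4
    )
    return _run_pipeline(cfg)


@pytest.fixture(scope="session")
def neutral_run() -> PipelineRun:
    """500 fully neutral genes: no deleterious class, no adaptive injection,
    equal omega on every branch."""
    cfg = neutral_config(seed=0, n_genes=500, theta_syn=4.0)
    return _run_pipeline(cfg)
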