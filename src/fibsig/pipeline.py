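"""Orchestration of the two pipeline stages.

Stage 1 (signature discovery): per-cohort differential expression →
at-least-k-of-n membership pools for the CD and other-fibrosis cohorts →
pool intersection with an exact overlap statistic.

Stage 2 (validation): median-of-ratios normalization of the paired-biopsy
counts → restriction to the signature → co-expression module discovery →
module-vs-stratum NES table → degree hubs of the largest module → ORA of
the largest module against a supplied pathway collection.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import counts as counts_mod
from . import coexpression as coex
from . import de as de_mod
from . import io as io_mod
from . import multiset, ora as ora_mod, ppi
from .simulate import MultiCohortSpec, PairedBiopsySpec, simulate_cohorts, simulate_paired_counts
from .types import ExpressionMatrix, GeneSet, GeneSetCollection, InteractionNetwork, SampleAnnotation

log = logging.getLogger("fibsig")


@dataclass
class PipelineConfig:
    """Settings for both stages; defaults reproduce the 9+5-cohort, paired-biopsy design."""

    de: de_mod.DEConfig = field(default_factory=de_mod.DEConfig)
    scheme_cd: multiset.CombinationScheme = field(
        default_factory=lambda: multiset.CombinationScheme(n_lists=9, min_k=7)
    )
    scheme_other: multiset.CombinationScheme = field(
        default_factory=lambda: multiset.CombinationScheme(n_lists=5, min_k=4)
    )
    background_n: int | None = None
    coexpression: coex.CoexpressionConfig = field(
        default_factory=coex.CoexpressionConfig
    )
    hub_rule: str = "mean_plus_sd"
    hub_k: int | None = None
    n_perm: int = 1000
    ora: ora_mod.OraConfig = field(default_factory=ora_mod.OraConfig)
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Stable per-stage seed derived from the global seed."""
        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)

    def digest(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        payload = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.md5(payload.encode()).hexdigest()[:12]


def _header(config: PipelineConfig) -> str:
    return f"# fibsig config={config.digest()} seed={config.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig,
               index_label: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=index_label is not None,
                  index_label=index_label)


def run_signature_stage(
    config: PipelineConfig,
    cohorts: dict[str, tuple[ExpressionMatrix, list[str], list[str]]] | None = None,
    gene_lists: dict[str, GeneSet] | None = None,
    cohort_groups: dict[str, str] | None = None,
    synthetic_spec: MultiCohortSpec | None = None,
    outdir: str | Path | None = None,
) -> multiset.SignatureResult:
    """Run stage 1 and return the signature with its overlap statistic.

    Inputs, by priority: precomputed per-cohort ``gene_lists`` (with
    ``cohort_groups`` mapping cohort name → "CD"/"other"; skips DE),
    expression ``cohorts``, or a ``synthetic_spec`` to simulate them.
    """
    measured_union: set[str] = set()
    if gene_lists is None:
        if cohorts is None:
            spec = synthetic_spec or MultiCohortSpec(
                seed=config.stage_seed("simulate_cohorts")
            )
            cohorts, _ = simulate_cohorts(spec)
        gene_lists, cohort_groups = {}, {}
        for name, (matrix, cases, controls) in cohorts.items():
            result = de_mod.run_de(matrix, cases, controls, config.de)
            gene_lists[name] = de_mod.significant_genes(result, name)
            cohort_groups[name] = "CD" if name.upper().startswith("CD") else "other"
            measured_union.update(matrix.genes)
            log.info("DE %s: %d significant genes", name, len(gene_lists[name]))
    if cohort_groups is None:
        raise ValueError("cohort_groups required with precomputed gene lists")

    cd_lists = [gs for n, gs in gene_lists.items() if cohort_groups[n] == "CD"]
    other_lists = [gs for n, gs in gene_lists.items() if cohort_groups[n] != "CD"]
    m_cd = multiset.membership_matrix(cd_lists)
    m_other = multiset.membership_matrix(other_lists)
    gs1 = multiset.k_of_n_filter(m_cd, config.scheme_cd, name="GeneSet1")
    gs2 = multiset.k_of_n_filter(m_other, config.scheme_other, name="GeneSet2")
    log.info("pools: |GeneSet1|=%d |GeneSet2|=%d", len(gs1), len(gs2))

    background_n = config.background_n
    if background_n is None:
        universe = measured_union or (gs1.as_set() | gs2.as_set())
        background_n = len(universe)
    result = multiset.build_signature(gs1, gs2, background_n)
    log.info("FIBSig: %d genes (p=%.3g, fold=%.2f)",
             len(result.fibsig), result.stats.p_value,
             result.stats.fold_enrichment)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "fibsig.txt", "w") as fh:
            fh.write(_header(config))
            fh.write("\n".join(result.fibsig.genes) + "\n")
        for name, gs in gene_lists.items():
            io_mod.write_gene_list(gs, outdir / f"genes_{name}.txt")
        stats = dataclasses.asdict(result.stats)
        stats["pool_sizes"] = {"GeneSet1": len(gs1), "GeneSet2": len(gs2)}
        (outdir / "intersection_stats.json").write_text(
            json.dumps(stats, indent=2, default=str)
        )
    return result


@dataclass
class ValidationResult:
    normalized: counts_mod.NormalizedMatrix
    pca: counts_mod.PcaSummary
    coexpression: coex.CoexpressionResult
    nes_table: pd.DataFrame
    hub_report: ppi.HubReport | None
    ora_table: pd.DataFrame | None


def run_validation_stage(
    config: PipelineConfig,
    signature: GeneSet,
    counts: ExpressionMatrix | None = None,
    annotation: SampleAnnotation | None = None,
    network: InteractionNetwork | None = None,
    collection: GeneSetCollection | None = None,
    synthetic_spec: PairedBiopsySpec | None = None,
    outdir: str | Path | None = None,
) -> ValidationResult:
    """Run stage 2 on counts (real or synthetic) against a signature."""
    if counts is None or annotation is None:
        spec = synthetic_spec or PairedBiopsySpec(
            seed=config.stage_seed("simulate_paired_counts")
        )
        if spec.gene_names is None and len(signature) > 0:
            # simulate the validation counts on the signature's own genes
            n = min(spec.genes, len(signature))
            spec = dataclasses.replace(
                spec, genes=n, module_genes=min(spec.module_genes, n),
                gene_names=tuple(signature.genes[:n]),
            )
        counts, annotation, _ = simulate_paired_counts(spec)

    factors = counts_mod.median_ratio_size_factors(counts)
    norm = counts_mod.log_normalize(counts, factors)
    pca = counts_mod.pca_summary(norm, n_components=2)
    log.info("PC1 variance fraction: %.3f", pca.variance_fraction[0])

    restricted = norm.restrict(signature)
    if not restricted.genes:
        raise ValueError("signature shares no genes with the count matrix")
    result = coex.discover_modules(restricted, config.coexpression)
    sizes = result.assignments.value_counts().to_dict()
    log.info("modules: beta=%d rsq=%.2f sizes=%s", result.beta, result.rsq, sizes)

    nes = coex.module_class_nes_table(
        restricted, annotation, result,
        n_perm=config.n_perm, seed=config.stage_seed("gsea"),
    )

    hub_report = None
    ora_table = None
    if result.modules:
        m1 = result.module_genes(result.modules[0])
        if network is not None:
            sub = ppi.induced_subnetwork(network, m1)
            hub_report = ppi.select_hubs(
                ppi.degree_centrality(sub), rule=config.hub_rule, k=config.hub_k
            )
            log.info("hubs: %d of %d module genes",
                     int(hub_report.table["is_hub"].sum()), len(m1))
        if collection is not None:
            ora_table = ora_mod.hypergeometric_ora(m1, collection, config=config.ora)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_tsv(norm.values, outdir / "normalized.tsv", config, "gene")
        _write_tsv(pca.scores, outdir / "pca_scores.tsv", config, "sample")
        _write_tsv(result.assignments.to_frame("module"),
                   outdir / "module_assignments.tsv", config, "gene")
        _write_tsv(result.eigengenes, outdir / "eigengenes.tsv", config, "module")
        _write_tsv(nes, outdir / "module_class_nes.tsv", config)
        if hub_report is not None:
            _write_tsv(hub_report.table, outdir / "hub_report.tsv", config, "gene")
        if ora_table is not None:
            _write_tsv(ora_table, outdir / "ora_results.tsv", config)
        (outdir / "pca_variance.json").write_text(
            json.dumps({"variance_fraction": list(map(float, pca.variance_fraction))})
        )
    return ValidationResult(
        normalized=norm, pca=pca, coexpression=result, nes_table=nes,
        hub_report=hub_report, ora_table=ora_table,
    )
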