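"""Synthetic data generators with exported ground truth.

Three generators cover the statistical structure each pipeline stage
assumes:

* :func:`simulate_cohorts` — multi-cohort microarray-like log-intensity
  matrices with a planted cross-disease core signature.  Planted genes
  carry their effect in each cohort only with probability ``detect_prob``,
  so the at-least-k-of-n membership filter is exercised exactly as
  intended: no single cohort sees every signature gene.
* :func:`simulate_paired_counts` — negative-binomial counts for a paired
  two-tissue biopsy design with one planted co-expression module driven
  by a latent factor elevated in a single tissue × condition stratum.
* :func:`simulate_scale_free_network` — a preferential-attachment
  interaction network whose initial clique members are the planted hubs.

All generators are pure functions of their spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GeneSet, InteractionNetwork, SampleAnnotation


@dataclass
class PlantedTruth:
    """Ground truth exported by the generators, for recall/precision checks."""

    core: GeneSet | None = None
    cd_only: GeneSet | None = None
    other_only: GeneSet | None = None
    carried: dict[str, GeneSet] = field(default_factory=dict)
    module_genes: GeneSet | None = None
    module_class: tuple[str, str] | None = None
    latent_factor: pd.Series | None = None
    size_factors: pd.Series | None = None
    hub_nodes: GeneSet | None = None


@dataclass
class MultiCohortSpec:
    """Multi-cohort differential-expression simulation settings.

    ``effect_size`` is the case-vs-control mean shift on the log scale and
    ``noise_sd`` the within-group standard deviation, sized so a carried
    effect is detected with near-certainty at ``samples_per_group`` = 10;
    ``detect_prob`` is the per-cohort probability that a planted gene
    carries its effect at all, which is what makes the k-of-n membership
    filter necessary.
    """

    n_cohorts_cd: int = 9
    n_cohorts_other: int = 5
    genes: int = 5000
    samples_per_group: int = 10
    n_core: int = 240
    n_cd_only: int = 200
    n_other_only: int = 600
    effect_size: float = 2.0
    detect_prob: float = 0.95
    noise_sd: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_core + self.n_cd_only + self.n_other_only > self.genes:
            raise ValueError("planted gene counts exceed total genes")
        if not 0 < self.detect_prob <= 1:
            raise ValueError("detect_prob must be in (0, 1]")


def simulate_cohorts(
    spec: MultiCohortSpec,
) -> tuple[dict[str, tuple[ExpressionMatrix, list[str], list[str]]], PlantedTruth]:
    """Per-cohort (matrix, case sample ids, control sample ids) plus truth."""
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.genes - 1))
    genes = [f"G{i:0{width}d}" for i in range(spec.genes)]
    core = genes[: spec.n_core]
    cd_only = genes[spec.n_core: spec.n_core + spec.n_cd_only]
    other_only = genes[
        spec.n_core + spec.n_cd_only:
        spec.n_core + spec.n_cd_only + spec.n_other_only
    ]
    baseline = rng.normal(7.0, 1.0, size=spec.genes)
    cohorts = [f"CD{i+1}" for i in range(spec.n_cohorts_cd)] + [
        f"OTH{i+1}" for i in range(spec.n_cohorts_other)
    ]
    out: dict[str, tuple[ExpressionMatrix, list[str], list[str]]] = {}
    carried_truth: dict[str, GeneSet] = {}
    n = spec.samples_per_group
    gene_pos = {g: i for i, g in enumerate(genes)}
    for cohort in cohorts:
        planted = core + (cd_only if cohort.startswith("CD") else other_only)
        carried_mask = rng.random(len(planted)) < spec.detect_prob
        carried = [g for g, c in zip(planted, carried_mask) if c]
        carried_truth[cohort] = GeneSet(f"{cohort}_carried", carried)
        cases = [f"{cohort}_case{i+1}" for i in range(n)]
        controls = [f"{cohort}_ctrl{i+1}" for i in range(n)]
        x = rng.normal(0.0, spec.noise_sd, size=(spec.genes, 2 * n))
        x += baseline[:, None]
        idx = [gene_pos[g] for g in carried]
        x[idx, :n] += spec.effect_size
        matrix = ExpressionMatrix(
            pd.DataFrame(x, index=genes, columns=cases + controls),
            mode="intensity",
        )
        out[cohort] = (matrix, cases, controls)
    truth = PlantedTruth(
        core=GeneSet("planted_core", core),
        cd_only=GeneSet("planted_cd_only", cd_only),
        other_only=GeneSet("planted_other_only", other_only),
        carried=carried_truth,
    )
    return out, truth


@dataclass
class PairedBiopsySpec:
    """Paired-biopsy count simulation settings.

    The planted module's genes share a latent factor elevated (mean 1) in
    ``module_class`` samples and centred at 0 elsewhere, with a
    patient-level random effect shared between a patient's two tissues.
    ``nb_dispersion`` is the negative-binomial alpha (variance =
    mu + alpha·mu²); ``factor_loading`` scales the factor on the log-mean.

    ``n_background`` unmodulated genes outside the signature are simulated
    alongside the ``genes`` signature genes so that library-size estimation
    sees a realistic composition (the planted module is a small fraction of
    the transcriptome, as in real data); downstream analyses restrict to
    the signature genes.
    """

    n_cd: int = 7
    n_uc: int = 6
    n_ci: int = 9
    genes: int = 241
    module_genes: int = 112
    n_background: int = 1800
    module_class: tuple[str, str] = ("ILEAL", "CD")
    factor_loading: float = 1.5
    nb_dispersion: float = 0.05
    base_mean: float = 200.0
    depth_range: tuple[float, float] = (0.5, 2.0)
    patient_sd: float = 0.1
    factor_sd: float = 0.1
    gene_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_genes > self.genes:
            raise ValueError("module_genes must be <= genes")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.gene_names is not None and len(self.gene_names) != self.genes:
            raise ValueError("gene_names length must equal genes")


def simulate_paired_counts(
    spec: PairedBiopsySpec,
) -> tuple[ExpressionMatrix, SampleAnnotation, PlantedTruth]:
    """Negative-binomial paired counts with one planted co-expression module."""
    rng = np.random.default_rng(spec.seed)
    if spec.gene_names is not None:
        genes = list(spec.gene_names)
    else:
        width = len(str(spec.genes - 1))
        genes = [f"G{i:0{width}d}" for i in range(spec.genes)]
    module = genes[: spec.module_genes]
    genes = genes + [f"BG{i:04d}" for i in range(spec.n_background)]

    rows = []
    patients = (
        [("CD", i) for i in range(spec.n_cd)]
        + [("UC", i) for i in range(spec.n_uc)]
        + [("CI", i) for i in range(spec.n_ci)]
    )
    for cond, i in patients:
        pid = f"{cond}P{i+1}"
        for tissue in ("ILEAL", "SIGMOID"):
            rows.append(
                {"sample_id": f"{pid}_{tissue}", "patient_id": pid,
                 "tissue": tissue, "condition": cond, "sex": "unknown",
                 "age": pd.NA}
            )
    annotation = SampleAnnotation(pd.DataFrame(rows))
    samples = annotation.sample_ids

    patient_effect = {
        f"{cond}P{i+1}": rng.normal(0.0, spec.patient_sd) for cond, i in patients
    }
    mt, mc = spec.module_class
    factor = []
    for _, row in annotation.table.iterrows():
        active = row["tissue"] == mt and row["condition"] == mc
        f = (1.0 if active else 0.0)
        f += patient_effect[row["patient_id"]] + rng.normal(0.0, spec.factor_sd)
        factor.append(f)
    factor = pd.Series(factor, index=samples, name="latent_factor")

    size_factors = pd.Series(
        np.exp(rng.uniform(np.log(spec.depth_range[0]),
                           np.log(spec.depth_range[1]), size=len(samples))),
        index=samples, name="size_factor",
    )
    gene_base = spec.base_mean * np.exp(rng.normal(0.0, 0.5, size=len(genes)))
    in_module = np.array([g in set(module) for g in genes])

    log_mu = (
        np.log(gene_base)[:, None]
        + np.log(size_factors.to_numpy())[None, :]
        + spec.factor_loading * np.outer(in_module, factor.to_numpy())
    )
    mu = np.exp(log_mu)
    if spec.nb_dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / spec.nb_dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    matrix = ExpressionMatrix(
        pd.DataFrame(counts.astype(np.int64), index=genes, columns=samples),
        mode="counts",
        annotation=annotation,
    )
    truth = PlantedTruth(
        module_genes=GeneSet("planted_module", module),
        module_class=spec.module_class,
        latent_factor=factor,
        size_factors=size_factors,
    )
    return matrix, annotation, truth


def simulate_scale_free_network(
    n_nodes: int = 500,
    m_attach: int = 2,
    n_planted_hubs: int = 10,
    seed: int = 0,
) -> tuple[InteractionNetwork, PlantedTruth]:
    """Preferential-attachment network; the initial clique is the hub set.

    Edge confidence scores are sampled uniformly in [400, 999].  With a
    single-node initial clique and ``m_attach`` = 1 the result is a tree.
    """
    if m_attach < 1:
        raise ValueError("m_attach must be >= 1")
    if n_planted_hubs < 1 or n_planted_hubs >= n_nodes:
        raise ValueError("need 1 <= n_planted_hubs < n_nodes")
    rng = np.random.default_rng(seed)
    # preferential attachment needs at least one seed edge
    initial = nx.complete_graph(max(n_planted_hubs, m_attach, 2))
    g = nx.barabasi_albert_graph(
        n_nodes, m_attach, seed=int(rng.integers(2**31)), initial_graph=initial
    )
    width = len(str(n_nodes - 1))
    mapping = {i: f"G{i:0{width}d}" for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    net = InteractionNetwork.from_edges(
        (a, b, float(rng.integers(400, 1000))) for a, b in sorted(g.edges())
    )
    hubs = GeneSet("planted_hubs", [mapping[i] for i in range(n_planted_hubs)])
    return net, PlantedTruth(hub_nodes=hubs)
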