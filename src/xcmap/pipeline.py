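"""End-to-end orchestration: simulate -> filter -> signatures -> cluster ->
enrichment -> ortholog mapping -> cross-species enrichment.

Both entry points (:func:`run_within_species`, :func:`run_cross_species`)
write every intermediate artifact in a re-readable text format and are
byte-reproducible: the same config and seed yield identical output files.
Per-stage random streams are forked from the run seed by stage name, so
adding a stage does not perturb the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .clustering import Dendrogram, correlation_distance, hcluster
from .enrichment import EnrichmentResult, enrichment_table, results_to_frame
from .io import (
    ExpressionMatrix,
    GeneSet,
    read_expression,
    read_gmt,
    subset_mean_profile,
    write_expression,
    write_gmt,
)
from .orthology import OrthologTable, map_signature, read_orthologs
from .signatures import (
    GeneSignature,
    derive_signature,
    pool_signature,
    remove_genes,
    signature_to_gene_sets,
    tissue_specific_genes,
)
from .synth import CohortDesign, default_design, generate_cohort

__all__ = [
    "AnalysisConfig",
    "WithinSpeciesReport",
    "CrossSpeciesReport",
    "load_config",
    "stage_seed",
    "run_within_species",
    "run_cross_species",
]

# fields of CohortDesign that may be overridden from a flat config file
_DESIGN_FIELDS = (
    "n_genes",
    "n_marker_genes_per_lineage",
    "n_tissue_genes_per_tissue",
    "lineage_effect",
    "tissue_effect",
    "donor_sd",
    "noise_sd",
    "ortholog_fraction",
    "one_to_many_rate",
)


@dataclass
class AnalysisConfig:
    """Run configuration.  ``seed`` is mandatory; everything else has a
    default.  When the matrix paths are unset, a synthetic cohort is
    simulated from the default two-species design (with any
    ``design_overrides`` applied)."""

    seed: int
    human_matrix: str | None = None
    human_annotations: str | None = None
    mouse_matrix: str | None = None
    mouse_annotations: str | None = None
    orthologs: str | None = None
    signature_size: int = 150
    fdr: float = 0.05
    permutations: int = 1000
    per_sample: bool = True
    linkage: str = "average"
    ortholog_policy: str = "one_to_one_only"
    tissue_filter_method: str = "blocked"
    query_subset: str = "CD141_DC"
    query_tissue: str | None = "skin"
    lineage_queries: tuple[tuple[str, str], ...] = (
        ("CD141_lineage", "CD141_DC"),
        ("CD1c_lineage", "CD1c_DC"),
        ("CD14_monocyte", "CD14_DC"),
    )
    design_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must set a seed")
        bad = set(self.design_overrides) - set(_DESIGN_FIELDS)
        if bad:
            raise ValueError(f"unknown design overrides: {sorted(bad)}")

    def design(self) -> CohortDesign:
        return default_design(seed=int(stage_seed(self.seed, "simulate").generate_state(1)[0]) % (2**31),
                              **self.design_overrides)

    def echo(self) -> str:
        d = asdict(self)
        lines = [f"{k}: {d[k]}" for k in sorted(d)]
        return "\n".join(lines)


def load_config(path: str | Path) -> AnalysisConfig:
    """Read a flat key-value YAML config; design fields go to overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError(f"{path}: config must set a seed")
    overrides = {k: raw.pop(k) for k in list(raw) if k in _DESIGN_FIELDS}
    if "lineage_queries" in raw:
        raw["lineage_queries"] = tuple(tuple(q) for q in raw["lineage_queries"])
    return AnalysisConfig(design_overrides=overrides, **raw)


def stage_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Fork a per-stage seed from the run seed, keyed by stage name."""
    return np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])


def _crc(path: Path) -> str:
    return f"{zlib.crc32(path.read_bytes()):08x}"


def _load_species(
    cfg: AnalysisConfig,
) -> tuple[dict[str, ExpressionMatrix], OrthologTable | None]:
    if cfg.human_matrix is None:
        matrices, table, _truth = generate_cohort(cfg.design())
        return matrices, table
    matrices = {"human": read_expression(cfg.human_matrix, cfg.human_annotations)}
    table = None
    if cfg.mouse_matrix is not None:
        matrices["mouse"] = read_expression(cfg.mouse_matrix, cfg.mouse_annotations)
    if cfg.orthologs is not None:
        table = read_orthologs(cfg.orthologs)
    return matrices, table


@dataclass
class WithinSpeciesReport:
    tissue_genes: GeneSet
    filtered: ExpressionMatrix
    signatures: list[GeneSignature]
    dendrogram: Dendrogram
    enrichment: list[EnrichmentResult]
    outdir: Path


def run_within_species(cfg: AnalysisConfig, outdir: str | Path) -> WithinSpeciesReport:
    """Single-species stage: tissue filter, per-subset signatures, dendrogram
    and the connectivity of the configured query signature against all
    subsets of the same species."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = ["stage=config", *cfg.echo().splitlines()]
    try:
        matrices, _ = _load_species(cfg)
        human = matrices["human"]
        tissues = list(dict.fromkeys(human.annotations["tissue"]))
        if len(tissues) != 2:
            raise ValueError(f"within-species run needs exactly 2 tissues, found {tissues}")
        stage = "tissue_filter"
        tissue_set = tissue_specific_genes(
            human, tissues[0], tissues[1], alpha=cfg.fdr, method=cfg.tissue_filter_method
        )
        write_gmt([tissue_set], outdir / "tissue_genes.gmt")
        log.append(f"stage={stage} n_tissue_genes={len(tissue_set)}")

        stage = "filter_matrix"
        filtered = remove_genes(human, tissue_set)
        write_expression(filtered, outdir / "filtered_matrix.tsv", outdir / "filtered_annotations.tsv")
        log.append(f"stage={stage} n_genes={filtered.n_genes} crc={_crc(outdir / 'filtered_matrix.tsv')}")

        stage = "signatures"
        sigs: list[GeneSignature] = []
        anno = filtered.annotations
        for subset in dict.fromkeys(anno["subset"]):
            for tissue in dict.fromkeys(anno.loc[anno["subset"] == subset, "tissue"]):
                sigs.append(
                    derive_signature(
                        filtered, subset, size=cfg.signature_size, target_tissue=tissue
                    )
                )
        gene_sets = [gs for s in sigs for gs in signature_to_gene_sets(s)]
        write_gmt(gene_sets, outdir / "signatures.gmt")
        log.append(f"stage={stage} n_signatures={len(sigs)}")

        stage = "cluster"
        profiles = subset_mean_profile(filtered, group_by=("subset", "tissue"))
        tree = hcluster(correlation_distance(profiles), linkage=cfg.linkage)
        (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
        log.append(f"stage={stage} n_leaves={len(tree.leaves)}")

        stage = "enrichment"
        query_name = (
            f"{cfg.query_subset}.{cfg.query_tissue}" if cfg.query_tissue else cfg.query_subset
        )
        query = next((s for s in sigs if s.name == query_name), None)
        if query is None:
            raise ValueError(f"query signature {query_name!r} was not derived")
        enrich_seed = int(stage_seed(cfg.seed, stage).generate_state(1)[0]) % (2**31)
        results = enrichment_table(
            query,
            filtered,
            per_sample=cfg.per_sample,
            B=cfg.permutations,
            seed=enrich_seed,
        )
        frame = results_to_frame(results)
        frame.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.10g")
        log.append(f"stage={stage} n_rows={len(frame)}")
    except Exception as exc:  # annotate failures with the failing stage
        raise RuntimeError(f"within-species pipeline failed at stage {stage!r}: {exc}") from exc
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    return WithinSpeciesReport(
        tissue_genes=tissue_set,
        filtered=filtered,
        signatures=sigs,
        dendrogram=tree,
        enrichment=results,
        outdir=outdir,
    )


@dataclass
class CrossSpeciesReport:
    pooled_signatures: list[GeneSignature]
    mapped_signatures: list[GeneSignature]
    retention: dict[str, tuple[float, float]]
    enrichment: dict[str, list[EnrichmentResult]]
    outdir: Path


def run_cross_species(cfg: AnalysisConfig, outdir: str | Path) -> CrossSpeciesReport:
    """Cross-species stage: pooled human lineage signatures, translated to
    mouse orthologs and scored against every mouse subset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = ["stage=config", *cfg.echo().splitlines()]
    stage = "load"
    try:
        matrices, table = _load_species(cfg)
        if "mouse" not in matrices or table is None:
            raise ValueError("cross-species run needs both species' matrices and an ortholog table")
        human, mouse = matrices["human"], matrices["mouse"]

        stage = "tissue_filter"
        tissues = list(dict.fromkeys(human.annotations["tissue"]))
        if len(tissues) == 2:
            tissue_set = tissue_specific_genes(
                human, tissues[0], tissues[1], alpha=cfg.fdr, method=cfg.tissue_filter_method
            )
            filtered = remove_genes(human, tissue_set)
        else:
            filtered = human
        log.append(f"stage={stage} n_genes={filtered.n_genes}")

        stage = "pooled_signatures"
        pooled: list[GeneSignature] = []
        for name, subset in cfg.lineage_queries:
            pooled.append(
                pool_signature([filtered], [subset], size=cfg.signature_size, name=name)
            )
        write_gmt(
            [gs for s in pooled for gs in signature_to_gene_sets(s)],
            outdir / "pooled_signatures.gmt",
        )
        log.append(f"stage={stage} n={len(pooled)}")

        stage = "map_signatures"
        mapped: list[GeneSignature] = []
        retention: dict[str, tuple[float, float]] = {}
        for s in pooled:
            res = map_signature(s, table, policy=cfg.ortholog_policy)
            mapped.append(res.signature)
            retention[s.name] = (res.retention_up, res.retention_down)
            log.append(
                f"stage={stage} query={s.name} retention_up={res.retention_up:.4f} "
                f"retention_down={res.retention_down:.4f}"
            )
        write_gmt(
            [gs for s in mapped for gs in signature_to_gene_sets(s)],
            outdir / "mapped_signatures.gmt",
        )

        stage = "cross_enrichment"
        enrichment: dict[str, list[EnrichmentResult]] = {}
        frames = []
        for pooled_sig, s in zip(pooled, mapped):
            enrich_seed = int(
                stage_seed(cfg.seed, f"{stage}:{pooled_sig.name}").generate_state(1)[0]
            ) % (2**31)
            res = enrichment_table(
                s, mouse, per_sample=cfg.per_sample, B=cfg.permutations, seed=enrich_seed
            )
            enrichment[pooled_sig.name] = res
            frames.append(results_to_frame(res))
        import pandas as pd

        frame = pd.concat(frames, ignore_index=True)
        frame.to_csv(outdir / "cross_enrichment.tsv", sep="\t", index=False, float_format="%.10g")
        log.append(f"stage={stage} n_rows={len(frame)}")
    except Exception as exc:
        raise RuntimeError(f"cross-species pipeline failed at stage {stage!r}: {exc}") from exc
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    return CrossSpeciesReport(
        pooled_signatures=pooled,
        mapped_signatures=mapped,
        retention=retention,
        enrichment=enrichment,
        outdir=outdir,
    )


def plot_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    """Scatter of per-sample scaled scores with the subset mean, one column
    per reference subset (the standard connectivity-panel presentation)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(results) + 2, 4))
    for i, r in enumerate(results):
        x = np.full(len(r.scaled_scores), i, dtype=float)
        ax.scatter(x, r.scaled_scores, s=18, alpha=0.7, color="tab:gray")
        ax.hlines(r.mean_scaled, i - 0.3, i + 0.3, color="tab:red", linewidth=2)
    ax.axhline(0.0, color="black", linewidth=0.7)
    ax.set_xticks(range(len(results)))
    ax.set_xticklabels([r.reference_subset for r in results], rotation=45, ha="right")
    ax.set_ylabel("scaled connectivity score")
    ax.set_ylim(-1.05, 1.05)
    if results:
        ax.set_title(results[0].query)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
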