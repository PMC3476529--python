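"""Synthetic two-species microarray cohorts with planted lineage homology.

The generator emulates the design of a human/mouse dendritic-cell (DC)
profiling study: FACS-purified subsets from two human tissues (blood, skin;
six blood and four skin donors) and four mouse compartments (lung, liver,
spleen, blood; four experimental sets), with subsets tied together across
species by shared *lineage* labels (cd141_like, cd1c_like, monocyte_like,
pdc_like).  Expression is an additive Gaussian model on the log2 scale:

    value = baseline(gene)
          + lineage_effect * [gene is a marker of the sample's lineage]
          + tissue_effect  * [gene is a tissue gene of the sample's tissue]
          + donor_offset(donor)            # scalar shared across genes
          + Normal(0, noise_sd)            # per gene per sample

Marker genes of lineages present in both species correspond through 1:1
orthologs, so a human signature translated to mouse gene space lands on the
homologous mouse subsets.  Everything is deterministic given the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, read_gmt, write_gmt
from .orthology import OrthologTable, read_orthologs, write_orthologs

LINEAGES = ("cd141_like", "cd1c_like", "monocyte_like", "pdc_like", "none")

__all__ = [
    "LINEAGES",
    "SubsetSpec",
    "SpeciesDesign",
    "CohortDesign",
    "SyntheticTruth",
    "default_design",
    "generate_cohort",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class SubsetSpec:
    """One sorted cell population: its name, lineage label and tissue(s)."""

    name: str
    lineage: str
    tissues: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {self.lineage!r} for subset {self.name!r}")
        if not self.tissues:
            raise ValueError(f"subset {self.name!r} has no tissues")


@dataclass(frozen=True)
class SpeciesDesign:
    """Subsets and replicate (donor) structure for one species.

    ``donors`` maps donor id -> tissue restriction (``None`` means the donor
    contributes a replicate to every tissue, as for pooled mouse experimental
    sets; a tissue name restricts the donor to that tissue, as for human
    blood vs skin donors).
    """

    name: str
    subsets: tuple[SubsetSpec, ...]
    donors: tuple[tuple[str, str | None], ...]
    gene_prefix: str = ""

    def tissues(self) -> tuple[str, ...]:
        out: list[str] = []
        for s in self.subsets:
            for t in s.tissues:
                if t not in out:
                    out.append(t)
        return tuple(out)

    def donors_for(self, tissue: str) -> list[str]:
        return [d for d, restr in self.donors if restr is None or restr == tissue]

    def prefix(self) -> str:
        return self.gene_prefix or self.name[:2].upper()


@dataclass(frozen=True)
class CohortDesign:
    """Full design of a synthetic cohort; all effects in log2 units."""

    species: tuple[SpeciesDesign, ...]
    n_genes: int = 2000
    n_marker_genes_per_lineage: int = 80
    n_tissue_genes_per_tissue: int = 100
    lineage_effect: float = 2.0
    tissue_effect: float = 1.0
    donor_sd: float = 0.1
    noise_sd: float = 0.5
    ortholog_fraction: float = 0.9
    one_to_many_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for eff in (self.lineage_effect, self.tissue_effect, self.donor_sd, self.noise_sd):
            if eff < 0:
                raise ValueError("effect sizes and noise levels must be >= 0")
        if not 0.0 <= self.ortholog_fraction <= 1.0:
            raise ValueError("ortholog_fraction must lie in [0, 1]")
        if not 0.0 <= self.one_to_many_rate <= 1.0:
            raise ValueError("one_to_many_rate must lie in [0, 1]")
        lineages = {s.lineage for sp in self.species for s in sp.subsets if s.lineage != "none"}
        n_marker = len(lineages) * self.n_marker_genes_per_lineage
        n_tissue = max(
            (len(sp.tissues()) * self.n_tissue_genes_per_tissue for sp in self.species),
            default=0,
        )
        if n_marker + n_tissue > self.n_genes:
            raise ValueError(
                f"marker ({n_marker}) + tissue ({n_tissue}) genes exceed n_genes ({self.n_genes})"
            )
        if self.ortholog_fraction * self.n_genes < n_marker and len(self.species) > 1:
            raise ValueError("not enough orthologous genes to host shared lineage markers")
        for sp in self.species:
            for sub in sp.subsets:
                for t in sub.tissues:
                    n_rep = len(sp.donors_for(t))
                    if n_rep < 2:
                        raise ValueError(
                            f"{sp.name}/{sub.name}/{t}: {n_rep} replicate(s); "
                            "downstream statistics need >= 2 per subset-tissue"
                        )

    def with_(self, **kwargs) -> "CohortDesign":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery tests.

    marker_genes: lineage -> species -> gene ids (each gene in one lineage).
    tissue_genes: species -> tissue -> gene ids (disjoint from markers).
    homologous_subsets: symmetric cross-species subset pairs sharing a lineage.
    """

    marker_genes: dict[str, dict[str, tuple[str, ...]]]
    tissue_genes: dict[str, dict[str, tuple[str, ...]]]
    orthologs: OrthologTable
    homologous_subsets: tuple[tuple[str, str], ...]


def default_design(seed: int = 0, **overrides) -> CohortDesign:
    """The default two-species study design.

    Human: five blood subsets (six donors) and three skin subsets (four
    donors).  Mouse: CD103+ and CD11b+ DCs from lung and liver, CD8+ and
    CD4+/CD11b+ DCs from spleen, monocytes from blood; four experimental
    sets each contributing one replicate per subset-tissue.
    """
    human = SpeciesDesign(
        name="human",
        subsets=(
            SubsetSpec("CD141_DC", "cd141_like", ("blood", "skin")),
            SubsetSpec("CD1c_DC", "cd1c_like", ("blood", "skin")),
            SubsetSpec("CD14_DC", "monocyte_like", ("blood", "skin")),
            SubsetSpec("CD16_monocyte", "monocyte_like", ("blood",)),
            SubsetSpec("pDC", "pdc_like", ("blood",)),
        ),
        donors=tuple(
            [(f"blood_d{i}", "blood") for i in range(1, 7)]
            + [(f"skin_d{i}", "skin") for i in range(1, 5)]
        ),
        gene_prefix="HU",
    )
    mouse = SpeciesDesign(
        name="mouse",
        subsets=(
            SubsetSpec("CD103_DC", "cd141_like", ("lung", "liver")),
            SubsetSpec("CD11b_DC", "none", ("lung", "liver")),
            SubsetSpec("CD8_DC", "cd141_like", ("spleen",)),
            SubsetSpec("CD4_DC", "cd1c_like", ("spleen",)),
            SubsetSpec("monocyte", "monocyte_like", ("blood",)),
        ),
        donors=tuple((f"set{i}", None) for i in range(1, 5)),
        gene_prefix="MO",
    )
    return CohortDesign(species=(human, mouse), seed=seed, **overrides)


def _gene_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}G{i:05d}" for i in range(n)]


def generate_cohort(
    design: CohortDesign,
) -> tuple[dict[str, ExpressionMatrix], OrthologTable, SyntheticTruth]:
    """Simulate expression matrices, the ortholog table and the ground truth.

    Returns a mapping species name -> ExpressionMatrix, the (possibly empty)
    ortholog table between the first two species, and the SyntheticTruth.
    Byte-identical for identical designs (same seed).
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n = design.n_genes

    # --- gene index bookkeeping (global across species) -------------------
    n_orth = int(round(design.ortholog_fraction * n))
    orth_idx = np.sort(rng.choice(n, size=n_orth, replace=False))
    orth_set = set(orth_idx.tolist())

    lineages_by_species: dict[str, set[str]] = {
        sp.name: {s.lineage for s in sp.subsets if s.lineage != "none"} for sp in design.species
    }
    all_lineages: list[str] = []
    for sp in design.species:
        for s in sp.subsets:
            if s.lineage != "none" and s.lineage not in all_lineages:
                all_lineages.append(s.lineage)
    shared = [
        lin for lin in all_lineages
        if sum(lin in lins for lins in lineages_by_species.values()) > 1
    ]

    orth_pool = list(rng.permutation(orth_idx))
    non_orth = np.array(sorted(set(range(n)) - orth_set), dtype=int)
    other_pool = list(rng.permutation(non_orth)) if len(non_orth) else []

    marker_idx: dict[str, np.ndarray] = {}
    k = design.n_marker_genes_per_lineage
    for lin in all_lineages:
        if lin in shared:
            take, orth_pool = orth_pool[:k], orth_pool[k:]
        else:
            # species-private lineage: prefer non-orthologous genes
            take = other_pool[:k]
            other_pool = other_pool[k:]
            if len(take) < k:
                extra = k - len(take)
                take, orth_pool = take + orth_pool[:extra], orth_pool[extra:]
        if len(take) < k:
            raise ValueError("gene universe exhausted while placing lineage markers")
        marker_idx[lin] = np.array(sorted(take), dtype=int)
    all_marker = set(int(i) for v in marker_idx.values() for i in v)

    # --- per-species tissue genes, baselines, donors, samples -------------
    matrices: dict[str, ExpressionMatrix] = {}
    tissue_idx: dict[str, dict[str, np.ndarray]] = {}
    gene_ids: dict[str, list[str]] = {}
    for sp in design.species:
        gene_ids[sp.name] = _gene_ids(sp.prefix(), n)
        free = np.array(sorted(set(range(n)) - all_marker), dtype=int)
        pool = list(rng.permutation(free))
        tmap: dict[str, np.ndarray] = {}
        for t in sp.tissues():
            take, pool = pool[: design.n_tissue_genes_per_tissue], pool[design.n_tissue_genes_per_tissue:]
            tmap[t] = np.array(sorted(take), dtype=int)
        tissue_idx[sp.name] = tmap

        baseline = rng.uniform(4.0, 12.0, size=n)
        donor_offset = {d: rng.normal(0.0, design.donor_sd) for d, _ in sp.donors}

        cols: dict[str, np.ndarray] = {}
        anno: dict[str, dict[str, str]] = {}
        for sub in sp.subsets:
            lin_mask = np.zeros(n)
            if sub.lineage != "none":
                lin_mask[marker_idx[sub.lineage]] = 1.0
            for t in sub.tissues:
                t_mask = np.zeros(n)
                t_mask[tmap[t]] = 1.0
                for d in sp.donors_for(t):
                    sample = f"{sub.name}.{t}.{d}"
                    noise = rng.normal(0.0, design.noise_sd, size=n) if design.noise_sd > 0 else np.zeros(n)
                    cols[sample] = (
                        baseline
                        + design.lineage_effect * lin_mask
                        + design.tissue_effect * t_mask
                        + donor_offset[d]
                        + noise
                    )
                    anno[sample] = {
                        "subset": sub.name,
                        "tissue": t,
                        "species": sp.name,
                        "donor": d,
                    }
        values = pd.DataFrame(cols, index=gene_ids[sp.name])
        matrices[sp.name] = ExpressionMatrix(values, pd.DataFrame.from_dict(anno, orient="index"))

    # --- ortholog table between the first two species ---------------------
    pairs: list[tuple[str, str]] = []
    if len(design.species) >= 2:
        a, b = design.species[0], design.species[1]
        for i in orth_idx.tolist():
            pairs.append((gene_ids[a.name][i], gene_ids[b.name][i]))
        if design.one_to_many_rate > 0 and len(non_orth):
            extra_targets = list(rng.permutation(non_orth))
            flips = rng.random(len(orth_idx)) < design.one_to_many_rate
            for i, flip in zip(orth_idx.tolist(), flips.tolist()):
                if flip and extra_targets:
                    j = int(extra_targets.pop())
                    pairs.append((gene_ids[a.name][i], gene_ids[b.name][j]))
    table = OrthologTable.from_pairs(pairs)

    # --- ground truth -----------------------------------------------------
    marker_genes: dict[str, dict[str, tuple[str, ...]]] = {}
    for lin in all_lineages:
        marker_genes[lin] = {
            sp.name: tuple(gene_ids[sp.name][i] for i in marker_idx[lin])
            for sp in design.species
            if lin in lineages_by_species[sp.name]
        }
    tissue_genes = {
        sp.name: {t: tuple(gene_ids[sp.name][i] for i in idx) for t, idx in tissue_idx[sp.name].items()}
        for sp in design.species
    }
    homologous: list[tuple[str, str]] = []
    if len(design.species) >= 2:
        a, b = design.species[0], design.species[1]
        for sa in a.subsets:
            for sb in b.subsets:
                if sa.lineage != "none" and sa.lineage == sb.lineage:
                    homologous.append((sa.name, sb.name))
    truth = SyntheticTruth(
        marker_genes=marker_genes,
        tissue_genes=tissue_genes,
        orthologs=table,
        homologous_subsets=tuple(homologous),
    )
    return matrices, table, truth


# --------------------------------------------------------------------------
# Truth serialization: GMT for gene sets, TSV for pairs.

_MARKERS_FILE = "truth_markers.gmt"
_TISSUE_FILE = "truth_tissue_genes.gmt"
_ORTHOLOG_FILE = "truth_orthologs.tsv"
_HOMOLOG_FILE = "truth_homologous_subsets.tsv"


def write_truth(truth: SyntheticTruth, directory: str | Path, overwrite: bool = False) -> None:
    """Serialize the ground truth into a directory (GMT + TSV files)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = [directory / f for f in (_MARKERS_FILE, _TISSUE_FILE, _ORTHOLOG_FILE, _HOMOLOG_FILE)]
    if not overwrite:
        existing = [str(p) for p in paths if p.exists()]
        if existing:
            raise FileExistsError(f"refusing to overwrite: {existing}")
    marker_sets = [
        GeneSet(name=f"{lin}|{species}", genes=genes, description="lineage markers")
        for lin, per_sp in truth.marker_genes.items()
        for species, genes in per_sp.items()
    ]
    write_gmt(marker_sets, directory / _MARKERS_FILE)
    tissue_sets = [
        GeneSet(name=f"{species}|{tissue}", genes=genes, description="tissue genes")
        for species, per_t in truth.tissue_genes.items()
        for tissue, genes in per_t.items()
    ]
    write_gmt(tissue_sets, directory / _TISSUE_FILE)
    write_orthologs(truth.orthologs, directory / _ORTHOLOG_FILE)
    with open(directory / _HOMOLOG_FILE, "w") as fh:
        fh.write("subset_a\tsubset_b\n")
        for a, b in truth.homologous_subsets:
            fh.write(f"{a}\t{b}\n")


def read_truth(directory: str | Path) -> SyntheticTruth:
    """Read back a truth directory written by :func:`write_truth`."""
    directory = Path(directory)
    marker_genes: dict[str, dict[str, tuple[str, ...]]] = {}
    for s in read_gmt(directory / _MARKERS_FILE):
        lin, species = s.name.split("|", 1)
        marker_genes.setdefault(lin, {})[species] = s.genes
    tissue_genes: dict[str, dict[str, tuple[str, ...]]] = {}
    tissue_path = directory / _TISSUE_FILE
    if tissue_path.exists():
        for s in read_gmt(tissue_path):
            species, tissue = s.name.split("|", 1)
            tissue_genes.setdefault(species, {})[tissue] = s.genes
    orthologs = read_orthologs(directory / _ORTHOLOG_FILE)
    homologous: list[tuple[str, str]] = []
    with open(directory / _HOMOLOG_FILE) as fh:
        next(fh)  # header
        for line in fh:
            line = line.rstrip("\n")
            if line:
                a, b = line.split("\t")
                homologous.append((a, b))
    return SyntheticTruth(
        marker_genes=marker_genes,
        tissue_genes=tissue_genes,
        orthologs=orthologs,
        homologous_subsets=tuple(homologous),
    )
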