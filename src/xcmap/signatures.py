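"""Tissue-gene filtering and rank-based subset signatures.

A subset *signature* is a pair of ordered tag lists — genes most up- and
most down-regulated in the target population relative to all other profiled
populations — ranked by the signal-to-noise ratio

    SNR(g) = (mu_target - mu_rest) / (sd_target' + sd_rest'),
    sd' = max(sd, 0.2 * |mu|, 0.2),

the canonical ranking statistic of the GSEA family.  The variance floor
keeps low-variance genes from dominating the ranking.  Signatures are taken
after removing *tissue-specific* genes — genes differentially expressed
between anatomical sources within matched subsets — so that they reflect
subset identity rather than tissue of origin.

Two tissue-filter methods are provided.  The default fits, per gene, a
blocked linear model (tissue effect plus subset covariates) over all samples
of subsets present in both tissues and applies one Benjamini-Hochberg pass:
pooling the matched subsets is what gives the per-gene test usable power at
microarray-scale replication (a handful of donors per subset).  The
alternative ``per_subset_union`` method runs an independent Welch t test and
BH correction inside each matched subset and unions the significant genes;
it is the more conservative reading of a within-subset contrast but has very
low per-gene power at small donor counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSet

__all__ = [
    "GeneSignature",
    "DifferentialResult",
    "signal_to_noise",
    "welch_t_by_gene",
    "tissue_specific_genes",
    "remove_genes",
    "derive_signature",
    "pool_signature",
    "signature_to_gene_sets",
    "gene_sets_to_signature",
]


@dataclass(frozen=True)
class GeneSignature:
    """Named, disjoint, ordered up/down tag lists for one subset or lineage."""

    name: str
    up: tuple[str, ...]
    down: tuple[str, ...]
    source_subsets: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.up or not self.down:
            raise ValueError(f"signature {self.name!r}: up and down lists must be nonempty")
        if len(set(self.up)) != len(self.up) or len(set(self.down)) != len(self.down):
            raise ValueError(f"signature {self.name!r}: duplicate genes within a tag list")
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"signature {self.name!r}: up/down overlap: {sorted(overlap)[:5]}")


@dataclass(frozen=True)
class DifferentialResult:
    """Per-gene ranking statistics for a target-vs-rest contrast."""

    statistic: pd.Series  # SNR per gene, index = gene ids
    mean_target: pd.Series
    mean_rest: pd.Series
    sd_target: pd.Series
    sd_rest: pd.Series


def _floored_sd(sd: np.ndarray, mu: np.ndarray) -> np.ndarray:
    return np.maximum(sd, np.maximum(0.2 * np.abs(mu), 0.2))


def signal_to_noise(target: np.ndarray, rest: np.ndarray) -> np.ndarray:
    """Vectorized SNR over rows (genes); columns are samples.

    Group standard deviations (population form, so duplicating a sample set
    leaves the statistic exactly unchanged) are floored at
    ``max(0.2*|mean|, 0.2)``, keeping the statistic finite and damping
    low-variance genes.
    """
    mt, mr = target.mean(axis=1), rest.mean(axis=1)
    st = _floored_sd(target.std(axis=1), mt)
    sr = _floored_sd(rest.std(axis=1), mr)
    return (mt - mr) / (st + sr)


def welch_t_by_gene(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample Welch t statistic and two-sided p per gene (rows)."""
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return np.asarray(t), np.asarray(p)


TissueFilterMethod = Literal["blocked", "per_subset_union"]


def tissue_specific_genes(
    m: ExpressionMatrix,
    tissue_a: str,
    tissue_b: str,
    alpha: float = 0.05,
    method: TissueFilterMethod = "blocked",
) -> GeneSet:
    """Genes differentially expressed between two tissues within matched subsets.

    Only subsets present in both tissues (with >= 2 samples per subset-tissue
    cell) contribute.  ``blocked`` (default) fits one per-gene linear model
    with a tissue indicator and subset dummies over all matched samples and
    BH-adjusts the tissue-coefficient p-values at ``alpha``.
    ``per_subset_union`` Welch-tests each matched subset separately,
    BH-adjusts within each subset, and unions the significant genes.
    The result may be empty (no tissue effect); it is deterministic.
    """
    anno = m.annotations
    for t in (tissue_a, tissue_b):
        if t not in set(anno["tissue"]):
            raise ValueError(f"tissue {t!r} not present in annotations")
    matched = []
    for subset in dict.fromkeys(anno["subset"]):
        n_a = ((anno["subset"] == subset) & (anno["tissue"] == tissue_a)).sum()
        n_b = ((anno["subset"] == subset) & (anno["tissue"] == tissue_b)).sum()
        if n_a >= 2 and n_b >= 2:
            matched.append(subset)
    if not matched:
        raise ValueError(
            f"no subset has >=2 samples in both {tissue_a!r} and {tissue_b!r}; "
            "the tissue filter is undefined"
        )

    name = f"tissue_{tissue_a}_vs_{tissue_b}"
    if method == "per_subset_union":
        flagged = np.zeros(m.n_genes, dtype=bool)
        for subset in matched:
            in_sub = anno["subset"] == subset
            a = m.values.loc[:, (in_sub & (anno["tissue"] == tissue_a)).to_numpy()].to_numpy()
            b = m.values.loc[:, (in_sub & (anno["tissue"] == tissue_b)).to_numpy()].to_numpy()
            _, p = welch_t_by_gene(a, b)
            flagged |= multipletests(p, alpha, method="fdr_bh")[0]
        genes = tuple(g for g, f in zip(m.gene_ids, flagged) if f)
        return GeneSet(name=name, genes=genes, description=method)
    if method != "blocked":
        raise ValueError(f"unknown tissue filter method {method!r}")

    keep = anno["subset"].isin(matched) & anno["tissue"].isin([tissue_a, tissue_b])
    sub = m.select_samples(keep)
    tissue = (sub.annotations["tissue"] == tissue_a).to_numpy(dtype=float)
    subset_labels = sub.annotations["subset"].to_numpy()
    dummies = [
        (subset_labels == s).astype(float) for s in matched[1:]
    ]
    X = np.column_stack([np.ones(sub.n_samples), tissue, *dummies])
    Y = sub.values.to_numpy()  # genes x samples
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ XtX_inv.T
    resid = Y - beta @ X.T
    df_resid = X.shape[0] - X.shape[1]
    if df_resid < 1:
        raise ValueError("not enough samples for the blocked tissue model")
    sigma2 = (resid**2).sum(axis=1) / df_resid
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta[:, 1] / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
    flagged = multipletests(pvals, alpha, method="fdr_bh")[0]
    genes = tuple(g for g, f in zip(sub.gene_ids, flagged) if f)
    return GeneSet(name=name, genes=genes, description=method)


def remove_genes(m: ExpressionMatrix, s: GeneSet | Sequence[str]) -> ExpressionMatrix:
    """Drop the rows in ``s``; the order of remaining genes is preserved.

    Removing an empty set is the identity; removing everything is an error.
    """
    drop = set(s.genes) if isinstance(s, GeneSet) else set(s)
    keep = [g for g in m.gene_ids if g not in drop]
    if not keep:
        raise ValueError("gene removal would empty the matrix")
    return ExpressionMatrix(m.values.loc[keep].copy(), m.annotations.copy())


def _ranked_statistic(
    target_values: np.ndarray, rest_values: np.ndarray, gene_ids: Sequence[str]
) -> pd.Series:
    snr = signal_to_noise(target_values, rest_values)
    # descending statistic, ties broken by gene id (lexicographic ascending)
    order = np.lexsort((np.array(gene_ids), -snr))
    return pd.Series(snr[order], index=np.array(gene_ids)[order])


def differential_result(
    m: ExpressionMatrix, target_mask: np.ndarray
) -> DifferentialResult:
    """Full target-vs-rest SNR table (unordered, matrix gene order)."""
    tv = m.values.loc[:, target_mask].to_numpy()
    rv = m.values.loc[:, ~target_mask].to_numpy()
    mt, mr = tv.mean(axis=1), rv.mean(axis=1)
    st, sr = tv.std(axis=1), rv.std(axis=1)
    snr = (mt - mr) / (_floored_sd(st, mt) + _floored_sd(sr, mr))
    idx = m.values.index
    return DifferentialResult(
        statistic=pd.Series(snr, index=idx),
        mean_target=pd.Series(mt, index=idx),
        mean_rest=pd.Series(mr, index=idx),
        sd_target=pd.Series(st, index=idx),
        sd_rest=pd.Series(sr, index=idx),
    )


def derive_signature(
    m: ExpressionMatrix,
    target: str,
    size: int = 150,
    target_tissue: str | None = None,
    name: str | None = None,
) -> GeneSignature:
    """Signature of ``target`` (optionally restricted to one tissue) vs rest.

    The up list holds the ``size`` genes with the largest SNR (descending);
    the down list the ``size`` smallest (ascending, most negative first).
    Ties are broken by gene id so the result is fully deterministic.
    """
    anno = m.annotations
    mask = (anno["subset"] == target).to_numpy()
    if target_tissue is not None:
        mask &= (anno["tissue"] == target_tissue).to_numpy()
    if mask.sum() < 2:
        raise ValueError(f"target {target!r} (tissue={target_tissue!r}) has < 2 samples")
    if (~mask).sum() < 1 or anno.loc[~mask, "subset"].nunique() < 1:
        raise ValueError("no non-target subset to contrast against")
    if m.n_genes < 2 * size:
        raise ValueError(f"need >= {2 * size} genes for a size-{size} signature, have {m.n_genes}")
    ranked = _ranked_statistic(
        m.values.loc[:, mask].to_numpy(), m.values.loc[:, ~mask].to_numpy(), m.gene_ids
    )
    up = tuple(ranked.index[:size])
    down = tuple(ranked.index[::-1][:size])
    label = name or (f"{target}.{target_tissue}" if target_tissue else target)
    return GeneSignature(name=label, up=up, down=down, source_subsets=frozenset([target]))


def pool_signature(
    matrices: Sequence[ExpressionMatrix],
    targets: Sequence[str],
    size: int = 150,
    target_tissues: Sequence[str | None] | None = None,
    name: str | None = None,
) -> GeneSignature:
    """Pooled lineage signature: the listed targets' samples (one target per
    matrix entry) are concatenated as the target class; all other samples of
    all matrices form the rest class.  Matrices must share the same gene
    space in the same order."""
    if len(matrices) != len(targets):
        raise ValueError("matrices and targets must have equal length")
    if target_tissues is None:
        target_tissues = [None] * len(targets)
    ref_genes = matrices[0].gene_ids
    for m in matrices[1:]:
        if m.gene_ids != ref_genes:
            diff = len(set(m.gene_ids) ^ set(ref_genes))
            raise ValueError(f"gene spaces differ (symmetric difference of {diff} genes)")
    size_ok = len(ref_genes) >= 2 * size
    if not size_ok:
        raise ValueError(f"need >= {2 * size} genes for a size-{size} signature")
    target_cols: list[np.ndarray] = []
    rest_cols: list[np.ndarray] = []
    for m, target, tissue in zip(matrices, targets, target_tissues):
        anno = m.annotations
        mask = (anno["subset"] == target).to_numpy()
        if tissue is not None:
            mask &= (anno["tissue"] == tissue).to_numpy()
        if not mask.any():
            raise ValueError(f"target {target!r} not present in its matrix")
        target_cols.append(m.values.loc[:, mask].to_numpy())
        rest_cols.append(m.values.loc[:, ~mask].to_numpy())
    tv = np.hstack(target_cols)
    rv = np.hstack(rest_cols)
    if tv.shape[1] < 2:
        raise ValueError("pooled target class has < 2 samples")
    ranked = _ranked_statistic(tv, rv, ref_genes)
    up = tuple(ranked.index[:size])
    down = tuple(ranked.index[::-1][:size])
    label = name or "+".join(dict.fromkeys(targets))
    return GeneSignature(
        name=label, up=up, down=down, source_subsets=frozenset(targets)
    )


def signature_to_gene_sets(sig: GeneSignature) -> list[GeneSet]:
    """Serialize as two GMT records, names suffixed ``_UP`` / ``_DN``."""
    desc = ",".join(sorted(sig.source_subsets)) or "na"
    return [
        GeneSet(name=f"{sig.name}_UP", genes=sig.up, description=desc),
        GeneSet(name=f"{sig.name}_DN", genes=sig.down, description=desc),
    ]


def gene_sets_to_signature(sets: Sequence[GeneSet], name: str) -> GeneSignature:
    """Rebuild a signature from its ``_UP`` / ``_DN`` GMT records."""
    by_name = {s.name: s for s in sets}
    up = by_name.get(f"{name}_UP")
    down = by_name.get(f"{name}_DN")
    if up is None or down is None:
        raise ValueError(f"GMT is missing {name}_UP or {name}_DN")
    sources = frozenset(up.description.split(",")) if up.description not in ("", "na") else frozenset()
    return GeneSignature(name=name, up=up.genes, down=down.genes, source_subsets=sources)
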