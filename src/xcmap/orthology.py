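"""Ortholog tables and cross-species translation of gene signatures.

A signature derived in one species (e.g. human) is translated into the gene
space of another (e.g. mouse) through an ortholog pair table so it can be
scored against that species' expression profiles.  Ortholog relations may be
many-to-many; the default policy keeps only reciprocally unique (1:1) pairs,
because expanding paralog families inflates tag-set sizes and biases the
rank-based enrichment statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from .signatures import GeneSignature

__all__ = [
    "OrthologTable",
    "MappedSignature",
    "read_orthologs",
    "write_orthologs",
    "map_signature",
]


@dataclass(frozen=True)
class OrthologTable:
    """Directed gene-id pairs (source species -> target species) with
    lookup indices in both directions.  Duplicate pairs are rejected at
    construction; use :meth:`from_pairs` to deduplicate with a warning."""

    pairs: tuple[tuple[str, str], ...]
    forward: dict[str, tuple[str, ...]] = field(init=False, repr=False, compare=False)
    backward: dict[str, tuple[str, ...]] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        fwd: dict[str, list[str]] = {}
        bwd: dict[str, list[str]] = {}
        seen: set[tuple[str, str]] = set()
        for a, b in self.pairs:
            if not a or not b:
                raise ValueError(f"empty gene id in ortholog pair {(a, b)!r}")
            if (a, b) in seen:
                raise ValueError(f"duplicate ortholog pair {(a, b)!r}")
            seen.add((a, b))
            fwd.setdefault(a, []).append(b)
            bwd.setdefault(b, []).append(a)
        object.__setattr__(self, "forward", {k: tuple(v) for k, v in fwd.items()})
        object.__setattr__(self, "backward", {k: tuple(v) for k, v in bwd.items()})

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "OrthologTable":
        materialized = [tuple(p) for p in pairs]
        uniq = list(dict.fromkeys(materialized))
        if len(uniq) < len(materialized):
            warnings.warn("duplicate ortholog pairs were dropped", stacklevel=2)
        return cls(pairs=tuple(uniq))

    def __len__(self) -> int:
        return len(self.pairs)

    def targets(self, gene: str) -> tuple[str, ...]:
        return self.forward.get(gene, ())

    def sources(self, gene: str) -> tuple[str, ...]:
        return self.backward.get(gene, ())


def read_orthologs(path: str | Path) -> OrthologTable:
    """Read a two-column tab-delimited ortholog file (header required)."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        header = fh.readline()
        if "\t" not in header:
            raise ValueError(f"{path}: line 1: expected a two-column tab-delimited header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}: line {lineno}: expected exactly two nonempty fields")
            pairs.append((fields[0], fields[1]))
    return OrthologTable.from_pairs(pairs)


def write_orthologs(table: OrthologTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("human_gene\tmouse_gene\n")
        for a, b in table.pairs:
            fh.write(f"{a}\t{b}\n")


@dataclass(frozen=True)
class MappedSignature:
    """A translated signature plus the fraction of each tag list retained."""

    signature: GeneSignature
    retention_up: float
    retention_down: float


Policy = Literal["one_to_one_only", "expand_all"]


def map_signature(
    sig: GeneSignature,
    table: OrthologTable,
    policy: Policy = "one_to_one_only",
    min_retention: float = 0.2,
) -> MappedSignature:
    """Translate a signature into the target species' gene space.

    one_to_one_only
        A gene is translated only if it has exactly one ortholog that maps
        back uniquely; everything else is dropped.
    expand_all
        Every ortholog of every gene is included, in source order.

    A target gene landing in both the up and the down list is removed from
    both (a gene cannot be proximal and distal evidence at once).  If either
    translated list retains less than ``min_retention`` of its source genes
    the signature is deemed no longer representative and an error is raised.
    """
    if policy not in ("one_to_one_only", "expand_all"):
        raise ValueError(f"unknown orthology policy {policy!r}")

    def translate(genes: tuple[str, ...]) -> list[str]:
        out: list[str] = []
        for g in genes:
            targets = table.targets(g)
            if policy == "one_to_one_only":
                if len(targets) == 1 and len(table.sources(targets[0])) == 1:
                    out.append(targets[0])
            else:
                out.extend(targets)
        return list(dict.fromkeys(out))  # keep first occurrence

    up = translate(sig.up)
    down = translate(sig.down)
    conflicts = set(up) & set(down)
    if conflicts:
        warnings.warn(
            f"{len(conflicts)} gene(s) mapped into both tag lists and were removed: "
            f"{sorted(conflicts)[:5]}...",
            stacklevel=2,
        )
        up = [g for g in up if g not in conflicts]
        down = [g for g in down if g not in conflicts]
    r_up = len(up) / len(sig.up)
    r_down = len(down) / len(sig.down)
    if r_up < min_retention or r_down < min_retention:
        raise ValueError(
            f"ortholog mapping retained up={r_up:.2f}, down={r_down:.2f} of signature "
            f"{sig.name!r}; below the representativeness floor {min_retention}"
        )
    mapped = GeneSignature(
        name=f"{sig.name}|mapped",
        up=tuple(up),
        down=tuple(down),
        source_subsets=sig.source_subsets,
    )
    return MappedSignature(signature=mapped, retention_up=r_up, retention_down=r_down)
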