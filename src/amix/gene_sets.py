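"""Polygenic-phenotype gene sets: GMT parsing, filtering, LD pruning.

A phenotype gene set collects the genes harboring genome-wide-significant
GWAS associations for one trait.  Sets are grouped into the functional
categories used throughout: anthropometric, neurological, HLA, or other.
Before meta-analysis, sets are restricted to genes that survived the
ancestry-genotype threshold and pruned so that no retained pair of genes is
in linkage disequilibrium (max inter-genic SNP r-squared above a cutoff,
from a precomputed table).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

CATEGORIES = ("anthropometric", "neurological", "HLA", "other")


@dataclass(frozen=True, slots=True)
class GeneSet:
    phenotype_id: str
    category: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"{self.phenotype_id}: duplicate gene ids")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.phenotype_id}: unknown category {self.category!r}")


def _parse_category(description: str) -> str:
    token = description.strip().split()[0].lower() if description.strip() else ""
    for cat in CATEGORIES:
        if token == cat.lower():
            return cat
    return "other"


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read GMT: per line, set name, description (category token), genes.

    Duplicate genes within a set are collapsed with a warning; lines with no
    genes are skipped with a warning.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d: empty gene set %r skipped", path, lineno,
                               fields[0] if fields else "")
                continue
            name, description = fields[0], fields[1]
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    logger.warning("%s:%d: duplicate gene %s in set %s collapsed",
                                   path, lineno, g, name)
                    continue
                seen.add(g)
                genes.append(g)
            if not genes:
                logger.warning("%s:%d: empty gene set %r skipped", path, lineno, name)
                continue
            sets.append(GeneSet(name, _parse_category(description), tuple(genes)))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.phenotype_id, s.category, *s.gene_ids]) + "\n")


def filter_gene_sets(
    sets: Sequence[GeneSet],
    callable_genes: Iterable[str],
    min_size: int = 2,
) -> list[GeneSet]:
    """Restrict sets to callable genes; drop sets below ``min_size`` genes.

    Polygenic phenotypes are analyzed by meta-analysis over their genes, so
    a set needs at least two informative genes to be meaningful.
    """
    callable_set = set(callable_genes)
    if not callable_set:
        raise ValueError("no callable genes in any set")
    out: list[GeneSet] = []
    for s in sets:
        kept = tuple(g for g in s.gene_ids if g in callable_set)
        if len(kept) < min_size:
            logger.info("set %s dropped: %d callable genes < min_size %d",
                        s.phenotype_id, len(kept), min_size)
            continue
        out.append(replace(s, gene_ids=kept))
    return out


def read_ld_table(path: str | Path) -> dict[frozenset[str], float]:
    """Read TSV (gene_a, gene_b, r2) of max inter-genic SNP r-squared."""
    table: dict[frozenset[str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            a, b, r2 = fields[0], fields[1], float(fields[2])
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"{path}:{lineno}: r2 {r2} outside [0, 1]")
            table[frozenset((a, b))] = max(r2, table.get(frozenset((a, b)), 0.0))
    return table


def ld_prune_gene_sets(
    sets: Sequence[GeneSet],
    ld_table: Mapping[frozenset[str], float],
    r2_max: float = 0.1,
    min_size: int = 2,
) -> list[GeneSet]:
    """Greedily break up gene pairs in linkage disequilibrium, within each set.

    Offending pairs (r2 above ``r2_max``) are processed in decreasing r2; of
    each pair still intact, the later-listed gene is dropped.  The earlier
    gene is kept so the procedure is deterministic given the set's gene
    order.  After pruning, no retained pair exceeds ``r2_max``; sets falling
    below ``min_size`` are dropped.
    """
    for pair, r2 in ld_table.items():
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 {r2} for pair {sorted(pair)} outside [0, 1]")
    out: list[GeneSet] = []
    for s in sets:
        order = {g: i for i, g in enumerate(s.gene_ids)}
        offending = [
            (r2, tuple(sorted(pair, key=order.__getitem__)))
            for pair, r2 in ld_table.items()
            if r2 > r2_max and pair <= set(s.gene_ids)
        ]
        # decreasing r2; gene order as deterministic tie-break
        offending.sort(key=lambda x: (-x[0], order[x[1][0]], order[x[1][1]]))
        kept = set(s.gene_ids)
        for r2, (first, later) in offending:
            if first in kept and later in kept:
                kept.discard(later)
                logger.info("set %s: dropped %s (r2 %.3f with %s)",
                            s.phenotype_id, later, r2, first)
        genes = tuple(g for g in s.gene_ids if g in kept)
        if len(genes) < min_size:
            logger.info("set %s dropped after LD pruning (%d genes)",
                        s.phenotype_id, len(genes))
            continue
        out.append(replace(s, gene_ids=genes))
    return out
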