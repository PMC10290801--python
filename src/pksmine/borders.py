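"""Coregulation-based cluster-border calling.

Fungal BGC borders are rarely obvious from sequence alone; what marks
them in practice is the coordinated switch of transcription.  Here the
"producing pattern" — silent during active growth (24 h), expressed in
stationary phase (48 h) — serves as the coregulation signature.  Border
calling starts from the inclusive interval between the two anchor PKS
genes, demands that every interior gene shows the pattern, and then
walks outward gene by gene in both directions until the first gene that
breaks the pattern (or the scaffold ends).  Gap tolerance is zero: a
single non-matching gene terminates extension on that side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .expression import ExpressionRecord
from .genome import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "BorderCall",
    "ClusterInterruptedError",
    "producing_pattern",
    "call_borders",
    "write_border_gff",
]


class ClusterInterruptedError(ValueError):
    """An interior gene between the anchors violates the coregulation pattern."""

    def __init__(self, gene_id: str):
        self.gene_id = gene_id
        super().__init__(
            f"cluster interrupted: interior gene {gene_id} does not show the "
            "producing pattern"
        )


def producing_pattern(record: ExpressionRecord) -> bool:
    """Silent at 24 h and expressed at 48 h — the producing signature."""
    return (not record.expressed_24h) and record.expressed_48h


def _significant_producing_pattern(record: ExpressionRecord) -> bool:
    return producing_pattern(record) and record.significant


@dataclass(frozen=True)
class BorderCall:
    scaffold: str
    gene_ids: tuple[str, ...]
    anchor_ids: tuple[str, str]
    pattern: str = "producing_pattern"

    @property
    def first_gene_id(self) -> str:
        return self.gene_ids[0]

    @property
    def last_gene_id(self) -> str:
        return self.gene_ids[-1]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def call_borders(
    genes_on_scaffold: Sequence[GeneModel],
    records: Mapping[str, ExpressionRecord],
    anchors: tuple[str, str],
    require_significant: bool = False,
) -> BorderCall:
    """Call BGC borders around an anchor PKS pair by coregulation.

    ``genes_on_scaffold`` must be the coordinate-ordered genes of one
    scaffold.  Both anchors must be present and satisfy the pattern; an
    interior violation raises :class:`ClusterInterruptedError`.  With
    ``require_significant`` the pattern additionally demands the
    differential test's significance flag for each gene.
    """
    pattern: Callable[[ExpressionRecord], bool]
    if require_significant:
        pattern, pattern_name = _significant_producing_pattern, "producing_pattern+significant"
    else:
        pattern, pattern_name = producing_pattern, "producing_pattern"

    scaffolds = {g.scaffold for g in genes_on_scaffold}
    if len(scaffolds) != 1:
        raise ValueError("genes_on_scaffold must come from exactly one scaffold")
    starts = [g.start for g in genes_on_scaffold]
    if starts != sorted(starts):
        raise ValueError("genes must be in coordinate order")

    index = {g.gene_id: i for i, g in enumerate(genes_on_scaffold)}
    for anchor in anchors:
        if anchor not in index:
            raise ValueError(f"anchor {anchor} not on scaffold")
        if anchor not in records:
            raise KeyError(f"no expression record for anchor {anchor}")
        if not pattern(records[anchor]):
            raise ValueError(f"anchor {anchor} fails the coregulation pattern")
    lo, hi = sorted(index[a] for a in anchors)

    def matches(i: int) -> bool:
        gene = genes_on_scaffold[i]
        if gene.gene_id not in records:
            raise KeyError(f"no expression record for gene {gene.gene_id}")
        return pattern(records[gene.gene_id])

    for i in range(lo + 1, hi):
        if not matches(i):
            raise ClusterInterruptedError(genes_on_scaffold[i].gene_id)
    while lo > 0 and matches(lo - 1):
        lo -= 1
    while hi < len(genes_on_scaffold) - 1 and matches(hi + 1):
        hi += 1
    if lo == 0 and hi == len(genes_on_scaffold) - 1:
        logger.warning(
            "border call spans the whole scaffold %s; borders are unresolved",
            genes_on_scaffold[0].scaffold,
        )
    return BorderCall(
        scaffold=genes_on_scaffold[0].scaffold,
        gene_ids=tuple(g.gene_id for g in genes_on_scaffold[lo : hi + 1]),
        anchor_ids=(anchors[0], anchors[1]),
        pattern=pattern_name,
    )


def write_border_gff(
    call: BorderCall, genes: Sequence[GeneModel], path
) -> None:
    """Emit the called span as a GFF3 ``biosynthetic_gene_cluster`` feature."""
    by_id = {g.gene_id: g for g in genes}
    first = by_id[call.first_gene_id]
    last = by_id[call.last_gene_id]
    start = min(first.start, last.start)
    end = max(first.end, last.end)
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        out.write(
            "\t".join(
                [
                    call.scaffold, "pksmine", "biosynthetic_gene_cluster",
                    str(start), str(end), ".", ".", ".",
                    f"ID=bgc_{call.first_gene_id}_{call.last_gene_id};"
                    f"anchors={call.anchor_ids[0]},{call.anchor_ids[1]};"
                    f"n_genes={call.n_genes};pattern={call.pattern}",
                ]
            )
            + "\n"
        )
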