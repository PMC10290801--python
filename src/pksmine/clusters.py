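"""Cluster assembly and candidate-BGC selection.

Contiguous genes are grouped into clusters either by a supplied cluster
assignment (e.g. antiSMASH region ids carried in the gene table) or by
an explicit intergenic-distance rule.  A cluster becomes a candidate for
a two-chain polyketide pathway when it holds at least two PKS genes
whose domain architecture covers the retro-derived requirement and — if
the compound is an ester of two chains — a transferase gene.  The
transcriptome then arbitrates: the candidate whose anchor PKS pair is
expressed under the producing condition outranks silent candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .expression import ExpressionRecord, LOG2_RPKM_THRESHOLD
from .genome import GeneModel, matches_required

__all__ = [
    "GeneCluster",
    "CandidateBGC",
    "RSF_ROLES",
    "group_clusters",
    "find_candidates",
    "apply_expression_filter",
    "DEFAULT_MAX_GAP_BP",
    "TRANSFERASE_DOMAINS",
]

DEFAULT_MAX_GAP_BP = 10_000
TRANSFERASE_DOMAINS = frozenset({"OAT", "cAT"})

#: The experimentally verified rasfonin cluster: gene ids and roles of
#: rsf1-rsf9 (DNG_02774..DNG_02782).  Used to annotate a winning cluster
#: and as the template the synthetic generator plants.
RSF_ROLES: Mapping[str, tuple[str, str]] = {
    "rsf1": ("DNG_02774", "HR-PKS (CgPKS4)"),
    "rsf2": ("DNG_02775", "cytochrome P450"),
    "rsf3": ("DNG_02776", "O-acyltransferase"),
    "rsf4": ("DNG_02777", "MFS1 transporter"),
    "rsf5": ("DNG_02778", "trans-thioesterase (FSH domain, alpha/beta-hydrolase fold)"),
    "rsf6": ("DNG_02779", "cytochrome P450"),
    "rsf7": ("DNG_02780", "uncharacterised protein"),
    "rsf8": ("DNG_02781", "cytochrome P450"),
    "rsf9": ("DNG_02782", "HR-PKS (CgPKS5)"),
}


@dataclass(frozen=True)
class GeneCluster:
    cluster_id: str
    scaffold: str
    genes: tuple[GeneModel, ...]
    source: str = "distance_grouping"  # or "given"

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if not self.genes:
            raise ValueError("empty cluster")
        if any(g.scaffold != self.scaffold for g in self.genes):
            raise ValueError(f"cluster {self.cluster_id}: genes on multiple scaffolds")
        starts = [g.start for g in self.genes]
        if starts != sorted(starts):
            raise ValueError(f"cluster {self.cluster_id}: genes not in coordinate order")

    @property
    def start(self) -> int:
        return self.genes[0].start

    @property
    def end(self) -> int:
        return self.genes[-1].end

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.genes)


@dataclass(frozen=True)
class CandidateBGC:
    cluster: GeneCluster
    matching_pks: tuple[str, ...]
    has_transferase: bool
    expression_verdict: str = "other"  # producing_pattern | silent | other
    rank: int | None = None


def _check_sorted(genes: Sequence[GeneModel]) -> None:
    keys = [(g.scaffold, g.start) for g in genes]
    if keys != sorted(keys):
        raise ValueError("genes must be sorted by (scaffold, start)")


def group_clusters(
    genes: Sequence[GeneModel],
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
    use_given: bool = True,
) -> list[GeneCluster]:
    """Partition genes into clusters.

    If the gene table carries cluster assignments (``cluster_id``) and
    ``use_given`` is true, those are passed through (genes without an
    assignment are clusterless, mirroring region callers that leave most
    of a genome unassigned).  Otherwise maximal runs of same-scaffold
    genes whose intergenic distance is at most ``max_gap_bp`` form the
    clusters.  Every gene lands in at most one cluster.
    """
    _check_sorted(genes)
    if use_given and any(g.cluster_id is not None for g in genes):
        by_id: dict[str, list[GeneModel]] = {}
        for g in genes:
            if g.cluster_id is not None:
                by_id.setdefault(g.cluster_id, []).append(g)
        clusters = [
            GeneCluster(cid, members[0].scaffold, tuple(members), source="given")
            for cid, members in by_id.items()
        ]
        clusters.sort(key=lambda c: (c.scaffold, c.start))
        return clusters
    if max_gap_bp <= 0:
        raise ValueError("max_gap_bp must be positive")
    clusters: list[GeneCluster] = []
    run: list[GeneModel] = []
    for g in genes:
        if run and (
            g.scaffold != run[-1].scaffold or g.start - run[-1].end > max_gap_bp
        ):
            clusters.append(_close_run(run, len(clusters)))
            run = []
        run.append(g)
    if run:
        clusters.append(_close_run(run, len(clusters)))
    return clusters


def _close_run(run: list[GeneModel], index: int) -> GeneCluster:
    return GeneCluster(
        cluster_id=f"cluster_{index + 1:03d}",
        scaffold=run[0].scaffold,
        genes=tuple(run),
        source="distance_grouping",
    )


def find_candidates(
    clusters: Iterable[GeneCluster],
    required: Iterable[str],
    require_transferase: bool = True,
) -> list[CandidateBGC]:
    """Clusters holding >= 2 architecture-matching PKSs (+ a transferase).

    Shrinking ``required`` can only grow the candidate list (matching is
    set containment).  Output order is deterministic: scaffold, then
    cluster start coordinate.
    """
    required = frozenset(required)
    candidates = []
    for cluster in clusters:
        matching = tuple(
            g.gene_id for g in cluster.genes if matches_required(g.architecture, required)
        )
        if len(matching) < 2:
            continue
        has_transferase = any(
            set(g.architecture) & TRANSFERASE_DOMAINS for g in cluster.genes
        )
        if require_transferase and not has_transferase:
            continue
        candidates.append(
            CandidateBGC(
                cluster=cluster,
                matching_pks=matching,
                has_transferase=has_transferase,
            )
        )
    candidates.sort(key=lambda c: (c.cluster.scaffold, c.cluster.start))
    return candidates


def apply_expression_filter(
    candidates: Sequence[CandidateBGC],
    records: Mapping[str, ExpressionRecord],
    producing_condition: str = "48h",
) -> list[CandidateBGC]:
    """Rank candidates by the expression of their matching PKS pair.

    Verdicts: ``producing_pattern`` if every matching PKS is expressed at
    the producing condition; ``silent`` if none is expressed at either
    time point; ``other`` in between.  Producing-pattern candidates rank
    first; ties break by scaffold then start coordinate.  A candidate
    gene without an expression record is an error.
    """
    if producing_condition not in ("24h", "48h"):
        raise ValueError("producing_condition must be '24h' or '48h'")
    attr = f"expressed_{producing_condition}"
    verdicts = []
    for cand in candidates:
        for gene_id in cand.matching_pks:
            if gene_id not in records:
                raise KeyError(f"no expression record for candidate gene {gene_id}")
        recs = [records[g] for g in cand.matching_pks]
        if all(getattr(r, attr) for r in recs):
            verdict = "producing_pattern"
        elif not any(r.expressed_24h or r.expressed_48h for r in recs):
            verdict = "silent"
        else:
            verdict = "other"
        verdicts.append(replace(cand, expression_verdict=verdict))
    order = {"producing_pattern": 0, "other": 1, "silent": 2}
    verdicts.sort(
        key=lambda c: (
            order[c.expression_verdict],
            c.cluster.scaffold,
            c.cluster.start,
        )
    )
    return [replace(c, rank=i + 1) for i, c in enumerate(verdicts)]
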