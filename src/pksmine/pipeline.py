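"""End-to-end orchestration: retro-decomposition to border call.

``predict`` runs the full inference chain on a gene table and a count
matrix: derive the required PKS domain inventory from the compound
description, group genes into clusters, keep clusters with two matching
PKSs (plus a transferase when the compound is an ester of two chains),
rank candidates by the producing expression pattern, and call the
cluster borders around the winning PKS pair by coregulation.  ``report``
renders the resulting bundle as a human-readable summary including the
expression-category tally of backbone genes and, for a winning cluster,
the proposed pathway steps annotated with the cluster's own genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import borders as _borders
from . import chem, clusters as _clusters, expression as _expression
from .borders import BorderCall, ClusterInterruptedError
from .clusters import CandidateBGC, GeneCluster, DEFAULT_MAX_GAP_BP
from .expression import CountMatrix, ExpressionRecord
from .genome import GeneModel, classify_backbone

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PredictionResult", "PATHWAY_STEPS", "predict", "report"]

#: The proposed biosynthetic route, step by step, with catalyst classes.
#: Role keys match the architecture-derived role labels of cluster genes.
PATHWAY_STEPS: tuple[tuple[str, str], ...] = (
    ("polyketide chain assembly (hexaketide + tetraketide)", "HR-PKS"),
    ("chain release / alpha-pyrone formation", "trans-thioesterase"),
    ("C4 hydroxylation of the pyrone chain", "cytochrome P450"),
    ("transacylation: ester linkage of the two chains", "O-acyltransferase"),
    ("C8'/C10' hydroxylation of the tetraketide moiety", "cytochrome P450"),
    ("product transport / compartmentalisation", "MFS transporter"),
)

_ROLE_BY_DOMAIN = (
    ("KS", "HR-PKS"),
    ("OAT", "O-acyltransferase"),
    ("cAT", "O-acyltransferase"),
    ("TE_FSH", "trans-thioesterase"),
    ("P450", "cytochrome P450"),
    ("MFS", "MFS transporter"),
)


@dataclass(frozen=True)
class PipelineConfig:
    producing_condition: str = "48h"
    max_gap_bp: int = DEFAULT_MAX_GAP_BP
    required_override: frozenset[str] | None = None
    require_transferase: bool | None = None  # None: inferred from compound
    require_significant_borders: bool = False

    def __post_init__(self) -> None:
        if self.max_gap_bp <= 0:
            raise ValueError("max_gap_bp must be positive")


@dataclass
class PredictionResult:
    retro: chem.RetroReport
    required: frozenset[str]
    clusters: list[GeneCluster]
    candidates: list[CandidateBGC]
    expression: pd.DataFrame
    records: dict[str, ExpressionRecord]
    border_call: BorderCall | None
    status: str  # "ok" | "no_candidate" | "ambiguous" | "interrupted"

    @property
    def winner(self) -> CandidateBGC | None:
        producing = [
            c for c in self.candidates if c.expression_verdict == "producing_pattern"
        ]
        return producing[0] if producing else None


def predict(
    genes: Sequence[GeneModel],
    cm: CountMatrix,
    compound: chem.CompoundSpec | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> PredictionResult:
    """Run the whole inference chain; see the module docstring."""
    compound = compound or chem.rasfonin_compound()
    retro = chem.retro_compound(compound)
    required = config.required_override or retro.all_required_domains
    logger.info("required domain set: %s", sorted(required))

    gene_ids = {g.gene_id for g in genes}
    missing = gene_ids - set(cm.gene_ids)
    if missing:
        raise ValueError(
            f"{len(missing)} genes lack counts, e.g. {sorted(missing)[:5]}"
        )

    require_transferase = config.require_transferase
    if require_transferase is None:
        require_transferase = "O-acyltransferase" in retro.post_pks_enzymes
    logger.info(
        "thresholds: log2RPKM >= %.1f, p < %.2f, |log2FC| >= %.1f, max gap %d bp",
        _expression.LOG2_RPKM_THRESHOLD, _expression.P_CUTOFF,
        _expression.STRONG_LOG2FC, config.max_gap_bp,
    )

    cluster_list = _clusters.group_clusters(list(genes), max_gap_bp=config.max_gap_bp)
    candidates = _clusters.find_candidates(
        cluster_list, required, require_transferase=require_transferase
    )
    table = _expression.expression_table(cm)
    records = _expression.expression_records(table)
    ranked = _clusters.apply_expression_filter(
        candidates, records, producing_condition=config.producing_condition
    )

    producing = [c for c in ranked if c.expression_verdict == "producing_pattern"]
    border_call = None
    status = "ok"
    if not producing:
        status = "no_candidate"
    else:
        if len(producing) > 1:
            status = "ambiguous"
        top = producing[0]
        anchors = (top.matching_pks[0], top.matching_pks[-1])
        scaffold_genes = sorted(
            (g for g in genes if g.scaffold == top.cluster.scaffold),
            key=lambda g: g.start,
        )
        try:
            border_call = _borders.call_borders(
                scaffold_genes, records, anchors,
                require_significant=config.require_significant_borders,
            )
        except ClusterInterruptedError as exc:
            logger.warning("border call failed: %s", exc)
            status = "interrupted"
    return PredictionResult(
        retro=retro,
        required=frozenset(required),
        clusters=cluster_list,
        candidates=ranked,
        expression=table,
        records=records,
        border_call=border_call,
        status=status,
    )


def _gene_role(gene: GeneModel) -> str:
    arch = set(gene.architecture)
    for domain, role in _ROLE_BY_DOMAIN:
        if domain in arch:
            return role
    return "unknown"


def candidate_table(result: PredictionResult) -> pd.DataFrame:
    """Candidate report: one row per candidate, deterministic order."""
    rows = []
    for c in result.candidates:
        rows.append(
            {
                "cluster_id": c.cluster.cluster_id,
                "scaffold": c.cluster.scaffold,
                "span": f"{c.cluster.start}-{c.cluster.end}",
                "matching_pks": ",".join(c.matching_pks),
                "has_transferase": c.has_transferase,
                "verdict": c.expression_verdict,
                "rank": c.rank,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "scaffold", "span", "matching_pks",
            "has_transferase", "verdict", "rank",
        ],
    )


def report(result: PredictionResult) -> str:
    """Human-readable markdown summary of a prediction bundle."""
    lines = ["# BGC prediction report", ""]
    req = ",".join(sorted(result.required))
    lines.append(f"Required domain set: {req}")
    enz = ", ".join(
        f"{name} x{n}" for name, n in sorted(result.retro.post_pks_enzymes.items())
    )
    lines.append(f"Post-PKS enzyme demands: {enz or 'none'}")
    lines.append(f"Clusters examined: {len(result.clusters)}")
    lines.append("")

    lines.append("## Backbone-gene expression categories")
    backbone = [
        g for c in result.clusters for g in c.genes
        if classify_backbone(g.architecture).clazz != "none"
    ]
    tally = {"Cat1": 0, "Cat2": 0, "Cat3": 0}
    for g in backbone:
        rec = result.records.get(g.gene_id)
        if rec is not None:
            tally[rec.category] += 1
    total = sum(tally.values())
    lines.append(
        f"Cat1 (silent at both): {tally['Cat1']}; "
        f"Cat2 (expressed at one): {tally['Cat2']}; "
        f"Cat3 (expressed at both): {tally['Cat3']}; total backbone genes: {total}"
    )
    lines.append("")

    lines.append("## Candidates")
    table = candidate_table(result)
    if table.empty:
        lines.append("no candidate")
    else:
        lines.append(table.to_string(index=False))
    lines.append("")

    winner = result.winner
    if winner is not None and result.border_call is not None:
        call = result.border_call
        lines.append("## Border call")
        lines.append(
            f"{call.scaffold}: {call.first_gene_id}..{call.last_gene_id} "
            f"({call.n_genes} genes), anchors {call.anchor_ids[0]}/{call.anchor_ids[1]}, "
            f"pattern {call.pattern}"
        )
        lines.append("")
        lines.append("## Winning cluster gene roles")
        by_id = {g.gene_id: g for g in winner.cluster.genes}
        for i, gene_id in enumerate(call.gene_ids, start=1):
            gene = by_id.get(gene_id)
            role = _gene_role(gene) if gene is not None else "unknown"
            lines.append(f"rsf{i}: {gene_id} — {role}")
        lines.append("")
        lines.append("## Proposed pathway")
        for i, (step, catalyst) in enumerate(PATHWAY_STEPS, start=1):
            lines.append(f"{i}. {step} [{catalyst}]")
    elif result.status == "no_candidate":
        lines.append("## Border call")
        lines.append("no candidate")
    lines.append("")
    return "\n".join(lines)
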