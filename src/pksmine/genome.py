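"""Gene/domain data model, gene-table I/O and assembly summary statistics.

Genes are consumed as annotated tables (TSV or GFF3) in which each gene
carries an ordered list of predicted enzymatic domain codes (produced
upstream by CDD/InterPro-style annotators, or by the synthetic
generator).  A small closed vocabulary of domain codes covers the
backbone enzyme families that matter for polyketide/NRPS genome mining;
anything else maps to ``UNK`` with a warning so heterogeneous annotation
sources do not abort a scan.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "DOMAIN_CODES",
    "GeneModel",
    "BackboneClass",
    "normalize_domain",
    "parse_architecture",
    "read_gene_table",
    "write_gene_table",
    "classify_backbone",
    "matches_required",
    "gc_content",
    "n50",
    "assembly_stats",
]

#: Closed domain-code vocabulary.  PKS module domains (KS..ACP), NRPS
#: core (C/A/PCP), type III PKS halves (CHS_N/CHS_C), terpene synthase
#: (TPS), and the tailoring/transport families used in cluster scans.
DOMAIN_CODES = frozenset(
    {
        "KS", "AT", "DH", "MT", "ER", "KR", "ACP",
        "cAT", "C", "A", "PCP", "TPS", "CHS_N", "CHS_C",
        "P450", "MFS", "TE_FSH", "OAT", "UNK",
    }
)

TSV_COLUMNS = ["gene_id", "scaffold", "start", "end", "strand", "product", "domains"]


def normalize_domain(code: str) -> str:
    """Map an annotation string onto the closed vocabulary (UNK fallback)."""
    code = code.strip()
    if code in DOMAIN_CODES:
        return code
    warnings.warn(f"unknown domain annotation {code!r} mapped to UNK", stacklevel=2)
    return "UNK"


def parse_architecture(text: str) -> tuple[str, ...]:
    """Parse a semicolon-separated domain string into an architecture."""
    if not text or not str(text).strip() or str(text) == "-":
        return ()
    return tuple(normalize_domain(c) for c in str(text).split(";") if c.strip())


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: coordinates (1-based inclusive) plus domains."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str
    product: str = ""
    architecture: tuple[str, ...] = ()
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        object.__setattr__(self, "architecture", tuple(self.architecture))

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class BackboneClass:
    clazz: str  # PKS | type3_PKS | NRPS | NRPS_like | PKS_NRPS_hybrid | TPS | none
    reduction: str  # HR | PR | NR | NA

    def __post_init__(self) -> None:
        if self.reduction != "NA" and self.clazz != "PKS":
            raise ValueError("reduction grade applies to type I PKSs only")


def classify_backbone(architecture: Sequence[str]) -> BackboneClass:
    """Assign a backbone enzyme class from domain presence.

    KS+AT marks a type I PKS (graded HR/PR/NR by its reductive loop);
    C+A+PCP an NRPS; both together a hybrid; A without C an NRPS-like
    protein; chalcone-synthase halves a type III PKS; TPS a terpene
    synthase.  Total: every architecture maps to exactly one class.
    """
    arch = set(architecture)
    is_pks = {"KS", "AT"} <= arch
    is_nrps = {"C", "A", "PCP"} <= arch
    if is_pks and is_nrps:
        return BackboneClass("PKS_NRPS_hybrid", "NA")
    if is_pks:
        if {"KR", "DH", "ER"} <= arch:
            reduction = "HR"
        elif arch & {"KR", "DH", "ER"}:
            reduction = "PR"
        else:
            reduction = "NR"
        return BackboneClass("PKS", reduction)
    if is_nrps:
        return BackboneClass("NRPS", "NA")
    if "A" in arch and "C" not in arch:
        return BackboneClass("NRPS_like", "NA")
    if arch & {"CHS_N", "CHS_C"}:
        return BackboneClass("type3_PKS", "NA")
    if "TPS" in arch:
        return BackboneClass("TPS", "NA")
    return BackboneClass("none", "NA")


def matches_required(architecture: Sequence[str], required: Iterable[str]) -> bool:
    """True iff every required domain occurs in the architecture.

    Set containment only: iterative PKSs vary in domain order, and the
    mining logic argues from domain presence, not arrangement.
    """
    return set(required) <= set(architecture)


# ---------------------------------------------------------------------------
# Gene-table I/O
# ---------------------------------------------------------------------------


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        return "gff3"
    return "tsv"


def read_gene_table(path, fmt: str | None = None) -> list[GeneModel]:
    """Read an annotated gene table (TSV dialect or GFF3).

    TSV columns: gene_id, scaffold, start, end, strand, product, domains
    (semicolon-separated), optionally cluster_id.  GFF3: features of type
    ``gene`` with ``ID``, optional ``product``, ``domains`` and
    ``cluster_id`` attributes.  Genes are returned sorted by
    (scaffold, start); duplicate gene ids are an error.
    """
    path = Path(path)
    if fmt is None:
        fmt = _infer_format(path)
    if fmt == "tsv":
        genes = _read_tsv(path)
    elif fmt == "gff3":
        genes = _read_gff3(path)
    else:
        raise ValueError(f"unknown gene-table format {fmt!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    genes.sort(key=lambda g: (g.scaffold, g.start, g.end))
    return genes


def _read_tsv(path: Path) -> list[GeneModel]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TSV_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"gene table {path} missing columns: {missing}")
    has_cluster = "cluster_id" in table.columns
    genes = []
    for row in table.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"gene {row.gene_id}: malformed coordinates "
                f"({row.start!r}, {row.end!r})"
            ) from exc
        cluster = getattr(row, "cluster_id", None) if has_cluster else None
        if cluster is None or pd.isna(cluster) or cluster in ("", "-"):
            cluster = None
        domains = "" if pd.isna(row.domains) else str(row.domains)
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                scaffold=str(row.scaffold),
                start=start,
                end=end,
                strand=str(row.strand),
                product="" if pd.isna(row.product) else str(row.product),
                architecture=parse_architecture(domains),
                cluster_id=cluster,
            )
        )
    return genes


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        attrs = feat.attributes
        domains = attrs.get("domains", [""])[0]
        cluster = attrs.get("cluster_id", [None])[0]
        genes.append(
            GeneModel(
                gene_id=attrs["ID"][0],
                scaffold=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                product=attrs.get("product", [""])[0],
                architecture=parse_architecture(domains),
                cluster_id=cluster,
            )
        )
    return genes


def _gff_escape(value: str) -> str:
    """Percent-encode the characters GFF3 reserves inside attribute values."""
    for char, code in (("%", "%25"), (";", "%3B"), ("=", "%3D"),
                       ("&", "%26"), (",", "%2C")):
        value = value.replace(char, code)
    return value


def write_gene_table(genes: Sequence[GeneModel], path, fmt: str | None = None) -> None:
    """Write genes in the TSV dialect or as GFF3 (round-trips with read)."""
    path = Path(path)
    if fmt is None:
        fmt = _infer_format(path)
    if fmt == "tsv":
        rows = [
            {
                "gene_id": g.gene_id,
                "scaffold": g.scaffold,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "product": g.product,
                "domains": ";".join(g.architecture),
                "cluster_id": g.cluster_id if g.cluster_id is not None else "",
            }
            for g in genes
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    elif fmt == "gff3":
        with open(path, "w") as out:
            out.write("##gff-version 3\n")
            for g in genes:
                attrs = [f"ID={_gff_escape(g.gene_id)}"]
                if g.product:
                    attrs.append(f"product={_gff_escape(g.product)}")
                if g.architecture:
                    # the ';'-joined domain string is percent-encoded so it
                    # survives as a single GFF3 attribute value
                    attrs.append("domains=" + _gff_escape(";".join(g.architecture)))
                if g.cluster_id is not None:
                    attrs.append(f"cluster_id={_gff_escape(g.cluster_id)}")
                out.write(
                    "\t".join(
                        [
                            g.scaffold, "pksmine", "gene",
                            str(g.start), str(g.end), ".",
                            g.strand, ".", ";".join(attrs),
                        ]
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown gene-table format {fmt!r}")


# ---------------------------------------------------------------------------
# Assembly summary statistics
# ---------------------------------------------------------------------------


def _iter_sequences(source) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        for record in SeqIO.parse(str(source), "fasta"):
            yield str(record.seq)
    else:
        for item in source:
            yield str(getattr(item, "seq", item))


def gc_content(sequences) -> float:
    """(G+C) / (A+C+G+T) over all sequences; other codes are excluded.

    ``sequences`` may be a FASTA path, SeqRecords, or plain strings.
    """
    gc = 0
    acgt = 0
    for seq in _iter_sequences(sequences):
        seq = seq.upper()
        g = seq.count("G")
        c = seq.count("C")
        gc += g + c
        acgt += g + c + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("no unambiguous nucleotides in input")
    return gc / acgt


def n50(contig_lengths: Sequence[int]) -> int:
    """Largest L with the summed length of contigs >= L covering half the total."""
    lengths = sorted(contig_lengths, reverse=True)
    if not lengths:
        raise ValueError("empty length list")
    total = sum(lengths)
    running = 0
    for length in lengths:
        running += length
        if 2 * running >= total:
            return length
    raise AssertionError("unreachable")


def assembly_stats(fasta) -> dict:
    """GC fraction, N50, scaffold count and total bp for an assembly."""
    lengths = []
    gc = 0
    acgt = 0
    total = 0
    for seq in _iter_sequences(fasta):
        seq = seq.upper()
        lengths.append(len(seq))
        total += len(seq)
        g, c = seq.count("G"), seq.count("C")
        gc += g + c
        acgt += g + c + seq.count("A") + seq.count("T")
    if not lengths:
        raise ValueError("empty FASTA")
    return {
        "n_scaffolds": len(lengths),
        "total_bp": total,
        "gc": gc / acgt if acgt else float("nan"),
        "n50": n50(lengths),
    }
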