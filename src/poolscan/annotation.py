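"""Candidate-gene identification and QTL-gene collocation.

Putative diastase-related genes are pulled from a gene annotation table by
the union of PFAM accession matches (amylase catalytic and inhibitor
domains, glycosyl hydrolase family 14, maltogenic amylase C-terminal
domain) and case-insensitive keyword matches in the functional description
("amylase", "dextrin").  A gene is collocated with a QTL when its span lies
within the QTL interval extended by the QTL-independence gap on each side
(400 Mbp across centromeres, 10 Mbp elsewhere).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .scan import (
    DEFAULT_GAP_CENTROMERIC,
    DEFAULT_GAP_OTHER,
    CentromereMap,
    QTLCall,
    _gap_for_span,
)

log = logging.getLogger(__name__)

#: PFAM domains with diastase-related function
DEFAULT_PFAM: tuple[str, ...] = ("PF00128", "PF01356", "PF01373", "PF02806", "PF16657")
#: functional-description keywords (case-insensitive substrings)
DEFAULT_KEYWORDS: tuple[str, ...] = ("amylase", "dextrin")


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene: location, functional description and PFAM terms."""

    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    functional_description: str = ""
    pfam_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


def read_genes_tsv(path: str | Path) -> list[GeneAnnotation]:
    """Flat gene table: gene_id, chromosome, start, end, description, pfam.

    ``pfam`` is a comma-separated accession list; both text columns may be
    empty.
    """
    df = pd.read_table(path, dtype={"pfam": str, "description": str})
    genes = []
    for _, r in df.iterrows():
        raw_pfam = r.get("pfam", "")
        raw_desc = r.get("description", "")
        pfam_text = "" if pd.isna(raw_pfam) else str(raw_pfam)
        genes.append(
            GeneAnnotation(
                gene_id=str(r["gene_id"]),
                chromosome=str(r["chromosome"]),
                start=int(r["start"]),
                end=int(r["end"]),
                functional_description="" if pd.isna(raw_desc) else str(raw_desc),
                pfam_terms=tuple(p.strip() for p in pfam_text.split(",") if p.strip()),
            )
        )
    return genes


def read_genes_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneAnnotation]:
    """Gene records from GFF3; description and PFAM terms from attributes.

    Recognised attribute keys (case-insensitive): ``ID``, ``description`` or
    ``Note``, and ``pfam`` (comma-separated).  Coordinates are taken as-is
    (GFF3 is already 1-based inclusive).
    """
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9 or parts[2] != feature_type:
                continue
            attrs = {}
            for kv in parts[8].split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attrs[k.strip().lower()] = v.strip()
            pfam_raw = attrs.get("pfam", "")
            genes.append(
                GeneAnnotation(
                    gene_id=attrs.get("id", f"{parts[0]}:{parts[3]}-{parts[4]}"),
                    chromosome=parts[0],
                    start=int(parts[3]),
                    end=int(parts[4]),
                    functional_description=attrs.get("description", attrs.get("note", "")),
                    pfam_terms=tuple(p for p in re.split(r"[,|]", pfam_raw) if p),
                )
            )
    return genes


def find_candidate_genes(
    genes: Sequence[GeneAnnotation],
    pfam_filter: Sequence[str] = DEFAULT_PFAM,
    keyword_filter: Sequence[str] = DEFAULT_KEYWORDS,
) -> list[GeneAnnotation]:
    """Union of PFAM-accession and description-keyword matches, deduplicated.

    Keywords match as case-insensitive substrings of the functional
    description; PFAM terms match exactly.  Input order is preserved.
    """
    pfam = set(pfam_filter)
    keywords = [k.lower() for k in keyword_filter]
    seen: set[str] = set()
    hits = []
    for g in genes:
        if g.gene_id in seen:
            continue
        desc = g.functional_description.lower()
        if (pfam & set(g.pfam_terms)) or any(k in desc for k in keywords):
            hits.append(g)
            seen.add(g.gene_id)
    return hits


def collocate_qtl_genes(
    qtls: Sequence[QTLCall],
    genes: Sequence[GeneAnnotation],
    gap_centromeric: float = DEFAULT_GAP_CENTROMERIC,
    gap_other: float = DEFAULT_GAP_OTHER,
    centromeres: CentromereMap | None = None,
) -> dict[str, list[GeneAnnotation]]:
    """Genes collocated with each QTL under the independence-gap criterion.

    A gene is collocated when its span intersects the QTL interval, or lies
    within the applicable gap of the interval edge (strictly less than the
    gap: a separation reaching the gap would make an independent QTL).  The
    gap is centromeric when the span between gene and interval crosses the
    centromere, as in QTL clustering.
    """
    qtl_chroms = {q.chromosome for q in qtls}
    missing = sorted({g.chromosome for g in genes} - qtl_chroms)
    if missing:
        log.warning("genes on chromosomes without QTL are ignored: %s", ", ".join(missing))
    warned: set[str] = set()
    out: dict[str, list[GeneAnnotation]] = {q.name: [] for q in qtls}
    for q in qtls:
        qs, qe = q.interval
        for g in genes:
            if g.chromosome != q.chromosome:
                continue
            if g.end >= qs and g.start <= qe:  # overlap
                out[q.name].append(g)
                continue
            if g.start > qe:
                span, sep = (qe, g.start), g.start - qe
            else:
                span, sep = (g.end, qs), qs - g.end
            gap = _gap_for_span(
                q.chromosome, span, centromeres, gap_centromeric, gap_other, warned
            )
            if sep < gap:
                out[q.name].append(g)
    return out


def collocation_table(collocated: dict[str, list[GeneAnnotation]]) -> pd.DataFrame:
    rows = [
        {
            "qtl": qtl,
            "gene_id": g.gene_id,
            "chromosome": g.chromosome,
            "start": g.start,
            "end": g.end,
            "description": g.functional_description,
            "pfam": ",".join(g.pfam_terms),
        }
        for qtl, genes in collocated.items()
        for g in genes
    ]
    return pd.DataFrame(
        rows, columns=["qtl", "gene_id", "chromosome", "start", "end", "description", "pfam"]
    )
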