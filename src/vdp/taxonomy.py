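"""Contig-level viral taxonomy from per-gene database hits by majority vote,
plus lifestyle label attachment.

A contig is eligible for assignment when (i) at least 20% of its genes have a
database hit, or, for contigs with fewer than ten genes, at least two genes
have hits.  Among the hit genes the lineage ranks are walked from most to
least specific and the contig is assigned at the deepest rank where a single
taxon collects at least 60% of the hit genes.  Both thresholds are inclusive.
If no rank qualifies the contig stays unassigned (no fallback to a root
taxon).  Genes with multiple hits are reduced to their single lowest-E-value
hit before voting: the rule counts genes, not hits.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .io import ContigRecord, ValidationError, lineage_from_string, lineage_to_string

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_THRESHOLD = 1e-5


@dataclass(frozen=True)
class GeneHit:
    """Best database hit of one predicted gene on a viral contig."""

    contig_id: str
    gene_index: int
    lineage: tuple[tuple[str, str], ...]
    evalue: float

    def __post_init__(self) -> None:
        if self.gene_index < 0:
            raise ValidationError("gene_index must be >= 0")
        if self.evalue <= 0:
            raise ValidationError("evalue must be > 0")


@dataclass(frozen=True)
class TaxonomyRuleParams:
    min_hit_fraction: float = 0.2
    min_hits_short: int = 2
    short_gene_count: int = 10
    min_consensus: float = 0.6
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD


@dataclass(frozen=True)
class TaxonAssignment:
    contig_id: str
    assigned_lineage: tuple[tuple[str, str], ...] = ()
    rank_assigned: str | None = None
    hit_fraction: float = 0.0
    consensus_fraction: float = 0.0

    @property
    def assigned(self) -> bool:
        return self.rank_assigned is not None


def _dedupe_hits(hits: list[GeneHit]) -> list[GeneHit]:
    best: dict[int, GeneHit] = {}
    for h in hits:
        cur = best.get(h.gene_index)
        if cur is None or h.evalue < cur.evalue:
            best[h.gene_index] = h
    return [best[i] for i in sorted(best)]


def assign_contig_taxonomy(
    hits: list[GeneHit],
    n_genes: int,
    params: TaxonomyRuleParams = TaxonomyRuleParams(),
) -> TaxonAssignment:
    """Vote a single contig's taxonomy from its per-gene hits (see module doc)."""
    if n_genes <= 0:
        raise ValidationError(f"n_genes must be > 0, got {n_genes}")
    hits = [h for h in hits if h.evalue <= params.evalue_threshold]
    hits = _dedupe_hits(hits)
    contig_id = hits[0].contig_id if hits else ""
    if hits and max(h.gene_index for h in hits) >= n_genes:
        raise ValidationError(
            f"contig {contig_id!r}: gene_index exceeds n_genes={n_genes}"
        )
    n_hit = len(hits)
    hit_fraction = n_hit / n_genes
    eligible = hit_fraction >= params.min_hit_fraction or (
        n_genes < params.short_gene_count and n_hit >= params.min_hits_short
    )
    if not hits or not eligible:
        return TaxonAssignment(contig_id, hit_fraction=hit_fraction)
    # walk ranks from most specific to least; ranks are ordered least->most
    # specific within each lineage, so index from the end of the deepest one
    max_depth = max(len(h.lineage) for h in hits)
    for depth in range(max_depth, 0, -1):
        counts: Counter[tuple[tuple[str, str], ...]] = Counter()
        for h in hits:
            if len(h.lineage) >= depth:
                counts[h.lineage[:depth]] += 1
        if not counts:
            continue
        prefix, votes = counts.most_common(1)[0]
        consensus = votes / n_hit
        if consensus >= params.min_consensus:
            return TaxonAssignment(
                contig_id,
                assigned_lineage=prefix,
                rank_assigned=prefix[-1][0],
                hit_fraction=hit_fraction,
                consensus_fraction=consensus,
            )
    return TaxonAssignment(contig_id, hit_fraction=hit_fraction)


def read_gene_hits(path) -> tuple[dict[str, list[GeneHit]], dict[str, int]]:
    """Read gene_hits.tsv (contig_id, gene_index, n_genes, lineage, evalue).

    Returns per-contig hit lists and the per-contig total gene counts.
    """
    df = pd.read_csv(path, sep="\t")
    hits: dict[str, list[GeneHit]] = {}
    n_genes: dict[str, int] = {}
    for row in df.itertuples(index=False):
        lineage = tuple(lineage_from_string(row.lineage))
        hits.setdefault(str(row.contig_id), []).append(
            GeneHit(str(row.contig_id), int(row.gene_index), lineage, float(row.evalue))
        )
        n_genes[str(row.contig_id)] = int(row.n_genes)
    return hits, n_genes


def assign_taxonomy_table(
    hits: dict[str, list[GeneHit]],
    n_genes: dict[str, int],
    params: TaxonomyRuleParams = TaxonomyRuleParams(),
) -> pd.DataFrame:
    """Vote every contig; one row per contig with hits or a gene count."""
    rows = []
    for contig_id in sorted(set(hits) | set(n_genes)):
        a = assign_contig_taxonomy(
            hits.get(contig_id, []), n_genes.get(contig_id, 1), params
        )
        rows.append(
            {
                "contig_id": contig_id,
                "lineage": lineage_to_string(a.assigned_lineage),
                "rank_assigned": a.rank_assigned or "",
                "hit_fraction": a.hit_fraction,
                "consensus_fraction": a.consensus_fraction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig_id", "lineage", "rank_assigned", "hit_fraction",
            "consensus_fraction",
        ],
    )


def attach_lifestyles(
    contigs: list[ContigRecord],
    labels: dict[str, str],
) -> list[ContigRecord]:
    """Attach lytic/lysogenic labels to viral contigs (in place, returned).

    Unlabeled viral contigs become ``unknown``; prophage-category contigs are
    forced ``lysogenic`` (they are integrated by construction); labels for
    non-viral contigs are ignored with a warning.
    """
    viral_ids = {c.contig_id for c in contigs if c.category in ("free_viral", "prophage")}
    for cid, label in labels.items():
        if cid not in viral_ids:
            warnings.warn(f"lifestyle label for non-viral contig {cid!r} ignored",
                          stacklevel=2)
    for c in contigs:
        if c.category == "prophage":
            label = labels.get(c.contig_id)
            if label == "lytic":
                logger.info(
                    "prophage %s labelled lytic; forcing lysogenic", c.contig_id
                )
            c.lifestyle = "lysogenic"
        elif c.category == "free_viral":
            c.lifestyle = labels.get(c.contig_id, "unknown")
    return contigs
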