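"""Greedy sequence dereplication at identity/coverage thresholds.

The clustering strategy follows CD-HIT's semantics: sort sequences longest
first; each sequence joins the first existing representative it matches at
``identity >= min_identity`` and ``coverage of the shorter sequence >=
min_short_coverage``, otherwise it founds a new cluster.  Identity comes from
the best local alignment (match +1, mismatch -1, gap -2 by default) with the
denominator counting aligned columns *including* internal gaps; bit-for-bit
CD-HIT replication is a non-goal.

A shared-k-mer prefilter (word size 16 by default) skips hopeless pairs: any
alignment that clears the default thresholds on sequences of a few hundred bp
or more must contain an exact run of >= word_size matches.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .io import ContigRecord, ValidationError


@dataclass(frozen=True)
class DereplicationParams:
    min_identity: float = 0.95
    min_short_coverage: float = 0.8
    word_size: int = 16
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_score: float = -2.0

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValidationError("min_identity must be in (0, 1]")
        if not 0 < self.min_short_coverage <= 1:
            raise ValidationError("min_short_coverage must be in (0, 1]")
        if self.word_size < 4:
            raise ValidationError("word_size must be >= 4")


def _aligner(params: DereplicationParams) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner(mode="local")
    al.match_score = params.match_score
    al.mismatch_score = params.mismatch_score
    al.open_gap_score = params.gap_score
    al.extend_gap_score = params.gap_score
    return al


def pairwise_identity(
    a: ContigRecord | str,
    b: ContigRecord | str,
    params: DereplicationParams = DereplicationParams(),
) -> tuple[float, float]:
    """Best-local-alignment identity and coverage of the shorter sequence.

    Returns ``(identity, short_coverage)`` where identity = matches / aligned
    columns (gap columns included) and short_coverage = aligned span on the
    shorter sequence / its length.  Symmetric in its arguments.
    """
    sa = a.sequence if isinstance(a, ContigRecord) else a
    sb = b.sequence if isinstance(b, ContigRecord) else b
    if not sa or not sb:
        raise ValidationError("pairwise_identity needs non-empty sequences")
    if sa == sb:
        return 1.0, 1.0
    # canonical argument order keeps the result exactly symmetric
    if (len(sa), sa) > (len(sb), sb):
        sa, sb = sb, sa
    aln = _aligner(params).align(sa, sb)
    if len(aln) == 0 or aln.score <= 0:
        return 0.0, 0.0
    best = aln[0]
    c = best.counts()
    columns = c.identities + c.mismatches + c.internal_gaps
    identity = c.identities / columns if columns else 0.0
    # sa is the shorter sequence and the alignment target
    spans = best.aligned[0]
    span = int(spans[-1][1] - spans[0][0]) if len(spans) else 0
    return float(identity), float(span / len(sa))


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def dereplicate(
    contigs: list[ContigRecord],
    params: DereplicationParams = DereplicationParams(),
    use_prefilter: bool = True,
) -> tuple[list[ContigRecord], dict[str, str]]:
    """Greedy longest-first clustering; returns representatives and the
    contig_id -> representative_id map (representatives map to themselves).

    Length ties break lexicographically on contig_id, so the result is
    deterministic regardless of input order.
    """
    ids = [c.contig_id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValidationError("dereplicate requires unique contig ids")
    ordered = sorted(contigs, key=lambda c: (-c.length, c.contig_id))
    reps: list[ContigRecord] = []
    rep_kmers: list[set[str]] = []
    cluster_map: dict[str, str] = {}
    for contig in ordered:
        assigned = False
        query_kmers = _kmers(contig.sequence, params.word_size) if use_prefilter else None
        for i, rep in enumerate(reps):
            if use_prefilter and query_kmers is not None and not (
                query_kmers & rep_kmers[i]
            ):
                continue
            identity, short_cov = pairwise_identity(contig, rep, params)
            if identity >= params.min_identity and short_cov >= params.min_short_coverage:
                cluster_map[contig.contig_id] = rep.contig_id
                assigned = True
                break
        if not assigned:
            reps.append(contig)
            if use_prefilter:
                rep_kmers.append(_kmers(contig.sequence, params.word_size))
            cluster_map[contig.contig_id] = contig.contig_id
    return reps, cluster_map
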