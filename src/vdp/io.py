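"""Readers and writers for the formats the pipeline touches, plus the shared data model.

Contig sequences travel as :class:`ContigRecord`; tabular inputs (alignments,
gene hits, defense annotations, prophage coordinates, tRNA genes, lifestyles,
sample metadata) travel as pandas DataFrames with fixed column schemas.
All coordinates are 0-based half-open internally; conversion, if any, happens
only at file boundaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: valid contig categories
CATEGORIES = ("prokaryotic", "free_viral", "prophage")

#: strict alphabet for stored sequences
DNA_ALPHABET = frozenset("ACGTN")

#: IUPAC ambiguity codes collapsed to N on input
IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHVU")

ALIGNMENT_COLUMNS = ("read_id", "contig_id", "aligned_length")


class ValidationError(ValueError):
    """An input violated a schema or domain invariant."""


@dataclass
class ContigRecord:
    """A contig with its category and (optional) taxonomy.

    Parameters
    ----------
    contig_id :
        Unique, non-empty identifier.
    sequence :
        Uppercase DNA over ``{A,C,G,T,N}``.
    category :
        One of ``prokaryotic``, ``free_viral``, ``prophage``.
    lineage :
        Ordered ``(rank, taxon)`` pairs, least to most specific.
    lifestyle :
        For viral contigs: ``lytic`` / ``lysogenic`` / ``unknown``.
    """

    contig_id: str
    sequence: str
    category: str = "prokaryotic"
    lineage: list[tuple[str, str]] = field(default_factory=list)
    lifestyle: str | None = None

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise ValidationError("contig_id must be non-empty")
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"unknown category {self.category!r} for contig {self.contig_id!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def genus(self) -> str | None:
        for rank, taxon in self.lineage:
            if rank == "genus":
                return taxon
        return None


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-contig alignment (row schema of the alignments table)."""

    read_id: str
    contig_id: str
    aligned_length: int


@dataclass(frozen=True)
class SampleMetadata:
    """A sample with its condition and environmental covariates."""

    sample_id: str
    condition: str
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in ("disinfected", "non_disinfected"):
            raise ValidationError(
                f"unknown condition {self.condition!r} for sample {self.sample_id!r}"
            )


def _clean_sequence(raw: str, contig_id: str) -> str:
    seq = raw.upper()
    bad = set(seq) - DNA_ALPHABET
    if not bad:
        return seq
    mappable = bad & IUPAC_AMBIGUOUS
    if mappable:
        warnings.warn(
            f"contig {contig_id!r}: IUPAC ambiguity codes {sorted(mappable)} mapped to N",
            stacklevel=3,
        )
        seq = seq.translate(str.maketrans({c: "N" for c in mappable}))
        bad -= mappable
    if bad:
        pos = min(i for i, c in enumerate(seq) if c in bad)
        raise ValidationError(
            f"contig {contig_id!r}: non-IUPAC character {seq[pos]!r} at position {pos}"
        )
    return seq


def read_fasta(path, category: str = "prokaryotic") -> list[ContigRecord]:
    """Read a (possibly wrapped) multi-FASTA into :class:`ContigRecord` objects.

    Sequences are uppercased; IUPAC ambiguity codes other than N are mapped to
    N with a warning; any other character is a :class:`ValidationError`.
    Duplicate header ids are rejected.
    """
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _clean_sequence(str(rec.seq), rec.id)
        if not seq:
            raise ValidationError(f"contig {rec.id!r} has an empty sequence")
        records.append(ContigRecord(rec.id, seq, category=category))
    logger.info("read %d contigs from %s", len(records), path)
    return records


def write_fasta(records, path, width: int = 70) -> None:
    """Write contigs as wrapped FASTA; round-trips with :func:`read_fasta`."""
    if width < 1:
        raise ValidationError(f"width must be >= 1, got {width}")
    seqs = [SeqRecord(Seq(r.sequence), id=r.contig_id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def _validate_alignment_frame(df: pd.DataFrame, source) -> pd.DataFrame:
    df = df.loc[:, list(ALIGNMENT_COLUMNS)].copy()
    df["aligned_length"] = df["aligned_length"].astype(int)
    if (df["aligned_length"] < 0).any():
        bad = df.loc[df["aligned_length"] < 0].iloc[0]
        raise ValidationError(
            f"negative aligned_length for read {bad.read_id!r} in {source}"
        )
    return df


def read_alignments(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read read-to-contig alignments from TSV (canonical) or SAM.

    TSV dialect expects a header row ``read_id  contig_id  aligned_length``.
    SAM dialect keeps mapped primary records only; ``aligned_length`` is the
    summed length of M/=/X CIGAR operations.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "contig_id": str})
        missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        return _validate_alignment_frame(df, path)
    if dialect == "sam":
        import pysam

        rows = []
        skipped = 0
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    skipped += 1
                    continue
                stats = aln.get_cigar_stats()[0]
                # M (0), = (7), X (8) consume both query and reference
                aligned = int(stats[0] + stats[7] + stats[8])
                rows.append((aln.query_name, aln.reference_name, aligned))
        logger.info(
            "read %d mapped primary records from %s (%d skipped)",
            len(rows), path, skipped,
        )
        df = pd.DataFrame(rows, columns=list(ALIGNMENT_COLUMNS))
        return _validate_alignment_frame(df, path)
    raise ValidationError(f"unknown alignment dialect {dialect!r} (use 'tsv' or 'sam')")


def write_alignments(df: pd.DataFrame, path) -> None:
    df.loc[:, list(ALIGNMENT_COLUMNS)].to_csv(path, sep="\t", index=False)


def lineage_to_string(lineage) -> str:
    return ";".join(f"{rank}={taxon}" for rank, taxon in lineage)


def lineage_from_string(text: str) -> list[tuple[str, str]]:
    if not text or pd.isna(text):
        return []
    pairs = []
    for item in str(text).split(";"):
        if not item:
            continue
        rank, _, taxon = item.partition("=")
        pairs.append((rank, taxon))
    return pairs


def read_table(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a UTF-8 TSV with a header row, checking required columns."""
    df = pd.read_csv(path, sep="\t")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_sample_metadata(path) -> list[SampleMetadata]:
    """Read samples.tsv: sample_id, condition, then one column per covariate."""
    df = read_table(path, required=("sample_id", "condition"))
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id {dup!r} in {path}")
    covar_cols = [c for c in df.columns if c not in ("sample_id", "condition")]
    out = []
    for row in df.itertuples(index=False):
        covs = {c: float(getattr(row, c)) for c in covar_cols}
        for name, val in covs.items():
            if not pd.notna(val) or val != val or abs(val) == float("inf"):
                raise ValidationError(
                    f"non-finite covariate {name!r} for sample {row.sample_id!r}"
                )
        out.append(SampleMetadata(str(row.sample_id), str(row.condition), covs))
    return out
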