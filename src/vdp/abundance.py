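"""TPM quantification from filtered alignments and grouped relative abundance.

TPM (transcripts per kilobase million) is the length-normalised relative
abundance of a contig in a sample:

    TPM_i = (c_i / L_i) / sum_j (c_j / L_j) * 1e6

where c_i is the number of alignment records surviving the minimum aligned
length filter and L_i the contig length in bp.  Every sample column of an
abundance table sums to 1e6 (or is all-zero when no read survives).
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .io import ValidationError

logger = logging.getLogger(__name__)

#: default minimum aligned length in bp (reads mapping fewer bases are noise)
MIN_ALIGNED_DEFAULT = 30

SCALE = 1e6


def filter_alignments(
    alignments: pd.DataFrame,
    min_aligned: int = MIN_ALIGNED_DEFAULT,
    strict: bool = False,
) -> pd.DataFrame:
    """Drop alignment records shorter than ``min_aligned``.

    The default comparator is inclusive (``aligned_length >= min_aligned``);
    ``strict=True`` switches to a strict ``>``.  Row order is preserved.
    """
    if min_aligned < 0:
        raise ValidationError(f"min_aligned must be >= 0, got {min_aligned}")
    if alignments.empty:
        return alignments.copy()
    if strict:
        mask = alignments["aligned_length"].to_numpy() > min_aligned
    else:
        mask = alignments["aligned_length"].to_numpy() >= min_aligned
    dropped = int((~mask).sum())
    if dropped:
        logger.info("filter_alignments: dropped %d/%d records", dropped, len(mask))
    return alignments.loc[mask].copy()


def counts_to_tpm(counts: pd.Series, lengths: Mapping[str, int]) -> pd.Series:
    """Convert per-contig read counts to a TPM column over all contigs in ``lengths``."""
    length_ser = pd.Series(lengths, dtype=float)
    if (length_ser <= 0).any():
        bad = length_ser.index[length_ser <= 0][0]
        raise ValidationError(f"non-positive length for contig {bad!r}")
    unknown = set(counts.index) - set(length_ser.index)
    if unknown:
        raise ValidationError(
            f"alignment references unknown contig {sorted(unknown)[0]!r}"
        )
    full = counts.reindex(length_ser.index, fill_value=0).astype(float)
    rate = full / length_ser
    total = rate.sum()
    if total == 0:
        return pd.Series(0.0, index=length_ser.index, name=counts.name)
    return rate / total * SCALE


def compute_tpm(
    alignments: pd.DataFrame,
    lengths: Mapping[str, int],
    sample_id: str,
) -> pd.Series:
    """TPM column for one sample from (already filtered) alignment records.

    Each record counts once; contigs with no surviving reads get 0.  An
    all-zero column (no surviving reads at all) is logged, not an error.
    """
    counts = alignments["contig_id"].value_counts()
    counts.name = sample_id
    tpm = counts_to_tpm(counts, lengths)
    tpm.name = sample_id
    if tpm.sum() == 0:
        logger.warning("sample %s: no surviving reads, all-zero TPM column", sample_id)
    return tpm


def tpm_table(
    alignments_by_sample: Mapping[str, pd.DataFrame],
    lengths: Mapping[str, int],
    min_aligned: int = MIN_ALIGNED_DEFAULT,
) -> pd.DataFrame:
    """Filter and quantify every sample; contigs as rows, samples as columns."""
    cols = {
        sample: compute_tpm(filter_alignments(aln, min_aligned), lengths, sample)
        for sample, aln in alignments_by_sample.items()
    }
    return pd.DataFrame(cols)


def aggregate_abundance(
    table: pd.DataFrame,
    membership: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum member-contig TPM per group and sample.

    Returns ``(group_tpm, group_share)`` where ``group_share`` is the group's
    fraction of the per-sample total scale (TPM / 1e6).  Contigs absent from
    ``membership`` are ignored.
    """
    for cid, label in membership.items():
        if label == "":
            raise ValidationError(f"empty group label for contig {cid!r}")
    member_ids = [c for c in table.index if c in membership]
    if not member_ids:
        empty = pd.DataFrame(columns=table.columns, dtype=float)
        return empty, empty.copy()
    groups = pd.Series({c: membership[c] for c in member_ids}, name="group")
    group_tpm = table.loc[member_ids].groupby(groups).sum()
    group_tpm = group_tpm.sort_index()
    return group_tpm, group_tpm / SCALE
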