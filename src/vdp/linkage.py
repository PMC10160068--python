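"""In-situ phage-host linkage via three evidence channels, genus-level
merging, polyvalent-phage classification and host-population summaries.

Channels:

* ``crispr`` — a CRISPR spacer from a prokaryotic contig occurs (either
  strand, no indels) in a viral contig: the spacer's contig is the putative
  host.  Nucleotide-level matching, 0 mismatches by default.
* ``trna`` — a viral tRNA gene is a full-length, 100%-identity match (either
  strand) to a prokaryotic tRNA gene.
* ``prophage`` — a prophage's containing prokaryotic contig is its host.

The same two matching operations applied against a user-supplied reference
table give the ex-situ channels (``exsitu_similarity`` / ``exsitu_spacer``);
no reference database is bundled.

A phage linked to two or more distinct host genera is *polyvalent*.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .io import ContigRecord, ValidationError

logger = logging.getLogger(__name__)

LINK_COLUMNS = ["phage_id", "host_contig_id", "genus", "channel", "detail"]

CHANNELS = ("crispr", "trna", "prophage", "exsitu_similarity", "exsitu_spacer")

MIN_SPACER_LEN = 18

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _find_approx(haystack: str, needle: str, max_mismatch: int) -> int:
    """Leftmost start of an occurrence with <= max_mismatch mismatches, or -1.

    N matches nothing.  Exact search delegates to str.find.
    """
    if max_mismatch == 0 and "N" not in needle:
        pos = haystack.find(needle)
        while pos != -1 and "N" in haystack[pos : pos + len(needle)]:
            pos = haystack.find(needle, pos + 1)
        return pos
    n, m = len(haystack), len(needle)
    if m > n:
        return -1
    hs = np.frombuffer(haystack.encode(), dtype=np.uint8)
    nd = np.frombuffer(needle.encode(), dtype=np.uint8)
    N = ord("N")
    for i in range(n - m + 1):
        window = hs[i : i + m]
        mism = int((window != nd).sum() + ((window == N) & (nd == N)).sum())
        if mism <= max_mismatch:
            return i
    return -1


def match_spacers(
    spacers: pd.DataFrame,
    viral_contigs: list[ContigRecord],
    max_mismatch: int = 0,
) -> pd.DataFrame:
    """CRISPR-channel links: spacer occurs in a viral contig on either strand.

    ``spacers`` needs columns contig_id and spacer.  Spacers shorter than
    18 bp are rejected with a warning.  One link per (host contig, phage)
    pair per spacer occurrence; detail records spacer, strand, position.
    """
    rows = []
    for row in spacers.itertuples(index=False):
        sp = str(row.spacer)
        if len(sp) < MIN_SPACER_LEN:
            warnings.warn(
                f"spacer on {row.contig_id} shorter than {MIN_SPACER_LEN} bp skipped",
                stacklevel=2,
            )
            continue
        for v in viral_contigs:
            for strand, probe in (("+", sp), ("-", revcomp(sp))):
                pos = _find_approx(v.sequence, probe, max_mismatch)
                if pos != -1:
                    rows.append(
                        {
                            "phage_id": v.contig_id,
                            "host_contig_id": str(row.contig_id),
                            "channel": "crispr",
                            "detail": f"spacer={sp};strand={strand};pos={pos}",
                        }
                    )
                    break  # one hit per (spacer, viral contig) is evidence enough
    return pd.DataFrame(rows, columns=[c for c in LINK_COLUMNS if c != "genus"])


def match_trnas(
    viral_trnas: pd.DataFrame,
    prok_trnas: pd.DataFrame,
) -> pd.DataFrame:
    """tRNA-channel links: full-length perfect match on either strand.

    Both tables need columns contig_id, trna_id, seq.  One link per
    (phage, host contig) pair.
    """
    index: dict[str, list[tuple[str, str]]] = {}
    for row in prok_trnas.itertuples(index=False):
        index.setdefault(str(row.seq).upper(), []).append(
            (str(row.contig_id), str(row.trna_id))
        )
    rows = []
    seen: set[tuple[str, str]] = set()
    for row in viral_trnas.itertuples(index=False):
        seq = str(row.seq).upper()
        for probe in (seq, revcomp(seq)):
            for host, trna_id in index.get(probe, []):
                key = (str(row.contig_id), host)
                if key in seen:
                    continue
                seen.add(key)
                rows.append(
                    {
                        "phage_id": str(row.contig_id),
                        "host_contig_id": host,
                        "channel": "trna",
                        "detail": f"trna={row.trna_id}~{trna_id}",
                    }
                )
    return pd.DataFrame(rows, columns=[c for c in LINK_COLUMNS if c != "genus"])


def link_prophages(
    prophage_table: pd.DataFrame,
    host_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Prophage-channel links: the containing contig is the host.

    ``prophage_table`` needs columns prophage_id, host_contig_id, start, end
    (0-based half-open).  Out-of-bounds intervals are validation errors.
    """
    rows = []
    for row in prophage_table.itertuples(index=False):
        host = str(row.host_contig_id)
        start, end = int(row.start), int(row.end)
        if host not in host_lengths:
            raise ValidationError(f"prophage host contig {host!r} unknown")
        if not (0 <= start < end <= host_lengths[host]):
            raise ValidationError(
                f"prophage {row.prophage_id!r} interval ({start},{end}) out of "
                f"bounds for {host!r} (length {host_lengths[host]})"
            )
        rows.append(
            {
                "phage_id": str(row.prophage_id),
                "host_contig_id": host,
                "channel": "prophage",
                "detail": f"interval=({start},{end})",
            }
        )
    return pd.DataFrame(rows, columns=[c for c in LINK_COLUMNS if c != "genus"])


def merge_links(
    link_tables: list[pd.DataFrame],
    genus_of: Mapping[str, str | None],
) -> tuple[pd.DataFrame, dict[str, int], int]:
    """Concatenate channels, attach host genus, deduplicate exact rows.

    Deduplication key is (phage, host contig, channel): the same pair found
    by two channels keeps both rows.  Returns the merged table, per-channel
    counts, and the number of phages linked by >= 2 distinct channels.
    Links without a genus are retained but excluded from genus-level
    summaries downstream.
    """
    frames = [t for t in link_tables if t is not None and not t.empty]
    if not frames:
        return pd.DataFrame(columns=LINK_COLUMNS), {}, 0
    df = pd.concat(frames, ignore_index=True)
    bad = set(df["channel"]) - set(CHANNELS)
    if bad:
        raise ValidationError(f"unknown link channel(s) {sorted(bad)}")
    df = df.drop_duplicates(subset=["phage_id", "host_contig_id", "channel"])
    df = df.copy()
    df["genus"] = df["host_contig_id"].map(lambda h: genus_of.get(h) or "")
    df = df[LINK_COLUMNS].sort_values(
        ["phage_id", "host_contig_id", "channel"]
    ).reset_index(drop=True)
    channel_counts = df["channel"].value_counts().to_dict()
    multi = int(
        (df.groupby("phage_id")["channel"].nunique() >= 2).sum()
    )
    logger.info(
        "merged links: %d rows, channels %s, %d multi-channel phages",
        len(df), channel_counts, multi,
    )
    return df, channel_counts, multi


def classify_polyvalent(
    links: pd.DataFrame,
    abundance: pd.Series | None = None,
) -> tuple[pd.DataFrame, float | None, float | None]:
    """Host-range summary per phage and the polyvalent fractions.

    Counts distinct host *genera* per phage (rows without genus ignored);
    polyvalent means >= 2.  Count-basis fraction = polyvalent / host-linked
    phages.  Abundance-basis fraction (when a TPM column is given) weights
    each host-linked phage by its TPM.  Both are None when nothing is linked.
    """
    with_genus = links[links["genus"].astype(str) != ""] if not links.empty else links
    if with_genus is None or with_genus.empty:
        empty = pd.DataFrame(columns=["phage_id", "n_genera", "genera", "polyvalent"])
        return empty, None, None
    grouped = with_genus.groupby("phage_id")["genus"].agg(
        lambda g: tuple(sorted(set(g)))
    )
    summary = pd.DataFrame(
        {
            "phage_id": grouped.index,
            "n_genera": [len(g) for g in grouped],
            "genera": [";".join(g) for g in grouped],
            "polyvalent": [len(g) >= 2 for g in grouped],
        }
    ).reset_index(drop=True)
    count_frac = float(summary["polyvalent"].mean())
    abund_frac = None
    if abundance is not None:
        tpm = summary["phage_id"].map(
            lambda p: float(abundance.get(p, 0.0))
        ).to_numpy()
        total = tpm.sum()
        if total > 0:
            abund_frac = float(tpm[summary["polyvalent"].to_numpy()].sum() / total)
    return summary, count_frac, abund_frac


def host_population_summary(
    links: pd.DataFrame,
    prok_abundance: pd.Series,
    genus_of: Mapping[str, str | None],
    top_k: int = 20,
) -> pd.DataFrame:
    """Per-genus host summary (dominant predicted hosts vs the community).

    For each genus with at least one genus-level link: its TPM share among
    all predicted host contigs, its TPM share among all prokaryotes, and the
    fraction of its links that came through the prophage channel.  Rows are
    ranked by predicted-host abundance; ``in_top_k_community`` flags overlap
    of the top-k host genera with the top-k community genera.
    """
    if top_k < 1:
        raise ValidationError(f"top_k must be >= 1, got {top_k}")
    with_genus = links[links["genus"].astype(str) != ""] if not links.empty else links
    if with_genus is None or with_genus.empty:
        return pd.DataFrame(
            columns=[
                "genus", "host_abundance_share", "community_share",
                "prophage_link_share", "in_top_k_community",
            ]
        )
    host_contigs = with_genus[["host_contig_id", "genus"]].drop_duplicates()
    host_tpm = host_contigs.assign(
        tpm=host_contigs["host_contig_id"].map(lambda c: float(prok_abundance.get(c, 0.0)))
    )
    genus_host_tpm = host_tpm.groupby("genus")["tpm"].sum()
    total_host = genus_host_tpm.sum()

    community = pd.Series(
        {c: float(v) for c, v in prok_abundance.items()}
    )
    comm_genus = community.groupby(
        community.index.map(lambda c: genus_of.get(c) or "")
    ).sum()
    comm_genus = comm_genus[comm_genus.index != ""]
    total_comm = comm_genus.sum()

    prophage_share = with_genus.groupby("genus")["channel"].agg(
        lambda ch: float((ch == "prophage").mean())
    )

    rows = pd.DataFrame(
        {
            "genus": genus_host_tpm.index,
            "host_abundance_share": (
                genus_host_tpm / total_host if total_host > 0 else 0.0
            ).to_numpy(),
            "community_share": [
                float(comm_genus.get(g, 0.0) / total_comm) if total_comm > 0 else 0.0
                for g in genus_host_tpm.index
            ],
            "prophage_link_share": [
                float(prophage_share.get(g, 0.0)) for g in genus_host_tpm.index
            ],
        }
    ).sort_values(
        ["host_abundance_share", "genus"], ascending=[False, True]
    ).reset_index(drop=True)
    top_hosts = set(rows["genus"].head(top_k))
    top_comm = set(comm_genus.sort_values(ascending=False).head(top_k).index)
    rows["in_top_k_community"] = rows["genus"].map(
        lambda g: g in top_hosts and g in top_comm
    )
    return rows
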