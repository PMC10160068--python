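"""Repeat-spacer array detection, spacer extraction, and the spacer burden
statistic M.

The detector finds maximal chains of at least ``min_repeats`` exact copies of
a direct repeat (length within ``repeat_len_range``) separated by gaps within
``spacer_len_range``; arrays are selected greedily, longest repeat first, and
may not overlap.  It is a deliberately exact-match stand-in for HMM/ML array
detectors: mismatch tolerance exists as a parameter but defaults to 0.

The burden statistic normalises spacer counts by contig length and weights by
relative abundance:

    M = sum over CRISPR-carrying contigs of (N / L) * A

with N the spacer count on the contig (all arrays summed), L the contig
length in bp, and A the contig's TPM in the sample.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import pandas as pd

from .io import ContigRecord, ValidationError


@dataclass(frozen=True)
class ArrayDetectionParams:
    repeat_len_range: tuple[int, int] = (23, 55)
    spacer_len_range: tuple[int, int] = (20, 60)
    min_repeats: int = 3
    max_repeat_mismatches: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.repeat_len_range, self.spacer_len_range):
            if lo >= hi:
                raise ValidationError("length ranges must be non-degenerate")
        if self.min_repeats < 2:
            raise ValidationError("min_repeats must be >= 2")


@dataclass(frozen=True)
class CrisprArray:
    contig_id: str
    repeat: str
    spacers: tuple[str, ...]
    interval: tuple[int, int]  # 0-based half-open on the contig

    def __post_init__(self) -> None:
        if len(self.spacers) < 1:
            raise ValidationError("an array needs at least one spacer")
        expected = (len(self.spacers) + 1) * len(self.repeat) + sum(
            map(len, self.spacers)
        )
        if self.interval[1] - self.interval[0] != expected:
            raise ValidationError(
                f"array interval on {self.contig_id!r} inconsistent with content"
            )

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)


@dataclass(frozen=True)
class SpacerBurden:
    sample_id: str
    M: float
    contributions: dict[str, float]


def _mismatches(a: str, b: str, limit: int) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > limit:
                return m
    return m


def _chains_for_word(
    seq: str, positions: list[int], length: int, params: ArrayDetectionParams
) -> list[tuple[int, ...]]:
    """Maximal occurrence chains of one repeat word, nearest-next greedy."""
    smin, smax = params.spacer_len_range
    pos_set = set(positions)
    nxt: dict[int, int | None] = {}
    for p in positions:
        chosen = None
        for gap in range(smin, smax + 1):
            if p + length + gap in pos_set:
                chosen = p + length + gap
                break
        nxt[p] = chosen
    has_pred = {q for q in nxt.values() if q is not None}
    chains = []
    for p in positions:
        if p in has_pred:
            continue
        chain = [p]
        while nxt[chain[-1]] is not None:
            chain.append(nxt[chain[-1]])
        if len(chain) >= params.min_repeats:
            chains.append(tuple(chain))
    return chains


def detect_crispr_arrays(
    contig: ContigRecord | str,
    params: ArrayDetectionParams = ArrayDetectionParams(),
) -> list[CrisprArray]:
    """Detect repeat-spacer arrays on one contig (see module docstring).

    Candidate (repeat, chain) pairs are ranked repeat-length descending, then
    start position, then repeat text; arrays are accepted in that order if
    they do not overlap an already accepted array.  Deterministic.
    """
    if params.max_repeat_mismatches != 0:
        raise NotImplementedError(
            "inexact repeat matching is exposed as a parameter but not implemented"
        )
    seq = contig.sequence if isinstance(contig, ContigRecord) else contig
    cid = contig.contig_id if isinstance(contig, ContigRecord) else ""
    lmin, lmax = params.repeat_len_range
    # any repeat of length >= lmin repeated min_repeats times implies a
    # repeated lmin-word, so contigs without one (the vast majority) exit here
    seed_counts: dict[str, int] = {}
    has_seed = False
    for i in range(len(seq) - lmin + 1):
        w = seq[i : i + lmin]
        seed_counts[w] = seed_counts.get(w, 0) + 1
        if seed_counts[w] >= params.min_repeats:
            has_seed = True
            break
    if not has_seed:
        return []
    candidates: list[tuple[int, int, str, tuple[int, ...]]] = []
    for length in range(min(lmax, len(seq)), lmin - 1, -1):
        index: dict[str, list[int]] = {}
        for i in range(len(seq) - length + 1):
            word = seq[i : i + length]
            if "N" in word:  # N matches nothing in exact operations
                continue
            index.setdefault(word, []).append(i)
        for word, positions in index.items():
            if len(positions) < params.min_repeats:
                continue
            for chain in _chains_for_word(seq, positions, length, params):
                candidates.append((length, chain[0], word, chain))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    taken: list[tuple[int, int]] = []
    arrays: list[CrisprArray] = []
    for length, start, word, chain in candidates:
        end = chain[-1] + length
        if any(start < e and s < end for s, e in taken):
            continue
        spacers = tuple(
            seq[chain[i] + length : chain[i + 1]] for i in range(len(chain) - 1)
        )
        arrays.append(CrisprArray(cid, word, spacers, (start, end)))
        taken.append((start, end))
    arrays.sort(key=lambda a: a.interval)
    return arrays


def detect_all_arrays(
    contigs: list[ContigRecord],
    params: ArrayDetectionParams = ArrayDetectionParams(),
    categories: tuple[str, ...] = ("prokaryotic",),
) -> list[CrisprArray]:
    out = []
    for c in contigs:
        if c.category in categories:
            out.extend(detect_crispr_arrays(c, params))
    return out


def extract_spacers(arrays: list[CrisprArray]) -> pd.DataFrame:
    """Spacer table in genomic order: contig_id, spacer_index, spacer, duplicate.

    ``duplicate`` flags spacers byte-identical to an earlier spacer on the
    same contig; rows are kept (the count matters for N).
    """
    rows = []
    per_contig_seen: dict[str, set[str]] = {}
    per_contig_index: dict[str, int] = {}
    for arr in sorted(arrays, key=lambda a: (a.contig_id, a.interval)):
        seen = per_contig_seen.setdefault(arr.contig_id, set())
        for sp in arr.spacers:
            idx = per_contig_index.get(arr.contig_id, 0)
            rows.append(
                {
                    "contig_id": arr.contig_id,
                    "spacer_index": idx,
                    "spacer": sp,
                    "duplicate": sp in seen,
                }
            )
            seen.add(sp)
            per_contig_index[arr.contig_id] = idx + 1
    return pd.DataFrame(rows, columns=["contig_id", "spacer_index", "spacer", "duplicate"])


def spacer_counts(arrays: list[CrisprArray]) -> dict[str, int]:
    """N per contig: spacers summed over all arrays on the contig."""
    n: dict[str, int] = {}
    for arr in arrays:
        n[arr.contig_id] = n.get(arr.contig_id, 0) + arr.n_spacers
    return n


def spacer_burden(
    arrays: list[CrisprArray],
    lengths: Mapping[str, int],
    abundance: pd.Series,
) -> SpacerBurden:
    """M = sum(N/L * A) for one sample's abundance column."""
    sample_id = str(abundance.name) if abundance.name is not None else ""
    contributions: dict[str, float] = {}
    for cid, n in sorted(spacer_counts(arrays).items()):
        if cid not in lengths:
            raise ValidationError(f"no length for CRISPR contig {cid!r}")
        if cid not in abundance.index:
            raise ValidationError(f"no abundance for CRISPR contig {cid!r}")
        contributions[cid] = n / lengths[cid] * float(abundance[cid])
    return SpacerBurden(sample_id, float(sum(contributions.values())), contributions)
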