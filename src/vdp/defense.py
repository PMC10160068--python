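"""Community-level profiling of prokaryotic antiviral systems.

All quantities follow contig-level abundance semantics: "relative abundance
of contigs with system X" is the summed TPM of the contigs carrying X, not a
per-gene copy abundance.  A contig carrying several systems of the same
family contributes its TPM once per family; carrier fractions count each
carrying contig once regardless of how many annotations it has.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Iterable, Mapping

import pandas as pd

from .abundance import SCALE
from .io import ValidationError

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("contig_id", "family", "subtype")

#: default controlled vocabulary of subtypes per family (config-extensible)
DEFAULT_SUBTYPE_VOCAB: dict[str, tuple[str, ...]] = {
    "RM": ("Type_I", "Type_II", "Type_IIG", "Type_III", "Type_IV"),
    "CRISPR-Cas": ("Type_I", "Type_II", "Type_III", "Type_IV", "Type_V"),
}


def validate_annotations(
    annotations: pd.DataFrame,
    vocab: Mapping[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Check the defense annotation schema and (optionally) subtype vocabulary."""
    missing = set(ANNOTATION_COLUMNS) - set(annotations.columns)
    if missing:
        raise ValidationError(f"defense annotations missing columns {sorted(missing)}")
    if (annotations["family"].astype(str) == "").any():
        raise ValidationError("defense annotation with empty family")
    if vocab is not None:
        for row in annotations.itertuples(index=False):
            sub = "" if pd.isna(row.subtype) else str(row.subtype)
            if sub and row.family in vocab and sub not in vocab[row.family]:
                raise ValidationError(
                    f"subtype {sub!r} not in vocabulary of family {row.family!r}"
                )
    return annotations


def carrier_fraction(
    annotations: pd.DataFrame,
    abundance: pd.Series,
    universe: Iterable[str],
) -> float:
    """TPM share of annotation-carrying contigs within ``universe``.

    Each carrying contig counts once.  The denominator is the summed TPM of
    the universe; an empty universe is a validation error.
    """
    universe = list(universe)
    if not universe:
        raise ValidationError("carrier_fraction: empty universe")
    uni_tpm = abundance.reindex(universe, fill_value=0.0)
    total = float(uni_tpm.sum())
    if total == 0:
        return 0.0
    carriers = set(annotations["contig_id"].astype(str)) & set(universe)
    return float(uni_tpm.reindex(sorted(carriers), fill_value=0.0).sum() / total)


def _family_tpm_one_sample(
    annotations: pd.DataFrame, abundance: pd.Series
) -> pd.Series:
    pairs = annotations[["contig_id", "family"]].drop_duplicates()
    tpm = pairs["contig_id"].map(lambda c: float(abundance.get(c, 0.0)))
    out = tpm.groupby(pairs["family"].to_numpy()).sum()
    return out.sort_index()


def profile_families(
    annotations: pd.DataFrame,
    abundance: pd.DataFrame | pd.Series,
    grouping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-family TPM and proportion of total defense TPM, per grouping.

    ``abundance`` is a contig x sample table (or one column).  With a
    ``grouping`` (sample -> condition) the per-sample profiles are averaged
    within each group; without one, each sample is its own group.  Output
    rows: group, family, tpm, proportion, share_of_total (TPM / 1e6), sorted
    by TPM descending then family name within each group.
    """
    if isinstance(abundance, pd.Series):
        abundance = abundance.to_frame()
    per_sample = {}
    for sample in abundance.columns:
        per_sample[sample] = _family_tpm_one_sample(annotations, abundance[sample])
    fam_tpm = pd.DataFrame(per_sample).fillna(0.0)
    if fam_tpm.empty:
        logger.warning("profile_families: no annotations, zero profile")
        return pd.DataFrame(
            columns=["group", "family", "tpm", "proportion", "share_of_total"]
        )
    if grouping is not None:
        groups = fam_tpm.T.groupby(
            [grouping[s] for s in fam_tpm.columns]
        ).mean().T
    else:
        groups = fam_tpm
    rows = []
    for group in groups.columns:
        col = groups[group]
        total = float(col.sum())
        for family, tpm in col.items():
            rows.append(
                {
                    "group": group,
                    "family": family,
                    "tpm": float(tpm),
                    "proportion": float(tpm / total) if total > 0 else 0.0,
                    "share_of_total": float(tpm / SCALE),
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["group", "tpm", "family"], ascending=[True, False, True]
    ).reset_index(drop=True)


def subtype_shares(
    annotations: pd.DataFrame,
    abundance: pd.Series,
    family: str,
    vocab: Mapping[str, tuple[str, ...]] | None = None,
) -> pd.Series:
    """TPM share of each subtype within one family (sums to 1).

    Mass from annotations without a subtype is reported under ``unknown``.
    An unknown family (absent from the vocabulary) is a validation error; a
    family simply absent from the annotations yields an empty mapping.
    """
    vocab = DEFAULT_SUBTYPE_VOCAB if vocab is None else vocab
    if family not in vocab:
        raise ValidationError(f"family {family!r} not in subtype vocabulary")
    fam = annotations[annotations["family"] == family]
    if fam.empty:
        logger.warning("subtype_shares: no annotations for family %s", family)
        return pd.Series(dtype=float)
    fam = fam.copy()
    fam["subtype"] = fam["subtype"].map(
        lambda s: "unknown" if pd.isna(s) or str(s) == "" else str(s)
    )
    pairs = fam[["contig_id", "subtype"]].drop_duplicates()
    tpm = pairs["contig_id"].map(lambda c: float(abundance.get(c, 0.0)))
    shares = tpm.groupby(pairs["subtype"].to_numpy()).sum().sort_index()
    total = float(shares.sum())
    if total == 0:
        return pd.Series(0.0, index=shares.index)
    return shares / total


def restricted_profile(
    annotations: pd.DataFrame,
    abundance: pd.DataFrame | pd.Series,
    restriction: Callable[[str], bool],
    grouping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """``profile_families`` restricted to contigs satisfying a predicate.

    Typical predicates: "contig hosts a prophage" (lysogenized prokaryotes)
    or "contig is a lytic/lysogenic viral contig" (phage-carried systems).
    The predicate must be decidable for every annotated contig.
    """
    keep = []
    for cid in annotations["contig_id"].astype(str):
        verdict = restriction(cid)
        if verdict is None:
            raise ValidationError(f"restriction undecidable for contig {cid!r}")
        keep.append(bool(verdict))
    restricted = annotations.loc[keep]
    if restricted.empty:
        logger.warning("restricted_profile: restriction satisfied by no contig")
    return profile_families(restricted, abundance, grouping)
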