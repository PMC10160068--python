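#!/usr/bin/env python
"""Profile the antiviral arsenal: carrier fractions, per-family abundance and
proportions, RM / CRISPR-Cas subtype shares, and the CRISPR spacer burden
M = sum(N/L * A).

Reads results/community/ and results/abundance/, writes results/defense/.
"""

from pathlib import Path

import pandas as pd

from vdp.crispr import detect_all_arrays, spacer_burden
from vdp.defense import carrier_fraction, profile_families, subtype_shares
from vdp.io import read_fasta, read_table

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    community = BASE / "community"
    out = BASE / "defense"
    out.mkdir(parents=True, exist_ok=True)

    contigs = read_fasta(community / "contigs.fasta")
    categories = read_table(community / "categories.tsv")
    cat = dict(zip(categories["contig_id"], categories["category"]))
    for c in contigs:
        c.category = cat[c.contig_id]
    tpm = pd.read_csv(BASE / "abundance" / "tpm.tsv", sep="\t", index_col=0)
    samples = read_table(community / "samples.tsv")
    grouping = dict(zip(samples["sample_id"], samples["condition"]))
    defense = read_table(community / "defense.tsv")

    prok_ids = [c.contig_id for c in contigs if c.category == "prokaryotic"]
    prok_defense = defense[defense["contig_id"].isin(prok_ids)]

    carriers = pd.DataFrame(
        {
            "sample_id": tpm.columns,
            "condition": [grouping[s] for s in tpm.columns],
            "carrier_fraction": [
                carrier_fraction(prok_defense, tpm[s], prok_ids)
                for s in tpm.columns
            ],
        }
    )
    carriers.to_csv(out / "carrier_fraction.tsv", sep="\t", index=False)

    profile = profile_families(prok_defense, tpm, grouping=grouping)
    profile.to_csv(out / "family_profile.tsv", sep="\t", index=False)

    mean_tpm = tpm.mean(axis=1)
    shares = []
    for family in ("RM", "CRISPR-Cas"):
        s = subtype_shares(prok_defense, mean_tpm, family)
        shares.extend(
            {"family": family, "subtype": k, "share": float(v)}
            for k, v in s.items()
        )
    pd.DataFrame(shares).to_csv(out / "subtype_shares.tsv", sep="\t", index=False)

    arrays = detect_all_arrays(contigs)
    lengths = {c.contig_id: c.length for c in contigs}
    burden = pd.DataFrame(
        {
            "sample_id": tpm.columns,
            "condition": [grouping[s] for s in tpm.columns],
            "M": [spacer_burden(arrays, lengths, tpm[s]).M for s in tpm.columns],
        }
    )
    burden.to_csv(out / "spacer_burden.tsv", sep="\t", index=False)

    by_cond = carriers.groupby("condition")["carrier_fraction"].mean()
    print("defense-carrier TPM share by condition:")
    print((100 * by_cond).round(2).astype(str).add("%").to_string())
    print(f"fold change: "
          f"{by_cond['disinfected'] / by_cond['non_disinfected']:.1f}x")
    top = profile[profile["group"] == "disinfected"].head(3)
    print("top defense families (disinfected):")
    for row in top.itertuples(index=False):
        print(f"  {row.family}: {100 * row.proportion:.0f}% of defense TPM")
    print(f"{len(arrays)} CRISPR arrays; mean M = {burden['M'].mean():.3f}")


if __name__ == "__main__":
    main()
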