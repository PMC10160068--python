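#!/usr/bin/env python
"""Quantify contig abundance (TPM) per sample after the 30 bp aligned-length
filter, and summarise per-sample diversity.

Reads results/community/, writes results/abundance/.
"""

from pathlib import Path

import pandas as pd

from vdp.abundance import tpm_table
from vdp.io import read_alignments, read_fasta, read_table
from vdp.stats import shannon

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    community = BASE / "community"
    out = BASE / "abundance"
    out.mkdir(parents=True, exist_ok=True)

    contigs = read_fasta(community / "contigs.fasta")
    lengths = {c.contig_id: c.length for c in contigs}
    samples = read_table(community / "samples.tsv")
    alignments = {
        s: read_alignments(community / f"alignments_{s}.tsv", "tsv")
        for s in samples["sample_id"]
    }
    table = tpm_table(alignments, lengths, min_aligned=30)
    table.rename_axis("contig_id").to_csv(out / "tpm.tsv", sep="\t")

    n_raw = sum(len(a) for a in alignments.values())
    diversity = pd.DataFrame(
        {
            "sample_id": table.columns,
            "condition": samples.set_index("sample_id").loc[
                table.columns, "condition"
            ].to_numpy(),
            "shannon": [shannon(table[s].to_numpy()) for s in table.columns],
        }
    )
    diversity.to_csv(out / "diversity.tsv", sep="\t", index=False)

    print(f"TPM table: {table.shape[0]} contigs x {table.shape[1]} samples "
          f"(from {n_raw} alignment records)")
    print("mean Shannon index by condition:")
    print(diversity.groupby("condition")["shannon"].mean().round(3).to_string())


if __name__ == "__main__":
    main()
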