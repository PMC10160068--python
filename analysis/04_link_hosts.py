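#!/usr/bin/env python
"""Link phages to hosts through the three in-situ evidence channels (CRISPR
spacers, shared tRNAs, prophage localization), classify polyvalent phages and
summarise the host populations; evaluate against the planted truth.

Reads results/community/ and results/abundance/, writes results/linkage/.
"""

from pathlib import Path

import pandas as pd

from vdp.crispr import detect_all_arrays, extract_spacers
from vdp.io import lineage_from_string, read_fasta, read_table
from vdp.linkage import (
    classify_polyvalent,
    host_population_summary,
    link_prophages,
    match_spacers,
    match_trnas,
    merge_links,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    community = BASE / "community"
    out = BASE / "linkage"
    out.mkdir(parents=True, exist_ok=True)

    contigs = read_fasta(community / "contigs.fasta")
    categories = read_table(community / "categories.tsv")
    cat = dict(zip(categories["contig_id"], categories["category"]))
    taxonomy = read_table(community / "prok_taxonomy.tsv")
    genus_of = {}
    for row in taxonomy.itertuples(index=False):
        genus_of[row.contig_id] = dict(lineage_from_string(row.lineage)).get("genus")
    for c in contigs:
        c.category = cat[c.contig_id]

    viral = [c for c in contigs if c.category in ("free_viral", "prophage")]
    prok_ids = {c.contig_id for c in contigs if c.category == "prokaryotic"}
    lengths = {c.contig_id: c.length for c in contigs}

    arrays = detect_all_arrays(contigs)
    spacers = extract_spacers(arrays)
    trna = read_table(community / "trna.tsv")
    merged, channel_counts, multi = merge_links(
        [
            match_spacers(spacers, viral),
            match_trnas(
                trna[~trna["contig_id"].isin(prok_ids)],
                trna[trna["contig_id"].isin(prok_ids)],
            ),
            link_prophages(read_table(community / "prophages.tsv"), lengths),
        ],
        genus_of,
    )
    merged.to_csv(out / "links.tsv", sep="\t", index=False)

    tpm = pd.read_csv(BASE / "abundance" / "tpm.tsv", sep="\t", index_col=0)
    mean_tpm = tpm.mean(axis=1)
    summary, count_frac, abund_frac = classify_polyvalent(
        merged, mean_tpm[mean_tpm.index.isin({v.contig_id for v in viral})]
    )
    summary.to_csv(out / "hostrange.tsv", sep="\t", index=False)
    hosts = host_population_summary(
        merged, mean_tpm[mean_tpm.index.isin(prok_ids)], genus_of
    )
    hosts.to_csv(out / "host_populations.tsv", sep="\t", index=False)

    truth = read_table(community / "truth_links.tsv")
    planted = set(zip(truth["phage_id"], truth["host_contig_id"], truth["channel"]))
    predicted = set(zip(merged["phage_id"], merged["host_contig_id"],
                        merged["channel"]))
    tp = len(planted & predicted)

    print(f"{len(merged)} links: {channel_counts} "
          f"({multi} phages linked by >= 2 channels)")
    print(f"polyvalent phages: {100 * count_frac:.0f}% by count, "
          f"{100 * abund_frac:.0f}% by abundance")
    print(f"vs planted truth: precision {tp / len(predicted):.3f}, "
          f"recall {tp / len(planted):.3f}")
    print(f"top predicted host genus: {hosts.iloc[0]['genus']} "
          f"({100 * hosts.iloc[0]['host_abundance_share']:.0f}% of host TPM)")


if __name__ == "__main__":
    main()
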