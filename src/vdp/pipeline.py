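"""End-to-end orchestration: quantify -> annotate -> CRISPR -> link ->
profile -> compare conditions; emits a TSV report bundle plus a manifest.

All stage outputs are accumulated in memory and written only on success, so
a failing stage leaves no partial output directory behind.  Reruns with the
same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import tpm_table
from .crispr import detect_all_arrays, extract_spacers, spacer_burden
from .defense import (
    DEFAULT_SUBTYPE_VOCAB,
    carrier_fraction,
    profile_families,
    restricted_profile,
    subtype_shares,
    validate_annotations,
)
from .io import (
    ContigRecord,
    ValidationError,
    lineage_from_string,
    read_alignments,
    read_fasta,
    read_table,
)
from .linkage import (
    classify_polyvalent,
    host_population_summary,
    link_prophages,
    match_spacers,
    match_trnas,
    merge_links,
)
from .stats import (
    bray_curtis_matrix,
    euclidean_matrix,
    mantel,
    pcoa,
    pearson,
    shannon,
    t_test,
)
from .synth import (
    SyntheticConfig,
    config_to_dict,
    generate_community,
    simulate_alignments,
)
from .taxonomy import assign_taxonomy_table, attach_lifestyles, read_gene_hits

logger = logging.getLogger(__name__)

ALL_STAGES = ("quant", "taxa", "crispr", "link", "profile", "stats")


@dataclass
class PipelineConfig:
    outdir: str | Path
    synthetic: SyntheticConfig | None = None
    input_dir: str | Path | None = None
    seed: int = 0
    min_aligned: int = 30
    stages: tuple[str, ...] = ALL_STAGES
    mantel_permutations: int = 199
    top_k_hosts: int = 20

    def validate(self) -> None:
        if self.synthetic is None and self.input_dir is None:
            raise ValidationError("need either a synthetic config or an input_dir")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages {sorted(unknown)}")


def _load_inputs(input_dir: Path):
    contigs = read_fasta(input_dir / "contigs.fasta")
    cats = read_table(input_dir / "categories.tsv", required=("contig_id", "category"))
    cat_map = dict(zip(cats["contig_id"].astype(str), cats["category"].astype(str)))
    for c in contigs:
        c.category = cat_map.get(c.contig_id, "prokaryotic")
    taxonomy = read_table(
        input_dir / "prok_taxonomy.tsv", required=("contig_id", "lineage")
    )
    for c in contigs:
        row = taxonomy.loc[taxonomy["contig_id"] == c.contig_id, "lineage"]
        if len(row):
            c.lineage = lineage_from_string(row.iloc[0])
    samples = read_table(input_dir / "samples.tsv", required=("sample_id", "condition"))
    alignments = {
        str(r.sample_id): read_alignments(
            input_dir / f"alignments_{r.sample_id}.tsv", "tsv"
        )
        for r in samples.itertuples(index=False)
    }
    features = {
        "prophages": read_table(input_dir / "prophages.tsv"),
        "trna": read_table(input_dir / "trna.tsv"),
        "defense": read_table(input_dir / "defense.tsv"),
        "lifestyles": read_table(input_dir / "lifestyles.tsv"),
        "samples": samples,
    }
    gene_hits_path = input_dir / "gene_hits.tsv"
    features["gene_hits_parsed"] = (
        read_gene_hits(gene_hits_path) if gene_hits_path.exists() else ({}, {})
    )
    return contigs, features, alignments


def per_sample_summaries(
    tpm: pd.DataFrame,
    contigs: list[ContigRecord],
    defense: pd.DataFrame,
    arrays,
) -> pd.DataFrame:
    """Per-sample headline quantities: viral share, lysogenic fraction,
    defense-carrier share, spacer burden M, Shannon index."""
    prok_ids = [c.contig_id for c in contigs if c.category == "prokaryotic"]
    viral_ids = [c.contig_id for c in contigs if c.category in ("free_viral", "prophage")]
    lys_ids = [
        c.contig_id for c in contigs
        if c.category in ("free_viral", "prophage") and c.lifestyle == "lysogenic"
    ]
    lengths = {c.contig_id: c.length for c in contigs}
    prok_defense = defense[defense["contig_id"].isin(prok_ids)]
    rows = []
    for sample in tpm.columns:
        col = tpm[sample]
        viral_tpm = float(col.reindex(viral_ids, fill_value=0).sum())
        lys_tpm = float(col.reindex(lys_ids, fill_value=0).sum())
        burden = spacer_burden(arrays, lengths, col) if arrays is not None else None
        rows.append(
            {
                "sample_id": sample,
                "viral_share": viral_tpm / 1e6,
                "lysogenic_fraction": lys_tpm / viral_tpm if viral_tpm > 0 else 0.0,
                "defense_carrier_share": carrier_fraction(prok_defense, col, prok_ids),
                "spacer_burden_M": burden.M if burden is not None else np.nan,
                "shannon": shannon(col.to_numpy() + 0.0)
                if float(col.sum()) > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def evaluate_links(merged: pd.DataFrame, truth_links: set) -> dict[str, float]:
    """Precision/recall of predicted (phage, host, channel) triples vs truth."""
    insitu = merged[merged["channel"].isin(["crispr", "trna", "prophage"])]
    predicted = {
        (r.phage_id, r.host_contig_id, r.channel)
        for r in insitu.itertuples(index=False)
    }
    true = {(p, h, ch) for p, h, _g, ch in truth_links}
    tp = len(predicted & true)
    precision = tp / len(predicted) if predicted else float("nan")
    recall = tp / len(true) if true else float("nan")
    return {"precision": precision, "recall": recall,
            "n_predicted": len(predicted), "n_true": len(true)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the report bundle and writes it."""
    config.validate()
    report: dict = {}
    tables: dict[str, pd.DataFrame] = {}
    counts: dict[str, int] = {}

    truth = None
    if config.synthetic is not None:
        syn = config.synthetic
        contigs, features, truth = generate_community(syn)
        alignments = simulate_alignments(contigs, truth, syn)
    else:
        contigs, features, alignments = _load_inputs(Path(config.input_dir))
    counts["contigs"] = len(contigs)
    counts["samples"] = len(alignments)
    logger.info("pipeline: %d contigs, %d samples", len(contigs), len(alignments))

    lengths = {c.contig_id: c.length for c in contigs}
    sample_conditions = dict(
        zip(
            features["samples"]["sample_id"].astype(str),
            features["samples"]["condition"].astype(str),
        )
    )
    defense = validate_annotations(features["defense"])
    prok_ids = [c.contig_id for c in contigs if c.category == "prokaryotic"]
    viral_contigs = [c for c in contigs if c.category in ("free_viral", "prophage")]
    genus_of = {c.contig_id: c.genus for c in contigs}

    # --- quant ---------------------------------------------------------------
    tpm = tpm_table(alignments, lengths, min_aligned=config.min_aligned)
    tables["abundance"] = tpm.rename_axis("contig_id").reset_index()
    counts["alignment_records"] = int(sum(len(a) for a in alignments.values()))

    # --- taxa ----------------------------------------------------------------
    if "taxa" in config.stages:
        if config.synthetic is not None:
            from .taxonomy import GeneHit

            gh_df = features["gene_hits"]
            hits: dict[str, list] = {}
            n_genes: dict[str, int] = {}
            for r in gh_df.itertuples(index=False):
                hits.setdefault(str(r.contig_id), []).append(
                    GeneHit(str(r.contig_id), int(r.gene_index),
                            tuple(lineage_from_string(r.lineage)), float(r.evalue))
                )
                n_genes[str(r.contig_id)] = int(r.n_genes)
        else:
            hits, n_genes = features["gene_hits_parsed"]
        tables["taxonomy"] = assign_taxonomy_table(hits, n_genes)
        counts["taxa_assigned"] = int(
            (tables["taxonomy"]["rank_assigned"] != "").sum()
        )
    labels = dict(
        zip(
            features["lifestyles"]["phage_id"].astype(str),
            features["lifestyles"]["lifestyle"].astype(str),
        )
    )
    attach_lifestyles(contigs, labels)

    # --- crispr --------------------------------------------------------------
    arrays = None
    spacers = pd.DataFrame(columns=["contig_id", "spacer_index", "spacer", "duplicate"])
    if "crispr" in config.stages:
        arrays = detect_all_arrays(contigs)
        spacers = extract_spacers(arrays)
        tables["arrays"] = pd.DataFrame(
            [
                {"contig_id": a.contig_id, "repeat": a.repeat,
                 "n_spacers": a.n_spacers, "start": a.interval[0],
                 "end": a.interval[1]}
                for a in arrays
            ],
            columns=["contig_id", "repeat", "n_spacers", "start", "end"],
        )
        tables["spacers"] = spacers
        tables["burden"] = pd.DataFrame(
            [
                {"sample_id": s,
                 "M": spacer_burden(arrays, lengths, tpm[s]).M}
                for s in tpm.columns
            ]
        )
        counts["crispr_arrays"] = len(arrays)

    # --- link ----------------------------------------------------------------
    merged = pd.DataFrame()
    if "link" in config.stages:
        crispr_links = match_spacers(spacers, viral_contigs)
        prok_trna = features["trna"][features["trna"]["contig_id"].isin(prok_ids)]
        viral_ids_set = {c.contig_id for c in viral_contigs}
        viral_trna = features["trna"][features["trna"]["contig_id"].isin(viral_ids_set)]
        trna_links = match_trnas(viral_trna, prok_trna)
        prophage_links = link_prophages(features["prophages"], lengths)
        merged, channel_counts, multi = merge_links(
            [crispr_links, trna_links, prophage_links], genus_of
        )
        tables["links"] = merged
        mean_viral_tpm = tpm.loc[tpm.index.isin(viral_ids_set)].mean(axis=1)
        summary, count_frac, abund_frac = classify_polyvalent(merged, mean_viral_tpm)
        tables["hostrange"] = summary
        mean_prok_tpm = tpm.loc[tpm.index.isin(prok_ids)].mean(axis=1)
        tables["host_populations"] = host_population_summary(
            merged, mean_prok_tpm, genus_of, top_k=config.top_k_hosts
        )
        report["linkage"] = {
            "channel_counts": channel_counts,
            "multi_channel_phages": multi,
            "polyvalent_fraction_count": count_frac,
            "polyvalent_fraction_abundance": abund_frac,
        }
        counts.update({f"links_{k}": v for k, v in channel_counts.items()})
        if truth is not None:
            report["linkage_truth"] = evaluate_links(merged, truth.true_host_links)

    # --- profile -------------------------------------------------------------
    if "profile" in config.stages:
        prok_defense = defense[defense["contig_id"].isin(prok_ids)]
        tables["defense_profile"] = profile_families(
            prok_defense, tpm, grouping=sample_conditions
        )
        carrier_rows = []
        for s in tpm.columns:
            carrier_rows.append(
                {"sample_id": s, "condition": sample_conditions[s],
                 "carrier_fraction": carrier_fraction(prok_defense, tpm[s], prok_ids)}
            )
        tables["carrier_fraction"] = pd.DataFrame(carrier_rows)
        mean_tpm = tpm.mean(axis=1)
        sub_rows = []
        for family in sorted(DEFAULT_SUBTYPE_VOCAB):
            shares = subtype_shares(prok_defense, mean_tpm, family)
            for subtype, share in shares.items():
                sub_rows.append(
                    {"family": family, "subtype": subtype, "share": float(share)}
                )
        tables["subtype_shares"] = pd.DataFrame(
            sub_rows, columns=["family", "subtype", "share"]
        )
        lysogen_hosts = set(features["prophages"]["host_contig_id"].astype(str))
        tables["defense_profile_lysogens"] = restricted_profile(
            prok_defense, tpm, lambda cid: cid in lysogen_hosts,
            grouping=sample_conditions,
        )
        lifestyle_of = {c.contig_id: c.lifestyle for c in viral_contigs}
        category_of = {c.contig_id: c.category for c in contigs}
        phage_defense = defense[defense["contig_id"].isin(lifestyle_of)]
        phage_rows = []
        for split, pred in (
            ("lytic", lambda cid: category_of[cid] == "free_viral"
             and lifestyle_of[cid] == "lytic"),
            ("lysogenic", lambda cid: category_of[cid] == "free_viral"
             and lifestyle_of[cid] == "lysogenic"),
            ("prophage", lambda cid: category_of[cid] == "prophage"),
        ):
            prof = restricted_profile(phage_defense, tpm, pred)
            prof.insert(0, "carrier_split", split)
            if not prof.empty:
                phage_rows.append(prof)
        cols = ["carrier_split", "group", "family", "tpm", "proportion",
                "share_of_total"]
        tables["defense_profile_phage"] = (
            pd.concat(phage_rows, ignore_index=True)
            if phage_rows else pd.DataFrame(columns=cols)
        )

    # --- stats ---------------------------------------------------------------
    if "stats" in config.stages:
        summaries = per_sample_summaries(tpm, contigs, defense, arrays)
        summaries["condition"] = summaries["sample_id"].map(sample_conditions)
        tables["per_sample"] = summaries
        stat_rows = []
        a_mask = summaries["condition"] == "disinfected"
        quantities = [
            "viral_share", "lysogenic_fraction", "defense_carrier_share", "shannon",
        ]
        if arrays is not None:
            quantities.append("spacer_burden_M")
        for col in quantities:
            a = summaries.loc[a_mask, col].dropna().to_numpy()
            b = summaries.loc[~a_mask, col].dropna().to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                try:
                    res = t_test(a, b)
                except ValidationError:
                    continue
                stat_rows.append(
                    {"test": f"t:{col}", "statistic": res.statistic,
                     "p_value": res.p_value, "method": res.method,
                     "n_permutations": ""}
                )
        pr = pearson(
            summaries["viral_share"].to_numpy(),
            summaries["defense_carrier_share"].to_numpy(),
        )
        stat_rows.append(
            {"test": "pearson:viral_share~defense_carrier_share",
             "statistic": pr.statistic, "p_value": pr.p_value,
             "method": pr.method, "n_permutations": ""}
        )
        bc = bray_curtis_matrix(tpm)
        coords, evals, var_exp = pcoa(bc, k=2)
        tables["pcoa"] = pd.DataFrame(
            {"sample_id": bc.ids, "PCo1": coords[:, 0], "PCo2": coords[:, 1],
             "condition": [sample_conditions[s] for s in bc.ids]}
        )
        report["pcoa_variance_explained"] = [float(var_exp[0]), float(var_exp[1])]
        meta = features["samples"].set_index("sample_id").loc[list(bc.ids)]
        for covariate in ("chlorine", "phosphate"):
            if covariate in meta.columns:
                env = euclidean_matrix(meta[covariate].to_numpy(), bc.ids)
                res = mantel(
                    bc, env, n_perm=config.mantel_permutations,
                    seed=config.seed + 1,
                )
                stat_rows.append(
                    {"test": f"mantel:bray_curtis~{covariate}",
                     "statistic": res.statistic, "p_value": res.p_value,
                     "method": res.method, "n_permutations": res.n_permutations}
                )
        tables["stats"] = pd.DataFrame(stat_rows)

    # --- write everything ----------------------------------------------------
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    manifest = {
        "package": "vdp",
        "version": __version__,
        "seed": config.seed,
        "min_aligned": config.min_aligned,
        "stages": list(config.stages),
        "synthetic": config_to_dict(config.synthetic) if config.synthetic else None,
        "counts": counts,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    report["tables"] = tables
    report["counts"] = counts
    report["manifest"] = manifest
    return report
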