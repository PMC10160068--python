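"""Seeded synthetic drinking-water-like metagenome with planted ground truth.

The generator emulates the data layout of a two-condition drinking-water
study (disinfected vs non-disinfected distribution systems): genus-structured
prokaryotic contigs, i.i.d.-random free viral contigs, prophages embedded
verbatim into host contigs, CRISPR arrays whose viral-sourced spacers occur
verbatim (either strand) in exactly one viral contig, tRNA genes shared
between viral contigs and their hosts, defense-system annotations, lifestyle
labels, per-sample alignment records, and environmental covariates.

Abundance model: lognormal genus and contig effects, multinomial reads.
Carrier/lifestyle status is a per-contig property; the condition effects on
defense-carrier abundance and lysogeny are realised as abundance tilts so
that the *expected TPM-weighted share* of carriers (within prokaryotes) and
of lysogenic phages (within the virome) in a sample equals the configured
per-condition rate.

Seeding: one master seed; per-stage child generators derived from fixed
stage offsets, so stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .crispr import CrisprArray
from .io import ContigRecord, ValidationError, lineage_to_string, write_fasta
from .linkage import revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")

CONDITIONS = ("disinfected", "non_disinfected")

# fixed stage offsets for child generators
_STAGE = {
    "prok_seq": 0, "viral_seq": 1, "prophage": 2, "crispr": 3, "trna": 4,
    "defense": 5, "lifestyle": 6, "abundance": 7, "covariates": 8,
    "gene_hits": 9, "alignments": 100,
}


def _rng(seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, _STAGE[stage], extra])


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic community (defaults are the
    desk-scale analogue of the two-condition drinking-water design)."""

    n_genera: int = 8
    contigs_per_genus: int = 12
    contig_length_range: tuple[int, int] = (2000, 6000)
    n_viral_contigs: int = 60
    viral_length_range: tuple[int, int] = (1500, 4000)
    prophage_rate: float = 0.1
    crispr_rate: float = 0.3
    spacers_per_array_range: tuple[int, int] = (2, 6)
    spacer_source_rate: float = 0.8
    spacer_length: int = 32
    repeat_length: int = 28
    trna_share_rate: float = 0.15
    prok_trna_rate: float = 0.8
    trna_length: int = 72
    defense_rate_by_condition: dict[str, float] = field(
        default_factory=lambda: {"disinfected": 0.14, "non_disinfected": 0.02}
    )
    viral_defense_rate: float = 0.1
    defense_family_weights: dict[str, float] = field(
        default_factory=lambda: {
            "RM": 0.51, "CRISPR-Cas": 0.15, "BREX": 0.08, "Abi": 0.06,
            "CBASS": 0.05, "Other": 0.15,
        }
    )
    lysogeny_rate_by_condition: dict[str, float] = field(
        default_factory=lambda: {"disinfected": 0.3, "non_disinfected": 0.1}
    )
    viral_share_by_condition: dict[str, float] = field(
        default_factory=lambda: {"disinfected": 0.014, "non_disinfected": 0.003}
    )
    n_samples_per_condition: int = 10
    reads_per_sample: int = 20000
    abundance_lognormal_sigma: float = 1.0
    short_aligned_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.prophage_rate, self.crispr_rate, self.spacer_source_rate,
            self.trna_share_rate, self.prok_trna_rate, self.viral_defense_rate,
            self.short_aligned_fraction,
            *self.defense_rate_by_condition.values(),
            *self.lysogeny_rate_by_condition.values(),
            *self.viral_share_by_condition.values(),
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValidationError("all probabilities must be in [0, 1]")
        for lo, hi in (
            self.contig_length_range, self.viral_length_range,
            self.spacers_per_array_range,
        ):
            if lo >= hi:
                raise ValidationError("ranges must be non-degenerate (lo < hi)")
        if self.spacers_per_array_range[0] < 2:
            raise ValidationError("need at least 2 spacers per array")
        w = list(self.defense_family_weights.values())
        if any(x < 0 for x in w) or sum(w) == 0:
            raise ValidationError("family weights must be non-negative, not all zero")
        for mapping in (
            self.defense_rate_by_condition, self.lysogeny_rate_by_condition,
            self.viral_share_by_condition,
        ):
            if set(mapping) != set(CONDITIONS):
                raise ValidationError(f"condition mappings must cover {CONDITIONS}")
        if self.n_genera < 1 or self.contigs_per_genus < 1 or self.n_viral_contigs < 1:
            raise ValidationError("community sizes must be positive")
        if self.reads_per_sample <= 0:
            raise ValidationError("reads_per_sample must be > 0")
        if self.n_samples_per_condition < 1:
            raise ValidationError("n_samples_per_condition must be >= 1")


@dataclass
class GroundTruth:
    """Planted truth for every downstream stage."""

    true_host_links: set[tuple[str, str, str, str]]
    true_lifestyles: dict[str, str]
    true_arrays: list[CrisprArray]
    true_defense: pd.DataFrame
    true_abundance: pd.DataFrame  # contig x sample expected relative abundance
    sample_conditions: dict[str, str]


def _sample_ids(config: SyntheticConfig) -> dict[str, str]:
    ids = {}
    for i in range(config.n_samples_per_condition):
        ids[f"D{i + 1:02d}"] = "disinfected"
    for i in range(config.n_samples_per_condition):
        ids[f"N{i + 1:02d}"] = "non_disinfected"
    return ids


def _draw_array_spacers(
    rng: np.random.Generator,
    n_spacers: int,
    config: SyntheticConfig,
    viral_seqs: dict[str, str],
    viral_ids: list[str],
) -> tuple[list[str], list[tuple[str, str] | None]]:
    """Spacers plus their (source viral contig, strand) provenance.

    Adjacent spacers are guaranteed to differ in both their first and last
    characters.  This keeps any run of same-end-character spacers below the
    length that would let a chain of single-base-extended repeats outrank the
    planted repeat, so planted arrays detect exactly as planted.
    Viral-sourced spacers stay verbatim substrings: the guard is enforced by
    redrawing the source window, never by mutating the spacer.
    """
    spacers: list[str] = []
    provenance: list[tuple[str, str] | None] = []
    k = config.spacer_length
    for j in range(n_spacers):
        for _ in range(200):
            if rng.random() < config.spacer_source_rate:
                vid = viral_ids[int(rng.integers(len(viral_ids)))]
                vseq = viral_seqs[vid]
                start = int(rng.integers(0, len(vseq) - k + 1))
                window = vseq[start : start + k]
                strand = "+" if rng.random() < 0.5 else "-"
                spacer = window if strand == "+" else revcomp(window)
                prov = (vid, strand)
            else:
                spacer = _random_dna(rng, k)
                prov = None
            if j >= 1 and (
                spacer[0] == spacers[j - 1][0] or spacer[-1] == spacers[j - 1][-1]
            ):
                continue
            if spacer in spacers:
                continue
            break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw a guarded spacer")
        spacers.append(spacer)
        provenance.append(prov)
    return spacers, provenance


def generate_community(
    config: SyntheticConfig,
) -> tuple[list[ContigRecord], dict[str, pd.DataFrame], GroundTruth]:
    """Generate contigs, feature tables and ground truth (deterministic per seed)."""
    config.validate()
    seed = config.seed
    samples = _sample_ids(config)

    # --- viral contigs ------------------------------------------------------
    rng_v = _rng(seed, "viral_seq")
    viral_ids = [f"v{i + 1:04d}" for i in range(config.n_viral_contigs)]
    vlo, vhi = config.viral_length_range
    viral_seqs = {
        vid: _random_dna(rng_v, int(rng_v.integers(max(1500, vlo), vhi + 1)))
        for vid in viral_ids
    }
    n_families = max(2, config.n_viral_contigs // 10)
    viral_family = {
        vid: int(rng_v.integers(n_families)) for vid in viral_ids
    }

    # --- prokaryotic contigs (base sequences) -------------------------------
    rng_p = _rng(seed, "prok_seq")
    prok_ids: list[str] = []
    prok_genus: dict[str, str] = {}
    base_seqs: dict[str, str] = {}
    lo, hi = config.contig_length_range
    for g in range(config.n_genera):
        genus = f"Genus{g + 1:02d}"
        for c in range(config.contigs_per_genus):
            cid = f"p{g + 1:02d}_{c + 1:03d}"
            prok_ids.append(cid)
            prok_genus[cid] = genus
            base_seqs[cid] = _random_dna(rng_p, int(rng_p.integers(lo, hi + 1)))

    # --- prophage planting --------------------------------------------------
    rng_pp = _rng(seed, "prophage")
    insertions: dict[str, list[tuple[int, str, str, str]]] = {c: [] for c in prok_ids}
    embedded: dict[str, str] = {}  # viral id -> host contig id
    for vid in viral_ids:
        if rng_pp.random() < config.prophage_rate:
            host = prok_ids[int(rng_pp.integers(len(prok_ids)))]
            pos = int(rng_pp.integers(0, len(base_seqs[host]) + 1))
            insertions[host].append((pos, viral_seqs[vid], "prophage", vid))
            embedded[vid] = host

    # --- CRISPR array planting ----------------------------------------------
    rng_c = _rng(seed, "crispr")
    planted_arrays: list[dict] = []
    crispr_links: set[tuple[str, str, str, str]] = set()
    slo, shi = config.spacers_per_array_range
    for cid in prok_ids:
        if rng_c.random() >= config.crispr_rate:
            continue
        repeat = _random_dna(rng_c, config.repeat_length)
        n_sp = int(rng_c.integers(slo, shi + 1))
        spacers, provenance = _draw_array_spacers(
            rng_c, n_sp, config, viral_seqs, viral_ids
        )
        array_seq = repeat + "".join(s + repeat for s in spacers)
        pos = int(rng_c.integers(0, len(base_seqs[cid]) + 1))
        insertions[cid].append((pos, array_seq, "crispr", ""))
        planted_arrays.append(
            {"contig_id": cid, "repeat": repeat, "spacers": spacers, "pos": pos}
        )
        for prov in provenance:
            if prov is not None:
                crispr_links.add((prov[0], cid, prok_genus[cid], "crispr"))

    # --- assemble prokaryotic contigs, record final intervals ---------------
    prok_seqs: dict[str, str] = {}
    prophage_rows: list[dict] = []
    true_arrays: list[CrisprArray] = []
    for cid in prok_ids:
        base = base_seqs[cid]
        ins = sorted(insertions[cid], key=lambda t: (t[0], t[2], t[3]))
        parts = []
        cursor = 0
        offset = 0
        for pos, seq, kind, ref in ins:
            parts.append(base[cursor:pos])
            start = pos + offset
            end = start + len(seq)
            if kind == "prophage":
                prophage_rows.append(
                    {"prophage_id": ref, "host_contig_id": cid,
                     "start": start, "end": end}
                )
            else:
                rec = next(
                    a for a in planted_arrays
                    if a["contig_id"] == cid and a["pos"] == pos
                )
                true_arrays.append(
                    CrisprArray(cid, rec["repeat"], tuple(rec["spacers"]), (start, end))
                )
            parts.append(seq)
            cursor = pos
            offset += len(seq)
        parts.append(base[cursor:])
        prok_seqs[cid] = "".join(parts)

    # --- tRNA genes ---------------------------------------------------------
    rng_t = _rng(seed, "trna")
    trna_rows: list[dict] = []
    host_trnas: dict[str, tuple[str, str]] = {}
    used_seqs: set[str] = set()
    for cid in prok_ids:
        if rng_t.random() >= config.prok_trna_rate:
            continue
        while True:
            seq = _random_dna(rng_t, config.trna_length)
            if seq not in used_seqs and revcomp(seq) not in used_seqs:
                break
        used_seqs.add(seq)
        trna_id = f"trna_{cid}"
        host_trnas[cid] = (trna_id, seq)
        trna_rows.append(
            {"contig_id": cid, "trna_id": trna_id, "seq": seq, "source": "prokaryotic"}
        )
    trna_links: set[tuple[str, str, str, str]] = set()
    donor_ids = sorted(host_trnas)
    for vid in viral_ids:
        if donor_ids and rng_t.random() < config.trna_share_rate:
            donor = donor_ids[int(rng_t.integers(len(donor_ids)))]
            trna_id, seq = host_trnas[donor]
            trna_rows.append(
                {"contig_id": vid, "trna_id": f"trna_{vid}", "seq": seq,
                 "source": "viral"}
            )
            trna_links.add((vid, donor, prok_genus[donor], "trna"))

    # --- defense annotations -------------------------------------------------
    rng_d = _rng(seed, "defense")
    fam_names = sorted(config.defense_family_weights)
    fam_w = np.array([config.defense_family_weights[f] for f in fam_names], dtype=float)
    fam_w = fam_w / fam_w.sum()
    rm_subs = ["Type_I", "Type_II", "Type_IIG", "Type_III", "Type_IV"]
    rm_w = np.array([0.14, 0.30, 0.30, 0.11, 0.15])
    cas_subs = ["Type_I", "Type_II", "Type_III", "Type_IV", "Type_V"]
    cas_w = np.array([0.19, 0.74, 0.02, 0.04, 0.01])
    rm_w, cas_w = rm_w / rm_w.sum(), cas_w / cas_w.sum()

    def draw_annotation(cid: str) -> dict:
        family = fam_names[int(rng_d.choice(len(fam_names), p=fam_w))]
        if family == "RM":
            subtype = rm_subs[int(rng_d.choice(len(rm_subs), p=rm_w))]
        elif family == "CRISPR-Cas":
            subtype = cas_subs[int(rng_d.choice(len(cas_subs), p=cas_w))]
        else:
            subtype = ""
        return {"contig_id": cid, "family": family, "subtype": subtype}

    p_carrier = float(np.mean(list(config.defense_rate_by_condition.values())))
    defense_rows: list[dict] = []
    prok_carriers: list[str] = []
    for cid in prok_ids:
        if rng_d.random() < p_carrier:
            prok_carriers.append(cid)
    if not prok_carriers and p_carrier > 0:
        prok_carriers = [prok_ids[0]]
    for cid in prok_carriers:
        n_ann = 1 + int(rng_d.random() < 0.3)
        for _ in range(n_ann):
            defense_rows.append(draw_annotation(cid))
    for vid in viral_ids:
        if rng_d.random() < config.viral_defense_rate:
            defense_rows.append(draw_annotation(vid))
    defense_df = pd.DataFrame(
        defense_rows, columns=["contig_id", "family", "subtype"]
    ).drop_duplicates().reset_index(drop=True)

    # --- lifestyles ----------------------------------------------------------
    rng_l = _rng(seed, "lifestyle")
    p_lys = float(np.mean(list(config.lysogeny_rate_by_condition.values())))
    lifestyles: dict[str, str] = {}
    for vid in viral_ids:
        if vid in embedded:
            lifestyles[vid] = "lysogenic"  # integrated by construction
        else:
            lifestyles[vid] = "lysogenic" if rng_l.random() < p_lys else "lytic"
    if all(v == "lytic" for v in lifestyles.values()):
        lifestyles[viral_ids[0]] = "lysogenic"
    if all(v == "lysogenic" for v in lifestyles.values()):
        free = [v for v in viral_ids if v not in embedded]
        if free:  # embedded prophages must stay lysogenic
            lifestyles[free[-1]] = "lytic"

    # --- expected abundances (per condition, tilted) -------------------------
    rng_a = _rng(seed, "abundance")
    genus_effect = {
        f"Genus{g + 1:02d}": float(rng_a.lognormal(0, config.abundance_lognormal_sigma))
        for g in range(config.n_genera)
    }
    prok_base = np.array(
        [
            genus_effect[prok_genus[c]]
            * rng_a.lognormal(0, config.abundance_lognormal_sigma / 2)
            for c in prok_ids
        ]
    )
    viral_base = np.array(
        [rng_a.lognormal(0, config.abundance_lognormal_sigma) for _ in viral_ids]
    )

    def _tilt(base: np.ndarray, flag: np.ndarray, target: float) -> np.ndarray:
        """Scale flagged entries so their share of the vector equals target."""
        s_f = base[flag].sum()
        s_o = base[~flag].sum()
        if s_f == 0 or s_o == 0 or not 0 < target < 1:
            return base
        out = base.copy()
        out[flag] *= target * s_o / ((1 - target) * s_f)
        return out

    carrier_flag = np.array([c in set(prok_carriers) for c in prok_ids])
    lys_flag = np.array([lifestyles[v] == "lysogenic" for v in viral_ids])
    all_ids = prok_ids + viral_ids
    expected = {}
    for cond in CONDITIONS:
        prok_a = _tilt(prok_base, carrier_flag, config.defense_rate_by_condition[cond])
        viral_a = _tilt(viral_base, lys_flag, config.lysogeny_rate_by_condition[cond])
        v_share = config.viral_share_by_condition[cond]
        prok_a = prok_a / prok_a.sum() * (1 - v_share)
        viral_a = viral_a / viral_a.sum() * v_share
        expected[cond] = np.concatenate([prok_a, viral_a])
    true_abundance = pd.DataFrame(
        {s: expected[cond] for s, cond in samples.items()}, index=all_ids
    )

    # --- covariates -----------------------------------------------------------
    rng_cov = _rng(seed, "covariates")
    sample_rows = []
    for s, cond in samples.items():
        if cond == "disinfected":
            chlorine = max(0.2, float(rng_cov.normal(0.6, 0.1)))
            phosphate = max(0.001, float(rng_cov.normal(0.02, 0.005)))
        else:
            chlorine = float(rng_cov.uniform(0.0, 0.02))
            phosphate = max(0.02, float(rng_cov.normal(0.2, 0.03)))
        sample_rows.append(
            {"sample_id": s, "condition": cond,
             "chlorine": round(chlorine, 4), "phosphate": round(phosphate, 4)}
        )

    # --- per-gene taxonomy hits for viral contigs -----------------------------
    rng_g = _rng(seed, "gene_hits")
    gene_rows = []
    for vid in viral_ids:
        n_genes = max(3, len(viral_seqs[vid]) // 400)
        if rng_g.random() >= 0.7:
            continue  # unannotatable contig: no hits at all
        fam = viral_family[vid]
        lineage = [("order", f"Ord{fam // 2 + 1}"), ("family", f"Fam{fam + 1}")]
        n_hits = max(2, int(np.ceil(0.25 * n_genes)))
        n_hits = min(n_hits, n_genes)
        n_agree = max(int(np.ceil(0.75 * n_hits)), n_hits - max(n_hits - 1, 0))
        gene_indices = rng_g.choice(n_genes, size=n_hits, replace=False)
        for k, gi in enumerate(sorted(int(x) for x in gene_indices)):
            if k < n_agree:
                lin = lineage
            else:
                decoy = (fam + 1) % n_families
                lin = [("order", f"Ord{decoy // 2 + 1}"), ("family", f"Fam{decoy + 1}")]
            gene_rows.append(
                {
                    "contig_id": vid, "gene_index": gi, "n_genes": n_genes,
                    "lineage": lineage_to_string(lin),
                    "evalue": float(10 ** -rng_g.uniform(6, 20)),
                }
            )

    # --- assemble outputs -----------------------------------------------------
    contigs: list[ContigRecord] = []
    for cid in prok_ids:
        contigs.append(
            ContigRecord(
                cid, prok_seqs[cid], category="prokaryotic",
                lineage=[("domain", "Bacteria"), ("genus", prok_genus[cid])],
            )
        )
    for vid in viral_ids:
        contigs.append(
            ContigRecord(
                vid, viral_seqs[vid],
                category="prophage" if vid in embedded else "free_viral",
            )
        )

    prophage_links = {
        (r["prophage_id"], r["host_contig_id"], prok_genus[r["host_contig_id"]],
         "prophage")
        for r in prophage_rows
    }
    features = {
        "prophages": pd.DataFrame(
            prophage_rows, columns=["prophage_id", "host_contig_id", "start", "end"]
        ),
        "trna": pd.DataFrame(trna_rows, columns=["contig_id", "trna_id", "seq", "source"]),
        "defense": defense_df,
        "lifestyles": pd.DataFrame(
            [{"phage_id": v, "lifestyle": lifestyles[v]} for v in viral_ids]
        ),
        "gene_hits": pd.DataFrame(
            gene_rows,
            columns=["contig_id", "gene_index", "n_genes", "lineage", "evalue"],
        ),
        "prok_taxonomy": pd.DataFrame(
            [
                {"contig_id": c,
                 "lineage": lineage_to_string(
                     [("domain", "Bacteria"), ("genus", prok_genus[c])])}
                for c in prok_ids
            ]
        ),
        "samples": pd.DataFrame(sample_rows),
    }
    truth = GroundTruth(
        true_host_links=crispr_links | trna_links | prophage_links,
        true_lifestyles=lifestyles,
        true_arrays=true_arrays,
        true_defense=defense_df.copy(),
        true_abundance=true_abundance,
        sample_conditions=dict(samples),
    )
    return contigs, features, truth


def simulate_alignments(
    contigs: list[ContigRecord],
    truth: GroundTruth,
    config: SyntheticConfig,
) -> dict[str, pd.DataFrame]:
    """Per-sample alignment records (read_id, contig_id, aligned_length).

    Read counts per contig are multinomial with probability proportional to
    expected relative abundance x contig length; a configurable fraction of
    reads gets an aligned length below 30 bp (15-29), the rest 30-250 bp.
    Deterministic given the config seed.
    """
    if config.reads_per_sample <= 0:
        raise ValidationError("reads_per_sample must be > 0")
    lengths = pd.Series({c.contig_id: c.length for c in contigs}, dtype=float)
    out: dict[str, pd.DataFrame] = {}
    for idx, (sample, _cond) in enumerate(truth.sample_conditions.items()):
        rng = _rng(config.seed, "alignments", idx)
        a = truth.true_abundance[sample].reindex(lengths.index)
        if a.isna().any():
            raise ValidationError("true_abundance must cover all contigs")
        weights = (a * lengths).to_numpy()
        p = weights / weights.sum()
        counts = rng.multinomial(config.reads_per_sample, p)
        contig_col = np.repeat(lengths.index.to_numpy(), counts)
        n = contig_col.size
        short = rng.random(n) < config.short_aligned_fraction
        aligned = np.where(
            short,
            rng.integers(15, 30, size=n),
            rng.integers(30, 251, size=n),
        )
        out[sample] = pd.DataFrame(
            {
                "read_id": [f"{sample}:r{i}" for i in range(n)],
                "contig_id": contig_col,
                "aligned_length": aligned.astype(int),
            }
        )
    return out


def write_community(
    contigs: list[ContigRecord],
    features: dict[str, pd.DataFrame],
    truth: GroundTruth,
    alignments: dict[str, pd.DataFrame],
    outdir,
) -> None:
    """Write the community in the TSV/FASTA schemas the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(contigs, outdir / "contigs.fasta")
    pd.DataFrame(
        [{"contig_id": c.contig_id, "category": c.category} for c in contigs]
    ).to_csv(outdir / "categories.tsv", sep="\t", index=False)
    for name, df in features.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    for sample, df in alignments.items():
        df.to_csv(outdir / f"alignments_{sample}.tsv", sep="\t", index=False)
    links = pd.DataFrame(
        sorted(truth.true_host_links),
        columns=["phage_id", "host_contig_id", "genus", "channel"],
    )
    links.to_csv(outdir / "truth_links.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"phage_id": k, "lifestyle": v} for k, v in sorted(truth.true_lifestyles.items())]
    ).to_csv(outdir / "truth_lifestyles.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"contig_id": a.contig_id, "repeat": a.repeat,
             "spacers": ",".join(a.spacers), "start": a.interval[0],
             "end": a.interval[1]}
            for a in truth.true_arrays
        ]
    ).to_csv(outdir / "truth_arrays.tsv", sep="\t", index=False)
    truth.true_abundance.rename_axis("contig_id").to_csv(
        outdir / "truth_abundance.tsv", sep="\t"
    )


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)
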