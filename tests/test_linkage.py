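import numpy as np
import pandas as pd
import pytest

from vdp.io import ContigRecord, ValidationError
from vdp.linkage import (
    classify_polyvalent,
    host_population_summary,
    link_prophages,
    match_spacers,
    match_trnas,
    merge_links,
    revcomp,
)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def spacer_table(rows):
    return pd.DataFrame(
        [{"contig_id": c, "spacer_index": i, "spacer": s} for i, (c, s) in enumerate(rows)]
    )


class TestMatchSpacers:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.vseq = random_dna(rng, 2000)
        self.viral = [ContigRecord("v1", self.vseq, "free_viral")]
        self.rng = rng

    def test_exact_containment(self):
        sp = self.vseq[100:132]
        links = match_spacers(spacer_table([("p1", sp)]), self.viral)
        assert links.iloc[0][["phage_id", "host_contig_id", "channel"]].tolist() == [
            "v1", "p1", "crispr",
        ]
        assert "pos=100" in links.iloc[0]["detail"]

    def test_reverse_complement_matches(self):
        sp = revcomp(self.vseq[500:532])
        links = match_spacers(spacer_table([("p1", sp)]), self.viral)
        assert len(links) == 1
        assert "strand=-" in links.iloc[0]["detail"]

    def test_absent_spacer_no_link(self):
        sp = random_dna(self.rng, 32)
        assert match_spacers(spacer_table([("p1", sp)]), self.viral).empty

    def test_short_spacer_rejected_with_warning(self):
        with pytest.warns(UserWarning, match="shorter"):
            links = match_spacers(
                spacer_table([("p1", self.vseq[10:27])]), self.viral
            )
        assert links.empty

    def test_one_mismatch_tolerated_when_allowed(self):
        sp = list(self.vseq[300:332])
        sp[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[sp[10]]
        sp = "".join(sp)
        assert match_spacers(spacer_table([("p1", sp)]), self.viral).empty
        links = match_spacers(spacer_table([("p1", sp)]), self.viral, max_mismatch=1)
        assert len(links) == 1

    def test_equals_naive_scan_oracle(self):
        """Spacer matcher equals a position-by-position scan over both strands."""
        rng = np.random.default_rng(7)
        viral = [
            ContigRecord(f"v{i}", random_dna(rng, 1500), "free_viral")
            for i in range(6)
        ]
        spacers = []
        for i in range(12):
            if i % 3 == 0:  # planted forward
                v = viral[i % 6].sequence
                spacers.append(("h", v[200 + i : 232 + i]))
            elif i % 3 == 1:  # planted reverse
                v = viral[i % 6].sequence
                spacers.append(("h", revcomp(v[700 + i : 732 + i])))
            else:
                spacers.append(("h", random_dna(rng, 32)))
        got = match_spacers(spacer_table(spacers), viral)
        got_pairs = set(zip(got["phage_id"], got["host_contig_id"]))
        expected = set()
        for _, sp in spacers:
            for v in viral:
                hay = v.sequence
                m = len(sp)
                found = any(
                    hay[j : j + m] == probe
                    for probe in (sp, revcomp(sp))
                    for j in range(len(hay) - m + 1)
                )
                if found:
                    expected.add((v.contig_id, "h"))
        assert got_pairs == expected


class TestMatchTrnas:
    def test_perfect_match_links(self):
        seq = "".join(np.random.default_rng(1).choice(list("ACGT"), size=72))
        viral = pd.DataFrame(
            [{"contig_id": "v1", "trna_id": "t1", "seq": seq}]
        )
        prok = pd.DataFrame(
            [{"contig_id": "p1", "trna_id": "t2", "seq": seq}]
        )
        links = match_trnas(viral, prok)
        assert links.iloc[0][["phage_id", "host_contig_id", "channel"]].tolist() == [
            "v1", "p1", "trna",
        ]

    def test_reverse_complement_counts_as_perfect(self):
        seq = "".join(np.random.default_rng(2).choice(list("ACGT"), size=72))
        viral = pd.DataFrame([{"contig_id": "v1", "trna_id": "t1", "seq": seq}])
        prok = pd.DataFrame(
            [{"contig_id": "p1", "trna_id": "t2", "seq": revcomp(seq)}]
        )
        assert len(match_trnas(viral, prok)) == 1

    def test_single_mismatch_breaks_link(self):
        seq = "A" * 36 + "C" * 36
        viral = pd.DataFrame([{"contig_id": "v1", "trna_id": "t1", "seq": seq}])
        prok = pd.DataFrame(
            [{"contig_id": "p1", "trna_id": "t2", "seq": "G" + seq[1:]}]
        )
        assert match_trnas(viral, prok).empty

    def test_empty_viral_table(self):
        prok = pd.DataFrame([{"contig_id": "p1", "trna_id": "t", "seq": "ACGT" * 18}])
        assert match_trnas(prok.iloc[0:0], prok).empty


class TestLinkProphages:
    def test_direct_assignment(self):
        table = pd.DataFrame(
            [{"prophage_id": "pp1", "host_contig_id": "p7", "start": 1000,
              "end": 36000}]
        )
        links = link_prophages(table, {"p7": 40000})
        assert links.iloc[0]["phage_id"] == "pp1"
        assert links.iloc[0]["host_contig_id"] == "p7"

    def test_out_of_bounds_interval_rejected(self):
        table = pd.DataFrame(
            [{"prophage_id": "pp1", "host_contig_id": "p7", "start": 1000,
              "end": 50001}]
        )
        with pytest.raises(ValidationError, match="out of bounds"):
            link_prophages(table, {"p7": 50000})

    def test_unknown_host_rejected(self):
        table = pd.DataFrame(
            [{"prophage_id": "pp1", "host_contig_id": "ghost", "start": 0, "end": 10}]
        )
        with pytest.raises(ValidationError, match="ghost"):
            link_prophages(table, {"p7": 50000})


def links_df(rows):
    return pd.DataFrame(
        rows, columns=["phage_id", "host_contig_id", "channel", "detail"]
    )


class TestMergeLinks:
    def test_channels_kept_distinct_and_multi_counted(self):
        crispr = links_df([("v1", "p1", "crispr", "")])
        trna = links_df([("v1", "p1", "trna", "")])
        merged, counts, multi = merge_links([crispr, trna], {"p1": "GenusA"})
        assert len(merged) == 2  # distinct channels both retained
        assert counts == {"crispr": 1, "trna": 1}
        assert multi == 1

    def test_exact_duplicates_removed(self):
        t = links_df([("v1", "p1", "crispr", "x"), ("v1", "p1", "crispr", "y")])
        merged, counts, _ = merge_links([t], {"p1": "GenusA"})
        assert len(merged) == 1 and counts == {"crispr": 1}

    def test_empty_input(self):
        merged, counts, multi = merge_links([], {})
        assert merged.empty and counts == {} and multi == 0

    def test_channel_totals_are_additive(self):
        # miniature of the three-channel bookkeeping: totals must add up
        rng = np.random.default_rng(3)
        tables = []
        sizes = {"trna": 18, "crispr": 7, "prophage": 3}
        for channel, n in sizes.items():
            tables.append(
                links_df(
                    [
                        (f"v{rng.integers(40)}", f"p{i}_{channel}", channel, "")
                        for i in range(n)
                    ]
                )
            )
        merged, counts, _ = merge_links(tables, {})
        assert counts == sizes
        assert len(merged) == sum(sizes.values())

    def test_missing_genus_retained_blank(self):
        merged, _, _ = merge_links(
            [links_df([("v1", "p1", "crispr", "")])], {}
        )
        assert merged.iloc[0]["genus"] == ""


class TestClassifyPolyvalent:
    def test_two_genera_is_polyvalent(self):
        merged, _, _ = merge_links(
            [links_df([("v1", "p1", "crispr", ""), ("v1", "p2", "trna", "")])],
            {"p1": "A", "p2": "B"},
        )
        summary, frac, _ = classify_polyvalent(merged)
        assert summary.iloc[0]["polyvalent"]
        assert frac == 1.0

    def test_same_genus_twice_not_polyvalent(self):
        merged, _, _ = merge_links(
            [links_df([("v2", "p1", "crispr", ""), ("v2", "p2", "crispr", "")])],
            {"p1": "A", "p2": "A"},
        )
        summary, frac, _ = classify_polyvalent(merged)
        assert summary.iloc[0]["n_genera"] == 1
        assert not summary.iloc[0]["polyvalent"]
        assert frac == 0.0

    def test_no_links_not_applicable(self):
        summary, frac, abund = classify_polyvalent(pd.DataFrame(
            columns=["phage_id", "host_contig_id", "genus", "channel", "detail"]
        ))
        assert summary.empty and frac is None and abund is None

    def test_invariant_to_duplicated_link_rows(self):
        merged, _, _ = merge_links(
            [links_df([
                ("v1", "p1", "crispr", ""), ("v1", "p2", "trna", ""),
                ("v2", "p1", "crispr", ""),
            ])],
            {"p1": "A", "p2": "B"},
        )
        dup = pd.concat([merged, merged.iloc[[0]]], ignore_index=True)
        _, frac1, _ = classify_polyvalent(merged)
        _, frac2, _ = classify_polyvalent(dup)
        assert frac1 == frac2 == 0.5

    def test_abundance_basis_fraction(self):
        merged, _, _ = merge_links(
            [links_df([("v1", "p1", "crispr", ""), ("v1", "p2", "trna", ""),
                       ("v2", "p1", "crispr", "")])],
            {"p1": "A", "p2": "B"},
        )
        tpm = pd.Series({"v1": 300.0, "v2": 100.0})
        _, _, abund = classify_polyvalent(merged, tpm)
        assert abund == pytest.approx(0.75)


class TestHostPopulationSummary:
    def test_single_genus_all_shares_full(self):
        merged, _, _ = merge_links(
            [links_df([("v1", "p1", "prophage", "")])], {"p1": "A"}
        )
        tpm = pd.Series({"p1": 1000.0})
        table = host_population_summary(merged, tpm, {"p1": "A"})
        row = table.iloc[0]
        assert row["host_abundance_share"] == pytest.approx(1.0)
        assert row["community_share"] == pytest.approx(1.0)
        assert row["prophage_link_share"] == pytest.approx(1.0)

    def test_prophage_share_ratio(self):
        rows = [("v%d" % i, "p1", "trna", "") for i in range(18)]
        rows += [("v%d" % i, "p1", "prophage", "") for i in range(18, 25)]
        merged, _, _ = merge_links([links_df(rows)], {"p1": "A"})
        tpm = pd.Series({"p1": 1000.0})
        table = host_population_summary(merged, tpm, {"p1": "A"})
        assert table.iloc[0]["prophage_link_share"] == pytest.approx(7 / 25)

    def test_no_links_empty(self):
        table = host_population_summary(
            pd.DataFrame(columns=["phage_id", "host_contig_id", "genus",
                                  "channel", "detail"]),
            pd.Series(dtype=float), {},
        )
        assert table.empty

    def test_top_k_validation(self):
        with pytest.raises(ValidationError):
            host_population_summary(
                pd.DataFrame(columns=["phage_id", "host_contig_id", "genus",
                                      "channel", "detail"]),
                pd.Series(dtype=float), {}, top_k=0,
            )


def test_planted_links_recovered_exactly(community):
    """Zero-noise community: merged in-situ links equal the planted truth."""
    from vdp.crispr import detect_all_arrays, extract_spacers

    _cfg, contigs, features, truth = community
    arrays = detect_all_arrays(contigs)
    spacers = extract_spacers(arrays)
    viral = [c for c in contigs if c.category in ("free_viral", "prophage")]
    prok_ids = {c.contig_id for c in contigs if c.category == "prokaryotic"}
    trna = features["trna"]
    lengths = {c.contig_id: c.length for c in contigs}
    merged, _, _ = merge_links(
        [
            match_spacers(spacers, viral),
            match_trnas(
                trna[~trna["contig_id"].isin(prok_ids)],
                trna[trna["contig_id"].isin(prok_ids)],
            ),
            link_prophages(features["prophages"], lengths),
        ],
        {c.contig_id: c.genus for c in contigs},
    )
    predicted = set(
        zip(merged["phage_id"], merged["host_contig_id"], merged["channel"])
    )
    planted = {(p, h, ch) for p, h, _g, ch in truth.true_host_links}
    assert predicted == planted
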