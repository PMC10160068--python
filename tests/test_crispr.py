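from collections import Counter

import numpy as np
import pandas as pd
import pytest

from vdp.crispr import (
    ArrayDetectionParams,
    CrisprArray,
    detect_crispr_arrays,
    extract_spacers,
    spacer_burden,
    spacer_counts,
)
from vdp.io import ValidationError


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def build_array(repeat, spacers):
    return repeat + "".join(s + repeat for s in spacers)


def exhaustive_chain_oracle(seq, params=ArrayDetectionParams()):
    """Brute-force array finder: enumerate every candidate repeat word via a
    Counter, chase occurrence chains with str.find, then apply the same
    longest-repeat-first non-overlap selection."""
    lmin, lmax = params.repeat_len_range
    smin, smax = params.spacer_len_range
    candidates = []
    for length in range(lmin, min(lmax, len(seq)) + 1):
        counts = Counter(
            seq[i : i + length]
            for i in range(len(seq) - length + 1)
            if "N" not in seq[i : i + length]
        )
        for word, c in counts.items():
            if c < params.min_repeats:
                continue
            positions = []
            p = seq.find(word)
            while p != -1:
                positions.append(p)
                p = seq.find(word, p + 1)
            pos_set = set(positions)
            nxt = {}
            for p in positions:
                chosen = None
                for gap in range(smin, smax + 1):
                    if p + length + gap in pos_set:
                        chosen = p + length + gap
                        break
                nxt[p] = chosen
            succ = {q for q in nxt.values() if q is not None}
            for p in positions:
                if p in succ:
                    continue
                chain = [p]
                while nxt[chain[-1]] is not None:
                    chain.append(nxt[chain[-1]])
                if len(chain) >= params.min_repeats:
                    candidates.append((length, chain[0], word, tuple(chain)))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    taken, arrays = [], []
    for length, start, word, chain in candidates:
        end = chain[-1] + length
        if any(start < e and s < end for s, e in taken):
            continue
        spacers = tuple(
            seq[chain[i] + length : chain[i + 1]] for i in range(len(chain) - 1)
        )
        arrays.append(CrisprArray("", word, spacers, (start, end)))
        taken.append((start, end))
    return sorted(arrays, key=lambda a: a.interval)


class TestDetection:
    def test_planted_array_recovered(self):
        rng = np.random.default_rng(0)
        repeat = random_dna(rng, 28)
        s1, s2 = "A" + random_dna(rng, 30) + "C", "G" + random_dna(rng, 30) + "T"
        seq = random_dna(rng, 900) + build_array(repeat, [s1, s2]) + random_dna(rng, 900)
        (arr,) = detect_crispr_arrays(seq)
        assert arr.repeat == repeat
        assert arr.spacers == (s1, s2)
        assert arr.interval == (900, 900 + 3 * 28 + 64)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_sequence_has_no_arrays(self, seed):
        rng = np.random.default_rng(seed)
        assert detect_crispr_arrays(random_dna(rng, 2000)) == []

    def test_gap_outside_spacer_range_breaks_chain(self):
        rng = np.random.default_rng(1)
        repeat = random_dna(rng, 28)
        seq = (
            random_dna(rng, 200)
            + repeat
            + random_dna(rng, 100)  # gap too long for a spacer
            + repeat
            + random_dna(rng, 100)
            + repeat
            + random_dna(rng, 200)
        )
        assert detect_crispr_arrays(seq) == []

    def test_two_repeats_only_below_min(self):
        rng = np.random.default_rng(2)
        repeat = random_dna(rng, 28)
        seq = random_dna(rng, 200) + build_array(repeat, ["A" + random_dna(rng, 30)]) \
            + random_dna(rng, 200)
        # 2 repeat copies < min_repeats=3
        assert detect_crispr_arrays(seq) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_detector_equals_exhaustive_oracle(self, seed):
        """Detector equals brute-force chain enumeration on <=3 kb contigs,
        with and without planted arrays."""
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 500)
        if seed % 2 == 0:  # plant one or two arrays
            for _ in range(1 + seed // 4):
                repeat = random_dna(rng, int(rng.integers(24, 40)))
                spacers = []
                prev = None
                for _k in range(int(rng.integers(2, 5))):
                    while True:
                        s = random_dna(rng, int(rng.integers(25, 45)))
                        if prev is None or (s[0] != prev[0] and s[-1] != prev[-1]):
                            break
                    spacers.append(s)
                    prev = s
                seq += build_array(repeat, spacers) + random_dna(rng, 400)
        seq += random_dna(rng, 300)
        assert len(seq) <= 3000
        got = detect_crispr_arrays(seq)
        expected = exhaustive_chain_oracle(seq)
        assert [(a.repeat, a.spacers, a.interval) for a in got] == [
            (a.repeat, a.spacers, a.interval) for a in expected
        ]

    def test_interval_invariant(self):
        rng = np.random.default_rng(5)
        repeat = random_dna(rng, 30)
        s = ["A" + random_dna(rng, 28) + "C", "G" + random_dna(rng, 33) + "T"]
        seq = random_dna(rng, 100) + build_array(repeat, s) + random_dna(rng, 100)
        (arr,) = detect_crispr_arrays(seq)
        start, end = arr.interval
        assert end - start == (arr.n_spacers + 1) * len(arr.repeat) + sum(
            map(len, arr.spacers)
        )


class TestSpacers:
    def test_extract_in_genomic_order(self):
        arr = CrisprArray("c1", "R" * 25, ("A" * 30, "C" * 30), (0, 135))
        table = extract_spacers([arr])
        assert table["spacer"].tolist() == ["A" * 30, "C" * 30]
        assert table["spacer_index"].tolist() == [0, 1]
        assert not table["duplicate"].any()

    def test_empty_input(self):
        assert extract_spacers([]).empty

    def test_identical_spacers_flagged(self):
        arr = CrisprArray("c1", "R" * 25, ("A" * 30, "A" * 30), (0, 135))
        table = extract_spacers([arr])
        assert table["duplicate"].tolist() == [False, True]
        assert len(table) == 2  # both rows kept: the count feeds N

    def test_counts_sum_over_arrays_per_contig(self):
        a1 = CrisprArray("c1", "R" * 25, ("A" * 30, "C" * 30), (0, 135))
        a2 = CrisprArray("c1", "G" * 25, ("T" * 30,), (500, 580))
        assert spacer_counts([a1, a2]) == {"c1": 3}


class TestSpacerBurden:
    def test_no_arrays_zero(self):
        col = pd.Series({"c1": 100.0}, name="s1")
        assert spacer_burden([], {"c1": 1000}, col).M == 0.0

    def test_hand_computed_single_contig(self):
        arr = CrisprArray("c1", "R" * 25, tuple("ACGT"[i % 4] * 30 for i in range(4)),
                          (0, 245))
        col = pd.Series({"c1": 2500.0}, name="s1")
        burden = spacer_burden([arr], {"c1": 10000}, col)
        assert burden.M == pytest.approx(1.0)  # 4/10000 * 2500

    def test_hand_computed_two_contigs(self):
        a1 = CrisprArray("c1", "R" * 25, ("A" * 30, "C" * 30), (0, 135))
        a2 = CrisprArray(
            "c2", "R" * 25, ("A" * 30, "C" * 30, "G" * 30), (0, 190)
        )
        col = pd.Series({"c1": 1000.0, "c2": 3000.0}, name="s1")
        burden = spacer_burden([a1, a2], {"c1": 5000, "c2": 15000}, col)
        assert burden.contributions["c1"] == pytest.approx(0.4)
        assert burden.contributions["c2"] == pytest.approx(0.6)
        assert burden.M == pytest.approx(1.0)

    def test_linear_in_abundance(self):
        arr = CrisprArray("c1", "R" * 25, ("A" * 30, "C" * 30), (0, 135))
        col = pd.Series({"c1": 1234.0}, name="s1")
        m1 = spacer_burden([arr], {"c1": 4000}, col).M
        m2 = spacer_burden([arr], {"c1": 4000}, 2 * col).M
        assert m2 == pytest.approx(2 * m1)

    def test_missing_abundance_rejected(self):
        arr = CrisprArray("c1", "R" * 25, ("A" * 30,), (0, 80))
        with pytest.raises(ValidationError, match="c1"):
            spacer_burden([arr], {"c1": 1000}, pd.Series({"other": 1.0}))


def test_planted_arrays_in_community_recovered(community):
    """Every planted array is recovered exactly; nothing spurious appears."""
    _cfg, contigs, _features, truth = community
    from vdp.crispr import detect_all_arrays

    detected = {
        (a.contig_id, a.repeat, a.spacers, a.interval)
        for a in detect_all_arrays(contigs)
    }
    planted = {
        (a.contig_id, a.repeat, a.spacers, a.interval) for a in truth.true_arrays
    }
    assert detected == planted


def test_param_validation():
    with pytest.raises(ValidationError):
        ArrayDetectionParams(min_repeats=1)
    with pytest.raises(ValidationError):
        ArrayDetectionParams(repeat_len_range=(30, 30))
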