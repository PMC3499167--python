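import itertools

import pytest
from hypothesis import given, settings, strategies as st

from repeatst.motif_repeats import (RepeatRegion, RepeatUnit,
                                    count_duf_like_domains, derive_consensus,
                                    is_st_protein, psim, scan_motif,
                                    segment_repeats)


def region_from_units(unit_strings, statuses=None):
    units, pos = [], 0
    statuses = statuses or ["canonical"] * len(unit_strings)
    for k, (s, status) in enumerate(zip(unit_strings, statuses)):
        units.append(RepeatUnit(index=k, start=pos, end=pos + len(s),
                                residues=s, status=status))
        pos += len(s)
    lengths = [len(s) for s, status in zip(unit_strings, statuses)
               if status == "canonical"]
    modal = max(set(lengths), key=lengths.count) if lengths else len(unit_strings[0])
    return RepeatRegion(units=units, modal_length=modal, length_pattern="uniform")


class TestScanMotif:
    def test_anchor_position(self):
        # 1-based position 3 -> 0-based index 2
        assert scan_motif("RKDFEPRPNVSAYKKK") == [2]

    def test_glu_variant_accepted(self):
        assert scan_motif("EFEPRPKVTAYKK") == [0]

    def test_missing_tyrosine_rejected(self):
        assert scan_motif("DFEPRPNVSA") == []
        assert scan_motif("DFEPRPNVSAK") == []

    def test_anchor_requires_tyr_at_offset_11(self):
        s = "DFEPRPNVSAY"
        a = scan_motif(s)[0]
        assert s[a + 10] == "Y"

    def test_mismatch_tolerance_hexamer_only(self):
        s = "DFAPRPNVSAYKK"  # one hexamer mismatch
        assert scan_motif(s) == []
        assert scan_motif(s, max_hexamer_mismatch=1) == [0]
        # the tyrosine is never relaxed
        assert scan_motif("DFAPRPNVSAKKK", max_hexamer_mismatch=1) == []

    def test_tandem_anchors(self):
        unit = "DFEPRPNVSAYDNDADKSKAKKDFK"
        assert scan_motif(unit * 3) == [0, 25, 50]

    def test_is_st_protein(self):
        assert is_st_protein("X" * 30 + "DFEPRPNVSAY" + "X" * 5)
        assert not is_st_protein("MKLVVAGSTSDQ" * 10)


class TestSegmentation:
    def test_unit_spans_and_truncated_flag(self):
        unit = "DFEPRPNVSAYDNDADKSKAKKDFK"   # 25 aa
        s = unit + unit + "DFEPRPNVSAYDN"    # 63 aa total
        region = segment_repeats(s, scan_motif(s))
        assert [u.length for u in region.units] == [25, 25, 13]
        assert region.units[-1].status == "truncated_terminal"
        assert region.units[0].status == "canonical"
        assert region.modal_length == 25

    def test_units_partition_span(self):
        unit = "DFEPRPNVSAYDNDADKSKAKKDFK"
        s = "RRKK" + unit * 4 + unit[:13]
        region = segment_repeats(s, scan_motif(s))
        assert region.start == 4
        assert region.end == len(s)
        for a, b in zip(region.units, region.units[1:]):
            assert a.end == b.start

    def test_single_short_unit_flagged_truncated(self):
        s = "DFEPRPNVSAYDN"  # 13 residues from the only anchor
        region = segment_repeats(s, scan_motif(s))
        assert len(region.units) == 1
        assert region.units[0].status == "truncated_terminal"

    def test_no_anchor_is_error(self):
        with pytest.raises(ValueError, match="ST signature"):
            segment_repeats("MKLV" * 10, [])

    def test_alternating_length_pattern(self):
        u25 = "DFEPRPNVSAYDNDADKSKAKKDFK"
        u26 = "DFEPRPNVSAYDNDADTKSKAKKDFK"
        s = u25 + u26 + u25 + u26 + u25[:13]
        region = segment_repeats(s, scan_motif(s))
        assert [u.length for u in region.canonical_units()] == [25, 26, 25, 26]
        assert region.length_pattern == "alternating"

    def test_uniform_and_heterogeneous_patterns(self):
        u25 = "DFEPRPNVSAYDNDADKSKAKKDFK"
        u24 = "DFEPRPNVSAYDNDAKSKAKKDFK"
        u26 = "DFEPRPNVSAYDNDADTKSKAKKDFK"
        uniform = segment_repeats(u25 * 3 + u25[:13], scan_motif(u25 * 3 + u25[:13]))
        assert uniform.length_pattern == "uniform"
        s = u25 + u25 + u24 + u26 + u25[:13]
        het = segment_repeats(s, scan_motif(s))
        assert het.length_pattern == "heterogeneous"

    def test_modal_length_tie_goes_to_smaller(self):
        u25 = "DFEPRPNVSAYDNDADKSKAKKDFK"
        u26 = "DFEPRPNVSAYDNDADTKSKAKKDFK"
        s = u25 + u26 + u25[:13]
        region = segment_repeats(s, scan_motif(s))
        assert region.modal_length == 25

    def test_fuzzy_leading_adds_imperfect_unit(self):
        u25 = "DFEPRPNVSAYDNDADKSKAKKDFK"
        imperfect = "DFAPRPNVSAYDNDADKSKAKKDFK"  # hexamer 1 mismatch
        s = imperfect + u25 + u25 + u25[:13]
        exact = scan_motif(s)
        assert exact[0] == 25
        region = segment_repeats(s, exact, fuzzy_leading=True)
        assert region.units[0].status == "imperfect_leading"
        assert region.units[0].start == 0


class TestConsensus:
    def test_unanimous_consensus(self):
        unit = "DFEPRPNVSAYDNDADKSKAKKDFK"
        region = region_from_units([unit] * 4)
        assert derive_consensus(region) == unit

    def test_fifty_fifty_tie_takes_first_unit_residue(self):
        a = "DFEPRPNVSAYDNDADKSKAKKDFK"
        b = "DFEPRPSVTAYDNDADKSKAKKDFK"
        cons = derive_consensus(region_from_units([a, b]))
        assert cons == a

    def test_below_threshold_emits_x(self):
        units = ["DFEPRPNVSAYAAAAAAAAAAAAAA",
                 "DFEPRPNVSAYCCCCCCCCCCCCCC",
                 "DFEPRPNVSAYDDDDDDDDDDDDDD"]
        cons = derive_consensus(region_from_units(units))
        assert cons.startswith("DFEPRPNVSAY")
        assert set(cons[11:]) == {"X"}

    def test_requires_two_eligible_units(self):
        with pytest.raises(ValueError):
            derive_consensus(region_from_units(["DFEPRPNVSAYDNDADKSKAKKDFK"]))

    def test_synthetic_family_consensus_shape(self, iia_family):
        from repeatst.motif_repeats import scan_motif as scan
        rec, _ = iia_family[0]
        region = segment_repeats(rec.residues, scan(rec.residues))
        cons = derive_consensus(region)
        assert cons.startswith("DFEPRP")
        assert cons[10] == "Y"


def bruteforce_psim(unit_strings):
    """Independent oracle: per column, the best achievable matches are
    the count of the most frequent residue; Psim is their sum over the
    total number of unit positions."""
    total = sum(len(u) for u in unit_strings)
    matches = 0
    for col in range(max(len(u) for u in unit_strings)):
        col_res = [u[col] for u in unit_strings if col < len(u)]
        matches += max(col_res.count(r) for r in set(col_res))
    return matches / total


class TestPsim:
    def test_identical_units_perfect(self):
        assert psim(["DFEPRPNVSAYDNDADKSKAKKDFK"] * 2) == 1.0

    def test_single_mismatch_pair(self):
        a = "DFEPRPNVSAYDNDADKSKAKKDFK"
        b = "DFEPRPNVSAYDNDADKSKAKKDFT"
        assert psim([a, b]) == pytest.approx(49 / 50)

    def test_degenerate_units_score_low(self):
        a = "DFEPRPNVSAY" + "ACDEGHIKLMNPQR"
        b = "DFEPRPSITAY" + "STVWYACDEGHIKL"
        c = "DFEPRPKAEAY" + "MNPQRSTVWYACDE"
        assert psim([a, b, c]) < 0.7

    def test_truncated_compared_over_own_length(self):
        a = "DFEPRPNVSAYDNDADKSKAKKDFK"
        t = a[:13]
        assert psim([a, a, t]) == 1.0

    def test_requires_two_units(self):
        with pytest.raises(ValueError):
            psim(["DFEPRPNVSAYDNDADKSKAKKDFK"])

    @pytest.mark.parametrize("n_units,length", [(2, 2), (3, 2), (2, 3), (4, 2)])
    def test_matches_bruteforce_on_exhaustive_toys(self, n_units, length):
        alphabet = "AG"
        strings = ["".join(t) for t in itertools.product(alphabet, repeat=length)]
        for combo in itertools.product(strings, repeat=n_units):
            assert psim(list(combo)) == pytest.approx(bruteforce_psim(list(combo)))

    @given(st.lists(st.text(alphabet="ADEKG", min_size=3, max_size=3),
                    min_size=2, max_size=6),
           st.randoms(use_true_random=False))
    @settings(max_examples=60, deadline=None)
    def test_permutation_invariance(self, units, rnd):
        value = psim(units)
        shuffled = list(units)
        rnd.shuffle(shuffled)
        assert psim(shuffled) == pytest.approx(value)

    @given(st.lists(st.text(alphabet="ADEK", min_size=4, max_size=4),
                    min_size=2, max_size=5))
    @settings(max_examples=60, deadline=None)
    def test_unity_iff_unanimous(self, units):
        assert (psim(units) == 1.0) == (len(set(units)) == 1)


class TestDufProxy:
    @pytest.mark.parametrize("n_units,expected", [
        (3, (1, 0)),   # 2 canonical + truncated = one complete domain
        (2, (0, 1)),
        (7, (2, 1)),   # 7 = 3 + 3 + 1 trailing
        (6, (2, 0)),
        (1, (0, 1)),
    ])
    def test_window_arithmetic(self, n_units, expected):
        unit = "DFEPRPNVSAYDNDADKSKAKKDFK"
        statuses = ["canonical"] * (n_units - 1) + ["truncated_terminal"]
        strings = [unit] * (n_units - 1) + [unit[:13]]
        region = region_from_units(strings, statuses)
        assert count_duf_like_domains(region) == expected
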