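"""Conversion-aware assignment, SNP masking and per-unit counting."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from helpers import (brute_force_align, brute_force_counts,
                     random_alignment_instance)
from mirslam import (AlignParams, SimConfig, SnpParams, align_insert,
                     align_sample, build_index, call_snp_mask,
                     count_conversions, generate_reference,
                     index_from_reference)
from mirslam.quant import CountingUnit, FeatureIndex, SnpMask

PARAMS = AlignParams(flank=0)


def _index(*seqs: str) -> FeatureIndex:
    units = [CountingUnit(name=f"u{i}", members=(f"u{i}",), mature_seq=s,
                          template=s, mature_start=0)
             for i, s in enumerate(seqs)]
    return FeatureIndex(units=units)


def _bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


class TestBuildIndex:
    def test_identical_sequences_collapse_to_one_unit(self):
        seq = "ACGTACGTACGTACGTACGTAC"
        mature = {"mir-a": seq, "mir-b": seq, "mir-c": "TTGCATTGCATTGCATTGCA"}
        bed = _bed([("c", 10, 32, "mir-a", 0, "+"),
                    ("c", 50, 72, "mir-b", 0, "+"),
                    ("c", 90, 110, "mir-c", 0, "+")])
        index = build_index(mature, bed)
        assert len(index.units) == 2
        collapsed = next(u for u in index.units if len(u.members) == 2)
        assert collapsed.members == ("mir-a", "mir-b")
        assert collapsed.name == "mir-a|mir-b"

    def test_empty_inputs_give_empty_index(self):
        index = build_index({}, _bed([]))
        assert index.units == []

    def test_unique_sequences_one_unit_each(self):
        ref = generate_reference(SimConfig(n_mirnas=50, seed=21))
        index = index_from_reference(ref)
        assert len(index.units) == 50

    def test_orphan_ids_raise_listing_them(self):
        with pytest.raises(ValueError, match="mir-b"):
            build_index({"mir-a": "ACGTACGT", "mir-b": "TTTTACGT"},
                        _bed([("c", 0, 8, "mir-a", 0, "+")]))

    def test_templates_carry_genomic_flanks_both_strands(self):
        ref = generate_reference(SimConfig(n_mirnas=30, seed=5,
                                           minus_strand_fraction=0.5))
        index = index_from_reference(ref, flank=3)
        for unit in index.units:
            assert len(unit.template) == len(unit.mature_seq) + 6
            assert unit.template[3:-3] == unit.mature_seq


class TestAlignInsert:
    def test_identity_assignment(self):
        index = _index("ACGTTGCAACGTTGCAACGTTG", "GGCCATTACGGCCATTACGGCC")
        a = align_insert("ACGTTGCAACGTTGCAACGTTG", index, PARAMS)
        assert (a.unit_index, a.n_mismatches, a.n_conversions) == (0, 0, 0)

    def test_single_conversion_kept_and_recorded(self):
        tmpl = "ACGTTGCAACGTTGCAACGTTG"  # 22 nt
        insert = tmpl[:3] + "C" + tmpl[4:]  # T>C at position 3
        # kept under both integrity conventions: 21/22 = 0.954 clears 0.95
        # even when the conversion is penalized
        assert 21 / 22 >= PARAMS.integrity_min
        for strict in (False, True):
            p = AlignParams(flank=0, integrity_counts_conversions=strict)
            a = align_insert(insert, _index(tmpl), p)
            assert a is not None
            assert (a.n_conversions, a.n_mismatches) == (1, 0)
            assert list(a.c_positions) == [3]

    def test_two_other_mismatches_fail_integrity(self):
        tmpl = "ACGTTGCAACGTTGCAACGTTG"
        insert = "G" + tmpl[1:7] + "T" + tmpl[8:]  # A>G and A>T: not conversions
        # rejected under both conventions even though nm <= 3: the integrity
        # filter is the binding one for short reads
        assert 20 / 22 < PARAMS.integrity_min
        for strict in (False, True):
            p = AlignParams(flank=0, integrity_counts_conversions=strict)
            assert align_insert(insert, _index(tmpl), p) is None

    def test_multiply_converted_read_kept_unless_strict_integrity(self):
        """Two conversions on 22 nt: kept by default (conversions are not
        mismatches for integrity), rejected by the strict variant (20/22
        < 0.95) -- the setting that would censor heavily labeled reads."""
        tmpl = "ATTTTGCAACGTTGCAACGTTG"
        insert = tmpl.replace("T", "C", 2)
        assert align_insert(insert, _index(tmpl), PARAMS) is not None
        strict = AlignParams(flank=0, integrity_counts_conversions=True)
        assert align_insert(insert, _index(tmpl), strict) is None

    def test_cross_unit_tie_is_unassigned(self):
        a = "AAGGAAGGAAGGAAGGAAGG"
        b = "CAGGAAGGAAGGAAGGAAGC"  # differs from a at positions 0 and 19
        insert = "CAGGAAGGAAGGAAGGAAGG"  # one mismatch from each
        assert align_insert(insert, _index(a, b), PARAMS) is None
        assert align_insert(insert, _index(a), PARAMS) is not None

    def test_offset_within_flanked_template(self):
        mature = "ACGTTGCAACGTTGCAACGTTG"
        unit = CountingUnit(name="u", members=("u",), mature_seq=mature,
                            template="GGG" + mature + "CCC", mature_start=3)
        a = align_insert(mature, FeatureIndex(units=[unit]), AlignParams())
        assert a.offset == 3
        assert set(a.t_positions) == {3 + i for i, c in enumerate(mature)
                                      if c == "T"}


class TestCounting:
    def test_rate_arithmetic(self):
        tmpl = "TATATATATATATATATATA"  # 10 reference-T positions
        index = _index(tmpl)
        insert_conv = "CATATATATATATATATATA"  # one T>C
        align = align_sample([tmpl, insert_conv], index, PARAMS)
        prof = count_conversions(align)
        row = prof.iloc[0]
        assert (row["t_coverage"], row["tc_count"]) == (20, 1)
        assert row["conversion_rate"] == pytest.approx(1 / 20)

    def test_masked_position_excluded_from_both_sides(self):
        tmpl = "TATATATATATATATATATA"
        index = _index(tmpl)
        align = align_sample([tmpl, "CATATATATATATATATATA"], index, PARAMS)
        mask = SnpMask(frozenset({("u0", 0)}))
        row = count_conversions(align, mask).iloc[0]
        # the only converted position is masked: 0/18, not 1/18
        assert (row["t_coverage"], row["tc_count"]) == (18, 0)
        assert row["conversion_rate"] == 0.0

    def test_cpm_normalization(self):
        index = _index("ACGTTGCAACGTTGCAACGTTG", "GGCCATTACGGCCATTACGGCC",
                       "TTGGCCAATTGGCCAATTGGCC")
        inserts = [index.units[0].template] * 10 + \
                  [index.units[1].template] * 90
        prof = count_conversions(align_sample(inserts, index, PARAMS))
        assert prof["cpm"].sum() == pytest.approx(1e6)
        assert prof.set_index("unit").loc["u0", "cpm"] == pytest.approx(1e5)

    def test_masking_monotonicity(self):
        tmpl = "TAGTTGCAACGTTGCAACGTTG"
        index = _index(tmpl)
        rng = np.random.default_rng(0)
        inserts = []
        for _ in range(30):
            s = list(tmpl)
            for i, b in enumerate(s):
                if b == "T" and rng.random() < 0.2:
                    s[i] = "C"
            inserts.append("".join(s))
        align = align_sample(inserts, index, PARAMS)
        t_pos = [i for i, b in enumerate(tmpl) if b == "T"]
        prev = count_conversions(align).iloc[0]
        masked: set[tuple[str, int]] = set()
        for p in t_pos:
            masked.add(("u0", p))
            cur = count_conversions(align, SnpMask(frozenset(masked))).iloc[0]
            assert cur["t_coverage"] <= prev["t_coverage"]
            assert cur["tc_count"] <= prev["tc_count"]
            prev = cur


class TestSnpMask:
    def _control(self, inserts):
        tmpl = "GGTAACGGCAACGGCAACGG"  # reference T at position 2
        index = _index(tmpl)
        return tmpl, align_sample(inserts, index, PARAMS)

    def test_heterozygous_fraction_masked(self):
        tmpl, align = self._control(
            ["GGTAACGGCAACGGCAACGG"] * 10 + ["GGCAACGGCAACGGCAACGG"] * 10)
        mask = call_snp_mask([align], SnpParams())
        assert ("u0", 2) in mask.positions  # 10/20 = 0.5 >= 0.4

    def test_low_fraction_not_masked(self):
        tmpl, align = self._control(
            ["GGTAACGGCAACGGCAACGG"] * 17 + ["GGCAACGGCAACGGCAACGG"] * 3)
        assert call_snp_mask([align], SnpParams()).positions == frozenset()

    def test_low_coverage_not_masked(self):
        tmpl, align = self._control(["GGCAACGGCAACGGCAACGG"] * 5)
        assert call_snp_mask([align], SnpParams()).positions == frozenset()

    def test_requires_a_control(self):
        with pytest.raises(ValueError):
            call_snp_mask([], SnpParams())


class TestOracleEquivalence:
    def test_assignment_and_counts_match_bruteforce(self):
        rng = np.random.default_rng(2024)
        params = AlignParams()
        for _ in range(10):
            index, inserts = random_alignment_instance(rng, max_reads=60)
            for insert in inserts:
                got = align_insert(insert, index, params)
                want = brute_force_align(insert, index, params)
                if want is None:
                    assert got is None
                else:
                    assert got is not None
                    assert (got.unit_index, got.offset, len(got.c_positions),
                            len(got.t_positions)) == want
            align = align_sample(inserts, index, params)
            prof = count_conversions(align).set_index("unit")
            want_counts = brute_force_counts(inserts, index, params)
            for ui, (rc, tc, cov) in want_counts.items():
                row = prof.loc[index.units[ui].name]
                assert (row["read_count"], row["tc_count"],
                        row["t_coverage"]) == (rc, tc, cov)
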