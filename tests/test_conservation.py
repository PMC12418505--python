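"""Site/protein conservation scoring, the S/T rule, and group comparisons."""

from __future__ import annotations

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phosphocons import (
    Msa,
    PhosphoSite,
    compare_groups,
    default_registry,
    profile_protein,
    profile_site,
    site_conserved,
)
from phosphocons.conservation import classify_disorder, residues_equivalent, tukey_box_stats
from phosphocons.io_formats import AMINO_ACIDS


class TestSiteConservedRule:
    @pytest.mark.parametrize(
        "ref,other,st_eq,expected",
        [
            ("S", "T", True, True),   # Thr aligned with reference Ser
            ("T", "S", True, True),   # and vice versa
            ("S", "T", False, False),
            ("Y", "Y", True, True),
            ("Y", "F", True, False),
            ("S", "-", True, False),
            ("S", "X", True, False),
            ("X", "X", True, False),
        ],
    )
    def test_rule_table(self, ref, other, st_eq, expected):
        assert residues_equivalent(ref, other, st_eq) is expected

    def test_st_symmetry(self):
        """Swapping S<->T in both reference and subject never changes the result."""
        swap = {"S": "T", "T": "S"}
        for ref in AMINO_ACIDS:
            for other in AMINO_ACIDS + "-X":
                for st_eq in (True, False):
                    swapped = residues_equivalent(
                        swap.get(ref, ref), swap.get(other, other), st_eq
                    )
                    assert residues_equivalent(ref, other, st_eq) == swapped

    def test_site_conserved_on_msa(self, toy_msa):
        assert site_conserved(toy_msa, 2, "identical", True)
        assert site_conserved(toy_msa, 2, "st_swap", True)
        assert not site_conserved(toy_msa, 2, "st_swap", False)
        assert not site_conserved(toy_msa, 2, "decayed", True)
        assert not site_conserved(toy_msa, 2, "gappy", True)

    def test_position_beyond_reference_rejected(self, toy_msa):
        with pytest.raises(ValueError):
            site_conserved(toy_msa, 99, "identical", True)


class TestProfileSite:
    def _registry(self):
        return default_registry({"primates": 2, "fish": 2})

    def _msa(self, rows):
        return Msa({"REF": "ASPKY", **rows}, reference_id="REF")

    def test_group_percentages(self):
        registry = self._registry()
        msa = self._msa(
            {
                "primates_01": "ASPKY",
                "primates_02": "ATPKY",  # S->T swap still conserved
                "fish_01": "AAPKY",
                "fish_02": "ASPKY",
            }
        )
        prof = profile_site(msa, PhosphoSite("REF", "S", 2, 9), registry)
        assert prof.group_percent["primates"] == 100.0
        assert prof.group_percent["fish"] == 50.0

    def test_missing_species_counted_in_denominator(self):
        registry = self._registry()
        msa = self._msa({"primates_01": "ASPKY"})  # primates_02, fish absent
        prof = profile_site(msa, PhosphoSite("REF", "S", 2, 9), registry)
        assert prof.group_percent["primates"] == 50.0
        assert prof.group_percent["fish"] == 0.0
        assert prof.flags["fish_01"] is False

    def test_c_terminal_site_has_no_plus1(self):
        registry = self._registry()
        msa = self._msa({"primates_01": "ASPKY"})
        prof = profile_site(msa, PhosphoSite("REF", "Y", 5, 9), registry)
        assert prof.plus1_flags is None

    def test_plus1_st_equivalence_follows_reference_plus1(self):
        registry = default_registry({"primates": 1})
        # site S1, reference +1 is S: a T at +1 counts as conserved
        msa = Msa({"REF": "SSK", "primates_01": "STK"}, reference_id="REF")
        prof = profile_site(msa, PhosphoSite("REF", "S", 1, 9), registry)
        assert prof.plus1_flags["primates_01"] is True
        # reference +1 is K: only K matches
        msa2 = Msa({"REF": "SKA", "primates_01": "SRA"}, reference_id="REF")
        prof2 = profile_site(msa2, PhosphoSite("REF", "S", 1, 9), registry)
        assert prof2.plus1_flags["primates_01"] is False

    def test_no_st_equivalence_for_tyr_sites(self):
        registry = default_registry({"primates": 1})
        msa = Msa({"REF": "AYK", "primates_01": "ASK"}, reference_id="REF")
        prof = profile_site(msa, PhosphoSite("REF", "Y", 2, 9), registry)
        assert prof.flags["primates_01"] is False

    def test_wrong_reference_residue_rejected(self, toy_msa):
        registry = default_registry({"primates": 1})
        with pytest.raises(ValueError):
            profile_site(toy_msa, PhosphoSite("REF", "T", 2, 9), registry)

    def test_broad_group_is_weighted_mean_of_base_groups(self, small_bundle):
        b = small_bundle
        rec = b.reference_records[0]
        site = b.sites_of(rec.accession)[0]
        prof = profile_site(b.msas[rec.accession], site, b.registry)
        for broad, parts in [("mammals", ("primates", "other-mammals"))]:
            weighted = sum(
                prof.group_percent[g] * len(b.registry.group(g)) for g in parts
            ) / sum(len(b.registry.group(g)) for g in parts)
            assert prof.group_percent[broad] == pytest.approx(weighted)

    def test_adding_conserved_species_never_decreases_percentage(self):
        # (c+1)/(n+1) >= c/n for 0 <= c <= n
        for n in range(1, 30):
            for c in range(n + 1):
                assert (c + 1) / (n + 1) >= c / n


class TestProfileProtein:
    def _profiles(self, percents_list):
        registry = default_registry({"primates": 1})
        profiles = []
        for i, pct in enumerate(percents_list):
            msa = Msa(
                {"REF": "SA", "primates_01": "SA" if pct else "AA"},
                reference_id="REF",
            )
            profiles.append(
                profile_site(msa, PhosphoSite("REF", "S", 1, 9), registry)
            )
        return profiles

    def test_mean_of_two_sites(self):
        profs = self._profiles([True, False])  # 100 and 0
        prot = profile_protein(profs, "ST")
        assert prot.group_percent["primates"] == 50.0
        assert prot.n_sites == 2

    def test_single_site_equals_site_profile(self):
        profs = self._profiles([True])
        assert profile_protein(profs, "ST").group_percent["primates"] == 100.0

    def test_reordering_invariant(self):
        profs = self._profiles([True, False, True])
        fwd = profile_protein(profs, "ST").group_percent
        rev = profile_protein(list(reversed(profs)), "ST").group_percent
        assert fwd == rev

    def test_missing_class_returns_none(self):
        profs = self._profiles([True])
        assert profile_protein(profs, "Y") is None

    def test_mixed_proteins_rejected(self):
        registry = default_registry({"primates": 1})
        a = profile_site(
            Msa({"P1": "SA", "primates_01": "SA"}, reference_id="P1"),
            PhosphoSite("P1", "S", 1, 9),
            registry,
        )
        b = profile_site(
            Msa({"P2": "SA", "primates_01": "SA"}, reference_id="P2"),
            PhosphoSite("P2", "S", 1, 9),
            registry,
        )
        with pytest.raises(ValueError):
            profile_protein([a, b], "ST")


class TestDisorderAndBoxes:
    @pytest.mark.parametrize(
        "score,expected",
        [(0.7, "disordered"), (0.5, "ordered"), (0.51, "disordered"), (0.0, "ordered")],
    )
    def test_disorder_threshold_strict(self, score, expected):
        assert classify_disorder(score) == expected

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            classify_disorder(1.2)

    def test_tukey_by_hand(self):
        """{1,2,3,4,100}: IQR fence puts 100 out, whisker_high stays at 4."""
        box = tukey_box_stats([1, 2, 3, 4, 100])
        assert (box.q1, box.median, box.q3) == (2.0, 3.0, 4.0)
        assert box.whisker_high == 4.0
        assert box.whisker_low == 1.0
        assert box.outliers == (100.0,)

    def test_identical_lists_give_null_test(self):
        _, _, t, p = compare_groups([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
        assert t == 0.0 and p == 1.0

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(42)
        a = rng.normal(50, 10, size=50)
        b = rng.normal(80, 10, size=50)  # +30 conservation points
        _, _, _, p = compare_groups(list(a), list(b))
        assert p < 0.05

    def test_insufficient_data_gives_nan_test_but_boxes(self):
        box_a, box_b, t, p = compare_groups([1.0], [2.0, 3.0])
        assert math.isnan(t) and math.isnan(p)
        assert box_a.median == 1.0 and box_b.median == 2.5


class TestOracleEquivalence:
    """A brute-force column scanner reproduces flags and percentages exactly."""

    @staticmethod
    def brute_force(rows, ref_id, position, st_eq):
        """Independent scan over the raw MSA strings."""
        ref_row = rows[ref_id]
        seen, col = 0, None
        for i, c in enumerate(ref_row):
            if c != "-":
                seen += 1
                if seen == position:
                    col = i
                    break
        assert col is not None
        ref_char = ref_row[col]
        out = {}
        for rid, row in rows.items():
            if rid == ref_id:
                continue
            c = row[col]
            ok = (
                c not in "-X"
                and ref_char not in "-X"
                and (c == ref_char or (st_eq and ref_char in "ST" and c in "ST"))
            )
            out[rid] = ok
        return out

    def test_randomized_msas(self):
        rng = random.Random(123)
        registry = default_registry({"primates": 3, "fish": 3})
        species = [s[0] for s in registry.species]
        for _ in range(60):
            length = rng.randint(5, 40)
            ref = [rng.choice(AMINO_ACIDS) for _ in range(length)]
            site_pos = rng.randint(1, length - 1)
            ref[site_pos - 1] = rng.choice("STY")
            rows = {"REF": "".join(ref)}
            for sid in species[: rng.randint(2, len(species))]:
                row = [
                    rng.choice(AMINO_ACIDS + "--X") if rng.random() < 0.4 else c
                    for c in ref
                ]
                rows[sid] = "".join(row)
            msa = Msa(rows, reference_id="REF")
            site = PhosphoSite("REF", rows["REF"][site_pos - 1], site_pos, 9)
            prof = profile_site(msa, site, registry)
            expected = self.brute_force(rows, "REF", site_pos, site.residue in "ST")
            for sid in species:
                assert prof.flags[sid] == expected.get(sid, False)
            for gname, members in registry.groups.items():
                pct = 100.0 * sum(prof.flags[s] for s in members) / len(members)
                assert prof.group_percent[gname] == pytest.approx(pct)


@given(st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=30))
@settings(max_examples=50, derandomize=True)
def test_box_stats_invariants(values):
    box = tukey_box_stats(values)
    assert box.q1 <= box.median <= box.q3
    assert box.whisker_low <= box.q1 and box.q3 <= box.whisker_high
    iqr = box.q3 - box.q1
    for out in box.outliers:
        assert out < box.q1 - 1.5 * iqr or out > box.q3 + 1.5 * iqr
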