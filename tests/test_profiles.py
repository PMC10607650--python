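"""Degree of unsaturation and weighted average melting temperature."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fametrics.fa_core import MeltingPointTable, parse_fatty_acid
from fametrics.profiles import (
    ProfileSet,
    ReplicateProfile,
    censored_below,
    degree_of_unsaturation,
    not_detected,
    quantified,
    summarize,
    wamt,
)


def make_profile(components, organism="X", condition="co2_10C", **kw):
    return ReplicateProfile(
        organism=organism, condition=condition, components=components, **kw
    )


def brute_force_du(components, policy="zero"):
    """Independent oracle: direct per-acid bond-count × fraction sum."""
    total = 0.0
    for label, cell in components.items():
        n_bonds = int(label.split(":")[1].split()[0])
        if cell.kind == "quantified":
            pct = cell.mean
        elif cell.kind == "censored_below" and policy == "midpoint":
            pct = cell.threshold / 2
        else:
            pct = 0.0
        total += n_bonds * pct / 100.0
    return total


class TestDegreeOfUnsaturation:
    def test_co2_yeast_row(self):
        """A CO₂-grown yeast profile dominated by oleic/linoleic/linolenic
        acid lands at DU 1.49."""
        profile = make_profile(
            {
                "C16:0": quantified(10.4, 0.5),
                "C16:1 cis 9": quantified(8.9, 1.8),
                "C18:0": censored_below(1),
                "C18:1 cis 9": quantified(38.7, 3.1),
                "C18:2 cis 9, 12": quantified(24.8, 1.9),
                "C18:3 cis 9, 12, 15": quantified(17.3, 2.6),
            }
        )
        assert round(degree_of_unsaturation(profile), 2) == 1.49

    def test_polyunsaturated_mould_row(self):
        profile = make_profile(
            {
                "C16:0": quantified(8.9, 0.4),
                "C18:0": quantified(6.8, 2.9),
                "C18:1 cis 9": quantified(4.2, 2.2),
                "C18:2 cis 9, 12": quantified(47.3, 4.6),
                "C18:3 cis 9, 12, 15": quantified(32.8, 4.5),
            }
        )
        assert round(degree_of_unsaturation(profile), 2) == 1.97

    def test_saturated_only_profile_is_zero(self):
        profile = make_profile(
            {"C16:0": quantified(60.0), "C18:0": quantified(40.0)}
        )
        assert degree_of_unsaturation(profile) == 0.0

    def test_midpoint_policy_adds_half_threshold(self):
        profile = make_profile(
            {
                "C16:0": quantified(99.0),
                "C18:2 cis 9, 12": censored_below(1),
            }
        )
        assert degree_of_unsaturation(profile, "zero") == 0.0
        assert degree_of_unsaturation(profile, "midpoint") == pytest.approx(
            2 * 0.5 / 100
        )

    def test_empty_profile_raises(self):
        with pytest.raises(ValueError, match="empty"):
            degree_of_unsaturation(make_profile({}))

    def test_polyene_contributes_actual_bond_count(self):
        profile = make_profile(
            {"C20:4": quantified(10.0), "C16:0": quantified(90.0)}
        )
        assert degree_of_unsaturation(profile) == pytest.approx(0.4)

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=3),
                st.floats(min_value=0.5, max_value=40.0),
            ),
            min_size=2,
            max_size=6,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_oracle(self, spec):
        # build distinct labels; rescale into a valid composition
        total = sum(p for _, p in spec)
        components = {}
        labels = [
            "C14:0", "C16:1 cis 9", "C18:2 cis 9, 12", "C18:3 cis 9, 12, 15",
            "C20:1 cis 11", "C22:3 cis 7, 10, 13",
        ]
        by_bonds = {0: "C14:0", 1: "C16:1 cis 9", 2: "C18:2 cis 9, 12",
                    3: "C18:3 cis 9, 12, 15"}
        alt = {0: "C18:0", 1: "C20:1 cis 11", 2: "C20:2 cis 11, 14",
               3: "C20:3 cis 8, 11, 14"}
        for i, (bonds, pct) in enumerate(spec):
            label = (by_bonds if i % 2 == 0 else alt)[bonds]
            pct = pct / total * 100.0
            if label in components:
                old = components[label]
                components[label] = quantified(old.mean + pct)
            else:
                components[label] = quantified(pct)
        profile = make_profile(components)
        assert degree_of_unsaturation(profile) == pytest.approx(
            brute_force_du(components), abs=1e-12
        )

    def test_linearity_moving_mass_to_triene(self):
        """Moving x points from a saturated acid to a triene raises DU by
        exactly 3x/100."""
        base = make_profile(
            {"C16:0": quantified(50.0), "C18:3 cis 9, 12, 15": quantified(50.0)}
        )
        shifted = make_profile(
            {"C16:0": quantified(40.0), "C18:3 cis 9, 12, 15": quantified(60.0)}
        )
        assert degree_of_unsaturation(shifted) - degree_of_unsaturation(
            base
        ) == pytest.approx(3 * 10 / 100.0)


SIMPLE_TABLE = MeltingPointTable(
    entries={"C16:0": 62.9, "C18:1 cis 9": 13.4, "C18:3 cis 9, 12, 15": -11.3}
)


class TestWamt:
    def test_single_acid_collapses_to_table_entry(self):
        profile = make_profile({"C16:0": quantified(100.0)})
        temp, coverage = wamt(profile, SIMPLE_TABLE)
        assert temp == pytest.approx(62.9)
        assert coverage == 1.0

    def test_equal_weights_give_arithmetic_mean(self):
        profile = make_profile(
            {"C16:0": quantified(50.0), "C18:1 cis 9": quantified(50.0)}
        )
        temp, _ = wamt(profile, SIMPLE_TABLE)
        assert temp == pytest.approx((62.9 + 13.4) / 2)

    def test_renormalizes_over_covered_acids_and_reports_coverage(self):
        profile = make_profile(
            {
                "C16:0": quantified(50.0),
                "C18:1 cis 9": quantified(25.0),
                "C17:0": quantified(25.0),  # not in table
            }
        )
        temp, coverage = wamt(profile, SIMPLE_TABLE)
        assert temp == pytest.approx((50 * 62.9 + 25 * 13.4) / 75)
        assert coverage == pytest.approx(0.75)

    def test_zero_coverage_is_an_error(self):
        profile = make_profile({"C17:0": quantified(100.0)})
        with pytest.raises(ValueError, match="no melting temperatures"):
            wamt(profile, MeltingPointTable())

    def test_bounded_by_covered_extremes(self, fungal_profiles, melting_table):
        for profile in fungal_profiles:
            temp, _ = wamt(profile, melting_table)
            temps = [
                melting_table.get(lab)
                for lab, c in profile.components.items()
                if c.kind == "quantified" and melting_table.get(lab) is not None
            ]
            assert min(temps) <= temp <= max(temps)

    def test_replacing_saturated_mass_with_colder_acid_lowers_wamt(self):
        base = make_profile(
            {"C16:0": quantified(60.0), "C18:1 cis 9": quantified(40.0)}
        )
        swapped = make_profile(
            {"C16:0": quantified(40.0), "C18:1 cis 9": quantified(60.0)}
        )
        assert wamt(swapped, SIMPLE_TABLE)[0] < wamt(base, SIMPLE_TABLE)[0]


class TestProfileValidation:
    def test_total_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            make_profile({"C16:0": quantified(50.0)})

    def test_replicate_summary_mismatch_rejected(self):
        reps = pd.DataFrame({"C16:0": [60.0, 60.0, 60.0], "C18:0": [40.0] * 3})
        with pytest.raises(ValueError, match="replicate mean"):
            make_profile(
                {"C16:0": quantified(55.0, 1.0), "C18:0": quantified(45.0, 1.0)},
                replicates=reps,
            )

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            quantified(-5.0)


class TestSummarize:
    def test_fixture_has_sixty_rows_in_stable_order(
        self, fungal_profiles, melting_table
    ):
        df = summarize(fungal_profiles, melting_table)
        assert len(df) == 60
        assert df["organism"].nunique() == 20
        # conditions grouped per organism, CO2 condition first
        first = df.groupby("organism", sort=False)["condition"].first()
        assert (first == "co2_10C").all()

    def test_empty_set_gives_empty_table(self, melting_table):
        df = summarize(ProfileSet(), melting_table)
        assert len(df) == 0
        assert list(df.columns) == [
            "organism", "condition", "du", "wamt", "wamt_coverage",
        ]

    def test_du_column_matches_per_profile_recomputation(
        self, fungal_profiles, melting_table
    ):
        df = summarize(fungal_profiles, melting_table)
        for _, row in df.iterrows():
            profile = fungal_profiles.get(row["organism"], row["condition"])
            assert row["du"] == pytest.approx(
                brute_force_du(profile.components), abs=1e-12
            )
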