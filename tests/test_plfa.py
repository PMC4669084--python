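"""PLFA incorporation, biomarker groups, proportions, logit transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sipriming.isotope import SubstrateSpec, delta_to_fraction, fraction_to_delta
from sipriming.plfa import (
    BiomarkerMap,
    canonical_plfa,
    default_biomarker_map,
    empirical_logit,
    enrichment_matrix,
    filter_low_enrichment,
    group_incorporation,
    plfa_incorporation,
    relative_enrichment,
)

LC = SubstrateSpec("lignocellulose", atom_fraction_13c=0.97, dose_mgc_per_ml=0.15)
BASE_DELTA = -25.0


def plfa_rows(vial_id, treatment, day, entries):
    """entries: list of (plfa, conc, delta)."""
    return [
        {
            "vial_id": vial_id,
            "treatment": treatment,
            "day": day,
            "plfa": p,
            "conc": c,
            "delta": d,
        }
        for p, c, d in entries
    ]


def delta_for_excess(excess, background_delta=BASE_DELTA):
    return fraction_to_delta(delta_to_fraction(background_delta) + excess)


class TestCanonicalNames:
    @pytest.mark.parametrize(
        "raw, canon",
        [
            ("18:1ω7", "18:1w7"),
            ("18:1n7", "18:1w7"),
            ("i-15:0", "i15:0"),
            ("a-15:0", "a15:0"),
            (" 16:1w7 ", "16:1w7"),
            ("10Me16:0", "10Me16:0"),
            ("cy17:0", "cy17:0"),
            ("18:2ω6", "18:2w6"),
        ],
    )
    def test_dialects(self, raw, canon):
        assert canonical_plfa(raw) == canon

    def test_biomarker_groups_must_be_disjoint(self):
        with pytest.raises(ValueError, match="disjoint"):
            BiomarkerMap({"a": ("i15:0",), "b": ("i-15:0",)})

    def test_default_map_members(self):
        m = default_biomarker_map()
        assert set(m.members("bacteria")) == {"i15:0", "a15:0", "i16:0", "18:1w7"}
        assert "18:1w9" in m.members("eukaryotes")


class TestIncorporation:
    def table(self, sample_entries):
        ctrl = plfa_rows(
            "c1", "CTRL", 7.0, [(p, c, BASE_DELTA) for p, c, _ in sample_entries]
        )
        samp = plfa_rows("s1", "LC", 7.0, sample_entries)
        return pd.DataFrame(ctrl + samp)

    def test_zero_when_sample_matches_background(self):
        df = self.table([("i15:0", 5.0, BASE_DELTA), ("16:0", 8.0, BASE_DELTA)])
        out = plfa_incorporation(df, LC)
        assert out["i_plfa"].abs().max() < 1e-15

    def test_hand_value_and_linearity(self):
        d = delta_for_excess(0.002)
        df = self.table([("i15:0", 5.0, d), ("a15:0", 10.0, d)])
        out = plfa_incorporation(df, LC).set_index("plfa")
        assert out.loc["i15:0", "i_plfa"] == pytest.approx(0.010309278, rel=1e-6)
        assert out.loc["a15:0", "i_plfa"] == pytest.approx(
            2 * out.loc["i15:0", "i_plfa"], rel=1e-12
        )

    def test_missing_background_excluded_with_warning(self, caplog):
        df = self.table([("i15:0", 5.0, BASE_DELTA)])
        extra = pd.DataFrame(plfa_rows("s1", "LC", 7.0, [("cy19:0", 1.0, -20.0)]))
        df = pd.concat([df, extra], ignore_index=True)
        with caplog.at_level("WARNING"):
            out = plfa_incorporation(df, LC)
        assert "cy19:0" in caplog.text
        assert "cy19:0" not in set(out["plfa"])

    def test_duplicate_plfa_in_profile_rejected(self):
        df = pd.DataFrame(
            plfa_rows("s1", "LC", 7.0, [("i15:0", 5.0, -20.0), ("i-15:0", 5.0, -20.0)])
        )
        with pytest.raises(ValueError, match="duplicate"):
            plfa_incorporation(df, LC)


class TestGroups:
    def make_incorporation(self, rng):
        plfas = ["i15:0", "a15:0", "i16:0", "18:1w7", "16:0", "18:1w9", "18:2w6"]
        entries = [(p, float(rng.uniform(1, 10)), delta_for_excess(float(rng.uniform(0, 0.003)))) for p in plfas]
        ctrl = plfa_rows("c1", "CTRL", 7.0, [(p, c, BASE_DELTA) for p, c, _ in entries])
        samp = plfa_rows("s1", "LC", 7.0, entries)
        return plfa_incorporation(pd.DataFrame(ctrl + samp), LC)

    def test_matches_brute_force_filtered_sum(self):
        rng = np.random.default_rng(7)
        incorp = self.make_incorporation(rng)
        out = group_incorporation(incorp).set_index("group")
        bact = {"i15:0", "a15:0", "i16:0", "18:1w7"}
        brute = incorp[incorp["plfa"].isin(bact)]["i_plfa"].sum()
        assert out.loc["bacteria", "i_total"] == pytest.approx(brute, rel=1e-12)
        brute_conc = incorp[incorp["plfa"].isin(bact)]["conc"].sum()
        assert out.loc["bacteria", "conc_total"] == pytest.approx(brute_conc)

    def test_invariant_to_entry_order(self):
        rng = np.random.default_rng(8)
        incorp = self.make_incorporation(rng)
        shuffled = incorp.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = group_incorporation(incorp).set_index("group")["i_total"]
        b = group_incorporation(shuffled).set_index("group")["i_total"]
        pd.testing.assert_series_equal(a, b)

    def test_empty_group_warns_and_zeroes(self, caplog):
        df = pd.DataFrame(
            plfa_rows("c1", "CTRL", 7.0, [("i15:0", 5.0, BASE_DELTA)])
            + plfa_rows("s1", "LC", 7.0, [("i15:0", 5.0, delta_for_excess(0.001))])
        )
        incorp = plfa_incorporation(df, LC)
        with caplog.at_level("WARNING"):
            out = group_incorporation(incorp).set_index("group")
        assert out.loc["eukaryotes", "i_total"] == 0.0
        assert out.loc["bacteria", "i_total"] > 0
        assert "eukaryotes" in caplog.text


class TestProportions:
    def test_single_nonzero_gets_one(self):
        df = pd.DataFrame(
            plfa_rows("c1", "CTRL", 7.0, [("i15:0", 5.0, BASE_DELTA), ("16:0", 5.0, BASE_DELTA)])
            + plfa_rows(
                "s1", "LC", 7.0,
                [("i15:0", 5.0, delta_for_excess(0.002)), ("16:0", 5.0, BASE_DELTA)],
            )
        )
        props = relative_enrichment(plfa_incorporation(df, LC)).set_index("plfa")
        assert props.loc["i15:0", "proportion"] == pytest.approx(1.0, abs=1e-12)
        assert props.loc["16:0", "proportion"] == pytest.approx(0.0, abs=1e-12)

    def test_sums_to_one_and_matches_hand_normalisation(self):
        rng = np.random.default_rng(3)
        plfas = ["i15:0", "a15:0", "16:0", "18:1w9"]
        entries = [(p, 5.0, delta_for_excess(float(rng.uniform(1e-4, 3e-3)))) for p in plfas]
        df = pd.DataFrame(
            plfa_rows("c1", "CTRL", 7.0, [(p, 5.0, BASE_DELTA) for p in plfas])
            + plfa_rows("s1", "LC", 7.0, entries)
        )
        incorp = plfa_incorporation(df, LC)
        props = relative_enrichment(incorp)
        assert props["proportion"].sum() == pytest.approx(1.0, abs=1e-12)
        hand = incorp["i_plfa"] / incorp["i_plfa"].sum()
        assert np.allclose(props["proportion"], hand, rtol=1e-12)

    def test_nonpositive_total_names_vial(self):
        df = pd.DataFrame(
            plfa_rows("c1", "CTRL", 7.0, [("i15:0", 5.0, BASE_DELTA)])
            + plfa_rows("badvial", "LC", 7.0, [("i15:0", 5.0, BASE_DELTA)])
        )
        with pytest.raises(ValueError, match="badvial"):
            relative_enrichment(plfa_incorporation(df, LC))


class TestFilter:
    def matrix(self, cols):
        return pd.DataFrame(cols).T  # rows = plfa, columns = profiles

    def test_zero_column_dropped_and_boundary_retained(self):
        m = pd.DataFrame(
            {
                "p1": [0.0, 0.0],
                "p2": [0.001, 0.001],  # mean exactly at threshold: retained
                "p3": [0.5, 0.5],
            }
        ).T
        filtered, retained, dropped = filter_low_enrichment(m, 0.001)
        assert dropped == ["p1"]
        assert set(retained) == {"p2", "p3"}
        assert list(filtered.index) == ["p2", "p3"]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(
            rng.uniform(0, 0.004, size=(10, 6)),
            index=[f"p{i}" for i in range(10)],
        )
        _, retained, dropped = filter_low_enrichment(m, 0.001)
        brute_keep = [i for i in m.index if m.loc[i].mean() >= 0.001]
        assert retained == brute_keep
        assert set(dropped) == set(m.index) - set(brute_keep)


class TestEmpiricalLogit:
    def test_hand_values(self):
        assert empirical_logit(0.5) == pytest.approx(0.0, abs=1e-15)
        assert empirical_logit(0.0) == pytest.approx(-2.3978952728, abs=1e-9)
        assert empirical_logit(1.0) == pytest.approx(2.3978952728, abs=1e-9)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_antisymmetric_about_half(self, p):
        assert empirical_logit(p) + empirical_logit(1.0 - p) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_monotone(self):
        p = np.linspace(0, 1, 101)
        assert np.all(np.diff(empirical_logit(p)) > 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            empirical_logit(1.2)
        with pytest.raises(ValueError):
            empirical_logit(0.5, tol=0.0)


class TestEnrichmentMatrix:
    def test_time_average_collapses_days(self, rates_sim):
        incorp = plfa_incorporation(rates_sim.plfa, LC)
        props = relative_enrichment(incorp[incorp.day > 0])
        by_time = enrichment_matrix(props, time_average=False)
        averaged = enrichment_matrix(props, time_average=True)
        assert averaged.shape[1] == 3  # one column per labelled treatment
        assert by_time.shape[1] == 12  # treatment x sampling-day combinations
        assert set(averaged.columns) == {"LC", "LC1D", "LC2D"}
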