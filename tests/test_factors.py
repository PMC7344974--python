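"""Scoring-model tests: table validation, lookup, the log-product score,
category banding, and the scoring invariants."""

import math
from dataclasses import replace

import numpy as np
import pytest

from expoband import (
    FACTOR_IDS,
    FactorTable,
    FactorTableError,
    SituationProfile,
    UnknownLabelError,
    assign_category,
    compute_exposure_score,
    enumerate_attainable_log_scores,
    load_factor_table,
    lookup_factor_score,
    max_attainable_score,
    score_breakdown_report,
)
from expoband.factors import Classification, FactorSpec, round_half_up

from conftest import no_exposure_profile, random_profile


class TestFactorTable:
    def test_default_table_structure(self, table):
        assert [f.factor_id for f in table.factors] == list(FACTOR_IDS)
        assert table.divisor.factor_id == "room_volume"
        assert sorted(table.factor("room_volume").scores()) == [1.0, 5.0, 10.0]
        em = table.factor("potential_emission")
        assert em.phase_dependent
        assert list(em.scores("liquid")) == [1.0, 1.5, 2.0, 3.0, 5.0]
        assert list(em.scores("solid")) == [1.0, 1.5, 2.0, 3.0, 5.0]

    def test_every_factor_has_one_no_exposure_class_scoring_one(self, table):
        for f in table.factors:
            flagged = [c for c in f.classifications if c.no_exposure]
            assert len(flagged) == 1
            assert flagged[0].score == 1.0

    def test_all_scores_within_allowed_range(self, table):
        for f in table.factors:
            for c in f.classifications:
                assert 1.0 <= c.score <= 10.0

    def test_missing_factor_rejected(self, table):
        without_ppe = tuple(f for f in table.factors if f.factor_id != "ppe")
        with pytest.raises(FactorTableError, match="ppe"):
            FactorTable(factors=without_ppe)

    def test_duplicate_label_rejected(self):
        with pytest.raises(FactorTableError, match="duplicate"):
            FactorSpec(
                factor_id="distance",
                role="multiplier",
                classifications=(
                    Classification("No exposure", 1.0, no_exposure=True),
                    Classification(">1 m", 1.5),
                    Classification(">1  M", 2.0),  # same after normalisation
                ),
            )

    def test_score_out_of_range_rejected(self):
        with pytest.raises(FactorTableError, match="outside"):
            FactorSpec(
                factor_id="distance",
                role="multiplier",
                classifications=(
                    Classification("No exposure", 1.0, no_exposure=True),
                    Classification("far", 0.5),
                ),
            )

    def test_second_divisor_rejected(self, table):
        bad = tuple(
            replace(f, role="divisor") if f.factor_id == "distance" else f
            for f in table.factors
        )
        with pytest.raises(FactorTableError, match="divisor"):
            FactorTable(factors=bad)


class TestLookup:
    @pytest.mark.parametrize(
        "factor_id,label,phase,expected",
        [
            ("health_hazard", "Hazard category 2", None, 4.0),
            ("ppe", "0% protection (no use of PPE)", None, 5.0),
            ("potential_emission", "Neither potential emission nor handling", "liquid", 1.0),
            ("position_factor", "General worker", None, 2.0),
            ("room_volume", ">1000 m3", None, 10.0),
            ("room_volume", "<100 m3", None, 1.0),
        ],
    )
    def test_lookup_examples(self, table, factor_id, label, phase, expected):
        assert lookup_factor_score(table, factor_id, label, phase) == expected

    def test_lookup_is_case_and_whitespace_insensitive(self, table):
        assert lookup_factor_score(table, "position_factor", "  GENERAL   worker ") == 2.0

    def test_alias_resolution(self, table):
        # abbreviated entry label maps onto the canonical manual-handling class
        assert (
            lookup_factor_score(table, "process_type", "Manual handling with low-level cleaning")
            == 2.0
        )

    def test_unknown_label_lists_valid_options(self, table):
        with pytest.raises(UnknownLabelError) as exc:
            lookup_factor_score(table, "distance", "2 km away")
        assert ">1 m" in str(exc.value)


class TestScore:
    def test_worked_frp_lamination_example(self, table, bands, frp_profile):
        r = compute_exposure_score(table, frp_profile, bands)
        assert r.raw_product == pytest.approx(552.96, abs=1e-9)
        assert r.score_2dp == 6.32
        assert r.category == 3
        assert not r.clamped

    def test_breakdown_sums_to_log_score(self, table, bands, frp_profile):
        r = compute_exposure_score(table, frp_profile, bands)
        assert sum(e.log_contribution for e in r.breakdown) == pytest.approx(
            r.log_score, abs=1e-9
        )
        vol = next(e for e in r.breakdown if e.factor_id == "room_volume")
        assert vol.log_contribution == pytest.approx(-math.log(10.0))
        assert "6.32" in score_breakdown_report(r)

    def test_all_no_exposure_profile_scores_one(self, table, bands):
        r = compute_exposure_score(table, no_exposure_profile(table), bands)
        assert r.score == 1.00
        assert r.category == 1
        assert all(e.log_contribution == 0.0 for e in r.breakdown)

    def test_maximal_profile_reaches_upper_band_limit(self, table, bands):
        selections = {}
        for f in table.factors:
            classes = [
                c for c in f.classifications
                if not f.phase_dependent or c.phase == "liquid"
            ]
            pick = min if f.role == "divisor" else max
            selections[f.factor_id] = pick(classes, key=lambda c: c.score).label
        r = compute_exposure_score(
            table, SituationProfile("max", "liquid", selections), bands
        )
        assert r.score_2dp == 14.01
        assert r.category == 4

    def test_small_nontrivial_profile_is_clamped_into_band_two(self, table, bands):
        p = no_exposure_profile(table)
        sels = dict(p.selections)
        sels["position_factor"] = (
            "Utility engineer, EHS manager, field inspector, etc."
        )
        r = compute_exposure_score(
            table, SituationProfile("tiny", "liquid", sels), bands
        )
        assert r.log_score == pytest.approx(math.log(1.2))
        assert r.clamped
        assert r.score == 1.01
        assert r.category == 2

    def test_invalid_selection_propagates(self, table, bands, frp_profile):
        sels = dict(frp_profile.selections)
        sels["ppe"] = "wizard hat"
        with pytest.raises(UnknownLabelError):
            compute_exposure_score(
                table, SituationProfile("bad", "liquid", sels), bands
            )

    def test_profile_must_cover_every_factor(self, frp_profile):
        sels = dict(frp_profile.selections)
        del sels["distance"]
        with pytest.raises(ValueError, match="distance"):
            SituationProfile("partial", "liquid", sels)


class TestCategory:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (1.00, 1),
            (1.01, 2),
            (4.76, 2),
            (4.764, 2),   # rounds down into band 2
            (4.765, 3),   # half-up rounding crosses into band 3
            (4.77, 3),
            (6.32, 3),
            (9.38, 3),
            (9.39, 4),
            (10.57, 4),
            (14.01, 4),
        ],
    )
    def test_banding(self, bands, score, expected):
        assert assign_category(bands, score) == expected

    def test_score_above_table_maximum_rejected(self, bands):
        with pytest.raises(ValueError, match="exceeds"):
            assign_category(bands, 14.50)

    def test_band_cutpoints_sit_at_34_and_67_percent_of_maximum(self, table, bands):
        m = max_attainable_score(table)
        assert abs(bands.bands[1].upper - 0.34 * m) <= 0.01
        assert abs(bands.bands[2].upper - 0.67 * m) <= 0.01
        assert round_half_up(m) == bands.max_score

    def test_rounding_is_half_up(self):
        assert round_half_up(4.765) == 4.77
        assert round_half_up(1.005) == 1.01


class TestInvariants:
    def test_max_score_agrees_with_exhaustive_enumeration(self, table):
        logs = enumerate_attainable_log_scores(table)
        assert logs.max() == pytest.approx(max_attainable_score(table), abs=1e-8)
        assert round(logs.max(), 2) == 14.01
        # the all-no-exposure combination yields ln(1) = 0
        assert logs.min() <= 0.0 <= logs.max()

    def test_score_equals_direct_formula_on_random_profiles(self, table, bands):
        rng = np.random.default_rng(20260929)
        for _ in range(1000):
            p = random_profile(table, rng)
            r = compute_exposure_score(table, p, bands)
            direct = 1.0
            for fid in FACTOR_IDS[:-1]:
                direct *= lookup_factor_score(table, fid, p.selections[fid], p.phase)
            direct /= lookup_factor_score(table, "room_volume", p.selections["room_volume"])
            assert r.log_score == pytest.approx(math.log(direct), abs=1e-12)
            assert 1.00 <= r.score <= max_attainable_score(table) + 1e-9

    def test_raising_a_multiplier_strictly_raises_the_log_score(self, table, bands):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = random_profile(table, rng)
            base = compute_exposure_score(table, p, bands).log_score
            fid = FACTOR_IDS[int(rng.integers(len(FACTOR_IDS)))]
            spec = table.factor(fid)
            phase = p.phase if spec.phase_dependent else None
            current = spec.find(p.selections[fid], phase)
            higher = [
                c
                for c in (spec.classifications if phase is None
                          else [c for c in spec.classifications if c.phase == phase])
                if c.score > current.score
            ]
            if not higher:
                continue
            sels = dict(p.selections)
            sels[fid] = higher[0].label
            bumped = compute_exposure_score(
                table, SituationProfile("bump", p.phase, sels), bands
            ).log_score
            if spec.role == "divisor":
                assert bumped < base
            else:
                assert bumped > base
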