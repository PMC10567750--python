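"""Weight-factor scoring: normalization, raw scores, final estimates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adlhub import (
    ADLDefinition,
    CHANNELS,
    ChannelFeatures,
    ConfigurationError,
    DeviceKind,
    FEATURE_NAMES,
    FeatureVector,
    NormalizationRanges,
    SensorChannel,
    TriggeringEvent,
    WeightTable,
    estimate,
    normalize,
    score,
)

T = SensorChannel.TEMPERATURE
H = SensorChannel.HUMIDITY


def uniform_ranges(lo=0.0, hi=10.0):
    return NormalizationRanges({(ch, f): (lo, hi) for ch in CHANNELS for f in FEATURE_NAMES})


def flat_fv(value=5.0, duration=5.0):
    cf = ChannelFeatures(duration=duration, mean=value, peak_high=value,
                         peak_low=value, rise_to_peak=0.0)
    return FeatureVector(channels={ch: cf for ch in CHANNELS})


def weight_table(rows, **kw):
    sensor = {}
    for adl, w in rows.items():
        sensor[adl] = {ch: {f: w.get((ch, f), 0.0) for f in FEATURE_NAMES} for ch in CHANNELS}
    return WeightTable(sensor=sensor, **kw)


class TestNormalize:
    def test_endpoints_midpoint_and_clamping(self):
        ranges = uniform_ranges(0, 10)
        assert normalize(flat_fv(0.0, duration=0.0), ranges)[T]["mean"] == 0.0
        assert normalize(flat_fv(5.0), ranges)[T]["mean"] == 0.5
        assert normalize(flat_fv(25.0), ranges)[T]["peak_high"] == 1.0
        assert normalize(flat_fv(-3.0), ranges)[H]["peak_low"] == 0.0

    def test_missing_range_entry_names_the_pair(self):
        ranges = NormalizationRanges({(ch, f): (0.0, 10.0)
                                      for ch in CHANNELS for f in FEATURE_NAMES
                                      if not (ch is H and f == "mean")})
        with pytest.raises(ConfigurationError, match="humidity.mean"):
            normalize(flat_fv(), ranges)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            NormalizationRanges({(T, "mean"): (5.0, 5.0)})


class TestScore:
    def test_all_zero_weights_score_zero(self):
        table = weight_table({"a": {}})
        assert score(normalize(flat_fv(), uniform_ranges()), table, "a") == 0.0

    def test_single_weight_single_term(self):
        table = weight_table({"a": {(H, "mean"): 1.0}})
        nfv = normalize(flat_fv(9.0), uniform_ranges())
        assert score(nfv, table, "a") == pytest.approx(0.9)

    def test_unknown_adl_is_configuration_error(self):
        table = weight_table({"a": {}})
        with pytest.raises(ConfigurationError):
            score(normalize(flat_fv(), uniform_ranges()), table, "b")

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_equals_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        adls = ["a", "b"]
        sensor = {
            adl: {ch: {f: float(rng.uniform(0, 2)) for f in FEATURE_NAMES} for ch in CHANNELS}
            for adl in adls
        }
        table = WeightTable(sensor=sensor)
        nfv = {ch: {f: float(rng.uniform(0, 1)) for f in FEATURE_NAMES} for ch in CHANNELS}
        for adl in adls:
            expected = 0.0
            for ch in CHANNELS:
                for f in FEATURE_NAMES:
                    expected += sensor[adl][ch][f] * nfv[ch][f]
            assert score(nfv, table, adl) == pytest.approx(expected, rel=1e-12)


def catalog(*names):
    return [ADLDefinition(n, "kitchen", (10, 20)) for n in names]


class TestEstimate:
    def test_single_adl_catalog_always_wins(self):
        table = weight_table({"only": {}})
        card = estimate(flat_fv(), None, table, uniform_ranges(), catalog("only"))
        assert card.winner == "only"

    def test_empty_catalog_is_configuration_error(self):
        table = weight_table({"a": {}})
        with pytest.raises(ConfigurationError):
            estimate(flat_fv(), None, table, uniform_ranges(), [])

    def test_device_weight_breaks_raw_tie(self):
        # both ADLs raw-score 0.5; device weights 1.2 vs 0.8
        rows = {"a": {(T, "mean"): 1.0}, "b": {(T, "mean"): 1.0}}
        ev = TriggeringEvent(0.0, DeviceKind.CURRENT_TAG, {"appliance": "microwave", "state": "on"})
        table = weight_table(rows, device={"a": {"current_tag:microwave": 1.2},
                                           "b": {"current_tag:microwave": 0.8}})
        card = estimate(flat_fv(), ev, table, uniform_ranges(), catalog("a", "b"))
        assert card.raw["a"] == pytest.approx(card.raw["b"]) == pytest.approx(0.5)
        assert card.final["a"] == pytest.approx(0.6)
        assert card.final["b"] == pytest.approx(0.4)
        assert card.winner == "a" and not card.tie

    def test_additive_device_mode(self):
        rows = {"a": {(T, "mean"): 1.0}, "b": {(T, "mean"): 1.0}}
        ev = TriggeringEvent(0.0, DeviceKind.IR_DIRECTION, {"direction": "in"})
        table = weight_table(rows, device={"b": {"ir_direction": 1.3}}, device_mode="additive")
        card = estimate(flat_fv(), ev, table, uniform_ranges(), catalog("a", "b"))
        assert card.final["b"] == pytest.approx(0.5 + 0.3)
        assert card.winner == "b"

    def test_exact_tie_sets_flag_and_breaks_lexicographically(self):
        rows = {"zeta": {(T, "mean"): 1.0}, "alpha": {(T, "mean"): 1.0}}
        card = estimate(flat_fv(), None, weight_table(rows), uniform_ranges(),
                        catalog("zeta", "alpha"))
        assert card.tie and card.winner == "alpha" and card.margin == 0.0

    def test_winner_invariant_under_catalog_permutation(self):
        rows = {"a": {(T, "mean"): 1.0}, "b": {(H, "mean"): 0.7}}
        table = weight_table(rows)
        fwd = estimate(flat_fv(8.0), None, table, uniform_ranges(), catalog("a", "b"))
        rev = estimate(flat_fv(8.0), None, table, uniform_ranges(), catalog("b", "a"))
        assert fwd.winner == rev.winner

    def test_score_floor_reports_unknown(self):
        table = weight_table({"a": {(T, "mean"): 1.0}}, score_floor=0.9)
        card = estimate(flat_fv(2.0), None, table, uniform_ranges(), catalog("a"))
        assert card.winner == "unknown"

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_equals_brute_force_enumeration(self, seed):
        """estimate == argmax of independently computed sum(w*f)*d."""
        rng = np.random.default_rng(seed)
        names = ["a", "b", "c"]
        sensor = {
            adl: {ch: {f: float(rng.uniform(0, 1)) for f in FEATURE_NAMES} for ch in CHANNELS}
            for adl in names
        }
        device = {adl: {"ir_direction": float(rng.uniform(0.5, 1.5))} for adl in names}
        table = WeightTable(sensor=sensor, device=device)
        vals = {ch: {f: float(rng.uniform(0, 10)) for f in FEATURE_NAMES} for ch in CHANNELS}
        fv = FeatureVector(channels={
            ch: ChannelFeatures(
                duration=vals[ch]["duration"],
                mean=vals[ch]["mean"],
                peak_high=max(vals[ch].values()) + 1,
                peak_low=-1.0,
                rise_to_peak=0.0,
            )
            for ch in CHANNELS
        })
        ranges = uniform_ranges(0, 12)
        ev = TriggeringEvent(0.0, DeviceKind.IR_DIRECTION, {"direction": "in"})
        card = estimate(fv, ev, table, ranges, catalog(*names))
        # independent brute force straight from first principles
        expected = {}
        for adl in names:
            total = 0.0
            for ch in CHANNELS:
                cf = fv[ch]
                for f in FEATURE_NAMES:
                    x = (getattr(cf, f) - 0.0) / 12.0
                    x = min(1.0, max(0.0, x))
                    total += sensor[adl][ch][f] * x
            expected[adl] = total * device[adl]["ir_direction"]
        best = sorted(expected.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        assert card.winner == best
        for adl in names:
            assert card.final[adl] == pytest.approx(expected[adl], rel=1e-12)

    def test_scaling_a_weight_row_up_never_lowers_its_rank(self):
        rng = np.random.default_rng(4)
        sensor = {
            adl: {ch: {f: float(rng.uniform(0, 1)) for f in FEATURE_NAMES} for ch in CHANNELS}
            for adl in ("a", "b")
        }
        ranges = uniform_ranges()
        fv = flat_fv(6.0)
        base = estimate(fv, None, WeightTable(sensor=sensor), ranges, catalog("a", "b"))
        boosted_sensor = {
            "a": {ch: {f: 3.0 * w for f, w in feats.items()} for ch, feats in sensor["a"].items()},
            "b": sensor["b"],
        }
        boosted = estimate(fv, None, WeightTable(sensor=boosted_sensor), ranges, catalog("a", "b"))
        rank = lambda card: sorted(card.final, key=lambda k: (-card.final[k], k)).index("a")
        assert rank(boosted) <= rank(base)


class TestDefaultCalibration:
    def test_every_catalogued_adl_has_a_complete_unit_norm_row(self, weight_table):
        for adl, per_ch in weight_table.sensor.items():
            flat = [per_ch[ch][f] for ch in CHANNELS for f in FEATURE_NAMES]
            assert all(w >= 0 for w in flat)
            assert np.linalg.norm(flat) == pytest.approx(1.0, rel=1e-9)
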