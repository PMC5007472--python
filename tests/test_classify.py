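"""Channel calls, lysis detection, the fate state machine and polarity."""

import numpy as np
import pytest

from vitrace.classify import (
    CellState,
    ChannelCall,
    FateCall,
    FateLabel,
    Thresholds,
    call_cal_level,
    call_channel,
    classify_fate,
    classify_polarity,
    detect_lysis,
)
from vitrace.kinetics import Channel, KineticParams, uptake_curve

TH = Thresholds()


def _plateau_series(basal=0.0, plateau=1100.0, onset=20, n=60, k=0.08, dt=8.0):
    t = np.arange(n) * dt
    return basal + uptake_curve(t, KineticParams(A=plateau, t0=onset * dt, k_in=k))


class TestCallChannel:
    def test_steady_rise_to_plateau_positive(self):
        # basal 100, rise to a 1200 plateau: onset at the first sustained
        # frame above the rise threshold
        x = _plateau_series(basal=100.0, plateau=1100.0, onset=20)
        call = call_channel(x, TH)
        assert call.positive
        assert call.evidence in ("jump", "sustained_rise")
        assert call.onset_frame == 21  # first frame above basal after t0
        assert call.equilibrium_value == pytest.approx(1200.0, rel=0.05)

    def test_constant_series_negative(self):
        for level in (0.0, 90.0):
            call = call_channel(np.full(30, level), TH)
            assert not call.positive
            assert call.status(29) == "neg"

    def test_single_frame_step_is_a_jump(self):
        x = np.array([100.0, 102.0, 99.0, 101.0, 900.0] + [900.0] * 10)
        call = call_channel(x, TH)
        assert call.onset_frame == 4
        assert call.evidence == "jump"
        assert call.status(3) == "neg" and call.status(4) == "pos"

    def test_already_stained_at_start(self):
        x = np.full(30, 1200.0) + np.linspace(0, -30, 30)  # slow bleach-ish
        call = call_channel(x, TH)
        assert call.onset_frame == 0
        assert call.evidence == "initial"

    def test_slow_sustained_rise_without_jump(self):
        # per-frame increments < 50 AU, but sustained + trending + plateau
        x = _plateau_series(basal=0.0, plateau=400.0, onset=10, k=0.012)
        call = call_channel(x, TH)
        assert call.positive
        assert call.evidence == "sustained_rise"

    def test_rel_rise_monotonicity(self):
        x = _plateau_series(basal=200.0, plateau=60.0, onset=15, k=0.02, n=80)
        onsets = []
        for r in (0.03, 0.1, 0.25):
            th = Thresholds(rel_rise=r)
            onsets.append(call_channel(x, th).onset_frame)
        # raising rel_rise can only delay or remove the onset
        prev = -1
        for o in onsets:
            if o is None:
                prev = np.inf
                continue
            assert o >= prev or prev == -1
            prev = o


class TestCalLevel:
    def test_identical_cells_none_high(self):
        cell = np.full(30, 200.0)
        ref = np.full(100, 200.0)
        assert call_cal_level(cell, ref, TH, noise_sd=5.0) == "pos"

    def test_ratio_arithmetic(self):
        # reference median 200, cell mean 500: ratio 2.5 >= 2.0 -> high
        assert call_cal_level(np.full(30, 500.0), np.full(50, 200.0), TH, 5.0) == "high"

    def test_background_cell_neg(self):
        assert call_cal_level(np.zeros(30), np.full(50, 200.0), TH, 5.0) == "neg"

    def test_empty_reference_falls_back_with_warning(self):
        warn = []
        lvl = call_cal_level(np.full(30, 500.0), [], TH, 5.0, warn=warn)
        assert lvl == "high" and warn


class TestDetectLysis:
    def test_rise_then_collapse(self):
        pi = np.concatenate([_plateau_series(0, 1200, 10, 40), np.zeros(10)])
        cal = np.concatenate([np.full(40, 200.0), np.zeros(10)])
        f = detect_lysis({Channel.PI: pi, Channel.CAL: cal}, {Channel.PI: 5.0, Channel.CAL: 5.0}, TH)
        assert f == 40

    def test_never_stained_is_not_lysis(self):
        rng = np.random.default_rng(0)
        x = 5.0 * rng.standard_normal(60)
        assert detect_lysis({Channel.PI: x}, {Channel.PI: 5.0}, TH) is None

    def test_cal_loss_with_pi_high_is_not_lysis(self):
        pi = _plateau_series(0, 1200, 10, 50)
        cal = np.concatenate([np.full(30, 200.0), np.zeros(20)])
        assert detect_lysis({Channel.PI: pi, Channel.CAL: cal},
                            {Channel.PI: 5.0, Channel.CAL: 5.0}, TH) is None

    def test_gradual_decay_is_not_lysis(self):
        # slow first-order loss (recovery-like) fails the abruptness guard
        x = np.concatenate([
            _plateau_series(0, 600, 5, 25),
            600.0 * np.exp(-0.08 * 8.0 * np.arange(1, 26)),
        ])
        assert detect_lysis({Channel.POPRO: x}, {Channel.POPRO: 5.0}, TH) is None


def _call(channel, onset, basal=0.0):
    return ChannelCall(channel=channel, onset_frame=onset, basal=basal, noise_sd=5.0)


class TestClassifyFate:
    def test_simultaneous_onsets_necrotic(self):
        calls = {Channel.PI: _call(Channel.PI, 10), Channel.POPRO: _call(Channel.POPRO, 10)}
        fc = classify_fate(calls, growth_rate=0.0, lineage_events=[], thresholds=TH)
        assert fc.final_label is FateLabel.NECROTIC_LIKE

    def test_staged_onsets_apoptotic(self):
        calls = {Channel.PI: _call(Channel.PI, 14), Channel.POPRO: _call(Channel.POPRO, 8)}
        fc = classify_fate(calls, growth_rate=0.0, lineage_events=[], thresholds=TH)
        assert fc.final_label is FateLabel.APOPTOTIC_LIKE
        assert [s for _, s in fc.state_sequence] == [
            CellState.ALIVE, CellState.MORIBUND, CellState.DEAD,
        ]

    def test_pi_without_popro_channel_is_dead(self):
        calls = {Channel.PI: _call(Channel.PI, 20), Channel.CAL: _call(Channel.CAL, None)}
        fc = classify_fate(calls, growth_rate=0.0, lineage_events=[], thresholds=TH)
        assert fc.final_label is FateLabel.DEAD

    def test_growing_when_nothing_positive(self):
        calls = {Channel.PI: _call(Channel.PI, None)}
        fc = classify_fate(calls, growth_rate=0.012, lineage_events=[], thresholds=TH,
                           reference_rate=0.0115)
        assert fc.final_label is FateLabel.GROWING

    def test_dead_then_lysed_precedence(self):
        # PI+ at frame 20, everything at background from frame 26
        calls = {Channel.PI: _call(Channel.PI, 20)}
        fc = classify_fate(calls, growth_rate=0.0, lineage_events=[], thresholds=TH,
                           lysis_frame=26)
        assert fc.final_label is FateLabel.DEAD_THEN_LYSED
        assert fc.state_at(19) is CellState.ALIVE
        assert fc.state_at(22) is CellState.DEAD
        assert fc.state_at(30) is CellState.LYSED

    def test_lysis_without_pi_is_direct(self):
        calls = {Channel.CAL: _call(Channel.CAL, 0)}
        fc = classify_fate(calls, growth_rate=0.0, lineage_events=[], thresholds=TH,
                           lysis_frame=30)
        assert fc.final_label is FateLabel.LYSED_DIRECT

    def test_resuscitation_needs_drop_and_division(self):
        n = 60
        popro = np.zeros(n)
        popro[15:] = 600.0
        popro[30:] = 600.0 * np.exp(-0.06 * 8.0 * np.arange(1, n - 29))
        calls = {Channel.PI: _call(Channel.PI, None), Channel.POPRO: _call(Channel.POPRO, 15)}
        with_div = classify_fate(calls, 0.01, [45], TH, series={Channel.POPRO: popro})
        without_div = classify_fate(calls, 0.01, [], TH, series={Channel.POPRO: popro})
        assert with_div.final_label is FateLabel.RESUSCITATED
        assert with_div.recovery_frame is not None
        assert without_div.final_label is not FateLabel.RESUSCITATED

    def test_tolerant_vs_arrested_by_cal_level(self):
        cal_high = np.full(40, 500.0)
        cal_mod = np.full(40, 200.0)
        ref = np.full(60, 200.0)
        base = {Channel.PI: _call(Channel.PI, None)}
        for series, expected in ((cal_high, FateLabel.TOLERANT),
                                 (cal_mod, FateLabel.ARRESTED_VIABLE)):
            calls = dict(base, CAL=_call(Channel.CAL, 0))
            calls = {Channel.PI: base[Channel.PI], Channel.CAL: _call(Channel.CAL, 0)}
            fc = classify_fate(calls, growth_rate=0.0, lineage_events=[], thresholds=TH,
                               series={Channel.CAL: series}, cal_reference_values=ref)
            assert fc.final_label is expected

    def test_apoptotic_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            FateCall(
                final_label=FateLabel.APOPTOTIC_LIKE,
                state_sequence=[(0, CellState.ALIVE)],
                onset_pi=5,
                onset_popro=9,
            )

    def test_state_sequence_transition_graph(self):
        with pytest.raises(ValueError):
            FateCall(
                final_label=FateLabel.GROWING,
                state_sequence=[(0, CellState.DEAD), (5, CellState.ALIVE)],
            )


class TestPolarity:
    def _fc(self, label):
        return FateCall(final_label=label, state_sequence=[(0, CellState.ALIVE)])

    def test_dead_vs_tolerant_segmented(self):
        assert classify_polarity(self._fc(FateLabel.DEAD), self._fc(FateLabel.TOLERANT)) == "segmented"

    def test_both_growing_uniform(self):
        assert classify_polarity(self._fc(FateLabel.GROWING), self._fc(FateLabel.GROWING)) == "uniform"

    def test_two_dead_class_poles_uniform(self):
        assert (
            classify_polarity(self._fc(FateLabel.DEAD), self._fc(FateLabel.DEAD_THEN_LYSED))
            == "uniform"
        )
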