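"""Simulator: presets, generative identities, determinism, lineage/dilution,
causality and the spontaneous-death hazard."""

import math

import numpy as np
import pytest

from vitrace.io import traces_to_frame
from vitrace.kinetics import BleachModel, Channel, KineticParams, uptake_curve
from vitrace.simulate import (
    AcquisitionConfig,
    ChannelProfile,
    FateLabel,
    FateProgram,
    PopulationConfig,
    _simulate_cell,
    make_program,
    preset_acquisition,
    simulate_population,
    simulate_trace,
)


class TestPresets:
    @pytest.mark.parametrize(
        "species,interval",
        [
            ("C. glutamicum", 8.0),
            ("E. coli", 5.0),
            ("B. subtilis", 5.0),
            ("V. harveyi", 5.0),
            ("S. cerevisiae", 30.0),
            ("M. luteus", 60.0),
        ],
    )
    def test_frame_intervals(self, species, interval):
        assert preset_acquisition(species).frame_interval_min == interval

    def test_unknown_species(self):
        with pytest.raises(KeyError):
            preset_acquisition("H. sapiens")


class TestGenerativeIdentity:
    def test_dead_trace_is_exact_uptake_curve(self):
        # zero noise, b=1: the PI series IS the closed-form curve
        acq = AcquisitionConfig.clean(frame_interval_min=8.0, n_frames=60)
        pi = KineticParams(A=1200.0, t0=160.0, k_in=0.08)
        prog = FateProgram(
            label=FateLabel.DEAD,
            kinetics={Channel.PI: ChannelProfile(rise=pi)},
            t_arrest=80.0,
            t_pi=160.0,
        )
        tr = simulate_trace(prog, acq, seed=0)
        expected = uptake_curve(tr.times_min, KineticParams(A=1200.0, t0=160.0, k_in=0.08,
                                                            B=acq.background_mean))
        np.testing.assert_allclose(tr.values[Channel.PI], expected, rtol=1e-12)

    def test_causality_exact_background_before_onset(self):
        acq = AcquisitionConfig.clean(8.0, 50)
        prog = make_program(FateLabel.NECROTIC_LIKE, acq, np.random.default_rng(3))
        tr = simulate_trace(prog, acq, seed=0)
        onset_frame = int(math.ceil(prog.t_pi / acq.frame_interval_min))
        for ch in (Channel.PI, Channel.POPRO):
            assert np.all(tr.values[ch][:onset_frame] == acq.background_mean)

    def test_lysed_trace_collapses_to_background(self):
        acq = AcquisitionConfig.clean(8.0, 60)
        prog = make_program(FateLabel.LYSED_DIRECT, acq, np.random.default_rng(5))
        tr = simulate_trace(prog, acq, seed=0)
        f_lys = int(prog.t_lysis / acq.frame_interval_min)
        tail = tr.values[Channel.CAL][f_lys + 5 :]
        assert np.all(tail <= acq.background_mean + 25.0)
        assert tail[-1] == pytest.approx(acq.background_mean, abs=1.0)

    def test_bleached_plateau_decays_geometrically(self):
        acq = AcquisitionConfig(
            frame_interval_min=8.0,
            n_frames=80,
            bleach={ch: BleachModel(0.998) for ch in Channel},
            noise_sd_add=0.0,
            noise_cv_mult=0.0,
            background_mean=0.0,
            size_noise_cv=0.0,
        )
        prog = FateProgram(
            label=FateLabel.DEAD,
            kinetics={Channel.PI: ChannelProfile(rise=KineticParams(A=1000.0, t0=0.0, k_in=5.0))},
            t_pi=0.0,
        )
        tr = simulate_trace(prog, acq, seed=0)
        v = tr.values[Channel.PI][40:]
        ratios = v[1:] / v[:-1]
        np.testing.assert_allclose(ratios, 0.998, rtol=1e-9)


class TestDeterminism:
    def test_same_seed_same_trace(self):
        acq = AcquisitionConfig(frame_interval_min=8.0, n_frames=40)
        prog = make_program(FateLabel.APOPTOTIC_LIKE, acq, np.random.default_rng(11))
        a = simulate_trace(prog, acq, seed=42)
        b = simulate_trace(prog, acq, seed=42)
        for ch in a.values:
            np.testing.assert_array_equal(a.values[ch], b.values[ch])
        np.testing.assert_array_equal(a.size, b.size)

    def test_population_bit_identical(self):
        pop = PopulationConfig(
            n_cells=20,
            composition={FateLabel.GROWING: 0.5, FateLabel.DEAD: 0.5},
        )
        acq = AcquisitionConfig(frame_interval_min=8.0, n_frames=50)
        t1, g1 = simulate_population(pop, acq, 9)
        t2, g2 = simulate_population(pop, acq, 9)
        assert traces_to_frame(t1).equals(traces_to_frame(t2))
        assert g1.cell_labels == g2.cell_labels


class TestPopulation:
    def test_all_growing_no_hazard_never_stains(self):
        pop = PopulationConfig(n_cells=10, composition={FateLabel.GROWING: 1.0})
        acq = AcquisitionConfig.clean(8.0, 60)
        traces, truth = simulate_population(pop, acq, 2)
        assert all(l is FateLabel.GROWING for l in truth.cell_labels.values())
        for tr in traces:
            assert np.all(tr.values[Channel.PI] == acq.background_mean)

    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PopulationConfig(n_cells=10, composition={FateLabel.GROWING: 0.7})

    def test_spontaneous_hazard_binomial_oracle(self):
        # p=0.001/frame, 200 ancestors, 100 frames, no division:
        # expected ever-dead fraction 1-(1-p)^99 ~ 9.4%, within 3 binomial SE
        p = 0.001
        pop = PopulationConfig(
            n_cells=200,
            composition={FateLabel.GROWING: 1.0},
            spontaneous_death_hazard=p,
            max_lineage_cells=1,
        )
        acq = AcquisitionConfig(frame_interval_min=8.0, n_frames=100)
        _, truth = simulate_population(pop, acq, 5)
        frac = np.mean([l is not FateLabel.GROWING for l in truth.cell_labels.values()])
        expect = 1.0 - (1.0 - p) ** 99
        se = math.sqrt(expect * (1 - expect) / 200)
        assert abs(frac - expect) <= 3 * se

    def test_every_label_represented(self, small_benchmark):
        labels = set(small_benchmark.truth.cell_labels.values())
        assert labels == set(FateLabel)

    def test_onset_ordering_against_truth(self, small_benchmark):
        # generative invariant: apoptotic programs stage PO-PRO-1 strictly
        # before PI; necrotic programs fire both on the same frame
        for key, prog in small_benchmark.truth.programs.items():
            if prog.label is FateLabel.APOPTOTIC_LIKE:
                assert prog.t_popro < prog.t_pi
            if prog.label is FateLabel.NECROTIC_LIKE and prog.t_popro is not None:
                assert abs(prog.t_popro - prog.t_pi) <= 8.0  # one frame


class TestDivisionDilution:
    def _mother_with_division(self, partition):
        acq = AcquisitionConfig.clean(8.0, 40)
        # fast-saturating uptake: influx ~0 at the division frame, so the
        # split is the only change there
        prog = FateProgram(
            label=FateLabel.GROWING,
            kinetics={Channel.POPRO: ChannelProfile(rise=KineticParams(A=600.0, t0=0.0, k_in=0.5))},
            division_times=[160.0],
            partition=partition,
            growth_rate=math.log(2) / 60.0,
        )
        rng = np.random.default_rng(0)
        return _simulate_cell(prog, acq, rng, "m", None, "whole", 0, None, 1.0, [20]), acq

    def test_conservation_at_division(self):
        (tr, spawns), acq = self._mother_with_division(0.5)
        f, content, _ = spawns[0]
        bg = acq.background_mean
        pre = tr.values[Channel.POPRO][f - 1] - bg
        post = tr.values[Channel.POPRO][f] - bg
        assert post + content[Channel.POPRO] == pytest.approx(pre, abs=1e-9)

    @pytest.mark.parametrize("partition", [0.3, 0.5])
    def test_partition_fraction(self, partition):
        (tr, spawns), acq = self._mother_with_division(partition)
        f, content, _ = spawns[0]
        pre = tr.values[Channel.POPRO][f - 1] - acq.background_mean
        assert content[Channel.POPRO] == pytest.approx(partition * pre, abs=1e-9)

    def test_geometric_dilution_across_generations(self):
        # partition 0.5 on a non-replenished dye: inherited content halves
        (tr, spawns), acq = self._mother_with_division(0.5)
        _, content, _ = spawns[0]
        mother_level = 600.0
        assert content[Channel.POPRO] == pytest.approx(mother_level / 2, rel=1e-6)


class TestProgramInvariants:
    def test_apoptotic_needs_staged_onsets(self):
        with pytest.raises(ValueError):
            FateProgram(
                label=FateLabel.APOPTOTIC_LIKE,
                kinetics={},
                t_popro=100.0,
                t_pi=50.0,
            )

    def test_dead_then_lysed_ordering(self):
        with pytest.raises(ValueError):
            FateProgram(
                label=FateLabel.DEAD_THEN_LYSED,
                kinetics={},
                t_pi=100.0,
                t_lysis=90.0,
            )

    def test_resuscitated_needs_division_after_recovery(self):
        with pytest.raises(ValueError):
            FateProgram(
                label=FateLabel.RESUSCITATED,
                kinetics={},
                t_popro=50.0,
                t_recover=100.0,
                division_times=[80.0],
            )
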