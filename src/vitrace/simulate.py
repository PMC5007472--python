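"""Seeded generator of lineage-resolved synthetic fluorescence trace sets.

The generator emulates what a perfused microfluidic viability experiment
records: per-cell mean fluorescence in up to three channels (PI, calcein,
PO-PRO-1) at fixed frame intervals, plus a cell-size proxy, under defined
cell-fate programs. Each program fixes the event times (growth arrest, dye
onsets, lysis, recovery, divisions) and the kinetic parameters of the
channel curves; the generator then plays the program forward frame by frame:

* dye content follows the closed-form kinetic curves (first-order uptake to a
  plateau drawn from the 1000-1500 AU range for PI, optional slow Bateman-like
  decline, fast first-order collapse of all channels after lysis);
* each imaging exposure retains a per-channel fraction ``b`` of the current
  pool (photobleaching; default cumulative loss drawn from 1-3% across the
  movie);
* divisions split dye content between mother and daughter according to the
  partition fraction (dye dilution across generations) and halve the size;
* observed values add a constant background plus additive (read) and
  multiplicative (illumination) Gaussian noise.

Everything is driven by a single integer seed through per-cell
``numpy.random.SeedSequence`` children, so identical configurations produce
bit-identical trace tables.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .kinetics import BleachModel, Channel, KineticParams, bateman_curve, uptake_curve

__all__ = [
    "FateLabel",
    "ChannelProfile",
    "FateProgram",
    "AcquisitionConfig",
    "PopulationConfig",
    "CellTrace",
    "GroundTruth",
    "SPECIES_FRAME_INTERVAL",
    "preset_acquisition",
    "make_program",
    "simulate_trace",
    "simulate_population",
    "pezt_population",
    "LIVE_LABELS",
    "PI_POSITIVE_LABELS",
]


class FateLabel(str, Enum):
    GROWING = "GROWING"
    ARRESTED_VIABLE = "ARRESTED_VIABLE"
    TOLERANT = "TOLERANT"
    DEAD = "DEAD"
    LYSED_DIRECT = "LYSED_DIRECT"
    DEAD_THEN_LYSED = "DEAD_THEN_LYSED"
    SEGMENTED_BIPOLAR = "SEGMENTED_BIPOLAR"
    NECROTIC_LIKE = "NECROTIC_LIKE"
    APOPTOTIC_LIKE = "APOPTOTIC_LIKE"
    RESUSCITATED = "RESUSCITATED"


#: labels whose cells count as alive for their whole trace (transient states
#: are handled per frame by the classifier's state sequences)
LIVE_LABELS = frozenset(
    {FateLabel.GROWING, FateLabel.ARRESTED_VIABLE, FateLabel.TOLERANT, FateLabel.RESUSCITATED}
)
#: labels whose terminal state is PI-positive
PI_POSITIVE_LABELS = frozenset(
    {FateLabel.DEAD, FateLabel.NECROTIC_LIKE, FateLabel.APOPTOTIC_LIKE}
)

# frame-interval presets, minutes (species as imaged in the source experiments)
SPECIES_FRAME_INTERVAL: dict[str, float] = {
    "C. glutamicum": 8.0,
    "E. coli": 5.0,
    "B. subtilis": 5.0,
    "V. harveyi": 5.0,
    "S. cerevisiae": 30.0,
    "M. luteus": 60.0,
}


@dataclass(frozen=True)
class ChannelProfile:
    """Noiseless dye-content profile for one channel (background excluded).

    ``rise`` is the primary uptake (uptake_curve, or bateman_curve when
    ``bateman`` is set and rise.k_out > 0). ``rise2`` adds a second uptake
    (e.g. the elevated calcein accumulation of tolerant cells after arrest).
    From ``decay_t0`` onward the accumulated content decays first-order with
    rate ``decay_k`` (ghost-cell collapse, post-recovery PO-PRO-1 loss).
    """

    rise: KineticParams | None = None
    rise2: KineticParams | None = None
    decay_t0: float | None = None
    decay_k: float = 0.0
    bateman: bool = False

    def content(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        c = np.zeros_like(t)
        if self.rise is not None:
            curve = bateman_curve if self.bateman else uptake_curve
            c = c + curve(t, self.rise)
        if self.rise2 is not None:
            c = c + uptake_curve(t, self.rise2)
        if self.decay_t0 is not None:
            t0 = float(self.decay_t0)
            c0 = float(self.content_at(t0)) if self.rise is not None or self.rise2 is not None else 0.0
            after = t >= t0
            c = np.where(after, c0 * np.exp(-self.decay_k * (t - t0)), c)
        return c

    def content_at(self, t: float) -> float:
        # pre-decay content at a single time
        c = 0.0
        if self.rise is not None:
            curve = bateman_curve if self.bateman else uptake_curve
            c += float(curve(np.array([t]), self.rise)[0])
        if self.rise2 is not None:
            c += float(uptake_curve(np.array([t]), self.rise2)[0])
        return c


@dataclass
class FateProgram:
    """Generative ground truth for one cell (or cell pole).

    Event times are absolute minutes on the acquisition clock; ``None`` means
    the event never happens. ``division_times`` are the minutes at which the
    cell divides (snapped to frames by the engine). ``partition`` is the dye
    fraction handed to the daughter at each division.
    """

    label: FateLabel
    kinetics: dict[Channel, ChannelProfile]
    t_arrest: float | None = None
    t_popro: float | None = None
    t_pi: float | None = None
    t_lysis: float | None = None
    t_recover: float | None = None
    division_times: list[float] = field(default_factory=list)
    partition: float = 0.5
    growth_rate: float = 0.0  # 1/min size growth while growing
    birth_time: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.partition <= 1.0):
            raise ValueError("partition must lie in [0, 1]")
        if self.label is FateLabel.APOPTOTIC_LIKE:
            if self.t_popro is None or self.t_pi is None or self.t_popro > self.t_pi:
                raise ValueError("apoptotic-like programs need t_popro <= t_pi")
        if self.label is FateLabel.DEAD_THEN_LYSED:
            if self.t_pi is None or self.t_lysis is None or self.t_lysis <= self.t_pi:
                raise ValueError("dead-then-lysed programs need t_lysis > t_pi")
        if self.label is FateLabel.RESUSCITATED:
            if self.t_popro is None or self.t_recover is None or self.t_recover <= self.t_popro:
                raise ValueError("resuscitated programs need t_recover > t_popro")
            if not any(d > self.t_recover for d in self.division_times):
                raise ValueError("resuscitated programs need a division after t_recover")

    def growth_active(self, t: float) -> bool:
        """Whether the cell is elongating at time t (arrest/death halt growth;
        resuscitated cells resume after recovery)."""
        stops = [x for x in (self.t_arrest, self.t_popro, self.t_pi, self.t_lysis) if x is not None]
        t_stop = min(stops) if stops else math.inf
        if t < t_stop:
            return True
        return self.t_recover is not None and t >= self.t_recover


@dataclass(frozen=True)
class AcquisitionConfig:
    """Imaging settings: grid, per-channel bleaching, noise and background.

    ``bleach=None`` asks the population generator to draw each cell's
    per-channel retention from a 1-3% cumulative loss across the movie.
    """

    frame_interval_min: float
    n_frames: int
    bleach: dict[Channel, BleachModel] | None = None
    noise_sd_add: float = 5.0
    noise_cv_mult: float = 0.02
    background_mean: float = 100.0
    size_noise_cv: float = 0.01

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for name in ("noise_sd_add", "noise_cv_mult", "background_mean", "size_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min

    @classmethod
    def clean(cls, frame_interval_min: float = 8.0, n_frames: int = 120, background_mean: float = 100.0) -> "AcquisitionConfig":
        """Noiseless, bleach-free settings for generative-identity checks."""
        b1 = {ch: BleachModel(1.0) for ch in Channel}
        return cls(
            frame_interval_min=frame_interval_min,
            n_frames=n_frames,
            bleach=b1,
            noise_sd_add=0.0,
            noise_cv_mult=0.0,
            background_mean=background_mean,
            size_noise_cv=0.0,
        )


def preset_acquisition(species: str) -> AcquisitionConfig:
    """Acquisition preset for one of the imaged species (frame interval per paper-grade protocol).

    The movie length default keeps total observation near 16 h.
    """
    if species not in SPECIES_FRAME_INTERVAL:
        raise KeyError(
            f"unknown species {species!r}; known: {sorted(SPECIES_FRAME_INTERVAL)}"
        )
    dt = SPECIES_FRAME_INTERVAL[species]
    n = max(int(round(960.0 / dt)), 16)
    return AcquisitionConfig(frame_interval_min=dt, n_frames=n)


@dataclass
class PopulationConfig:
    """Ancestor population: size, fate composition, spontaneous-death hazard."""

    n_cells: int
    composition: dict[FateLabel, float]
    spontaneous_death_hazard: float = 0.0
    max_lineage_cells: int = 8
    doubling_time_min: float = 60.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        total = sum(self.composition.values())
        if any(v < 0 for v in self.composition.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError("composition proportions must be >= 0 and sum to 1")
        if not (0.0 <= self.spontaneous_death_hazard <= 1.0):
            raise ValueError("spontaneous_death_hazard must lie in [0, 1]")


@dataclass
class CellTrace:
    """One cell's (or pole's) per-frame multi-channel series on the absolute grid."""

    cell_id: str
    parent_id: str | None
    compartment: str  # whole | pole_A | pole_B
    frames: np.ndarray
    times_min: np.ndarray
    values: dict[Channel, np.ndarray]
    size: np.ndarray

    @property
    def birth_frame(self) -> int:
        return int(self.frames[0])

    @property
    def channels(self) -> tuple[Channel, ...]:
        return tuple(self.values.keys())


@dataclass
class GroundTruth:
    """Realized programs per trace plus the final per-cell truth label."""

    programs: dict[tuple[str, str], FateProgram]
    cell_labels: dict[str, FateLabel]
    division_frames: dict[str, list[int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# program construction


def _chol_rates(rng: np.random.Generator, dt: float, lo: float, hi: float) -> float:
    # rates are drawn per frame interval so classifier behaviour is preserved
    # across the 5/8/30/60-min presets
    return rng.uniform(lo, hi) / dt


#: mean calcein plateau of unperturbed growing cells (AU above background)
GROWING_CAL_MEAN = 200.0
#: tolerant cells accumulate calcein to this multiple of the growing mean
TOLERANT_CAL_MULTIPLIER = 2.5


def _cal_profile(rng, dt: float, birth: float, decay_t0: float | None = None,
                 boost_t0: float | None = None) -> ChannelProfile:
    base = KineticParams(
        A=rng.uniform(0.75 * GROWING_CAL_MEAN, 1.25 * GROWING_CAL_MEAN),
        t0=birth,
        k_in=_chol_rates(rng, dt, 0.4, 1.0),
    )
    rise2 = None
    if boost_t0 is not None:
        # reduced-metabolism cells stop effluxing calcein and accumulate it to
        # a markedly elevated level relative to the growing population
        target = TOLERANT_CAL_MULTIPLIER * GROWING_CAL_MEAN * rng.uniform(0.95, 1.15)
        rise2 = KineticParams(
            A=max(target - base.A, 0.5 * GROWING_CAL_MEAN),
            t0=boost_t0,
            k_in=_chol_rates(rng, dt, 0.4, 1.0),
        )
    decay_k = _chol_rates(rng, dt, 2.5, 5.0) if decay_t0 is not None else 0.0
    return ChannelProfile(rise=base, rise2=rise2, decay_t0=decay_t0, decay_k=decay_k)


def _pi_profile(rng, dt: float, t_pi: float, slow_decay: bool = False,
                lysis_t0: float | None = None) -> ChannelProfile:
    k_out = rng.uniform(0.0008, 0.0025) if slow_decay else 0.0
    rise = KineticParams(
        A=rng.uniform(1000.0, 1500.0), t0=t_pi, k_in=_chol_rates(rng, dt, 0.5, 1.2), k_out=k_out
    )
    decay_k = _chol_rates(rng, dt, 2.5, 5.0) if lysis_t0 is not None else 0.0
    return ChannelProfile(rise=rise, decay_t0=lysis_t0, decay_k=decay_k, bateman=slow_decay)


def _popro_profile(rng, dt: float, t_popro: float, recover_t0: float | None = None) -> ChannelProfile:
    rise = KineticParams(
        A=rng.uniform(400.0, 800.0), t0=t_popro, k_in=_chol_rates(rng, dt, 0.5, 1.2)
    )
    decay_k = _chol_rates(rng, dt, 0.4, 0.7) if recover_t0 is not None else 0.0
    return ChannelProfile(rise=rise, decay_t0=recover_t0, decay_k=decay_k)


def _division_schedule(rng, birth: float, horizon: float, doubling: float) -> list[float]:
    times = []
    t = birth + doubling * rng.uniform(0.6, 1.4)
    while t < horizon:
        times.append(t)
        t += doubling * rng.uniform(0.85, 1.15)
    return times


def make_program(
    label: FateLabel,
    acq: AcquisitionConfig,
    rng: np.random.Generator,
    doubling_time_min: float = 60.0,
    birth_time: float = 0.0,
) -> FateProgram:
    """Draw a randomized fate program of the given label on the acquisition grid.

    Event frames are placed so every rule of the downstream classifier is
    decidable within the movie: death onsets in the 20-60% span of the movie,
    lysis at least ~6 frames before the end, recovery early enough to leave
    room for a post-recovery division.
    """
    dt = acq.frame_interval_min
    T = acq.n_frames
    horizon = (T - 1) * dt
    growth = math.log(2.0) / doubling_time_min

    def f2t(f: int) -> float:
        return f * dt

    f_arrest = int(rng.integers(max(3, T // 24), max(5, T // 8) + 1))
    t_arrest = f2t(f_arrest)

    if label is FateLabel.GROWING:
        return FateProgram(
            label=label,
            kinetics={Channel.PI: ChannelProfile(), Channel.CAL: _cal_profile(rng, dt, birth_time)},
            division_times=_division_schedule(rng, birth_time, horizon, doubling_time_min),
            growth_rate=growth,
            birth_time=birth_time,
        )
    if label is FateLabel.ARRESTED_VIABLE:
        return FateProgram(
            label=label,
            kinetics={Channel.PI: ChannelProfile(), Channel.CAL: _cal_profile(rng, dt, birth_time)},
            t_arrest=t_arrest,
            growth_rate=growth,
            birth_time=birth_time,
        )
    if label is FateLabel.TOLERANT:
        return FateProgram(
            label=label,
            kinetics={
                Channel.PI: ChannelProfile(),
                Channel.CAL: _cal_profile(rng, dt, birth_time, boost_t0=t_arrest),
            },
            t_arrest=t_arrest,
            growth_rate=growth,
            birth_time=birth_time,
        )
    if label is FateLabel.DEAD:
        f_pi = int(rng.integers(T // 5, int(0.6 * T)))
        t_pi = f2t(f_pi)
        slow = rng.random() < 0.3  # slow Bateman-like fluorescence/DNA decay
        return FateProgram(
            label=label,
            kinetics={
                Channel.PI: _pi_profile(rng, dt, t_pi, slow_decay=slow),
                Channel.CAL: _cal_profile(rng, dt, birth_time, decay_t0=t_pi),
            },
            t_arrest=min(t_arrest, t_pi),
            t_pi=t_pi,
            growth_rate=growth,
            birth_time=birth_time,
        )
    if label is FateLabel.LYSED_DIRECT:
        f_lys = int(rng.integers(T // 5, int(0.6 * T)))
        t_lys = f2t(f_lys)
        return FateProgram(
            label=label,
            kinetics={
                Channel.PI: ChannelProfile(),
                Channel.CAL: _cal_profile(rng, dt, birth_time, decay_t0=t_lys),
            },
            t_arrest=min(t_arrest, t_lys),
            t_lysis=t_lys,
            growth_rate=growth,
            birth_time=birth_time,
        )
    if label is FateLabel.DEAD_THEN_LYSED:
        f_pi = int(rng.integers(T // 5, int(0.42 * T)))
        f_lys = min(f_pi + int(rng.integers(max(6, T // 15), max(8, T // 5))), T - 6)
        t_pi, t_lys = f2t(f_pi), f2t(f_lys)
        return FateProgram(
            label=label,
            kinetics={
                Channel.PI: _pi_profile(rng, dt, t_pi, lysis_t0=t_lys),
                Channel.CAL: _cal_profile(rng, dt, birth_time, decay_t0=t_pi),
            },
            t_arrest=min(t_arrest, t_pi),
            t_pi=t_pi,
            t_lysis=t_lys,
            growth_rate=growth,
            birth_time=birth_time,
        )
    if label is FateLabel.NECROTIC_LIKE:
        f_ev = int(rng.integers(T // 5, int(0.6 * T)))
        t_ev = f2t(f_ev)
        return FateProgram(
            label=label,
            kinetics={
                Channel.PI: _pi_profile(rng, dt, t_ev),
                Channel.POPRO: _popro_profile(rng, dt, t_ev),
            },
            t_arrest=min(t_arrest, t_ev),
            t_popro=t_ev,
            t_pi=t_ev,
            growth_rate=growth,
            birth_time=birth_time,
        )
    if label is FateLabel.APOPTOTIC_LIKE:
        f_pop = int(rng.integers(T // 6, int(0.42 * T)))
        lag = int(rng.integers(4, 15))
        f_pi = min(f_pop + lag, int(0.65 * T))
        t_pop, t_pi = f2t(f_pop), f2t(f_pi)
        return FateProgram(
            label=label,
            kinetics={
                Channel.PI: _pi_profile(rng, dt, t_pi),
                Channel.POPRO: _popro_profile(rng, dt, t_pop),
            },
            t_arrest=min(t_arrest, t_pop),
            t_popro=t_pop,
            t_pi=t_pi,
            growth_rate=growth,
            birth_time=birth_time,
        )
    if label is FateLabel.RESUSCITATED:
        doubling_frames = doubling_time_min / dt
        f_pop = int(rng.integers(max(4, T // 8), max(6, int(0.3 * T))))
        f_rec = f_pop + int(rng.integers(8, 17))
        f_rec = min(f_rec, T - int(2 * doubling_frames) - 3)
        if f_rec <= f_pop:
            f_rec = f_pop + 4
        t_pop, t_rec = f2t(f_pop), f2t(f_rec)
        divisions = _division_schedule(rng, t_rec + 2 * dt, horizon, doubling_time_min)
        if not divisions:
            divisions = [t_rec + 2 * dt + doubling_time_min]
        return FateProgram(
            label=label,
            kinetics={
                Channel.PI: ChannelProfile(),
                Channel.POPRO: _popro_profile(rng, dt, t_pop, recover_t0=t_rec),
            },
            t_arrest=None,
            t_popro=t_pop,
            t_recover=t_rec,
            division_times=divisions,
            growth_rate=growth,
            birth_time=birth_time,
        )
    raise ValueError(f"no program generator for label {label}")


def spontaneous_death(program: FateProgram, t_death: float, rng: np.random.Generator,
                      dt: float) -> FateProgram:
    """Convert a growing cell to sudden (necrotic-entry) death at ``t_death``.

    The cell keeps its channel set: with a PO-PRO-1 channel the conversion is
    a simultaneous double-onset (necrotic-like); without it the cell is simply
    dead. Divisions after the death time are cancelled.
    """
    kin = dict(program.kinetics)
    kin[Channel.PI] = _pi_profile(rng, dt, t_death)
    if Channel.CAL in kin:
        prof = kin[Channel.CAL]
        kin[Channel.CAL] = replace(prof, decay_t0=t_death, decay_k=_chol_rates(rng, dt, 2.5, 5.0))
    has_popro = Channel.POPRO in kin
    if has_popro:
        kin[Channel.POPRO] = _popro_profile(rng, dt, t_death)
    return FateProgram(
        label=FateLabel.NECROTIC_LIKE if has_popro else FateLabel.DEAD,
        kinetics=kin,
        t_arrest=min(program.t_arrest, t_death) if program.t_arrest is not None else t_death,
        t_popro=t_death if has_popro else None,
        t_pi=t_death,
        division_times=[d for d in program.division_times if d < t_death],
        partition=program.partition,
        growth_rate=program.growth_rate,
        birth_time=program.birth_time,
    )


# ---------------------------------------------------------------------------
# trace engine


def _draw_bleach(acq: AcquisitionConfig, channels, rng: np.random.Generator) -> dict:
    if acq.bleach is not None:
        return {ch: acq.bleach.get(ch, BleachModel(1.0)) for ch in channels}
    return {
        ch: BleachModel.from_cumulative_loss(rng.uniform(0.01, 0.03), acq.n_frames)
        for ch in channels
    }


def _simulate_cell(
    program: FateProgram,
    acq: AcquisitionConfig,
    rng: np.random.Generator,
    cell_id: str,
    parent_id: str | None,
    compartment: str,
    birth_frame: int,
    inherited: dict[Channel, float] | None,
    birth_size: float,
    division_frames: list[int],
):
    """Play one program forward; returns (trace, spawn list).

    spawn list entries are (frame, inherited content dict, daughter birth size).
    """
    dt = acq.frame_interval_min
    frames = np.arange(birth_frame, acq.n_frames)
    times = frames * dt
    n = frames.size
    inherited = inherited or {}
    div_set = {f: i for i, f in enumerate(division_frames)}
    spawns: list[tuple[int, dict[Channel, float], float]] = []
    spawn_content: list[dict[Channel, float]] = [dict() for _ in division_frames]

    bleach = _draw_bleach(acq, program.kinetics.keys(), rng)
    values: dict[Channel, np.ndarray] = {}
    for ch, profile in program.kinetics.items():
        # conversion/uptake influx from the rise components; the programmed
        # decay (ghost-cell collapse, recovery loss) acts multiplicatively on
        # the whole pool, inherited dye included
        c_pre = np.zeros(n)
        if profile.rise is not None:
            curve = bateman_curve if profile.bateman else uptake_curve
            c_pre = c_pre + curve(times, profile.rise)
        if profile.rise2 is not None:
            c_pre = c_pre + uptake_curve(times, profile.rise2)
        in_decay = (
            times > profile.decay_t0 if profile.decay_t0 is not None else np.zeros(n, dtype=bool)
        )
        d = math.exp(-profile.decay_k * dt) if profile.decay_t0 is not None else 1.0
        b = bleach[ch].b
        # ongoing conversion (calcein from its perfused AM ester) refills the
        # pool towards steady state after a division drains it; one-shot dyes
        # (PI, PO-PRO-1 after recovery) are not replenished
        replenish_rate = 0.0
        if ch is Channel.CAL and profile.rise is not None:
            replenish_rate = -math.expm1(-profile.rise.k_in * dt)
        inh = max(inherited.get(ch, 0.0), 0.0)
        # for an efflux-balanced dye, inherited excess relaxes back to the
        # cell's own steady state (negative deficit drains it)
        deficit = -inh if replenish_rate > 0.0 else 0.0
        F = np.empty(n)
        F[0] = inh + c_pre[0]
        for i in range(1, n):
            if in_decay[i]:
                F[i] = b * F[i - 1] * d
            else:
                refill = replenish_rate * deficit
                deficit -= refill
                F[i] = b * F[i - 1] + (c_pre[i] - c_pre[i - 1]) + refill
            if F[i] < 0.0:
                F[i] = 0.0
            f_abs = int(frames[i])
            if f_abs in div_set:
                j = div_set[f_abs]
                lost = program.partition * F[i]
                spawn_content[j][ch] = lost
                F[i] -= lost
                deficit += lost
        values[ch] = F

    # size: exponential while growing, frozen otherwise, halved at divisions
    size = np.empty(n)
    size[0] = birth_size
    daughter_sizes = {}
    for i in range(1, n):
        g = program.growth_rate if program.growth_active(times[i - 1]) else 0.0
        size[i] = size[i - 1] * math.exp(g * dt)
        f_abs = int(frames[i])
        if f_abs in div_set:
            size[i] *= 0.5
            daughter_sizes[div_set[f_abs]] = size[i]

    for j, f in enumerate(division_frames):
        spawns.append((f, spawn_content[j], daughter_sizes.get(j, birth_size * 0.5)))

    # observation: background + content, multiplicative then additive noise
    bg = acq.background_mean
    obs = {}
    for ch, F in values.items():
        v = bg + F
        if acq.noise_cv_mult > 0:
            v = v * (1.0 + acq.noise_cv_mult * rng.standard_normal(n))
        if acq.noise_sd_add > 0:
            v = v + acq.noise_sd_add * rng.standard_normal(n)
        obs[ch] = np.maximum(v, 0.0)
    if acq.size_noise_cv > 0:
        size = size * (1.0 + acq.size_noise_cv * rng.standard_normal(n))
        size = np.maximum(size, 1e-6)

    trace = CellTrace(
        cell_id=cell_id,
        parent_id=parent_id,
        compartment=compartment,
        frames=frames,
        times_min=times,
        values=obs,
        size=size,
    )
    return trace, spawns


def simulate_trace(program: FateProgram, acq: AcquisitionConfig, seed: int) -> CellTrace:
    """Simulate a single cell (no lineage) deterministically from ``seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    dt = acq.frame_interval_min
    div_frames = sorted(
        {
            int(math.ceil(t / dt))
            for t in program.division_times
            if 0 < t / dt < acq.n_frames - 1
        }
    )
    trace, _ = _simulate_cell(
        program, acq, rng, "cell", None, "whole", 0, None, 1.0, div_frames
    )
    return trace


def _allocate_labels(composition: dict[FateLabel, float], n: int) -> list[FateLabel]:
    """Deterministic largest-remainder allocation so every class is represented."""
    items = sorted(composition.items(), key=lambda kv: kv[0].value)
    raw = [(lab, p * n) for lab, p in items if p > 0]
    counts = {lab: int(math.floor(x)) for lab, x in raw}
    rem = n - sum(counts.values())
    for lab, _ in sorted(raw, key=lambda kv: kv[1] - math.floor(kv[1]), reverse=True)[:rem]:
        counts[lab] += 1
    labels: list[FateLabel] = []
    for lab, _ in items:
        labels.extend([lab] * counts.get(lab, 0))
    return labels


def simulate_population(
    pop: PopulationConfig,
    acq: AcquisitionConfig,
    seed: int,
) -> tuple[list[CellTrace], GroundTruth]:
    """Simulate an ancestor population with lineage, ground truth included.

    Ancestors receive labels by largest-remainder allocation of the
    composition (every listed class is represented at its documented
    proportion). Growing and resuscitated cells divide, with dye partition
    applied; the spontaneous-death hazard converts growing cells (ancestors
    and daughters) to sudden death at a geometric random frame. Deterministic
    for a fixed (config, seed).
    """
    dt = acq.frame_interval_min
    labels = _allocate_labels(pop.composition, pop.n_cells)
    master = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xA,)))
    master.shuffle(labels)

    traces: list[CellTrace] = []
    programs: dict[tuple[str, str], FateProgram] = {}
    cell_labels: dict[str, FateLabel] = {}
    division_frames_out: dict[str, list[int]] = {}
    counter = 0

    def next_rng():
        nonlocal counter
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(counter,)))
        counter += 1
        return rng

    def maybe_spontaneous(program: FateProgram, rng, birth_frame: int) -> FateProgram:
        h = pop.spontaneous_death_hazard
        if h <= 0 or program.label is not FateLabel.GROWING:
            return program
        # geometric waiting time: per-frame death probability h
        f_death = birth_frame + 1 + int(rng.geometric(h))
        if f_death >= acq.n_frames - 1:
            return program  # survives the movie
        return spontaneous_death(program, f_death * dt, rng, dt)

    def lineage(ancestor_idx: int, program: FateProgram):
        nonlocal counter
        budget = pop.max_lineage_cells - 1
        anc_id = f"c{ancestor_idx:04d}"
        # event-tree first: approve divisions chronologically across the tree
        cells = {anc_id: {"program": program, "parent": None, "birth_frame": 0, "divs": []}}
        heap: list[tuple[float, int, str, float]] = []
        seq = 0

        def push_divisions(cid: str, prog: FateProgram):
            nonlocal seq
            for t in prog.division_times:
                f = int(math.ceil(t / dt))
                if cells[cid]["birth_frame"] < f < acq.n_frames - 1:
                    heapq.heappush(heap, (t, seq, cid, f))
                    seq += 1

        push_divisions(anc_id, program)
        n_daughters = 0
        while heap and budget > 0:
            t_div, _, cid, f_div = heapq.heappop(heap)
            if f_div in cells[cid]["divs"]:
                continue
            cells[cid]["divs"].append(f_div)
            n_daughters += 1
            did = f"{anc_id}.{n_daughters}"
            drng = next_rng()
            dprog = FateProgram(
                label=FateLabel.GROWING,
                kinetics={
                    ch: (_cal_profile(drng, dt, f_div * dt) if ch is Channel.CAL else ChannelProfile())
                    for ch in cells[cid]["program"].kinetics
                },
                division_times=_division_schedule(
                    drng, f_div * dt, (acq.n_frames - 1) * dt, pop.doubling_time_min
                ),
                partition=program.partition,
                growth_rate=program.growth_rate or math.log(2.0) / pop.doubling_time_min,
                birth_time=f_div * dt,
            )
            dprog = maybe_spontaneous(dprog, drng, f_div)
            cells[did] = {"program": dprog, "parent": cid, "birth_frame": f_div, "divs": [], "rng": drng}
            push_divisions(did, dprog)
            budget -= 1

        # simulate in birth order, mothers before daughters
        order = sorted(cells, key=lambda c: (cells[c]["birth_frame"], c))
        inherited_map: dict[str, tuple[dict, float]] = {}
        for cid in order:
            rec = cells[cid]
            rng = rec.get("rng") or next_rng()
            inh, bsize = inherited_map.get(cid, (None, 1.0))
            trace, spawns = _simulate_cell(
                rec["program"], acq, rng, cid, rec["parent"], "whole",
                rec["birth_frame"], inh, bsize, sorted(rec["divs"]),
            )
            traces.append(trace)
            programs[(cid, "whole")] = rec["program"]
            cell_labels[cid] = rec["program"].label
            division_frames_out[cid] = sorted(rec["divs"])
            # hand content to daughters in division order
            spawn_iter = iter(sorted(spawns, key=lambda s: s[0]))
            for f, content, dsize in spawn_iter:
                for did, drec in cells.items():
                    if drec["parent"] == cid and drec["birth_frame"] == f:
                        inherited_map[did] = (content, dsize)
                        break

    for idx, label in enumerate(labels):
        arng = next_rng()
        if label is FateLabel.SEGMENTED_BIPOLAR:
            cid = f"c{idx:04d}"
            t_arrest = float(arng.integers(max(3, acq.n_frames // 24), max(5, acq.n_frames // 8) + 1)) * dt
            dead = make_program(FateLabel.DEAD, acq, arng, pop.doubling_time_min)
            tol = make_program(FateLabel.TOLERANT, acq, arng, pop.doubling_time_min)
            dead.t_arrest = t_arrest
            tol.t_arrest = t_arrest
            tol.kinetics[Channel.CAL] = replace(
                tol.kinetics[Channel.CAL],
                rise2=replace(tol.kinetics[Channel.CAL].rise2, t0=t_arrest),
            )
            for comp, prog in (("pole_A", dead), ("pole_B", tol)):
                prng = next_rng()
                trace, _ = _simulate_cell(prog, acq, prng, cid, None, comp, 0, None, 0.5, [])
                traces.append(trace)
                programs[(cid, comp)] = prog
            cell_labels[cid] = FateLabel.SEGMENTED_BIPOLAR
            division_frames_out[cid] = []
            continue
        program = make_program(label, acq, arng, pop.doubling_time_min)
        program = maybe_spontaneous(program, arng, 0)
        lineage(idx, program)

    return traces, GroundTruth(
        programs=programs, cell_labels=cell_labels, division_frames=division_frames_out
    )


# ---------------------------------------------------------------------------
# scenario: lytic toxin induction (live-fraction dynamics)


def pezt_population(
    seed: int,
    n_ancestors: int = 24,
    induction_frame: int = 31,
    n_frames: int = 100,
    frame_interval_min: float = 5.0,
    dead_seed_frac: float = 0.05,
    nonlytic_frac: float = 0.014,
    resistant_frac: float = 0.015,
    doubling_time_min: float = 40.0,
    acq: AcquisitionConfig | None = None,
) -> tuple[list[CellTrace], GroundTruth, AcquisitionConfig]:
    """Lytic toxin-induction scenario.

    A few PI-positive seeds are overgrown by dividing cells until toxin
    expression is induced at ``induction_frame``; from then on growth stops
    and cells mass-convert to lysis, except small non-lytic-death and
    non-replicating PI-negative resistant fractions. The live-fraction curve
    of this population rises toward 1 and falls after induction.
    """
    if acq is None:
        acq = AcquisitionConfig(frame_interval_min=frame_interval_min, n_frames=n_frames)
    dt = acq.frame_interval_min
    t_ind = induction_frame * dt
    master = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xB,)))

    traces: list[CellTrace] = []
    programs: dict[tuple[str, str], FateProgram] = {}
    cell_labels: dict[str, FateLabel] = {}
    division_frames_out: dict[str, list[int]] = {}
    counter = [0]

    def next_rng():
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xB0, counter[0])))
        counter[0] += 1
        return rng

    n_dead = max(1, int(round(dead_seed_frac * n_ancestors)))

    def convert(prog: FateProgram, rng: np.random.Generator) -> FateProgram:
        """Post-induction fate of a live cell."""
        u = rng.random()
        kin = dict(prog.kinetics)
        divs = [d for d in prog.division_times if d < t_ind]
        if u < resistant_frac:
            return replace(prog, label=FateLabel.ARRESTED_VIABLE, t_arrest=t_ind,
                           division_times=divs)
        if u < resistant_frac + nonlytic_frac:
            t_pi = t_ind + float(rng.integers(1, 4)) * dt
            kin[Channel.PI] = _pi_profile(rng, dt, t_pi)
            kin[Channel.CAL] = replace(kin[Channel.CAL], decay_t0=t_pi,
                                       decay_k=_chol_rates(rng, dt, 2.5, 5.0))
            return FateProgram(label=FateLabel.DEAD, kinetics=kin, t_arrest=t_ind, t_pi=t_pi,
                               division_times=divs, partition=prog.partition,
                               growth_rate=prog.growth_rate, birth_time=prog.birth_time)
        t_lys = t_ind + float(rng.integers(1, 4)) * dt
        kin[Channel.CAL] = replace(kin[Channel.CAL], decay_t0=t_lys,
                                   decay_k=_chol_rates(rng, dt, 2.5, 5.0))
        return FateProgram(label=FateLabel.LYSED_DIRECT, kinetics=kin, t_arrest=t_ind,
                           t_lysis=t_lys, division_times=divs, partition=prog.partition,
                           growth_rate=prog.growth_rate, birth_time=prog.birth_time)

    growth = math.log(2.0) / doubling_time_min
    for idx in range(n_ancestors):
        rng = next_rng()
        cid = f"p{idx:04d}"
        if idx < n_dead:
            # stained already at seeding (pre-culture death): PI high from frame 0
            prog = FateProgram(
                label=FateLabel.DEAD,
                kinetics={
                    Channel.PI: _pi_profile(rng, dt, -10.0 * dt),
                    Channel.CAL: ChannelProfile(),
                },
                t_arrest=0.0,
                t_pi=0.0,
            )
            trace, _ = _simulate_cell(prog, acq, rng, cid, None, "whole", 0, None, 0.8, [])
            traces.append(trace)
            programs[(cid, "whole")] = prog
            cell_labels[cid] = FateLabel.DEAD
            division_frames_out[cid] = []
            continue
        # grower: divisions until induction, then conversion
        base = FateProgram(
            label=FateLabel.GROWING,
            kinetics={Channel.PI: ChannelProfile(), Channel.CAL: _cal_profile(rng, dt, 0.0)},
            division_times=_division_schedule(rng, 0.0, t_ind, doubling_time_min),
            growth_rate=growth,
        )
        # lineage with conversion applied to every cell
        cells = {cid: {"program": base, "parent": None, "birth_frame": 0, "rng": rng}}
        order = [cid]
        i = 0
        n_d = 0
        budget = 48
        while i < len(order):
            this = order[i]
            i += 1
            prog = cells[this]["program"]
            for t in prog.division_times:
                f = int(math.ceil(t / dt))
                if not (cells[this]["birth_frame"] < f < acq.n_frames - 1) or budget <= 0:
                    continue
                budget -= 1
                n_d += 1
                did = f"{cid}.{n_d}"
                drng = next_rng()
                dprog = FateProgram(
                    label=FateLabel.GROWING,
                    kinetics={Channel.PI: ChannelProfile(),
                              Channel.CAL: _cal_profile(drng, dt, f * dt)},
                    division_times=_division_schedule(drng, f * dt, t_ind, doubling_time_min),
                    growth_rate=growth,
                    birth_time=f * dt,
                )
                cells[did] = {"program": dprog, "parent": this, "birth_frame": f, "rng": drng}
                order.append(did)
        # convert and simulate in birth order
        inherited_map: dict[str, tuple[dict, float]] = {}
        for this in sorted(order, key=lambda c: (cells[c]["birth_frame"], c)):
            rec = cells[this]
            prog = convert(rec["program"], rec["rng"])
            # only divisions that actually spawned a daughter
            div_frames = sorted(
                {cells[d]["birth_frame"] for d in cells if cells[d]["parent"] == this}
            )
            inh, bsize = inherited_map.get(this, (None, 1.0))
            trace, spawns = _simulate_cell(
                prog, acq, rec["rng"], this, rec["parent"], "whole",
                rec["birth_frame"], inh, bsize, div_frames,
            )
            traces.append(trace)
            programs[(this, "whole")] = prog
            cell_labels[this] = prog.label
            division_frames_out[this] = div_frames
            for f, content, dsize in spawns:
                for did, drec in cells.items():
                    if drec["parent"] == this and drec["birth_frame"] == f:
                        inherited_map[did] = (content, dsize)
                        break

    truth = GroundTruth(programs=programs, cell_labels=cell_labels,
                        division_frames=division_frames_out)
    return traces, truth, acq
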