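"""Chip, media and feeding-schedule model for counter-current gradient culture.

The culture compartment is a shallow rectangular hydrogel chamber (default
1.3 mm wide by 7.9 mm long) fed through four media channels that interface
with the chamber along 2.6 mm segments at its four corners (top-left,
top-right, bottom-left, bottom-right).  Each end of the chip is served by a
media reservoir whose growth-factor concentrations decay by first-order
half-life kinetics between media exchanges; exchanges may replace the media
entirely (full) or mix it 1:1 with fresh media (half).

Concentrations are in ng/mL, lengths in mm unless noted, times in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

DAY = 86400.0
HOUR = 3600.0

__all__ = [
    "DAY",
    "HOUR",
    "GrowthFactor",
    "MediaComposition",
    "ChannelSegment",
    "ChipGeometry",
    "MediaEvent",
    "FeedingSchedule",
    "ReservoirState",
    "decay_rate",
    "reservoir_concentration",
    "apply_media_event",
    "build_gradient_schedule",
    "load_default_factors",
    "load_default_media",
    "schedule_to_dict",
    "schedule_from_dict",
]


@dataclass(frozen=True)
class GrowthFactor:
    """Transport, decay and potency parameters of one media supplement.

    Parameters
    ----------
    name : str
        Factor label (e.g. ``"IGF-1"``).
    supplemented_conc : float
        Concentration in freshly supplemented media, ng/mL.
    molecular_weight : float
        g/mol (informational; not used by the transport model).
    diffusivity : float
        Diffusion coefficient in liquid media, um^2/s.
    half_life : float
        First-order decay half-life, s.
    ec50 : float
        Half-maximal effective concentration, ng/mL; the bioactivity
        threshold used by the design metrics.
    """

    name: str
    supplemented_conc: float
    molecular_weight: float
    diffusivity: float
    half_life: float
    ec50: float
    group: str = ""

    def __post_init__(self) -> None:
        for f in ("supplemented_conc", "molecular_weight", "diffusivity",
                  "half_life", "ec50"):
            v = getattr(self, f)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{self.name}: {f} must be positive and finite, got {v}")

    @property
    def decay_rate(self) -> float:
        """First-order rate constant k = ln(0.5)/half_life (negative), 1/s."""
        return decay_rate(self.half_life)


@dataclass(frozen=True)
class MediaComposition:
    """A named culture medium as a map from factor name to ng/mL."""

    name: str
    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        for k, v in self.factors.items():
            if v < 0:
                raise ValueError(f"{self.name}: concentration of {k} is negative")

    def concentration(self, factor: str) -> float:
        return float(self.factors.get(factor, 0.0))


@dataclass(frozen=True)
class ChannelSegment:
    """One corner media-channel interface along a long edge of the chamber.

    ``edge`` is ``"top"`` or ``"bottom"`` (the two long sides), ``end`` is
    ``"left"`` or ``"right"`` (which corner the segment starts from), and
    ``reservoir`` names the media reservoir feeding it.
    """

    edge: str
    end: str
    reservoir: str

    def __post_init__(self) -> None:
        if self.edge not in ("top", "bottom"):
            raise ValueError(f"edge must be top|bottom, got {self.edge!r}")
        if self.end not in ("left", "right"):
            raise ValueError(f"end must be left|right, got {self.end!r}")

    def x_extent(self, geometry: "ChipGeometry") -> tuple[float, float]:
        """Interval of chamber length (mm from the left end) the segment spans."""
        if self.end == "left":
            return (0.0, geometry.channel_segment_length)
        return (geometry.length - geometry.channel_segment_length, geometry.length)


def _default_segments() -> tuple[ChannelSegment, ...]:
    # Both corner segments on one end share that end's reservoir.
    return (
        ChannelSegment("top", "left", "left"),
        ChannelSegment("bottom", "left", "left"),
        ChannelSegment("top", "right", "right"),
        ChannelSegment("bottom", "right", "right"),
    )


@dataclass(frozen=True)
class ChipGeometry:
    """Culture-compartment footprint and channel-interface layout.

    The non-segment boundary (short ends and the mid-length stretch of the
    long edges) is impermeable wall (no-flux).
    """

    length: float = 7.9
    width: float = 1.3
    channel_segment_length: float = 2.6
    segments: tuple[ChannelSegment, ...] = field(default_factory=_default_segments)

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0 or self.channel_segment_length <= 0:
            raise ValueError("geometry dimensions must be positive")
        if 2 * self.channel_segment_length > self.length:
            raise ValueError(
                "corner channel segments overlap: 2 x segment length exceeds chamber length")

    @property
    def reservoirs(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.segments:
            seen.setdefault(s.reservoir, None)
        return tuple(seen)

    def segments_for(self, reservoir: str) -> tuple[ChannelSegment, ...]:
        return tuple(s for s in self.segments if s.reservoir == reservoir)


@dataclass(frozen=True)
class MediaEvent:
    """A media exchange in one or more reservoirs at a given time.

    ``kind="full"`` replaces reservoir contents with ``new_media``;
    ``kind="half"`` mixes equal parts of the (decayed) current media and
    fresh ``new_media``.
    """

    time: float
    reservoirs: tuple[str, ...]
    kind: str
    new_media: MediaComposition

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.kind not in ("full", "half"):
            raise ValueError(f"kind must be full|half, got {self.kind!r}")


@dataclass(frozen=True)
class FeedingSchedule:
    """Time-ordered media events over a culture of given duration (s)."""

    events: tuple[MediaEvent, ...]
    duration: float

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")
        if times and times[-1] > self.duration:
            raise ValueError("event times must not exceed the schedule duration")

    def events_for(self, reservoir: str) -> tuple[MediaEvent, ...]:
        return tuple(e for e in self.events if reservoir in e.reservoirs)


@dataclass(frozen=True)
class ReservoirState:
    """Concentrations in one reservoir immediately after its last event."""

    last_event_time: float = 0.0
    concentration_at_event: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.concentration_at_event.items():
            if v < 0:
                raise ValueError(f"reservoir concentration of {k} is negative")


def decay_rate(half_life: float) -> float:
    """First-order decay rate k (1/s) for a given half-life (s).

    k = ln(0.5) / t_half, so k < 0 and C(t) = C0 * exp(k t) halves every
    half-life.
    """
    if not (half_life > 0):
        raise ValueError(f"half_life must be positive, got {half_life}")
    return math.log(0.5) / half_life


def reservoir_concentration(
    state: ReservoirState,
    factor: GrowthFactor | None,
    t: float,
    *,
    name: str | None = None,
) -> float:
    """Concentration (ng/mL) of ``factor`` in a reservoir at absolute time ``t``.

    Media sits in the channels between exchanges, so the concentration decays
    from its post-event value by the factor's half-life:
    ``C(t) = C_event * 2**(-(t - t_event)/t_half)``.

    Pass ``factor=None`` with ``name=`` to look up a factor that decays
    infinitely slowly (no decay applied) — mainly useful in tests.
    """
    label = factor.name if factor is not None else name
    if label is None:
        raise ValueError("either a GrowthFactor or a name is required")
    if label not in state.concentration_at_event:
        raise KeyError(f"factor {label!r} unknown to this reservoir state")
    dt = t - state.last_event_time
    if dt < 0:
        raise ValueError("t precedes the reservoir's last event")
    c0 = state.concentration_at_event[label]
    if factor is None:
        return c0
    return c0 * 2.0 ** (-dt / factor.half_life)


def apply_media_event(
    state: ReservoirState,
    event: MediaEvent,
    factors: Mapping[str, GrowthFactor],
) -> ReservoirState:
    """Return the reservoir state right after ``event``.

    A full exchange sets concentrations to the fresh media values.  A half
    exchange mixes the decayed current contents 1:1 with fresh media, so each
    factor ends at ``0.5 * decayed + 0.5 * fresh``.
    """
    if event.time < state.last_event_time:
        raise ValueError("event precedes the reservoir's last event")
    fresh = dict(event.new_media.factors)
    if event.kind == "full":
        new = {k: float(v) for k, v in fresh.items()}
    else:
        labels = set(state.concentration_at_event) | set(fresh)
        new = {}
        for label in labels:
            if label in state.concentration_at_event:
                gf = factors.get(label)
                decayed = reservoir_concentration(state, gf, event.time, name=label)
            else:
                decayed = 0.0
            new[label] = 0.5 * decayed + 0.5 * fresh.get(label, 0.0)
    return ReservoirState(last_event_time=event.time, concentration_at_event=new)


def _data_text(name: str) -> str:
    return resources.files("gradientchip.data").joinpath(name).read_text()


def load_default_factors() -> dict[str, GrowthFactor]:
    """The packaged default growth-factor parameter set."""
    raw = yaml.safe_load(_data_text("growth_factors.yaml"))
    return {
        name: GrowthFactor(name=name, **params)
        for name, params in raw["factors"].items()
    }


def load_default_media() -> dict[str, MediaComposition]:
    """The packaged default media compositions (stromal, vascular, adipogenic)."""
    raw = yaml.safe_load(_data_text("growth_factors.yaml"))
    return {
        name: MediaComposition(name=name, factors=dict(fac))
        for name, fac in raw["media"].items()
    }


DEFAULT_EXCHANGE_DAYS = (0, 1, 3, 5, 7, 10, 12, 14, 17, 19, 21, 24, 26, 28, 31)


def build_gradient_schedule(
    *,
    media: Mapping[str, MediaComposition] | None = None,
    vascular_side: str = "left",
    exchange_days: Iterable[float] = DEFAULT_EXCHANGE_DAYS,
    inversion_day: float | None = 17,
    duration_days: float = 31,
) -> FeedingSchedule:
    """Build the 31-day counter-current gradient feeding schedule.

    One side of the chip receives complete vascular media (full exchanges on
    every listed day).  The other side starts on stromal (MSC) media, is
    stepped toward adipogenic initiation media by half exchanges on the first
    two post-loading exchange days, then toward adipogenic maturation media by
    half exchanges every 2-3 days.  On the inversion day the sides swap roles
    and the pattern repeats mirrored until the end of culture.

    Passing ``exchange_days=[0]`` with ``duration_days=2`` yields the
    single-loading two-day schedule used for distribution design runs.
    """
    media = media if media is not None else load_default_media()
    vascular = media["vascular"]
    stromal = media["stromal"]
    initiation = media["adipogenic_initiation"]
    maturation = media["adipogenic_maturation"]

    days = sorted(set(float(d) for d in exchange_days))
    if not days or days[0] != 0.0:
        days = [0.0] + days
    if days[-1] > duration_days:
        raise ValueError("exchange days exceed the culture duration")
    if inversion_day is not None and not (0 < inversion_day <= duration_days):
        raise ValueError("inversion day falls outside the culture duration")

    adipo_side = "right" if vascular_side == "left" else "left"
    events: list[MediaEvent] = []

    def emit(day: float, vasc_to: str, adipo_media: MediaComposition, kind: str) -> None:
        t = day * DAY
        events.append(MediaEvent(t, (vasc_to,), "full", vascular))
        other = "right" if vasc_to == "left" else "left"
        events.append(MediaEvent(t, (other,), kind, adipo_media))

    # Phase boundaries are counted in exchange days since the phase start:
    # loading and day-1 full exchanges on both sides, then two initiation
    # half-exchange days, then maturation half exchanges.
    def phase(days_in_phase: list[float], vasc_to: str, first_day: float) -> None:
        post_load = [d for d in days_in_phase if d > first_day]
        for i, d in enumerate(days_in_phase):
            if d <= first_day or (d - first_day) <= 1.0:
                t = d * DAY
                events.append(MediaEvent(t, (vasc_to,), "full", vascular))
                other = "right" if vasc_to == "left" else "left"
                start_media = stromal if first_day == 0.0 else initiation
                kind = "full" if first_day == 0.0 else "half"
                events.append(MediaEvent(t, (other,), kind, start_media))
            else:
                rank = [d2 for d2 in post_load if (d2 - first_day) > 1.0].index(d)
                adipo_media = initiation if rank < 2 else maturation
                emit(d, vasc_to, adipo_media, "half")

    if inversion_day is None or inversion_day >= duration_days:
        phase(days, vascular_side, 0.0)
    else:
        pre = [d for d in days if d < inversion_day]
        post = [d for d in days if d >= inversion_day]
        phase(pre, vascular_side, 0.0)
        # Inversion: the maturation side is flushed with vascular media and
        # the previously vascular side begins adipogenic initiation.
        t_inv = inversion_day * DAY
        events.append(MediaEvent(t_inv, (adipo_side,), "full", vascular))
        events.append(MediaEvent(t_inv, (vascular_side,), "half", initiation))
        post_rest = [d for d in post if d > inversion_day]
        for i, d in enumerate(post_rest):
            adipo_media = initiation if i < 1 else maturation
            emit(d, adipo_side, adipo_media, "half")

    events.sort(key=lambda e: e.time)
    return FeedingSchedule(tuple(events), duration=duration_days * DAY)


# -- serialization ----------------------------------------------------------

def schedule_to_dict(schedule: FeedingSchedule) -> dict:
    return {
        "duration": schedule.duration,
        "events": [
            {
                "time": e.time,
                "reservoirs": list(e.reservoirs),
                "kind": e.kind,
                "media": {"name": e.new_media.name,
                          "factors": dict(e.new_media.factors)},
            }
            for e in schedule.events
        ],
    }


def schedule_from_dict(d: Mapping) -> FeedingSchedule:
    events = tuple(
        MediaEvent(
            time=float(e["time"]),
            reservoirs=tuple(e["reservoirs"]),
            kind=e["kind"],
            new_media=MediaComposition(e["media"]["name"], dict(e["media"]["factors"])),
        )
        for e in d["events"]
    )
    return FeedingSchedule(events, duration=float(d["duration"]))
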