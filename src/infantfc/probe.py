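"""Probe geometry, channel→section assignment, and headgear-displacement handling.

The packaged ``bright_infant`` fixture describes a two-band infant headgear:
14 sources and 12 detectors forming 34 channels (17 per hemisphere) at a
nominal 2 cm source–detector separation, sampled at 10 Hz at 780 and 850 nm.
Each hemisphere's 17 channels are ordered along the band from anterior to
posterior and grouped into three sections (front / middle / back), giving six
sections in total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

SECTIONS = ("L-front", "L-middle", "L-back", "R-front", "R-middle", "R-back")
HEMISPHERES = ("L", "R")


class FixtureError(ValueError):
    """Raised when a probe fixture is unknown or violates its invariants."""


@dataclass(frozen=True)
class Channel:
    index: int          # 1-based, unique and contiguous
    source: str         # source label, e.g. "S1"
    detector: str       # detector label, e.g. "D4"


@dataclass(frozen=True)
class Probe:
    """Optode layout and acquisition constants.

    ``sources`` and ``detectors`` map labels to 2-D layout positions (cm) in a
    schematic flattened-band coordinate frame (x increases anterior →
    posterior along each band).
    """

    sources: dict[str, tuple[float, float]]
    detectors: dict[str, tuple[float, float]]
    channels: tuple[Channel, ...]
    separation_cm: float = 2.0
    wavelengths_nm: tuple[float, float] = (780.0, 850.0)
    sampling_rate_hz: float = 10.0

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_position(self, ch: Channel) -> tuple[float, float]:
        sx, sy = self.sources[ch.source]
        dx, dy = self.detectors[ch.detector]
        return ((sx + dx) / 2.0, (sy + dy) / 2.0)

    def validate(self) -> None:
        idx = [c.index for c in self.channels]
        if sorted(idx) != list(range(1, len(idx) + 1)):
            raise FixtureError("channel indices must be unique and contiguous from 1")
        for c in self.channels:
            if c.source not in self.sources:
                raise FixtureError(f"channel {c.index} references missing source {c.source}")
            if c.detector not in self.detectors:
                raise FixtureError(f"channel {c.index} references missing detector {c.detector}")
        if self.separation_cm <= 0:
            raise FixtureError("separation_cm must be positive")
        if self.sampling_rate_hz <= 0:
            raise FixtureError("sampling_rate_hz must be positive")


@dataclass
class SectionMap:
    """Channel → section assignment plus the along-band channel ordering.

    ``section_of_channel`` maps channel index to one of the six section
    labels, or ``None`` for a channel left unassigned (e.g. shifted off the
    band end by displacement renumbering). ``chains`` records, per
    hemisphere, the channel indices ordered anterior → posterior; it defines
    the direction along which displacement renumbering shifts assignments.
    """

    section_of_channel: dict[int, str | None]
    chains: dict[str, list[int]] = field(default_factory=dict)

    def channels_in_section(self, section: str) -> list[int]:
        return [c for c, s in self.section_of_channel.items() if s == section]

    def hemisphere_of(self, channel: int) -> str | None:
        for hemi, chain in self.chains.items():
            if channel in chain:
                return hemi
        return None

    @property
    def assigned_channels(self) -> list[int]:
        return [c for c, s in self.section_of_channel.items() if s is not None]

    def validate(self, probe: Probe | None = None) -> None:
        for s in self.section_of_channel.values():
            if s is not None and s not in SECTIONS:
                raise FixtureError(f"unknown section label {s!r}")
        for section in SECTIONS:
            if not self.channels_in_section(section):
                raise FixtureError(f"section {section} has no channels")
        if probe is not None:
            probe_idx = {c.index for c in probe.channels}
            if set(self.section_of_channel) != probe_idx:
                raise FixtureError("section map channels do not match probe channels")


@dataclass(frozen=True)
class PlacementInfo:
    """Headgear placement annotations recorded in the field.

    ``frontal_grade`` is the traffic-light photographic grade (recorded, not
    computed here); a red grade flags the recording as excluded upstream.
    ``lateral_displacement_cm`` is signed: positive means the reference
    optode sat anterior of its ideal position.
    """

    lateral_displacement_cm: float = 0.0
    frontal_grade: str = "green"

    def __post_init__(self):
        if self.frontal_grade not in ("green", "orange", "red"):
            raise ValueError("frontal_grade must be green, orange or red")

    @property
    def excluded(self) -> bool:
        return self.frontal_grade == "red"


DISPLACEMENT_THRESHOLD_CM = 1.6


def load_probe_fixture(name: str = "bright_infant") -> tuple[Probe, SectionMap]:
    """Load a packaged probe fixture and its section map, validated."""
    try:
        text = resources.files("infantfc.data").joinpath(f"{name}.json").read_text()
    except FileNotFoundError:
        raise FixtureError(f"unknown probe fixture {name!r}") from None
    return probe_from_dict(json.loads(text))


def probe_from_dict(spec: dict) -> tuple[Probe, SectionMap]:
    probe = Probe(
        sources={k: tuple(v) for k, v in spec["sources"].items()},
        detectors={k: tuple(v) for k, v in spec["detectors"].items()},
        channels=tuple(Channel(c["index"], c["source"], c["detector"]) for c in spec["channels"]),
        separation_cm=spec.get("separation_cm", 2.0),
        wavelengths_nm=tuple(spec.get("wavelengths_nm", (780.0, 850.0))),
        sampling_rate_hz=spec.get("sampling_rate_hz", 10.0),
    )
    probe.validate()
    smap = SectionMap(
        section_of_channel={int(k): v for k, v in spec["section_of_channel"].items()},
        chains={k: list(v) for k, v in spec["chains"].items()},
    )
    smap.validate(probe)
    return probe, smap


def probe_to_dict(probe: Probe, smap: SectionMap) -> dict:
    """Serialize a probe + section map to the plain-JSON sidecar form."""
    return {
        "sources": {k: list(v) for k, v in probe.sources.items()},
        "detectors": {k: list(v) for k, v in probe.detectors.items()},
        "channels": [
            {"index": c.index, "source": c.source, "detector": c.detector}
            for c in probe.channels
        ],
        "separation_cm": probe.separation_cm,
        "wavelengths_nm": list(probe.wavelengths_nm),
        "sampling_rate_hz": probe.sampling_rate_hz,
        "section_of_channel": {str(k): v for k, v in smap.section_of_channel.items()},
        "chains": {k: list(v) for k, v in smap.chains.items()},
    }


def renumber_for_displacement(smap: SectionMap, placement: PlacementInfo) -> SectionMap:
    """Shift section assignments one channel location for a displaced band.

    Below the 1.6 cm threshold the map is returned unchanged. At or above
    threshold, every channel takes the section of the neighbouring chain
    position in the compensating direction; shifts never cross the midline,
    and channels shifted past a band end become unassigned (``None``).

    Sign convention (flagged in the docs): positive displacement = band slid
    anterior, so each channel physically covers anatomy one slot anterior of
    nominal and inherits the section of the preceding (more anterior) chain
    position; the most anterior channel of each band falls off the covered
    anatomy and is unassigned. Negative displacement mirrors this.
    """
    d = float(placement.lateral_displacement_cm)
    if not (d == d and abs(d) != float("inf")):
        raise ValueError("displacement must be finite")
    if abs(d) < DISPLACEMENT_THRESHOLD_CM:
        return SectionMap(dict(smap.section_of_channel), {k: list(v) for k, v in smap.chains.items()})

    new = dict(smap.section_of_channel)
    for chain in smap.chains.values():
        old = [smap.section_of_channel[c] for c in chain]
        if d > 0:   # take section of previous (more anterior) position
            shifted = [None] + old[:-1]
        else:       # take section of next (more posterior) position
            shifted = old[1:] + [None]
        for c, s in zip(chain, shifted):
            new[c] = s
    return SectionMap(new, {k: list(v) for k, v in smap.chains.items()})
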