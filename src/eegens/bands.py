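"""Canonical EEG frequency-band definitions."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BandDefinition", "CANONICAL_BANDS", "BAND_ORDER", "BROADBAND"]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.name}: low must be < high")


#: The six-band decomposition used throughout: delta through gamma.
CANONICAL_BANDS: dict[str, BandDefinition] = {
    b.name: b
    for b in (
        BandDefinition("delta", 0.5, 4.0),
        BandDefinition("theta", 4.0, 8.0),
        BandDefinition("alpha", 8.0, 12.0),
        BandDefinition("low_beta", 12.0, 20.0),
        BandDefinition("high_beta", 20.0, 30.0),
        BandDefinition("gamma", 30.0, 45.0),
    )
}

BAND_ORDER = tuple(CANONICAL_BANDS)

#: Sentinel band name for unfiltered (1–45 Hz broadband) signals.
BROADBAND = "broadband"
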