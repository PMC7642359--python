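"""Canonical frequency bands for resting-state envelope analysis."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A frequency band with inclusive edges in Hz.

    Canonical bands: theta 4-8 Hz, alpha 8-12 Hz, beta 12-30 Hz, and the
    wide 4-30 Hz band used for the state-dynamics analysis.
    """

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < lo < hi, got ({self.lo}, {self.hi})"
            )

    def check_nyquist(self, fs: float) -> None:
        if self.hi >= fs / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.hi} Hz is at or above "
                f"Nyquist ({fs / 2} Hz for fs={fs})"
            )


BANDS: dict[str, BandSpec] = {
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "beta": BandSpec("beta", 12.0, 30.0),
    "wide": BandSpec("wide", 4.0, 30.0),
}

#: Narrow bands used for the static connectome analysis.
NARROW_BANDS = ("theta", "alpha", "beta")


def get_band(band: "str | BandSpec") -> BandSpec:
    """Resolve a band name or pass a BandSpec through."""
    if isinstance(band, BandSpec):
        return band
    try:
        return BANDS[band]
    except KeyError:
        raise KeyError(
            f"unknown band {band!r}; known bands: {sorted(BANDS)}"
        ) from None
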