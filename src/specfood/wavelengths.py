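"""Wavelength labels and spectral-band bookkeeping.

The acquisition protocol uses 19 narrow-band LED light sources plus one
white-light shot that yields an RGB image.  Every channel is identified by a
:class:`WavelengthLabel`.  Band membership follows the convention used for
the selection-rate analyses: the white LED spans roughly 430-640 nm, so the
two shortest wavelengths count as UV, the nine sources from 430 to 660 nm as
VIS, and the eight sources from 810 nm upward as NIR.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import total_ordering


class Band(str, enum.Enum):
    UV = "UV"
    VIS = "VIS"
    NIR = "NIR"
    RGB = "RGB"


_NARROW_BAND_NM = (
    385, 405, 430, 470, 490, 510, 560, 590, 625, 645, 660,
    810, 850, 870, 890, 910, 950, 970, 1020,
)

_UV_NM = frozenset({385, 405})
_NIR_NM = frozenset({810, 850, 870, 890, 910, 950, 970, 1020})


@total_ordering
@dataclass(frozen=True)
class WavelengthLabel:
    """One illumination channel: a narrow-band center wavelength or RGB.

    Ordering sorts RGB first, then by ascending wavelength; this is the
    canonical channel order used when assembling CNN inputs and when breaking
    ties in wavelength selection.
    """

    name: str

    def __post_init__(self) -> None:
        if self.name != "RGB":
            try:
                nm = int(self.name)
            except ValueError:
                raise ValueError(f"unknown wavelength label: {self.name!r}")
            if nm not in _NARROW_BAND_NM:
                raise ValueError(f"not an employed center wavelength: {nm} nm")

    @property
    def is_rgb(self) -> bool:
        return self.name == "RGB"

    @property
    def nm(self) -> int | None:
        """Center wavelength in nm, or None for the RGB shot."""
        return None if self.is_rgb else int(self.name)

    @property
    def band(self) -> Band:
        if self.is_rgb:
            return Band.RGB
        nm = int(self.name)
        if nm in _UV_NM:
            return Band.UV
        if nm in _NIR_NM:
            return Band.NIR
        return Band.VIS

    def sort_key(self) -> tuple[int, int]:
        # RGB outranks every narrow band; ties elsewhere break to shorter nm.
        return (0, -1) if self.is_rgb else (1, int(self.name))

    def __lt__(self, other: "WavelengthLabel") -> bool:
        return self.sort_key() < other.sort_key()

    def __str__(self) -> str:
        return self.name


def wl(name: str | int) -> WavelengthLabel:
    """Shorthand constructor: ``wl(890)`` or ``wl("RGB")``."""
    return WavelengthLabel(str(name))


RGB = wl("RGB")
NARROW_BAND: tuple[WavelengthLabel, ...] = tuple(wl(nm) for nm in _NARROW_BAND_NM)
ALL_LABELS: tuple[WavelengthLabel, ...] = (RGB,) + NARROW_BAND

UV_LABELS = tuple(w for w in NARROW_BAND if w.band is Band.UV)
VIS_LABELS = tuple(w for w in NARROW_BAND if w.band is Band.VIS)
NIR_LABELS = tuple(w for w in NARROW_BAND if w.band is Band.NIR)
#: UV and NIR together: everything invisible to an RGB camera.
NON_VISIBLE_LABELS = tuple(w for w in NARROW_BAND if w.band in (Band.UV, Band.NIR))
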