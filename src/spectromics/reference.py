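"""Reference band assignments for articular-cartilage vibrational spectra.

Wavenumber intervals of the Raman and NIR-SWIR bands reported as
discriminating osteoarthritic from control cartilage, with their chemical
assignments. Used to annotate corroborated biomarker regions and to plant
class effects in the synthetic cohort generator.
"""

from __future__ import annotations

from dataclasses import dataclass

from .spectrum import NIRSWIR, RAMAN


@dataclass(frozen=True)
class BandAssignment:
    """A literature band: closed wavenumber interval plus assignment text."""

    low: float
    high: float
    modality: str
    assignment: str

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("BandAssignment requires low <= high")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


#: Cartilage band table: OA-discriminating regions and their assignments.
BAND_ASSIGNMENTS: tuple[BandAssignment, ...] = (
    BandAssignment(1334.0, 1343.0, RAMAN, "CH wagging (GAG)"),
    BandAssignment(1246.0, 1255.0, RAMAN, "amide III (C-N stretch)"),
    BandAssignment(1616.0, 1617.0, RAMAN, "amide I"),
    BandAssignment(1063.0, 1064.0, RAMAN, "SO3- symmetric stretch (sGAG)"),
    BandAssignment(6472.0, 6543.0, NIRSWIR, "N-H stretch 1st overtone (PG)"),
    BandAssignment(4366.0, 4402.0, NIRSWIR, "C-H bend 2nd overtone (ECM)"),
    BandAssignment(7094.0, 7159.0, NIRSWIR, "O-H stretch 1st overtone (water)"),
    BandAssignment(8744.0, 8767.0, NIRSWIR, "C-H stretch 2nd overtone"),
    BandAssignment(5333.0, 5357.0, NIRSWIR, "water combination band"),
)

#: Annotation margin (cm^-1) when matching a region to a listed band;
#: roughly half a typical bandwidth per modality.
ASSIGNMENT_MARGIN = {RAMAN: 6.0, NIRSWIR: 40.0}


def lookup_assignment(
    modality: str, wn_low: float, wn_high: float
) -> str | None:
    """Assignment text for the first listed band overlapping the interval.

    The interval is widened by the per-modality margin before the overlap
    test; returns None when no listed band matches.
    """
    margin = ASSIGNMENT_MARGIN[modality]
    for band in BAND_ASSIGNMENTS:
        if band.modality != modality:
            continue
        if wn_low - margin <= band.high and wn_high + margin >= band.low:
            return band.assignment
    return None
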