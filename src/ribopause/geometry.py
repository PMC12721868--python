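"""Ribosome footprint geometry.

The coordinate backbone of the package: how a footprint's 5' end relates to
the decoding (A-site) codon of the ribosome that produced it.

Monosome footprints are assigned with length/frame-specific 5' offsets: the
A-site nucleotide is ``five_prime_pos + offset`` and the codon index is its
floor division by three, so the offset may point at any nucleotide of the
A-site codon.  The defaults are 16 nt for 28-nt frame-0 and 29-nt frame-0
reads and 17 nt for 29-nt frame-2 reads.  Disome footprints are assigned
unconditionally with a single offset from the 5' end to the A site of the
lead (stalled) ribosome, 45 nt by default.

Collided (queued) elongating ribosomes sit with a fixed 5'-to-5' spacing of
30 nt (a 28-nt footprint plus a 2-nt gap), i.e. their A sites are 10 codons
apart.  A terminating ribosome protects a footprint whose 5' end lies 18 nt
upstream of the first aligned position past the stop codon, and the ribosome
queued directly behind it therefore peaks 48 nt upstream (48 = 28 + 2 + 18).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

#: default (length, frame) -> A-site offset for monosome footprints
DEFAULT_MONOSOME_OFFSETS: Mapping[tuple[int, int], int] = MappingProxyType(
    {(28, 0): 16, (29, 0): 16, (29, 2): 17}
)

DEFAULT_DISOME_OFFSET = 45

#: raw length windows accepted at load time
MONOSOME_LENGTH_RANGE = (25, 35)
DISOME_LENGTH_RANGE_RAW = (50, 70)
#: analysis selection window for disome footprints
DISOME_SELECTION_RANGE = (56, 64)


class OffsetError(KeyError):
    """Raised when no A-site offset is configured for a (length, frame)."""


@dataclass(frozen=True)
class OffsetTable:
    """A-site offset configuration for monosome and disome footprints."""

    entries: Mapping[tuple[int, int], int] = field(
        default_factory=lambda: dict(DEFAULT_MONOSOME_OFFSETS)
    )
    disome_offset: int = DEFAULT_DISOME_OFFSET

    def offset(self, length: int, frame: int) -> int:
        try:
            return self.entries[(length, frame)]
        except KeyError:
            raise OffsetError(
                f"no A-site offset configured for (length={length}, frame={frame})"
            ) from None

    @property
    def keys(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.entries)


DEFAULT_OFFSETS = OffsetTable()


@dataclass(frozen=True)
class GeometryModel:
    """Footprint emission geometry used by the simulator.

    Emission positions are derived from the offset table so that A-site
    assignment is the exact inverse of emission: a footprint of class
    ``(length, frame)`` produced by a ribosome decoding codon ``k`` starts at

        five_prime = cds_start + 3*k - offset + ((offset + frame) mod 3)

    which is the unique position congruent to ``frame`` (mod 3) whose
    assigned A-site nucleotide falls inside codon ``k``.
    """

    offsets: OffsetTable = DEFAULT_OFFSETS
    #: 5'-to-5' distance between collided elongating ribosomes (nt)
    queue_spacing_nt: int = 30
    #: nt accommodated in the A site of a terminating ribosome (eRF1 bound)
    termination_a_site_nt: int = 4
    #: 5' end of the initiating-ribosome footprint relative to the start A (nt)
    initiation_five_prime_offset: int = -12

    @property
    def queue_spacing_codons(self) -> int:
        return self.queue_spacing_nt // 3

    def monosome_five_prime(
        self, cds_start: int, codon: int, length: int, frame: int
    ) -> int:
        """5' position of a monosome footprint decoding ``codon`` (0-based)."""
        off = self.offsets.offset(length, frame)
        return cds_start + 3 * codon - off + ((off + frame) % 3)

    def disome_five_prime(self, cds_start: int, lead_codon: int) -> int:
        """5' position of a disome whose lead ribosome decodes ``lead_codon``."""
        return cds_start + 3 * lead_codon - self.offsets.disome_offset


DEFAULT_GEOMETRY = GeometryModel()
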