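"""Read-1 layout of the single-end duplex-UMI adapter.

Read 1 of a library fragment begins with the adapter-derived prefix

    UMI (12 nt) | spacer 1 (10 nt) | strand barcode (2 nt) | spacer 2 (11 nt)

followed by the genomic insert.  The two-base strand barcode records which
strand of the original double-stranded molecule the read derives from:
``TT`` marks the original top strand, while the original bottom strand is
converted during the first enrichment cycle and is sequenced as ``CC``.
The combination (UMI, strand barcode) is what makes duplex recovery possible
from a single read.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReadLayout:
    """Fixed coordinates of the adapter-derived prefix on read 1."""

    umi_length: int = 12
    spacer1: str = "TTCTGAGCGA"
    barcode_top: str = "TT"
    #: the original bottom strand carries GG physically; it is read as CC
    barcode_bottom: str = "CC"
    spacer2: str = "ATAGGAGTCCT"

    @property
    def barcode_start(self) -> int:
        return self.umi_length + len(self.spacer1)

    @property
    def barcode_end(self) -> int:
        return self.barcode_start + len(self.barcode_top)

    @property
    def insert_offset(self) -> int:
        """0-based offset of the first genomic base on read 1."""
        return self.barcode_end + len(self.spacer2)

    def prefix(self, umi: str, strand: str) -> str:
        """Assemble the read-1 prefix for a given UMI and strand.

        ``strand`` is ``"TOP"`` or ``"BOTTOM"``.
        """
        if len(umi) != self.umi_length:
            raise ValueError(f"UMI must be {self.umi_length} nt, got {len(umi)}")
        barcode = self.barcode_top if strand == "TOP" else self.barcode_bottom
        return umi + self.spacer1 + barcode + self.spacer2


DEFAULT_LAYOUT = ReadLayout()
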