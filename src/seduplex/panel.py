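"""Panel definition: target loci, primer anchors and the reference sequence.

A panel is the set of single-primer-extension (SPE) amplicons interrogated by
the assay.  Each locus has one gene-specific primer that anchors the fixed
end of the amplicon; the opposite end is the random fragmentation end where
the UMI adapter is ligated.  Internally all coordinates are 0-based
half-open; BED round-trips preserve this, VCF output is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

BASES = "ACGT"


@dataclass(frozen=True)
class Locus:
    locus_id: str
    chrom: str
    #: genomic coordinate of the primer anchor: the fixed fragment end.
    #: Fragments extend leftward from here; the ligated (UMI) end is the
    #: random left end.
    primer_start: int
    primer_strand: str  # '+' or '-'
    target_start: int
    target_end: int

    def target_sites(self) -> range:
        return range(self.target_start, self.target_end)


@dataclass
class PanelDesign:
    loci: list[Locus]
    #: per-chromosome top-strand sequence
    reference: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [loc.locus_id for loc in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("locus_ids must be unique")
        for loc in self.loci:
            if loc.target_end <= loc.target_start:
                raise ValueError(f"{loc.locus_id}: empty target interval")
            if loc.chrom in self.reference:
                if loc.target_end > len(self.reference[loc.chrom]):
                    raise ValueError(f"{loc.locus_id}: target beyond reference end")

    def locus(self, locus_id: str) -> Locus:
        for loc in self.loci:
            if loc.locus_id == locus_id:
                return loc
        raise KeyError(locus_id)

    def ref_base(self, chrom: str, pos: int) -> str:
        return self.reference[chrom][pos]

    def primer_sequence(self, locus: Locus, length: int = 20) -> str:
        """Gene-specific primer as sequenced at the start of read 2.

        The primer sits on the bottom strand at the anchor and extends
        leftward, so read 2 begins with the reverse complement of the
        top-strand bases immediately left of the anchor.
        """
        seq = self.reference[locus.chrom][locus.primer_start - length : locus.primer_start]
        return revcomp(seq)

    # ------------------------------------------------------------------ I/O

    def write_bed(self, path: str | Path) -> None:
        """Write target intervals as BED6 (score column = primer anchor)."""
        with open(path, "w") as fh:
            for loc in self.loci:
                fh.write(
                    f"{loc.chrom}\t{loc.target_start}\t{loc.target_end}\t"
                    f"{loc.locus_id}\t{loc.primer_start}\t{loc.primer_strand}\n"
                )

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.reference.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @classmethod
    def from_files(cls, bed_path: str | Path, fasta_path: str | Path) -> "PanelDesign":
        reference: dict[str, str] = {}
        with pysam.FastxFile(str(fasta_path)) as fx:
            for entry in fx:
                reference[entry.name] = entry.sequence.upper()
        loci = []
        with open(bed_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                fields = line.rstrip("\n").split("\t")
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                primer_start = int(fields[4]) if len(fields) > 4 else end
                strand = fields[5] if len(fields) > 5 else "+"
                loci.append(Locus(name, chrom, primer_start, strand, start, end))
        return cls(loci=loci, reference=reference)


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_panel(
    n_loci: int = 8,
    target_length: int = 90,
    seed: int = 0,
    chrom: str = "chrSim",
    spacing: int = 400,
) -> PanelDesign:
    """Synthetic single-chromosome panel for simulations and tests.

    Each locus occupies a ``spacing`` bp slot.  The primer anchor sits at the
    right edge of the slot and the target interval is placed so that ~170 bp
    fragments ending at the anchor cover it through the sequenced insert.
    """
    rng = np.random.default_rng(seed)
    ref_len = n_loci * spacing + 200
    ref = "".join(rng.choice(list(BASES), size=ref_len))
    loci = []
    for i in range(n_loci):
        anchor = (i + 1) * spacing
        # insert of a mean-length fragment covers roughly [anchor-170, anchor-55)
        target_end = anchor - 60
        target_start = target_end - target_length
        loci.append(Locus(f"L{i:03d}", chrom, anchor, "+", target_start, target_end))
    return PanelDesign(loci=loci, reference={chrom: ref})
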