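"""UMI and strand-barcode decoding, family grouping, merging and duplex pairing.

Reads sharing (sample, locus, fragmentation position, UMI, strand label) form
a UMI family — the unit of consensus.  Families whose UMIs differ by a single
substitution and whose fragmentation sites lie within 5 bp are merged when
their sizes are lopsided (sequencing/PCR error in the UMI itself).  A top-
and a bottom-strand family with the same UMI at the same fragment position
reconstitute the two strands of one original molecule: a duplex.
"""

from __future__ import annotations

import collections
import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from .layout import DEFAULT_LAYOUT, ReadLayout
from .panel import PanelDesign


class RejectReason(enum.Enum):
    TOO_SHORT = "TOO_SHORT"
    BAD_SPACER = "BAD_SPACER"
    BAD_BARCODE = "BAD_BARCODE"


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_umi_strand(
    read1_sequence: str, layout: ReadLayout = DEFAULT_LAYOUT
) -> tuple[str, str, int] | RejectReason:
    """Decode (umi, strand_label, insert_offset) from a read-1 sequence.

    Each spacer tolerates one mismatch (sequencing error); the two-base
    barcode must match exactly — it is the strand signal, and any other
    dinucleotide is uninterpretable.  Failures return a
    :class:`RejectReason`, a tallied outcome rather than an exception.
    """
    k = layout.umi_length
    if len(read1_sequence) < layout.insert_offset + 1:
        return RejectReason.TOO_SHORT
    umi = read1_sequence[:k]
    sp1 = read1_sequence[k : layout.barcode_start]
    barcode = read1_sequence[layout.barcode_start : layout.barcode_end]
    sp2 = read1_sequence[layout.barcode_end : layout.insert_offset]
    if _hamming(sp1, layout.spacer1) > 1 or _hamming(sp2, layout.spacer2) > 1:
        return RejectReason.BAD_SPACER
    if barcode == layout.barcode_top:
        strand = "TOP"
    elif barcode == layout.barcode_bottom:
        strand = "BOTTOM"
    else:
        return RejectReason.BAD_BARCODE
    return umi, strand, layout.insert_offset


@dataclass
class TaggedRead:
    read_id: str
    umi: str
    strand_label: str
    locus_id: str
    chrom: str
    frag_pos: int  # 0-based position of the ligated end
    start: int  # 0-based genomic start of the insert
    seq: str  # insert bases (genomic portion only)
    quals: list[int]
    mapping_quality: int = 60
    mismatch_count: int = 0
    sample_id: str = "S1"

    def base_at(self, pos: int) -> str | None:
        off = pos - self.start
        if 0 <= off < len(self.seq):
            return self.seq[off]
        return None

    def qual_at(self, pos: int) -> int:
        return self.quals[pos - self.start]

    def covers(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.start + len(self.seq)


FamilyKey = tuple[str, str, int, str, str]  # sample, locus, frag_pos, umi, strand


@dataclass
class UmiFamily:
    sample_id: str
    locus_id: str
    frag_pos: int
    umi: str
    strand_label: str
    reads: list[TaggedRead] = field(default_factory=list)

    @property
    def key(self) -> FamilyKey:
        return (self.sample_id, self.locus_id, self.frag_pos, self.umi, self.strand_label)

    @property
    def read_count(self) -> int:
        return len(self.reads)

    @property
    def chrom(self) -> str:
        return self.reads[0].chrom


@dataclass(frozen=True)
class MergeConfig:
    max_umi_distance: int = 1
    max_frag_pos_delta: int = 5
    #: "much larger" family: absorber must be at least this many times bigger
    min_count_ratio: float = 5.0

    def __post_init__(self) -> None:
        if self.max_umi_distance < 0 or self.max_frag_pos_delta < 0:
            raise ValueError("distances must be >= 0")
        if self.min_count_ratio <= 1.0:
            raise ValueError("min_count_ratio must be > 1")


@dataclass
class DuplexGroup:
    top_family: UmiFamily | None = None
    bottom_family: UmiFamily | None = None

    @property
    def classification(self) -> str:
        return "DUPLEX" if self.top_family and self.bottom_family else "SINGLEPLEX"

    @property
    def lone_family(self) -> UmiFamily:
        fam = self.top_family or self.bottom_family
        assert fam is not None
        return fam

    @property
    def families(self) -> list[UmiFamily]:
        return [f for f in (self.top_family, self.bottom_family) if f is not None]

    @property
    def locus_id(self) -> str:
        return self.families[0].locus_id


# ------------------------------------------------------------- operations


def group_families(tagged_reads: list[TaggedRead]) -> list[UmiFamily]:
    """Partition reads by (sample, locus, frag_pos, UMI, strand label)."""
    by_key: dict[FamilyKey, UmiFamily] = {}
    for r in tagged_reads:
        key = (r.sample_id, r.locus_id, r.frag_pos, r.umi, r.strand_label)
        fam = by_key.get(key)
        if fam is None:
            fam = UmiFamily(r.sample_id, r.locus_id, r.frag_pos, r.umi, r.strand_label)
            by_key[key] = fam
        fam.reads.append(r)
    return [by_key[k] for k in sorted(by_key)]


def _umi_neighbors(umi: str) -> list[str]:
    out = [umi]
    for i, b in enumerate(umi):
        for c in "ACGTN":
            if c != b:
                out.append(umi[:i] + c + umi[i + 1 :])
    return out


def merge_families(
    families: list[UmiFamily], cfg: MergeConfig = MergeConfig()
) -> list[UmiFamily]:
    """Absorb small families into much larger near-duplicate ones.

    Within each (sample, locus, strand) stratum, families are visited in
    descending read count (ties broken by UMI, then position).  A family is
    absorbed by an already-kept family when the UMIs are within
    ``max_umi_distance`` substitutions, the fragmentation sites within
    ``max_frag_pos_delta`` bp, and the absorber's (pre-merge) count is at
    least ``min_count_ratio`` times the absorbee's.  The merged family keeps
    the absorber's key; absorbed families never absorb in turn.
    """
    strata: dict[tuple, list[UmiFamily]] = collections.defaultdict(list)
    for fam in families:
        strata[(fam.sample_id, fam.locus_id, fam.strand_label)].append(fam)

    merged: list[UmiFamily] = []
    for stratum_key in sorted(strata):
        fams = sorted(
            strata[stratum_key], key=lambda f: (-f.read_count, f.umi, f.frag_pos)
        )
        snapshot = {id(f): f.read_count for f in fams}
        kept: list[UmiFamily] = []
        umi_index: dict[str, list[UmiFamily]] = collections.defaultdict(list)
        for fam in fams:
            candidates = []
            seen: set[int] = set()
            for neighbor in _umi_neighbors(fam.umi):
                for other in umi_index.get(neighbor, ()):
                    if id(other) in seen:
                        continue
                    seen.add(id(other))
                    if (
                        abs(other.frag_pos - fam.frag_pos) <= cfg.max_frag_pos_delta
                        and _hamming(other.umi, fam.umi) <= cfg.max_umi_distance
                        and snapshot[id(other)] >= cfg.min_count_ratio * snapshot[id(fam)]
                    ):
                        candidates.append(other)
            if candidates:
                best = min(
                    candidates,
                    key=lambda o: (
                        -snapshot[id(o)],
                        abs(o.frag_pos - fam.frag_pos),
                        o.umi,
                        o.frag_pos,
                    ),
                )
                best.reads.extend(fam.reads)
            else:
                kept.append(fam)
                umi_index[fam.umi].append(fam)
        merged.extend(kept)
    return merged


def pair_duplex(
    families: list[UmiFamily], max_frag_pos_delta: int = 5
) -> list[DuplexGroup]:
    """Pair top- and bottom-strand families from the same original molecule.

    Within (sample, locus, UMI), a TOP and a BOTTOM family whose fragment
    positions differ by at most ``max_frag_pos_delta`` bp form one DUPLEX
    group, paired greedily by nearest position.  Everything left over is
    SINGLEPLEX.  Every input family ends up in exactly one group.
    """
    by_umi: dict[tuple, dict[str, list[UmiFamily]]] = collections.defaultdict(
        lambda: {"TOP": [], "BOTTOM": []}
    )
    for fam in families:
        by_umi[(fam.sample_id, fam.locus_id, fam.umi)][fam.strand_label].append(fam)

    groups: list[DuplexGroup] = []
    for key in sorted(by_umi):
        tops = sorted(by_umi[key]["TOP"], key=lambda f: f.frag_pos)
        bottoms = sorted(by_umi[key]["BOTTOM"], key=lambda f: f.frag_pos)
        pairs = [
            (abs(t.frag_pos - b.frag_pos), ti, bi)
            for ti, t in enumerate(tops)
            for bi, b in enumerate(bottoms)
            if abs(t.frag_pos - b.frag_pos) <= max_frag_pos_delta
        ]
        pairs.sort()
        used_t: set[int] = set()
        used_b: set[int] = set()
        for _, ti, bi in pairs:
            if ti in used_t or bi in used_b:
                continue
            used_t.add(ti)
            used_b.add(bi)
            groups.append(DuplexGroup(top_family=tops[ti], bottom_family=bottoms[bi]))
        for ti, t in enumerate(tops):
            if ti not in used_t:
                groups.append(DuplexGroup(top_family=t))
        for bi, b in enumerate(bottoms):
            if bi not in used_b:
                groups.append(DuplexGroup(bottom_family=b))
    return groups


# ------------------------------------------------------------------- input


def tag_reads(
    fastq1: str | Path,
    alignment: pd.DataFrame,
    panel: PanelDesign,
    layout: ReadLayout = DEFAULT_LAYOUT,
    sample_id: str = "S1",
) -> tuple[list[TaggedRead], collections.Counter]:
    """Decode read-1 FASTQ records into tagged reads using a truth alignment.

    ``alignment`` maps read_id to (chrom, start, locus_id, frag_pos); the
    UMI and strand label always come from the read sequence itself, so
    decoding failures are observable.  Returns the tagged reads and a tally
    of reject reasons.
    """
    aln = alignment.set_index("read_id")
    rejects: collections.Counter = collections.Counter()
    tagged: list[TaggedRead] = []
    with pysam.FastxFile(str(fastq1)) as fx:
        for entry in fx:
            result = extract_umi_strand(entry.sequence, layout)
            if isinstance(result, RejectReason):
                rejects[result] += 1
                continue
            umi, strand, offset = result
            if entry.name not in aln.index:
                rejects["UNALIGNED"] += 1
                continue
            row = aln.loc[entry.name]
            insert = entry.sequence[offset:]
            quals = (
                [ord(c) - 33 for c in entry.quality[offset:]]
                if entry.quality
                else [40] * len(insert)
            )
            chrom = row["chrom"]
            start = int(row["start"])
            ref = panel.reference[chrom]
            mismatches = _hamming(insert, ref[start : start + len(insert)])
            tagged.append(
                TaggedRead(
                    read_id=entry.name,
                    umi=umi,
                    strand_label=strand,
                    locus_id=row["locus_id"],
                    chrom=chrom,
                    frag_pos=int(row["frag_pos"]),
                    start=start,
                    seq=insert,
                    quals=quals,
                    mismatch_count=mismatches,
                    sample_id=sample_id,
                )
            )
    return tagged, rejects


def tag_reads_from_bam(
    bam_path: str | Path, panel: PanelDesign, sample_id: str = "S1"
) -> list[TaggedRead]:
    """Tagged reads from pre-aligned input carrying UM (UMI) and SL (strand) tags.

    The aligned insert is taken as primer-trimmed; the fragmentation
    position is the leftmost aligned coordinate (the ligated end) and the
    locus is the panel locus whose window contains it.
    """
    windows = [
        (loc.chrom, max(0, loc.primer_start - 600), loc.primer_start, loc.locus_id)
        for loc in panel.loci
    ]

    def find_locus(chrom: str, pos: int) -> str | None:
        for c, lo, hi, lid in windows:
            if c == chrom and lo <= pos < hi:
                return lid
        return None

    tagged: list[TaggedRead] = []
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if not (rec.has_tag("UM") and rec.has_tag("SL")):
                continue
            locus_id = find_locus(rec.reference_name, rec.reference_start)
            if locus_id is None:
                continue
            quals = (
                list(rec.query_qualities)
                if rec.query_qualities is not None
                else [40] * rec.query_length
            )
            tagged.append(
                TaggedRead(
                    read_id=rec.query_name,
                    umi=str(rec.get_tag("UM")),
                    strand_label=str(rec.get_tag("SL")),
                    locus_id=locus_id,
                    chrom=rec.reference_name,
                    frag_pos=rec.reference_start,
                    start=rec.reference_start,
                    seq=rec.query_sequence,
                    quals=quals,
                    mapping_quality=rec.mapping_quality,
                    mismatch_count=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                    sample_id=sample_id,
                )
            )
    return tagged


def family_table(groups: list[DuplexGroup]) -> pd.DataFrame:
    """Per-family summary with duplex classification (TSV-ready)."""
    rows = []
    for g in groups:
        for fam in g.families:
            rows.append(
                (
                    fam.sample_id, fam.locus_id, fam.frag_pos, fam.umi,
                    fam.strand_label, fam.read_count, g.classification,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "locus_id", "frag_pos", "umi", "strand_label",
                 "read_count", "classification"],
    )
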