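"""Per-site consensus over UMI families and duplex groups.

A family reaches consensus at a site when at least 80% of its covering reads
and at least 80% of its *high-quality* covering reads agree on one allele;
singletons are excluded outright (a single read cannot be error-corrected).
A duplex group requires both strand families to reach the same consensus;
disagreement (DISCORDANT) is positive evidence of a single-strand artifact
and the group is excluded from both numerator and denominator.

Two count tables are produced:

* group-level ``SiteCounts`` (N1/n1 single-plex, N2/n2 duplex) feeding the
  variant caller;
* family-level qualified-UMI counts per alternative base feeding the
  background error model, where every consensus family is one observation.
"""

from __future__ import annotations

import collections
import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import BASES, PanelDesign
from .umi import DuplexGroup, UmiFamily


class Consensus(enum.Enum):
    NO_CONSENSUS = "NO_CONSENSUS"
    EXCLUDED_SINGLETON = "EXCLUDED_SINGLETON"
    DISCORDANT = "DISCORDANT"
    NOT_COVERED = "NOT_COVERED"


@dataclass(frozen=True)
class ConsensusConfig:
    min_allele_fraction: float = 0.80
    min_hq_fraction: float = 0.80
    min_base_quality: int = 25
    min_mapping_quality: int = 30
    max_mismatches: int = 3
    homopolymer_min_run: int = 5

    def __post_init__(self) -> None:
        for f in (self.min_allele_fraction, self.min_hq_fraction):
            if not 0.5 < f <= 1.0:
                raise ValueError("consensus fractions must be in (0.5, 1]")
        if self.min_base_quality < 0 or self.min_mapping_quality < 0:
            raise ValueError("quality thresholds must be >= 0")


@dataclass
class SiteCounts:
    chrom: str
    pos: int  # 0-based
    ref_base: str
    N1: int
    n1: int
    N2: int
    n2: int
    alt_allele: str | None
    discordant: int = 0


def _homopolymer_run(ref_seq: str, pos: int) -> tuple[int, int]:
    base = ref_seq[pos]
    lo = pos
    while lo > 0 and ref_seq[lo - 1] == base:
        lo -= 1
    hi = pos + 1
    while hi < len(ref_seq) and ref_seq[hi] == base:
        hi += 1
    return lo, hi


def family_consensus(
    family: UmiFamily,
    site: int,
    cfg: ConsensusConfig = ConsensusConfig(),
    ref_seq: str | None = None,
) -> str | Consensus:
    """Consensus allele of one UMI family at a genomic site.

    High-quality reads have base quality >= ``min_base_quality`` at the
    site, mapping quality >= ``min_mapping_quality``, at most
    ``max_mismatches`` reference mismatches, and — when the site sits in a
    reference homopolymer of ``homopolymer_min_run`` or more — fully span
    the run plus one flanking base on each side.
    """
    covering = [r for r in family.reads if r.base_at(site) is not None]
    if not covering:
        return Consensus.NOT_COVERED
    if family.read_count == 1:
        return Consensus.EXCLUDED_SINGLETON

    hp_span: tuple[int, int] | None = None
    if ref_seq is not None:
        lo, hi = _homopolymer_run(ref_seq, site)
        if hi - lo >= cfg.homopolymer_min_run:
            hp_span = (lo - 1, hi + 1)

    counts: collections.Counter = collections.Counter()
    hq_counts: collections.Counter = collections.Counter()
    n_hq = 0
    for r in covering:
        base = r.base_at(site)
        counts[base] += 1
        hq = (
            r.qual_at(site) >= cfg.min_base_quality
            and r.mapping_quality >= cfg.min_mapping_quality
            and r.mismatch_count <= cfg.max_mismatches
            and (hp_span is None or r.covers(hp_span[0], hp_span[1]))
        )
        if hq:
            n_hq += 1
            hq_counts[base] += 1

    # deterministic majority: highest count, ties by base order
    allele = min(counts, key=lambda b: (-counts[b], b))
    if counts[allele] < cfg.min_allele_fraction * len(covering):
        return Consensus.NO_CONSENSUS
    if n_hq == 0 or hq_counts[allele] < cfg.min_hq_fraction * n_hq:
        return Consensus.NO_CONSENSUS
    return allele


def duplex_consensus(
    group: DuplexGroup,
    site: int,
    cfg: ConsensusConfig = ConsensusConfig(),
    ref_seq: str | None = None,
) -> str | Consensus:
    """Joint consensus of the two strand families of a duplex group.

    Both strands must individually reach a consensus and agree; opposite
    consensus alleles are DISCORDANT (the single-strand-artifact signature).
    A duplex observation requires the site on both strands, so the group is
    NOT_COVERED unless both families cover it.
    """
    if group.classification != "DUPLEX":
        raise ValueError("duplex_consensus requires a DUPLEX group")
    top = family_consensus(group.top_family, site, cfg, ref_seq)
    bottom = family_consensus(group.bottom_family, site, cfg, ref_seq)
    if Consensus.NOT_COVERED in (top, bottom):
        return Consensus.NOT_COVERED
    if isinstance(top, Consensus) or isinstance(bottom, Consensus):
        return Consensus.NO_CONSENSUS
    if top != bottom:
        return Consensus.DISCORDANT
    return top


def site_counts(
    groups: list[DuplexGroup],
    site: int,
    ref_base: str,
    cfg: ConsensusConfig = ConsensusConfig(),
    ref_seq: str | None = None,
) -> SiteCounts:
    """Qualified duplex/single-plex UMI counts at one site.

    N2 counts concordant duplex groups (n2 of them non-reference), N1
    consensus-reaching single-plex families (n1 non-reference); discordant
    duplexes are excluded from both and tallied separately.  The reported
    alt allele is the most frequent non-reference consensus, ties broken
    alphabetically.
    """
    N1 = n1 = N2 = n2 = disc = 0
    alt_counts: collections.Counter = collections.Counter()
    chrom = groups[0].families[0].chrom if groups else ""
    for g in groups:
        if g.classification == "DUPLEX":
            res = duplex_consensus(g, site, cfg, ref_seq)
            if res is Consensus.DISCORDANT:
                disc += 1
            elif isinstance(res, str):
                N2 += 1
                if res != ref_base:
                    n2 += 1
                    alt_counts[res] += 1
        else:
            res = family_consensus(g.lone_family, site, cfg, ref_seq)
            if isinstance(res, str):
                N1 += 1
                if res != ref_base:
                    n1 += 1
                    alt_counts[res] += 1
    alt = min(alt_counts, key=lambda b: (-alt_counts[b], b)) if alt_counts else None
    return SiteCounts(chrom, site, ref_base, N1, n1, N2, n2, alt, disc)


_BASE_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_LUT[ord(_b)] = _i


class _FamilyPileup:
    """Per-position base/HQ counts of one family, built once and queried per site.

    Produces the same consensus outcome as :func:`family_consensus` for
    sites outside reference homopolymers (verified by tests); homopolymer
    sites fall back to the read-level path.
    """

    __slots__ = ("start", "end", "cov", "counts", "hq_counts", "hq_tot", "singleton")

    def __init__(self, fam: UmiFamily, cfg: ConsensusConfig) -> None:
        self.singleton = fam.read_count == 1
        self.start = min(r.start for r in fam.reads)
        self.end = max(r.start + len(r.seq) for r in fam.reads)
        L = self.end - self.start
        self.cov = np.zeros(L, dtype=np.int32)
        self.counts = np.zeros((5, L), dtype=np.int32)
        self.hq_counts = np.zeros((5, L), dtype=np.int32)
        self.hq_tot = np.zeros(L, dtype=np.int32)
        for r in fam.reads:
            idx = _BASE_LUT[np.frombuffer(r.seq.encode(), dtype=np.uint8)]
            off = r.start - self.start
            pos = np.arange(off, off + len(idx))
            self.cov[off : off + len(idx)] += 1
            np.add.at(self.counts, (idx, pos), 1)
            if (
                r.mapping_quality >= cfg.min_mapping_quality
                and r.mismatch_count <= cfg.max_mismatches
            ):
                qmask = np.asarray(r.quals) >= cfg.min_base_quality
                self.hq_tot[off : off + len(idx)] += qmask
                np.add.at(self.hq_counts, (idx[qmask], pos[qmask]), 1)

    def consensus(self, site: int, cfg: ConsensusConfig) -> str | Consensus:
        j = site - self.start
        if not 0 <= j < self.end - self.start or self.cov[j] == 0:
            return Consensus.NOT_COVERED
        if self.singleton:
            return Consensus.EXCLUDED_SINGLETON
        col = self.counts[:, j]
        k = int(np.argmax(col))  # first max wins = base-order tie-break
        if col[k] < cfg.min_allele_fraction * self.cov[j]:
            return Consensus.NO_CONSENSUS
        hq_tot = self.hq_tot[j]
        if hq_tot == 0 or self.hq_counts[k, j] < cfg.min_hq_fraction * hq_tot:
            return Consensus.NO_CONSENSUS
        if k == 4:
            return Consensus.NO_CONSENSUS  # non-ACGT majority is uncallable
        return BASES[k]


def _homopolymer_sites(ref_seq: str, start: int, end: int, min_run: int) -> set[int]:
    """Target sites lying in a reference homopolymer run of >= min_run."""
    sites: set[int] = set()
    i = max(0, start - 32)
    while i < min(len(ref_seq), end + 32):
        j = i + 1
        while j < len(ref_seq) and ref_seq[j] == ref_seq[i]:
            j += 1
        if j - i >= min_run:
            sites.update(range(max(i, start), min(j, end)))
        i = j
    return sites


def compute_site_counts(
    groups: list[DuplexGroup],
    panel: PanelDesign,
    cfg: ConsensusConfig = ConsensusConfig(),
) -> pd.DataFrame:
    """Count tables over every target site of the panel.

    Returns one row per site with the caller-facing group-level counts
    (N1, n1, N2, n2, discordant, alt) and the error-model-facing
    family-level counts (N families with consensus, per-base non-reference
    family counts n_A..n_T).
    """
    by_locus: dict[str, list[DuplexGroup]] = collections.defaultdict(list)
    for g in groups:
        by_locus[g.locus_id].append(g)

    rows = []
    for locus in panel.loci:
        locus_groups = by_locus.get(locus.locus_id, [])
        ref_seq = panel.reference[locus.chrom]
        pileups = {
            id(fam): _FamilyPileup(fam, cfg)
            for g in locus_groups
            for fam in g.families
        }
        hp_sites = _homopolymer_sites(
            ref_seq, locus.target_start, locus.target_end, cfg.homopolymer_min_run
        )
        fams = [(id(fam), fam) for g in locus_groups for fam in g.families]
        for site in locus.target_sites():
            ref_base = ref_seq[site]
            # one consensus evaluation per family, reused for both tables;
            # homopolymer sites need the read-level span check
            if site in hp_sites:
                fam_res = {fid: family_consensus(f, site, cfg, ref_seq) for fid, f in fams}
            else:
                fam_res = {fid: pileups[fid].consensus(site, cfg) for fid, f in fams}
            N1 = n1 = N2 = n2 = disc = 0
            alt_counts: collections.Counter = collections.Counter()
            fam_n = 0
            fam_alt: collections.Counter = collections.Counter()
            for g in locus_groups:
                if g.classification == "DUPLEX":
                    top = fam_res[id(g.top_family)]
                    bot = fam_res[id(g.bottom_family)]
                    if Consensus.NOT_COVERED in (top, bot):
                        pass
                    elif isinstance(top, Consensus) or isinstance(bot, Consensus):
                        pass
                    elif top != bot:
                        disc += 1
                    else:
                        N2 += 1
                        if top != ref_base:
                            n2 += 1
                            alt_counts[top] += 1
                else:
                    res = fam_res[id(g.lone_family)]
                    if isinstance(res, str):
                        N1 += 1
                        if res != ref_base:
                            n1 += 1
                            alt_counts[res] += 1
            for res in fam_res.values():
                if isinstance(res, str):
                    fam_n += 1
                    if res != ref_base:
                        fam_alt[res] += 1
            alt = (
                min(alt_counts, key=lambda b: (-alt_counts[b], b)) if alt_counts else None
            )
            sc = SiteCounts(locus.chrom, site, ref_base, N1, n1, N2, n2, alt, disc)
            row = {
                "chrom": locus.chrom,
                "pos": site,
                "locus_id": locus.locus_id,
                "ref": ref_base,
                "alt": sc.alt_allele,
                "N1": sc.N1,
                "n1": sc.n1,
                "N2": sc.N2,
                "n2": sc.n2,
                "discordant": sc.discordant,
                "N_fam": fam_n,
            }
            for b in BASES:
                row[f"n_{b}"] = fam_alt.get(b, 0)
            rows.append(row)
    return pd.DataFrame(rows)
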