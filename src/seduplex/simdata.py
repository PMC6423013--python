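"""Synthetic single-end duplex-UMI amplicon libraries with known truth.

The generator emulates a targeted SPE (single primer extension) library made
from an in-vitro reference mixture: a diploid-like pool of ~170 bp fragments
carrying known SNVs at low allele fraction, strand-specific base damage
(e.g. oxidative G>T, observed as C>A on the opposite template), end-repair
copying of damage lesions near the ligated fragment end, per-strand capture
that yields a duplex share of roughly ``s/(2-s)``, and UMI families of
``1 + Poisson(mean-1)`` reads.

Two levels are provided:

* read level — :func:`simulate_molecules` / :func:`tag_and_sequence` emit
  paired FASTQ plus a truth table, so the whole pipeline can run without an
  external aligner;
* consensus-count level — :func:`simulate_site_counts` /
  :func:`simulate_damage_site_counts` draw per-site qualified-UMI counts
  directly, for caller-scale experiments at full panel depth.

Design notes: strand sequences are stored *as sequenced* in top-strand
coordinates, so an undamaged molecule has identical top and bottom
sequences; a single-strand lesion differs on exactly one of them.  Damage is
applied before tagging (UMI-consistent), PCR error per family founder after
tagging (UMI-inconsistent) — the distinction duplex consensus exploits.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .layout import DEFAULT_LAYOUT, ReadLayout
from .panel import BASES, Locus, PanelDesign, revcomp

#: the 12 ordered base-substitution types (as-sequenced expected>alternative)
SUBSTITUTION_TYPES = [f"{r}>{a}" for r in BASES for a in BASES if r != a]

#: Beta law of per-site background substitution rates used by the
#: count-level simulations: mean alpha/(alpha+beta) = 5e-5, the magnitude of
#: the dominant (G>A) background type under mild sonication.
DEFAULT_NULL_ALPHA = 2.0
DEFAULT_NULL_BETA = 39998.0

_B2I = {b: i for i, b in enumerate(BASES)}
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    allele_fraction: float


@dataclass
class SampleProfile:
    """What the simulated DNA sample looks like before library prep."""

    variant_sites: list[Variant] = field(default_factory=list)
    #: per-base per-strand lesion probability for each substitution type
    damage_rate_per_type: dict[str, float] = field(default_factory=dict)
    #: lesions within this many bp of the ligated end are copied to the
    #: complementary strand during end repair (0 disables copying)
    end_repair_copy_distance: int = 15
    fragment_length_mean: float = 170.0
    fragment_length_sd: float = 15.0

    def __post_init__(self) -> None:
        for v in self.variant_sites:
            if not 0.0 < v.allele_fraction < 1.0:
                raise ValueError(f"allele fraction must be in (0,1): {v}")
        for t, r in self.damage_rate_per_type.items():
            if t not in SUBSTITUTION_TYPES:
                raise ValueError(f"unknown substitution type {t!r}")
            if not 0.0 <= r <= 0.01:
                raise ValueError(f"damage rate out of [0, 0.01]: {t}={r}")
        if self.end_repair_copy_distance < 0:
            raise ValueError("end_repair_copy_distance must be >= 0")


@dataclass
class SimConfig:
    molecules_per_locus: int = 1000
    #: probability that each strand of a tagged molecule yields a read family;
    #: 0.387 gives a duplex share s/(2-s) ~ 0.24 of observed UMIs
    strand_capture_prob: float = 0.387
    reads_per_family_mean: float = 4.5
    sequencing_error_rate: float = 0.0
    pcr_error_rate: float = 0.0
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.strand_capture_prob <= 1.0:
            raise ValueError("strand_capture_prob must be in (0, 1]")
        if self.reads_per_family_mean < 1.0:
            raise ValueError("reads_per_family_mean must be >= 1")
        for name in ("sequencing_error_rate", "pcr_error_rate"):
            if not 0.0 <= getattr(self, name) <= 0.1:
                raise ValueError(f"{name} must be in [0, 0.1]")


@dataclass(frozen=True)
class Lesion:
    pos: int  # 0-based genomic
    ref: str
    alt: str
    strand: str  # 'TOP' or 'BOTTOM' (the strand where the lesion arose)
    copied: bool


@dataclass
class Molecule:
    molecule_id: str
    locus_id: str
    chrom: str
    frag_start: int  # ligated (UMI-bearing) 5' end, 0-based
    frag_end: int  # primer-anchor end, exclusive
    umi: str
    top: np.ndarray  # as-sequenced bases, uint8 ASCII, top coordinates
    bottom: np.ndarray
    variants: list[tuple[int, str]] = field(default_factory=list)
    lesions: list[Lesion] = field(default_factory=list)

    @property
    def frag_pos(self) -> int:
        return self.frag_start

    def strand_seq(self, strand: str) -> np.ndarray:
        return self.top if strand == "TOP" else self.bottom


@dataclass
class SimulatedRead:
    read_id: str
    read1: str
    qual1: str
    read2: str
    qual2: str


@dataclass
class TruthTable:
    """Ground truth emitted alongside simulated reads.

    ``reads``: read_id, chrom, start (0-based genomic start of the insert),
    strand_label, locus_id, umi, frag_pos, molecule_id.
    ``molecules``: per-molecule capture status.
    ``events``: every planted variant allele and damage lesion.
    """

    reads: pd.DataFrame
    molecules: pd.DataFrame
    events: pd.DataFrame


def _random_umis(rng: np.random.Generator, n: int, k: int = 12) -> list[str]:
    arr = rng.integers(0, 4, size=(n, k))
    return ["".join(BASES[i] for i in row) for row in arr]


def simulate_molecules(
    panel: PanelDesign, sample: SampleProfile, config: SimConfig
) -> list[Molecule]:
    """Draw tagged duplex molecules for every locus of the panel.

    Each molecule gets a random 12-mer UMI shared by both strands, a
    fragmentation position (fragment length ~ Normal, truncated at 50 bp)
    with the ligated end opposite the primer anchor, variant alleles on both
    strands with probability equal to the allele fraction, per-strand damage
    lesions, and end-repair copying of lesions near the ligated end.
    """
    if not panel.loci:
        raise ValueError("empty panel")
    rng = np.random.default_rng([config.seed, 0])
    molecules: list[Molecule] = []
    for locus in panel.loci:
        ref = np.frombuffer(panel.reference[locus.chrom].encode(), dtype=np.uint8)
        locus_variants = [
            v
            for v in sample.variant_sites
            if v.chrom == locus.chrom and locus.target_start <= v.pos < locus.target_end
        ]
        n = config.molecules_per_locus
        lengths = np.maximum(
            50,
            np.rint(
                rng.normal(sample.fragment_length_mean, sample.fragment_length_sd, size=n)
            ).astype(int),
        )
        umis = _random_umis(rng, n)
        for m in range(n):
            frag_end = locus.primer_start
            frag_start = max(0, frag_end - int(lengths[m]))
            top = ref[frag_start:frag_end].copy()
            bottom = top.copy()
            mol = Molecule(
                molecule_id=f"{locus.locus_id}.{m}",
                locus_id=locus.locus_id,
                chrom=locus.chrom,
                frag_start=frag_start,
                frag_end=frag_end,
                umi=umis[m],
                top=top,
                bottom=bottom,
            )
            for v in locus_variants:
                if frag_start <= v.pos < frag_end and rng.random() < v.allele_fraction:
                    off = v.pos - frag_start
                    alt = ord(v.alt)
                    top[off] = alt
                    bottom[off] = alt
                    mol.variants.append((v.pos, v.alt))
            if sample.damage_rate_per_type:
                _apply_damage(mol, sample, rng)
            molecules.append(mol)
    return molecules


def _apply_damage(mol: Molecule, sample: SampleProfile, rng: np.random.Generator) -> None:
    length = mol.frag_end - mol.frag_start
    for strand, seq in (("TOP", mol.top), ("BOTTOM", mol.bottom)):
        for subst, rate in sample.damage_rate_per_type.items():
            if rate <= 0.0:
                continue
            ref_b, alt_b = ord(subst[0]), ord(subst[2])
            hits = np.flatnonzero((seq == ref_b) & (rng.random(length) < rate))
            for off in hits:
                seq[off] = alt_b
                mol.lesions.append(
                    Lesion(mol.frag_start + int(off), subst[0], subst[2], strand, False)
                )
    if sample.end_repair_copy_distance > 0 and mol.lesions:
        copied: list[Lesion] = []
        for les in mol.lesions:
            if les.pos - mol.frag_start < sample.end_repair_copy_distance:
                other = mol.bottom if les.strand == "TOP" else mol.top
                other[les.pos - mol.frag_start] = ord(les.alt)
                copied.append(Lesion(les.pos, les.ref, les.alt, les.strand, True))
            else:
                copied.append(les)
        mol.lesions = copied


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute bases uniformly at the given per-base rate."""
    if rate <= 0.0:
        return seq
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for off in hits:
        choices = _BASE_ARR[_BASE_ARR != out[off]]
        out[off] = rng.choice(choices)
    return out


def tag_and_sequence(
    molecules: list[Molecule],
    config: SimConfig,
    panel: PanelDesign,
    layout: ReadLayout = DEFAULT_LAYOUT,
) -> tuple[list[SimulatedRead], TruthTable]:
    """Capture strands, amplify and sequence, emitting reads plus truth.

    Each strand of a molecule is captured independently with probability
    ``strand_capture_prob``; a captured strand becomes a UMI family of
    ``1 + Poisson(reads_per_family_mean - 1)`` reads.  PCR error is applied
    once to the family founder copy, sequencing error per read.
    """
    if config.strand_capture_prob <= 0.0:
        raise ValueError("strand_capture_prob must be positive to produce output")
    rng = np.random.default_rng([config.seed, 1])
    max_insert = config.read_length - layout.insert_offset
    primer_cache = {loc.locus_id: panel.primer_sequence(loc) for loc in panel.loci}
    qual_char = "I"  # Q40 everywhere; realistic quality models are out of scope

    reads: list[SimulatedRead] = []
    read_rows: list[tuple] = []
    mol_rows: list[tuple] = []
    for mol in molecules:
        captured = {}
        for strand in ("TOP", "BOTTOM"):
            captured[strand] = bool(rng.random() < config.strand_capture_prob)
        mol_rows.append(
            (
                mol.molecule_id,
                mol.locus_id,
                mol.chrom,
                mol.umi,
                mol.frag_pos,
                captured["TOP"],
                captured["BOTTOM"],
            )
        )
        for strand in ("TOP", "BOTTOM"):
            if not captured[strand]:
                continue
            insert = mol.strand_seq(strand)[:max_insert]
            founder = _mutate(insert, config.pcr_error_rate, rng)
            n_reads = 1 + int(rng.poisson(config.reads_per_family_mean - 1.0))
            prefix = layout.prefix(mol.umi, strand)
            primer = primer_cache[mol.locus_id]
            for j in range(n_reads):
                obs = _mutate(founder, config.sequencing_error_rate, rng)
                insert_str = obs.tobytes().decode()
                read1 = prefix + insert_str
                read2 = (primer + revcomp(insert_str))[: config.read_length]
                rid = f"{mol.molecule_id}:{strand[0]}:{j}"
                reads.append(
                    SimulatedRead(
                        rid, read1, qual_char * len(read1), read2, qual_char * len(read2)
                    )
                )
                read_rows.append(
                    (
                        rid,
                        mol.chrom,
                        mol.frag_start,
                        strand,
                        mol.locus_id,
                        mol.umi,
                        mol.frag_pos,
                        mol.molecule_id,
                    )
                )

    event_rows = []
    for mol in molecules:
        for pos, alt in mol.variants:
            event_rows.append(
                (mol.molecule_id, mol.chrom, pos, "variant", alt, "BOTH", False,
                 pos - mol.frag_start)
            )
        for les in mol.lesions:
            event_rows.append(
                (mol.molecule_id, mol.chrom, les.pos, "lesion", les.alt, les.strand,
                 les.copied, les.pos - mol.frag_start)
            )

    truth = TruthTable(
        reads=pd.DataFrame(
            read_rows,
            columns=[
                "read_id", "chrom", "start", "strand_label", "locus_id", "umi",
                "frag_pos", "molecule_id",
            ],
        ),
        molecules=pd.DataFrame(
            mol_rows,
            columns=[
                "molecule_id", "locus_id", "chrom", "umi", "frag_pos",
                "captured_top", "captured_bottom",
            ],
        ),
        events=pd.DataFrame(
            event_rows,
            columns=["molecule_id", "chrom", "pos", "kind", "alt", "strand",
                     "copied", "end_distance"],
        ),
    )
    return reads, truth


# --------------------------------------------------------------------- I/O


def write_fastq(reads: list[SimulatedRead], path1: str | Path, path2: str | Path) -> None:
    """Write paired FASTQ; gzip if the path ends in ``.gz``."""
    for path, which in ((path1, 1), (path2, 2)):
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(str(path), "wt") as fh:
            for r in reads:
                seq = r.read1 if which == 1 else r.read2
                qual = r.qual1 if which == 1 else r.qual2
                fh.write(f"@{r.read_id}\n{seq}\n+\n{qual}\n")


def write_truth_alignment(truth: TruthTable, path: str | Path) -> None:
    truth.reads.to_csv(path, sep="\t", index=False)


def read_truth_alignment(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(
    sample: SampleProfile,
    panel: PanelDesign,
    vcf_path: str | Path,
    bed_path: str | Path | None = None,
) -> None:
    """Write planted variants as VCF (AF in INFO) and targets as BED."""
    header = pysam.VariantHeader()
    header.add_line('##source=seduplex-simulate')
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Planted allele fraction">')
    for chrom, seq in panel.reference.items():
        header.contigs.add(chrom, length=len(seq))
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vcf:
        for v in sorted(sample.variant_sites, key=lambda v: (v.chrom, v.pos)):
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos, stop=v.pos + 1, alleles=(v.ref, v.alt)
            )
            rec.info["AF"] = v.allele_fraction
            vcf.write(rec)
    if bed_path is not None:
        panel.write_bed(bed_path)


def read_truth_vcf(path: str | Path) -> pd.DataFrame:
    """Truth VCF back as a table with 0-based positions."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            af = rec.info.get("AF", (float("nan"),))
            rows.append((rec.contig, rec.start, rec.ref, rec.alts[0], float(af[0])))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "allele_fraction"])


# ----------------------------------------------- consensus-count simulators


def _capture_split(
    m: np.ndarray, s: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split molecule counts into (duplex, single-strand) captures.

    Both strands captured with probability s^2; exactly one with 2s(1-s).
    """
    duplex = rng.binomial(m, s * s)
    rest = m - duplex
    p_single = 2 * s * (1 - s) / (1 - s * s) if s < 1.0 else 0.0
    single = rng.binomial(rest, p_single)
    return duplex, single


def simulate_site_counts(
    n_variant_sites: int,
    n_wt_sites: int,
    mean_depth: float,
    duplex_fraction: float,
    vaf: float,
    alpha: float = DEFAULT_NULL_ALPHA,
    beta: float = DEFAULT_NULL_BETA,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Per-site qualified-UMI counts for a clean reference-mixture run.

    Skips the read level: the per-site UMI total is Poisson around
    ``mean_depth`` with a binomial duplex share; variant sites draw alt UMIs
    binomially at the planted VAF on both UMI classes, wild-type sites draw
    single-plex alt counts from the Beta-Binomial background (per-site rate
    ~ Beta(alpha, beta)) and duplex alt counts at the squared per-site rate
    (an error must recur on both strands to gain duplex support).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = n_variant_sites + n_wt_sites
    is_variant = np.zeros(n, dtype=bool)
    is_variant[:n_variant_sites] = True
    N = rng.poisson(mean_depth, size=n)
    N2 = rng.binomial(N, duplex_fraction)
    N1 = N - N2
    n1 = np.zeros(n, dtype=int)
    n2 = np.zeros(n, dtype=int)
    n1[is_variant] = rng.binomial(N1[is_variant], vaf)
    n2[is_variant] = rng.binomial(N2[is_variant], vaf)
    p_bg = rng.beta(alpha, beta, size=n_wt_sites)
    n1[~is_variant] = rng.binomial(N1[~is_variant], p_bg)
    n2[~is_variant] = rng.binomial(N2[~is_variant], p_bg**2)
    return pd.DataFrame(
        {"site": np.arange(n), "is_variant": is_variant, "N1": N1, "n1": n1,
         "N2": N2, "n2": n2}
    )


def simulate_damage_site_counts(
    n_variant_sites: int,
    n_wt_sites: int,
    molecules_per_site: float,
    capture_prob: float,
    vaf: float,
    damage_rate: float,
    copied_fraction: float = 0.0,
    damage_dispersion: float | None = 0.25,
    alpha: float = DEFAULT_NULL_ALPHA,
    beta: float = DEFAULT_NULL_BETA,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Molecule-level count simulation with strand-specific damage.

    Each site has ~Poisson ``molecules_per_site`` duplex molecules; variant
    sites carry the alt on both strands of a binomial fraction ``vaf``.
    Damage hits one strand per lesion at mean per-strand rate
    ``damage_rate``; the per-site rate is Beta-distributed with shape
    ``damage_dispersion`` (hotspot-like site-to-site variation, as seen for
    sonication/oxidation artifacts; ``None`` for a uniform rate).  A
    fraction ``copied_fraction`` of lesions is copied to the second strand
    (the end-repair artifact), gaining duplex support.  Capture, consensus
    and duplex pairing are collapsed to their exact category probabilities:
    single-strand-damaged molecules captured on both strands become
    discordant duplexes (excluded, tallied), captured on the damaged strand
    alone become alt single-plex UMIs.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    s = capture_prob
    n = n_variant_sites + n_wt_sites
    is_variant = np.zeros(n, dtype=bool)
    is_variant[:n_variant_sites] = True

    M = rng.poisson(molecules_per_site, size=n)
    m_var = np.where(is_variant, rng.binomial(M, vaf), 0)
    if damage_dispersion is not None and damage_rate > 0:
        a_d = damage_dispersion
        b_d = a_d * (1.0 - damage_rate) / damage_rate
        site_damage = rng.beta(a_d, b_d, size=n)
    else:
        site_damage = np.full(n, damage_rate)
    # per-molecule probability of >=1 lesion on either strand ~ 2*rate
    m_dmg = rng.binomial(M - m_var, np.minimum(1.0, 2.0 * site_damage))
    m_cop = rng.binomial(m_dmg, copied_fraction)
    m_dmg_ss = m_dmg - m_cop
    m_ref = M - m_var - m_dmg

    dup_ref, sgl_ref = _capture_split(m_ref, s, rng)
    dup_var, sgl_var = _capture_split(m_var + m_cop, s, rng)
    dup_dmg, sgl_dmg = _capture_split(m_dmg_ss, s, rng)

    N2 = dup_ref + dup_var
    n2 = dup_var.copy()
    sgl_dmg_alt = rng.binomial(sgl_dmg, 0.5)  # captured strand is damaged half the time
    N1 = sgl_ref + sgl_var + sgl_dmg
    n1 = sgl_var + sgl_dmg_alt

    # independent background (pre-tagging polymerase/lesion) noise
    p_bg = rng.beta(alpha, beta, size=n)
    n1 = n1 + rng.binomial(N1 - n1, p_bg)
    n2 = n2 + rng.binomial(N2 - n2, p_bg**2)

    # family-level view for error-model fitting: every strand family is one
    # observation (duplex groups contribute two, discordant pairs one alt)
    N_fam = N1 + 2 * N2 + 2 * dup_dmg
    n_fam = n1 + 2 * n2 + dup_dmg
    return pd.DataFrame(
        {"site": np.arange(n), "is_variant": is_variant, "N1": N1, "n1": n1,
         "N2": N2, "n2": n2, "discordant": dup_dmg, "N_fam": N_fam, "n_fam": n_fam}
    )


def event_end_distances(molecules: list[Molecule]) -> tuple[np.ndarray, np.ndarray]:
    """Distances (bp) from the ligated 5' end for artifact and variant alleles.

    Artifacts are the duplex-supported lesions (those copied during end
    repair); variants are the planted true alleles.  Mirrors the
    distance-to-UMI-end comparison used to diagnose end-repair artifacts.
    """
    artifact, variant = [], []
    for mol in molecules:
        for les in mol.lesions:
            if les.copied:
                artifact.append(les.pos - mol.frag_start)
        for pos, _alt in mol.variants:
            variant.append(pos - mol.frag_start)
    return np.asarray(artifact, dtype=float), np.asarray(variant, dtype=float)
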