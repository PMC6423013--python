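"""Reference-mixture evaluation experiments.

These functions reproduce, on synthetic data, the evaluation designs used to
characterise the assay: clean simulations matched to the 0.1%/0.2% GIAB
reference-mixture runs (87 true SNV sites over a ~17.8 kb panel at mean UMI
depths around 14,000–17,000 with a ~23–24% duplex share), the duplex-vs-
single-plex comparison under strand-specific damage, a zero-noise end-to-end
pipeline run, and the end-repair artifact distance signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .caller import (
    CallerConfig,
    fp_at_sensitivity,
    llr_scores,
    roc_sweep,
    sensitivity_at_fp,
)
from .consensus import ConsensusConfig
from .error_model import ErrorDistribution, end_distance_test, fit_beta
from .panel import random_panel
from .pipeline import process_tagged_reads
from .simdata import (
    DEFAULT_NULL_ALPHA,
    DEFAULT_NULL_BETA,
    SampleProfile,
    SimConfig,
    Variant,
    event_end_distances,
    simulate_damage_site_counts,
    simulate_molecules,
    simulate_site_counts,
    tag_and_sequence,
)
from .umi import TaggedRead

#: fitted-null error model at the background magnitude of the dominant
#: substitution type (mean 5e-5)
DEFAULT_NULL = ErrorDistribution(
    beta_alpha=DEFAULT_NULL_ALPHA, beta_beta=DEFAULT_NULL_BETA
)

#: panel geometry of the GIAB-mixture evaluation: 87 SNV sites in a
#: 17,859 bp target region (17,772 wild-type sites)
GIAB_N_VARIANT_SITES = 87
GIAB_N_WT_SITES = 17_772


def reference_mixture_sensitivity(
    mean_depth: float,
    duplex_fraction: float,
    vaf: float,
    max_fp: int = 0,
    n_variant_sites: int = GIAB_N_VARIANT_SITES,
    n_wt_sites: int = GIAB_N_WT_SITES,
    n_seeds: int = 5,
    seed: int = 0,
    em: ErrorDistribution = DEFAULT_NULL,
) -> float:
    """Mean sensitivity at the at-most-``max_fp``-FP operating point.

    Simulates per-site qualified UMI counts for a clean reference-mixture
    run, scores every site with the duplex LLR, sets the threshold to the
    smallest value with at most ``max_fp`` wild-type calls, and averages the
    fraction of variant sites called over ``n_seeds`` replicates.
    """
    sens = []
    for k in range(n_seeds):
        rng = np.random.default_rng([seed, k])
        df = simulate_site_counts(
            n_variant_sites, n_wt_sites, mean_depth, duplex_fraction, vaf,
            alpha=em.beta_alpha, beta=em.beta_beta, rng=rng,
        )
        df["llr"] = llr_scores(df["N1"], df["n1"], df["N2"], df["n2"], em)
        sens.append(sensitivity_at_fp(roc_sweep(df), max_fp))
    return float(np.mean(sens))


@dataclass
class DuplexAdvantageResult:
    duplex_fp: list[int]
    singleplex_fp: list[int]

    @property
    def win_fraction(self) -> float:
        wins = sum(d < s for d, s in zip(self.duplex_fp, self.singleplex_fp))
        return wins / len(self.duplex_fp)


def duplex_advantage(
    n_seeds: int = 20,
    seed: int = 0,
    vaf: float = 0.002,
    molecules_per_site: float = 24_000,
    capture_prob: float = 0.387,
    damage_rate: float = 2.5e-4,  # 5x the 5e-5 background mean
    n_variant_sites: int = GIAB_N_VARIANT_SITES,
    n_wt_sites: int = 3_000,
    target_sensitivity: float = 0.9,
) -> DuplexAdvantageResult:
    """False positives of DUPLEX vs SINGLEPLEX calling at matched sensitivity.

    Each replicate simulates molecule-level counts with hotspot-like
    strand-specific damage, fits the Beta-Binomial null on the wild-type
    family-level counts (as a real analysis would, from the same library),
    and records the fewest false positives each mode attains at the target
    sensitivity.  Single-strand damage inflates the single-plex channel but
    is excluded from duplex counts by strand discordance, so the duplex
    caller separates variants from damage where the single-plex caller
    cannot.
    """
    dup_fp, sgl_fp = [], []
    for k in range(n_seeds):
        rng = np.random.default_rng([seed, k])
        df = simulate_damage_site_counts(
            n_variant_sites, n_wt_sites, molecules_per_site, capture_prob,
            vaf, damage_rate, rng=rng,
        )
        wt = df[~df["is_variant"]]
        fit = fit_beta(wt["n_fam"].to_numpy(), wt["N_fam"].to_numpy())
        em = ErrorDistribution(beta_alpha=fit.alpha, beta_beta=fit.beta)
        for mode, out in (("DUPLEX", dup_fp), ("SINGLEPLEX", sgl_fp)):
            scored = df.copy()
            scored["llr"] = llr_scores(
                df["N1"], df["n1"], df["N2"], df["n2"], em, CallerConfig(mode=mode)
            )
            out.append(fp_at_sensitivity(roc_sweep(scored), target_sensitivity))
    return DuplexAdvantageResult(dup_fp, sgl_fp)


@dataclass
class ZeroNoiseResult:
    duplex_fraction: float
    expected_duplex_fraction: float
    n_true_sites: int
    n_true_called: int
    n_false_positives: int


def zero_noise_pipeline(
    seed: int = 0,
    n_loci: int = 6,
    molecules_per_locus: int = 1_650,
    vaf: float = 0.02,
    capture_prob: float = 0.387,
    em: ErrorDistribution = DEFAULT_NULL,
    llr_threshold: float = 6.0,
) -> ZeroNoiseResult:
    """Full FASTQ-level pipeline run with zero sequencing/PCR error.

    Plants one SNV per locus and runs simulate -> decode -> group -> merge ->
    pair -> consensus -> call.  With no read errors the recovered duplex
    share must match s/(2-s) and every planted variant must be called with
    no false positives.  The VAF is scaled to the molecule count so each
    variant is represented by the same tens-of-molecules evidence as a 0.2%
    variant at full (14,000 UMI) depth.
    """
    panel = random_panel(n_loci=n_loci, target_length=70, seed=seed)
    ref = panel.reference
    variants = []
    rng = np.random.default_rng([seed, 99])
    for loc in panel.loci:
        pos = int(loc.target_start + 10 + rng.integers(0, loc.target_end - loc.target_start - 20))
        ref_base = ref[loc.chrom][pos]
        alt = next(b for b in "ACGT" if b != ref_base)
        variants.append(Variant(loc.chrom, pos, ref_base, alt, vaf))
    sample = SampleProfile(variant_sites=variants)
    config = SimConfig(
        molecules_per_locus=molecules_per_locus,
        strand_capture_prob=capture_prob,
        reads_per_family_mean=4.5,
        sequencing_error_rate=0.0,
        pcr_error_rate=0.0,
        seed=seed,
    )
    molecules = simulate_molecules(panel, sample, config)
    reads, truth = tag_and_sequence(molecules, config, panel)

    # decode from the read sequences themselves; coordinates from truth
    from .umi import extract_umi_strand

    aln = truth.reads.set_index("read_id")
    tagged = []
    for r in reads:
        decoded = extract_umi_strand(r.read1)
        umi, strand, offset = decoded  # zero-noise reads always decode
        row = aln.loc[r.read_id]
        insert = r.read1[offset:]
        tagged.append(
            TaggedRead(
                read_id=r.read_id, umi=umi, strand_label=strand,
                locus_id=row["locus_id"], chrom=row["chrom"],
                frag_pos=int(row["frag_pos"]), start=int(row["start"]),
                seq=insert, quals=[40] * len(insert),
            )
        )
    result = process_tagged_reads(tagged, panel, consensus_cfg=ConsensusConfig())
    counts = result.site_counts
    counts["llr"] = llr_scores(counts["N1"], counts["n1"], counts["N2"], counts["n2"], em)
    n_alt = counts["n1"] + counts["n2"]
    called = (counts["llr"] >= llr_threshold) & (n_alt >= 2)
    truth_sites = {(v.chrom, v.pos) for v in variants}
    site_keys = list(zip(counts["chrom"], counts["pos"]))
    is_true = np.array([k in truth_sites for k in site_keys])
    s = capture_prob
    return ZeroNoiseResult(
        duplex_fraction=result.duplex_fraction,
        expected_duplex_fraction=s / (2 - s),
        n_true_sites=len(truth_sites),
        n_true_called=int((called & is_true).sum()),
        n_false_positives=int((called & ~is_true).sum()),
    )


def end_repair_signature(
    n_seeds: int = 5,
    seed: int = 0,
    copy_distance: int = 15,
    damage_rate: float = 1e-3,
    molecules_per_locus: int = 400,
    vaf: float = 0.3,
) -> list[float]:
    """One-sided t-test p-values: artifact vs variant distance to the 5' end.

    Simulates ~170 bp fragments with C>A damage and end-repair copying
    within ``copy_distance`` of the ligated end; duplex-supported artifacts
    (copied lesions) cluster near the end while true variants are spread
    across the insert, so the p-values sit below 0.5.
    """
    pvals = []
    for k in range(n_seeds):
        panel = random_panel(n_loci=3, target_length=80, seed=seed + 1000 + k)
        ref = panel.reference
        variants = []
        for loc in panel.loci:
            for pos in (loc.target_start + 15, loc.target_start + 45):
                ref_base = ref[loc.chrom][pos]
                alt = next(b for b in "ACGT" if b != ref_base)
                variants.append(Variant(loc.chrom, pos, ref_base, alt, vaf))
        sample = SampleProfile(
            variant_sites=variants,
            damage_rate_per_type={"C>A": damage_rate},
            end_repair_copy_distance=copy_distance,
            fragment_length_mean=170.0,
        )
        config = SimConfig(molecules_per_locus=molecules_per_locus, seed=seed + k)
        molecules = simulate_molecules(panel, sample, config)
        artifact, variant = event_end_distances(molecules)
        pvals.append(end_distance_test(artifact, variant))
    return pvals
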