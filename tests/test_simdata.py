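"""Simulator contracts: planted truth, capture statistics, determinism."""

import numpy as np
import pytest
from scipy import stats

import seduplex.simdata as sd
from seduplex import (
    SampleProfile,
    SimConfig,
    Variant,
    random_panel,
    simulate_molecules,
    tag_and_sequence,
    write_truth,
)


def clean_profile(**kw):
    return SampleProfile(variant_sites=[], damage_rate_per_type={}, **kw)


def first_variant(panel, vaf):
    loc = panel.loci[0]
    pos = loc.target_start + 20
    ref = panel.reference[loc.chrom][pos]
    alt = "A" if ref != "A" else "C"
    return Variant(loc.chrom, pos, ref, alt, vaf)


class TestSimulateMolecules:
    def test_zero_noise_molecules_match_reference(self, panel):
        cfg = SimConfig(molecules_per_locus=50, seed=5)
        for mol in simulate_molecules(panel, clean_profile(), cfg):
            ref = panel.reference[mol.chrom][mol.frag_start : mol.frag_end]
            assert mol.top.tobytes().decode() == ref
            assert mol.bottom.tobytes().decode() == ref
            assert len(mol.umi) == 12

    def test_variant_count_within_binomial_interval(self, panel):
        n, af = 10_000, 0.5
        prof = SampleProfile(variant_sites=[first_variant(panel, af)])
        cfg = SimConfig(molecules_per_locus=n, seed=7)
        mols = [m for m in simulate_molecules(panel, prof, cfg) if m.locus_id == "L000"]
        k = sum(1 for m in mols if m.variants)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, af)
        assert lo <= k <= hi

    def test_variant_present_on_both_strands(self, panel):
        prof = SampleProfile(variant_sites=[first_variant(panel, 0.5)])
        cfg = SimConfig(molecules_per_locus=200, seed=2)
        for mol in simulate_molecules(panel, prof, cfg):
            for pos, alt in mol.variants:
                off = pos - mol.frag_start
                assert chr(mol.top[off]) == alt
                assert chr(mol.bottom[off]) == alt

    def test_copy_distance_zero_keeps_lesions_single_strand(self, panel):
        prof = clean_profile(end_repair_copy_distance=0)
        prof.damage_rate_per_type = {"C>A": 1e-3}
        cfg = SimConfig(molecules_per_locus=2000, seed=3)
        mols = simulate_molecules(panel, prof, cfg)
        lesions = [(m, l) for m in mols for l in m.lesions]
        assert lesions, "expected some lesions at rate 1e-3"
        for mol, les in lesions:
            assert not les.copied
            off = les.pos - mol.frag_start
            other = mol.bottom if les.strand == "TOP" else mol.top
            assert chr(other[off]) != les.alt

    def test_copy_distance_copies_only_near_ligated_end(self, panel):
        prof = clean_profile(end_repair_copy_distance=15)
        prof.damage_rate_per_type = {"C>A": 2e-3}
        cfg = SimConfig(molecules_per_locus=2000, seed=4)
        mols = simulate_molecules(panel, prof, cfg)
        copied = [(m, l) for m in mols for l in m.lesions if l.copied]
        assert copied
        for mol, les in copied:
            assert les.pos - mol.frag_start < 15
            off = les.pos - mol.frag_start
            assert chr(mol.top[off]) == chr(mol.bottom[off]) == les.alt

    def test_empty_panel_rejected(self):
        import dataclasses
        from seduplex.panel import PanelDesign

        with pytest.raises(ValueError):
            simulate_molecules(
                PanelDesign(loci=[], reference={}), clean_profile(), SimConfig()
            )


class TestTagAndSequence:
    def test_zero_error_family_reads_identical(self, panel):
        cfg = SimConfig(molecules_per_locus=100, seed=9)
        mols = simulate_molecules(panel, clean_profile(), cfg)
        reads, truth = tag_and_sequence(mols, cfg, panel)
        by_family = truth.reads.groupby(["molecule_id", "strand_label"])["read_id"]
        seq_of = {r.read_id: r.read1 for r in reads}
        for _, ids in by_family:
            seqs = {seq_of[i] for i in ids}
            assert len(seqs) == 1

    def test_same_seed_gives_identical_fastq(self, panel, tmp_path):
        outs = []
        for _ in range(2):
            cfg = SimConfig(molecules_per_locus=60, seed=21,
                            sequencing_error_rate=0.005, pcr_error_rate=0.001)
            mols = simulate_molecules(panel, clean_profile(), cfg)
            reads, _ = tag_and_sequence(mols, cfg, panel)
            p1 = tmp_path / f"r1_{len(outs)}.fastq"
            p2 = tmp_path / f"r2_{len(outs)}.fastq"
            sd.write_fastq(reads, p1, p2)
            outs.append((p1.read_bytes(), p2.read_bytes()))
        assert outs[0] == outs[1]

    def test_different_seeds_give_different_umis(self, panel):
        umis = []
        for seed in (1, 2):
            cfg = SimConfig(molecules_per_locus=60, seed=seed)
            mols = simulate_molecules(panel, clean_profile(), cfg)
            umis.append({m.umi for m in mols})
        assert umis[0] != umis[1]

    def test_zero_capture_probability_is_an_error(self, panel):
        with pytest.raises(ValueError):
            SimConfig(strand_capture_prob=0.0)

    def test_duplex_share_matches_closed_form(self, panel):
        """Observed duplex UMIs / all UMIs converges to s/(2-s)."""
        s = 0.387
        cfg = SimConfig(
            molecules_per_locus=17_000, strand_capture_prob=s,
            reads_per_family_mean=1.0, seed=13,
        )
        small = random_panel(n_loci=1, seed=0)
        mols = simulate_molecules(small, clean_profile(), cfg)
        _, truth = tag_and_sequence(mols, cfg, small)
        m = truth.molecules
        n_duplex = int((m.captured_top & m.captured_bottom).sum())
        n_single = int((m.captured_top ^ m.captured_bottom).sum())
        observed = n_duplex / (n_duplex + n_single)
        assert observed == pytest.approx(s / (2 - s), abs=0.02)


class TestTruthFiles:
    def test_truth_vcf_roundtrip(self, panel, tmp_path):
        variants = []
        rng = np.random.default_rng(0)
        for loc in panel.loci:
            for k in range(3):
                pos = loc.target_start + 5 + 20 * k
                ref = panel.reference[loc.chrom][pos]
                alt = "T" if ref != "T" else "G"
                variants.append(Variant(loc.chrom, pos, ref, alt, float(rng.uniform(0.001, 0.01))))
        sample = SampleProfile(variant_sites=variants)
        vcf = tmp_path / "truth.vcf"
        bed = tmp_path / "targets.bed"
        write_truth(sample, panel, vcf, bed)
        back = sd.read_truth_vcf(vcf)
        assert len(back) == len(variants)
        expect = sorted((v.chrom, v.pos, v.ref, v.alt) for v in variants)
        got = sorted(zip(back.chrom, back.pos, back.ref, back.alt))
        assert got == expect
        np.testing.assert_allclose(
            sorted(back.allele_fraction),
            sorted(v.allele_fraction for v in variants),
            rtol=1e-5,
        )
        assert len(bed.read_text().splitlines()) == len(panel.loci)

    def test_empty_variant_list_gives_header_only_vcf(self, panel, tmp_path):
        vcf = tmp_path / "empty.vcf"
        write_truth(SampleProfile(variant_sites=[]), panel, vcf)
        assert len(sd.read_truth_vcf(vcf)) == 0
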