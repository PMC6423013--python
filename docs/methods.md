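# Methods

Model, parameter choices and limitations of the seduplex pipeline. The
README covers usage; this note covers *why* the defaults are what they
are and what the simulator does and does not emulate.

## 1. Library model

Each target locus is enriched by a single gene-specific primer anchored
at the right edge of the target window; input duplex molecules are
fragments of mean length 170 bp (SD 15, floor 50) whose left end — the
fragmentation point — carries the ligated adapter with the 12-mer UMI and
the strand barcode. Read 1 is

```
UMI(12) + TTCTGAGCGA(10) + TT|CC(2) + ATAGGAGTCCT(11) + insert
```

so the genomic insert starts at offset 35 and a 150 bp read covers up to
115 bp of insert. `TT` marks the original top strand; the physical bottom
barcode is read as `CC`. Decoding tolerates one mismatch per spacer and
none in the 2-base barcode.

Event timing is the load-bearing part of the simulator:

- **True variants** are placed on *both* strands of a molecule with
  probability equal to the allele fraction.
- **Damage (lesions)** happens *before* tagging, on one strand, at a
  per-type rate; it is UMI-consistent (every read of that strand family
  shows it) but single-stranded, so the duplex is discordant.
- **End repair** can copy a lesion to the opposite strand when it lies
  within `end_repair_copy_distance` (default 15 bp) of the ligated end —
  the one mechanism that makes damage look double-stranded, and the reason
  artifact sites cluster near the 5′ fragment end.
- **PCR errors** are applied per family founder *after* tagging
  (UMI-consistent, single strand); **sequencing errors** per read
  (removed by family consensus).

Strand capture is independent per strand with probability s (default
0.387). A molecule seen from both strands yields a duplex UMI, from one
strand a single-plex UMI, so the expected duplex share of observed UMIs
is s²/(s² + 2s(1−s)) = s/(2−s) = 0.240, matching the ~23–24% observed in
the targeted experiments the defaults are calibrated to. Family sizes are
1 + Poisson(mean − 1) with mean 4.5 reads/UMI, inside the 4.5–6.2 range
of those runs.

Damage types are expressed in as-sequenced (top-coordinate) space on each
strand; the same substitution can therefore hit both strands of one
molecule at the same position with probability d² — which is exactly the
duplex-channel null rate the caller assumes.

## 2. Consensus

A family (sample, locus, fragmentation position, UMI, strand) yields a
consensus base at a site when

- ≥ `min_family_size` (2) reads cover it — singletons are removed because
  a single read cannot be error-corrected;
- one base holds ≥ 80% of all covering reads **and** ≥ 80% of
  high-quality covering reads (base quality ≥ 25, mapping quality ≥ 30,
  ≤ 5 mismatches; at least one HQ read required);
- at homopolymer runs (reference run ≥ 5), only reads spanning the run
  plus one flanking base count.

Families within UMI edit distance 1 and fragmentation distance ≤ 5 bp are
merged into the larger family when the (pre-merge) count ratio is ≥ 5:1,
in a single deterministic pass in descending-count order — near-duplicate
UMIs at that ratio are overwhelmingly PCR/sequencing copies of the larger
family's tag. Top and bottom families sharing a UMI within 5 bp of
fragmentation position are paired into a duplex group (greedy
nearest-position).

A duplex group contributes to the duplex channel only when both strands
reach consensus and agree; disagreement is counted as *discordant* and
excluded from both channels (it is evidence of damage, not of a variant
and not of reference). Per site this yields the caller-facing counts
(N₁, n₁) over single-plex groups and (N₂, n₂) over duplex groups, plus
family-level counts (each strand family one observation) for the error
model — family counting is the unbiased estimator of the per-strand
background rate, group counting of per-molecule evidence.

## 3. Background error model

For each of the 12 substitution types, the panel-wise rate pools
non-reference family counts over all wild-type sites with the matching
reference base: rate = Σn / ΣN, with a Wilson 95% interval (score
interval — well-behaved at the tiny rates involved, unlike the Wald
interval). Site-to-site variation is captured by a Beta(α, β) over
per-site rates, fitted by maximising the Beta-Binomial likelihood
(Nelder–Mead on (log α, log β), method-of-moments start); the fit is
flagged `UNDETERMINED` when every site has zero counts.

Simulations use Beta(α = 2, β = 39,998) as the default null: the
calibration experiments constrain only the *mean* (dominant G>A type
≈ 5×10⁻⁵), and α = 2 gives a mildly overdispersed, unimodal shape
consistent with the parameter-recovery regime the fit is tested in.

The end-repair signature is tested with a one-sided Welch t-test
(artifact distances to the 5′ end < variant-site distances); degenerate
zero-variance inputs with equal means return p = 0.5.

## 4. Caller

Generalised likelihood-ratio test per site:

- **M0 (background):** n₁ ~ BetaBinomial(N₁, α, β);
  n₂ ~ Binomial(N₂, e_d) with e_d = max(ê², 10⁻⁷), ê the fitted mean
  single-strand rate. The square encodes strand independence of errors;
  the 10⁻⁷ floor acknowledges that end-repair copying violates it.
- **M1 (variant):** n₁ ~ Binomial(N₁, f̂), n₂ ~ Binomial(N₂, f̂) at the
  plug-in f̂ = (n₁+n₂)/(N₁+N₂).

llr = log L(M1) − log L(M0); call when llr ≥ 6.0 (≈ e⁶ ≈ 400:1) and
n₁ + n₂ ≥ 2 (a single UMI is never sufficient evidence). `SINGLEPLEX`
mode scores the same data with strand information discarded
(N₁ ← N₁ + 2N₂, n₁ ← n₁ + 2n₂, Beta-Binomial null only); the plug-in GLRT
(rather than a marginalised Bayes factor) keeps the statistic closed-form,
fast and monotone in the evidence.

At the calibration depths (~14–17k UMIs/site, ~24% duplex, null mean
5×10⁻⁵), a clean simulation gives zero-FP sensitivity ≈ 100% at both
0.2% and 0.1% VAF — the sample-free upper envelope of the corresponding
wet-lab results (96.6% and 77%/86.2%), as expected for matched
simulations without sample artifacts.

The duplex advantage becomes visible exactly when the background is
*not* clean: with hotspot-like strand-specific damage (per-site rates
Beta-dispersed around 5× background) and the null refitted from the
contaminated library itself, the single-plex null inflates while the
duplex channel stays at ê²; DUPLEX calling then reaches matched
sensitivity with 0 false positives where SINGLEPLEX incurs tens to
hundreds (`benchmarks.duplex_advantage`, 20/20 replicates).

## 5. What the simulator does not model

- No indels, structural variants or multi-allelic sites (substitutions
  only, as is the caller).
- No alignment: simulated reads carry their true coordinates (a truth
  alignment table stands in for a mapper); `tag_reads_from_bam` accepts
  externally aligned reads with UM/SL tags.
- Primer synthesis errors, chimeras, index hopping and sample
  cross-contamination are out of scope.
- PCR errors are applied once per family founder, not along a branching
  amplification tree; late-cycle subfamily structure is therefore absent
  (it is removed by the 80% rule anyway).
- Fragment-length and capture parameters are stationary across loci; no
  GC or coverage bias.

## 6. Numerical notes

- All pmfs are evaluated in log space via `scipy.special`
  (`gammaln`, `betaln`, `xlogy`, `xlog1py`); `xlogy`/`xlog1py` make the
  f̂ = 0 and f̂ = 1 boundaries exact instead of NaN.
- `scipy.stats.betabinom` is deliberately *not* used in the
  implementation; it serves as the independent oracle in tests.
- The Beta fit optimises (log α, log β), keeping the search unconstrained
  and scale-free.
- Consensus over large runs uses a vectorised per-family pileup with a
  slow-path fallback at homopolymer sites; both paths are
  property-tested for equality.
- Randomness is `numpy.random.default_rng([seed, stream])` throughout:
  every experiment is reproducible from a single integer seed and streams
  are independent by construction.
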