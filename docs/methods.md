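# Methods

## Genetic model

All genetic distance is sex-averaged centimorgans from pter. Crossovers
follow Haldane's model: per meiosis, breakpoints are a Poisson process with
rate 0.01 cM⁻¹ and the starting phase is a fair coin; no chiasma
interference is modeled. A table of sex-averaged autosome genetic lengths
(3,454.7 cM total, `qhmap/data/autosome_lengths.yaml`) is bundled as the
default `L_autosome` and as default simulator chromosome lengths; any
reference map (TSV of chrom/bp/cM anchors) can replace it. Marker cM
positions are interpolated piecewise-linearly between anchors — the
simplest monotone scheme — with linear extrapolation from the two outermost
anchors beyond the map ends, floored at 0 cM.

## Consanguinity-loop simulator

The pedigree loop is modeled with a common-ancestor **couple** (four
founder haplotypes A1, A2, B1, B2); the paternal and maternal paths pass
through two different children of the couple, `m` and `n` meioses from the
subject. Along a chromosome each meiosis is an independent two-state
telegraph process (switch rate 0.01 cM⁻¹), and the founder origin of each
homolog is a deterministic function of the switch states: the lower `m−2`
switches decide loop-vs-outside material, one switch picks the ancestor,
and the top meiosis picks that ancestor's haplotype. An autozygous segment
is a maximal interval where both homologs carry the same founder label.
Locus-wise this gives P(autozygous) = 4·(1/2)^(m+n): 1/16 for first
cousins, recovered by simulation within Monte Carlo error. `m = 1` (or
`n = 1`) means the corresponding parent *is* one member of the couple
(ancestor A paternally, B maternally), so `m = n = 1` — a child of the
unrelated couple — is correctly never autozygous.

The longest-AS distribution is accumulated over events with at least one
AS, matching how the family-history check is framed; the "95% range" is
read as the central interval, so the lower bound is the 2.5th percentile
(`alpha` is exposed for one-sided use). Per-event summaries (count, mean
length, autozygous fraction) are conditional on the same event set.
Simulation is seeded (`numpy.random.default_rng`) and bit-reproducible.

## Cutoff model

The closed forms assume (i) AS lengths ~ Exp((m+n)/100), valid when ASs are
much shorter than the chromosome, and (ii) heterozygote spacings ~
Exp(N_het/L_autosome), i.e. random SNP placement and no LD. The type B rate
deliberately assumes *every* RHS contains an AS — an overestimate preferred
to an underestimate when choosing a conservative cutoff. Each RHS
contributes two expected end overhangs of ½·L/N_het, giving
R_typeB = n_RHS/N_het. The default cutoff 0.6 cM is a fixed package
constant (the trade-off is tabulated by `qhm cutoff-table` on a 0–3 cM
grid, step 0.01); no automatic optimization is attempted.

## Error correction

λ_het = N_het/L_autosome is estimated per sample genome-wide **before** any
removal and held fixed. For each heterozygous call the span `d` from the
previous to the next heterozygous SNP (chromosome map ends for the first
and last) is scored with the Erlang-2 survival (1 + λd)e^{−λd} — the exact
law of the sum of two independent exponential gaps — and calls below the
0.01 threshold are set to NO_CALL ("removed"; the true homozygous allele is
not inferable from calls alone). For a genuine heterozygote the span is
itself Erlang-2, so its survival probability is uniform on (0,1) and the
expected collateral loss is about the threshold mass (~1% of heterozygous
calls), which leaves run detection essentially unaffected.

The pass is **not** iterated to a fixpoint, by design: the two calls
flanking any genuine long run have spans at least the run's length and are
legitimately removed, but after their removal the next flanking calls
inherit an even larger span, so iteration would cascade outward and consume
the entire chromosome. A single simultaneous pass, with every span measured
in the original configuration, is self-limiting: clustered mistypes inside
a long run still each see a large span (their neighbours are close, but the
span reaches across the surrounding run), so they are removed together in
one pass. `max_passes` exposes iteration for experimentation only.

Error injection flips `floor(N_called × rate)` uniformly chosen called
genotypes to one of the other two calls with equal probability — a
symmetric confusion model; only HOM→HET flips can break runs, and the
symmetric choice is the least-informative completion where the true error
process is unknown.

## RHS detection

Candidate runs are maximal HET-free stretches. Genetic bounds extend to the
flanking heterozygous SNPs (or chromosome map ends) — consistent with the
type B accounting of half-spacing overhangs — while physical (BED) bounds
come from the outermost homozygous SNPs. NO_CALL sites neither extend nor
break runs and are excluded from all counts. A run qualifies strictly above
the cutoff and needs `min_snps` (default 1) homozygous SNPs, which
suppresses SNP-free pseudo-runs in sparse regions. F is estimated as total
RHS genetic length over `L_autosome`.

## Overlap and case-control prioritization

Overlaps are interval intersections in genetic coordinates (half-open
`[start, end)`), with physical bounds intersected in parallel. At each SNP,
coverage proportions of n₁ cases and n₂ controls are compared with the
continuity-corrected two-proportion statistic
u = (p̂₁* − p̂₂*)/√(p̂*(1 − p̂*)(1/n₁ + 1/n₂)), p̂ᵢ* = (xᵢ + ½)/(nᵢ + 1),
and a one-sided upper-tail normal P. The variance uses the standard
two-sample form; `legacy_variance=True` reproduces a published
variant with (1/n₁ + 1/n₁), which we read as a misprint. No
multiple-testing correction is applied; −log₁₀(P) is reported per SNP and
overlaps are ranked by their maximum, ties broken by genetic length then
coordinate.

## Synthetic data

The generator scatters SNPs uniformly in cM (toy physical scale 1 cM =
1 Mb), draws per-SNP major-allele frequencies from Uniform(0.5, 0.95) —
a reasonable profile for a genotyping array's common SNPs — and founder
haplotypes at linkage equilibrium. Inbred genomes reuse the simulator's
label tracks, so every sample carries exact truth AS intervals, and inside
a truth AS all pre-error calls are homozygous by construction. Benchmark
cases are rejection-sampled to be autozygous at a planted locus; controls
are outbred. Defaults (4 chromosomes × 150 cM, 5,000 SNPs each, error rate
0.003) keep a full test run in minutes; an array-scale configuration
(~890k SNPs genome-wide) is reachable through the same config but is not
the default.

What the synthetic data deliberately omits: linkage disequilibrium and
haplotype blocks (real arrays therefore show *more* chance runs and type B
inflation than these tests), population substructure, and non-uniform SNP
spacing. Passing tests demonstrate correctness of the algorithms under the
stated model, not field performance on any particular array.

## Numerical and scale choices

* Quantiles use `numpy.quantile` (linear interpolation); the
  family-history verdict compares against the central 1 − 2α interval and
  reports the empirical percentile.
* The acceptance script simulates 100,000 qualifying events (~35 s); the
  test suite uses 20,000 for the same quantity and correspondingly smaller
  replicate counts elsewhere (100 restoration genomes at 3,000 SNPs ×
  4 × 150 cM chromosomes; 100 planted-gene replicates at 2,000 SNPs ×
  3 × 100 cM with 5 cases / 20 controls). Problem sizes are stated in each
  test.
* Degenerate inputs: empty tracks yield empty RHS lists; a track with no
  heterozygous calls is returned unchanged by correction; zero-length
  intersections are dropped; bp extents are forced ≥ 1 so BED rows remain
  valid.
* Input physical coordinates are 1-based; emitted BED is 0-based
  half-open. Only autosomes 1–22 are processed; other rows are dropped
  with a logged count.

## Known limitations

* The exponential AS-length law degrades for loops so shallow (m + n ≤ 3)
  that segments rival chromosome lengths; the simulator remains exact, only
  the closed forms approximate.
* F̂ from total RHS length is biased upward at low SNP density, where type
  A false positives contribute genuine-looking runs (at 20 SNPs/cM roughly
  a tenth of the genome clears a 0.6 cM cutoff by chance; at the README
  example's 53 SNPs/cM the effect is negligible).
* The case-control statistic assumes independent samples and a large-n
  normal approximation; with 5 cases the P values are indicative ranks, not
  calibrated tail probabilities.
* Sex chromosomes, sex-specific maps and arbitrary pedigrees (beyond the
  single loop) are out of scope.
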