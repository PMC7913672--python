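# Methods

## Problem and approach

Nitrous-acid deamination converts the exocyclic amines of RNA bases:
adenosine becomes inosine (read as G by reverse transcription), cytidine
becomes uridine (read as T) and — much more slowly — guanosine becomes
xanthosine (X), which partially blocks reverse transcription.
N6-methyladenosine (m6A) carries a methylated exocyclic amine and resists
the reaction, so after partial deamination an m6A site retains an
anomalously high A signal among A positions whose unmethylated fraction has
partly turned to G.  This package analyses such amplicon libraries — and
simulates them — to detect m6A sites in a defined target sequence.

Complete deamination is unusable in practice: the accumulated xanthosines
block reverse transcription, so sequencing output is dominated by the few
molecules that escaped conversion.  The useful regime is *partial*
deamination with A-to-I conversion roughly between 10% and 50%, which is
what the chemistry presets encode.

## Alignment model

Partial deamination degenerates the read signal, so alignment scores each
(read base, reference base) pairing with an asymmetric ±1 matrix whose +1
entries are exactly the chemistry-compatible pairings

    (A,A) (C,C) (G,G) (T,T)   identities
    (G,A)                     A->I read as G
    (T,C)                     C->U read as T
    (A,G)                     minor xanthosine read-through A signal

and −1 everywhere else.  The direction matters: read T over reference C is
a deamination product, read C over reference T is not.  The matrix is a
single configurable table (`SubstitutionMatrix.from_table`) so an
alternative scoring can be swapped in verbatim.

Mapping is seed-and-extend against an alphabetically ordered k-mer index of
the reference (k = 11 by default).  Seeding is *matrix-compatible*: a read
k-mer seeds at a reference k-mer when all k pairings score +1, not when the
strings are equal — with literal seeding a strongly converted read could
contain no exact 11-mer of the reference and would be unmappable, defeating
the purpose.  Extension is ungapped; the retention filter (below) makes any
gap or −1 pairing fatal anyway, so gapless extension loses nothing.

Three filters decide retention, and their counts form the reported funnel:

1. perfect score — total score must equal the read length;
2. anchor — the alignment must start at reference position 1 (keeps the
   reading frame, removes ambiguous placements, limits NGS-error impact);
3. coverage — the read must span the evaluation window (default: the whole
   reference), so downstream denominators are constant per position.

Truncated (RT-blocked) reads therefore drop out at the coverage filter:
this *reproduces* the survivor bias of the chemistry rather than hiding it.
A read contributes at most one alignment; seeds are tried in lexicographic
(read offset, reference offset) order, though under the anchor filter at
most one placement can survive.  The aligner is verified against a
brute-force all-placements scorer on hundreds of random instances.

## Rates and the calling statistic

Per-position A/C/G/T counts over the aligned reads give, at reference A
positions, the A rate (fraction of reads still reading A) and G rate
(A-to-I conversion), and at C positions the T rate.  Denominators are
always the total aligned-read count, so sequencing errors reduce
a_rate + g_rate below 1 instead of being silently dropped.

Candidate calling standardises each A position's A rate against all A
positions of the amplicon:

    z_p = (a_p − mean(a)) / sd(a),    probability_p = Φ(z_p)

with the sample SD (ddof = 1) and the candidate *included* in mean and SD —
conservative, since a genuine site inflates the SD; a leave-one-out variant
is available behind a flag.  Positions with probability strictly above the
threshold (default 0.95) are candidates: the construction flags the ~5% of
A rates most distant above the bulk.  The test is one-sided because the
chemistry can only *protect* m6A (high A rate); low-tail outliers are
surfaced as QC warnings.  No multiple-testing correction is applied —
amplicons have on the order of ten A positions; this is a documented caveat
for long references.  At least 3 A positions are required, and identical
rates (σ = 0) raise a degenerate-distribution error.

## Simulator

The generator inverts the observed signal rules into a generative model.
Per unique molecule:

1. methylation state per annotated site ~ Bernoulli(stoichiometry);
2. optional antibody (MeRIP-style) retention by rejection sampling —
   methylated molecules weighted by `enrichment_factor`, unmethylated by
   `background_retention`, output renormalised to `n_reads`;
3. per-base conversion ~ Bernoulli of the position's rate; methylated
   sites convert only with `p_m6A_deaminated` (default 0);
4. RT truncation: each converted G is an X that blocks with `p_X_block`;
   the emitted fragment runs from the anchored end to the first blocking
   X (exclusive), so truncated reads later fail the coverage filter;
   nitrosated m6A (`p_NOm6A`) can be modelled as reading A (default under
   mild conditions) or as RT-blocking;
5. readout: converted A→G, converted C→T, read-through X→A with
   `p_X_reads_A` = 0.1 else G (matching the minor A signal observed at G
   positions), intact m6A→A;
6. a random 7-nt UMI per molecule; PCR duplicates (expected fraction
   `pcr_duplication_rate`) are exact copies sharing sequence and UMI;
7. optional uniform per-read sequencing error (default 0).

Site-to-site reactivity variance is a mean-preserving lognormal
multiplicative jitter on the A and C conversion rates
(`position_rate_jitter`, default σ = 0.15), drawn once per simulation run.
This is the minimal mechanism that gives the method a realistic detection
floor: without it the z-statistic would resolve arbitrarily small
stoichiometries at high depth.  Because the jitter is redrawn per run it
conflates sequence-intrinsic reactivity with batch-to-batch variation; the
two are not separable from a single library anyway.

Chemistry presets encode the documented constraints rather than measured
constants (the useful regime is reported as ranges): `optimal_oligo` uses
p_AtoI = 0.30, p_CtoU = 0.35, p_GtoX = 0.03 (strong partial deamination of
the synthetic oligo), `amplicon` 0.15/0.20/0.01 (milder conditions for
biological targets).  Defaults sit mid-range; G conversion is kept well
below A and C in both.  `p_X_block` = 0.5 is a free parameter — the
survivor fraction under harsh conditions is not quantified anywhere — and
the condition grid (3 temperatures × 4 pH × 6 times = 72) is enumerative
only: no Arrhenius-style kinetic model maps (T, pH, t) to rates.

What the simulator deliberately does not model: acid-induced RNA
degradation (beyond X truncation), ligation/PCR sequence bias, quality
score structure, paired-end layouts.  Passing tests therefore demonstrate
the statistical machinery under the stated generative model, not the full
error structure of real libraries.

## UMI redundancy

Duplicates are reads whose UMI string was already seen (exact equality;
optional Hamming-distance-1 clustering absorbs UMI sequencing errors,
default off).  With 7-nt UMIs the diversity is 4^7 = 16384, so at depths of
10^4 reads random collisions between distinct molecules dominate the raw
duplicate fraction (birthday floor ≈ 25% at that depth).  The report
therefore includes the expected collision redundancy and a
collision-corrected PCR-redundancy estimate obtained by inverting
E[distinct] = M(1 − (1 − 1/M)^n); at a few hundred reads per amplicon —
the realistic depth for this assay — the correction is negligible.

## Numerical and design choices

* Coordinates are 1-based fully closed everywhere user-facing; RNA input is
  normalised U→T at the boundary.
* Reads containing N are discarded before alignment: the perfect-score
  filter is unattainable with N under the ±1 matrix.
* Reads longer than the reference are rejected (coverage), not clipped;
  reverse-complement mapping is not attempted (amplicon orientation is
  fixed by the primer design).
* Φ is `scipy.stats.norm.cdf`, cross-checked in tests against the
  erf closed form to 1e−12.
* The calibration fit is ordinary least squares (`scipy.stats.linregress`);
  inverse prediction is clipped to [0, 1].  The titration harness averages
  3 replicate libraries per level over 11 levels: with single runs the
  site-jitter residuals alone bound E[r²] near 0.93, while averaging
  restores the clearly-linear regime (E[r²] ≈ 0.98).  Slope uncertainty is
  assessed with the generative-model (delta-method) SE rather than the
  few-point residual SE.
* Under the null (no methylation, jitter on) the fraction of A positions
  above the 0.95 threshold is nominally 5% but realises at ~3–4% on an
  11-A-position amplicon: the sample SD includes the tested position, and
  lognormal rate jitter makes A rates left-skewed, thinning the upper tail.
  The null-calibration test accepts 2–7.5% accordingly.
* Determinism: a single `numpy` Generator per simulation seed; identical
  seeds give byte-identical FASTQ/TSV output, and the pipeline manifest
  records seed, funnel and SHA-256 checksums of every emitted file.

## Problem sizes

Simulation-based checks use 10^4 reads per library (binomial SE on a rate
≈ 0.005, an order of magnitude below the site-jitter SD, so jitter — the
quantity of interest — dominates), 20–100 replicate libraries for
median/frequency statements, and 1000 amplicons for the null calibration at
2000 reads each (the null is scale-free in depth once binomial noise is
small relative to jitter).

## Known limitations

Single-reference, single-end, ungapped by design; not suitable for
transcriptome-wide mapping.  Absolute stoichiometry is not reported for
enriched libraries (enrichment destroys the linear signal/content
relationship; the saturation map m_eff = mE/(mE + (1−m)b) is monotone, so
detection survives).  The probability statistic calibrates against the
amplicon's own A positions, so amplicons with very few A positions (< 3)
cannot be called, and a reference whose every A is methylated would leave
no null to calibrate against.
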