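# noseq

Detection of N6-methyladenosine (m6A) in targeted sequencing amplicons
after partial chemical deamination.

Nitrous-acid treatment deaminates the exocyclic amines of RNA: adenosine
becomes inosine (read as **G** by reverse transcription), cytidine becomes
uridine (read as **T**), and guanosine slowly becomes xanthosine, which
partially blocks reverse transcription.  m6A carries a methylated exocyclic
amine and **resists** the reaction.  After *partial* deamination (A-to-I
conversion in the 10–50% regime) an m6A site therefore stands out as an A
position whose A rate stays anomalously high while its neighbours have
partly turned to G.

This package is for RNA-modification researchers who want to validate or
quantify m6A at defined sites in an amplicon.  It provides:

* a **deamination-aware aligner** — seed-and-extend over a k-mer index
  (k = 11) with an asymmetric ±1 substitution matrix whose +1 entries are
  exactly the chemistry-compatible pairings {(A,A), (C,C), (G,G), (T,T),
  (G,A), (T,C), (A,G)}, retaining only reads with score = length that start
  at reference position 1 and cover the full evaluation window;
* **per-position conversion-rate tables** (A/G rates at A positions, T rate
  at C positions) from the aligned reads;
* an **m6A caller**: for each A position, z = (a_p − μ)/σ over the A rates
  of all A positions and probability Φ(z); positions with Φ(z) > 0.95 are
  candidates.  A linear calibration of site A signal versus m6A content
  supports stoichiometry estimation;
* **UMI redundancy assessment** (7-nt UMIs, exact-match duplicates, with a
  birthday-collision-corrected PCR-redundancy estimate);
* a **chemistry-faithful simulator** (partial A→I / C→U conversion, slow
  G→X with RT blockage and survivor bias, m6A resistance, per-site
  stoichiometry, lognormal site-reactivity jitter, MeRIP-style antibody
  enrichment, PCR duplication under UMIs) that replaces wet-lab input for
  development and testing.

## Worked example

The built-in demo simulates 10,000 reads of the synthetic 53-mer test
amplicon (m6A at position 33, here at 100% stoichiometry) under the
`optimal_oligo` chemistry preset (p_AtoI = 0.30, p_CtoU = 0.35,
p_GtoX = 0.03) and runs the full pipeline:

```bash
noseq demo --out demo_out --seed 0
# candidates: [33]
```

The alignment funnel in `demo_out/manifest.json` shows the survivor-bias
mechanism at work — reads truncated at an RT-blocking xanthosine fail the
full-coverage filter:

```
input 10000 -> seeded 9284 -> accepted 7584
(1700 rejected for coverage, 716 unseeded/truncated short)
```

`demo_out/calls.tsv` holds the per-position statistic (excerpt):

```
position   a_rate        z  probability  is_candidate
      30 0.760417 0.211678     0.583821         False
      33 1.000000 2.579230     0.995049          True
      51 0.703718 -0.348612    0.363690         False
```

Unmethylated A positions sit near a_rate ≈ 0.70 (the 30% of their
molecules deaminated to inosine read as G); position 33 keeps a_rate = 1.0
because m6A resists deamination, giving Φ(z) = 0.995 > 0.95 — the only
candidate.  `rates.tsv`, `composition.png`, `rates.png` and
`probability.png` show the per-position composition, the A/G rate profiles
and the probability plot with the 0.95 threshold line.

The same stages are available separately (`noseq simulate | align | rates |
call | calibrate | umi | run`) and as library functions
(`noseq.simulate_reads`, `noseq.align_all`, `noseq.tabulate`,
`noseq.call_sites`, ...).

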