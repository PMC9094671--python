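# Methods

This note documents the models implemented in `spikemap`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data generator does and does not emulate.

## Study design being modelled

A mutagenised line carries a load of induced point mutations, one of which
acts as a single Mendelian semidominant allele: heterozygotes form paired
spikelets with normal leaves, homozygotes form paired spikelets and curled
leaves, wild-type segregants show neither trait. The line is backcrossed to
the recurrent (unmutagenised) parent and selfed; phenotype-selected DNA
bulks from the segregating family are exome-sequenced; the causal mutation
is the site that is absent from the wild-type bulk, ~0.5 in the
heterozygous-phenotype bulk and ~1.0 in the homozygous-phenotype bulk; and
marker cosegregation in further backcross families narrows the interval.

## Genetic model

- **Genotypes** are alt-allele dosages d ∈ {0, 1, 2} per mutation; the
  simulator tracks the two haplotypes explicitly so linkage is exact.
- **Meiosis**: loci on each chromosome are sorted by physical position;
  map distance between neighbours is `rate [cM/Mb] × Δbp / 1e6`, converted
  to a recombination fraction with the Haldane map function
  r = (1 − e^(−2d_M))/2 (no interference). Crossovers between adjacent
  loci are independent Bernoulli draws; each gamete starts on a random
  haplotype. The default uniform 1 cM/Mb map is deliberately simple and
  analytically checkable (the simulator's recombinant fraction is tested
  against the closed form).
- **Phenotypes**: the semidominant map above, with penetrance fixed at 1.0
  by default (the segregation expectations assume full penetrance); a
  penetrance knob exists on `CausalSpec` for sensitivity work.
- **Mendelian expectations** are derived by enumerating gamete
  combinations, not hard-coded: a het × het self gives 1:2:1 genotypes,
  hence 1:3 wild-type:affected and 1/3 curled among affected; a het ×
  wild-type backcross gives 1:1.

## Sequencing model

Pooled alt fraction of a bulk of n plants is p = Σd / 2n. Per site and
bulk, depth ~ Poisson(λ) and alt reads ~ Binomial(depth, p′) with
p′ = p(1−e) + (1−p)e, where e is a symmetric per-read miscall rate.
Zero-depth sites are retained and flagged; their frequency is undefined
(`None`), which is distinct from an observed frequency of 0.0.

### Default parameters and rationale

| parameter | default | units | rationale |
|---|---|---|---|
| mutations_per_line | 2,500 | count | typical induced SNP load order for an EMS TILLING line; configurable |
| ems_fraction | 0.98 | proportion | EMS produces almost exclusively G>A / C>T transitions |
| genome | 1A/1B/1D, 594/689/495 Mb, 1 cM/Mb | — | group-1 stand-in for a hexaploid wheat assembly |
| family size / progeny per step | 200 | plants | a realistic BC1F2 family; yields ≥ 20 plants in every phenotype class |
| bulk_size | 20 | plants | routine bulked-segregant pool size; Σd/2n then resolves het (0.5) from hom (1.0) pools well |
| mean_depth | 180 | reads/site | pooled exome depth at the scale of the per-bulk read counts this design reports (order 150–200 per site); at ~30× the binomial noise of a 0.5-frequency site leaves the [0.4, 0.6] window far too often for reliable filtering |
| error_rate | 0.001 | per read | Illumina-order miscall rate after QC |
| wt_max_alt_reads | 2 | reads | with e = 1e-3 at 180× the wild-type bulk shows a mean 0.18 error reads at a true-negative site; tolerating 2 (P(Poisson(0.18) > 2) ≈ 1e-3) keeps error reads from vetoing true candidates while still excluding any genuinely segregating site |
| het_window / hom_window | [0.4, 0.6] / [0.9, 1.0] | frequency | the frequency signature of het/hom selection; closed intervals (the permissive reading) |
| mutant_bulk_min_freq | 0.8 (strict >) | frequency | two-bulk mode threshold |
| min_depth | 10 | reads | sites below it are rejected with reason `insufficient_depth`, never silently passed |
| finemap radius | 79.5 | Mb | search window around the first associated marker |

All thresholds live in `RunConfig`/`FilterConfig`; no stage hides its own
defaults.

## Filter cascade

Rules are applied per mutation in a fixed order — EMS-type, whitelist,
wild-type-bulk alt reads, het-bulk window, hom-bulk window, minimum depth —
and the first failing rule is logged. The retained set is independent of
rule order; only the log depends on it. The het↔hom cross-bulk consistency
requirement is inherent in demanding both windows simultaneously: a site
that is homozygous-like in the het bulk fails the het window. The cascade
is idempotent and monotone (shrinking any window or raising a threshold
never adds a candidate); both are property-tested.

## Fine mapping

A marker cosegregates completely when every scored line matches the
expected call for its phenotype class (wild type → hom-ref, paired/normal
→ het, paired/curled → hom-alt). Missing calls are skipped rather than
counted discordant: failed genotyping assays carry no linkage information.
The narrowed interval runs from 1 bp above the nearest discordant marker
below the completely cosegregating block to 1 bp below the nearest
discordant marker above it, falling back to the search-window edge on an
unflanked side. A discordant marker strictly inside the block would imply
a double recombinant between fully concordant neighbours and raises an
error rather than being papered over. Intron and silent mutations are
excluded a priori before cosegregation scoring.

## miRNA site scanning

Plant miRNAs cleave near-perfectly complementary sites, so scanning is
penalty-based rather than seed-based: for each target window of miRNA
length, antiparallel pairing is scored with mismatch 1.0 and G:U wobble
0.5, and penalties are doubled at miRNA positions 2–13 from the 5′ end
(the region where pairing defects are most disruptive to cleavage);
windows with total penalty ≤ 4 (default) are reported. U and T are unified
internally; only the sense strand is scanned since the miRNA targets the
mRNA. SNP annotation rescans the single affected window, so a SNP outside
a site has score delta 0 by construction. The scanner is verified against
a naive per-window enumeration oracle on random sequences. Codon effects
use the standard genetic code via Biopython; codon index is
⌊(pos−1)/3⌋ + 1.

## End-to-end study

Each replicate: simulate the mutation load, plant the causal G>A missense
SNP at 1D:217,644,011, run the pedigree (backcross then self), assign
phenotypes, pool the three bulks, sample reads, filter, then fine-map by
scoring all non-intron/non-silent mutations within the radius against the
same family with error-free marker calls. The report records per replicate
whether the causal SNP was retained and whether it lies in the narrowed
interval. The default study is 100 replicates and runs in well under a
minute on one core; the study-scale knobs (family size, replicate count)
are plain config fields.

**Randomness**: one master seed; replicate streams are
`SeedSequence(seed, spawn_key=(replicate,))`, further spawned per stage, so
results are bit-reproducible and independent of execution order. All
derived integer seeds are masked below 2³¹.

## What the generator does and does not emulate

Emulated: the EMS substitution spectrum, Mendelian transmission with
physical linkage, phenotype-based bulk selection, pooled binomial
sequencing noise with symmetric errors, and depth variation. Not emulated:
read-level artifacts (alignment error, duplicates), polyploid homeolog
cross-mapping (a real concern in hexaploid wheat exome data), variant-
calling error structure, segregation distortion, incomplete penetrance by
default, and non-uniform recombination (real maps concentrate crossovers
distally). Passing tests therefore demonstrate the correctness and
statistical behaviour of the pipeline under its stated model, not
robustness to every artifact of real exome captures; the whitelist rule is
the main line of defence against caller artifacts in real data, exactly as
in the modelled design.

## Numerical conventions and degenerate inputs

- Coordinates are 1-based inclusive everywhere internally; converted to
  0-based half-open only when writing BED.
- Frequency windows are closed; the two-bulk threshold is a strict `>`.
- Zero-depth frequencies are `None`, never 0.0; such sites fail with
  `insufficient_depth` at the first rule that needs the frequency.
- Chi-square tests renormalise the hypothesis proportions, so 1:3 and 2:6
  are identical; df = k − 1; no continuity correction.
- Decile binning of spikelet positions uses right-closed bins
  (0, 0.1], …, (0.9, 1], computed in integer arithmetic so position 1.0
  lands in the apex bin without floating-point edge cases.
- Zero simulated mutations: the study records a per-replicate error row
  ("no mutations simulated") and aggregates 0/0; any stage exception is
  caught per replicate and the run continues.

## Known limitations

- The interval-narrowing contract assumes a single causal locus and
  error-free marker calls; with genotyping errors the double-recombinant
  check raises instead of attempting error correction.
- The two-bulk mode implements only the frequency/whitelist rules of the
  design it models; it does not attempt SNP-index smoothing along the
  chromosome (discrete candidates, not curves, are the intended output).
- The scoring scheme for miRNA sites is a convention, not a thermodynamic
  model; site membership calls are robust to the convention, exact scores
  are not, and no ΔG hybridisation model is provided.
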