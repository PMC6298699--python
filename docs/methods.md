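# Methods

## System being modelled

A dCas9–MC fusion plus free MN (a split M.SssI CpG methyltransferase) is
directed by a single guide RNA to a protospacer + NGG PAM on a circular
reporter plasmid in *E. coli*, which has no native CpG methylation. The
enzyme methylates the target CpG dyad — placed g nucleotides 3' of the PAM —
at a frequency that depends on g, on the dCas9–MC linker length, and on
DNA-affinity mutations in MC, with distinct frequencies for the two strands
of the dyad (cis = PAM/protospacer strand, trans = sgRNA-complementary
strand). All 241 other CpG dyads on the plasmid receive a low off-target
baseline. Methylation is read out in two ways: strand-resolved bisulfite
sequencing of the whole plasmid, and methylation-sensitive
restriction-protection assays (FspI/SnaBI are blocked by methylation of the
CpG inside their recognition site; SacI linearises).

## Synthetic plasmid

`build_plasmid` generates a random circular backbone scrubbed of CG
dinucleotides, so every CpG dyad is deliberately placed: the target dyad
inside FspI site 1 (TGCGCA, CpG at the third base) at the requested gap, one
dyad inside the non-target FspI site 2 (placed near 0.55·L), optionally one
inside a SnaBI site (near 0.70·L), and the remainder as isolated CG plants
spaced ≥ 4 bp apart. A SacI site (no internal CpG) sits near 0.25·L. A
repair pass breaks any enzyme site completed accidentally by motif/plant
flanks, so the restriction layout is exactly the annotated one. Coordinates
are 1-based and circular.

**Gap convention** (not uniquely defined in the field): g counts the
nucleotides strictly between the last PAM base and the C of the target CpG
on the cis strand. The convention is recorded on the `PlasmidSpec` itself.
Gaps 0–1 are rejected: the FspI site embedding the target CpG would overlap
the PAM.

## Condition profiles

Ground-truth per-strand methylation frequency at gap g:

    p_s(g) = baseline                                    outside [g_min, g_max]
    p_s(g) = clip(A_s · exp(κ·(cos(2π(g − peak_s)/T) − 1)),
                  baseline, 1)                            inside

a von-Mises-shaped angular factor (the tethered enzyme prefers one face of
the helix) times a strand amplitude, floored at the off-target baseline and
windowed by a hard support (the linker's reach). Parameters per condition
live in `data/conditions.yaml`:

* Amplitudes at the optimal gap are the measured per-strand frequencies:
  trans 52.4% (4-aa linker), 36.7% (15-aa), 55% (25-aa), ~30% (Y305F/T313A),
  21%/2.2% (S291F trans/cis), 20.6%/3.5% (S317A).
* T = 11.0 bp (the observed oscillation period) for every condition. The
  geometry module's angle model separately defaults to canonical B-DNA
  (360/10.5 °/bp); the two are deliberately distinct and both configurable.
* The 15-aa support is the observed 8–26 bp window; the 4-aa support (9–14)
  and mutant supports (9–13, 9–15) encode the observed narrowing; the 25-aa
  support (8–36) encodes the observed reach extension.
* Trans peaks sit at gap 11 (the observed optimum); cis peaks at gap 14
  (a ~98° helix rotation away — a model choice, as cis peak positions were
  not printed). S291F/S317A were measured only at gap 12 (single replicas),
  so their peaks are anchored at gap 12 with the measured amplitudes.
* κ (angular sharpness) is a model choice per condition: 1.0 (15-aa), 3.0
  (4-aa, "narrow range of effective gaps"), 0.8 (25-aa, broad), 4.0
  (Y305F/T313A, frequency drops steeply one bp off the optimum), 2.0
  (S291F/S317A).
* Off-target baselines: per-cytosine frequencies are drawn from
  Beta(α = dispersion, β) with β solved numerically so the median equals the
  condition's observed off-target median (0.60%, 0.62%, 0.59% for the 4/15/25
  aa linkers; 0.10% for the mutants, which suppressed off-target methylation
  many-fold). Dispersion 1.0 gives an interquartile spread of roughly
  0.25–1.2%, consistent with "median below 1%" plus a tail of hotter sites;
  dispersion → ∞ degenerates to a point mass at the median. Whether the
  published ± values are SD or SEM is not stated; they are treated as
  between-replicate SD and not used to parameterise the baseline.

## Bisulfite read simulation

Directional protocol only (the two original converted strands are sequenced,
no CTOT/CTOB). Molecules are drawn uniformly from both strands of the
circle; each CpG cytosine is methylated with its ground-truth frequency
(non-CpG cytosines are never methylated — no Dcm/Dam is modelled);
unmethylated cytosines convert C→T with probability `conversion_rate`
(default 0.995) while methylated cytosines never convert; uniform
substitution errors are applied at `error_rate` (default 0.001); qualities
are constant. No indels, PCR duplicates or quality modelling. A sidecar
records each molecule's origin and the true methylation state of every CpG
cytosine it covers. `coverage` is total fold coverage
(reads·read_length/plasmid_length), so per-strand cytosine depth is about
half of it.

## Alignment and calling

The reference is a single ≤ ~10 kb circle, so alignment is exhaustive:
minimum Hamming distance over all circular offsets of both three-letter-
transformed strands (reference C→T vs C→T-collapsed read for plus origins;
reference G→A vs G→A-collapsed reverse-complemented read for minus origins).
No indel alignment. Ties across distinct placements are discarded as
ambiguous rather than randomly assigned; reads above the mismatch budget
(default ⌈5% of read length⌉) are discarded as no-hits. The batch aligner
seeds candidates with max_mismatch+1 disjoint k-mers, which by pigeonhole
finds every placement within budget, so it is exactly equivalent to the
exhaustive scan (tested against an independent brute-force oracle).

Calls follow the Bismark convention (reference C covered by a plus read:
C = methylated, T = unmethylated; mirrored at reference G for minus reads),
with context (CpG/CHG/CHH) and trinucleotide from the reference. Sites below
`min_coverage` (default 10) are reported missing, never as 0. The per-site
frequency is count_methylated/(count_methylated+count_unmethylated), raw by
default.

**Conversion-background correction** (optional, used by the recovery
pipeline): since the system has no non-CpG methylation, the pooled apparent
methylation at non-CpG cytosines estimates the combined non-conversion +
sequencing-error background b̂ directly from the data; corrected
frequencies are max(0, (raw − b̂)/(1 − b̂)). Raw frequencies are always
reported alongside. At 500× fold coverage the median off-target estimate
retains a small upward residual (~0.04 pp) because per-site noise convolved
with a right-skewed frequency distribution inflates the sample median; this
shrinks with depth.

## Gap-profile summaries

The combined any-strand frequency is 1 − (1−p_cis)(1−p_trans) (strand
independence). `dominant_period` resamples the profile onto the integer gap
grid (missing gaps mean-imputed), mean-centres it, and returns the lag in
[2, span/2] at the highest **local** maximum of the overlap-normalised
linear autocorrelation: the global maximum at small lags only reflects the
smooth support-window envelope, and a circularised autocorrelation shifts
the peak by ±1 bp when the series length is not a multiple of the period.
With the packaged 15-aa profile on gaps 2–42 this yields 11 bp; periods are
recovered exactly for T ∈ {7, 9, 11, 13} on unwindowed profiles, whereas
inside the 8–26 bp support a 13 bp period is genuinely unresolvable (barely
one full period fits). `methylation_support` returns the smallest and
largest gap whose combined frequency reaches the threshold; the default
threshold of 2% separates the off-target baseline (combined ≈ 1.2%) from
on-target signal and reproduces the 8–26 bp window.

## Kinetic specificity model

Michaelis–Menten saturation in effective CpG concentration,
v(C) = kcat·C/(Km+C), is the minimal model consistent with the qualitative
specificity argument; the full ordered mechanism of the homologous
methyltransferase M.HhaI is a documented extension point, not implemented.
Units are arbitrary (effective concentrations are relative); kcat defaults
to 1 and cancels from the specificity ratio, which is why the argument
applies equally to the catalytically compromised split enzyme. No kinetic
constants are fitted to data.

## Digest model

Each methylation-blockable site cuts with probability (1−p_cis)(1−p_trans)
under the default either-strand-blocks rule (hemimethylation sensitivity is
not documented for these enzymes, so the rule is configurable: 'both' gives
1 − p_cis·p_trans, 'none' gives 1). Sites are independent (molecule-level
phasing is unobserved), all 2^k cut subsets are enumerated exactly (bound
k ≤ 20, with a Monte-Carlo fallback), fragments are circular interval
lengths, and identical length multisets merge. Partial digestion is not
modelled: probability mass comes only from methylation states. Fractions
sum to 1 and each pattern's fragments sum to the plasmid length by
construction; the enumeration is cross-checked against per-molecule
Monte-Carlo sampling.

## Statistics

Unpaired condition comparisons use Welch's t (group variances differ
several-fold between conditions); paired comparisons use the exact Wilcoxon
signed-rank test (the natural paired rank test; "paired rank-sum" is a
contradiction, as rank-sum is the unpaired test). P values are raw
per-comparison values with no multiple-testing correction, and are labelled
as such. Replicate reproducibility is Pearson correlation over paired
non-target frequencies (Spearman optional).

## Problem sizes and determinism

The packaged test suite runs the full pipeline at 1200–4000 bp and
150–1500× coverage; the acceptance script uses the full 4 kb / 241-dyad
plasmid at 5000× for target recovery and 500× for off-target medians —
about 200 000 reads per run, a few seconds each. One master seed drives
every stage through fixed affine offsets; identical config + seed gives
byte-identical summaries.

## What the synthetic data does and does not show

The generator emulates the measured quantities (per-strand target
frequencies vs gap, off-target medians, conversion failure, sequencing
error, restriction protection) but not the mechanisms behind them: no
enzyme kinetics drive the profiles (they are parametric anchors), no DNA
topology or supercoiling (which the off-target hotspots are thought to
reflect), no gap-library co-culture structure, no PCR or library-prep
artefacts, no real pReporter sequence (the plasmid is an explicit stand-in,
not a reconstruction). Passing recovery tests therefore demonstrates that
the analysis stack is correct and well calibrated on data generated under
its own assumptions — not that those assumptions capture everything in the
real experiments.
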