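# Methods

## Genotyping model

Each SNP marker of the hybrid is called from the read counts supporting the
two parental alleles. With `f1 = n_p1 / (n_p1 + n_p2)`:

| call    | condition                         |
|---------|-----------------------------------|
| HOM_P1  | `f1 > 0.95`                       |
| HET     | `0.25 <= f1 <= 0.95`              |
| HOM_P2  | `f1 < 0.25` (i.e. `f2 > 0.75`)    |
| NO_CALL | total depth `<= 5`, or parental reads `< 2/3` of all reads |

The asymmetry (95% vs 75%) reflects reference-alignment bias toward the
P1-like (reference) parent. All homozygous cutoffs are strict, the
heterozygous ranges inclusive, and "greater than 5×" is read literally
(callable from 6 reads); every bound is configurable through
`GenotypingThresholds`. The 2/3 parental-read rule compares parental to
total reads, which is only informative when non-parental counts are
supplied (`n_other`); with two-allele depth tables it never fires.

A post-call filter removes genotype switches supported by fewer than 3
adjacent markers: a short homozygous run embedded in heterozygous context is
reassigned to HET. Design choices here that the genotyping rules leave
open:

* **NO_CALL transparency.** Uncalled markers neither break runs nor count
  toward run length; fragmenting tracts at random low-coverage sites would
  bias tract counts upward. Reassignments are logged.
* **Asymmetric by default.** The filter guards against read-ratio bias
  turning heterozygous markers homozygous; the reverse error is not
  ratio-driven, so HET islands inside homozygous tracts are kept. A
  `symmetric=True` option exists.
* Runs touching chromosome ends are held to the same minimum.

The coverage screen averages depth in 10 kb windows, normalises by the
genome-wide median of window means, and flags windows at ratio ≤ 0.75 or
≥ 1.25 as candidate CNVs (plumbing thresholds, not calibrated values);
markers in flagged windows can be excluded from LOH analysis.

## Tract assembly and event calling

Mother/daughter marker pairs are classified 2:2 / 3:1 / 4:0; 4:0 markers
(same homozygote in both cells, the signature of a premeiotic conversion)
are excluded up front. Assembly is two-step: first 3:1 markers are set
aside and contiguous 2:2-homozygous markers of one orientation become rLOH
tracts (so an embedded conversion does not split an rLOH); then all markers
are regrouped and maximal same-genotype 3:1 runs become nrLOH tracts.

Tract coordinates span the outermost member markers; an event breakpoint is
reported as the interval between a tract's edge marker and the nearest
flanking retained marker of different genotype (marker data cannot localise
it more finely). A tract is terminal iff it contains the arm's distal-most
*retained* marker. Arms are defined by the centromere interval; markers
inside it belong to no arm, and tracts whose ends fall on different arms
are flagged for review rather than classified.

nrLOH classification: contained in an rLOH span → NCO; immediate retained
neighbour inside an rLOH span → CO-associated GC (the corresponding CO
event is upgraded to `CO_GC`); holds the arm's last marker → terminal NCO;
otherwise NCO. `count_cos` counts one CO per terminal and two per
interstitial rLOH. `merge_events` collapses events whose intervals lie
within `max_gap` (default 5 kb — a scale just above conversion-tract
lengths; configurable) with precedence CO_GC > CO > NCO, upgrading a CO
merged with a nearby conversion to CO_GC; merges are logged instead of
manually reviewed.

## Detection probability and corrections

The enumeration model: four chromatids (two sisters per homolog, joined at
the centromere), distal content initially `(P1, P1, P2, P2)`. COs apply
proximal → distal; each picks uniformly one of the four chromatid pairs of
*opposite current distal content* and exchanges distal content; equational
segregation then sends one chromatid of each original sister pair to the
mother (4 equiprobable outcomes). Detected COs per outcome equal the number
of zygosity changes along the arm (equivalently terminal tracts + 2 ×
interstitial tracts). `enumerate_detection` enumerates all `4^k × 4`
outcomes exactly (rationals; k ≤ 8), and `detection_table` uses an
equivalent exact dynamic program over the six content states for any k; the
two are cross-checked in the tests, as is a vectorised Monte-Carlo sampler
of the same model.

The pair-choice rule matters. A content-neutral rule choosing uniformly
among the four homolog-crossing chromatid pairs (`inter_homolog`) yields
only 3/8 detection at k = 2 and is provided for model comparison; the
opposite-content rule is the package default because it is the one whose
exact values (1/2, 5/8, 5/8, 41/64) the analysis relies on. Both rules are
selectable everywhere.

`correct_counts` divides observed COs by the detection bounds
`[p_low, p_high] = [1/2, 2/3]`, applies the GC-association fraction
(default 0.81) for the GC-CO range, subtracts to get NCOs (pairing low NCO
with high GC-CO), and pairs low NCO with high CO for the fold-excess range.
Counts round half-up to integers. `compare_detection_rates` contrasts an
observed detected/masked split with an expected percentage via a two-sided
Fisher exact test, applying the expected proportion to the same total to
form the second row of the 2×2 table (the comparison convention is a
package choice; only the observed percentage is a primary result).

## Masked-CO revealing from tetrads

Sporulating an RTG diploid replicates its two haplotypes into four
chromatids, recombines them and delivers one per spore. In regions
heterozygous in the RTG parent, a spore's genotype switch between adjacent
retained parent-heterozygous markers marks a breakpoint. Per gap:

* **4 switching spores** — both parental haplotypes were recombinant there:
  a crossover already present in the parent that made no rLOH (masked CO).
  This signature is robust to CO-adjacent conversions because the parent is
  homozygous over its own conversion tract, so those markers leave the
  heterozygous frame and both haplotype breakpoints collapse into one gap.
* **2 switching spores** — a crossover arising during sporulation (only two
  chromatids involved).
* **1 switch** — a sporulation conversion-tract boundary; **3 switches** are
  flagged (a sporulation event colliding with a masked CO's gap — the rare
  genuinely ambiguous case, surfaced for review rather than guessed).

Gaps spanning a detected rLOH tract of the pair (whose COs were already
counted — including narrow rLOHs from close double COs) or wider than
10 kb are skipped. Mendelian QC (parent-homozygous markers 4:0,
heterozygous markers 2:2/3:1) is reported with every run.

## Synthetic-data generator

The generator emulates the hybrid-RTG study design end to end; its defaults
are the study conditions, fixed once:

| parameter | default | rationale |
|---|---|---|
| genome | 16 yeast chromosomes, 12.1 Mb | standard chromosome lengths and centromere positions |
| marker spacing | exponential, mean 191 bp | hybrid SNP density (~0.7% divergence) |
| COs per arm | Poisson(0.7) | ≈22 true COs/cell, matching observed CO counts after detection loss |
| NCOs per arm | Poisson(1.3) | ≈42 true NCOs/cell, matching corrected NCO counts |
| GC with CO | 0.81 | observed CO–GC association |
| GC tract length | gamma(shape 2, mean 2.3 kb) | observed mean nrLOH size; shape 2 keeps sub-marker tracts rare |
| centromere exclusion | 10 kb | centromeric DSB depletion (no profile assumed) |
| telomere exclusion | 15 kb | subtelomeric repeats are not genotyped in the emulated data; also keeps terminal conversions, which marker data cannot resolve, out of the observable frame |
| read depth | Poisson(50), error 0.005 | typical short-read genotyping depth |
| sporulation rates | 2.3 CO / 0.85 NCO per arm | a complete meiosis (~73 COs, ~27 NCOs per tetrad) |
| premeiotic 4:0 rate | 0 (switchable) | observed to be rare |

Event placement keeps footprints (CO gap flanks plus conversion tract) at
least one marker apart and clamps each CO's conversion tract to one side of
the exchange point, so every simulated event has a well-defined observable
signature; per-cell event counts beyond these rates are a modelling choice,
as the real per-cell distribution is known only to vary widely.
Conversions are whole-marker, unidirectional content copies — heteroduplex
and intra-marker breakpoints are not modelled, since only marker-level
genotypes are scored. `SimTruth` records every choice, replays
deterministically, and `expected_events` projects the truth onto what an
ideal caller sees given the recorded segregation (a masked CO's conversion
tract, for instance, projects to an independent NCO). `co_per_arm_fixed`
pins the per-arm CO count for calibration experiments (it also applies to
sporulation runs using the same config).

What passing simulator-based tests shows — and what it does not: the caller
recovers exactly what the generative model makes observable, and the
detection-probability machinery is self-consistent at cohort scale. Real
data add alignment artefacts, coverage heterogeneity, marker-QC losses and
aneuploidy, which the generator does not model beyond per-read error and
Poisson depth.

## Linkage scan

Single-marker LOD: phenotype normal with one mean per diploid genotype
class, `LOD = (n/2) log10(RSS0/RSS1)`; monomorphic markers are skipped, a
perfect fit is capped by flooring RSS1 at 1e-12 of RSS0, and binary traits
use the same machinery (an optional `binary_collapse` pools the homozygous
classes). No interval mapping: the cohorts are fully genotyped at dense
markers. The genome-wide threshold is the conservative ceiling order
statistic of max-LOD over seeded phenotype permutations (1000 by default,
5% tail). Calibration and power checks in the tests use a two-chromosome
0.7 Mb genome at 1 kb marker spacing — adjacent markers at RTG LOH-tract
scale are in near-complete linkage, so denser maps add markers but no
information — with 36-strain cohorts matching the study design.

## Numerical and degenerate-input conventions

Exact enumeration uses `fractions.Fraction` throughout; corrected counts
round half-up; the genotype caller's fraction comparisons carry a 1e-9
epsilon against float division; empty inputs raise (`coverage_windows`,
`expected_detection_frequency`) or return empty structures (`merge_events`,
tract assembly on all-HET pairs); a constant phenotype warns and returns an
empty scan rather than dividing by zero.

## Known limitations

* Breakpoints are resolved only to inter-marker intervals; tract lengths are
  visible spans (outermost member markers), which under-report true tract
  lengths by about one marker spacing per end.
* The masked-CO reveal attributes events by switch parity per gap; two
  independent sporulation COs landing in the same inter-marker gap, or a
  sporulation event colliding with a masked CO's gap, are mis-attributed or
  flagged, respectively (both rare at yeast event densities).
* `classify_nrloh` trusts the run-length filter upstream; with very noisy
  calls and `min_markers=1` spurious single-marker conversions survive.
* The equational-segregation model assumes no chromatid interference and
  uniform CO placement along arms outside the exclusion zones.
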