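# Methods

## Motif model

A *cre* site is represented as an ordered list of allowed-base sets parsed
from an IUPAC string (default `TGWNANCGNTNWCA`). Positions whose allowed
set is a strict subset of {A, C, G, T} are *conserved*; a configurable
subset of conserved positions (default the central `CG`, positions 7–8) is
*exempt*, meaning no substitution is tolerated there at all. A window
matches when every exempt position agrees and the number of disagreeing
conserved, non-exempt positions is at most the budget (default 2).
Non-conserved (N) positions never contribute mismatches. This is a hard
count model, not a position-weight matrix: the operator definition in the
CCR literature is itself a degenerate consensus, and a mismatch budget
keeps the match predicate exact and auditable.

Scanning encodes the sequence as integers and accumulates, for each of the
14 pattern offsets, a boolean "disallowed base" lookup over all window
starts, so a 2 Mb chromosome scans in well under a second without any
per-window Python loop. The reverse strand is scanned on the reverse
complement and coordinates are mirrored back (`start' = L − end`). Windows
containing non-ACGT characters are skipped rather than wildcarded —
ambiguity runs would otherwise match the many N positions of the consensus
and inflate hit counts. Forward and reverse hits at the same footprint are
both reported by default; `dedupe_overlap` collapses reverse-complement
pairs at identical footprints, because published genome-wide hit totals
rarely state which convention they used and the two modes bracket the
truth.

### Promoter coordinates

Internally all coordinates are 0-based half-open; file interfaces follow
each format (GFF3 and the annotation TSV are 1-based inclusive, BED is
0-based half-open). A hit's promoter position is the signed offset of its
5′-most base *on the gene's coding strand* (leftmost base for + genes,
rightmost for − genes) from the first base of the start codon, with no
zero: −1 is immediately 5′ of the ATG, +1 is the A. Anchoring on the
5′-most base rather than the motif centre is what allows a site physically
overlapping the start codon to carry a small negative offset (e.g. −8 with
its last six bases covering +1…+6), matching how such sites are reported.
The hit's own strand is deliberately ignored during mapping — cre sites
are quasi-palindromic and bound by a dimer, so either orientation is
biologically meaningful. The default window of −300…+15 covers the offsets
at which functional sites are reported (roughly −160 to −8, including
start-codon overlap) with generous margin; it is a parameter, not a claim
about promoter architecture.

## Two-color differential expression

The experimental unit is one strain grown on glucose and on ribose,
co-hybridized on the same array, with three biological parallels, three
probe replicates per gene per array, and one additional dye-swap
hybridization of one parallel (four arrays per strain in total).

1. **M/A values.** M = log₂(ribose/glucose) after orientation correction
   (the design records which channel carries the ribose sample), A = mean
   log₂ intensity. Excluded spots and spots with a non-positive channel
   are dropped and counted.
2. **Normalization.** Within arrays, a loess fit of M on A (span 0.4,
   interpolation step 1% of the A range) is subtracted; arrays with fewer
   than 20 spots fall back to median centering. Between arrays of a
   strain, M is rescaled to a common MAD (geometric mean of per-array
   normal-consistent MADs). Print-tip loess is not offered because the
   simplified intensity format carries no grid metadata. A constant dye
   offset is absorbed by the loess centering, so the dye-swap array mainly
   guards against gene-specific dye bias, which this model does not
   attempt to estimate.
3. **Probe-replicate correlation.** Replicate spots of a gene within an
   array are correlated; treating them as independent would overstate
   precision roughly three-fold. Per gene, the within-array correlation is
   estimated as the one-way intraclass correlation over array groups
   (ICC(1), with the unequal-group-size correction for the average group
   size); per-gene values are Fisher-z transformed, combined by a 10%
   trimmed mean over genes, and transformed back. The trimmed mean makes
   the consensus robust to degenerate genes; values are clipped to ±0.999
   before the z-transform.
4. **Gene-wise GLS.** Each gene is an intercept-only generalized
   least-squares fit with block-diagonal compound-symmetric correlation
   (blocks = arrays). The block structure gives closed-form sufficient
   statistics — for a block of k replicates, 1ᵀV⁻¹1 = k/(1−ρ+kρ) and
   yᵀV⁻¹y = (Σy² − ρ/(1−ρ+kρ)(Σy)²)/(1−ρ) — so the 2000-gene fit is a
   pandas groupby, with residual df = n_obs − 1. Genes observed on fewer
   than two arrays are reported untestable with NA statistics.
5. **Empirical-Bayes moderation.** The prior (d₀, s₀²) is estimated by
   matching the mean and variance of log s² using digamma/trigamma
   identities; the trigamma inverse is solved by Newton iteration
   (relative tolerance 1e-8), and d₀ ≥ 1e6 — which arises when the
   between-gene spread of log s² is no larger than its sampling
   variance — is treated as infinite, shrinking every variance to s₀².
6. **Multiple testing and calls.** BH step-up adjustment (delegated to
   statsmodels, with an independent brute-force oracle in the tests);
   up/down calls use strict inequalities q < 0.01 and |log₂| > 0.5, with
   |log₂| > 1 flagged strong. Strains are analyzed independently — they
   are separate hybridization series, and no cross-strain shrinkage is
   attempted.

## Cross-strain comparison

Venn regions are computed over the up/down call sets per strain. A locus
is *common* only if called in the same direction in every strain **and**
marked present (status P) everywhere in the optional presence matrix;
divergent/absent (D) and uncertain (U) loci are excluded from the common
set (U can optionally be treated as P). Loci called up in one strain and
down in another are direction-discordant: they are excluded from both
common lists and reported separately rather than silently assigned to
either side.

## ΔCT qPCR

Relative expression assumes an amplification efficiency of exactly 2 (one
cycle = one log₂ unit): per condition, ΔCT = mean CT(target) − mean
CT(reference); log₂fc = ΔCT_glucose − ΔCT_ribose (lower CT = more
transcript). CT replicates are averaged arithmetically before
differencing. Concordance with array ratios is summarized as sign
agreement and Spearman correlation over shared genes; no efficiency
calibration or absolute quantification is attempted.

## Synthetic data: what it emulates, and what it does not

The generators exist so that every stage has a testable input with known
truth. Defaults are the study conditions used throughout the tests and
the acceptance script:

| parameter | default | meaning |
|---|---|---|
| gc_fraction | 0.41 | low-GC Gram-positive background |
| n_genes | 2000 | genes on the array |
| strains | 3 | independent hybridization series |
| arrays/strain | 3 + 1 dye swap | biological parallels + swap of parallel 1 |
| probe replicates | 3 | spots per gene per array |
| pi0 | 0.85 | fraction of unregulated genes |
| effect_range | 0.5–4.0 | magnitude of planted log₂ effects |
| d0, s0_2 | 4, 0.05 | variance prior (gives spot SDs of ~0.15–0.5) |
| rho | 0.4 | within-array probe-replicate correlation |
| dye_effect | 0.2 | constant dye bias on the measured log-ratio |
| exclude_rate | 0.01 | spots flagged bad |
| A | Normal(10, 1) | mean log₂ intensity per spot |
| qPCR noise | 0.3 cycles | CT measurement noise |

These values were chosen once to give roughly 90%+ detection power at
|log₂| = 1.5 with three arrays, matching the sensitivity regime the
thresholds (q < 0.01, |log₂| > 0.5) imply. The genome generator is i.i.d.:
no codon structure, operons, or repeat families. The array generator plants
effects additively on the M scale with Gaussian array- and spot-level
noise and reconstructs intensities from (M, A); it has no
intensity-dependent dye trend beyond the constant offset, no spatial
artifacts, and no background subtraction issue. Passing tests therefore
demonstrate that the statistical machinery is correct under its own model
assumptions — correlation recovery, variance-prior recovery, FDR control,
power — not that real hybridization data meet those assumptions.
Accidental consensus matches arising in random background are legitimate
hits; the planting step re-scans the genome and records them in the truth
set so recovery tests compare against planted ∪ accidental.

## Numerical and degenerate-input choices

- Scanner: contigs shorter than the pattern yield no hits and no error;
  empty genomes yield empty hit lists.
- GLS: ρ is required in (−1, 1); residual sums are clipped at zero before
  division to absorb −1e-18-type round-off.
- Moderation: all-identical variances give d₀ = ∞ (documented limit);
  genes with df = 0 are excluded from prior estimation.
- BH: NaN p-values pass through as NaN q-values without affecting the
  ranks of the finite entries.
- Correlation estimation requires ≥ 50 usable genes and raises otherwise;
  degenerate zero-variance genes are skipped.
- Pipeline: stage failures abort with the stage name; the manifest is
  written with a FAILED marker and partial outputs are retained.

## Problem sizes

The test suite and acceptance script run at deliberately moderate sizes
chosen to exercise the asymptotics the methods rely on while keeping a
full run in tens of seconds: 100 × 2 kb sequences for scanner-oracle
equivalence, 2000 genes for prior/correlation recovery, 100 fully null
runs of 2000 genes for realized-FDR measurement, 20 runs of 500 genes for
power, and a 400-gene 3-strain experiment with 40 planted common-up and
20 common-down genes for the end-to-end Venn recovery. The synthetic
pipeline default (200 kb genome, 300 genes) is sized similarly.

## Known limitations

- The mismatch-count model gives every within-budget hit equal status; no
  score ranks a 0-mismatch site above a 2-mismatch one beyond the count
  itself.
- The DE model estimates one consensus replicate correlation per strain,
  not per gene, and assumes compound symmetry within arrays.
- Gene-specific dye bias is not modelled; the dye swap enters only through
  orientation correction and the normalization.
- Operon structure is not inferred: promoter mapping is per gene, and the
  report join treats an optional operon map as future input.
- The ΔCT method's efficiency-2 assumption is taken as given; no
  standard-curve correction is implemented.
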