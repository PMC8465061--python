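# Methods

`selexscan` implements the computational side of a reverse-genetic workflow
for defining a transcription factor's DNA-binding consensus: iterative
cleavage-protection selection (REPSA) on a randomized-core template library,
sequencing-read refinement, EM motif discovery with an optional palindromic
constraint, palindromic matrix extension, genome scanning with exact
p-values and promoter-window annotation, 1:1 binding-kinetics fitting, and
cleavage-protection (REPA) titration quantification.  This note records the
models, the parameters that matter, and the design decisions taken where
the design was genuinely open.

## Selection simulation

**Template model.** Selection templates are 73-bp duplexes: a 25-nt left
flank and 24-nt right flank (synthetic stand-in sequences carrying FokI
`GGATG` and BpmI `CTGGAG` recognition sites in the orientations needed to
cut into the core) around a randomized 24-nt core.  Libraries are weighted
multisets of cores; flanks are constant within a library.

**Occupancy and survival.** Protein binding follows single-site occupancy:
θ = C/(C + K_D), with C the per-round protein concentration (34 nM dimer by
default).  A template survives a round with probability
θ + (1 − θ)(1 − e), where e is the enzyme's cleavage efficiency (default
0.9).  Enzyme identity (FokI rounds 1–2, BpmI rounds 3–5) is carried as a
schedule label that can modulate e only; the enzymes differ in artifact
propensity, not sequence preference, so the simulator gives them no
specificity.  Survival is sampled binomially per core; survivors are then
resampled multinomially with replacement to a fixed depth (default 1e5),
the analogue of PCR amplification at constant library size.  No mutation is
introduced at any step: selection can only re-weight sequences present in
the initial pool.

**Sequence → affinity map.** The true map is unknown, so the simulator uses
a parametric stand-in: a planted motif (letter-probability matrix, built
from an IUPAC consensus with probability uniform over each code's allowed
bases), scored as the best log2-odds over all placements on either strand
of the core (one site per template, as expected for a homodimer), and

    K_D(seq) = kd_min · exp(β · (s_max − s(seq)))

with `kd_min` the affinity of a maximal-score core (default 3 nM, the
measured consensus affinity scale) and β the energy slope per log-odds unit
(bit).  At β = 1 and the scoring pseudocount 0.01, a single mismatch at a
fully conserved consensus position costs ≈ 6.7 bits, i.e. ≈ 800-fold in
K_D — deliberately sharp, matching the observed ≥ tenfold penalties for
single point mutations.

**Scale caveat.** A real selection starts from ~6×10^10 molecules, so even
a 14-informative-position dyad consensus (match probability ≈ 6×10⁻⁷ per
random 24-mer) is present in tens of thousands of copies at round 1.  At
the desk-scale default of 1e5 templates the expected number of
zero-mismatch cores is ≈ 0.06: a simulated selection usually has no perfect
site to enrich, and the round-5 zero-mismatch fraction is then 0% no matter
how strong the selection pressure.  Passing enrichment tests at this scale
therefore exercises the machinery (surviving cores enrich in proportion to
occupancy; mean motif score is non-decreasing over rounds) rather than
reproducing the real experiment's >50% round-5 takeover, which is a
library-size effect.  Tests that need an enrichable pool use either a short
planted pattern (so perfect matches exist at desk scale) or the
`planted_core_library` generator, which embeds one sampled consensus
realization per site-bearing core at a stated prevalence.

**Sequencing reads.** Reads are flank+core+flank with i.i.d. substitution
errors at a stated rate, an optional fraction of reads with a truncated
left flank, and a constant per-base Phred score (default Q30): the
refinement stage needs a thresholdable quality signal, not a full
platform-specific error model (homopolymer indels are out of scope).

## Read refinement

A read passes if (1) its mean Phred quality is ≥ 20 (the read-level
statistic; no per-base trimming), (2) both flank anchors are found —
leftmost match, allowing one mismatch per 10 anchor bases by default — in
the read or its reverse complement, and (3) exactly 24 bases lie between
them.  Cores are reported in template orientation.  Deduplication removes
later exact string duplicates only; reverse-complement pairs are kept
because collapsing them would discard the strand information that palindrome
analysis relies on.  Refinement itself never deduplicates (so a zero-noise
round trip returns the exact input multiset); deduplication is a separate,
idempotent operation.

## Motif discovery (ZOOPS EM)

The model: each sequence contains, with probability γ, exactly one motif
site at an unknown offset on an unknown strand; otherwise it is 0-order
background (the input's base composition).  EM alternates soft assignment
over all 2(L−w+1) placements with matrix/γ re-estimation; counts receive a
Dirichlet pseudocount of 0.1 per base per position.  The palindromic
variant averages the matrix with its own reverse complement after every
M-step — the natural constraint for dyad sites bound by homodimers.

Numerical notes:

- The likelihood surface over 24-nt cores is multimodal in the alignment
  register; discovery restarts EM from 20 data-derived seedings by default
  (each from a random width-w subsequence, either strand) and keeps the
  best final log-likelihood.
- The log-likelihood is non-decreasing across iterations up to two caveats:
  pseudocounts make the M-step a MAP update, and the palindromic averaging
  is a projection, not a strict EM step.  Both effects are far below 1e-6
  relative in practice, which is the tolerance the property tests assert.
- Convergence: Δlog-likelihood < 1e-3 or 200 iterations.
- Significance is reported as the log-likelihood ratio against the
  background-only model.  MEME's E-value calibration is deliberately not
  reproduced; the statistic is labelled for what it is.

The IUPAC consensus reduces each matrix position to its top base (if
probability ≥ 0.8), the top two bases' degenerate code (if their sum
≥ 0.8), else N; dyad structure (half sites and spacer) is inferred from the
central maximal all-N run when it splits the pattern into equal N-free
halves.

## Matrix extension and formats

A dyad matrix is built from a half-site block by concatenation-with-mirror:
columns `block_start..block_end` (1-based, matching motif-report position
numbering) followed by their reverse complement, giving an exactly
self-reverse-complementary matrix of twice the block width — the only
construction consistent with an 11-column block yielding a 22-column
matrix.  An overlay-average mode (symmetrise the block with its own reverse
complement first) is available behind an option.  Motifs are read and
written in MEME minimal motif format (version, alphabet, strands,
letter-probability matrix with nsites); round trips are identity to 1e-6
per cell.

## Genome scanning

Windows on both strands are scored with log2-odds `log2((p + pc)/bg)`
(pseudocount default 0.01, background defaulting to the scanned genome's
own composition, complement-symmetrised so one null distribution is exact
for both strands).  P-values are exact under the 0-order background:
per-position scores are discretised to a shared integer grid (default 1000
bins across the widest per-position range; discretisation error is far
below the 1e-4 and 5e-6 thresholds in use) and the null distribution of the
total integer score is obtained by position-wise convolution.  Window
scores are computed on the same grid, so DP p-values equal brute-force
enumeration exactly at the same discretisation.  Benjamini–Hochberg
q-values are computed over all 2·Σ(len − w + 1) tested windows.
Overlapping opposite-strand hits of a palindromic motif at one locus are
reported separately, never merged.

Promoter annotation assigns each retained hit (p ≤ 5e-6 by default) to
every gene whose annotated start places the hit within −200..+20 on that
gene's strand.  Gene (translation) starts are the TSS proxy — predicted
transcription starts are not modelled, so offsets are not comparable to
numbers computed against externally predicted +1 sites.  Hits in the
windows of two divergent genes produce two calls flagged bidirectional;
hits inside a gene body and in no window are intragenic; the rest are
intergenic_far.

## Kinetics

The 1:1 Langmuir association-then-dissociation model (equations in the
module docstring) is fit globally — one (k_on, k_off, R_max) for all
concentrations, R_max shared as a single sensor-load parameter (per-trace
R_max available as an option) — by bounded least squares in log10 parameter
space from a grid of ≥ 8 multi-starts log-spaced over k_on 1e4–1e7 M⁻¹s⁻¹
and k_off 1e-4–1e-1 s⁻¹, tie-broken by lowest SSE; the loss is multimodal
when the signal is weak.  Concentrations are dimeric protein in nM
(converted to molar internally); K_D = k_off/k_on × 1e9 nM; R² is pooled
over all points.  A fit is reported `ambiguous` — not as numbers — when
K_D > 1000 nM (the assay's stated determination limit), when any parameter
lands on its optimisation bound, or when R² < 0.5; flat traces give R² = 0
and are therefore ambiguous.

## REPA quantification

Per-lane protection is uncleaved/(uncleaved + cleaved) for probe and
control; the normalised protection is the probe fraction minus the control
fraction (clipped to [0, 1]) — subtraction, not ratio, because the control
probe shares the reaction (and hence the enzyme-activity fluctuation) but
not the binding site.  For noiseless simulated bands the normalised
protection is exactly e·C/(C + K_D), so the optional occupancy-curve
summary A·C/(C + K) recovers K = K_D exactly; it is a one-number summary,
not a calibrated affinity measurement.

## Pipeline and reproducibility

`selexscan run` executes simulate → refine → discover → extend → genome →
scan → annotate with on-disk artifacts, per-stage sub-seeds spawned from
one global seed, and a manifest recording SHA-256 hashes of every output;
reruns are byte-identical.  The demo configuration starts from a pool with
consensus sites planted at 50% prevalence (see the scale caveat above) and
completes in well under a minute on one CPU.

## Problem sizes used in tests

Statistical contracts are checked at the largest sizes that keep the suite
fast: 1e5 cores for library composition and selection runs, 1e4 reads for
error-rate calibration, genomes of 2e4–1e5 bp for scanning, brute-force
p-value enumeration at widths ≤ 6, and a 3×3 log grid for kinetic parameter
recovery at 1% noise.  These sizes were chosen as the package's own test
design; all generators accept larger sizes unchanged.

## Known limitations

- No mutation/indel processes in selection or PCR; no platform-specific
  sequencing error models.
- ZOOPS only (no multi-site or variable-spacer motif models); single best
  motif per run, no MEME-style multi-motif erasure; no E-values.
- 0-order background throughout; no higher-order genome composition models.
- Kinetics: no mass-transport limitation, bivalent analytes, or drift
  correction beyond what a constant R_max absorbs.
- Gel densitometry is out of scope; REPA input is the intensity table.
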