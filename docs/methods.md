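# Methods

This note documents the models behind `l1screen`, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical choices that affect results.

## Limiting-dilution Poisson quantification

A well seeded with *m* pg of genomic DNA at concentration λ amplifiable
molecules/pg receives a Poisson(λm) number of molecules and is PCR-positive
iff it received at least one, so P(positive) = 1 − e^(−λm). Replicate wells
across dilutions give a product-binomial likelihood

L(λ) = Π_i C(n_i, k_i) (1 − e^(−λ m_i))^{k_i} (e^(−λ m_i))^{n_i − k_i}.

The score dℓ/dλ = Σ k_i m_i e^(−λm_i)/(1 − e^(−λm_i)) − Σ (n_i − k_i) m_i
is strictly decreasing, so the MLE is the unique root of the score,
located by bracketed root-finding (Brent, xtol 1e−15). On a single
dilution this collapses to the zero-class closed form
λ̂ = −ln(k⁻/n)/m, and the implementation agrees with it to better than
1e−9 relative (tested).

The 95% CI is the profile-likelihood interval {λ : 2[ℓ(λ̂) − ℓ(λ)] ≤
χ²₁(0.95) = 3.841}, found by root-finding on each side of the MLE.
Boundary data are flagged rather than estimated: all-negative series give
λ̂ = 0 with a one-sided upper limit (closed form 1.921/Σ n_i m_i);
all-positive series have no finite MLE and return an `all_positive` flag
with a lower limit only. Calibration is checked by simulation at the
regime the screen operates in — λ = 1/12 molecules/pg over a half-log
input series of 1, 3, 10, 30, 100 pg with 8 replicate wells per dilution
(the replicate count used at the bench; the half-log step is this
package's choice of an informative serial-dilution design spanning
1–100 pg) — where the profile CI covers the generating λ in ≥93% of 500
seeded series (nominal 95%).

Single-molecule PCR efficiency is the estimated concentration divided by
the physical copy density (copies per genome / pg per genome). One
amplifiable molecule per 12 pg at one copy per 6-pg diploid genome is 50%
efficiency — the filled-site value the screen's depth calculation assumes.

## Molecule accounting through PCR and enrichment

The accounting is at the level of expectations: n cycles of per-cycle gain
g multiply a compartment by gⁿ, and each enrichment round multiplies the
filled and empty compartments by their recovery fractions. Defaults are
the measured operating point: g_empty = 1.8 and g_filled = 1.6 over 20
cycles (long ~12 kb filled amplicons replicate less efficiently than ~5-6
kb empty ones), recovery ≥2×10⁻² for element-containing molecules versus
<4.5×10⁻⁸ for empty-site molecules per round. The net per-round
re-extraction protocol is folded into the recovery fraction. No
branching-process variance is modelled — the quantities of interest
(ratios of ~10⁴-fold different populations) are insensitive to it, and a
stochastic PCR model is out of scope.

With one filled molecule in 0.5 µg of input (≈8.3×10⁴ diploid genomes),
20 cycles yield 1.6²⁰ ≈ 12,089 filled molecules against
8.3×10⁴ × 1.8²⁰ × 10 targets ≈ 1.06×10¹¹ empty ones. With the
conventional intermediate rounding (12,000; 8×10⁴ genomes; 10¹¹ empty)
the filled:empty ratio is 1 : 8×10⁶. Note the printed recovery fractions
imply a per-round enrichment factor of 0.02/4.5×10⁻⁸ = 4.4×10⁵ and a
post-round ratio of 1:18.75; headline descriptions of this step sometimes
round these to ">500,000-fold" and ">1/16", which are not exactly
recoverable from the stated fractions. Rounding helpers
(`to_sig_figs`, `floor_to_nearest`, `nearest_power_of_ten`) live in the
reporting layer only and are never applied inside computations.

## Screening depth and the zero-event bound

The panel's effective per-sperm target is Σ lengths with X-linked loci at
half weight (they are present in only 50% of sperm). Kilobases screened =
effective kb × amplifiable molecules per target, where molecules = (mass /
pg per haploid genome) × filled-site efficiency. Observing k insertions
bounds the expected count by the exact one-sided Poisson upper limit: the
smallest λ with P(X ≤ k; λ) ≤ α, computed by root-finding on the Poisson
CDF (for k = 0 this is −ln α; it equals χ²_{2k+2}(1−α)/2, which serves as
an independent cross-check in the tests). This choice of a one-sided
exact bound is the only convention under which zero events at α = 0.05
gives "three insertions", the screen's stated event bound. The haploid
genome is fixed at 3×10⁶ kb and the diploid genome at 6 pg.

With the packaged ten-locus panel (50,819 bp; 37,782.5 bp effective) and
the full screen's constants, the chain gives 3.63×10⁹ kb screened and
<1 insertion per 403.6 → floored 400 haploid genomes; the floor is stable
whether the unrounded chain or the conventionally rounded intermediates
(38 kb, 3.7×10⁹ kb) are used.

## Target-locus suitability

Three criteria, applied to candidate trap loci:

1. **Capture-oligo cleanliness** — gapless Hamming scan of every window on
   both strands against each capture oligo; any window within 3
   substitutions disqualifies the locus (otherwise empty sites are
   themselves captured). Ambiguous bases count as mismatches. Both strands
   are scanned because the amplicon is double-stranded; this is
   configurable.
2. **Integration-site supply** — exact occurrences of the L1 endonuclease
   nick consensus 5'-TTAAAA-3' on either strand (minus-strand sites are
   occurrences of the reverse complement). The motif is configurable; the
   canonical hexamer is the default since the consensus is degenerate and
   no single authoritative pattern exists.
3. **Primer real estate** — maximal repeat-free intervals of at least a
   minimum width, computed as the complement of the union of repeat
   intervals supplied as BED input (repeat annotation itself is out of
   scope).

## Amplicon classification

Scoring scheme for all alignments: match +1, mismatch −1, gap open −2,
gap extension −1 (a gap of length L scores −(L+1)). Small problems
(query × reference ≤ 10⁶ cells) are solved by exact affine-gap
Smith-Waterman (Biopython's `PairwiseAligner`); the tests verify these
scores against an independent exhaustive DP implementation on sequences
≤300 nt. Larger problems (a ~11 kb amplicon against a ~5-6 kb reference)
are localized by exact 16-mer seeding chained on a diagonal band
(skipping reference k-mers occurring more than 8 times, which suppresses
homopolymer noise), greedily extended by exact matches, scored via an
edit-distance path (edlib), and trimmed to the best-scoring local
sub-path — the standard seed-and-extend design of read mappers, with the
same scoring scheme applied to the final path. The heuristic may decline
marginal mismatch extensions the full DP would accept; boundary
placements agree to within a few bases, which is within the intrinsic
microhomology ambiguity of junction calling anyway. Ties between
equal-scoring alignments are broken toward the smaller start coordinate.

Annotation proceeds as: (i) flank search — best target hit anchored at
each amplicon terminus (amplicons are primed from their ends, so a true
flank must reach its terminus; interior hits found first are carved out
and the search repeated); (ii) element search on both strands, reporting
orientation and the 5'-truncation offset; (iii) poly-A search anchored at
the element's 3' side (an A-tract 3' of the element in plus orientation;
a T-tract 5' of it in minus), extended by a +1/−2 score argmax so the
tract does not absorb flanking sequence; (iv) TSD search — the longest
exact repeat that is simultaneously a suffix of the target before the 5'
flank's endpoint and a prefix from the 3' flank's startpoint.

Verdict rules: **genuine** requires both flanks present and collinear on
the target (3' flank resuming at or slightly before where the 5' flank
ended, the overlap being the TSD), an element segment, and a poly-A tail;
a TSD is recorded but not required, since blunt insertions occur and the
defining criteria are flanks + element + poly-A. **no_insertion** means
no element segment was found (the evidence notes whether the flanks
reconstruct the bare target). **chimera** means an element segment with a
missing or discordant flank; the A+T fraction in a 20-nt window at the
discordance junction is recorded, mirroring the observation that
template-switch artifacts fuse at A/T-rich tracts. Everything else is
**unresolved**. Thresholds (flank identity ≥0.90 over ≥50 nt; element
identity ≥0.85 over ≥100 nt; poly-A ≥10 nt at ≥0.8 purity within 10 nt of
the element end; TSD 4–30 nt; junction window 20 nt at 0.70) are all
configurable; defaults reflect canonical TPRT hallmarks.

TSD lengths are recovered up to small chance extension: when the target
base preceding the nick happens to match the base preceding the
duplication (microhomology), the longest exact repeat exceeds the planted
length. This ambiguity is intrinsic to junction annotation, so round-trip
tests allow the recovered TSD to exceed truth by up to 4 nt.

## Synthetic data

The generator emulates the structural content of the screen, not its
physics. Backgrounds are i.i.d. nucleotides at a configurable GC fraction
(default 0.42, the human genome-wide value) — the simplest model
satisfying the scan constraints. The element reference is a random 6-kb
sequence whose 3'-terminal 1.5 kb supplies the capture oligos (exact
reverse complements of evenly spaced windows); being random, it has no
repeat structure, so oligo uniqueness holds by construction and is
verified by scanning. Target loci are scrubbed of incidental endonuclease
motifs (replacement with G/C cannot create new occurrences of an A/T-only
motif, so scrubbing converges), then seeded with a requested number of
motifs at spaced interior positions, and rejected/regenerated if any
window comes within 3 mismatches of a capture oligo.

Genuine amplicons follow the TPRT convention: `target[:p+t] + element +
polyA + target[p:]`, duplicating the *t* bases 5' of the nick; the
bundle generator varies truncation (0 to 4 kb), orientation, TSD length
(7–20 nt) and poly-A length (15–30 nt). Chimeras fuse the target's
planted 25-nt A-homopolymer linker to a donor locus's linker, the donor
carrying a 1.5-kb element 3' end downstream — the anatomy of a
template-switch artifact joined through a shared A-rich tract, yielding
an intact ~50-nt A-tract at the fusion point. A `polyA_error_rate` knob
degrades tail purity for robustness experiments.

Not emulated: sequencing error, cloning bias, bead-capture kinetics, PCR
plateau effects, element divergence from the reference (synthetic
elements are exact copies, so alignment identities are ~1.0; real
candidates at ≥85-90% identity exercise the same code paths but with
noisier boundaries), and the genome-scale repeat landscape. Passing
round-trip tests therefore demonstrate that the classification logic
implements its stated criteria, not that those criteria are robust to
every artifact of real trace data.

All generators are pure functions of their seed (sub-streams are derived
as `default_rng([seed, stream_id])` with a fixed stream id per
generator), and byte-identical reproducibility is tested end to end
through the CLI.

## Problem sizes in the test suite

The calibration simulation uses 500 series; the classifier round-trip
uses 300 amplicons (100 genuine, 100 chimeric, 100 empty over six 5-kb
targets with a 6-kb element); oracle comparisons run on ≤10-kb inputs.
These sizes give binomial standard errors small enough to resolve the
tested tolerances (e.g. ±0.9% on 95% coverage at n=500) while keeping the
whole suite under a minute.

## Known limitations

- The seeded aligner assumes a single dominant collinear hit per search
  region; structurally rearranged insertions (twin-priming inversions,
  internal deletions) would be reported `unresolved` rather than
  annotated in detail.
- Chimera donor loci are not mapped genome-wide; identifying which known
  element a chimera borrowed from requires a genome-scale search that is
  out of scope.
- The zero-event bound is frequentist and exact; no Bayesian alternative
  is provided.
- `estimate_molecules` assumes independent wells and perfect Poisson
  partitioning; inhibition and cross-contamination are not modelled.
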