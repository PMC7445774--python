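# Methods

This note documents the models behind `qtermseq`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Library design model

A terminator variant is a DNA template

```
prefix · A^a · S · L · revcomp(S) · T^u · suffix
```

with `S` the hairpin 5′ arm (5′→3′, basal positions first), `L` the loop,
`a`/`u` the poly(A)/poly(U) tract lengths (poly(U) written as T in DNA;
all design types are DNA, RNA rendering is a display concern). The 3′
arm is always the exact reverse complement of the 5′ arm — imperfect
hairpins are out of design scope (the simulator and pipeline treat them
as artifacts).

Defaults: `S` pattern `SSNNNNNNGCCGCC` (basal randomized 8-mer closed by
two strong S = C/G pairs, fixed distal hexamer), loop `GAAA`, a = u = 8,
BioBrick RFC10 prefix/suffix. The degenerate space is 2^#S·4^#N = 16,384.
**The fixed distal hexamer and the exact published assembly oligos are
not in the open literature; `GCCGCC` is a documented placeholder** chosen
to be strongly paired without introducing extra NotI sites. It does not
affect the combinatorics, geometry or any statistical property; users
reproducing a specific physical library should set the real sequences on
`TerminatorDesign`.

Enumeration order is lexicographic over resolved stems, for determinism.
Degenerate coordinates are 0-based within the stem pattern. Sampling is
uniform without replacement via lexicographic-rank decoding, so a
sampled variant's id (`V<rank+1>`) is stable regardless of sample size.

### Half-oligo assembly model

`design_half_oligos` emits a top-strand 5′ half (prefix + poly(A) + stem
pattern + loop) and a bottom-strand, 5′-phosphorylated 3′ half
(revcomp(suffix) + poly(A)-mirror + stem pattern + revcomp(loop)). Their
3′ termini pair across the constant loop; each degenerate block lies in
a single-stranded tail and is copied onto the opposite strand during
extension, which is what guarantees perfect arm pairing. In the wet
protocol the complementarity of the two independently synthesized
randomized blocks is enforced by hybridization selection during
slow-cool annealing; `assemble_in_silico` idealizes this by applying one
resolution to both oligos and performing deterministic
overlap-extension. Ligation is a no-op at sequence level. Designs whose
degenerate letters would fall inside the anneal overlap are refused.
PCR/ligation efficiency and assembly error spectra are deliberately not
modelled here (artifacts are injected downstream by the simulator).

## Read simulator

Each read is a transcript fragment starting at the amplicon 5′ end
(prefix start) whose 3′ end encodes its fate. With hairpin-end
coordinate 0 and the first downstream nucleotide +1:

* **terminated** (probability `true_te` after the truncation branch):
  offset drawn from `terminated_offset_dist` on +1..+8. Default weights
  (.30, .25, .20, .05, .04, .04, .06, .06): the mass peaks at +1..+3,
  where real libraries show their dominant 3′-end peak, with residual
  mass out to the canonical +6..+8 termination sites.
* **read-through**: offset = poly(U) length + round(Normal(30, 3)) nt,
  clipped to [+9, template end]. The ~30 nt mirrors the
  oligo-directed RNase H cleavage that gives read-through transcripts a
  proximal, sequencable 3′ end; the normal jitter is a smooth stand-in
  since only the approximate distance is known. A constant 60 nt
  reporter context (eGFP 5′ CDS) downstream of the suffix gives these
  ends a template to land on.
* **truncated** (probability `truncation_rate`, default 0.15): offset
  uniform over the hairpin-internal positions (−(hairpin length−1)..0).
  Real libraries show a large truncated population whose shape is not
  published; uniform is the minimal-assumption choice.

Base-call errors are i.i.d. substitutions (default 10⁻³). Quality
strings use one Phred level per read, drawn Normal(32, 3.3) and clipped
to [2, 40] — calibrated so that ≈73 % of reads clear the mean-Q ≥ 30
filter, the fraction reported for the original sequencing run. Per-base
quality variation adds nothing to the 3′-end logic and is omitted.
Reads are single-end; the published 2×150 paired-end layout adds no
information for 3′-end classification at amplicon scale.

FACS-bin simulation routes each variant, per replicate, to the gate
containing `true_te·100 + Normal(0, sort_noise_sd)` (default sd 5 TE
points; gates left-closed/right-open, last gate closed) and re-simulates
each gate fraction at the configured depth. Temperature-series
simulation draws independent samples per (temperature, replicate) with
seeds derived deterministically from the master seed via
`numpy.random.SeedSequence`, so any sub-experiment is reproducible in
isolation. `simulate_te_table` provides the same estimator sampling law
(TE = 100·Binomial(n, te)/n) without sequence overhead, for calibration
studies at thousands of variants.

What a green simulation-based test does **not** establish: recovery of
real-data values (622 analysed variants, 423 > 90 % TE, specific
benchmark TEs, …), which depend on the original sequencing archive and
the unpublished oligo sequences; PCR amplification bias; context
dependence of TE; RNA degradation beyond the uniform truncation model.

## Quantification conventions

* **Coordinates**: the hairpin's last (3′-arm-final) nucleotide is 0;
  offsets downstream are positive. The terminated window is the closed
  interval [+1, +8]; ≥ +9 is read-through; ≤ 0 is truncated. The window
  is configurable but these are the published boundaries.
* **QC**: "≥Q30" is implemented as mean read quality ≥ 30 (per-base
  minimum available via a flag), mirroring how run-level Q30 fractions
  are reported. Adapter suffixes are trimmed at ≥ 90 % identity with a
  hand-rolled leftmost-suffix scanner (the cutadapt tool itself is not a
  dependency).
* **Matching** anchors reads by exact match to prefix + poly(A)
  (configurable mismatch budget, default 0 — conservative, testable) and
  assigns a variant only when the *complete* hairpin (both arms + loop)
  is present and self-complementary; the loop identifies orientation
  (GAAA forward / TTTC reverse). Because the amplicon geometry is fixed,
  anchored-but-truncated reads still get an offset (≤ 0) and are
  discarded from TE with an explicit class label. Variants are
  discovered de novo (keyed by stem) unless a library is supplied.
* **TE/TPM**: TE_TS = 100·terminated/(terminated+read-through). TPM is
  reads-per-million over classified reads, *without* length
  normalization (all variants share one locus and near-identical
  length), computed before the ≥200-read and top-2000 filters so the
  unfiltered table conserves 10⁶ exactly. Naming T1, T2, … follows
  descending total reads with lexicographic stem tie-break.

## Statistics

Two-sample comparisons use pooled-variance two-tailed Student t-tests
(verified against scipy to 10⁻⁸). Zero-variance degenerate groups
resolve deterministically (equal means → p = 1, unequal → p = 0), which
matters for zero-sort-noise bin enrichment where absent bins are exact
zeros.

The published analysis quotes *df = 1* for t-tests on triplicates, which
matches neither pooled (df = 4) nor Welch degrees of freedom; the default
here is the standard pooled test, with `df_override` available as a
fidelity switch.

For the per-variant differential-TE flag, the raw "any pair p < α" rule
over the six temperature pairs has a per-variant false-positive rate of
~20 % at α = 0.05 (measured on null simulations) — far above nominal. The
default flag therefore applies a Holm correction across the pairs within
each variant, which measures at ~4–5 % under the null while retaining
full power for large effects (a 78-point TE difference is flagged
essentially always). `correction="none"` restores the uncorrected rule;
Benjamini–Hochberg is also available. No across-variant multiple-testing
correction is applied by default, matching the original analysis.

Bin enrichment reports both published rules: the most-abundant bin
(greatest mean TPM) and significant enrichment (one bin beating all
others with every pairwise p < α). A variant unobserved in a bin has
TPM 0 there, not missing — after sorting, absence is informative.
Enrichment is computed on raw TPM (TPM counts are quoted directly in the
source analysis; log-scale was not indicated).

## Structure features

The built-in folding backend scores only a single outer-anchored perfect
helix: the longest contiguous complementary stem (allowing up to 3 nt of
end trimming), summing Watson-Crick nearest-neighbor stacking free
energies (Turner-style 37 °C parameters, kcal/mol; G-U stacks
approximated by a constant −1.0) plus a hairpin-loop initiation penalty
(5.6 kcal/mol for a tetraloop, Jacobson-Stockmayer extrapolation
otherwise). This is exact enough for the designed perfect hairpins and
for energy-ordering assertions; it is *not* a general structure
predictor — use the `vienna` backend (RNAfold at 37 °C, `-p -d2 --noLP`)
for real folding. Sequences with no stem of ≥ 2 pairs and a ≥ 3 nt loop
report ΔG = 0 and an all-dot structure.

Every ΔG carries a unit tag and threshold queries must state their unit:
the published TE/ΔG threshold is printed in kJ/mol while RNAfold reports
kcal/mol, and refusing silent conversion keeps that ambiguity visible
instead of propagating it.

TE pools use half-open boundaries [0,90), [90,99), [99,99.9),
[99.9,100] — the printed cutoffs (<90 %, >90 %, >99 %, >99.9 %) overlap
as stated, and counting requires a partition. The closing-pair motif is
5′-GG…CC-3′: both basal pairs G on the 5′ arm (a GC start is G-C then
C-G and does not count). Logo heights default to raw frequencies per
the source figures; information content (bits) is an option.

## Flow cytometry

The interference formula is implemented as
TE_IF = [1 − (⟨mB⟩/⟨eG⟩)₀ ÷ (⟨mB⟩/⟨eG⟩)_Term]·100 — the unique reading
of the (typographically garbled) printed formula under which a
no-terminator sample gives 0 % and complete eGFP suppression gives
100 %. Channel means over gated events are used (matching the ⟨·⟩
notation); a per-event-ratio mode is available. The estimate is
invariant to common intensity rescaling. Raw (possibly negative) and
[0,100]-clipped values are both reported. Synthetic events model mB as
log-normal with eG tracking mB through a control ratio attenuated by
(1 − TE), so copy-number variation cancels exactly as in the real assay.

## Reproducibility

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; sub-experiment seeds derive from the master
seed via `SeedSequence`, and identical configurations produce
byte-identical FASTQ. CLI runs record version, parameters, seeds and
input checksums in a JSON manifest, plus read counts at every filter
stage so each stage is independently re-derivable.

## Known limitations

* The built-in folder cannot score bulges, internal loops or multi-helix
  folds; imperfect hairpins simply score as their best contiguous stem.
* The simulator does not model sequence-dependent abundance bias (e.g.
  A/T-rich PCR favoritism) or cross-contamination between FACS bins
  beyond the Gaussian sort-noise model.
* Exact-match anchoring discards reads with errors in the constant
  flank; this loses depth but cannot bias TE, since errors are
  independent of read class.
* `quantify_replicates` reports only variants passing the read filter in
  every replicate; variants drifting around the threshold are dropped.
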