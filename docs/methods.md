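# Methods

## Background and model

Nucleosomal DNA (~147 bp wrapped around the histone octamer) carries a
statistical sequence signature: distinctive dinucleotides (AA/TT in yeast,
GC-type dinucleotides in several higher eukaryotes) recur with the DNA
helical repeat of roughly 10–10.4 bp, and their positional distribution is
pseudo-two-fold symmetric about the dyad, the central base pair of the
wrapped DNA. `nucpatterns` derives these *nucleosome positioning sequence
(NPS) patterns* from an ensemble of nucleosomal sequences aligned by a
common experimental end (typically the MNase cleavage end), and uses the
derived patterns to map the most likely dyad position in new sequences.

The pipeline is:

1. **Binary encoding** (`dinuc`). A sequence of length L is encoded, per
   dinucleotide class, as a binary vector of length L−1: entry *i* is 1 iff
   the dinucleotide starting at base *i* belongs to the class. Classes are
   the 16 literal dinucleotides plus the composites WW, SS, RR, YY.
   Composites are first-class codes, so all downstream operations are
   class-agnostic. Occurrences are indexed by the dinucleotide's first
   base, which fixes the profile length at L−1; all reported coordinates
   are 1-based.
2. **Frequency profiles** (`profiles`). The profile of a class is the
   column mean of its occurrence matrix across the batch — the fraction of
   sequences carrying the class at each position. No pseudocounts are
   added; exact zeros are legitimate and Pearson correlation downstream
   handles them (zero-variance windows become missing values rather than
   spurious scores). Profiles carry `n_sequences` so standard errors are
   computable.
3. **Start detection by dyad symmetry** (`dyad`). At candidate start *s*,
   the forward profile window `P_c[s..s+W−1]` is correlated with the
   mirrored window of the reverse-complement class,
   `P_rc(c)[s+W−1..s]`. This index pairing is chosen so that exact dyad
   symmetry of the window makes the correlation exactly 1, which is both
   the detection principle and a direct test invariant. W defaults to 146
   profile positions (the nucleosome core size); 147 is equally supported
   via the parameter, since both conventions are in common use.
   Because the informative class differs between systems (AA/TT in mouse
   chromatin, AT and GC in human), inference takes a user-chosen class set
   (default {AA, TT}), maximizes the mean track, and always returns a
   per-class argmax/max diagnostic table: the choice is automated but
   deliberately overridable. The default search interval starts one
   position past the global profile maximum — the cleavage-site peak that
   end-alignment produces — since the nucleosome start is expected close
   downstream of the cleavage site. Ties break toward the smaller
   position so outputs are deterministic.
4. **Pattern construction** (`pattern`). The core window of a profile is
   *symmetrized* — averaged with the mirrored window of its
   reverse-complement class, `out[j] = (P_c[s+j] + P_rc(c)[s+W−1−j])/2` —
   so both strands contribute equally; then *trimmed* by 4 positions per
   end (cleavage-boundary artifact removal) and *smoothed* with a
   3-position centered moving average (valid positions only, no padding).
   Trimming precedes smoothing so boundary positions cannot leak into the
   averages; the final length is `W − 2·trim − (smoothing − 1)` (136 for
   the defaults). Profile "normalization" is implemented as mean-centering
   at periodogram time rather than as a pattern mutation, keeping pattern
   values interpretable as frequencies.
5. **Periodogram** (`spectral`). Power is evaluated *directly* on a dense
   period grid (2–50 bp, 0.1-bp step) as
   `|Σ_j x̃[j]·exp(2πi·j/T)|²·2/len²` with mean-centered x̃, because the
   signal of interest (10–10.4 bp) falls between integer DFT bins at
   pattern lengths of 136–146. The 2/len² constant makes a unit cosine
   score ≈0.5 at any length; at exact DFT-bin periods the evaluation
   agrees with the FFT to 1e−9 (tested). Mean-centering makes power
   invariant to additive constants and zero at DC.
6. **Mapping** (`mapping`). A pattern is slid along a target sequence; at
   each placement the Pearson correlation between the pattern values and
   the binary class indicator of the underlying segment is recorded at the
   placement's dyad coordinate (offset + ⌊m/2⌋, m the pattern length; only
   symmetric trims are produced, so the geometric center and the dyad
   coincide). The binary indicator is used on the sequence side because it
   is the only per-sequence encoding the profile machinery defines, and it
   makes the correlation well-defined without tuning. The maximum positive
   aggregated CC (unweighted mean across patterns) is the dyad call;
   absence of any positive CC yields a flagged no-call rather than an
   exception so batch runs complete. Sequences longer than two nucleosome
   lengths (294 bp) trigger a non-uniqueness warning: several true
   nucleosomes may fit, and only the single best CC is reported.
7. **Null model** (`shuffle`). Dinucleotide-preserving shuffling
   (Altschul–Erickson Euler-path algorithm, generalized to k-lets)
   destroys positional periodicity while conserving the exact k-let
   multiset — the property the null comparison needs and the invariant the
   tests enforce, including an exhaustive-enumeration oracle showing all
   Eulerian arrangements are reachable. Seeds are mandatory in the API;
   the CLI draws and logs one if omitted.

## Synthetic data generator

`simulate` produces the ground-truthed batches used throughout the tests.
It emulates three features of an MNase-style end-aligned ensemble: (a)
i.i.d. uniform background composition; (b) a fixed dinucleotide (CG) at
position 1 of every sequence, reproducing the cleavage-site sequence bias
as a narrow profile peak at the batch start; (c) a dyad-symmetric core —
AA written with probability 0.8 at every 10th position of the left half of
a 147-bp core starting at position 30 of a 400-bp sequence, and TT at the
mirror-image positions of the right half, with one Bernoulli draw shared
per site pair so each planted sequence is individually dyad-symmetric at
its planted sites. Defaults (500 sequences × 400 bp) give a clearly
detectable but noisy signal: per-sequence indicators are dominated by
background occurrences, as in real data.

What the generator does **not** emulate: MNase digestion-bias sequence
preferences beyond the fixed start dinucleotide, fragment-length
variability (real cleavage ends wander by 10–20 bp), linker-sequence
composition, GC-content heterogeneity, and inter-nucleosome correlations.
Passing tests therefore demonstrate the correctness and statistical
behavior of the method, not mapping performance on any particular genome.

## Numerical and design choices

- Pearson correlations are computed by a vectorized two-pass formula;
  windows with zero variance return NaN and are excluded from argmaxes.
  Agreement with an independent per-window computation is enforced at
  1e−10 in tests.
- All argmax ties break toward the smaller position/period, making every
  output deterministic.
- Case-insensitive sequence input is canonicalized to upper case. Records
  containing non-ACGT characters are dropped (or rejected) whole; there is
  no per-position masking, mirroring how curated nucleosome collections
  exclude masked entries.
- For the dyad-recovery evaluation the mapping uses the *generating*
  AA/TT pattern pair over the full untrimmed, unsmoothed core window with
  mean aggregation. The generating signal spans the entire core, and the
  two outermost planted sites are precisely what disambiguates placements
  offset by one helical turn; the trimmed/smoothed variant remains the
  default for derived-pattern publication and spectral analysis, where
  boundary artifacts matter more than phase discrimination.
- Problem sizes in the test suite are chosen to keep the default run fast:
  replicate simulations use 100–200 sequences of 250–400 bp (50–100
  replicates), and oracle-equivalence checks use small windows on random
  batches. The headline pipeline check uses the full default batch
  (500 × 400 bp).

## Known limitations

- One start per batch: the dyad-symmetry detector infers a single common
  nucleosome start for an end-aligned ensemble; it does not call
  per-sequence dyads (that is the mapping stage's job).
- Mapping reports the best single dyad per sequence; genome-scale tiling
  with overlapping-call resolution is out of scope.
- Start inference is intentionally semi-automatic: when per-class argmaxes
  disagree, the diagnostic table is the intended interface, not a hidden
  heuristic.
- Spectral peaks carry no significance test; the shuffled-sequence null is
  the intended calibration.
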