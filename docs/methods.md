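# Methods

This note documents the models implemented in `dnapalette`, the parameter
choices that matter, and the reasoning behind design decisions the underlying
scheme leaves open. Nothing here states a measured result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. The palette bijection

Messages live in {0,1}^N with the convention that **x₁ is the rightmost
written character** (least significant). This is forced by requiring that the
rank formula Σ 2^{i−1}xᵢ map the written string '001' to rank 1. The oligo
universe is ordered lexicographically under A < T < G < C; subsets are
ordered by scanning largest members downward, with two clarifications the
informal description leaves open: equal sets compare as neither-less, and a
set that exhausts first while the scanned tails match is the smaller. Both
choices are validated against the only self-consistent reading — subset
order must equal integer order of indicator ranks — by exhaustive
enumeration up to n = 12 in the test suite.

Ranks are arbitrary-precision integers; for production block sizes (2¹⁹ bit
positions) the indicator form (sorted index arrays) is used throughout and
the 2^N family is never materialized. Encoding and decoding touch each set
bit once.

## 2. Oligo layout and the quaternary VT structure

A 155-nt oligo carries, in payload positions: a 12-symbol block label, 12
addresses of 10 symbols each (bit positions inside the block, base-4,
most-significant first), and is completed by 23 check symbols that force the
Tenengolts syndromes

  a(s) = Σ_{i=1}^{L−1} i·[sᵢ₊₁ ≥ sᵢ]  ≡ 0 (mod L),   b(s) = Σ value(sᵢ) ≡ 0 (mod 4).

Words satisfying fixed (a, b) form a single-deletion-correcting code, so one
insertion, deletion, or substitution per read can be handled; correction is
by candidate filtering (all single-edit repairs, keep those that check),
which by the VT distance property returns exactly the original codeword for
true single indels and otherwise either a unique consistent repair or a
rejection — never a silent substitution of a different codeword for a
recoverable read.

**Systematic syndrome forcing.** A check symbol influences the ascent
syndrome only through its two flanking ascents, whose weights are its
neighbour positions; check symbols appended at the tail can therefore shift
`a` only by subset sums of near-maximal weights and cannot reach every
residue mod L once L is large. Two layouts are used:

* **tail** (short codewords, c = 5 at L = 8): exhaustive search over 4^c
  assignments; feasibility for every payload context is proven by exhaustion
  at parameter construction (c = 4 is provably infeasible and rejected).
* **guarded** (pipeline oligos, L = 155): seven (C, x, A) triples centred at
  positions 24, 44, …, 144 plus one (C, x) tail pair. The high/low guards pin
  the flanking ascents regardless of payload, so each free symbol contributes
  a payload-independent (Δa, Δb); the eight free symbols together span all
  4L = 620 syndrome classes (verified at construction, with the solution
  cached as a lookup table, so forcing is O(1) per oligo). Cost: 23 check
  symbols per 155-nt oligo, leaving a 132-nt payload.

Null padding uses the all-C address (value 4^d − 1), excluded from the
addressable range.

## 3. Ladder transform and error budget

Label alignment pads files to a common length and gathers volatile label
fields to a prefix; XOR differencing stores file 0 absolutely (a corrupted
diff byte propagates only forward, so keeping one absolute anchor bounds
damage); RS(255, 191) over GF(256) protects the concatenated stream, parity
appended after the data region so that all-zero blocks yield all-zero parity
and sparsity is preserved.

**Why 25% parity and byte-grouped packing.** Dropout deletes whole oligos,
i.e. K = 12 one-bits. How those bits map to stream bytes decides whether RS
survives: packing sorted one-positions naively makes a dropped oligo either a
burst of ~K byte errors in one RS block (ascending packing) or K isolated
errors concentrated wherever ones are dense (stride packing). Both overload
blocks in dense image regions. The packing used orders one-positions by
(byte mod 4096, position) and chunks K at a time: bits of the *same* stream
byte travel on one oligo (losing it costs one byte error, not eight), and an
oligo's successive byte groups sit 4096 bytes — ≥ 16 RS blocks — apart. The
expected byte errors per RS block are then bounded by
p_eff × (non-zero bytes per block) ≤ p_eff × 255 with isolated-Poisson
statistics, where p_eff ≈ 6.5% covers 5% dropout plus majority-vote losses.
That gives λ ≤ ~11 for fully dense blocks; correcting t = 32 errors
(RS(255, 191)) leaves more than five standard deviations of margin, whereas
t = 16 (RS(255, 223)) would fail a few percent of dense blocks per run. The
geometry is config-exposed; 12.5% parity remains appropriate for channels
without dropout.

## 4. Decoder

Reads are VT-corrected (wrong-length-by-more-than-one and ambiguous reads
discarded), grouped by exact sequence, and voted: a sequence needs
multiplicity ≥ v (v = 2 when mean coverage ≥ 3, else 1 — at very low
coverage demanding two copies would discard most of the pool) and strict
plurality among candidates sharing its label + first-address prefix; ties
discard the whole group, since a false accepted oligo plants a wrong bit
while a missing one is just dropout for RS to fix. Accepted addresses are
unioned into the bitstream; spurious survivors (which require two identical
multi-error corruptions) are left to RS. Decoding is linear in reads, order-
and duplication-invariant, and never aborts: empty input produces zero-filled
output and a report, uncorrectable RS blocks are returned as received and
flagged.

## 5. Channel model

Per scanned position at most one event occurs: substitution (uniform over the
three alternatives), deletion, or insertion of a uniform base before the
symbol — the simplest model consistent with equal IDS rates; insertion does
not re-trigger on the inserted base. Dropout is per-oligo and precedes
duplication (fixed M or Poisson coverage). All randomness flows from one
seeded generator, making runs bit-reproducible. Real sequencing shows
coverage skew (log-normal-like abundance) and sequence-dependent error
profiles; neither is modelled, so measured dropout here equals the nominal
p_drop rather than emerging from coverage variance.

## 6. Synthetic archives

`generate_series` is format-agnostic: random first file, shared header,
δ-fraction of payload bytes rewritten at uniform random offsets per step —
worst-case content for any transform, used to show correctness does not
depend on compressibility.

`generate_dicom_like` emulates the archival imaging series the codec targets:
a 128-byte tag-length-value header (shared study fields; per-file instance
number and timestamp declared as label spans) and a 12-bit little-endian
phantom image — smooth elliptical foreground with internal Gaussian
structures on a zero background, values ≤ 4095 as in clinical practice.
Consecutive files differ in a few disc-shaped regions (~6 px radius) whose
count is set so about δ of payload bytes change; localized edits mirror how
slice series and daily geophysical products actually evolve, and keep RS
parity sparse. What passing tests on this generator do **not** show: real
modality headers parse, anatomical content compresses identically, or that
densities on real archives match — real pixel statistics (noise floors,
bias fields) will shift the sparsity and hence r(b/n).

Benchmark scales (10 files × 100 KiB for density, 10 × 10 KiB for the
channel round trip) were chosen so the full pipeline runs comfortably on one
CPU; density and error-budget arithmetic above are scale-free.

## 7. Numerical and degenerate-input choices

* Bit order within a byte is least-significant-first (`numpy` `bitorder='little'`),
  matching the x₁-least-significant message convention.
* An empty read set, an all-zero block (zero oligos), a single-file series,
  ragged file lengths, and streams shorter than one RS block all take defined
  paths (tests cover each).
* The indexed baseline chooses the smallest index width whose packing
  arithmetic closes (width ↑ until 4^width ≥ oligo count) and carries the
  same VT checks and RS stream — matched redundancy by construction.
* Tie-breaks: equal-count vote conflicts are discarded; RS blocks failing
  Berlekamp–Massey, Chien root count, or post-repair verification are
  returned as received and flagged.

## 8. Known limitations

* Substitution repair is rejected when ambiguous (common at small L, rarer at
  155 nt); rejected reads only cost coverage.
* No homopolymer or GC screening is applied to addresses; a screening hook
  would have to re-map offending addresses and is out of scope.
* The pool FASTA records are written in deterministic order with sequential
  ids for human convenience; ids are declared non-semantic and the decoder
  ignores them.
* Density on short series is dominated by the absolute first file; the
  advantage over indexed coding needs series long enough to amortize it
  (about six similar files at the benchmark δ).
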