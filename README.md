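# dnapalette

Index-free DNA data storage for time-series archives.

DNA is an attractive medium for cold archival data, but strands in a pool are
spatially disordered, so conventional codecs prepend a sequential index to
every oligonucleotide to recover bit order. `dnapalette` implements an
alternative: the **palette code**, which represents a binary message as an
*unordered set* of index-free oligos, together with the **ladder code**, a
pre-transform that makes series of similar files (consecutive MRI slices,
daily satellite or climate products, ...) extremely sparse so that storage
cost tracks how much the data *changed*, not how large it is. A sequencing
channel simulator and a trace-reconstruction decoder make the whole system
testable end to end without wet-lab data.

Intended users: researchers in DNA data storage and coding theory who need a
complete, reproducible software model of set-based (indicator) DNA coding.

## The codes

**Palette code.** Order the four bases A < T < G < C and a preset oligo
universe O = {o₁ < o₂ < … < o_n} lexicographically; order subsets of O by
comparing largest elements downward. The rank of a subset S in that order is
its indicator value Σ_{o_i∈S} 2^{i−1}, so the map

    f : x = (x_N … x_2 x_1)  ↦  the (Σ_i 2^{i−1} x_i)-th subset of O

is a bijection between N-bit messages and the first 2^N subsets: oligo o_i is
present exactly when bit x_i = 1. Encoding and decoding touch each set bit
once (linear time), no strand carries an index, and an all-zero message costs
zero oligos — the codeword *size* is the message's popcount. Synthesized
oligos are 155 nt: a block label, K = 12 ten-nt bit-position addresses, and
23 check symbols that force a quaternary Varshamov–Tenengolts (VT) structure
(ascent syndrome a = Σ i·αᵢ mod L and sum syndrome b = Σ sᵢ mod 4), which
lets the decoder repair one insertion, deletion, or substitution per read and
reject everything else.

**Ladder code.** Before palette encoding, a file series is (1) padded and
label-aligned so corresponding fields share offsets, (2) XOR-differenced
against the previous file (file 0 stays absolute), and (3) protected by a
block Reed–Solomon code over GF(256) — RS(255, 191) by default — which later
absorbs residual byte errors and dropout. Stages 1–2 add no redundancy; for
archives whose consecutive files differ in a fraction δ of bytes, the
resulting bitstream density, and hence oligo count, scales with δ.

**Decoder.** Reads are VT-checked/corrected, grouped, and majority-voted
(multiplicity threshold plus strict plurality within each label+first-address
group); accepted addresses are unioned into bits, then RS, differencing and
alignment are inverted. Decoding is invariant under read order and
duplication, and never aborts: partial pools yield partial files.

## Worked example

```
$ dnapalette synth --files 6 --size 16384 --diff-rate 0.003 --seed 1 --out series/
$ dnapalette encode --in series/file_0000.bin --in series/file_0001.bin \
    --in series/file_0002.bin --in series/file_0003.bin \
    --in series/file_0004.bin --in series/file_0005.bin \
    --out pool.fasta --verbose
encoded 98304 bytes into 5065 oligos
$ dnapalette simulate --pool pool.fasta --pr 0.01 --pdrop 0.05 --m 10 \
    --seed 7 --out reads.fastq
$ dnapalette decode --reads reads.fastq --manifest pool.fasta.manifest \
    --out decoded/ --verbose
accepted 4742/5065 oligos, dropout 6.38%, 0 RS blocks unrepaired
$ cmp series/file_0005.bin decoded/file_0005.bin && echo identical
identical
```

Six 16-KiB files became 5 065 oligos of 155 nt (1.0 bit/nt — short series
leave the absolute first file dominant; the 10 × 100 KiB acceptance benchmark
reaches 2.2 bits/nt). The simulated channel applied a 1% per-base
insertion/deletion/substitution rate, dropped 5% of oligos entirely, and
emitted 10 noisy copies of each survivor; the decoder still recovered every
byte — the missing 6.38% of oligos were repaired by the RS layer. The same
library calls are available in Python (`dnapalette.encode`,
`dnapalette.decode`, `dnapalette.sequence_pool`, ...). `dnapalette metrics`
reports the net information density r(b/n) = input bits / (oligo count ×
155 nt) together with coverage, dropout and byte error rates.

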