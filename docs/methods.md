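# Methods

## The problem and the model

Archival DNA storage compresses a file before transcoding it to
nucleotides, which makes restoration depend on a decompression program
that may no longer exist decades or centuries later. `dnastore` models a
*self-contained* archive: the tool needed to restore a file is stored in
the same oligo pool as the file, and the pool's indexing (PCR primers)
lets a reader pull out a chosen file *and* its tool without sequencing
everything else. The package covers the digital half of such a system —
container formats, transcoding, fragmentation, primer design, an
in-silico pool with PCR-style selection, and closed-form cost models.
Wet-lab chemistry (synthesis yield, amplification bias, read errors) is
deliberately out of scope; the pool is error-free and selection is exact
substring co-occurrence of the two primer sites.

## Container formats and self-extraction

Files are packed into fixed-offset binary records (big-endian integers).
A data record is `FT(1) | FID(4) | SM(1) | DL-or-TFID(4) | D | TD`; a
tool record is `FT(1) | FID(4) | TD`. The storage-method byte SM selects
how the record self-extracts: OF returns its bytes verbatim, CPF carries
its full tool inline, SPF references a shared tool record by FID. The
offset-6 field is always present and holds the data length for OF records
too — the layout stays position-parseable at the cost of four bytes.
Enum byte values (data=0/tool=1; OF=0/CPF=1/SPF=2) and endianness are
package conventions.

Stored tools are opaque blobs that round-trip byte-exactly but are never
executed. Actual (de)compression is dispatched through a registry of
built-in codecs (deflate, LZMA) keyed by tool FID and by blob SHA-256,
so an inline CPF tool is recognised by content. The FID-to-filename map
and the registry entries live in a JSON manifest on the conventional
storage side, consistent with a hybrid DNA/disk system.

## Transcoding

Codecs are pluggable; two are shipped. The `quaternary` codec is the
defining 2-bits-per-base mapping (base factor a = 0.5 bases/bit, density
2 bits/base). The `rot` codec is a rotating ternary code: each 5-byte
word becomes 26 base-3 digits (3^26 > 2^40) and each digit selects one of
the three bases different from the previous base, so no homopolymer
longer than 1 nt is ever emitted. Its cost is a = 26/40 = 0.65 bases/bit
(d ≈ 1.54 bits/base), in the range of practical constrained codes
(~1.6 bits/base). A trailing word of k < 5 bytes uses the minimal digit
count covering 256^k (6/11/16/21 digits); those counts are distinct
modulo 26, so the decoder recovers the exact byte length from the
sequence length alone and no external pad bookkeeping is needed. The
word size was chosen so the whole transform fits unsigned 64-bit
arithmetic and vectorises in numpy. Decoding validates the alphabet, the
no-repeat invariant and word value ranges, reporting the first offending
position.

## Fragment format

An oligo fragment is `head_primer | A | address | C | payload | RS | T |
tail_primer(s)`. The A/T direction markers sit at the payload boundaries
and are counted *in addition to* the synthesis length L_s, because the
capacity arithmetic (L_s − 2·L_p = 180 nt at L_s = 220, L_p = 20)
ignores them. The address is a big-endian quaternary integer; its width
`L_addr = ceil(log4(#fragments))` is chosen per stream and recorded in
the manifest. The class flag C (A = data, T = tool) separates the two
record classes when one amplification returns both. The RS field is
reserved for an error-correction code and is zero-length by default. All
fragments of a stream share one total length — the last payload is
A-padded and the manifest's true nt length trims it on reassembly.
Reassembly is order-free (fragments are sorted by decoded address),
detects gaps (naming the missing addresses) and raises on conflicting
duplicate addresses rather than guessing.

## Storage methods

* **1-1CS** (one-to-one continuous storage): each tool-using file is a
  CPF record embedding its full tool; k files sharing a tool store k
  copies. One PCR selection with the file's primer pair recovers
  everything: 1 sequencing round.
* **M-1CI** (many-to-one chain indexing): files are SPF records; the
  tool is stored once under its own primer pair; each file's encoded
  stream ends with a 2·L_p-nt pointer holding the tool's literal primer
  sequences. Round 1 recovers the file and the pointer, round 2 the
  tool: 2 rounds. Because the pointer is real primer sequence inside
  data payloads, the round-2 amplification also picks up those data
  fragments; streams are told apart by which primer a read *starts*
  with, and the class flag is verified — this is exactly the ambiguity
  the C field exists for.
* **1-MCI** (one-to-many chain indexing): files are SPF records; the
  tool's fragments carry the universal forward primer at the head and
  the reverse primers of all n client files at the tail, with payload
  capacity L_s − (n+1)·L_p (160 nt for n = 2, 140 nt for n = 3 at the
  reference lengths). Selecting with the file's primers plus the
  universal primer amplifies both classes at once: 1 round. n is
  enforced to satisfy 0 < n < floor(L_s/L_p) *and* positive payload
  capacity (the printed bound alone admits a zero-payload corner).

Tools with no client files are not emitted by the separate-storage
paths. When a tool serves exactly one file all three methods still emit
exactly what they specify; no auto-switching.

## Cost models

Stored bits Sb and stored bases Sd per method are the closed forms
documented in `dnastore.models`, implemented verbatim — including the
unit-mixing n·2L_p pointer term in the M-1CI bit count and the
double-weighting of S_T in the 1-MCI base count; `pool_payload_bits`
counts the pointer one unit per nt to match that convention. The models
use real-valued fragment counts while the write paths use integer
ceilings; the tested agreement allowance is one codec word (40 bits) per
fragment stream. Two always-true inequalities follow structurally:
Sb(1-MCI) ≤ Sb(M-1CI) (difference 2n·L_p) and Sb(1-MCI) ≤ Sb(1-1CS)
(difference (n−1)·S_T).

A caution the models make visible: the *base*-count ordering between
M-1CI and 1-MCI is parameter-dependent. Shared tool fragments give up
(n−1)·L_p of payload each, which outweighs the pointer saving unless the
compressed data volume is roughly an order of magnitude larger than the
tool. The reference sweep parameters (S_h = 10, S_T = 2010, L_p = 20,
a = 1/1.6, S_D = 100000, r_c = 0.34, L_s 100–400) sit in the regime
where 1-MCI ≤ M-1CI ≤ 1-1CS holds in every row; the tool-dominated
reference corpus below does not, and the end-to-end report exposes both
bit and base totals rather than asserting a universal base ordering.

## Primer design

Primers are the file index, so the design constraints are usability
(GC fraction in [0.4, 0.6], homopolymer runs ≤ 3 — standard oligo
heuristics) and mutual distinguishability, operationalised as minimum
pairwise Hamming distance 8 for L_p = 20 across the whole library
(forwards and reverses together). Generation is seeded rejection
sampling, which is exact and reproducible and comfortably fast at
library sizes up to a few hundred; it fails loudly with an
infeasibility error after a bounded number of consecutive rejections.
Melting temperature, secondary structure and cross-dimer thermodynamics
are not modelled, and primers are not checked against payload content —
an accidental primer hit inside a payload is caught at assembly time as
a conflict rather than silently mis-assembled. Reverse primers are
independent sequences; reverse-complement strand chemistry is not
modelled anywhere, consistently.

## Synthetic corpus

The reference corpus emulates a mixed archive: five data files of
16–64 KB whose redundancy spans 0.9 (bitmap-like, deflate r_c < 0.3)
down to 0.0 (incompressible noise, r_c ≈ 1), plus two tool blobs sized
like real compressor executables — 194 KB (7z-like, LZMA stand-in,
shared by two files) and 87 KB (zip-like, deflate stand-in, shared by
three), which puts both the n = 2 and n = 3 tool-fragment geometries in
play. Redundancy is generated as 32-byte blocks re-drawn from a small
per-file dictionary with the given probability, which makes measured
r_c a monotone function of the knob. Everything is deterministic under
the corpus seed. What the generator does *not* emulate: real file-format
structure (headers, long-range correlations), real executables, and any
sequencing noise — so passing tests demonstrate the indexing and
self-extraction logic, not robustness to wet-lab errors.

## Problem sizes and numerical choices

Property suites run on miniature corpora (files of 60–400 bytes, tools
under 200 bytes, 50 seeded corpora × 3 methods) so the full suite
finishes in seconds; the headline saving measurement runs the full-size
reference corpus (~0.8 M payload bytes across both pools, a few seconds
with the vectorised codec). Floating-point comparisons of the closed
forms use relative tolerances ~1e-9 with a cancellation-aware absolute
floor when differencing large sums. Degenerate inputs are first-class:
empty corpora, 0-byte files, empty bit strings, single-fragment streams.

## Known limitations

* PCR is substring matching: no strand chemistry, melting, bias, copy
  number or dropout; `sequence()` returns every fragment exactly once.
* The error-injection surface is the reserved RS field and is not
  populated; retrieval assumes error-free reads.
* The bit/byte convention for model sizes is bits throughout, isolated
  behind `SystemParameters`; display-layer conversions only.
* The rotating codec's density (1.54 bits/base) is a reference point,
  not a competitor to production fountain/constrained codes.
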