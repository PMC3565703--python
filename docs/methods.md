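# Methods

## The alignment problem and the bridge idea

Two protein families can occupy the same fold while sharing so little
sequence identity in their membrane-spanning helices that direct alignment
is unreliable. The method implemented here scores candidate *shifts*
(integer displacements between the two families' predicted transmembrane
windows) using signals that survive sequence divergence — the positional
pattern of conservation and of hydrophobicity around the helix — and
strengthens the inference by routing through a *bridge* family that has
detectable similarity to both targets. If the first target aligns to the
bridge at shift *p* and the second at shift *q*, the implied direct shift
is *p − q*; agreement between this implied shift and the direct scan is
the strongest available evidence.

## Scoring model

For one helix and an ordered pairing (x, y), three per-lag traces are
computed over lags −pad…+pad (default pad 8, hence 17 lags):

1. **BLOSUM62 profile alignment.** Each alignment column is summarized by
   its residue frequency vector over the 20 canonical amino acids (gaps
   and X excluded from the normalization). The score of a column pair is
   the expected substitution score Σ_ab f_x(a) f_y(b) M(a,b); the trace
   value at lag L is the sum over x's transmembrane window, pairing x's
   window offset j with y's column (TM start + j − L).
2. **Entropy correlation.** Per-column Shannon entropy in bits; the trace
   value is the Pearson correlation of the two windows at that lag.
3. **Hydrophobicity correlation.** Per-column frequency-weighted mean
   hydrophobicity; Pearson correlation as above.

Every trace is the mean of the forward scan and the reverse scan (roles
swapped, lag negated), which makes the raw blosum trace exactly
swap-symmetric: scan(x, y) at L equals scan(y, x) at −L. Traces are then
min–max scaled to [0, 1]; a flat trace is scored all-zero and flagged
degenerate. The consensus for the pairing is the per-lag product of the
three scaled traces. It is deliberately *not* re-scaled: each value lies
in [0, 1] and never exceeds any component's scaled value at the same lag,
which is what lets the product down-weight lags supported by a single
component. Consensus traces are treated ordinally (peak structure), never
calibrated as probabilities.

Sign convention, used consistently from scans through numbering: a
negative shift displaces the second family's sequences to the left;
position i in the first family pairs with position i − shift in the
second.

### Numerical conventions

* Zero-variance correlation windows are scored 0 and flagged rather than
  propagating NaN; a constant property track therefore yields a flat,
  degenerate trace.
* Lags whose clipped window overlap falls below 3 columns are reported as
  missing (NaN) and excluded from scaling; lags scored over a truncated
  overlap are flagged `truncated` but participate in min–max scaling.
* Scaling is applied after forward/reverse averaging.
* Columns more than half gapped are flagged but still scored, keeping the
  lag windows rectangular.
* Letters outside the 20 canonical amino acids (B, Z, J, U, O) are mapped
  to X with a warning; X and gaps contribute to no frequency count.

## Peaks, plausibility, triangulation

A *plausible* lag is a local maximum of the consensus trace whose value is
at least a threshold fraction (default 0.70) of the trace maximum. Local
maximum means ≥ both neighbours (ends compare against their single
neighbour; every member of a tied plateau counts). Because "peak" could
also be read as "any lag above threshold", that looser behaviour is
available via `peak_mode="threshold"`.

Triangulation forms every implied direct shift p − q from the two bridge
plausible sets and ranks hypotheses: tier 1 (in the direct set and
bridge-implied), tier 2 (bridge-implied only), tier 3 (direct only),
ordering within a tier by the product of supporting consensus values. The
composition sign is verified by a property test on synthetic triples
rather than assumed. Equal-evidence ties are reported unresolved — the
kind of external evidence that resolves them (mutagenesis, structural
constraints) is outside this package's scope. For reporting, hypotheses
can be relabelled so the preferred alignment is alignment 0; the
relabelling is an involution-safe operation (applying it twice is the
identity).

## Overlap significance test

Given per-family sets of group-conserved window positions (supplied as
curated CSV tables, which take precedence, or detected as positions where
some residue class — default partition: small AGSC, hydrophobic ILVMF,
aromatic WYH, positive KR, negative DE, polar NQT, proline — reaches a
combined frequency of 0.8), the observed number of aligned pairs at a
shift is compared with random placement *within the overlapping window*:
the exact one-sided p-value is the hypergeometric upper tail
P(X ≥ k | L, n_a, n_b) on the overlap length L and the position counts
inside it. The Monte-Carlo engine re-places one side uniformly (or with
user weights) with the (r+1)/(n+1) finite-sample correction, and the
reported p is the larger of randomize-A and randomize-B; under the uniform
model the two directions estimate the same quantity, but they can differ
under weighted placement. The Monte-Carlo path exists precisely so the
placement model can be changed; the hypergeometric closed form is its
oracle in tests.

## Generic numbering and motifs

Each helix window may carry a reference column numbered 50; columns are
numbered 50 + offset (x.50 style). Once a shift is inferred, columns map
across families by window offset minus shift, and `propagate_ref50`
extends one family's numbering to the other so that generic numbers agree
across the alignment (shift-covariance, tested). A shipped motif table
(curated from the class A/class B GPCR literature: W4.50, the NPxxY/VAVLY
TM7 motifs, KKLH at the TM1/IL1 junction, the class B DRY-equivalent
R2.39/H2.43/E3.46, KxxK6.35, T6.37, the non-aligned TM6 prolines) can be
read off any family's modal (consensus) residues, with ties reported as
ambiguity sets and out-of-range positions as unmapped rather than fatal.

## Synthetic data: what it emulates, and what it does not

The generator plants the statistical structure the method assumes two
remote homologues share: a per-position *architecture* of target entropy
(a conserved/variable mixture, 35% conserved by default) and target mean
hydrophobicity (a 3.6-residue-period oscillation mimicking the buried
versus lipid-facing helix faces, amplitude 2 on the Kyte–Doolittle scale,
plus per-position jitter that breaks the periodicity's ghost peaks). Each
position's frequency vector concentrates on the 8 residues closest in
hydrophobicity to the target, with the dominant-residue weight solved by
root-finding so the column entropy hits its target (to within sampling
error; a property test checks realized entropies stay within ±0.3 bits of
target at 100 sequences, noise 0). All three families draw sequences
column-independently from this one architecture, displaced by the planted
shifts s_A and s_B (bridge at 0), so the true direct shift is s_A − s_B by
construction; flanks are wide enough that every lag on the grid scores a
full window. Substitution noise (default 0.1) replaces residues uniformly
at random. Planted group-conserved positions get compositions drawn within
the small-residue group.

What this does *not* emulate: phylogenetic correlation between sequences
(columns are sampled i.i.d. given the architecture), indels and gapped
columns inside TM windows, family-specific amino-acid composition biases,
and inter-column correlation. Passing the recovery and null tests
therefore shows the scoring and triangulation machinery is correct and
well-calibrated under the method's own assumptions — not that real
receptor families satisfy those assumptions.

## Study conditions used by the checks

The recovery check runs 100 triples at 50 sequences/family, helix length
25, noise 0.1, and requires the tier-1 hypothesis to equal the planted
direct shift in ≥ 90. Because the scan grid is ±8, the planted *direct*
shift is drawn uniformly from [−8, 8] and split between s_A and s_B so
both bridge shifts stay within the grid (drawing the two independently
could imply a direct shift up to ±16 that no ±8 scan can represent). The
null control runs 100 independent-architecture pairs and tests the
consensus argmax against uniformity over the 17 lags (chi-square,
requiring p > 0.01); with 100 draws this has low power against the mild
lag-to-lag correlation that window overlap induces, which is the intended
reading — the method should manufacture no *systematic* alignment from
noise. The overlap-test check compares Monte-Carlo estimates at 10,000
replicates with the hypergeometric oracle over 20 random configurations
(3 binomial standard errors). These sizes keep the whole suite in the
tens of seconds on one CPU.

## Known limitations

* The method reports shifts for helices as rigid blocks; it cannot
  express within-helix insertions or deletions (the scans are ungapped by
  design).
* Consensus scores are comparable within a trace, not across helices or
  datasets.
* The significance check against the curated class A/class B
  group-conserved catalogues requires those reference tables and the
  master alignments they index; they are not redistributable here, so the
  corresponding end-to-end check cannot run and the overlap machinery is
  exercised on synthetic and constructed fixtures instead.
* Polarity-violation assessment is limited to what the user can derive
  from exported profiles; no structural accessibility calculation is
  attempted, and helical-moment output is a diagnostic aid, not a
  decision rule.
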