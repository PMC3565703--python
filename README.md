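# helixbridge

Aligning the transmembrane (TM) helices of two protein families that share
almost no direct sequence identity — the textbook case being class A and
class B G-protein-coupled receptors (GPCRs) — is beyond ordinary alignment
tools: within a TM helix the two families' sequences look unrelated, yet
their helices occupy equivalent structural positions. `helixbridge`
implements a bridge-mediated consensus approach for this problem, aimed at
structural biologists and modellers who need a defensible residue-level
correspondence (e.g. to transfer Ballesteros–Weinstein x.50 numbering, or
to build homology models of one family on the other's templates).

## Method

For each helix and each ordered family pairing (A–B directly, plus A–bridge
and B–bridge through a third *bridge* family with detectable similarity to
both), three traces are computed over integer lags `L = −8 … +8` (17 lags;
a negative lag displaces the second family's sequences to the left):

* **Profile alignment** — the expected BLOSUM62 score between column
  frequency profiles, summed over an ungapped sliding window the length of
  the first family's TM region:
  `S(L) = Σ_j Σ_{a,b} f_x(j,a) f_y(j−L,b) M62(a,b)`;
* **Entropy correlation** — Pearson correlation of the families'
  per-column Shannon entropy tracks over the same lagged windows;
* **Hydrophobicity correlation** — the same for frequency-weighted mean
  hydrophobicity (Kyte–Doolittle by default).

Each trace is the mean of a forward and a reverse (roles swapped, lag
negated) scan, min–max scaled to [0, 1]. The per-pairing **consensus** is
the product of the three scaled traces; lags supported by a single
component are thereby down-weighted. Local maxima of the consensus within
70% of its highest peak are *plausible* alignments; a bridge-peak pair
(p, q) implies the direct shift `p − q`, and hypotheses are ranked by
whether they satisfy all three plausible sets (tier 1), the bridge route
only (tier 2), or the direct scan only (tier 3).

A proposed shift is validated statistically by counting aligned
*group-conserved* positions (conserved as a residue class, e.g. small
residues A/G/S/C) and comparing against uniform random placement within
the overlapping window — hypergeometric upper tail in closed form, plus a
seeded Monte-Carlo engine; the reported p-value is the larger of the two
one-sided randomization directions.

## Worked example

Synthetic families make the machinery concrete: three 50-sequence MSAs
sharing one conservation/hydrophobicity architecture, with family A
displaced by +2 and family B by −1 relative to the bridge (so the true
direct shift is +3), 10% substitution noise, and three small-residue
positions planted in the helix window.

```python
from helixbridge import BridgeAlignment, FixtureSpec, generate_triple

spec = FixtureSpec(n_sequences=50, shift_a=2, shift_b=-1, noise=0.1,
                   group_conserved={"TM1": (4, 11, 18)}, seed=7)
fam_a, fam_b, bridge, truth = generate_triple(spec)
results = BridgeAlignment(fam_a, fam_b, bridge).fit()
results.run_overlap_tests(replicates=10000, seed=1)
print(results.summary())
```

```
                    Bridge-mediated helix alignment
========================================================================
families: classA vs classB via bridge
lags: -8..+8 (17); plausible-peak cutoff: 70% of max; hydrophobicity scale: kyte-doolittle
------------------------------------------------------------------------
TM1
  measure               direct    a_bridge    b_bridge   (best lag)
  blosum                    +3          +2          -1
  entropy                   +3          +2          -1
  hydrophobicity            +3          +2          -1
  consensus                 +3          +2          -1
  plausible[direct]: +3 (1.00)
  plausible[a_bridge]: +2 (1.00)
  plausible[b_bridge]: -1 (1.00)
  hypothesis shift +3  tier 1  support=direct,a_bridge,b_bridge <- preferred
  overlap test @ shift +3: observed 11 of 11x12 in L=22; p_exact=0.0000 reported_p=0.0002
========================================================================
```

Every measure peaks at the planted lags (+2 for A–bridge, −1 for
B–bridge), the bridge route implies the direct shift `+2 − (−1) = +3`,
which the direct scan confirms (tier 1, preferred), and 11 of the
group-conserved positions detected in family A align with family B's
under that shift — far more than chance placement would give
(reported p = 0.0002). For real data, the same run starts from three
aligned FASTA files and a region table:

```sh
helixbridge run-all --msa-a classA.fasta --msa-b classB.fasta \
    --msa-bridge gcr1.fasta --regions regions.csv --out-dir run/
```

which writes `scans.tsv`, `consensus.tsv`, `hypotheses.json`,
`overlap.tsv` and a `manifest.json` echoing the configuration. See
`helixbridge --help` for the stage-by-stage subcommands (`profiles`,
`scan`, `triangulate`, `overlap-test`, `simulate`).

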