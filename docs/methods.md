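# Methods

This note documents the models and procedures implemented in `tbpsig`, the
parameters that matter, the numerical choices at points where the published
procedure leaves freedom, and what the synthetic-data experiments do and do
not demonstrate.

## Conservation scoring

The unit statistic is the normalised substitution score
`nbs(a,b) = M(a,b) / max(M(a,a), M(b,b))` with BLOSUM62 as the default
matrix *M*. Because BLOSUM62's diagonal strictly dominates every
off-diagonal entry, `nbs` lies in [-1, 1] and equals 1 exactly for
identical residues; the package asserts this dominance property for the
packaged matrix and does not assume it for user-supplied matrices.

Column conservation (NBS) is the mean of `nbs` over all unordered sequence
pairs at the column. Gap and unknown-residue (X) pairs are excluded and the
pair count renormalised. A column is **unscorable** when fewer than two
standard residues remain or when standard residues occupy fewer than half
of the sequences. The residue-fraction form of the rule (rather than a
pair-fraction form) is deliberate: it treats a column of m sequences with
k residues the same regardless of how the quadratic pair count amplifies
missingness, and it keeps a 2-of-3 column (one gap) scorable, which is the
behaviour the downstream statistics assume. Nonstandard one-letter codes
(B, Z, J, U, O) are normalised to X on input so column geometry survives.

Profile summaries (mean, SD over scorable columns) use the population SD
(divide by the count). The choice is documented and configurable
(`sd_mode="sample"`); at 209-column scale the difference is negligible, but
the threshold `mean + SD` is a strict inequality, so the convention is
fixed rather than left implicit.

## Ancestral consensus

Universal-signature detection compares one reconstructed ancestral
sequence per superkingdom. The default reconstruction is per-column
majority consensus: a gap when gaps exceed half the subset, otherwise the
modal non-gap residue with a lexicographic tie-break. On a star tree with
independent identical branches, marginal maximum-likelihood reconstruction
degenerates to (weighted) consensus, which is why consensus is an adequate
default for the downstream thresholding decision; an import adapter
(`method="import"`) accepts an externally reconstructed sequence (e.g. from
a maximum-likelihood program) for exact replication work, validated only
for alignment length.

## Signature rules

*Universal*: with exactly three ancestral sequences, a column is flagged
when its three-pair NBS strictly exceeds `mean + SD` of the ancestral
profile. Strictness matters: a perfectly uniform profile (SD = 0) flags
nothing.

*Lobe-specific*: for target lobe T with counterpart O, a column is flagged
when `NBS_T > mean NBS_T` and either `NBS_T > ratio · NBS_O`
(`ratio` default 1.5, tag `ratio`) or, failing that, the modal residues of
the two lobes differ (tag `residue-switch`). Two deliberate edge policies:

- The ratio test is applied literally even when `NBS_O` is negative, where
  it is trivially true. Reports carry both NBS values so such flags can be
  filtered; `examples/02_signature_detection.py` shows why one wants to.
- Modal residues are computed over non-gap residues with a lexicographic
  tie-break; if the two lobes' argmax sets share any residue the position
  counts as "not different", so ties never manufacture a residue switch.

Columns unscorable in either lobe are skipped, since both profiles are
needed for the comparison.

## Coevolution

For *n* organism-paired sequences, the substitution-similarity vector of a
column is the length-C(n,2) vector of `nbs` values over all sequence pairs
in fixed lexicographic pair order. Coevolution of two columns is the
Pearson correlation (PC) of their vectors over jointly scorable entries
(pairwise deletion; the count used is reported as `n_pairs_used`). PC is
undefined — an error, not a number — when fewer than three joint entries
remain or either vector is constant.

The null model shuffles each column independently within itself, which
preserves residue composition exactly, and recomputes PC; the p-value is
`count(PC_random ≥ PC_observed) / n_perm` with `n_perm` defaulting to 1000.
Numerical choices:

- A tie tolerance of 1e-12 on the ≥ comparison makes the identity
  permutation count as a tie despite float roundoff.
- A permutation round whose PC is undefined (possible when gaps
  concentrate) counts as "not ≥" while remaining in the denominator, so the
  number of rounds is exactly `n_perm`.
- A zero count is reported as the bound `< 1/n_perm` rather than p = 0; the
  conservative `(count+1)/(n_perm+1)` estimator is available (`plus_one`).
- Scans derive one child seed per partner column from the master seed, so a
  column's p-value does not depend on which other columns were scanned.
- Multiple-testing adjustment (Benjamini–Hochberg) is opt-in and reported
  alongside the raw p, which is the primary statistic.

## Structure interfaces

Contacts between two chain sets use a heavy-atom distance rule (any pair of
heavy atoms ≤ cutoff, default 4.5 Å) or, optionally, per-element van der
Waals radius sums plus 0.5 Å; the rule descriptor is recorded in every
contact set. Hydrogens and waters are excluded; alternate locations resolve
to the highest-occupancy conformer. Nucleic-acid chains are treated exactly
like protein chains.

Structure residues map to alignment columns through the ungapped index of
the structure's sequence within its aligned row, using author residue
numbering verbatim; when the structure sequence is supplied it must match
the ungapped row exactly and a mismatch is fatal, because silent
renumbering is the classic source of off-by-one interface errors.

Interface enrichment is the upper-tail hypergeometric probability
P(X ≥ k) for k of n signature columns falling in K interface columns out of
N. The background N and interface size K are explicit arguments: they are
context-dependent modelling decisions, not constants.

## Mutation densities

`MD = missense count / region length` per source;
`MDR = log2(MD_cancer / MD_natural)`. Records at the same position count
with multiplicity by default (the formula counts mutations, not mutated
sites); unique-site counting is a switch. When either missense count is
zero, 0.5 is added to both counts (Haldane–Anscombe) before densities are
formed and the result is flagged, keeping the fidelity of zero-handling
auditable. Indel and frameshift counts are tallied per region for reporting
but never enter MD/MDR, which are missense-only by definition.

## Synthetic-data model

`simulate_alignment` uses a star-tree model: each column draws a root
residue from a background distribution (uniform over the 20 residues by
default); each sequence keeps its ancestral residue with probability
1 − θ and otherwise draws a replacement from the background excluding it.
θ = 0 yields NBS = 1; θ → 1 drives the expected NBS to the background mean
pair score (checked in the tests within Monte-Carlo tolerance).

Two structural extensions make planted truth *identifiable*:

- **Lineage divergence.** For multi-superkingdom experiments, each
  superkingdom's lineage ancestor departs from the root with per-column
  probability `lineage_divergence`, and diverged lineage ancestors are
  drawn mutually non-conservative (pairwise normalised score ≤ 0.3, and
  distinct from the root and each other). This is not a cosmetic choice:
  under a substitution-matrix scoring model a conservative replacement
  (e.g. I→V) *is* residual conservation, and a "diverged" background that
  can draw I/L/V-type triples plants ambiguous truth — such a column is
  genuinely conserved under the score and no detector can (or should)
  reject it. Exact-recovery experiments therefore diverge backgrounds
  non-conservatively and keep planted columns shared.
- **Event-mirrored coupling.** Coevolving column pairs share, per organism
  and with probability κ, both the substitution decision and the
  replacement draw between the two families. κ = 0 is exactly two
  independent simulations; κ = 1 with equal θ makes the substitution
  patterns identical, driving PC toward 1 — an analyzable planted truth.

Variant tables draw per-region, per-source counts from
Poisson(rate × region length) with uniform positions.

All generators are pure functions of spec + seed (byte-identical reruns).

## Validation experiment sizes

The built-in experiments (`tbpsig.validation`, also run by
`scripts/acceptance.py`) use these problem sizes, chosen as the package's
study conditions:

- Signature recovery: 50 columns, 5 planted at θ = 0, background θ = 0.8,
  20 seeds. Depth: 300 sequences per superkingdom for the universal
  detector and 200 per lobe for the lobe-specific detector. The depths come
  from a measured identifiability analysis: the flagging margin of a
  background column is ≈ 0.11 NBS units (set by the 10% planted fraction),
  the column-NBS noise tail is heavier than Gaussian (composition-driven),
  and 200 sequences bound the maximum observed background deviation at
  ≈ 0.08 over 10⁴ columns; the consensus step needs ~300 per superkingdom
  so the modal residue's margin over the strongest noise competitor
  (≈ 60 vs ≈ 13 expected counts at θ = 0.8) makes consensus errors
  negligible. These scales also match the reference alignment's order of
  magnitude (hundreds of lobe sequences).
- Permutation calibration: 500 uncoupled column pairs, 20 organisms each,
  1000 permutations; power: 20 seeds at κ = 1.
- MDR recovery: 20 replicates, rate ratio 4, expected missense counts of
  100 (natural) and 400 (cancer) in the contrasted region; the recovered
  MDR is the mean over replicates.

What passing these experiments shows: the statistics are implemented
correctly, the permutation null is calibrated, and the detectors are
consistent when signal is strong and the background honest. What they do
not show: performance on real alignments, which have phylogenetic
correlation between sequences (the star-tree model has none), indel
processes, rate heterogeneity, and intermediate conservation levels where
sensitivity/specificity trade off. The permutation null in particular
inherits the exchangeability assumption that real phylogeny violates.

## Known limitations

- Consensus ancestors ignore the tree; strongly unbalanced subsets can
  bias the reconstruction toward overrepresented clades.
- The lobe-specific ratio rule is trivially true against a negative
  counterpart NBS (kept for fidelity; filter on the reported values).
- The empirical p-value has resolution 1/n_perm; genuinely extreme
  couplings are reported as bounds.
- The CTN map leaves columns outside consensus secondary-structure
  elements unlabelled and reports them rather than guessing a numbering.
- Contact extraction approximates published van der Waals criteria with a
  distance rule; both the flat cutoff and the radius-sum variant are
  recorded per contact set so downstream comparisons stay explicit.
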