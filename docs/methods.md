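# Methods

## The family model

ST proteins are modelled as a three-part architecture: a signal peptide
of 19–28 residues; a hydrophilic mature N-terminal region of roughly
30–80 residues that starts with Arg (usually Arg-Lys), carries a Tyr-Trp
dyad at mature positions 7–8 (offset to 8–9 in a minority of members)
and the single Cys of the mature protein; and a tandem-repeat region in
which every repeat opens with (D/E)FEPRP, continues with four partially
conserved residues (X₄, repeat positions 7–10) and a fully conserved Tyr
at position 11, and typically closes with a D/N-rich spacer and a
Lys-rich block (consensus shape `(D/E)FEPRP-X4-Y-X6-7-K.KK.F.K` for the
predominant 25/26-residue repeats). The region ends with a truncated
terminal repeat (~13 aa). Every motif occurrence opens a new repeat, so
the units partition the span from the first anchor to the C-terminus
with no gaps or overlaps.

## Motif scanning and segmentation

"Similar to (D/E)FEPRP-X₄-Y" is operationalized as exact `[DE]FEPRP`
plus an exact Tyr at offset 11 by default. An optional mismatch
tolerance (at most 1 in the hexamer; the Tyr is never relaxed) is
available for imperfect leading repeats, because the degree of
similarity admitted by manual curation is not quantifiable; it is off by
default and exposed as `--fuzzy-hexamer`. Overlapping candidate anchors
are resolved leftmost-first.

Segmentation derives the modal canonical unit length (most frequent;
ties to the smaller), flags the final unit `truncated_terminal` when
shorter than the modal length, and labels the length pattern `uniform`
(one canonical length), `alternating` (exactly two lengths strictly
interleaved) or `heterogeneous`. With a single unit there is no modal
length; the unit is flagged truncated when shorter than 22 aa, the low
end of the family's typical repeat range.

## Repeat perfection (Psim)

The perfection score is defined internally: the column-wise consensus of
the anchored (position-1-aligned) units is the plain-majority residue
(ties to the earliest unit; the tie choice never changes the score), and
Psim is the fraction of unit positions equal to their column consensus,
truncated units compared over their own length. It is 1.0 exactly when
all compared positions are unanimous. This is a re-definition, not a
reproduction of any external repeat-detection program's internals, so
published perfection percentages are treated as qualitative context
only.

## DUF2775-like domain proxy

The family's diagnostic ~135-aa domain spans about 20 non-repeat
residues plus two repeats and one truncated repeat. The package counts
domains by a window proxy — non-overlapping windows of three consecutive
units with at least two canonical members, with 1–2 trailing units
counted as one truncated domain. This is explicitly a proxy for a
conserved-domain-database search, not a reproduction of it.

## Maturation and completeness

Signal-peptide delineation is a rule-based stand-in for probabilistic
predictors, chosen because the family gives it unusual traction: the
mature protein starts with Arg almost without exception. Candidate
cleavage points 19–28 are screened for a hydrophobic core (mean
Kyte–Doolittle over positions 6..cleavage−4 strictly above 1.0; window
and threshold are configurable and were chosen to separate signal
peptides from the family's hydrophilic mature regions cleanly); the
first Arg-anchored passing candidate wins, a passing candidate without
the Arg is returned flagged low-confidence, and no passing candidate
yields a none-result — typical for mature-only fragments. Externally
determined cleavage sites can be supplied per sequence (TSV sidecar) and
are used verbatim.

Completeness follows the family's curation rules: N-complete means an
in-frame stop before the first Met (nucleotide evidence) or a signal
peptide plus the Tyr-Trp dyad; C-complete means a terminal stop without
a detected frameshift or the characteristic ending of Tyr followed by
two or three residues (Tyr at position −3 or −4); full is both, internal
neither. The call is monotone: restoring a missing terminus never
demotes it.

## Typing and glycosylation

Sequons are all matches of N-{P}-[ST] with the following residue, when
present, not Pro; overlaps are all reported. Per-repeat typing reads X₄
position 7 (S → I; N → II; D/T → III) and, within type II, position 9
(S/T → IIa, creating the sequon; F/L → IIb). Protein-level calls are a
strict majority (> 0.5) over canonical repeats — truncated units are
excluded because their X₄ may be absent — with ties reported as `mixed`
and components ordered by share (ties in share follow the canonical type
order). "Predominantly" is not quantified in the family literature, so
the strict-majority threshold is a design choice.

## Profiles

Logo information content is log₂20 − H per column with no small-sample
correction and no pseudocounts (zero frequencies contribute nothing to
H); the unanimous-column maximum is 4.32 bits. The two-group comparison
uses a two-sided Fisher exact test per column and residue on the 2×2
count table, reporting residues at p ≤ α (default 0.05, no multiplicity
correction, matching the two-sample-logo convention) split into enriched
and depleted; the exact test replaces a t-test because repeat counts are
small and the exact test needs no variance assumptions.

## Composition

The charged class is exactly {D,E,K,R,H,Y,C}, acidic {D,E}, basic
{K,R,H}, with undefined residues (X) excluded from denominators. Masses
are average (not monoisotopic); concatenation is additive up to one
water per peptide bond. The isoelectric point bisects the strictly
decreasing net-charge curve Q(pH) on [0, 14] using the EMBOSS pKa set
(N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5,
Y 10.1) until |Q| < 1e-4 and the bracket collapses; the root is unique
by monotonicity. Published pI ranges for the family come from
proprietary pKa tables and are treated as qualitative.

## Clustering

Pairwise distances are 1 − identities/alignment-length from a global
Needleman–Wunsch alignment (match +1, mismatch 0, linear gap −1,
configurable); full multiple alignment is deliberately out of scope
because distances, not alignments, drive the family's clading. Neighbor
joining is canonical Saitou–Nei with a deterministic tie-break on sorted
node labels, so identical inputs give identical trees; on additive
matrices it recovers the generating topology and branch lengths exactly.
Bootstrap resamples columns of an ungapped alignment (intended use:
anchored equal-length repeat units) with replacement, re-clusters each
replicate from its p-distance matrix, and reports per-edge support as
the percentage of replicates containing the bipartition; fixed seeds are
bit-reproducible.

## Synthetic data: what it emulates and what it does not

Generator defaults are the family's reported central values: signal
peptide 22 aa (range 19–28) ending in an A-S-A cleavage motif, mature
N-terminal region 55 aa (accepted range 30–114, covering the published
outliers) with Arg-Lys start, Tyr-Trp at 7–8 and the Cys placed so the
Cys-to-first-repeat distance falls in the common 10–20 band, six repeats
(range 2–17) of 25 aa (range 22–27), truncated terminal repeat 13 aa,
type IIa (the most abundant), substitution rate 0. Repeat tails are
drawn from a consensus-shaped template (D/N-rich spacer, fixed K/F
positions) rather than uniform residues so that logo and two-sample
statistics on generated families are meaningful; within-protein units
diverge by per-unit X₄ redraws and one substitution, giving near-perfect
repeats. Mixtures alternate the two most common co-occurring patterns
(NxSx and DxT/Sx). Fragment modes trim the precursor so each class
carries exactly its own completeness evidence (N-only fragments are
shifted off any accidental Tyr-tail ending; C-only/internal fragments
start after the dyad in the hydrophilic region).

Decoys follow the motif grammars of the cell-wall families used as
negative controls — PRP oligopeptide motifs, Ser-(Hyp→P)₄ HRGP repeats,
(Gly-X)ₙ GRP strings, Ala/Ser/Thr-Pro AGP glycomodules — plus
composition-preserving shuffles of generated ST sequences; all are
rejection-resampled so they never contain the signature.

The generator does **not** emulate: EST sequencing error or frameshifts,
intron mis-splicing, hydroxyproline chemistry (Hyp is written as P),
within-species paralog structure below the clade level, or database
contamination. Passing recovery tests therefore demonstrates that the
annotation rules invert the family's architectural grammar, not that
they are robust to every artifact of real EST data.

`generate_reference_cohort` reconstructs the published 136-member family
census synthetically (72 full-length including 103- and 493-residue
extremes, 38 N-complete, 7 C-complete, 19 internal; repeat counts 2–17;
type mix 29 I / 75 IIa / 3 IIb / 18 III / 11 mixed) so that
census-recovery tests can run without the curated sequence set, which is
not redistributable here. Cohort tests measure rule recovery on this
synthetic stand-in, labelled as such.

## Numerical and interface conventions

Coordinates are 0-based half-open internally and 1-based inclusive in
every file written (GFF3 convention). Ambiguous nucleotides translate to
X; stops render as `*` and are stripped from protein input with a
warning. Summary percentages round half-up to whole points. All
randomness flows through seeded NumPy generators; one stream per
generate call, seed recorded in the FASTA description. Test problem
sizes (200-sequence recovery sweeps, 1000 decoys, quartet oracles,
100–200 bootstrap replicates) were chosen as the smallest sets that
exercise every rule branch while keeping the default suite fast.

## Known limitations

The cleavage heuristic is tuned to the family's Arg-start regularity and
will underperform on proteins without it; supply external cleavage sites
in that case. The DUF proxy counts windows, not alignments, and can
disagree with domain-database counts on proteins with imperfect leading
repeats. Psim values are internally consistent but not comparable to
external repeat-detection scores. NJ branch lengths may be slightly
negative on strongly non-additive matrices; they are reported as
computed.
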