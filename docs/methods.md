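# Methods

This note records the models implemented in `bombemine`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices a maintainer would want to know.

## Sequence handling and ORFs

Coordinates are 0-based half-open on the forward strand everywhere;
reading frames are ±1/±2/±3 with reverse frames translating the
reverse complement. Translation uses the standard genetic code only
(Biopython table 1); codons containing N render as X.

An ORF is a **maximal stop-to-stop stretch — a Met start is not
required**. Precursor mining operates on translated transcript
fragments whose true initiation codon often lies outside the fragment;
requiring Met would silently drop true precursors. The minimum ORF
length before annotation defaults to 60 aa (`PipelineConfig.min_orf_aa`)
— long enough to hold a signal peptide plus one bounded peptide,
short enough not to discard compact precursors; it is exposed as
config because no principled universal value exists.

## The processing grammar

* **Cleavage sites.** Dibasic pairs from `{KR, RR}` by default; KK/RK
  are opt-in because they are much weaker convertase substrates.
  Scanning is leftmost-greedy and non-overlapping ("KRR" → the KR at
  positions 0–1). Monobasic cleavage (a single R not adjacent to
  another basic residue) is off by default: it is real but rare, and
  enabling it by default floods candidate lists.
* **Products.** Cleavage is C-terminal to the pair and the basic
  residues are assigned to neither product (carboxypeptidase-E
  trimming assumed). A trailing Gly marks C-terminal amidation and is
  removed; a leading Gln sets the pyroglutamate flag (Gln only, not
  Glu — pGlu from Glu is comparatively rare and never unambiguous from
  sequence). Length filtering (default 4–40 aa) applies after Gly
  removal.
* **Partial processing.** A site whose upstream product would fail the
  length filter is treated as incompletely processed: the flanking
  segments merge with the pair retained, giving the "full" peptide,
  and the C-terminal fragments generated when the internal site *is*
  used are reported as children (`parent_peptide`). Merging never
  crosses the signal-peptide cut, never absorbs an empty segment, and
  never extends into an unsignaled protein N terminus. This single
  rule reproduces the observed coexistence of a full amidated peptide
  containing an internal Arg-Arg pair and its C-terminal decapeptide,
  without enumerating all 2^sites processing states.
* **Signal peptides.** The gate is a deliberately simple heuristic —
  a basic residue within the first 5 positions plus a ≥8-residue
  window of mean Kyte–Doolittle hydropathy ≥2.0 within positions
  3–25, cleaved at the first position (15–35) preceded by a small
  residue (A/G/S/C). It is a stand-in for dedicated predictors, and an
  externally computed span can be passed through (`override`) to
  reproduce a published call. On generated precursors it recovers the
  planted cleavage point within ±3 residues in >90% of seeds; on real
  proteomes it is a *gate*, not a predictor, and should be replaced by
  a dedicated tool when available.
* **Precursor-likeness score.** A transparent additive surrogate for
  HMM-based precursor screens: 2·[signal] + 2·[amidated
  dibasic-bounded peptide] + 1·[motif hit] + 0.5·[peptide adjacent
  (≤2 residues) to the signal end]. The weights order the evidence by
  specificity; the score is for ranking only and has no probabilistic
  interpretation. Top-K retention defaults to 5000. An external score
  column can replace it to reproduce a published ranking.

## Family clustering

Peptides from distinct precursors (optionally distinct species) are
linked when they share ≥m identical residues in a k-residue terminal
window (defaults k=6, m=4); families are single-linkage connected
components of ≥2 members. Single linkage matches the transitive
"lists of peptides that shared termini" notion underlying such
screens; cliques would split families over one divergent member. For
peptides shorter than k the window shrinks and m scales as
⌈m·len/k⌉. The consensus string (strict majority, else x) is for
display only.

## Alignment and conservation

Pairwise alignment is Needleman–Wunsch with affine gaps (Gotoh),
BLOSUM62, gap open −10 / extend −1, deterministic traceback
(diagonal > up > left at ties). The progressive MSA orders merges by
average-linkage (UPGMA) clustering of pairwise alignment distances
(1 − identity/length) and aligns profiles column-against-column with
mean pairwise substitution scores. This is adequate for the short,
conserved peptide sets the pipeline aligns; it is not an iterative
refiner, and manual curation of published alignments cannot be
reproduced — thresholds stay explicit config instead. Group-aware
conserved columns report a residue present in ≥1 group-A row and
≥`min_b` group-B rows; "several" reference species is quantified as
min_b = 3 by default.

## Gene structure

The spliced aligner chains exact k-mer anchors (k=12) collinearly by
a dynamic program maximizing matched cDNA coverage, converts genomic
gaps between chained exons into introns (30–100,000 nt), and shifts
boundaries locally (≤k) to satisfy GT…AG. Full cDNA coverage is
required; anything else raises "unalignable" rather than returning a
partial model. This is exact-match splicing: it recovers planted
structures perfectly and is appropriate for same-species
cDNA-to-genome mapping, but it does not model substitutions or
sequencing error between cDNA and genome. Intron phase is the number
of CDS nucleotides 5′ of the intron mod 3; introns outside the CDS
are labeled UTR and counted separately (intron counts quoted for
genes are CDS-interrupting introns only). On a protein alignment,
phase-1/2 introns map to the column of the interrupted codon and
phase-0 introns to the column preceding the junction; two species
sharing column and phase are flagged `shared`.

## Trees

Distances are p-distances with pairwise gap deletion, optionally
Kimura-corrected (d = −ln(1 − p − 0.2p²), capped at p = 0.85 where
the correction diverges). Trees are Saitou–Nei neighbor joining with
a canonical tie-break (candidate pairs ordered by the smallest leaf
label under each node), which makes results deterministic *and*
invariant to input row order; negative branch lengths are clamped to
zero with the length transferred to the sibling so path lengths are
preserved. Support is column-resampling bootstrap; replicate trees are
compared by canonical bipartitions. Distance+NJ is a deliberate
desk-scale stand-in for likelihood inference with rate heterogeneity:
the quantity this package validates is clade recovery on synthetic
data, and the clade test accepts externally computed newick trees so
it can be run on published topologies. Rooting uses the outgroup stem,
falling back to midpoint.

## Peptide MS

Masses derive from one in-package table of monoisotopic and average
residue masses (proton 1.007276 Da, water 18.010565 Da; amide
−0.98402, pGlu −17.02655 monoisotopic), kept separate from any
external mass library so tests can compare against an independent
elemental-composition oracle. Fragment prediction covers singly- and
doubly-charged b/y ions (CID context); the C-terminal modification
applies to y ions only, the N-terminal one to b ions only, and
complementary b/y pairs sum to the neutral peptide mass — asserted as
an invariant. Spectrum matching is greedy nearest-peak assignment
within a ppm tolerance (each peak used once); coverage is the
fraction of inter-residue bonds supported by ≥1 ion. No isotope
envelopes, retention prediction, or search-engine scoring: the
intended use is confirming a handful of predicted peptides against
reference spectra, not database search.

## Pharmacology

The 4PL is parameterized in log₁₀ concentration and fitted by
Levenberg–Marquardt least squares over **all replicate points
jointly** (per-concentration averaging discards replicate
information). Initialization: bottom/top from the response range,
logEC50 at the concentration nearest the half-range response, Hill 1;
five multi-starts vary Hill ∈ {0.5, 1, 2} and jitter logEC50 ±1 log
unit; the lowest-RSS fit wins, and a negative-Hill solution is
canonicalized by swapping asymptotes. Fits require ≥4 distinct
concentrations. Luminescence is normalized to 100% of each
experiment's maximum before fitting (scale-invariant, so EC50 and
Hill are unaffected). Contraction amplitudes are expressed as % of a
reference agonist measured in the same preparation; for cumulative
(no-wash) series the value at each dose is reported as measured, and
non-monotone series are flagged rather than forced monotone. Area
time courses normalize to the last pre-injection measurement per
animal. Group comparison is the pooled two-tailed Student's t-test
(Welch behind a flag); degenerate zero-variance input returns p = 1
(equal means) or p = 0 with an infinite statistic (unequal).

## Synthetic data: what it does and does not emulate

Generators are pure functions of (seed, params). Planted precursors
have a 21-residue signal region (Met, a basic residue, a hydrophobic
core, a small residue at the cleavage point), one or more
dibasic-flanked peptide segments ending in an instantiated motif whose
final Gly is the amide donor (default `RIFGPxxG`, matching the
consensus C-terminus of the echinoderm peptide family), and random
linkers drawn from pools excluding K/R (no spurious cleavage sites)
and terminal G (no spurious amide donors). Decoys are polar/acidic
proteins with only isolated arginines, no signal-like N terminus, and
no dibasic-bounded Gly-terminated segment. Synthetic genes insert
GT…AG introns of specified phase at specified CDS positions between
UTRs; dose-response tables apply multiplicative normal noise (the
assay noise structure is not characterized in the literature;
multiplicative is the conventional choice for luminescence);
spectra contain all singly-charged b/y ions plus uniform noise peaks.

Consequently, passing the synthetic-recovery tests demonstrates
correctness of the algorithms under their stated assumptions — it does
not demonstrate robustness to real-data phenomena the generators omit:
codon-usage bias, sequencing error, EST fragmentation, compositional
drift between orthologs, intron boundary ambiguity beyond k-mer reach,
isotope envelopes, or assay-plate batch effects.

## Problem sizes

The test and acceptance workloads use 100-seed proteomes of 10 planted
precursors + 500 decoys, 100 synthetic three-intron genes, 50 random
additive matrices of 4–8 taxa, 100-replicate bootstraps, 1,000-peptide
fragment-identity sweeps, and 200-seed Monte-Carlo EC50 recovery at 5%
CV — sizes chosen so the full chain validates in well under a minute
per stage while keeping the statistical claims (≥95% recovery rates)
meaningful.
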