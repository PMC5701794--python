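# Methods

## Setting and data model

The pipeline analyses bulk TCRα cDNA amplicons from naïve CD4 T cells of mice
that express one fixed TCRβ chain, so that differences between repertoires
reflect which α chains could partner that β during positive selection on a
given MHCII allele. A read is modelled as

    read = TRAV[0 : L_V − t_V] + N + TRAJ[t_J : L_J]

an amplicon beginning at the 5′ end of a TRAV allele, with `t_V` nucleotides
trimmed from the V 3′ end, `t_J` from the J 5′ end, and `N` untemplated bases
between them. Indels are not modelled anywhere (assignment is ungapped), and
qualities are ignored.

## Germline reference and ambiguity groups

The reference is a FASTA of TRAV/TRAJ alleles plus a TSV sidecar
(`segment_id, kind, family, subfamily, dup_class, anchor_offset`). The sidecar
keeps the FASTA standard instead of encoding metadata in headers. On load,
every V anchor codon must translate to Cys and every J anchor to F/W/L
followed by Gly; violations are hard errors naming the segment.

Mouse TRAV subfamilies contain duplicated members (classes A/D/N) whose stored
sequences can be identical and hence indistinguishable by sequence analysis.
Members sharing both the family–subfamily stem and the full sequence are
collapsed into one ambiguity group named stem + sorted class letters
(`TRAV06-3ADN`). Identical sequences across *different* stems are not merged
(only subfamily duplications are a known biological identity); a warning is
emitted. The comparison region is the full stored sequence — how much V a
read covers is controlled by the reference the user supplies (and, in
testing, by the simulator), so no arbitrary sub-region needs to be chosen.

## Assignment, correction, CDR3, N bases

**Assignment.** For each candidate group the read is scored against the
representative with an end-anchored ungapped walk (+1 match, −3 mismatch; V
anchored at the read 5′ end, J at the 3′ end); the span maximising the score
wins, ties resolved toward the shorter span, then across groups by score,
span, mismatch count and id. A read is unassignable when the best span is
< 12 nt, its score ≤ 0, or its mismatch rate exceeds 10%. The −3 penalty
makes extension into the random junction (expected score −2/nt) stop near
the true boundary while single sequencing errors are absorbed.

**Correction.** Germline-templated sequencing errors are replaced by the
germline base. The junction-proximal window is protected: corrections are
applied only more than 3 nucleotides before the predicted V end and more
than 3 after the predicted J start (strict reading — positions 1–3 from the
boundary are never touched, position 4 is correctable). Boundary prediction
walks the alignment from the anchored end and treats a mismatch as a
correctable candidate only when the next three aligned bases match germline
again (an *evidence run*); otherwise the junction is considered reached.
This makes correction provably conservative: a candidate needs three more
germline positions beyond it, so junction bases — which have at most the
trimmed remnant of germline beyond them — cannot qualify when trimming is
short (≤ 3 nt, the simulator default), and any applied correction restores a
germline-templated base, i.e. the corrected read is never farther from the
pre-error sequence than the raw read. The protected window is defined
relative to the *predicted* boundary: the true boundary is not identifiable
when junction bases chance-match germline, and no data-driven rule can
guarantee a window around a quantity the data do not determine. Reads whose
predicted V and J spans overlap (junction-free) are flagged and the overlap
is left uncorrected.

**CDR3α** runs from the first base of the V anchor Cys codon through the last
base of the J anchor F/W/L codon, inclusive. *Productive* requires length
divisible by 3, translation starting with C, ending in F/W/L, and no stop.
Only productive sequences enter repertoires; the analysis is of protein
sequences.

**N bases** are estimated by parsimony: the maximal contiguous 5′ stretch
explained by germline V is attributed first, then the maximal contiguous 3′
stretch explained by germline J on the remainder; the unexplained middle is
the N estimate, capped at the CDR3 length. An untemplated base that happens
to match the trimmed germline continuation is attributed to the germline, so
the estimate is the *identifiable* insertion count, a lower bound on the
generative one; with zero trimming the two coincide exactly. The simulator
records both per clonotype (`n_drawn`, `n_identifiable`), and recovery is
judged against the identifiable count — the observable image of the
generative parameter.

**Singleton filter.** Errors within 3 nt of the junction cannot be corrected,
so a read with such an error masquerades as a novel rare clonotype. Sequences
whose clonotype key occurs only once in a sample are therefore removed. A corollary: after filtering, Chao1 sees no singletons and
collapses to observed richness, so richness estimation is most informative on
the unfiltered table (the acceptance script reports it there).

## Repertoire summaries

Clonotype keys: full TCRα protein (V group, J group, CDR3α) — the default —
CDR3α alone, or the V–J pair. Usage tables are abundance-weighted (percent of
reads) by default, since segment usage is a statement about the cell
population; CDR3 length, N-base and positional amino-acid summaries default
to unique-clonotype weighting, since they compare *different sequences*.
Both weightings are exposed. CDR3 positions are 1-based with the
anchor Cys as position 1. TRAV axes are ordered by family/subfamily number,
TRAJ axes by chromosomal position (in the synthetic locus the TRAJ id number
is the position rank, higher = more distal from the TRAV cluster). SEMs are
always across mice (or across sample pairs), never across clonotypes within
one mouse.

## Diversity and overlap

*Accumulation curves*: mean ± sd of unique clonotypes over seeded random
subsamples without replacement (default 100 permutations, 20 evenly spaced
depths); at full depth the curve equals observed richness with sd 0.

*Chao1*: S_obs + f1²/(2 f2), bias-corrected to S_obs + f1(f1−1)/(2(f2+1))
when f2 = 0, on clonotype counts — the standard abundance-based lower bound
for total-richness extrapolation.

*Chao–Jaccard (2005), abundance-based*: U and V estimate each sample's total
relative abundance of shared clonotypes, corrected for unseen shared species
via shared classes that are singletons/doubletons in the other sample
(f_+2 = 0 is replaced by 1; U, V clamped to 1 since the correction can
exceed it); the index is UV/(U+V−UV), 0 when no clonotype is shared. Its
variance estimators are not implemented; cohort SEMs across mice/pairs serve
instead.

*Usage distances*: counts scaled to per-10⁴ totals, incremented by a
pseudocount (default 1 in the same unit, so absent segments contribute
log2(1) = 0 rather than −∞; configurable), log2-transformed, Euclidean norm.
Sample ordering by average-linkage (UPGMA) agglomerative clustering on that
matrix — chosen as the conventional method for usage-profile heatmaps —
deterministic under scipy's tie-breaking, exported with leaf order and a
Newick tree.

*Comparison classes*: unordered pairs classified by shared MHCII and/or TCRβ;
self-pairs excluded from class means. SEMs across pairs ignore the
non-independence of pairs sharing a mouse — a documented limitation. The
V–J-pair junction comparison requires at least 5
distinct CDR3αs for the pair in *every* participating sample; inadmissible
pairs are excluded with a per-sample log. Significance testing (ANOVA etc.)
is out of scope; per-pair values and count matrices are exported for external
tools (e.g. edgeR/DESeq2 for differential segment usage).

## Simulator

The generator reproduces the statistical structure the analysis assumes, with
full ground truth; all outputs are pure functions of (config, seed), with
named numpy substreams per stage and mouse.

- **Germline pool**: random V (60 nt) and J (45 nt) segments with valid
  anchors; the V anchor sits 9 nt before the 3′ end and the J anchor at
  offset 18, so junction-proximal germline contributions are realistic and
  anchors always survive trimming. A configurable number of V families is
  emitted as identical A/D/N trios to exercise ambiguity-group collapsing.
- **Rearrangement**: V drawn by accessibility weights (default mildly uneven,
  0.85^i normalised); J drawn ∝ exp(bias × position/(n−1)) — a single
  exponential tilt for the distal-TRAJ preference rather than a mechanistic
  rescue-rearrangement model, since only the usage skew is observable.
  Geometric trims capped at 3 nt per end (p = 0.5) and geometric N additions
  capped at 12 (p = 0.25, mean ≈ 2.9). P-nucleotides are not modelled.
- **Selection**: a thymocyte re-rearranges until its candidate is productive
  *and* accepted, up to a bounded attempt budget (discards logged). Hash
  acceptance: accept iff a 64-bit SHA-256 hash of (CDR3α, genotype key) maps
  below the acceptance rate (default 0.1). Identical CDR3s are accepted
  identically in all mice of a genotype and across genotypes with probability
  ≈ the rate, so within-genotype sharing exceeds between-genotype sharing by
  construction for any rate < 1 — the qualitative observable — with zero
  hallucinated biology. An `aa_preference` mode multiplies the threshold per
  preferred residue at configured positions/lengths to plant positional
  enrichments.
- **Abundance**: each selected cell draws a lognormal peripheral expansion
  factor (σ = 1.5 by default, giving the uneven, non-Poissonian clone sizes);
  convergently generated clonotypes pool their cells, so frequently generated
  (and hence shared) clonotypes are also abundant — which is exactly why the
  abundance-based overlap index exceeds plain Jaccard on such cohorts.
  Reads are multinomial to the configured depth (default 10⁴).
- **Errors**: per-base substitutions (default 0.002), no indels, matching the
  ungapped annotation model.

Defaults (6 genotypes = MHCII b/f/s × DObWT/DOb48A, 3 mice each, 1500 cells,
depth 10⁴) mirror the study design; tests and examples scale cell counts and
depth down (hundreds of cells, depths of 500–10⁴) to keep runs in seconds
while leaving every distributional assumption unchanged.

What the simulator does *not* emulate: real locus sequence content and
homology between segments, SHM-free but primer-biased amplification, UMI
structure, paired TCRβ information, thymic negative selection, or receptor
editing dynamics. Passing tests therefore demonstrate correctness of the
statistics and the annotation logic under the stated generative assumptions,
not performance on real reads with indels or segment homology.

## Numerical and degenerate-input conventions

Empty repertoires: overlap of two empty samples is flagged undefined (NaN);
summaries on empty tables are errors. Assignment ties are broken
deterministically (score, span, mismatches, id). Usage vectors must sum to
100 within 1e-9. The accumulation RNG, simulator streams and CLI seeds are
all explicit; no global RNG state is used. TSV floats are written with
`%.10g` so pipeline outputs are byte-stable; the determinism audit hashes
every stage output across two full runs.

## Known limitations

- Correction safety is guaranteed for trims ≤ 3 nt (evidence run of 3); with
  longer trimming a junction base can in principle chance-qualify, at
  probability ≈ 4^-(run+1) per read.
- The N-region estimate is a parsimony lower bound; comparisons should use it
  consistently (as the figures' "predicted" N counts do), not as the true
  insertion count.
- Pair-level SEMs ignore shared-mouse correlation.
- Ambiguity groups collapse only exact full-length duplicates; near-identical
  segments distinguishable at one position are kept separate even though a
  single read error could cross-assign them (the mismatch-rate ceiling and
  singleton filter mitigate this).
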