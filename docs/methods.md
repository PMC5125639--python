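# Methods

This note documents the models, rules and numerical choices behind the
package, and what the synthetic-data experiments do and do not demonstrate.

## Reference frame and diagnostic rules

All functional rules are expressed in 1-based coordinates of the 467-residue
human ADHFE1 protein, the family's customary reference frame. A query enters
that frame by affine-gap global alignment (Needleman–Wunsch, BLOSUM62, gap
open 11 / extend 1 — community defaults; the gap convention is
`open + (L−1)·extend` for a gap of length L). Only columns where both query
and reference carry a residue enter the position map; reference positions
deleted in the query (e.g. the HOT insert spans in non-HOT sequences) are
simply unmapped.

The rules themselves:

- **Coenzyme (position 81).** Asp or Thr → `NAD`; Gly or Ala → `NADP_or_dual`;
  anything else, including Ser and gap, → `ambiguous`. Glu is accepted as a
  charge-conservative stand-in for Asp (an extension beyond the literal
  residue list, documented as such). Ser is deliberately not called: within
  this family, Thr-carrying enzymes have been crystallized with NAD⁺, so a
  Ser→NADP rule would be an invention.
- **Metal (242/246/330/357).** The canonical D-H-H-H tetrad → 
  `metal_dependent`; Asn/Arg/Gln at 242 with the three histidines intact →
  `metal_independent_likely` (the maleylacetate-reductase pattern);
  everything else → `indeterminate`. Histidine substitutions are left
  indeterminate rather than guessed.
- **GDH exclusion.** His at 357 with neither His246 nor His330 marks a
  glycerol-dehydrogenase-like sequence; the classifier refuses such queries
  (`excluded_gdh_like`) because they belong to a related but distinct family.
- **GGGS motif (138–141).** Present if at most one mismatch against the
  consensus (tolerance configurable; unmapped positions count as
  mismatches).
- **HOT insertions (256–274, 342–354).** Insert length = number of reference
  positions in the span mapped to query residues; `hot_like` requires ≥15
  and ≥9 of the 19/13 positions (≈80%/70%, tolerating alignment slop).
- **Position 334** is reported but drives no call: it is catalytic, not
  metal-binding, and no decision rule exists for it.

## Classification

Each subfamily is represented by ≥3 seed sequences. A query's subfamily
score is the mean of its top-3 alignment scores against that subfamily's
seeds. Assignment requires (a) a margin between best and second-best
subfamily of at least 5% of the best score, and (b) a reciprocal best hit:
with s* the query's best seed, s*'s best partner in the pooled set
({query} ∪ all other seeds) must be the query itself or a seed of s*'s own
subfamily. Failing either, the query is `divergent_unassigned` — recorded
but not counted in the census. Ties break conservatively toward
non-assignment, and deterministically by CDD accession. BLAST bit-scores are
replaced throughout by the module's own global-alignment scores: no external
binary, deterministic, and adequate at this scale. The pooled-set RBH
definition is this package's operationalization of an otherwise unspecified
procedure.

The phyletic census counts only assigned queries, cross-tabulated by taxon
group × subfamily. Headline shares are reported both truncated to integer
percent (matching the prose style of family surveys, e.g. 656/868 → 75%)
and at one decimal.

## Phylogenetics

Distances are p-distances over shared (both-residue) columns, optionally
Poisson-corrected (−ln(1−p), capped at 10 when p→1). The column matrix for
tree building projects every sequence onto reference coordinates; columns
with >50% gaps are dropped. Neighbor joining follows Saitou–Nei with two
determinism guarantees: Q-matrix ties resolve to the smallest node-index
pair in the current ordering, and negative branch-length estimates are
clamped to zero with the raw value retained on the node. NJ is exact on
additive matrices (verified against enumerated trees for n ≤ 6 and against
scikit-bio's implementation). Bootstrap: columns resampled with replacement,
500 replicates by default, each replicate's NJ tree voting for the
bipartitions of the full-data tree; supports are vote percentages.
Monophyly of a subfamily is the support of the bipartition isolating exactly
its members; trees are unrooted, so monophyly is evaluated on bipartitions,
not rooted clades. Maximum-likelihood inference is out of scope: the
published family trees note that NJ, minimum-evolution and parsimony gave
essentially the same groupings, which licenses NJ as the desk-scale method.

## Sequence logos

Column information follows Schneider–Stephens:
R = log₂20 − (H + e_n), with H the Shannon entropy of observed frequencies
and e_n = 19/(2·n·ln 2) the small-sample correction (optional; both modes
are supported since published logos rarely state which was used). Letter
height = frequency × R. Gaps and X are excluded from counts. Output is
numeric (TSV); no image rendering is attempted, since the claims under test
are the numbers.

## The synthetic family

The generator emits data with the statistical structure the analyses assume,
with every planted fact recorded in a truth table:

- **Reference**: 467 residues with all anchors planted (D81, GGGS, D-H-H-H
  tetrad, Y334) and both insert spans present.
- **Ancestors**: one per subfamily, mutated from the reference and carrying
  subfamily-specific residues at 81 and 242 (e.g. MAR: Thr81 + Asn242;
  NADPH-BDH: Gly81; FeADH2: Ser81 + Gln242). Only the HOT ancestor keeps the
  insertions; all others have both spans deleted wholesale.
- **Samples**: per-subfamily descendants at a within-subfamily identity of
  ~70%, taxon-labeled only from domains/lineages the registry census allows.
- **Decoys**: GDH-like sequences retaining only His357 of the tetrad.

Three structural choices make planted truth recoverable by pairwise
alignment, mirroring properties of the real family rather than idealizing
them away:

1. **Conservative substitutions.** Mutations draw from the residue's
   BLOSUM62 neighborhood (score ≥ −2) instead of uniformly from 19
   alternatives. Real homologs at ~20% identity retain 30–40% *similarity* —
   which is exactly what makes their alignments computable — and the
   generator reproduces that band (~35% measured). Uniform proposals were
   tried first and demolish this property: at the family's stated identity
   the optimal alignment then misplaces gaps and no aligner, ours or
   otherwise, can transfer reference numbering.
2. **A conserved skeleton.** Diagnostic anchors sit inside ±2-residue
   conserved windows, sparse conserved columns (spacing 24) run through the
   sequence, and the insert flanks carry fixed distinct conserved runs —
   emulating the 21 strictly conserved secondary-structure elements of the
   real scaffold. Conserved columns carry high self-score residues
   (W/C/H/P/F/Y), as buried structural positions do; neighbouring conserved
   letters never repeat, so alignments cannot shift register for free.
   Insert interiors use a disjoint hydrophilic alphabet so gap placement at
   the spans is score-unique.
3. **Substitutions only.** Indels occur solely as whole-insert
   presence/absence, so reference numbering is exact by construction and any
   annotation error is attributable to alignment, not to the generator.

**Calibration.** The ancestor substitution rate is solved in closed form
from the target identity (free columns match with probability
(1−m)² + m²·κ, κ ≈ the pool-coincidence probability ≈ 0.08) and then refined
against the *measured* mean pairwise identity using the package's own
alignment metric (secant updates, ≤4 rounds, acceptance within ±2 points,
hard failure beyond ±5). The conserved skeleton imposes an identity floor:
with the anchors needed for reliable numbering transfer, the achievable mean
inter-subfamily identity is ~24%, which the generator reports honestly
rather than silently diluting the skeleton (which would trade calibration
cosmetics against annotation correctness). This sits within the ±5-point
band around the family's stated ~20%.

**What passing tests show — and don't.** On this synthetic family, rule
recovery and classification are exact (950/950 at default scale) and every
subfamily is a fully supported NJ clade. Real data are harder in ways the
generator deliberately omits: within-subfamily rate heterogeneity, genuine
indels outside the two insert spans, convergent residues at anchor
positions, fragmentary sequences, and subfamily relatedness structure
(an option adds the two known sister pairings, LPO–FeADH4 and
AAD-C–NADPH-BDH–PDD, via shared intermediate ancestors; the default is a
star). Results on synthetic data therefore validate the machinery —
correctness of the rules, determinism, and the statistical pipeline — not
the field performance of annotation on divergent natural sequences.

## Numerical and interface choices

- Alignment tie-breaks: the aligner's canonical first traceback; repeated
  calls are byte-identical (verified by test).
- Identity metric: identical-residue columns (X never counts) over all
  alignment columns, so gaps count against identity; similarity counts
  positive-score residue pairs. The denominators are stated because the
  literature rarely defines them.
- Length filter: strictly greater than 200 residues, since genuine FeADHs
  run ~400 residues and shorter fragments carry too few anchors.
- Percentages: truncated-integer and one-decimal forms are both emitted;
  machine outputs always carry raw counts.
- Problem sizes: the default study uses 19 subfamilies × 50 sequences,
  3 seeds per subfamily for classification, 2 taxa per subfamily (38 leaves)
  for the bootstrap tree with 500 replicates — sizes chosen so the full
  analysis runs in minutes on one core while keeping every subfamily
  represented.
- Registry edge cases: single exotic finds (a Lokiarchaeum FeADH2, a
  Thaumarchaeota FeADH7, a Nannochloropsis HEPD) keep their domain-presence
  flags — the census of 8 tridomain subfamilies requires them — and are
  recorded as footnotes; the dubious *Posidonia oceanica* HVD record is a
  footnote only, not a plant-lineage presence.

## Known limitations

- Annotation quality is bounded by pairwise alignment to a single reference;
  an MSA- or profile-based numbering transfer would be more robust on real
  data.
- The RBH criterion is evaluated within the seed pool, not against a
  database; it inherits the seed sets' coverage.
- Distances ignore among-site rate variation; Poisson correction is the only
  multiple-hit model offered.
- The CLI's `classify`/`tree` commands default to generator-derived seed
  sets and reference; real-data use should supply curated equivalents.
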