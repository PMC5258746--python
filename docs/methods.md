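# Methods

## The inference problem

A transposable element found in two reproductively isolated species can have
arrived there in two ways: vertical descent from the species' common ancestor,
or horizontal transfer (HT) between the lineages. The two histories leave
different marks on synonymous divergence. Under vertical descent, the
synonymous divergence of the element between the species is at least as large
as expected from the species-split age and the element's clock rate — and for
a nuclear element compared against slow chloroplast host genes, much larger.
After an HT at time T younger than the split, element divergence instead
reflects T. `copiaht` operationalizes this as three conjunctive lines of
evidence (divergence comparison, tree incongruence, codon-bias control) plus
strict-clock dating.

## Divergence estimation (NG86)

Pairwise synonymous/nonsynonymous divergence uses the Nei–Gojobori (1986)
counting method: fractional synonymous site counts per codon (each of the
nine single-nucleotide mutants classified by whether it preserves the amino
acid), pathway-averaged difference counts for codons differing at more than
one position (unweighted mean over orderings of single steps; orderings that
pass through a stop codon are excluded, and a codon pair whose every pathway
is blocked is treated as missing), sites averaged over the two sequences,
and the Jukes–Cantor multiple-hit correction
Ks = −(3/4)·ln(1 − (4/3)·pS). The correction is undefined at pS ≥ 3/4
(saturation); such pairs are flagged and excluded from group summaries,
which report the mean and sample SD (n−1; SD = 0 for a single pair) over all
between-group pairs. The SD is reported in the conventional "mean ± SD over
pairwise values" style even though pairs sharing lineages are not
independent.

Stop codons encountered in alignments are treated as missing data (the codon
is masked NNN in that sequence only), and every codon column containing an
alignment gap in any sequence is deleted (complete deletion, not pairwise).
Both choices are the common conventions for this analysis style; the
stop-site rule for *site counting* is switchable between
`nonsynonymous` (default; mutations to stops count as nonsynonymous, so
s + n = 3 per codon) and `excluded` (PAML-style renormalisation). The two
rules answer slightly different questions: under a mutation process that
cannot fix stop codons (like the simulator's), the `excluded` rule is the
unbiased one for Ka/Ks, while the `nonsynonymous` rule matches the default
of the widely used distance-based implementations.

The implementation is table-driven (per-codon and per-codon-pair lookup
arrays precomputed at import); the test suite verifies exact agreement
(10⁻¹²) with an independently written brute-force enumerator on 1,000 random
sequence pairs.

## Codon bias index

CBI = (N_opt − N_ran)/(N_total − N_ran), where N_opt counts occurrences of
each family's single preferred codon, N_ran = Σ occurrences/family-size is
the count expected under uniform synonymous usage, and single-codon amino
acids (Met, Trp) and stops are excluded everywhere. CBI is 0 with no bias
and 1 when every counted codon is preferred. The preferred-codon set is
user-suppliable; the shipped default is a generic dicot-style table (one
majority codon per family from highly expressed plant nuclear genes).
Published CBI values computed with other software depend on that software's
internal preferred-codon table, so cross-package agreement is expected to be
approximate unless the same table is supplied.

The control itself is deliberately strict: the HT interpretation survives
only if the element's mean CBI is strictly below every host gene's CBI, i.e.
selection for codon usage cannot explain the element's low synonymous
divergence.

## Ks comparison test

"Element divergence comparable to host-gene divergence" is made precise with
a comparability constant c (default 1.5) and a codon-column bootstrap:
columns of the element alignment and of each host-gene alignment are
resampled independently (n_boot = 200 by default), the between-group mean Ks
is recomputed for each resample, and

p(gene) = P*(mean Ks_TE ≤ c · mean Ks_gene).

A small p (≤ α, default 0.05) means the element's divergence significantly
*exceeds* the comparability band — the vertical expectation for a fast-clock
element — and the comparison fails; it passes when p > α for every host
gene. On vertical simulations with the element clock ten times the host
clock the observed Ks ratio is ≈ 10 and the test fails essentially always;
false verdicts are additionally suppressed by the conjunction with the
incongruence requirement, which vertical histories do not produce. The
bootstrap respects codon-level dependence within columns and is
deterministic under a seed.

## Trees and incongruence

Trees are built by Saitou–Nei neighbor joining on Jukes–Cantor nucleotide
distances by default (synonymous distances saturate faster; the choice is
configurable). Negative NJ branch lengths are clamped to zero with the
deficit moved to the sibling branch; ties in the Q criterion are broken by
label order, making output deterministic. On additive matrices NJ provably
recovers the generating tree; the suite checks exact recovery (topology and
path lengths to 10⁻⁹) on random 4–10 taxon trees and cross-checks topology
against an independent NJ implementation.

For the incongruence scan the element tree (tips = copies) is collapsed to
one tip per species where the species' copies are monophyletic
(single-copy species are monophyletic by convention; monophyly is tested
as an unrooted bipartition property and is invariant to rerooting).
Non-monophyletic species are flagged, represented by their maximal
same-species clades (`species#k`), excluded from the bipartition comparison,
and reported as implicated. Conflict between the collapsed element tree and
the species tree (pruned to the shared species) is quantified by the
Robinson–Foulds symmetric difference, normalized by 2(n−3). Implicated
species are found by leaf pruning: a species whose single removal restores
full congruence is implicated; if no single removal suffices, any removal
that reduces the conflict count is used, and failing that the union of
minority sides of conflicting bipartitions. A single regrafted species is
thereby implicated exactly; an HT pair typically implicates both ends
(pruning either the recipient clade or the donor restores congruence).

The verdict for a pair requires all three evidence lines; any line can be
waived explicitly for exploratory use. Support values are not computed —
conflicts are reported topologically.

## Clock dating

T = Ks/(2r)/10⁶ Mya, rounded to two decimals at reporting. The divisor 2
reflects divergence accruing along both lineages since their common
ancestor: between-taxon element Ks dates the transfer, within-recipient
element Ks dates the amplification burst. Default rates: 1.3 × 10⁻⁸
synonymous substitutions per synonymous site per year for nuclear/TE
sequences and 1.3 × 10⁻⁹ for chloroplast *rbcL*-like genes. A burst date
older than the transfer date is reported with a warning (not an error),
since both are noisy estimates of ordered events.

## The simulator

`simulate.evolve_codon_sequence` evolves a coding sequence for t years by
thinning a dominating Poisson process: per-nucleotide proposals at rate
r·max(1, ω) with equal exchange rates (JC-like), classified in codon
context; synonymous proposals accepted with probability 1/max(1, ω),
nonsynonymous with ω/max(1, ω), stop-creating proposals rejected. This
realizes a synonymous substitution rate of exactly r per synonymous site
(synonymous changes never create stops, so rejection does not distort the
synonymous scale) and a nonsynonymous rate of r·ω. The expected NG86
divergence between two descendants separated for t each is 2·r·t; the suite
verifies this Monte-Carlo at 1,000 codons (50 replicates, within 3 SE, and
relative calibration error < 10%).

`simulate_dataset` evolves each locus along a genealogy derived from a
dated, ultrametric, rooted species tree (newick, branch lengths in years).
Host-gene loci descend strictly along the species tree. Element loci
additionally honour: HT events — the recipient-side clade whose stem spans
the transfer time is detached and regrafted onto the donor lineage at that
time (an HT older than the recipient's split from its sister correctly
carries the sister clade along); burst events — n copies star-radiate from
the named species' lineage at the burst time. Per-species copies
star-radiate at a configurable `copy_divergence_time` (default 0 years:
copies identical, appropriate for single-copy host genes; the spec-level
row-count contract copies_per_species × species + burst copies always
holds). A single seeded generator drives root-sequence draw and every
branch, so identical scenarios give byte-identical FASTA output. The truth
record stores all events and each locus's realized gene-tree newick.

Codon bias is imposed only at the root (each codon swapped for its family's
preferred codon with probability `preferred_codon_fraction`); evolution
itself is preference-neutral, so bias decays with divergence. This
deliberately decouples codon bias from divergence so the CBI control can be
tested independently. Not emulated: indels, recombination/solo-LTR
formation, within-species coalescent structure, selection on codon usage
during evolution, rate variation among sites or lineages, and base
composition bias. Passing tests therefore demonstrate correctness of the
estimators and decision procedure under a clean clock-like process, not
robustness to alignment error or rate heterogeneity in real data.

## Demonstration scenario

The bundled scenario fixes its geometry from the quantities the pipeline is
designed around: donor-side/recipient-side split at 79.6 Mya (so the
chloroplast host expectation is 2·1.3e-9·79.6e6 ≈ 0.207), recipient-clade
split 5.38 Mya, HT at 11.38 Mya (element expectation 0.296), burst of four
copies at 7.19 Mya (within-recipient expectation 0.187), 1,000 codons,
element ω = 0.5 (a free parameter — moderate purifying selection typical of
recently active elements), host ω = 0.1, root codon-bias fractions 0.35
(element) and 0.55 (host). Because the burst predates the recipient species'
split, the recipient species' copies are non-monophyletic by construction —
the burst happened in their common ancestor — and the scan handles and flags
this. Twenty seeded replicates of this scenario plus twenty matched
vertical-only nulls form the parameter-recovery check (verdict rate,
false-positive rate, dating error), sized to run in seconds.

## Element annotation

LTR pairs: exact 15-mer matches between the terminal thirds are binned by
diagonal, the best band is extended gaplessly with an X-drop rule
(match +1, mismatch −2, drop 10), and boundaries snap to the nearest TG…CA
frame within 20 bp when present; identity is matches/aligned columns.
PBS: best suffix-anchored reverse-complement match (≥ 12 nt) to a supplied
tRNA 3′ tail within 20 bp downstream of the 5′ LTR. PPT: longest window of
≥ 10 bp with ≥ 80% purines within 30 bp upstream of the 3′ LTR — a
content rule rather than a single conserved string, with the canonical
printed tract's purine-rich core as positive control. ORFs: forward frames,
first ATG per stop, nested starts suppressed. Motif scanning: IUPAC
patterns as regular expressions with overlapping, case-insensitive matches
(forward strand by default). Amino-acid identity: global alignment with
match +1, mismatch 0, gap open −2, extend −0.5, identity over non-gap
columns. The nucleotide identity filter uses match +1, mismatch −1, open
−10, extend −5 — gaps deliberately expensive so unrelated sequence cannot
inflate identity above the removal threshold by gapping mismatches out of
the denominator. Coordinates are 0-based half-open internally; GFF3 export
is 1-based closed.

## Assay arithmetic

Standard curves: OLS of Ct on log₁₀(copies) (R is the Pearson correlation;
1.0 by convention for two points); efficiency = 10^(−1/slope) − 1.
Copy number: copies = 10^((Ct − intercept)/slope)/template-pg, with
replicate Cts averaged before inversion by default (the alternative —
averaging inverted copies — is available and systematically higher, since
inverting a mean Ct yields the geometric mean). The template mass per
reaction is an explicit input. Terminal:internal ratios and P% (bands
present in ≥1 but not all samples over bands present in ≥1, within the
compared sample set) are rounded half-even to two decimals at reporting
only.

## Numerical and degenerate-input conventions

Saturated divergence (pS or pN ≥ 3/4) → undefined, excluded and counted;
zero comparable codons, empty groups, undefined CBI (N_total = N_ran),
non-positive rates, zero internal copies → errors; absent annotation
features (no LTR pair, no PBS/PPT) → reported absent, not errors. All
stochastic steps (simulation, bootstrap) take explicit seeds and are
reproducible byte-for-byte.

## Known limitations

- NG86 with Jukes–Cantor correction underestimates divergence under
  transition/transversion or codon-usage bias; the simulator's JC-like
  process matches the estimator's assumptions, so real-data biases are not
  exercised by the tests.
- NG86 pathway averaging can attribute a fractional nonsynonymous
  difference to a codon hit twice synonymously, so Ka is near—but not
  exactly—zero even under ω = 0 at appreciable divergence.
- NJ is a consistent but not maximum-likelihood estimator; on real,
  rate-heterogeneous data the collapsed element tree may differ from an ML
  tree, and the incongruence report carries no support values.
- The HT test's comparability constant c encodes how much faster the
  element clock may run before comparability is rejected; it is a design
  parameter, not an estimate.
- Dating assumes a strict clock on the synonymous scale and is linear in
  1/r: rate misspecification propagates proportionally into ages.
- Direction of transfer is not formally inferred; the recipient/donor roles
  are supplied by the user (e.g. from clade nesting).
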