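# Methods

This note records the models, conventions and parameter choices behind
`inframe`, in the order the pipeline applies them, together with what the
synthetic data do and do not establish.

## Variant normalization and transcript projection

Indels are held in VCF conventions (1-based position of the first REF base,
anchor-base style) and left-aligned by suffix/prefix trimming with leftward
extension through repeat tracts; the operation is idempotent and verified
against a brute-force enumeration of all equivalent representations.
Protein-level names instead follow the HGVS 3′-most rule: the shared prefix
of the wild-type and mutant translations is trimmed greedily before the
shared suffix, which pushes the named residues as C-terminal as possible.
Both representations are kept because they necessarily disagree inside
repeats.

A deletion whose CDS projection is non-contiguous (crossing an intron) is a
typed *junction-spanning* result with no protein change — inventing a
consequence for such events would be fabrication.  Deletions touching the
initiator or stop codon are typed *terminal-codon*.  Variants whose net
length change exceeds 21 nt are retained with an out-of-scope flag rather
than dropped, so the size definition stays auditable.  "≤ 21 nucleotides"
is interpreted as the **net** gain or loss, not max(len(REF), len(ALT)):
a balanced substitution does not change length and the size definition
speaks of gain or loss.

Filters run in a fixed order — read support (< 0.1 discards, strictly),
then population allele frequency (> 1 % is benign, strictly), then size —
and the first failing rule is reported.  A missing metric passes its rule:
the source pipeline can only filter where a metric exists.  Sample-level
inclusion requires ≥ 99.5 % of the target at ≥ 50×.  The depth/quality
gates that the upstream caller applies to SNVs specifically (depth ≥ 50×,
MQV ≥ 45) are exposed as optional configuration but off by default for
indels, since nothing documents their use there.

## Sequence context

A homopolymer run (HR) is a maximal run of ≥ 6 identical reference bases
containing the altered bases (an insertion qualifies if it lands strictly
inside a run, or abuts one and inserts only the run base).  A tandem repeat
(TR) is ≥ 2 consecutive reference copies of a unit of 1–21 nt spanning the
altered bases, with the indel unit-compatible: its net change is a multiple
of the unit length, or the changed sequence is itself a whole number of
(possibly rotated) unit copies.  The smallest qualifying unit is canonical
(CAGCAG is 2×CAG, not 1×CAGCAG).  The unit-length bound of 21 and the
±30 nt search flank cover every in-scope indel.  HR and TR are independent
flags plus a combined label (HR ⟹ TR, since a run is a repeat of a 1-mer);
summaries report both tallies because category-style counting is ambiguous
about 1-mer units.

## Template selection

The search emulates a protein-BLAST ranking without depending on one:
Smith–Waterman local alignment (Biopython's `PairwiseAligner`) under
BLOSUM62 with BLAST-style affine gaps (a length-k gap costs 11 + k), bit
score b = (λS − ln K)/ln 2 with the gapped Karlin–Altschul constants
λ = 0.267, K = 0.041, and E = m·n·2⁻ᵇ over the library's total residue
count.  Hits need E ≤ 10⁻³ and, decisively, local reliability at the
variant: strictly more than 5 identities out of the 11 alignment columns
made of the variant residues plus 5 flanking columns each side.  Gap
columns count as mismatches and X never counts as identity.  At sequence
termini the window truncates and the threshold scales proportionally
(count > 5·window/11, still strict), flagged as truncated in reports.  For
multi-residue indels the window spans the whole affected residue range.

Among surviving candidates the winner has the highest window-identity
fraction, then the highest global identity, then the lowest E-value, then
the lexicographically smallest template id — a documented cascade standing
in for "matched most closely", which no source specifies exactly.  Rather
than building homology models, the affected residues are mapped through the
alignment onto the template structure itself (the ATOM-derived sequence
must agree with the aligned template sequence, first mismatch fatal); every
structural judgement the verdict rules need is a property of the template's
local geometry, which a model built on that template would inherit.

## Structural annotation

Secondary structure follows the Kabsch–Sander electrostatic model: amide H
imputed 1.0 Å from N along the preceding residue's C→O direction (none for
proline or chain starts), hydrogen-bond energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with a bond at
E < −0.5, helix (H) from two consecutive i→i+4 turns, strand (E) from
parallel/antiparallel bridge patterns (|i−j| ≥ 3 within a chain, any pair
across chains), coil (C) otherwise.  Residues missing backbone atoms are
coil with a warning flag.  A strand is a maximal run of E residues in one
chain; it is *central* when its residues bridge to two or more distinct
partner strands, *edge* with exactly one.  On generated ideal fixtures the
assignment agrees with an independent DSSP implementation (mdtraj) for
≥ 95 % of interior residues; the chain termini are where DSSP
implementations legitimately differ.

Accessibility is Shrake–Rupley with a deterministic golden-spiral
quadrature (960 points, probe 1.4 Å; radii C 1.7, N 1.55, O 1.52, S 1.8,
P 1.8, default 1.7 Å).  An isolated atom's area is quadrature-exact,
4π(r+1.4)².  Residue RSA divides by the theoretical maxima of Tien et al.,
clipped to [0, 1]; *surface* means RSA ≥ 0.25.  Inter-chain contact is any
heavy-atom pair ≤ 4.5 Å; a salt bridge is a charged side-chain atom
(Arg NE/NH1/NH2, Lys NZ, His ND1/NE2, Asp OD1/OD2, Glu OE1/OE2) ≤ 4.0 Å
from an opposite charge, with DNA/RNA phosphate OP1/OP2 counted negative.

## Verdict rules

The disruption verdict applies the first matching rule over the affected
residues:

1. any residue in a β-strand → **probably**, sheet disruption (edge/central
   in evidence);
2. any helix residue whose helix touches another chain, with a disruptive
   register shift — (n·100°) mod 360, disruptive at ≥ 60° — → **probably**,
   register shift;
3. any residue with an inter-chain contact or salt bridge → **probably**,
   binding-site disruption;
4. all residues coil, surface, contact-free and ≥ 3 residues from the
   nearest helix/strand → **unlikely**;
5. otherwise → **unclear**, packing loss.

Unmapped variant residues give a typed *unassessable* result, not a
verdict.  The thresholds (−0.5 kcal/mol, 4.0 Å, 4.5 Å, RSA 0.25, 3
residues, 60°) quantify reasoning that is qualitative at source; each is a
named constant, chosen once so that the canonical contexts (edge strand,
central strand, interface helix, DNA salt bridge, near loop, remote loop)
land in their expected categories, and exercised by the fixture suite.
"Unclear" is produced structurally by rule 5 rather than by abstention:
a loop residue hugging secondary structure, or a buried loop residue, is
exactly the case where a structural call would be speculative.

## Evaluation conventions

The clinical report is the reference standard: "probably" is positive,
"unlikely" negative, "possibly" excluded.  Tools map D→positive,
N→negative.  The structural verdict maps probably→positive,
unlikely→negative, unassessable→excluded (for that predictor only), and
**unclear→positive** by default — an inconclusive structural call is scored
on the damaging side, the same conservative reading a lab would apply to an
inconclusive tool call.  The mapping is a parameter
(`unclear_as="positive"|"negative"|"excluded"`), and the packaged fixture's
metrics under each convention are covered by tests.  Specificity with no
clinical negatives is reported as NA, never 0/0.  Metrics are rounded to 2
decimals and rates to 1 decimal at a single choke point.

## Synthetic data

The cohort generator emulates the *output* of a panel indel-calling
pipeline at the study's scale: defaults of 667 probands, 55 indel sites and
a 63.6 % tandem-repeat fraction; an in-frame fraction of 0.5 and a
homopolymer fraction of 0.2 are generator choices (typical of exonic indel
calls, which no source quantifies) — fixed once, not tuned.  Contexts are
planted by overwriting reference bases and *verified by re-detection* with
the package's own detectors before a variant is emitted, so the truth table
is consistent with the library's definitions by construction; what the
recovery tests then establish is the stability of that agreement, not the
realism of the sequence.  Planting slots are spaced ≥ 100 nt so no
variant's ±30 nt context window can reach a neighbour's planted array.
Support fractions are Beta(20, 20) clipped above 0.1 with an 8 % low-support
tail, and allele frequencies are mostly rare with a 5 % benign (> 1 %)
tail.  One generator stream from a single mandatory seed drives everything;
identical seeds give byte-identical files.

The geometry builder grows backbones from internal coordinates (N–CA 1.46,
CA–C 1.52, C–N 1.33 Å; φ/ψ −57°/−47° helical, −139°/135° strand) and
places strand pairs by a deterministic search maximizing Kabsch–Sander
inter-strand bonding; ideal helices have i→i+4 O···N distances of 3.08 Å.
The β-hairpin (type II′ turn) exists so that loop fixtures are genuinely
intra-chain: a loop one residue from a separate-chain strand can never be
contact-free, because hydrogen-bonded strands sit ~2.8 Å apart.  The
protein–DNA fixture plants exactly one Arg–phosphate pair at 3.2 Å.

What the synthetic data do **not** emulate: read-level errors, alignment
artefacts, imperfect/degenerate repeats, real protein sequence
composition, side-chain packing beyond Cβ (plus full Arg/Leu side chains
where the fixtures need them).  Passing tests therefore demonstrate
correctness of the implemented definitions and rules, not calling accuracy
on real sequencing data.

## Numerical and degenerate-input choices

Coordinates are 1-based inclusive throughout; VCF positions follow VCF
convention.  PDB parsing (gemmi) resolves altLoc to the highest-occupancy
conformer (ties toward 'A'), drops waters and hydrogens, and fails loudly
on empty input or malformed coordinate fields (with line numbers).  The
SASA quadrature and all searches are deterministic; pipeline reruns with
identical inputs and seed are byte-identical, timestamps confined to the
log.  Empty VCFs exit cleanly with empty outputs.  Selection among tied
template hits and tied runs/units is made deterministic by explicit
tie-breaks (documented above).

## Known limitations

The verdict rules are first-match-wins and qualitative by design; they do
not estimate ΔΔG, repack side chains, or model dynamics.  Homology-model
construction is deliberately replaced by template-side analysis, so
verdicts inherit template geometry even where a real model would relax.
The separation between "unlikely" (remote surface loop) and "unclear"
(packing loss) rests on the RSA/contact/3-residue thresholds — one
defensible quantification of a distinction the motivating analyses drew by
expert judgement.  The structural-modeling accuracy and specificity
originally reported alongside the eight-variant fixture are not exactly
recoverable from the fixture rows under any single standard convention; the
package computes and reports the standard confusion-matrix definitions
under its documented mapping instead of imitating those summary values.
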