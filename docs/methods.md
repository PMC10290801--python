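# Methods

## Retro-biosynthetic model

A polyketide chain is represented as an annotated ketide-unit sequence,
not as a molecular graph: unit 1 is the acetate starter, each further
unit records whether its α-carbon carries a methyl branch and which
oxidation state its β-carbon reaches during that extension cycle
(ketone, hydroxyl, enoyl or fully reduced).  This is the level at which
iterative PKS programming is usually argued, and it fixes everything the
genome scan needs: a chain of *n* units implies *n − 1* malonyl-CoA
condensations, and the required domain set is {KS, AT, ACP} plus the
union over extension modules of the β-processing demands (hydroxyl → KR;
enoyl → KR, DH; reduced → KR, DH, ER; α-methyl → MT).  SMILES/InChI
parsing and stereochemistry are out of scope.

Whole compounds add three post-assembly demand rules: an ester link
between chains demands an O-acyltransferase; a chain released by
hydrolysis or pyrone cyclization (no intrinsic release domain in the
iterative PKS) demands a standalone *trans*-thioesterase; each post-PKS
hydroxylation demands one cytochrome P450.  Demands are carried as
enzyme-class counts, not gene assignments — which of several cluster
P450s performs which hydroxylation is not decidable from structure
alone.  A compound spec is rejected unless its carbon bookkeeping
closes: Σ over chains of (2 × units + methyls) must equal the formula's
carbon count.

### The shipped rasfonin description

Rasfonin (C₂₅H₃₈O₆) is encoded as a 6,8,10-trimethylated hexaketide
(12 backbone carbons, methyls on extension units 3–5) ester-linked to a
4′,6′-dimethylated tetraketide (8 backbone carbons, methyls on units 2
and 3), 2 × (6 + 4) + 5 = 25 carbons.  The unit counts, methyl counts
and the ester/hydroxylation/release demands are structurally forced;
the exact β-state per position is only partially constrained by the
final structure, because post-PKS tailoring overwrites some of it.  The
shipped states — hexaketide: enoyl, hydroxyl, reduced, enoyl, reduced
(units 2–6); tetraketide: reduced, enoyl, reduced — follow the
partially reduced chains with the C2=C3/C2′=C3′ enoyls conjugated to
the carbonyls and a β-hydroxyl at the future pyrone ring oxygen.  Any
assignment containing at least one each of hydroxyl/enoyl/reduced plus
a methylated unit yields the same required domain set
{KS, AT, DH, MT, ER, KR, ACP}, so the downstream pipeline is
insensitive to this choice.

## Mass bookkeeping

Monoisotopic masses use an embedded lightest-isotope table (NIST
values; ¹²C = 12 exactly, ¹H = 1.00782503207, ¹⁶O = 15.99491461956 …).
For ions the electron mass (5.48579909 × 10⁻⁴ Da) times the charge is
subtracted, so calculated m/z values match HR-MS software conventions;
with this correction the protonated-rasfonin value reproduces 435.2741
to four decimals (without it the value is 435.27466, off at the fourth
decimal).

## Genome model and matching

Genes are consumed as annotated tables (flat TSV or GFF3 with a
`domains` attribute); domain calling itself is upstream work
(CDD/InterPro-class annotators) and deliberately not reimplemented.
Coordinates are 1-based inclusive; strand is recorded but never used in
the mining logic.  Domain codes form a closed vocabulary; unknown
annotation strings map to `UNK` with a warning rather than an error, so
heterogeneous sources do not abort a scan.  Architecture matching is
set containment — the argument is from domain *presence*, and iterative
PKSs vary in domain order — which makes candidate selection monotone:
shrinking the required set can only add candidates.  Backbone
classification is a small rule table (KS∧AT → PKS, graded HR/PR/NR by
its reductive loop; C∧A∧PCP → NRPS; both → hybrid; A alone →
NRPS-like; chalcone-synthase halves → type III PKS; TPS → terpene
synthase); it approximates dedicated region callers and is validated
only on the shipped fixture.

## Clustering and candidate selection

Clusters are either passed through from a provided assignment column
(mirroring antiSMASH regions, as consumed in the original analysis) or
formed as maximal runs with intergenic distance ≤ 10 kb ("close
proximity" made explicit and tunable).  A candidate needs ≥ 2
architecture-matching PKS genes in one cluster, plus a gene with a
transferase domain code (OAT/cAT) when the compound's retro report
demands an O-acyltransferase.  The expression verdict of a candidate is
decided by its matching PKS pair (the anchor enzymes): `producing_pattern`
if all are expressed under the producing condition, `silent` if none is
expressed at either time point, `other` in between.  Border calling then
consults all genes.  Ranking is producing-first with scaffold/coordinate
tie-breaks for determinism.

## Expression machinery

RPKM = count × 10⁹ / (length_bp × library reads), with library size
defaulting to the column sum but overridable (needed whenever the gene
table covers only part of the sequenced library, as in the simulator).
Replicates are averaged per condition *before* thresholding, giving one
value per time point.  The expression call is log₂RPKM ≥ 1, i.e.
RPKM ≥ 2; the boundary is inclusive, and reported log-expression below
the threshold is floored to 0.  Categories: Cat1 silent at both time
points, Cat2 expressed at exactly one, Cat3 at both; the three always
partition the gene set.

TMM normalization follows the trimmed-mean-of-M-values definition
exactly as edgeR implements it: reference sample by 75th-percentile
count fraction closest to the mean, per-pair M/A statistics over genes
positive in both samples, a 30% two-sided rank trim on M and 5% on A,
an inverse-(delta-method-)variance weighted mean of the surviving M,
and a final rescaling of all factors to geometric mean 1.  The
implementation is validated against edgeR's `calcNormFactors` on a
frozen fixture matrix (agreement to 10⁻⁸).

The differential test is Welch's unequal-variance t-test on
TMM-normalized log₂-CPM with a 0.5-read pseudo-count, applied per gene
between the two conditions; significance is p < 0.05 (no
multiple-testing correction, matching the analysis this reproduces) and
"strong" regulation is |log₂FC| ≥ 1.  This is a deliberate, documented
substitute for a limma-voom fit: the empirical-Bayes moderation and
voom precision weights are out of scope, so genome-wide DE gene counts
are not expected to reproduce; instead the test's behaviour is
validated by properties — type-I error within [0.03, 0.07] on null
negative-binomial data (2 000 genes, 3 vs 3; Welch on log counts at
n = 3 runs mildly conservative, ≈ 0.031–0.036 in practice) and ≥ 90%
power for a planted four-fold change at low dispersion.  Degenerate
cases: fewer than two replicates in a group yields an undefined p and
no significance; exact replicate equality in both groups yields p = 1;
zero variance with unequal means yields p = 0.

## Border calling

"Coregulation" is operationalized as the binary producing pattern —
silent at 24 h and expressed at 48 h — rather than a correlation
coefficient; the biological signature is categorical (off during active
growth, on in stationary phase).  The call starts from the inclusive
anchor-to-anchor interval, errors out with the offending gene if an
interior gene violates the pattern, then extends outward one gene at a
time per side until the first violation or the scaffold end (gap
tolerance 0: border genes flip the pattern immediately).  A
whole-scaffold span is allowed but logged as unresolved.  Optionally the
pattern can additionally require the differential test's significance
flag; the categorical pattern alone reproduces the nine-gene reference
span on the fixture, so the flag is off by default.  Strand is ignored;
gene order is coordinate order.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not sequence realism.  Defaults (all config-exposed):

| parameter | default | rationale |
|---|---|---|
| genes / scaffolds | 300 / 3 | desk-scale stand-in for a gene-sparse genome slice |
| planted cluster | 9 genes, rsf-role order | HR-PKS, P450, O-acyltransferase, MFS, trans-TE, P450, unknown, P450, HR-PKS |
| decoys | 1 silent two-PKS, 2 single-PKS, 1 NRPS cluster | the confounders the filters must reject |
| counts | negative binomial, dispersion 0.1 | the mean–variance structure RNA-seq DE machinery assumes; Poisson in the φ → 0 limit |
| planted expression | RPKM 0.5 at 24 h, 16 at 48 h | clearly below / above the RPKM ≥ 2 call |
| background | 30% silent at RPKM 0.3; 70% expressed, log-normal median 16, σ = 1 | transcriptomes are bimodal: most genes either robustly expressed or effectively off; keeps little probability mass at the call boundary |
| replicates | 3 per condition | typical RNA-seq design |
| library depth | 5 × 10⁶ reads, 10% log-normal CV per sample | reported as the library size, since the emitted gene table covers only a slice of the transcriptome |
| gene lengths | log-normal, median 1.5 kb (7.5 kb for backbone genes), σ = 0.4 | plausible fungal gene geometry |
| intergenic gaps | 0.5–5 kb within a planted/decoy block, 12–30 kb otherwise | keeps blocks intact and separable under the 10 kb grouping distance |
| scaffold GC | 0.55 | fungal-like base composition for the emitted FASTA |

All randomness flows through one seeded PCG64 generator; a fixed seed
reproduces every emitted file byte for byte.  What the generator does
*not* emulate: overlapping/nested clusters, gene-dense layouts where
distance grouping is ambiguous, condition-dependent background genes,
batch effects, length biases in counting, or meaningful coding
sequence.  Passing tests therefore demonstrate that the inference chain
is correct under its own assumptions, not that those assumptions hold
for any particular real genome.

A separate deterministic fixture encodes the published reference facts
(cluster and gene totals, the 14 PKS architectures with exactly seven
full-inventory HR-PKSs, the two candidate clusters with transferases,
and the expression states of the rasfonin locus and its flanks).  The
seven non-matching PKS architectures are constructed by deleting at
least one required domain each (or adding NRPS cores for the hybrids);
only the counts and the candidate/border outcomes are asserted, not the
exact per-protein domain strings.  The published backbone inventory
(28 proteins by type) and the published expression-category tally
(29 backbone genes) disagree by one; the fixture encodes the inventory.

## Problem sizes and numerical choices

Property checks run at deliberately modest sizes chosen as the smallest
that make the statistics stable: type-I calibration on 2 000 null genes
at one fixed seed, planted-cluster recovery over 20 seeds of the
default 300-gene genome, the N50 oracle over all integer partitions up
to 15, and power/moment checks on a few hundred to ten thousand draws.
Ties in TMM trimming follow average ranks (matching edgeR); candidate
and report ordering is fully deterministic; report timestamps are
omitted so identical inputs yield identical bytes.

## Known limitations

* Domain annotation quality is inherited from the input table; the
  scanner has no opinion on HMM thresholds.
* The transferase rule is annotation-based (OAT/cAT codes); a cluster
  whose transferase was annotated differently would need the
  requirement lifted (`require_transferase=False`).
* The categorical producing pattern assumes a clean off→on switch; a
  cluster with leaky 24 h expression would need the threshold or
  pattern relaxed.
* The Welch substitute is conservative at n = 3 and uncorrected for
  multiple testing, as in the analysis it mirrors; its per-gene calls
  should not be over-interpreted.
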