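# pksmine

Transcriptome-guided genome mining for iterative type I polyketide
synthase (PKS) biosynthetic gene clusters (BGCs), modelled on the
inference chain that identifies the cluster behind a known compound in a
newly sequenced fungal genome.

## The problem

Given (i) the structure of an acetate-derived polyketide — here
rasfonin, an α-pyrone natural product of *Cephalotrichum gorgonifer*
composed of two ester-linked chains — (ii) an annotated genome and
(iii) a two-condition RNA-seq count matrix (active growth vs the
producing stationary phase), find the gene cluster that makes the
compound. `pksmine` walks that chain:

1. **Retro-biosynthesis** (`pksmine.chem`): a polyketide chain is an
   ordered series of ketide units with α-methyl flags and β-carbon
   oxidation states.  A chain of *n* units needs *n − 1* malonyl-CoA
   extensions and a PKS carrying {KS, AT, ACP} plus the union of the
   per-module β-processing demands: hydroxyl → KR, enoyl → KR + DH,
   fully reduced → KR + DH + ER, α-methyl → MT.  Ester-linked chains add
   an O-acyltransferase demand; chains released without an intrinsic
   release domain add a standalone *trans*-thioesterase; each post-PKS
   hydroxylation adds a cytochrome P450.  For rasfonin: a hexaketide
   (6 units, 5 extensions, 3 methyls) and a tetraketide (4 units, 2
   methyls), both requiring the full highly-reducing (HR) domain set
   {KS, AT, DH, MT, ER, KR, ACP}, with carbon bookkeeping
   2 × (6 + 4) + 5 = 25 closing against the molecular formula C₂₅H₃₈O₆.
2. **Architecture scan** (`pksmine.genome`): genes carry ordered domain
   codes; a gene matches when the required set is contained in its
   architecture (order-free — iterative PKSs vary in domain
   arrangement).
3. **Co-localization** (`pksmine.clusters`): clusters come from a
   supplied assignment (e.g. antiSMASH regions) or from an intergenic
   distance rule (default ≤ 10 kb); candidates must hold ≥ 2 matching
   HR-PKSs plus a transferase when the compound is an ester of two
   chains.
4. **Expression filter** (`pksmine.expression`): RPKM =
   count × 10⁹ / (length × library reads), replicate-averaged per
   condition; a gene is *expressed* iff log₂RPKM ≥ 1 (RPKM ≥ 2), with
   sub-threshold values reported as 0.  Genes are categorized Cat1
   (silent at both time points) / Cat2 (expressed at one) / Cat3 (both).
   Between-sample normalization uses TMM (trimmed mean of M-values,
   matching edgeR's definition); differential calls use Welch's t-test
   on TMM-normalized log₂-CPM with p < 0.05 and a two-fold (|log₂FC| ≥
   1) "strong" flag.  Candidates whose PKS pair is expressed under the
   producing condition outrank silent ones.
5. **Border calling** (`pksmine.borders`): starting from the anchor PKS
   pair, the cluster extends gene by gene while each neighbour shows the
   *producing pattern* (silent at 24 h, expressed at 48 h); the first
   violation on each side sets the border.

A synthetic-data generator (`pksmine.simulate`) plants a nine-gene
rasfonin-like cluster and configurable decoys into a random genome with
negative-binomial counts, and ships a deterministic fixture encoding the
published reference facts (308 genes in 24 clusters, 7 of 14 matching
PKSs, two candidate clusters, the nine-gene DNG_02774–DNG_02782 locus).

## Worked example

```sh
$ pksmine mass --formula C25H39O6 --charge 1
435.274115
```

The monoisotopic m/z of protonated rasfonin (C₂₅H₃₉O₆⁺, electron-mass
corrected), matching the calculated [M+H]⁺ of 435.2741 Da.

```sh
$ pksmine retro
compound: rasfonin
  chain hexaketide: 6 units, 5 malonyl extensions, 3 alpha-methyls, domains ACP,AT,DH,ER,KR,KS,MT
  chain tetraketide: 4 units, 3 malonyl extensions, 2 alpha-methyls, domains ACP,AT,DH,ER,KR,KS,MT
  post-PKS: O-acyltransferase x1
  post-PKS: cytochrome_p450 x2
  post-PKS: trans_thioesterase x1
```

Both chains demand a full highly-reducing PKS; the ester link, the two
post-PKS hydroxylations and the domain-less release imply a transferase,
two P450 steps and a standalone thioesterase in the same cluster.

```sh
$ pksmine sim --seed 1 --out simdir
$ pksmine predict --genes simdir/genes.tsv --counts simdir/counts.tsv \
    --samples simdir/samples.tsv
...
## Candidates
 cluster_id scaffold            span        matching_pks  has_transferase           verdict  rank
cluster_075    scf_1 1726744-1770527 SIM_00085,SIM_00093             True producing_pattern     1
cluster_011    scf_1   221204-277083 SIM_00011,SIM_00019             True            silent     2

## Border call
scf_1: SIM_00085..SIM_00093 (9 genes), anchors SIM_00085/SIM_00093, pattern producing_pattern
```

Two clusters carry a matching HR-PKS pair plus transferase; only the
planted one follows the producing pattern, and the coregulation walk
recovers exactly its nine genes (SIM_00085–SIM_00093 is the planted
cluster for seed 1).  The report continues with per-gene role
annotations (rsf1–rsf9) and the proposed pathway steps.

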