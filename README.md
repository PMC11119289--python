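# pulfinder

Rule-based prediction of **polysaccharide utilization loci (PULs)** from
annotated bacterial genomes, with substrate mapping for four marine algal
polysaccharides (sodium alginate, fucoidan, laminarin, red-algal
porphyran-type galactan), functional-category tabulation, and the
calibration arithmetic used in polysaccharide-fermentation experiments.

It is aimed at microbiologists studying glycan degradation by gut
*Bacteroides* (and relatives) who have an annotated genome — gene models
plus per-gene Pfam/CAZyme assignments — and want reproducible,
configurable locus calls rather than a web service.

## The locus model

*Bacteroidetes* organize glycan catabolism into PULs: co-located gene
clusters encoding sensing, binding, transport and hydrolysis functions.
The diagnostic signature is a **tandem SusC/SusD-like pair** — a
TonB-dependent transporter gene (SusC-like, detected here as
PF00593 + PF07715 on one gene) immediately upstream of a glycan-binding
lipoprotein gene (SusD-like, PF07980 and homologous domains) on the same
strand, where *upstream/downstream* is read along the transcription
direction. The caller:

1. assigns each gene a role (SusC, SusD, CAZyme + families, regulator
   HTCS/ECF-σ/anti-σ, sulfatase, unknown) from its domain hits, with a
   fixed priority on conflicts (SusC > SusD > CAZyme > sulfatase >
   regulator);
2. finds maximal tandem pair blocks, absorbing duplicated SusC or SusD
   genes (`susC-susC-susD-susD` is one block);
3. extends each block outward over CAZyme/sulfatase/regulator/SusC/SusD
   neighbours, tolerating ≤ 2 consecutive unannotated genes and
   intergenic gaps ≤ 5 kb (both configurable);
4. merges overlapping extensions and numbers the loci PUL1, PUL2, … by
   coordinate.

Each locus is then scored against substrate signatures built from CAZyme
families: alginate {PL6, PL7, PL8}, fucoidan {GH29, GH95, GH141} (+
sulfatase as accessory evidence), laminarin {GH3, GH16, GH51}, porphyran
{GH16, GH86} (+ GH2). Score = 1.0 per distinct core family matched + 0.5
per accessory; ties rank alphabetically.

A synthetic-genome generator plants loci with this exact grammar (plus
lone-SusC/lone-SusD/wrong-order/strand-split decoys) and emits a truth
table, so the whole pipeline is testable without any downloads; a
companion generator produces logistic OD600 growth curves and decaying
total-sugar / molecular-weight fermentation series.

## Worked example

```
$ pulfinder simulate --seed 3 --out sim --n-puls 8 --decoy-rate 0.005
wrote 4 files to sim
$ pulfinder predict sim/genome.gff3 sim/domains.tsv --out pred
called 8 PULs -> pred/puls.tsv
$ pulfinder substrates pred/puls.tsv --out sub
scored 8 PULs -> sub/substrates.tsv
```

`pred/puls.tsv` (columns abridged):

```
pul_id  contig  start  end    n_genes  strand  cazyme_families          regulators  substrate_calls
PUL1    ctg01   9412   21874  8        +       GH141;GH141;GH29;GH29;GH29  ECF_SIGMA  fucoidan:2.0
PUL2    ctg01   39737  54459  11       -       PL6;PL6;PL7;PL7;PL7;PL7;PL8 ECF_SIGMA  alginate:3.0
```

PUL1 spans 8 genes around one SusC/SusD pair with five fucosidase-family
genes (GH29, GH141): two distinct core families of the fucoidan
signature, hence score 2.0. PUL2 carries three distinct alginate-lyase
families (PL6, PL7, PL8 — score 3.0) and an ECF-σ regulator. A locus
containing only GH16 is reported for both laminarin and porphyran at
score 1.0 (the family genuinely acts on both β-glucans and porphyran):

```
$ head -5 sub/substrates.tsv
pul_id  substrate  score  evidence
PUL1    fucoidan   2.0    GH141(core);GH29(core)
PUL2    alginate   3.0    PL6(core);PL7(core);PL8(core)
PUL3    laminarin  1.0    GH16(core)
PUL3    porphyran  1.0    GH16(core)
```

Fermentation summaries (`pulfinder ferment sim/fermentation.csv --out ferm`)
report, per substrate, the growth phases of the mean OD600 curve
(lag end, maximum, stationary onset) and degradation metrics of the
total-sugar and molecular-weight series — e.g. for the simulated
red-algal galactan a 59.2 % Mw drop over 72 h.

All thresholds (role signatures, gap rule, substrate signatures, growth
deltas) live in a single `key = value` config file; see
`src/pulfinder/data/default.cfg` for every key and its default. The
library API (`pulfinder.predict_puls`, `pulfinder.map_substrates`, …)
exposes the same machinery for scripted use.

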