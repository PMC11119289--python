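# Methods

## Locus model and calling procedure

A PUL is modelled as a contiguous run of genes on one contig anchored by
at least one tandem SusC/SusD pair block. The three rules, in order:

**Pair detection.** A block is a maximal run of ≥ 1 SusC-like genes
followed immediately — zero intervening genes by default — by ≥ 1
SusD-like genes, all on one strand of one contig, read in transcription
order. On the minus strand "upstream" therefore means higher plus-strand
coordinates, so a minus-strand block appears as SusD…SusC in file order.
Consecutive duplicates of either partner are absorbed into the same block.
Two config keys alter this: `gap.pair_max_gap_genes` (default 0) allows a
bounded number of non-SusC/SusD genes between the runs, and
`gap.pair_orientation = plus_coordinate` switches to reading upstream/
downstream in plus-strand coordinate order regardless of strand. The
transcription-order reading is the default because the pair is an operon
and operon order is a transcriptional notion; the switch preserves the
alternative reading since the source description does not disambiguate.

**Extension.** From each block the caller walks outward gene by gene,
absorbing genes whose role is CAZyme, sulfatase, regulator, SusC or SusD.
A direction stops when more than `gap.max_gap_genes` (default 2)
consecutive unknown-role genes are met, or when a single intergenic
distance exceeds `gap.max_gap_bp` (default 5000 bp). Unknown genes lying
between absorbed members are retained as locus members. Contig edges are
hard boundaries. The defaults follow common PUL-calling practice; both
are config keys, and no claim is made that they reproduce any particular
published locus count (that would require the original genome and
databases).

**Merging and numbering.** Extended windows that share genes merge into
one locus (member union, pair blocks concatenated). Output is sorted by
(contig, start) and numbered `PUL1…` per run, so identifiers are
coordinates-stable but not comparable across genomes. A locus whose
members include no CAZyme is reported with a `cazyme_free` flag rather
than suppressed, since whether such pairs count as PULs is genuinely
unsettled.

### Role map

Roles come from per-gene domain accessions. Defaults (all overridable in
the config):

| role | rule | accessions |
|---|---|---|
| SusC-like | all required | PF00593, PF07715 |
| SusD-like | any | PF07980, PF12741, PF12771, PF14322 |
| CAZyme | label pattern | `(GH|GT|PL|CE|AA|CBM)N[_M]` |
| sulfatase | any | PF00884, `SULFATASE` |
| HTCS regulator | all required | PF00512, PF00072, PF12833 |
| ECF-σ regulator | all required | PF04542, PF04545 |
| anti-σ regulator | any | PF04773 |

A gene matching several roles keeps the highest-priority one
(SusC > SusD > CAZyme > sulfatase > regulator) with a logged warning;
transporter signatures win because they anchor the locus. The HTCS rule —
sensor-kinase + response-regulator + AraC-output domains fused on one
gene — encodes the defining hybrid architecture; the exact accession
choices are package defaults, not sourced constants.

## Substrate scoring

Each substrate signature has disjoint core and accessory family sets.
Score = 1.0 × |distinct core families present| + 0.5 × |distinct
accessory present|. Multiplicity is deliberately ignored: tandem
paralogs are common and would otherwise dominate ranking. Ties break
alphabetically so output is deterministic. `SULFATASE` in an accessory
set matches the presence of any sulfatase-role member (the locus table
carries an `n_sulfatases` column so re-scoring from a written table loses
nothing). The weighting scheme itself (1.0/0.5) is a package convention
chosen for monotonicity and simplicity — the source material lists
implicated families but no scoring rule. The porphyran signature's GH86
and GH2 entries extend the documented GH16 evidence via the β-porphyranase
and β-galactosidase activities involved; they live only in the default
config and can be deleted there.

## Tabulation arithmetic

Category tables count distinct (gene, category) pairs; a gene may carry
many categories and contributes once to each. Shares are
100 × count/total rounded **half-up to two decimals**, matching printed
precision; `decimal.Decimal` is used so 49.715 → 49.72 regardless of
binary float representation. For GO namespaces the denominator is the sum
of the three namespace counts — the only denominator that reproduces the
published triple exactly. Other published percentages (e.g. subcategory
shares inside KEGG level-1 groups) use denominators that cannot be
reconstructed from the printed numbers and are not reproduced.

CAZyme class profiles take the class from the family label prefix
(GH/GT/PL/CE/AA/CBM), splitting compound labels on `|` and `+`; a gene
with families in k classes counts once per class. Unrecognized prefixes
go to a logged `other` bucket excluded from proportions.

## Calibrations and time-series summaries

`fit_line` is ordinary least squares (scipy.stats.linregress) with
r² = 1 − SSres/SStot, defined as 1 when both sums vanish. Zero-slope
curves are rejected for calibration use. Inverse prediction of sugar
concentration is `dilution × (A − b)/m`, clipped to 0 (flagged) when
negative, because concentrations are physical; a negative smaller than
1e-12 is treated as the exact zero crossing rather than flagged, to keep
the flag meaningful under floating point.

The SEC calibration fits log10(Mw) on retention time — affine, not
proportional, since a zero-intercept line cannot pass through a realistic
dextran ladder (4.66–496 kDa). Predictions outside the fitted
retention-time domain ± `sec.extrapolation_margin` (default 10 % of the
domain width) raise an error naming the domain.

Growth summaries: `lag_end` is the last sampled time before OD first
exceeds OD(0) + `growth.baseline_delta` (default 0.05 OD);
`stationary_start` is the earliest time after which every successive
increase is < `growth.plateau_eps` (default 0.02 OD). Both thresholds are
conventions — source descriptions of the phases are qualitative — and are
config keys. Flat series flag `no_growth`; monotone rising series flag
`no_plateau` with `stationary_start` at the last time. Triplicates are
averaged (mean) before phase detection. Degradation metrics: percent drop
= 100(v₀ − v_last)/v₀; the steepest-decline interval maximizes the
pairwise slope (vᵢ − vᵢ₊₁)/(tᵢ₊₁ − tᵢ) with ties to the earliest
interval.

## Synthetic data

The genome generator plants each locus with the grammar
`[regulator] CAZyme* SusC{1,2} SusD{1,2} CAZyme* [sulfatase]` on a random
strand, CAZyme families drawn from the planted substrate's core
signature, flanking-CAZyme counts uniform in `pul_cazyme_range`
(default 1–4), duplication and regulator probabilities 0.3 and 0.7. Gene
lengths are clamped normal (mean 1200 bp, 20 % sd, min 90 bp) and
intergenic gaps clamped normal (mean 150 bp, 50 % sd, clamp [1, 3×mean]),
so within-locus gaps always respect the default gap rule. Elements
(loci and decoys) are separated by three unknown-role filler genes —
one more than `max_gap_genes` — which guarantees planted spans are
exactly recoverable and decoys cannot bleed into loci. Decoy classes
(lone SusC, lone SusD, wrong-order pair, strand-split pair, scattered
CAZyme) are the minimal set exercising every exclusion branch of pair
detection; their rates are fractions of the total gene budget. Domain
hits are emitted from the same accession sets the default role map reads,
which is what makes role re-derivation exact. A single
`numpy.random.default_rng(seed)` stream drives everything; equal seeds
give byte-identical files.

What the generator does **not** emulate — and hence what passing tests do
not show about real genomes: no nucleotide or protein sequences, no
annotation noise (missed or spurious domain hits, truncated genes), no
overlapping genes or nested operons, no compositional bias, and planted
loci never sit closer together than the separator rule allows. Recovery
precision/recall of 1.0 is therefore a statement about the caller's rule
fidelity, not about accuracy on noisy annotations.

The fermentation generator produces logistic OD600
(K = 0.8 OD, r = 0.3 h⁻¹, t₀ = 12 h), exponential residual sugar
(s₀ = 10 mg/mL ≙ a 1 % substrate medium, k = 0.02 h⁻¹) and exponential
molecular weight. Per-substrate Mw parameters are set so the simulated
72-h endpoint sits at a realistic fraction of the start (laminarin ≈ 77 %,
alginate ≈ 81 %, fucoidan ≈ 90 %, red-algal galactan ≈ 41 %). Noise is
multiplicative Gaussian (default sd 2 %) so one parameter scales across
analytes whose magnitudes differ by five orders; a single exponential is
deliberately simple and does not reproduce the front-loaded decline real
degradation curves show in their first day. Sampling defaults to
{0, 12, 24, 48, 72} h with three replicates.

## Validation problem sizes

The shipped checks use: 20 planted genomes of 12–50 loci (≈ 180–750
genes) for recovery; 1,000 randomized genomes of ≤ 30 genes against an
exhaustive window-enumeration oracle (every contiguous window tested
declaratively against the membership rules — an independent route to the
same definition); mirror-image symmetry on all of the above; 6-point
calibration ladders; and 200-replicate means for the noise
law-of-large-numbers check. The full suite runs in a few seconds on one
CPU.

## Known limitations

- Locus delimitation parameters are conventions; published locus counts
  from real genomes depend on the annotation pipeline and databases used
  and are not reproducible from rules alone.
- Substrate calls are qualitative evidence rankings, not enzymology;
  GH16-containing loci are intrinsically ambiguous between laminarin and
  porphyran without biochemical data.
- The GFF3 reader keeps one record per feature and ignores hierarchy
  (no mRNA→CDS joining); it expects prokaryotic-style flat annotations.
- `gc_skew` uses full windows only and does not wrap circular genomes.
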