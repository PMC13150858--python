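# Methods

`coresnp` re-creates, at desk scale, the analysis chain used to build a
DNA-fingerprinting and core-collection resource for a jujube (*Ziziphus
jujuba*) germplasm panel: SNP retention filtering, per-locus diversity
statistics, weighted core-subset selection, fingerprint-marker screening,
minimal discriminating marker sets, textual fingerprint/QR encodings, and
KASP assay design with a toy fluorescence caller. Every stage operates on
a `GenotypeMatrix` of biallelic SNP dosages (0/1/2, missing as a distinct
state excluded from all frequency denominators).

## Synthetic panels

Real resequencing input (hundreds of accessions at ~17x) is emulated by
`synthetic_data`. Loci are independent (no linkage disequilibrium); for
each locus an ancestral minor-allele frequency is drawn uniformly from
`maf_range` and randomly assigned to the ref or alt allele. Subpopulation
frequencies drift under the Balding–Nichols model,
`Beta(p(1-F)/F, (1-p)(1-F)/F)`, where the divergence parameter `F`
plays the role of FST. Each accession draws admixture fractions from a
symmetric Dirichlet(0.2) — most accessions are near-pure, a minority are
visibly admixed — and genotypes are `Binomial(2, q·P)` draws from its
admixed frequency. Per-cell depth is Poisson; missingness is i.i.d.
per cell.

Defaults are the emulated study conditions: 460 accessions, 3
subpopulations, F = 0.15, mean depth 17.22x, missing rate 0.005.
The missing rate reflects deep (~17x) resequencing after QC: with
i.i.d. masking, 0.5% leaves roughly `0.995^460 ≈ 10%` of loci free of
missing calls in a 460-accession panel, so the "no missing loci"
fingerprint criterion remains exercisable at study scale; rates of a few
percent would leave none, which is an artifact of the i.i.d. mechanism
rather than of real data (where missingness clusters in a few samples
and loci). Chromosome coordinates use twelve 1-Mb chromosomes — flank
extraction, spacing and thinning depend only on relative scale.

Because admixed accessions belong to no single subpopulation,
Weir–Cockerham FST computed over *all* accessions labeled by dominant
ancestry underestimates `F` substantially (~0.16 for F = 0.3 under these
defaults). The FST-recovery check therefore applies the estimator to
near-pure accessions (admixture fraction ≥ 0.95), where it recovers `F`
within ±0.05.

What passing tests do **not** show about real data: no linkage
disequilibrium, no genotyping error model, no depth/genotype-quality
correlation, no sample relatedness beyond admixture.

## Variant QC

A locus is retained iff mean depth > 4, missing fraction < 10% and
MAF > 0.5% — all strict inequalities, applied in that order for the
per-filter attribution (the retained set itself is order-free). "Depth"
is the per-locus mean over cells; a per-sample interpretation would need
per-cell call masking and is out of scope. MAF uses non-missing alleles
only. Region classes (exonic > intronic > other > intergenic priority)
are consumed from BED intervals, not computed from annotation.

## Diversity statistics

For alt-allele frequency `p`, `q = 1-p` on `n` non-missing diploid calls:
Ho = het fraction; He = 1 - p² - q²; Nei's gene diversity
= (2n/(2n-1))·He clipped to ≤ 1; Shannon–Weiner = -(p log₂p + q log₂q)
(base-2 logs, so the biallelic maximum is 1.0 — a natural-log convention
caps at ln 2 ≈ 0.693, below values this index must reach per locus);
PIC = 1 - (p²+q²) - 2p²q².

Hardy–Weinberg departure uses the exact conditional test (enumeration of
heterozygote counts given allele counts, two-sided by summing
configurations no more probable than the observed one). The fingerprint
gate sits at p > 1e-6, where chi-square approximations are unreliable;
the exact test matches an exact-rational enumeration oracle to 1e-9.

Modified Rogers' distance encodes calls as within-accession allele
frequencies (0, 0.5, 1) and is the root-mean-square allele-frequency
difference over pairwise-complete loci, 0 for identical accessions and
1 for opposite homozygotes everywhere.

PCA standardizes genotypes by per-locus centering and division by
sqrt(p(1-p)), mean-imputes missing calls, and drops monomorphic loci.
The marker-subset concordance score pairs full-panel and subset PCs by
maximal absolute Pearson correlation (Hungarian assignment) before
averaging: near-degenerate eigenvalues let structure components rotate
between decompositions, which index-wise pairing would misread as
disagreement.

## Core collection

A subset is scored by `0.7 · mean within-subset pairwise modified
Rogers' distance + 0.3 · mean per-locus Shannon index within the
subset`. The named core-collection engine behind the original protocol
is not called; its stated criteria and weights are re-implemented with a
deterministic search: greedy construction (seeded from the most distant
pair's anchor, iteratively adding the objective-maximizing accession),
steepest-ascent 1-swap local search, then a small number of seeded
perturbation restarts (re-descending from copies of the incumbent with
~20% of members swapped out). The restarts escape the occasional 1-swap
local optimum; on panels small enough to enumerate (N ≤ 12) the search
attains the exhaustive optimum in all tested cases. An `exhaustive`
strategy is available explicitly. Subset size is round-half-even of
`fraction × N` (0.2 × 460 = 92 exactly). The fraction sweep is reported
as a table; choosing the final fraction is a user decision, as no
coverage/diversity trade-off threshold is defined by the protocol.

For large panels the analysis driver searches on a random 800-locus
subset of the filtered panel and evaluates the chosen accessions
(coverage, diversity, genotype-class fit) on all loci; the objective is
a per-locus average, so a random locus subset estimates it unbiasedly.

## Fingerprint marker panel

The screen keeps loci with zero missing calls, MAF ≥ 0.005, gene
diversity > 0.4, exact-test HWE p > 1e-6 and no neighboring variant
within 200 bp either side, ranks survivors by PIC and caps at 500.
The 0.4 polymorphism gate operates on the gene-diversity (Nei) scale,
whose biallelic maximum is 0.5: the strict biallelic PIC formula caps at
0.375, so a literal PIC > 0.4 gate would retain nothing — protocols
printing per-locus "PIC" values above 0.4 are using the gene-diversity
scale (0.4 corresponds to MAF ≈ 0.28).

Thinning to the final panel (default 100) gives each candidate-bearing
chromosome a length-proportional quota (largest-remainder rounding,
minimum 1, capped by supply) and, within a chromosome, selects loci
maximizing the minimum pairwise spacing: binary search on the achievable
spacing with an exact greedy feasibility check on the line, then a
construction preferring higher PIC among spacing-preserving choices.

The minimal discriminating set is greedy set cover over unordered
accession pairs (a pair is separated only by differing *non-missing*
calls); greedy cover is within `ln(pairs)` of optimal in general and
within +1 locus of the brute-force optimum on all tested toy panels.
Indistinguishable pairs are reported, never fatal.

## Fingerprint encodings

Slash strings render one `X/Y` token per locus with heterozygotes as
ref-then-alt; compact strings use one character per locus (base for
homozygotes, IUPAC ambiguity code for heterozygotes). Missing calls are
`-/-` and `N` respectively — printed examples contain no missing calls,
so the convention is fixed here. The QR contract is the payload text
`Name: <name>; fingerprint code: <slash string>`; image rendering is
deliberately out of scope. Uniqueness checking treats `N` as a wildcard:
identical compact strings are confirmed duplicates, strings compatible
only through missing positions are reported as ambiguous matches.

## KASP design

Assays use the two universal fluorescent tails
(FAM `GAAGGTGACCAAGTTCATGCT`, VIC `GAAGGTCGGAGTCAACGGATT`) as published
in validated jujube assay sets. Each allele-specific primer is anchored
with its 3' terminus on the SNP base — the defining KASP constraint —
and grown leftward (18–30 nt core) until the nearest-neighbor Tm enters
55–62 °C with GC < 60%; tail bases are never counted in Tm/GC. The two
cores may differ in 5' length (validated assays show the same), but are
identical 3'-anchored except the terminal base. The common primer sits
on the reverse strand downstream, first compliant placement with product
≤ 120 bp. Tm uses the unified SantaLucia nearest-neighbor parameters at
50 mM Na⁺ and 200 nM oligo (Biopython's `Tm_NN`, DNA_NN3 table); since
the original design software's internals are unknown, no tolerance is
claimed against any printed Tm. Flank specificity is screened by exact
21-mer matching against the reference on both strands — a conservative
stand-in for a BLASTN uniqueness screen. Failures are reported with the
first unsatisfiable constraint (specificity, Tm, GC, product size,
flank); this taxonomy is a superset of the causes reported for real
conversion failures, not a reproduction of them.

The fluorescence caller marks points within 0.15 of the origin as
no-calls, clusters the rest with seeded k-means (k=3) and labels
clusters by centroid position (FAM-dominant → X-hom, VIC-dominant →
Y-hom, balanced → het). At plate noise σ = 0.05 it recovers ≥ 95% of
simulated truth labels.

## Problem sizes and numerical choices

The test suite and drivers run at desk scale by design: panels of tens
to hundreds of accessions and hundreds to thousands of loci, exhaustive
oracles at N ≤ 12 accessions or ≤ 6 loci, the acceptance computation at
460 accessions × 500 loci. Tolerances: HWE vs enumeration 1e-9;
per-formula diversity oracles 1e-12; stochastic recovery bands as stated
above. Degenerate inputs are first-class: all-missing loci raise
`no data` errors (QC rejects them with that reason), monomorphic loci
have zero diversity and are dropped before PCA with a warning, and
fluorescence clouds with fewer than three distinct points fall back to
nearest-ideal-center calls with a warning.

## Known limitations

Independent loci (no LD-aware thinning beyond physical spacing); no
genotyping-error or allele-dropout model; k-mer specificity is stricter
than BLASTN for diverged repeats and blind to near-identical paralogs
below k; the search is heuristic beyond exhaustively checkable sizes;
region annotation is consumed, not derived from gene structure.
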