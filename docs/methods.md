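# Methods

This note records the models, conventions and numerical choices behind each
module, what the synthetic-data generator does and does not emulate, and the
design decisions taken where more than one defensible option existed.

## Protein physicochemistry

Molecular weight is the sum of average (isotope-abundance-weighted) residue
masses plus one water (18.0153 Da), using the Expasy mass table shipped in
`camtakit/data/residue_masses.json`. Average rather than monoisotopic masses
match the convention of the standard web calculator that family surveys
cite. X and other non-canonical letters are rejected rather than assigned a
guessed mass.

The theoretical pI uses the Bjellqvist pKa set
(`camtakit/data/pka_bjellqvist.json`): side chains D/E/C/Y/H/K/R, a free
N-terminus with residue-specific overrides (A, M, S, P, T, V, E) and a free
C-terminus with overrides for D and E. Net charge is a sum of
Henderson–Hasselbalch terms and is strictly decreasing in pH, so the root is
unique; it is bracketed by bisection on [0, 14] to < 5×10⁻⁴ pH units and
reported at 2 decimals. The test suite pins both MW and pI against the
independent Biopython ProtParam implementation (pI to ±0.01; MW per residue,
since mass tables differ in the third decimal).

Protein length from an ORF is `orf/3 − 1`: the stop codon encodes nothing.

## Domain annotation

Profile-HMM hits (CG-1, TIG, ankyrin, IQ) are ingested from hmmscan
`--domtblout` using the alignment-coordinate columns; the package does not
retrain or run HMMs. Consensus matchers cover what motif servers located in
the original survey workflow:

- CaMBD: the 22-position degenerate consensus
  `WSVG[IV]LEK[VA][IV]LRWRRK[GR][SK]GLRG`, scanned at every offset with a
  mismatch budget (default 2, since family members match the consensus
  nearly but not perfectly). Hits carry their mismatch count as the score.
- Functional CaM-binding motif `WXVX(2)LXKX(2)[LF]RWRX[KR]X(3)[FL]RX` as an
  exact regular pattern (overlaps counted via lookahead).
- Bipartite NLS: two adjacent K/R, a 10–12 residue spacer, then ≥ 3 K/R in
  the next 5 positions. This classical rule is a stand-in for server-based
  NLS prediction, and output flags it as a consensus call. One hit per start
  position (shortest qualifying spacer).
- IQ: the conventional `[FILV]Qxxx[RK]Gxxx[RK]xx[FILVWY]` pattern; the
  motif's exact definition varies across databases, and overlapping
  occurrences are all reported so that "1–2 per protein" style statements
  can be made under either counting convention.

The amphipathic-helix analysis places an 18-residue window on a helical
wheel at 100°/residue and computes the Eisenberg-consensus hydrophobic
moment μH (vector magnitude). Because 18 × 100° is exactly five turns, any
homopolymer has μH = 0, which the tests exploit as a null. The hydrophobic
face is the set of positions whose wheel angle lies within ±90° of the
resultant. The Eisenberg scale was chosen because it is the default in
helical-wheel tools; the choice only scales μH and does not move the face.

## Gene structure and promoters

Coordinates are 0-based half-open internally; the GFF3 reader/writer pair is
the only place 1-based inclusive conversion happens. One model per mRNA;
intron *i* is the gap between exons *i* and *i+1*. The TSS is the gene
feature's 5′ end — the only operationalizable definition when the annotation
has no UTRs. Promoters are the 1000 bp (configurable) upstream of the TSS,
reported as forward-coordinate intervals with a reverse-complement flag for
minus-strand genes, clipped at scaffold edges with the achieved length
flagged (clipping, rather than skipping edge genes, keeps every gene in the
table).

## Paralogy, Ka/Ks and dating

Best-hit ranking uses deterministic global alignment scores
(Needleman–Wunsch, BLOSUM62, affine gaps 11/1) instead of BLAST e-values:
e-value statistics depend on database size and are not reproducible at this
scale, while the published thresholds — identity > 70% and coverage > 70% of
the longer sequence (terminal gaps excluded from the aligned span) — are
applied exactly as stated. A pair is reported iff each member is the other's
best score; RBH pairs are disjoint by construction and independent of input
order (ties break lexicographically).

Codon alignments are back-threaded from the protein alignment (each residue
column becomes its codon; gaps become `---`), with the CDS/protein
correspondence verified and the first discordant position named on error.
Columns containing gaps or ambiguity are dropped pairwise.

Ka/Ks follows Nei–Gojobori (1986): per-codon synonymous site fractions
(mutations to stops counted as nonsynonymous), site totals averaged over the
two sequences, differences averaged over all substitution orderings with
stop-passing pathways excluded whenever a stop-free ordering exists, and the
Jukes–Cantor correction d = −¾ ln(1 − 4p/3) applied per class (p ≥ ¾ is a
saturation error). The unit tests check the implementation against an
independent exhaustive-pathway oracle over every sense-codon pair and random
multi-codon instances. Exact agreement with codeml-style ML estimates is not
expected and not claimed; the functional checks are the Ka/Ks < 1 bound and
the recovery of generator-planted divergence (±15% at 1000 codons).

Duplication age is T = Ks/(2λ) with λ = 6.1×10⁻⁹ synonymous substitutions
per site per year (the eudicot rate; configurable). Selection is classified
purifying/neutral/positive by Ka/Ks against 1 with a tolerance of 1e-9.

## Phylogeny

A deliberate descriptive stand-in for ML inference: pairwise p or Poisson
(−ln(1−p)) distances under pairwise gap deletion, Saitou–Nei neighbor
joining with the standard Q criterion (ties to the lowest index pair,
negative branch lengths clamped to zero with a warning), and nonparametric
bootstrap by column resampling, with support = % of replicate trees
containing each internal bipartition. NJ is exact on additive matrices,
which the tests verify together with a topology cross-check against
scikit-bio's implementation. Newick output quotes labels needing it and is
round-tripped through an independent parser in tests. ML machinery (JTT,
model selection) is out of scope: the family trees here are groupings, not
rate estimates.

## Promoter motif scanning and enrichment

IUPAC patterns are expanded positionally; scanning slides over every offset
(overlapping matches counted — the order-free convention), N in the promoter
never matches, and reverse-strand hits come from scanning the reverse
complement and are reported at forward coordinates with strand "−". Counts
therefore satisfy strand symmetry, and the expected count on uniform
background is (L−k+1)·degeneracy/4^k per strand, which the tests verify to
within 3 standard errors.

Enrichment between two gene sets contrasts motif occurrences against total
scanned positions in a 2×2 table with a two-sided Fisher's exact test
(scipy's exact hypergeometric summation; verified against a brute-force
enumeration oracle in tests). The occurrence-level unit was chosen over
genes-with-hit because the scientific statement under test is about
frequency of occurrence; the odds ratio is the sample cross-product ratio
with Haldane's 0.5 correction when a cell is zero. A bundled example motif
library carries common plant cis-element consensi (ABRE, G-box, ERE, GT-1,
CGTCA/TGACG, …) plus the CAMTA recognition cores MCGCGB and MCGTGT; these
patterns are illustrative stand-ins for database lookups, which are out of
scope.

## Co-expression

TMM factors follow the edgeR algorithm: reference sample = the one whose
75th-percentile count fraction is closest to the across-sample mean; M and A
values over genes nonzero in both samples; 30% two-sided trim on M and 5% on
A (rank rule `floor(n·trim)+1 … n−floor(n·trim)`); inverse asymptotic
variance weights; factors rescaled to geometric mean 1. The implementation
agrees with edgeR's `calcNormFactors` to ~1e-6 (cross-checked via Rscript in
the test suite). Normalized expression is counts per million divided by the
factor.

Pearson partner sets are computed on log2(normalized + 1) by default — log
stabilization is the defensible default for count data, and a raw-scale flag
is provided — with thresholds r ≥ 0.95 / r ≤ −0.95 and a minimum sample
count of 4, all configurable. Zero-variance genes are skipped with a
warning; a zero-variance hub is an error. Cumulative expression between two
stages is compared by a two-sided Wilcoxon signed-rank test across the gene
set's paired group means (paired by gene, no normality assumption — the
choice is named in output); sets below 5 genes return no p.

## qPCR

Technical replicates are averaged per biological replicate before
statistics. ΔCt = Ct_target − Ct_reference per biological replicate, ΔΔCt
subtracts the calibrator group's mean ΔCt, and the reported fold is
2^(−mean ΔΔCt) — so the calibrator's fold is exactly 1 — with a delta-method
SE over biological replicates (biological, not technical, replication is the
error unit, and the output labels it so). Significance is a two-sided Welch
t-test on per-replicate ΔCt (the standard for ΔΔCt data), flagged at
p < 0.05 (*) and p < 0.01 (**).

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions: a ten-gene family as
five paralog pairs on eight scaffolds (two scaffolds carry two genes),
12–13 exons per gene, introns of 80–400 bp, 300-codon CDSs (desk-scale;
recovery experiments use 1000 codons), 1 kb promoters, synonymous-divergence
targets spanning Ks 0.1786–0.2190 — i.e. the family's published
14.64–17.95 MYA duplication window at λ = 6.1×10⁻⁹ — with Ka/Ks ≈ 0.3;
expression with 2 hubs, 30 positive and 30 negative partners each among 440
independent genes over 15+15 samples at target r = 0.97; and Ct tables with
3×3 replication at 0.2-cycle noise and folds 1/2/4 across stages.

Paralogs are derived by point substitutions classified against the codon
state at the moment of introduction (each position touched at most once, no
stops created, start/stop codons untouched), so realized synonymous and
nonsynonymous counts — and hence realized Ka/Ks — are well defined. The
required substitution count inverts the Jukes–Cantor map; targets implying a
proportion ≥ 0.70 are rejected as approaching saturation, naming the
limiting site class.

Promoter backgrounds are uniform over A/C/G/T (maximal tractability of
accidental-motif scrubbing), and every base outside a planted interval is
rewritten until no planted motif occurs on either strand, so scanner counts
equal the planting record exactly. Self-complementary planted words
legitimately produce reverse-strand hits; the generator returns the full
expected hit list alongside the planted list so exactness remains testable.

Count matrices are Poisson samples of exponentiated log2 signals times
per-sample library factors. Partner noise is calibrated against the hub's
*realized* signal variance plus the analytic (Jensen-corrected) Poisson
noise on the log2 scale, so the planted correlation is the observed
count-level correlation, not merely the latent one. A separate
composition generator plants a fraction of genes fold-changed in one sample,
for which the expected TMM factor ratio 1/(1 + fraction·(fold−1)) is known
analytically.

Not emulated: read-level sequencing (no alignment or assembly artifacts),
indels in paralogs, GC/nucleosome structure in promoters, overdispersion
beyond Poisson, and batch effects. Passing tests therefore demonstrate the
correctness of the computations and their recovery behavior under the
generative model, not robustness to the full messiness of real RNA-seq or
real draft-genome annotation. The transcriptome-scale partner counts of the
original study (hundreds of interacting genes from public RNA-seq) require
the external read data and are out of scope; the 134/126/361/16-style
numbers are consequently not reproduced here.

## Determinism and problem sizes

Every stochastic routine takes an explicit seeded generator; there is no
module-level randomness. `scripts/acceptance.py` derives all sub-seeds from
`--seed`. The test suite runs in well under a minute on one CPU; the heavier
pieces (20-seed Ks recovery at 1000 codons, 20-seed partner-recovery
sweeps, bootstrap at 200 replicates, the edgeR cross-check subprocess) were
sized so the whole validation remains interactive while keeping each check
at the scale its tolerance was stated for.
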