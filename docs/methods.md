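# Methods

`panscan` implements the desk-scale computational core of a genus-wide
analysis of calcium-dependent protein kinases (CPKs) and their related
kinase families (CRK, PPCK, PEPRK, CCaMK): motif-level domain-architecture
detection, duplication-mode classification over gene orders, a nine-type
taxonomy of splice-variant domain consequences, homoeolog expression bias
(HEB) calling in allotetraploids, and expression-atlas summaries.  A
synthetic-data generator with planted ground truth supplies every input the
pipeline consumes, so each stage can be validated against known answers.

## Domain detection

**EF-hand motifs.**  The functional calcium-binding site is the 13-position
PROSITE pattern PS00018
(`D-x-[DNS]-{ILVFYW}-[DENSTG]-[DNQGHRK]-{GP}-[LIVMC]-[DENQSTAGC]-x(2)-[DE]-[LIVMFYW]`),
matched by a small PROSITE-syntax engine that reports every overlapping
match.  An EF-hand is any 13-residue window that either matches the pattern
strictly (a functional Ca²⁺-binding site) or matches a relaxed variant — up
to two violations among the coordinating positions {1, 3, 5, 9, 12}, with
at least one anchor intact (Asp at position 1 or Asp/Glu at position 12) —
in which case it is a *degenerate* EF-hand that cannot bind Ca²⁺.  The
relaxed rule is this package's operationalisation of "degenerated EF-hand";
no published quantitative rule exists.  Overlapping candidate windows are
resolved greedily left to right (strict preferred at equal start), which is
deterministic and order-independent.  The ambiguity code X never satisfies
a constrained pattern position.

**Kinase domain.**  Generalized PROSITE profiles (PS50011/PS50222) are not
reimplemented; profile arithmetic is out of proportion to this analysis.
Instead the kinase domain is recognised through its three ordered anchor
motifs — the Walker-lysine context `[AV]-x-[IV]-K` (VAIK), the catalytic
`HRD`, and the activation-loop `DFG` — required to occur in order within a
first-to-last span of 180–340 residues (the extent of a protein kinase
fold).  All three anchors in order ⇒ complete; one or two ⇒ incomplete
(truncated); none ⇒ no kinase domain.  The reported span pads the anchor
extent by 25 residues.  For real proteomes already scanned with
ScanProsite/InterProScan, `load_external_domains` bypasses the built-in
scanners: PS50011 rows become complete kinase hits, PS50222 rows EF-hands,
and a PS00018 row inside an EF span sets its Ca-site flag (orphan rows
attach to an EF within 5 residues or are dropped with a warning).

**Architectures.**  An architecture is the kinase state plus the ordered
Ca-site flags of the EF-hands, serialised as a signature such as
`K|E*E*E*E*` (complete kinase, four functional EF-hands; `k` marks an
incomplete kinase, `*` a Ca-site).  When a kinase is present and there are
at least two EF-hands, the last two form the C-lobe of the calmodulin-like
domain and all preceding ones the N-lobe — a generalisation of the
four-EF case that is consistent with three-EF CPKs whose single Ca-site
sits in the C-lobe.  Within an ortholog group, signatures seen once are set
aside as solo layouts; among the rest the layout with the highest support
is the representative type and the others are variants (ties broken by more
total Ca-sites, then lexicographically smaller signature — an arbitrary but
deterministic rule).  Clustering is per ortholog group by default; an
evolutionary-subgroup grouping is a caller-side choice of grouping column.

**Family assignment.**  Proteins are assigned to a family by the
best-scoring seed under local alignment (BLOSUM62, gap open 11 / extend 1,
Biopython `PairwiseAligner`; BLOSUM62 rows for X zeroed).  A raw-score
floor (default 100) replaces the E-value cutoff a BLAST-based pipeline
would use; no E-value machinery exists here, and the emitted score tables
accept tabular BLAST substitutes.  A domain-consistency check warns when
the label contradicts the family's expected layout (CCaMK: complete kinase
+ 3 EF; CPK: complete kinase + 3–4 EF; CRK: ≤1 EF without Ca-site;
PPCK/PEPRK: kinase only).

## Molecular properties

Molecular weight is the ProtParam convention: the sum of average residue
masses plus one water (18.015 Da), with X counted at 110.0 Da.  The
isoelectric point solves net charge = 0 by bisection over
Henderson–Hasselbalch terms for {N-terminus, C-terminus, D, E, C, Y, H, K,
R} using a Bjellqvist-style pKa table (an EMBOSS table is selectable; the
choice moves pI by ~0.1 pH at most).  Bisection stops when |Q| < 1e-4; a
1e-10-pH interval guard handles floating-point exhaustion.  Note that the
root of the charge curve can fall slightly below the smallest pKa present
when acidic groups outnumber basic ones — the "pI inside the pKa bracket"
intuition holds only to within about one pH unit for short peptides.

Lipidation sites are deliberately transparent heuristics, not re-creations
of machine-learning predictors, and are labelled as such in output:
N-myristoylation requires a Met-Gly start whose mature N-terminus matches
`G-{EDRKHPFYW}-x(2)-[STAGCN]-{P}` (modified residue is always Gly-2);
S-palmitoylation lists cysteines within the first 25 residues.  A protein
with either kind of site is called membrane-targeted, otherwise
cytoplasm/nucleus — mirroring the reported correspondence between
lipidation and predicted localization in these families.

## Duplication modes and collinearity

Collinear blocks are chains of homologous gene pairs in conserved (or
inverted) order between two chromosomes.  Gene positions are gene-order
ranks (0-based index along the chromosome after sorting by start, ties by
gene id).  Per chromosome pair, the longest strictly monotone chain with
rank gaps ≤ `max_gap` (default 25) on both sides is found by O(n²) dynamic
programming in both orientations; the best chain is extracted, its pairs
removed, and chaining repeats while chains reach `min_anchors` (default 5)
— MCScanX-style conventions.  The DP is provably optimal per extraction and
is checked against an exhaustive oracle in the tests.

Duplicate pairs are classified hierarchically in the priority order
WGD > tandem > proximal > transposed > dispersed, DupGen-finder style
(the published pipeline is named but its order is not; the hierarchy is the
cited tool's logic):

- **WGD** — the pair is an anchor of an intra-genome collinear block
  (anchors-only by default; a rank-envelope option also accepts pairs lying
  inside a block's span on both sides).
- **TD** — same chromosome, adjacent ranks (|Δrank| = 1).
- **PD** — same chromosome, 1 < |Δrank| ≤ `proximal_window` (default 10
  genes, the cited pipeline's convention).
- **TRD** — exactly one member sits at an *ancestral locus* — operationally,
  it participates as an anchor in any collinear block against the outgroup
  genome — and the pair is in no intra-genome block.
- **DSD** — everything left.

Each gene takes the mode of its highest-priority pair; family genes with no
pair are singletons.  The copy-number (CNV) matrix counts family members
per ortholog group per genome/subgenome, with absences reported as 0.

## Splice-variant taxonomy

Against a canonical reference (complete kinase, 3–4 EF-hands), a variant's
type is decided by its **absolute** domain content: with a complete kinase,
3/2/1/0 EF-hands give Types 1–4; any variant with an incomplete kinase is
Type 5 regardless of EF count; without a kinase, 4/3/2/1 EF-hands give
Types 6–9.  A variant whose signature equals the reference is canonical;
variants gaining domains over the reference are left unclassified rather
than forced into the taxonomy.  The absolute mapping (rather than deficit
relative to the reference) is required for consistency with the three-EF
CCaMK reference, whose EF-only variants with three and two EF-hands carry
Types 7 and 8.  Ca-site flags are reported but ignored for the type label.
The exhaustive sweep over kinase state × EF count yields exactly the nine
non-canonical labels, with Type 5 the only label shared by several sweep
cells (by definition).

## Homoeolog expression bias and atlas

Replicates are averaged (arithmetic mean FPKM) before all rules; the
inclusion filter is strict (mean FPKM > 0.5).  For a 1:1 homoeolog pair in
one tissue, the relative contributions are p = (a, b)/(a + b) on the raw
means (a sub-threshold member keeps its measured value), and the category
is the Euclidean-nearest of three ideal patterns — (1, 0), (0, 1),
(0.5, 0.5), the geometrically natural choices and configurable — with exact
ties resolved to BALANCED (conservative: fewer false bias calls).  The
resulting dominance boundary sits exactly at p > 0.75.  A pair with neither
member expressed is NOT_EXPRESSED; a pair with exactly one expressed member
is still classified (it will be dominant) unless `require_both` is set —
both readings of the inclusion rule are supported, at-least-one being the
default.

Atlas summaries report per-tissue mean FPKM, the top tissue, and a
predominance flag (top/second ratio ≥ 2 and expressed there).  Display
transforms are log10(FPKM + 0.01) for atlas heatmaps (pseudocount chosen so
zero maps to −2) and log2(FPKM + 1) for HEB heatmaps.  Duplicate-pair
comparison calls a pair one-silent when exactly one member is expressed
nowhere (a pseudogenization signal), redundant when profiles agree (Pearson
r ≥ 0.8 across ≥ 3 tissues and mean |log2 ratio| ≤ 1, pseudocount +1), and
diverged otherwise; with fewer than three tissues or a constant profile the
concordance is undefined and the ratio rule decides alone.

## The synthetic-data generator

The generator emulates the statistical structure of a multi-genome kinase
family study — it is the package's study condition, not a tuning knob.

**Genomes.**  Default: a cultivated-like diploid, a wild diploid, one
allotetraploid as two subgenomes, and an always-emitted outgroup genome
with the unduplicated ancestral order (the transposed-duplication test
needs one).  Each genome carries 4 chromosomes × 130 genes in a shared
ancestral order, lightly perturbed by adjacent background swaps; 40 family
genes (1 CCaMK, 29 CPK, 5 CRK, 2 PEPRK, 3 PPCK per genome — the cultivated
composition) sit at evenly spaced slots.

**Proteins.**  Sequences are assembled from planted motifs (kinase anchors
with realistic spacing; EF loops sampled directly from the loop pattern,
degenerate loops flipping 1–2 coordinating positions to excluded residues —
a sharp, testable boundary) joined by random linkers.  One template and one
linker bank are drawn per family; every ortholog group rebuilds from the
same bank, so family members stay alignable (~8% substitutions per group,
~2% per genome, linker positions only), while families are mutually random.
Each protein is re-scanned at generation time and resampled if a random
linker accidentally creates a motif, so planting is noise-free by
construction; the mutation step re-verifies the same way.

**Duplication events.**  Eight planted events by default (a WGD, TD, PD,
TRD and DSD in the wild diploid; a WGD, TD and TRD in one subgenome).  Each
is planted so its definitional signature holds on the emitted tables: the
WGD copy sits inside a copied segment giving ≥ 8 flanking anchor pairs; TD
at adjacent rank; PD at rank gap 3–10; TRD at a novel chromosome with its
mate keeping outgroup collinearity; DSD with *both* copies relocated off
the ancestral locus (so neither keeps outgroup collinearity and no earlier
rule fires) — this keeps the outgroup itself untouched.

**Expression.**  For a dominant pair at total expression T (log-uniform in
[2, 200] FPKM) the dominant homoeolog receives T·p_dom and the other
T·(1 − p_dom) with p_dom = 0.9; balanced pairs split 0.5/0.5; unexpressed
pairs draw every replicate uniform in [0, 0.5].  Every replicate value is
multiplied by log-normal noise exp(N(0, sd)) with sd = 0.2 — the standard
multiplicative shape of RNA-seq abundance noise; no published value exists
for this design, and sd = 0 reproduces the planted fractions exactly.  Two
replicates per tissue; four tissues (root, stem, leaf, panicle).  Diploid
atlas matrices draw per-tissue baselines log-uniform in [1, 60] FPKM with a
10× root boost for CCaMK (root-predominant in these families) and planted
silent duplicates for pseudogenization calls.

**Splice variants.**  Requested types are realised by cutting the canonical
protein at recorded motif boundaries (C-terminal truncation for Types 1–5,
N-terminal for 6–9) and mapping the retained coding window back onto a
three-exon gene model, so variant transcripts differ from the canonical by
truncated terminal exons.  Variants are re-scanned and the whole set
regenerated on any mismatch.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequence-level homology noise (linkers are random,
so alignment scores separate families far more sharply than real paralogs);
fragmented assemblies and mis-annotated gene models; partially degraded
collinearity (planted blocks are clean); read-level quantification error
beyond log-normal FPKM noise; and genuine PROSITE profile scores (the
anchor-motif scanner is a deliberate simplification — the external-table
reader is the fidelity path for real proteomes).

## Determinism and problem sizes

Every stochastic step flows from one integer seed through
`numpy.random.default_rng`; identical configurations produce byte-identical
output files.  The default problem sizes — 5 genomes × 520 genes, ~210
family proteins, 1,000 homoeolog pairs and 200 splice-variant genes per
type in the verification scripts — were chosen so a full verification run
completes in well under a minute on one core while keeping every recovery
statistic's denominator large enough to be meaningful.

## Known limitations

- The kinase scanner keys on three anchor motifs; real kinase-dead variants
  that mutate HRD/DFG while keeping the fold would read as "incomplete".
- The relaxed EF-hand rule and the similarity-score floor are package
  conventions, calibrated to the synthetic conditions and configurable for
  real data.
- Lipidation/localization calls are consensus heuristics and should not be
  compared numerically against dedicated predictors.
- HEB ideal-category vectors default to the geometric ideals; studies using
  other ideals should pass them explicitly.
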