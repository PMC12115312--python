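# panscan

Genus-wide analysis of calcium-dependent protein kinase (CPK) gene families
and their relatives (CRK, PPCK, PEPRK, CCaMK) — the kinase families at the
heart of plant calcium signalling.  `panscan` is for comparative genomicists
who want to take a set of genomes (or a simulated stand-in) and ask, for one
kinase family across a genus:

- **Domain architectures** — where are the kinase domains, EF-hand motifs
  and functional Ca²⁺-binding sites, and which layout is the representative
  type of each ortholog group versus a minority variant?
- **Duplication modes** — is each duplicate pair whole-genome (WGD), tandem
  (TD), proximal (PD), transposed (TRD) or dispersed (DSD), given gene
  orders and collinear blocks?
- **Splice consequences** — which of nine domain-truncation types does each
  transcript variant realise?
- **Homoeolog expression bias (HEB)** — in an allotetraploid, is each 1:1
  homoeolog pair balanced or subgenome-dominant, tissue by tissue?

## The core statistics

An **EF-hand** is a 13-residue window matching the canonical
calcium-binding loop pattern
`D-x-[DNS]-{ILVFYW}-[DENSTG]-[DNQGHRK]-{GP}-[LIVMC]-[DENQSTAGC]-x(2)-[DE]-[LIVMFYW]`
(PROSITE PS00018) either strictly (a functional Ca²⁺-binding site) or with
up to two violated coordinating positions among {1, 3, 5, 9, 12} and one
intact anchor (degenerate).  A **kinase domain** is recognised by its three
ordered anchor motifs (VAIK context, HRD, DFG) within 180–340 residues;
all three ⇒ complete, a subset ⇒ truncated.  Architectures are signatures
such as `K|E*E*E*E*` (complete kinase + four functional EF-hands, the
canonical CPK).

**Duplication typing** runs in priority order WGD > TD > PD > TRD > DSD
over gene-order ranks: block anchors (longest-chain dynamic programming,
min 5 anchors, max gap 25) are WGD; |Δrank| = 1 is tandem; Δrank ≤ 10 is
proximal; a pair whose one member keeps collinearity with the outgroup
genome while the other sits at a novel locus is transposed; the rest is
dispersed.

**HEB** classifies each pair × tissue by the Euclidean-nearest of the ideal
patterns p ∈ {(1,0), (0,1), (0.5,0.5)} applied to the normalized
contributions p = (a, b)/(a + b) of replicate-mean FPKM, after a strict
FPKM > 0.5 expression filter; ties go to balanced, so dominance begins
exactly at p > 0.75.

A built-in synthetic-data generator plants all of the above — domain
layouts, duplication events with their definitional signatures, splice
variants, expression-bias categories — and records the truth, so every
stage is validated end to end.  See `docs/methods.md` for the full model
description and its limitations.

## Worked example

```python
from panscan import RunConfig, SimConfig, run_pipeline

result = run_pipeline(RunConfig(sim=SimConfig(seed=1), out_dir="out"))
print(result.report["counts"])
```

prints

```
{'scan': 208, 'family': 208, 'properties': 208, 'cluster': 40, 'blocks': 2,
 'duplication': 168, 'cnv_groups': 40, 'as': 18, 'heb': 148, 'atlas': 85}
```

— 208 family proteins scanned across 4 genomes plus the outgroup, 40
ortholog groups clustered, 168 duplication calls, 18 splice-variant calls
and 148 pair × tissue HEB calls.  The duplication calls recover every
planted event, e.g. (from `out/tables/duplication_calls.tsv`):

```
genome  gene_id       mode  partner        evidence
Gwild   Gwild_CPK12   TD    Gwild_CPK12d   adjacent ranks
Gwild   Gwild_CPK15   PD    Gwild_CPK15d   rank gap 6
Gwild   Gwild_CPK26   DSD   Gwild_CPK26d   no positional signature
Gwild   Gwild_CPK29   TRD   Gwild_CPK29d   novel locus Gwild_CPK29d
```

and the architecture table shows the canonical layouts with their
N-/C-lobe assignment:

```
protein_id   signature   kinase_state  ef_count  ca_count  lobes
Gsat_CCaMK1  K|E*E*E*    complete      3         3         N,C,C
Gsat_CPK4    K|E*E*E*E*  complete      4         4         N,N,C,C
```

HEB calls (`out/tables/heb_calls.tsv`) give the per-tissue subgenome
contributions and category per homoeolog pair:

```
pair_id  tissue  p_a    p_b    category
CCaMK1   root    0.497  0.503  BALANCED
CCaMK1   leaf    0.105  0.895  DOM_B
```

The report bundle (`out/report.json`) also carries truth-versus-call
confusion tables; under the default conditions they are diagonal.

The same stages are available on your own files through the CLI:

```bash
panscan scan-domains proteins.fasta --out arch.tsv
panscan properties proteins.fasta --out props.tsv
panscan find-blocks pairs.tsv gene_orders.tsv --out blocks.txt
panscan classify-heb fpkm.tsv samples.tsv pairs.tsv --out heb.tsv
panscan run --seed 1 --out-dir out      # full synthetic-mode pipeline
```

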