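# Methods

## Model and assumptions

The classifier infers the inheritance of a candidate variant — a biallelic
site where the proband carries a phased heterozygous call and the sequenced
parent is homozygous for the other allele — from local identity-by-descent
(IBD) between proband and parent haplotypes.

Within a *joint haplotype block* (a maximal run of variants in which every
proband-phased call shares one phase set and every parent-phased call
shares one phase set) the four haplotype sequences are well defined, and
exactly one of the proband's two haplotypes was transmitted by the
sequenced parent. If the candidate-bearing proband haplotype is identical
(Hamming distance exactly 0 over the block's informative positions) to
exactly one parental haplotype, the candidate allele sits on the
transmitted haplotype yet is absent from the parent — it must have arisen
de novo in that parent's germline (or very early post-zygotically; the
method cannot distinguish these). If instead the *other* proband haplotype
is IBD with a parental haplotype while the candidate-bearing one is
dissimilar to both, the candidate haplotype came from the non-sequenced
parent, and its variant's de novo status cannot be decided from the duo.
All other distance patterns — including IBD with *both* parental
haplotypes, which happens when the parent is locally homozygous by
descent — yield no classification (uncertain).

The exact-zero requirement is deliberately strict. Encoded positions
comprise three classes: proband-het/parent-hom sites carry the transmission
signal; both-het (phased) sites check phasing consistency in both samples;
proband-hom/parent-het sites check parental phasing. A single genotype
error or phase switch anywhere in the block therefore destroys the zero
and the candidate falls back to uncertain — trading sensitivity for
precision, which is the right trade for de novo calling where false
positives are costly.

Assumptions: the VCF is jointly called and read-back phased
(DeepVariant/GLnexus + HiPhase dialect: GT with `|`, GQ, DP, PS); sites
are diploid autosomal calls (haploid or missing genotypes are never
candidates); phase-set identifiers are consistent within a sample along
each contig. A phased GT without a PS value is treated as unphased,
because block construction consumes phase-set identity, not the separator.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `min_depth` | 20 | reads | site retention, both samples |
| `gq_input_min` | 30 | PHRED | site retention, both samples |
| `gq_final_min` | 40 | PHRED | post-classification gate on the candidate call |
| `min_block_span` | 10,000 | bp | discard candidates in smaller blocks |
| `boundary_margin` | 2,000 | bp | discard candidates near block edges |
| `hd_dissimilarity_threshold` (T) | 40 | mismatches | "dissimilar" = distance > T |
| `candidate_allele_kind` | alternative | — | or `reference` (negative control) |

The depth/GQ retention gates apply to *every* position before block
construction, so low-quality sites neither delimit blocks nor enter the
haplotype encodings; the stricter GQ ≥ 40 gate applies only to the
candidate's own calls, after classification. Lowering T toward 0 can only
add classifications (monotone by construction) at the cost of precision;
`parameter_sweep` exposes this trade-off. Boundary candidates are excluded
because phasing accuracy degrades at block edges; a candidate exactly at
`span_start + margin` passes (ties resolve permissively).

## Design choices where the design was open

- **Block extent** is the inclusive span of member variant positions, not
  phaser metadata — derivable from any input VCF.
- **Block delimiting**: a variant phased in only one sample constrains only
  that sample's phase set; a variant phased in neither joins the enclosing
  run without delimiting it. Records between two runs attach to the
  preceding run; they can never host a candidate (candidates require
  proband phase).
- **Encoding exclusions**: only candidates in the *same* phasing
  orientation as the evaluated candidate are excluded from the binary
  strings. Opposite-orientation candidates remain and are what drives the
  other haplotype's distances above T.
- **Shared encodings**: all same-orientation candidates of one block see
  identical vectors, so encodings and distances are computed once per
  (block, orientation) — contractually identical to per-candidate
  recomputation.
- **Filter order**: problematic-region exclusion, then the final GQ gate,
  then the clustered-de-novo discard. Clustering is judged only among
  calls that survived the quality gates, so a low-GQ spurious call cannot
  drag down a genuine one in the same block.
- **IBD with both parental haplotypes** returns uncertain ("exactly one"
  is read literally).
- **Trio truth NPV/denominators**: NPV is computed over
  inherited-from-non-sequenced calls only; uncertain candidates are
  reported separately, never counted as negative calls. Truth positions
  that never became duo candidates count against sensitivity.
- **Allele matching in evaluation** uses the specific tested allele string
  (the ALT for alternative-kind candidates, the REF for reference-kind),
  not "any non-reference allele".

## The simulator: what it emulates, what it does not

`simulate_family` generates one synthetic contig (default 5 Mb, 50,000
sites ≈ one per 100 bp) with: population ALT frequencies drawn from
Beta(2, 2); four parental haplotypes sampled from those frequencies; child
haplotypes formed by recombination (default 10⁻⁸ crossovers/bp per
transmission); de novo alleles injected at family-monomorphic positions on
the transmitted paternal or maternal haplotype (default 20 paternal : 5
maternal, reflecting the ~4:1 excess of paternal germline mutations);
per-sample phase-set fragmentation (exponential fragments, mean 300 kb,
emulating multi-hundred-kb long-read phase blocks) with a random emitted
orientation per fragment and optional switch errors; optional genotype
errors; GQ drawn from a high regime for correct calls (N(60, 7), clipped
to [2, 99]) and a low regime for erroneous calls (N(20, 8)); DP from
Poisson(33), matching ~33× coverage. `unrelated=True` emits two
independent diploids — the negative control in which no haplotype pair is
IBD.

Two calibrations are generator design decisions worth knowing about:

- **Allele-frequency density.** Beta(2, 2) makes two non-IBD haplotypes
  differ at ~0.4 of sites, so even a minimum-span block (10 kb ≈ 100
  sites) usually carries more than T = 40 informative differences. A
  heavier-tailed (U-shaped) frequency density would leave 10–16 kb blocks
  systematically unclassifiable at the default threshold: they pass the
  span filter yet cannot exceed T, deflating recovery for reasons that
  have nothing to do with the classifier. Real genomes sit even further
  toward sparsity (~1 het/kb), which is precisely why the classifier
  needs its multi-hundred-kb blocks; the simulator compresses that
  geometry ~10-fold to keep run times at desk scale. Blocks near the
  10 kb limit remain marginal even so — an injected event hosted there
  can stay uncertain, which is the classifier being honest, not wrong.
- **De novo placement.** Injected events are placed in pairwise-distinct
  haplotype blocks of both duos (redrawing the fragmentation
  deterministically if a draw cannot host them all). Real de novo events
  essentially never co-occur within one phase block; without this
  constraint the simulation's deliberately high event density (25 per
  5 Mb ≈ 10³× reality) routinely triggers the clustered-call discard and
  perturbs the exact-zero distance of unrelated candidates in the same
  block. Origin (paternal/maternal) is assigned after a shuffle so it is
  independent of block size.

Not emulated: read-level errors, reference sequence and alignment
artifacts, mutation-rate heterogeneity (CpG effects), multi-allelic sites,
sex chromosomes, structural variants, population structure between the
parents. Passing tests on these simulations therefore demonstrate the
correctness of the block/IBD/decision machinery and its filters under the
stated noise models — not calling performance on real sequencing data,
where error modes are richer and linkage structure is real.

## Numerical and degenerate-input conventions

Missing GQ/DP fails every threshold (never imputed, never zero). Empty
inputs yield empty outputs; empty metric denominators report missing, not
zero. Classification is fully deterministic and symmetric under swapping
the parent's two haplotypes; the simulator is byte-reproducible given its
seed. Problem sizes used by the test suite and the acceptance script — a
5 Mb contig with 50,000 sites per family, three replicate seeds per
regime, 2 Mb controls — keep a full run within a few minutes on one CPU
while leaving ≥10⁴ transmitted candidates per duo to bound the false
positive rate.

## Known limitations

- Only de novo events on the sequenced parent's transmitted haplotype are
  detectable; events on the other haplotype are reported as inherited from
  the non-sequenced parent (which is where they physically reside — their
  de novo status is unknowable from the duo).
- Post-zygotic mosaicism, X/Y hemizygosity and multi-allelic sites are out
  of scope; haploid calls are silently non-candidates.
- The exact-zero IBD criterion makes sensitivity degrade quickly with
  genotype-error and switch-error rates (each error in a block removes the
  whole block's candidates from contention); precision is largely
  unaffected, as the error pushes calls toward uncertain, not toward de
  novo.
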