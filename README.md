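# denovoduo

De novo variant classification from a **single parent–proband duo**,
using phased long-read variant calls and identity-by-descent (IBD)
haplotype blocks.

## The problem

A de novo variant is present in a child but absent from both parents'
constitutional genomes. Detecting one normally requires sequencing the full
trio — impossible for the many families where only one parent is available.
With accurate long reads (e.g. PacBio HiFi), read-backed phasing resolves
heterozygous calls into haplotype blocks spanning hundreds of kilobases.
That makes inheritance visible from a duo alone: within a joint block, each
of the proband's two haplotypes can be compared against each of the
sequenced parent's two haplotypes.

## The method

Variant calls come from a jointly-called, phased multi-sample VCF (GT with
`|` phase separator, GQ, DP and PS per sample). The pipeline:

1. **Site QC** — keep positions with DP ≥ 20 and GQ ≥ 30 in both samples.
2. **Haplotype blocks** — maximal runs of variants in which all
   proband-phased calls share one phase set (PS) and all parent-phased
   calls share one PS.
3. **Candidates** — biallelic sites with a phased heterozygous proband call
   (`0|1`/`1|0`) and a homozygous-reference parent (`0/0`); a
   reference-allele negative-control mode (`1|0` + parent `1/1`) is also
   available.
4. **Encoding + Hamming distances** — each block becomes four binary
   strings (0 = REF, 1 = ALT): proband hap₁/hap₂ and parent hap₁/hap₂ over
   the block's informative positions (phased-het or homozygous in both
   samples; candidates sharing the evaluated candidate's phasing
   orientation are excluded). Four Hamming distances are computed:
   d(c, p₁), d(c, p₂) for the candidate-bearing proband haplotype c, and
   d(o, p₁), d(o, p₂) for the other haplotype o.
5. **Decision rule** (dissimilarity threshold T = 40):
   - **de novo** — c has distance **exactly 0** to exactly one parental
     haplotype (IBD) while o has distance > T to both;
   - **inherited from the non-sequenced parent** — the mirror image
     (o is IBD with one parental haplotype, c is dissimilar to both);
   - **uncertain** — anything else.
6. **Filters** — candidates in blocks < 10 kb or within 2 kb of a block
   edge are discarded; classified candidates need GQ ≥ 40 in both samples;
   positions in a user-supplied problematic-regions BED fail outright; if
   two or more de novo calls share one block, all of them are discarded.

A distance of exactly 0 works as an IBD detector because the encoded
positions include phasing quality controls: besides proband-het/parent-hom
sites (which directly reveal transmission), both-het and
proband-hom/parent-het sites verify that phasing is locally consistent in
both samples — any switch or genotype error breaks the exact zero.

The package also ships a trio-based evaluation module (assessment of duo
calls against the masked parent, trio-derived ground-truth de novo sets,
PPV/NPV/FPR/sensitivity, mutation spectrum, parameter sweeps) and a
synthetic phased-family simulator with known ground truth, so the whole
pipeline is testable without any real data.

## Worked example

Simulate a family (2 Mb, 20,000 sites, 8 paternal + 2 maternal de novo
events, no errors), then classify the father–proband duo and evaluate it
against the full trio:

```bash
denovoduo simulate --seed 7 --out-dir demo --n-sites 20000 \
    --region-length 2000000 --de-novo-paternal 8 --de-novo-maternal 2
denovoduo classify --vcf demo/father_duo.vcf \
    --proband proband --parent father --out-prefix demo/fd
denovoduo evaluate --trio-vcf demo/trio.vcf \
    --proband proband --father father --mother mother \
    --sequenced-parent father \
    --classifications demo/fd.classifications.tsv --out-prefix demo/fd
```

The classify step logs the label counts:

```
de_novo: 7
inherited_from_non_sequenced: 835
uncertain: 1085
failed_qc: 54
```

Of 1,981 candidate sites (proband-het, father-hom-ref), 7 sit on a
haplotype that is IBD with one paternal haplotype while the other proband
haplotype matches neither — de novo on the paternal germline (the eighth
injected paternal event fell too close to a block edge and was discarded
by QC). The 835 "inherited" candidates sit on the maternal haplotype;
their variants came from the non-sequenced mother. The evaluate step
compares against the masked mother and the trio truth:

```
ppv = 1.0
npv = 0.9987980769230769
naive_npv = 0.9954476479514416
fpr = 0.0
sensitivity = 0.75
```

Every de novo call is absent from the mother (PPV 1.0), no
maternally-transmitted candidate was called de novo (FPR 0), and 3 of the
4 trio-truth de novo positions were recovered from the duo alone.

`demo/fd.classifications.tsv` holds one row per candidate with its label,
the four Hamming distances, the block span and any filter reasons.

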