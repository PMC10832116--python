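# teguide

Offline sgRNA design for transposable elements (TEs).

CRISPR experiments that target TEs face a problem ordinary guide
designers ignore: the target is not one locus but a *subfamily* of
dozens-to-thousands of interspersed copies descended from a common
consensus, and the best guide set must hit as many copies as possible
while avoiding near-identical sequence scattered through related
subfamilies and genes. `teguide` builds the complete search
infrastructure for this locally, with no server or downloads:

1. **Scan** — every SpCas9 target site (20-nt protospacer + NGG PAM,
   `N20NGG`) on both strands of a genome FASTA, with 6-bp flanks.
2. **Index** — all unique protospacers in a trie supporting exact
   Hamming-distance ≤ 3 neighborhood queries (substitutions only;
   every off-target candidate carries its own PAM by construction).
3. **Annotate** — RepeatMasker `.out` TE copies (subfamily / family /
   class, per-copy IDs `<subfamily>_dup<i>`) and a GTF gene model
   (promoter-TSS > exon > intron > intergenic precedence).
4. **Design** — either rank guides inside one TE copy by off-target
   minimality (occurrence counts at 0/1/2/3 mismatches), or greedily
   assemble a combination of up to three guides for a subfamily
   maximizing

   ```
   SCORE = Coverage − λ1·W1 − λ2·(λ3·W2 + λ4·W3 + λ5·W4 + λ6·W5)
   ```

   with Coverage the fraction of subfamily copies containing a guide
   site, W1 the number of off-target sites inside other TE copies, and
   W2–W5 the off-target sites in promoter-TSS / exon / intron /
   intergenic space (defaults λ1 = 1e-3, λ2 = 1e-4, λ3 = 0.4, λ4 = 0.3,
   λ5 = 0.4, λ6 = 0.3).
5. **Store** — a single-file SQLite database (gid-keyed main + mismatch
   tables) answering copy-ID / subfamily / interval queries offline.
6. **Simulate** — synthetic genomes with planted TE subfamilies of
   controlled divergence ("age"), decoy subfamilies, and a toy gene
   model, with exact ground-truth manifests, so the whole pipeline is
   testable without reference downloads.

## Worked example

```sh
teguide simulate --out demo --seed 1          # synthetic genome bundle
teguide build --fasta demo/genome.fa --te-out demo/repeats.out \
              --gtf demo/genes.gtf --db demo/guides.db
teguide subfamily --db demo/guides.db --name ERVsim | head -3
```

prints (CSV):

```
rank,gids,protospacers,coverage,W1,W2,W3,W4,W5,score
1,577;141;1913,AGATCTTCGCGTACACTTGT;AAGACATCCCTGTTAGGGCC;CGGTCGCCAATGCTCGAGGG,0.84,17,0,0,0,0,0.823
2,1913;3886;1729,CGGTCGCCAATGCTCGAGGG;TGCGGAGAGGACACACACAC;CGAAAAGAGGAAATCAAATT,0.82,3,0,0,0,0,0.817
```

Read: the top three-guide combination covers 84 % of the 50 planted
`ERVsim` copies; its mismatch neighborhood hits 17 sites inside copies of
the decoy subfamily (W1) and none in promoters/exons/introns/intergenic
space, so SCORE = 0.84 − 1e-3·17 = 0.823. Ranking guides for one copy
instead:

```sh
teguide single --db demo/guides.db --te-id ERVsim_dup1 | head -2
```

```
rank,gid,protospacer,pam,chrom,start,end,strand,gc,mm0,mm1,mm2,mm3,on_target
1,3563,TCCCCAACAAGTGTAAGCGA,AGG,chr1,2617,2639,+,0.5,0,0,0,0,0.5800000000000001
```

— the top guide's sequence occurs nowhere else in the genome within 3
mismatches (columns `mm0..mm3` count off-copy occurrences by mismatch
distance).

The same operations are available as library calls
(`teguide.scan_genome`, `build_index`, `greedy_combination`,
`single_copy_design`, ...); see the module docstrings and
`docs/methods.md` for the model details.

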