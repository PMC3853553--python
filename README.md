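# trnldiet

A DNA-metabarcoding diet-analysis pipeline for chloroplast **trnL P6-loop**
amplicons, built for fecal diet studies of herbivorous and frugivorous
vertebrates (the motivating system is a critically endangered island pigeon
whose diet mixes native and introduced plants). It is aimed at molecular
ecologists who have (a) a local reference collection of trnL intron
sequences with a species/genus/family taxonomy, and (b) pooled, MID-tagged
amplicon reads from fecal samples, and who want reproducible diet
composition tables and between-group community statistics.

## What it computes

**Reference database.** P6 inserts are cut from full trnL (UAA) intron
sequences between the universal primers g (`GGGCAATCCTGAGCCAA`) and h
(`CCATTGAGTCTCTGCACCTATC`). Species sharing an identical haplotype are
collapsed into a *haplotype group* labelled at the lowest rank containing
all members (e.g. `Gr. Lauraceae1`). Marker resolution is summarised by
discrimination rates

- Rs = 100 · (distinct haplotypes) / (species),
- Rf(family) = 100 · (distinct haplotypes in family) / (species in family),
- Rg = 100 · (genera owning ≥ 1 genus-exclusive haplotype) / (genera),

all rounded half-up to integer percent.

**Read processing.** Reads are demultiplexed by MID prefix, primer-trimmed,
dereplicated, clustered greedily at 98% global-alignment identity, and
filtered (centroid ≥ 40 bp, cluster ≥ 4 reads).

**Assignment.** Each retained cluster is aligned semi-globally against all
haplotype groups (identity ≥ 0.95 over ≥ 40 columns); all groups tied at
the maximal score are kept, and ties are resolved to the lowest common
taxonomic level (a tie spanning families is reported unassigned).

**Diet metrics.** Per food item: frequency of reads F_R (reads over all
assigned reads) and frequency of presence F_P (samples containing the item
over an explicit denominator), per-sample richness with a Welch t-test for
method comparison, origin (native/introduced/both) annotation, and monthly
relative presence frequencies of major food items.

**Community statistics.** Pearson chi-square on pooled island tables;
abundance-based Chao–Jaccard dissimilarity
(similarity = UV / (U + V − UV), with U, V corrected for unseen shared
species via shared singletons/doubletons) or plain Jaccard on
presence/absence; NMDS minimising Kruskal stress-1 with isotonic
regression; and ANOSIM, R = (mean between-group rank − mean within-group
rank) / (n(n−1)/4), with add-one permutation p-values.

**Synthetic data.** `trnldiet.simulate` generates complete studies with
known ground truth: a 222-species / 175-genus / 76-family taxonomy
collapsing to 167 distinct haplotypes of 66–148 bp, two islands of 24
samples, skewed Dirichlet diets with a dominant shared food item, depths
≈ 743 ± 338, and MID-tagged reads with substitution errors.

## Worked example

```python
from pathlib import Path
from trnldiet import io as tio
from trnldiet.config import RunConfig
from trnldiet.pipeline import run_pipeline
from trnldiet.simulate import SimulationConfig, simulate_study

out = Path("demo"); out.mkdir()
b = simulate_study(SimulationConfig(seed=42))
tio.write_fasta([tio.RawRead(r.species_id, r.intron_seq) for r in b["references"]],
                out / "reference.fasta")
b["taxonomy"].to_tsv(out / "taxonomy.tsv")
tio.write_fastq(b["reads"], out / "reads.fastq")
tio.write_midmap(b["midmap"], out / "mids.tsv")
tio.write_tsv(b["metadata"], out / "metadata.tsv")

cfg = RunConfig(reference_fasta="demo/reference.fasta", taxonomy_tsv="demo/taxonomy.tsv",
                reads_path="demo/reads.fastq", mids_tsv="demo/mids.tsv",
                metadata_tsv="demo/metadata.tsv", seed=1, out_dir="demo/out")
res = run_pipeline(cfg)
print(res["stats"]["stages"])
print(res["stats"]["discrimination"])
print(res["stats"]["island_comparison"]["presence"])
```

prints (numbers from this exact seed):

```
{'reads_in': 35831, 'reads_routed': 35831, 'reads_unassigned_mid': 0,
 'reads_rejected_preclustering': 0, 'reads_in_discarded_clusters': 6721,
 'reads_in_retained_clusters': 29110, 'reads_without_hit': 0}
{'Rs': 75, 'Rg': 69}
{'metric': 'jaccard', 'stress': 0.3163..., 'anosim_R': 0.3434..., 'anosim_p': 0.001}
```

So of 35,831 simulated reads all were routed to a sample; 6,721 ended in
clusters failing the ≥ 40 bp / ≥ 4-read filters; the 29,110 retained reads
all hit a reference group. The species-level discrimination rate of the
generated database is Rs = 75%, and presence-based ANOSIM cleanly detects
the built-in island contrast (R = 0.34, p = 0.001). The top of
`demo/out/diet_report.tsv` shows the dominant simulated food item holding
46.38% of reads and present in 100% of samples.

A CLI wraps the same steps:

```bash
trnldiet simulate --seed 42 --out demo
trnldiet run --reference demo/reference.fasta --taxonomy demo/taxonomy.tsv \
  --reads demo/reads.fastq --mids demo/mids.tsv --metadata demo/metadata.tsv \
  --seed 1 --out demo/out
trnldiet compare-islands --diet-matrix demo/out/diet_matrix.tsv \
  --metadata demo/metadata.tsv --out demo/islands
```

## Layout

- `src/trnldiet/taxonomy.py`, `reference.py` — taxonomy tree, P6 extraction,
  haplotype groups, discrimination rates
- `src/trnldiet/reads.py` — demultiplexing, trimming, clustering, filters
- `src/trnldiet/assign.py` — semi-global scoring, best hits, LCA labels
- `src/trnldiet/diet.py` — F_R / F_P, richness, monthly tables, origins
- `src/trnldiet/community.py` — chi-square, Chao/Jaccard, NMDS, ANOSIM
- `src/trnldiet/simulate.py` — synthetic studies with ground truth
- `src/trnldiet/io.py`, `config.py`, `pipeline.py`, `cli.py` — formats,
  configuration, orchestration, CLI

See `docs/methods.md` for the model details, defaults, and limitations.
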