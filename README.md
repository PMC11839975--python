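# phylotrx

Evolutionary transcriptomics of plant development: given a developmental
RNA-seq count matrix and per-gene evolutionary annotations, `phylotrx`
computes the expression-weighted transcriptome indices used to detect
hourglass-shaped phylogeny–ontogeny correlations, tests them with a
permutation flat-line test, and profiles stage-wise functional enrichment.
It is aimed at researchers studying developmental transcriptome evolution —
for example somatic embryogenesis sampled over an ordered series of stages —
who need the full path from raw counts to significance-tested index profiles
in one reproducible package.

## The statistics at its core

All four indices share a single form. For developmental stage *s*, with
normalized expression *e*ᵢₛ (fraction of transcripts, τ) and a per-gene
evolutionary weight *w*ᵢ:

```
x_s = Σᵢ wᵢ e_is / Σᵢ e_is
```

* **TAI** (transcriptome age index): *w*ᵢ = psᵢ, the gene's phylostratum —
  the oldest internode of the root-to-focal lineage with a detectable
  homolog (1 = oldest). Low TAI = evolutionarily old transcriptome.
* **TdNI / TdSI**: *w*ᵢ = dNᵢ / dSᵢ, nonsynonymous / synonymous divergence
  against a close relative's orthologs (reciprocal best hits).
* **TCBI**: *w*ᵢ = ENCᵢ, Wright's effective number of codons
  (20 = maximal codon bias, 61 = uniform usage); lower TCBI = stronger
  codon usage bias among expressed genes.

Profile shape is tested with the **flat-line test**: the variance of *x*
across stages is compared against the null distribution obtained by
permuting the gene weights while keeping expression fixed, which destroys
only the age–expression association. Per-phylostratum **relative
expression** RE(ps)ₛ = (f̄ₛ − f̄_min)/(f̄_max − f̄_min) locates each age
class's expression peak, and a stage-wise hypergeometric scan finds
annotation terms over-represented among genes expressed ≥ 0.5 log₂ units
above their own profile median.

A fully seeded synthetic-data generator produces every pipeline input
(counts + design, homology hit tables, coding sequences, divergence tables,
GO labels) with known ground truth, including a tunable hourglass effect.

## Worked example

```python
import phylotrx as px

cfg = px.SimulationConfig(n_genes=2000, n_ps=18, effect_size=2.0, seed=1)
catalog = px.simulate_gene_catalog(cfg)
counts, _ = px.simulate_counts(catalog, cfg)

expr = px.collapse_replicates(px.normalize_fraction_of_transcripts(counts), counts)
evol = px.GeneEvolStats(catalog.table.rename(columns={"true_ps": "ps"})[["ps", "dN", "dS"]])

profile = px.tai(expr, evol)
print(profile.values.round(3))
result = px.flat_line_test(expr, evol.weights("ps"), n_perm=1000, seed=2)
print(f"argmin={profile.argmin_stage()}  p={result.p_value:.4g}")
```

Output:

```
EI    7.180
PG    6.831
G1    5.822
G2    4.724
H     4.282
T1    4.751
T2    5.835
C1    6.684
C2    7.342
S     7.305
EP    7.366
JP    7.188
dtype: float64
argmin=H  p=0.000999
```

The TAI profile dips to its minimum at the designated phylotypic stage (H,
the heart stage): the evolutionarily oldest transcriptome is expressed
mid-development, with younger transcriptomes at both ends — the hourglass
pattern — and the permutation test rejects a flat profile (p ≈ 0.001, the
smallest value resolvable with 1000 permutations).

The same analysis runs from the shell:

```
phylotrx simulate --out sim/ --n-genes 2000 --seed 1
phylotrx run --config run.yaml
```

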