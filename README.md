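# grgsim

Phenotype simulation on **genotype representation graphs** (GRGs).

A GRG is a directed acyclic graph that losslessly encodes phased genotype
hard calls: leaves are haploid sample nodes, mutations attach to arbitrary
nodes, and sample *s<sub>j</sub>* carries mutation *m<sub>i</sub>* iff a
directed down-path runs from *m<sub>i</sub>*'s node to *s<sub>j</sub>*.  The
graph therefore implicitly stores the phased genotype matrix **G**
(2N × M, entries 0/1), and two traversals compute its matrix–vector
products without ever materializing it:

* **downward** (each node adds its parents' accumulated values to its own
  attached effects): **G u** for any length-M vector **u**;
* **upward** (each node sums its children): **Gᵀ v** for any length-2N
  vector **v**.

On top of these products, `grgsim` implements an additive polygenic trait
simulator.  With **X** the N × M diploid matrix
(X<sub>ij</sub> = G<sub>2i,j</sub> + G<sub>2i+1,j</sub>):

```
y = X β + ε
```

where β holds the causal effect sizes (zero off the causal set) and
ε ~ N(0, Var(Xβ)(1/h² − 1)) calibrates the narrow-sense heritability to
h².  In *standardized* mode the columns of X are centered by 2f and scaled
by 1/σ, σᵢ = √(2fᵢ(1−fᵢ)), and β ~ N(0, h²/M_causal); the standardized
product is computed graph-side as X(Σβ) − Σᵢ2fᵢβᵢ/σᵢ.  Binary traits come
from the liability threshold model: standardized phenotypes are thresholded
at Φ⁻¹(1−K) for population prevalence K.  Outputs follow the GCTA `.par`
(causal effects) and `.phen` (per-individual phenotypes) text conventions.

Who is this for: statistical geneticists who need fast, reproducible
simulated phenotypes — ground truth for GWAS, fine-mapping or heritability
method development — on graph-encoded genotype panels.

## Worked example

```python
import grgsim

# synthetic panel: 500 diploid individuals, 2,000 variants
gm  = grgsim.generate_matrix(grgsim.FixtureSpec(500, 2000, seed=1))
grg = grgsim.build_from_matrix(gm)

pheno = grgsim.sim_phenotypes(grg, heritability=0.3, m_causal=200, seed=42)
print(pheno.df.head(3).to_string(index=False))
print(f"realized h2 = {pheno.realized_heritability():.3f}")
```

prints

```
individual_id  causal_mutation_id  genetic_value  environmental_noise  phenotype
         ind0                   0       0.020225            -0.912932  -0.892706
         ind1                   0       0.540770             1.343519   1.884289
         ind2                   0      -0.012347            -1.475016  -1.487363
realized h2 = 0.307
```

`causal_mutation_id` is the trait index (one row per individual per trait);
`genetic_value` is the standardized Xβ, `phenotype` its sum with the drawn
noise.  The realized heritability Var(genetic)/Var(phenotype) fluctuates
around the requested 0.3 for a single replicate and converges to it across
replicates.

The same pipeline is available from the shell:

```bash
grgsim construct panel.vcf -o panel.grg       # VCF -> GRG-lite text graph
grgsim inspect  panel.grg                     # counts + invariant check
grgsim simulate panel.grg --heritability 0.3 --num-causal 200 --seed 42 -o run
# -> run.phen, run.par, run.*.tsv, run.config.json
```

Multiple graphs (e.g. one per chromosome, identical sample order) can be
passed to `grgsim simulate`; their genetic values are combined additively
before noise is drawn.

## GRG-lite format

Graphs serialize to a versioned, line-oriented text format: a `#grglite 1`
header, an `H` record (2N, node count, mutation count), an `I` record
(individual ids), `M` records (mutation id, position, ref, alt, frequency)
and `N` records (node id, comma-separated children, comma-separated
mutation ids).  Round-trips are exact.

## Acceptance script

`scripts/acceptance.py` regenerates the headline check from scratch: it
builds a synthetic panel of 2,000 diploid individuals × 5,000 variants,
runs the end-to-end standardized simulation at heritability 0.3 with 500
causal mutations for 50 replicates, and reports the mean realized
heritability Var(Xβ)/Var(y):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
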