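# rbpgraph

Graph-kernel models of RNA-binding protein (RBP) binding preferences.

RBPs recognize their targets through sequence motifs that are often
conditioned on secondary structure — a pyrimidine tract in a hairpin loop is
not the same binding site as the identical tract in a paired stem.
High-throughput experiments (HITS-CLIP, PAR-CLIP, iCLIP *in vivo*;
affinity assays such as RNAcompete *in vitro*) deliver thousands of bound
sites or graded affinities, but they are noisy, tissue-dependent and
incomplete.  `rbpgraph` learns a binding model from such data and applies it
to new transcripts: it scores candidate sites, produces per-nucleotide
binding profiles, calls high-affinity sites, and summarizes what the model
learned as sequence and structure motif matrices.

## The model

Each binding site is extended by 150 nt of flanking sequence so it can fold
in a realistic context; the site itself is marked as the *viewpoint*.  The
context is folded in sliding 150-nt windows (step 37); per window, up to
three representative low-energy structures are kept — one per abstract
*shape* class (stem lengths ignored), each within 10% of the window minimum
free energy.  Every structure becomes a component of a directed graph:
nucleotide vertices joined by 5'→3' backbone and base-pair edges, plus an
abstract layer of structure elements — stem (S), hairpin (H), internal loop
(I), bulge (B), multiloop (M), external region (E) — attached to their
nucleotides through non-traversable relation vertices (the incident-graph
form of a hypergraph).  A mirrored copy with reversed edges and `r`-prefixed
labels keeps the encoding orientation-aware.

Features are pairs of neighborhood subgraphs: for radii *r* ≤ *R* and root
distances *d* ≤ *D*, every ordered root pair at directed distance *d*
contributes the feature (*r*, *d*, *N_r(u)*, *N_r(v)*), provided at least
one root lies in the viewpoint.  Canonical neighborhood labels are hashed
into 2^bits dimensions; vectors are block-normalized per (*r*, *d*, feature
set).  On these explicit features a linear model is trained — hinge-loss
stochastic gradient descent for bound/unbound classification, or
ε-insensitive support vector regression when graded affinities are
available.  The prediction margin w·x + b scores a site: positive predicts
binding, magnitude tracks affinity.

## Worked example

```python
from rbpgraph import SyntheticSpec, generate_classification_set, RBPBindingModel

spec = SyntheticSpec(n_pos=200, n_neg=200, seq_len=60, motif="ACGUACGU",
                     mutation_rate=0.0, seed=42)
sites = generate_classification_set(spec)

model = RBPBindingModel(sites, mode="sequence")
result = model.fit(seed=0)
print(result.summary())

cv = model.cross_validate(k=10, seed=0)
print(f"tenfold CV mean AUROC: {cv.mean_score:.3f}")

prof = result.profile(sites[0])
print(f"profile peak: position {int(prof.values.argmax())}")
```

prints

```
RBP binding preference model
==================================
task:            classification
encoding mode:   sequence
n sites:         400
kernel:          R=1 D=4 bits=20
fit params:      {'lambda_': 0.0001, 'epochs': 10, 'seed': 0}
nonzero weights: 2242
bias:            -1.89976
train auroc              1.0000
train average_precision  1.0000

tenfold CV mean AUROC: 1.000
profile peak: position 8
```

The cross-validated AUROC of 1.0 says held-out bound sites are perfectly
separated from unbound ones (the implanted motif is unmutated here; at 10%
per-position mutation the same experiment gives ≈0.94).  The profile peak at
position 8 falls inside the implanted motif (positions 4–12 of that site):
the margin decomposition localizes the binding signal.  Structure-aware
models work the same way with `mode="structure"`, and affinity data swap the
classifier for a regression via sites that carry `affinity` instead of
`label`.

The same pipeline is scriptable from the shell:

```
rbpgraph simulate --out-prefix sim --n-pos 200 --n-neg 200 --seed 1
rbpgraph train --sites sim.sites.tsv --mode sequence --seed 1 --out model.json
rbpgraph cv    --sites sim.sites.tsv --folds 10 --seed 1 --out cv.tsv
rbpgraph profile --model model.json --sites sim.sites.tsv --out profiles.tsv
rbpgraph callsites --profiles profiles.tsv --out calls.bed
rbpgraph motif --model model.json --sites sim.sites.tsv --out-prefix motif
```

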