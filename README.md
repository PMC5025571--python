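# countnorm

Scaling normalization of RNA-seq count matrices: one coherent
implementation of **TMM** (trimmed mean of M-values), **RLE**
(relative log expression, median of ratios to a geometric-mean
pseudo-reference) and **MRN** (median ratio normalization), plus
executable numeric checks of the designs under which the three methods
provably coincide, and a negative-binomial simulator for count
matrices with controllable composition bias.

It is written for bioinformaticians who need normalization factors
from a genes × samples count table without pulling in a full
differential-expression framework, and for anyone who wants to *see*,
numerically, how the three standard methods relate.

## The methods

Let `X[g, k, r]` be the read count of gene *g* in condition *k*,
replicate *r*, and `N[k, r]` the library size (column sum). All three
methods estimate, for each sample or condition, a relative
transcriptome size against a reference, from ratios of (pre-)normalized
counts `Y = X / N`:

| step | TMM | RLE | MRN |
|---|---|---|---|
| reference | one sample (upper-quartile rule or explicit) | per-gene geometric mean of raw counts over all samples | replicate-averaged `Y` of the reference condition |
| relative factor τ | doubly trimmed mean of ratios `Y[g,s]/Y[g,ref]` (M- and A-value tails trimmed) | median of `X[g,s]/pseudo-ref[g]` | median of `Ȳ[g,k]/Ȳ[g,ref]` |
| final size factor f | τ rescaled to unit product (depth **not** folded in) | the median itself (depth folded in) | `τ_k·N[k,r]` rescaled to unit geometric mean |
| normalized output | counts per million `X/e·10⁶` with `e = τ̃·N` | `X/f` | `X/f` |

Three equivalence properties are implemented as numeric verifiers
(`check_proposition1/2/3`):

1. with no replicates, TMM at a 50% M-trim / 0% A-trim (unweighted,
   reference = first sample) equals MRN's relative factors exactly;
2. with two conditions and no replicates, RLE and MRN size factors are
   equal (both reduce to `sqrt` of the median count ratio);
3. under both sets of conditions, RLE- and MRN-normalized counts and
   TMM's CPM agree elementwise up to the constant `sqrt(N1·N2)/10⁶`.

## Worked example

A 3 × 2 matrix whose columns are exactly proportional (second column =
4 × first):

```python
>>> import numpy as np, countnorm as cn
>>> cm = cn.CountMatrix(np.array([[1, 4], [4, 16], [9, 36]]),
...                     ["g1", "g2", "g3"], ["s1", "s2"], ["c1", "c2"])
>>> cn.library_sizes(cm)
array([14., 56.])
>>> cn.rle_size_factors(cm)
array([0.5, 2. ])
>>> cn.mrn_size_factors(cm).size_factors
array([0.5, 2. ])
>>> cn.tmm_relative_factors(cm, cn.TMMOptions(reference=0, m_trim=0.5, a_trim=0.0))[0]
array([1., 1.])
>>> cn.rle_normalize(cm, cn.rle_size_factors(cm))
array([[ 2.,  2.],
       [ 8.,  8.],
       [18., 18.]])
```

Sample 2 was sequenced 4 × deeper but contains the same transcriptome,
so RLE and MRN assign it a size factor of 2 (= √4, depth folded in)
while TMM's relative factor stays 1 (depth handled separately through
the effective library size); dividing by the RLE/MRN factors equalizes
the two columns.

The same operations are available from a shell:

```sh
countnorm simulate --genes 2000 --replicates 1 --de-fraction 0.3 \
    --de-up-share 1.0 --fold-change 4 --seed 7 \
    --out counts.tsv --conditions-out cond.tsv
countnorm normalize --method mrn --counts counts.tsv --conditions cond.tsv \
    --out factors.tsv
countnorm verify --counts counts.tsv --conditions cond.tsv \
    --proposition all --report report.tsv
```

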