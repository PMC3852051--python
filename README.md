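# coevomap

Maximum-likelihood mapping of paralogs between two putatively interacting
protein families.

## The problem

Coevolution-based prediction of protein–protein interactions compares the
evolutionary histories of two protein families: if the families interact,
selection keeps their rates of sequence divergence in step. With one member
per species the correspondence between families is trivial, but gene
duplication produces *paralogs* — several same-species members per family —
and then the mapping between the families is ambiguous. `coevomap` resolves
that ambiguity by finding the one-to-one, same-species matching between the
two families that maximises a likelihood built from *units of coevolution*.

A unit of coevolution is a pair of mapped pairs ((a, b), (a′, b′)). Writing
Δ_A(a, a′) for the number of mismatched alignment columns between a and a′
and ℓ_A(a, a′) for the number of comparable (gap-free in both rows)
columns, and likewise Δ_B, ℓ_B for the other family, the unit's value is
the hypergeometric probability of the observed mismatch split under the
hypothesis H of equal evolutionary rates:

    f(Δ_A, Δ_B) = C(ℓ_A, Δ_A) · C(ℓ_B, Δ_B) / C(ℓ_A + ℓ_B, Δ_A + Δ_B)

The likelihood of a matching θ is the product of f over all pairs of its
edges, and the estimate θ* maximises it over all maximum-cardinality
matchings of the species-constrained bipartite graph. After an offset
shift that makes all quadruple weights strictly positive, the resulting
binary quadratic program is solved by a Lagrangian relaxation whose master
and local subproblems are maximum-weight bipartite matchings. The solver
returns the best matching found together with certified lower and upper
bounds on the optimal log likelihood, so every run reports a relative
optimality gap — and, frequently, a proof of optimality.

## Worked example

```python
from coevomap import SynthConfig, generate, ParalogMatchingModel

fam_a, fam_b, truth = generate(
    SynthConfig(n_species=3, paralogs_per_species=(2, 3), seed=7)
)
model = ParalogMatchingModel(fam_a, fam_b)
res = model.fit()
print(res.summary())
rep = res.evaluate_against(truth)
print(f"recall={rep.recall:.1f}%  precision={rep.precision:.1f}%")
```

prints

```
Maximum-likelihood paralog mapping
==================================================
families:            synthA / synthB
species shared:      3
candidate edges:     24
matching size n:     8
units of coevolution: 28
method:              lagrangian
log likelihood:      -84.902221
upper bound:         -84.902221
relative gap:        0.000e+00
proved optimal:      True
iterations:          2
avg unit log lik.:   -3.032222
--------------------------------------------------
family_A_id         family_B_id         species       coevo_degree
A00p0_SP00          B00p0_SP00          SP00               -2.8691
A00p1_SP00          B00p1_SP00          SP00               -2.7502
A00p2_SP00          B00p2_SP00          SP00               -2.6052
A01p0_SP01          B01p0_SP01          SP01               -3.2546
A01p1_SP01          B01p2_SP01          SP01               -2.8194
A01p2_SP01          B01p1_SP01          SP01               -3.6915
A02p0_SP02          B02p0_SP02          SP02               -3.4335
A02p1_SP02          B02p1_SP02          SP02               -2.8343
recall=75.0%  precision=75.0%
```

The fit is *proven* optimal (upper bound equals the log likelihood, gap 0):
the two swapped pairs in species SP01 are not a solver failure but a case
where two paralogs of that species happened to diverge at nearly the same
rate, so the data genuinely favour the swap. `coevo_degree` is each pair's
mean unit log score — its personal degree of coevolution with the rest of
the matching (closer to 0 is better).

The same pipeline runs from the shell on FASTA input:

```bash
coevomap simulate --n-species 4 --seed 1 --out-prefix demo
coevomap map --family-a demo_A.fasta --family-b demo_B.fasta \
             --out demo_pred.tsv --report demo_report.json
coevomap eval --family-a demo_A.fasta --family-b demo_B.fasta \
              --predicted demo_pred.tsv --reference demo_truth.tsv
```

Species labels are read from SwissProt-style `NAME_SPECIES` header suffixes
or from an explicit two-column TSV (`--species-a/--species-b`).

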