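# causalem

Causal-strength measures and causal emergence for discrete Markovian
systems.

Many quantitative notions of "how strong a cause is" have been proposed
across philosophy, psychology, statistics and information theory —
probability raising, causal power, weight of evidence, relative risk,
counterfactual closest-possible-world accounts, effect/effective
information, bit-flip perturbation sensitivity. For a system whose
dynamics are fully described by a row-stochastic transition probability
matrix (TPM) over a finite state space Ω — entry `P(e | do(c))` being the
probability of effect state *e* after intervening to set cause state *c* —
all of these measures can be written in terms of a small set of shared
*causal primitives*:

- sufficiency `suff(e,c) = P(e|c)` and necessity `nec(e,c) = 1 − P(e|C\c)`,
- their information-theoretic extensions, the determinism coefficient
  `det(c) = 1 − H(E|c)/log₂ n` and degeneracy coefficient
  `deg = 1 − H(E|C)/log₂ n` (entropies in bits).

Every measure additionally needs an **intervention distribution** `P_C`
over causes — the space of counterfactuals probed. Three constructions
are provided: maximum-entropy (uniform), observational (the stationary
distribution π = πT), and local (uniform on a Hamming ball of radius Δ
around the actual state).

Given a coarse-graining *h* from micro states onto macro states, the
package quantifies **causal emergence** as

```
CE = CS_macro − CS_micro
```

for any catalogued measure CS: positive CE means the dimensionally
reduced macroscale carries the *stronger* causal relationship (macroscale
error correction of microscale noise); negative CE is causal reduction.
Two rule-generated model systems are included for systematic study — a
bipartite Markov chain whose determinism and degeneracy are tuned by
dilution/rewiring knobs while its two-group macroscale stays a perfect
flip-flop, and a noisy NAND gate network.

## Worked example

Score the main transition `0000 → 1111` of the 16-state bipartite model
at intermediate noise (dilution 0.5, rewiring 0.5) under a local
intervention distribution (Hamming radius 1), then ask whether the weak
secondary transition `0000 → 1110` is causally emergent at the macroscale:

```python
from causalem import (BipartiteSpec, CoarseGraining, Transition, bipartite_model,
                      bipartite_macro_mapping, causal_emergence, compute_measure,
                      local_distribution)

spec = BipartiteSpec(8, 8, dilution=0.5, rewiring=0.5)
model = bipartite_model(spec)
pc = local_distribution(model.space, "0000", 1)
for name in ("eells", "cheng", "effect_information"):
    r = compute_measure(name, model, pc, Transition("0000", "1111"))
    print(f"{name:>20}  {r.value:.4f}")

cg = CoarseGraining.from_mapping(spec.space(), bipartite_macro_mapping(spec))
rep = causal_emergence("eells", model, cg,
                       transition=Transition("0000", "1110"), intervention="local")
print(f"micro {rep.cs_micro:.4f}  macro {rep.cs_macro:.4f}  CE {rep.ce:.4f}  {rep.sign}")
```

prints

```
               eells  0.3906
               cheng  0.4717
  effect_information  1.1699
micro -0.1094  macro 1.0000  CE 1.1094  emergence
```

The main transition is a solidly positive cause under every measure
(e.g. it raises the effect's probability by 0.39 over its local
counterfactuals and specifies 1.17 bits about the next state). The
secondary transition is *preventive* at the microscale (Eells value
−0.11) yet maps onto the perfect macro cause ON → OFF (value 1), so the
macroscale wins by 1.11: causal emergence.

The same machinery is scriptable from the shell:

```
causalem generate --model nand --nodes 2 --noise 0.1 \
    --out-tpm nand.csv --out-mapping nand_map.csv
causalem measures --tpm nand.csv --measure all --intervention maxent --out out.csv
causalem emergence --tpm nand.csv --mapping nand_map.csv --measure eells \
    --cause 00 --effect 11 --intervention local --out ce.csv
causalem sweep --config sweep.yaml --out sweep.csv
```

TPMs are plain CSVs (header = effect labels, first column = cause
labels); mappings are two-column `micro_state,macro_state` CSVs. All
outputs are long-format tidy tables plus a JSON manifest; everything is
rule-generated, so reruns are byte-identical.

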