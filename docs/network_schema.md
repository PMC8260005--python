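# Network JSON schema (version 1)

`crossfeed.networks.network_to_json` / `network_from_json` serialize a
`ReactionNetwork` to a versioned JSON document:

```json
{
 "schema_version": 1,
 "n": 10,
 "n_enzyme": 2,
 "enzyme_indices": [1, 2],
 "nutrient_indices": [0],
 "growth_rule": "designated_growth_reactions",
 "names": null,
 "reactions": [
  {
   "substrate": 3,
   "product": 4,
   "catalyst": 1,
   "k": 1.0,
   "r": 0.0,
   "substrate_coef": 1.0,
   "product_coef": 1.0,
   "co_substrates": [],
   "byproducts": []
  }
 ]
}
```

Field notes:

- `n`: number of chemicals; indices run 0..n−1.  For random networks
  the nutrient is chemical 0, enzymes are 1..n_enzyme, and the
  remaining indices are non-nutrient metabolites.
- `nutrient_indices`: externally supplied chemicals (usually one; the
  minimal bioreaction model has two).
- `growth_rule`: `designated_growth_reactions` (biomass reactions have
  `product: null`) or `enzyme_synthesis_total`.
- `reactions[*].product`: chemical index, or `null` for a biomass sink.
- `r`: reversibility; the reverse rate constant is `r * k`.  Only plain
  one-substrate/one-product reactions may be reversible.
- `co_substrates` / `byproducts`: `[index, coefficient]` pairs for
  coarse-grained multi-substrate reactions; co-substrates enter the
  rate law with one concentration factor each, byproducts do not.
- Documents with a `schema_version` greater than the library's are
  rejected; older documents load with defaults for missing fields.

`network_to_graphml` exports the conversion graph (nodes annotated with
`label` and `role`, edges with `catalyst`, `k`, `r`) for visualization;
GraphML is write-only and never read back.
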