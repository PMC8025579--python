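# hlindex — a Healthy Location Index for small areas

`hlindex` builds an area-level **Healthy Location Index (HLI)**: a
nine-class typology describing how accessible health-promoting and
health-constraining environments are from each small census area
("meshblock", ~60–120 residents). It is aimed at health geographers and
epidemiologists who need a transparent, rank-based exposure measure —
and a fully synthetic test bed for it.

Ten environmental domains are used:

* **'goods'** (health-promoting): green space, blue space,
  physical-activity facilities, fruit/vegetable outlets, supermarkets;
* **'bads'** (health-constraining): fast-food outlets, takeaway outlets,
  dairy/convenience stores, alcohol outlets, gaming venues.

## The index

For meshblock *i* and facility domain *d*, access is the road-network
distance from the meshblock's population-weighted centroid to the nearest
outlet. Green and blue space are area phenomena: their access is the
median, over the meshblock's 50 m raster cells, of the Euclidean
distance-transform to the nearest covered cell.

Each domain's distances are ranked 1..N (1 = closest; ties broken by
meshblock id). With R<sub>id</sub> the rank of meshblock *i* in domain
*d*, the two unweighted composites are

&nbsp;&nbsp;S<sub>i</sub><sup>goods</sup> = Σ<sub>d∈goods</sub> R<sub>id</sub>,&nbsp;&nbsp;
S<sub>i</sub><sup>bads</sup> = Σ<sub>d∈bads</sub> R<sub>id</sub>,

each re-ranked 1..N and cut into equal-count deciles
(decile = ⌈10·rank/N⌉; decile 1 = best access). Deciles collapse to
three categories (1–3 → 1, 4–7 → 2, 8–10 → 3) and the pair
(goods category – bads category) gives one of nine labels:
**"1–3"** (best goods access, worst bads access) is the healthiest class,
**"3–1"** the unhealthiest.

The synthetic-region generator plants a controllable deprivation gradient
(`gradient_strength`): with positive strength, 'bads' (and, mildly,
supermarkets and physical-activity facilities) are denser in more
deprived areas, emulating the social patterning observed in national
food-environment registers.

## Worked example

```python
from hlindex import (GeneratorConfig, generate_region, build_access_table,
                     compute_hli, population_share_by_hli)

region = generate_region(GeneratorConfig(n_meshblocks=500, seed=1))
table = build_access_table(region)      # 500 x 10 distances, km
result = compute_hli(table)
print(result.records["hli_label"].value_counts().sort_index())
```

```
hli_label
1–1    59
1–2    63
1–3    28
2–1    50
2–2    85
2–3    65
3–1    41
3–2    52
3–3    57
Name: count, dtype: int64
```

All nine classes occur. Balanced classes ("2–2") dominate, and the
planted gradient makes the extremes rare: few meshblocks combine the best
access to one polarity with the worst access to the other, because goods
and bads co-occur in space. Population shares per class, by deprivation
quintile or urban/rural class, come from
`population_share_by_hli(result.records, region.meshblock_frame(), ...)`.

The same pipeline is scriptable from the shell:

```bash
hli simulate --n 500 --gradient 0.8 --seed 1 --out region/
hli access   --region region/ --out access.csv
hli index    --access access.csv --out hli.csv
hli summarise --hli hli.csv --region region/ --out summary/
# or end to end, with a manifest:
hli run --n 500 --seed 1 --out out/
```

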