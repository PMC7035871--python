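# grazescape

Coupled remote-sensing and stable-isotope analysis of herbivore diet along a
savanna woody-cover gradient.

`grazescape` is for ecologists asking whether a large herbivore's grass
intake tracks the grass available around its feeding sites, and how that
tracking changes with season and spatial scale. It implements the full
chain from a categorical land-cover map to a seasonal significance test:

1. **Land cover** — random-forest classification of a dual-date (senescent +
   flushed) 12-band reflectance composite into a nine-class nomenclature
   that stratifies the forest→grassland gradient at 25% woody-cover
   intervals (CDW, ODW, DG, CG, plus non-gradient classes), with standard
   confusion-matrix accuracy assessment (overall, user's, producer's).
2. **Buffers** — per-class composition of concentric circular buffers
   (default radii 2, 4, 8, 12 km — the daily-range scale and its
   neighbours) around each faecal sample site, pixel-centre membership,
   explicit valid-fraction accounting at edges and nodata.
3. **Grassiness index** — `G = Σ pct(class) × modifier`, modifiers ×1 (closed
   deciduous woodland) … ×4 (continuous grassland); range 0–400.
4. **Isotopes** — two-endmember mixing model converting faecal δ13C (‰ VPDB)
   to %C4 intake: `%C4 = 100·((δ_faeces − ε) − δ_C3)/(δ_C4 − δ_C3)`, with
   diet–faeces discrimination ε and optional season/region endmember
   overrides.
5. **Permutation regression** — locality-blocked resampling of the OLS of
   %C4 on G: each of 10³ iterations draws one specimen per
   locality × sampling-interval unit, giving permuted means and 95%
   confidence limits for r², intercept and slope, the Monte Carlo
   significance `p̂ = 1 − #(p < 0.05)/10³`, and one-tailed dry-vs-wet
   comparisons (null: dry ≤ wet). This removes the bias from repeated
   collections at a locality.

A synthetic-data module generates autocorrelated landscapes and faecal
sample tables with exactly this statistical structure, so the whole pipeline
is testable end-to-end without imagery or field data. See
[docs/methods.md](docs/methods.md) for models, defaults and limitations.

## Worked example

```python
import grazescape as gz
from grazescape.permstats import permutation_regression, compare_seasons

# synthetic 40x40 km landscape and two-and-a-half thousand faecal samples
landscape = gz.generate_landscape(gz.LandscapeSpec(seed=42))
samples = gz.generate_samples(landscape, diet=gz.DietModelSpec(seed=42))

df = samples.rename(columns={"pct_c4_true": "pct_c4",
                             "grassiness_true": "grassiness"})
df["interval"] = df["date"].str[:7]

dry = permutation_regression(df, season="dry", iterations=1000, rng=1)
wet = permutation_regression(df, season="wet", iterations=1000, rng=2)
comp = compare_seasons(dry, wet, "slope")

print(f"n specimens: {len(df)}, dry units: {dry.n_units}, wet units: {wet.n_units}")
print(f"dry slope: {dry.means['slope']:.4f} "
      f"({dry.cl['slope'][0]:.4f}-{dry.cl['slope'][1]:.4f}), p_hat {dry.p_hat:.3f}")
print(f"wet slope: {wet.means['slope']:.4f} "
      f"({wet.cl['slope'][0]:.4f}-{wet.cl['slope'][1]:.4f}), p_hat {wet.p_hat:.3f}")
print(f"one-tailed dry>wet slope p: {comp.p_one_tailed}")
```

Output:

```text
n specimens: 2568, dry units: 300, wet units: 300
dry slope: 0.0992 (0.0988-0.0996), p_hat 0.000
wet slope: 0.0470 (0.0465-0.0474), p_hat 0.000
one-tailed dry>wet slope p: 0.0005
```

The generator's dry-season diet response (slope 0.10 %C4 per grassiness
unit) is recovered as 0.0992 with a tight resampling interval; the weak wet
response (0.04) as 0.0470; and the seasonal contrast is significant at the
Monte Carlo floor — dry-season diets track landscape grassiness far more
strongly than wet-season diets, which is the pattern the framework is built
to detect.

The same analysis runs from the shell:

```bash
grazescape simulate --out demo --seed 42
grazescape buffers --lc demo/landcover.asc --samples demo/samples.csv \
    --radii 2000,4000,8000,12000 --out demo/profiles.csv
grazescape grassiness --profiles demo/profiles.csv --out demo/g.csv
grazescape permtest --data merged.csv --iterations 1000 --seed 1 --out table.csv
grazescape run --config run.yaml      # full pipeline with a YAML config
```

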