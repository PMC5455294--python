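# seedmorph

Seed-silhouette morphometrics and multivariate discrimination for the ten
European species of *Elatine* (waterwort).

*Elatine* are tiny amphibious annuals whose vegetative characters are so
plastic that seeds are the one reliable basis for identification: the seed's
curvature and the reticulate sculpture of its coat separate the species.
`seedmorph` implements that workflow end to end for anyone working with seed
silhouettes (taxonomists, palaeoecologists identifying subfossil seeds,
morphometricians):

* **six shape descriptors** measured from a binary silhouette — surface
  area *S* (µm²), profile (perimeter) *P* (µm), the sides *a* ≥ *b* of the
  minimum-area enclosing rectangle (µm), the curvature angle γ of the
  seed's long axis (degrees, 0° straight to ~350° horseshoe), and the pit
  count *f* along the seed coat's middle row;
* **discrimination statistics**: Wilks Λ = det **W** / det **T** with Rao's
  F approximation, per-variable partial Λ / F-to-remove / tolerance,
  squared Mahalanobis distances D² between group centroids under the pooled
  within-group covariance, UPGMA dendrograms, classical (Torgerson)
  multidimensional scaling, canonical variates and resubstitution
  classification matrices;
* **nonparametric group tests**: tie-corrected Kruskal–Wallis H per trait
  with pairwise letter-code matrices, SD tables, and 1.5·IQR boxplot
  summaries in the "(min–)q25–q75(–max)" notation of the species
  descriptions;
* an executable **dichotomous identification key** (ten couplets over γ,
  pit count, length and width) plus the published per-species range cards,
  population coordinates and classification matrices as built-in reference
  data;
* a **synthetic seed generator**: constant-width circular-arc bands with
  semicircular caps (closed forms: S = Lw + π(w/2)², P = 2L + πw) and
  trait tables sampled from the range cards via truncated normals
  (σ = IQR/1.349), so the whole pipeline is testable with analytic ground
  truth and no raw images.

The discriminant machinery follows the scikit-learn estimator protocol
(`SeedDiscriminantAnalysis`, `KeyClassifier` with `fit`/`predict`/
`transform`) and composes with sklearn pipelines; module-level functions
(`wilks_lambda`, `mahalanobis_matrix`, `lda_classify`, …) are thin wrappers.

## Worked example

```python
import seedmorph as sm

table = sm.sample_trait_table(sm.builtin_species_cards(), n_per_species=50, rng_seed=1)
model = sm.fit_discriminant(table, "species")
print(model.wilks_report_)
print(model.diagnostics_[["partial_lambda", "F_to_remove", "tolerance"]].round(4))
print(sm.upgma_from_squared(model.mahalanobis_sq_).newick()[:120], "...")
d = sm.classify_traits({"length": 815, "width": 316, "angle": 80, "pits": 35})
print(d.species, [step[0] for step in d.path])
```

prints

```
lambda = 0.00100  F(54, 2477) = 132.04  p = 0
                partial_lambda  F_to_remove  tolerance
trait
surface_um2             0.6566      28.1802     0.1550
profile_um              0.7260      20.3388     0.2788
rectangle_a_um          0.3467     101.5316     0.7201
rectangle_b_um          0.6321      31.3696     0.2356
angle_deg               0.3826      86.9626     0.6203
pits                    0.3176     115.7843     0.9900
(((('E. alsinastrum':1.815961105,'E. orthosperma':1.815961105):0.3975669081,('E. hexandra':0.8839369976,'E. macropoda':0 ...
E. orthosperma [1, 2]
```

Reading it: Λ ≈ 0.001 says the ten species are almost perfectly separated
in six-trait space; pit count and curvature-related traits carry the
largest F-to-remove (unique discriminating contribution), while surface and
profile have low tolerance (they are nearly redundant with the rectangle
sides). The UPGMA tree pairs the classically confusable species first.
The key call identifies a straight, many-pitted seed as *E. orthosperma*
through couplets 1 → 2.

A CLI mirrors the library: `seedmorph simulate | measure | analyze | key |
span` (see `seedmorph --help`).

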