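# gapatlas

Quantification and comparison of **gap-gene expression boundaries** in
dipteran blastoderm embryos.

During the blastoderm stage, the trunk gap genes *hunchback* (*hb*),
*Krüppel* (*Kr*), *knirps* (*kni*) and *giant* (*gt*) are expressed in broad,
staggered domains along the antero-posterior (A–P) axis. Comparative and
perturbation studies of this system work from a common measurement chain:
embryo images are reduced to 1-D intensity profiles along the dorso-ventral
midline, each domain edge is localised as the position of half-maximal
expression, per-embryo positions are pooled into a spatio-temporal atlas,
and RNAi knock-down cohorts are scored against the wild-type atlas to
reconstruct a signed, strength-annotated gene interaction network.
`gapatlas` implements that chain as a tested, reusable library with a thin
CLI, and ships a synthetic embryo generator with known ground truth so
every stage can be validated without any external data.

## The measurement model

All positions are percent egg length (%EL), with 0% at the anterior pole.

- **Profile extraction.** The A–P axis is the principal axis of the embryo
  mask; a strip covering 10% of the local dorso-ventral mask extent is
  taken along the D–V midline and binned into 100 bins of 1 %EL. Profiles
  are normalised by percentile scaling (5th percentile → 0, 95th → 1).
- **Boundary localisation.** Each candidate edge window is fitted with a
  *clamped spline* — a monotone cubic Hermite segment with zero slope at
  both window ends, free plateau levels, and window ends adjustable by
  ±2 %EL. The boundary is the half-maximal crossing of the fitted cubic,
  which for this symmetric segment is the window midpoint:

      f(x) = lo + (hi − lo) · (3t² − 2t³),   t = (x − x₀)/(x₁ − x₀)

- **Aggregation.** Per gene × domain edge × time class (cleavage cycles
  C10–C13, then T1–T8 within cycle 14A): the median position across
  embryos, with variability reported as **1.5 × MAD** (median absolute
  deviation), which approximates one standard deviation for roughly
  normal scatter.
- **Comparison metrics.** Domain widths, signed boundary shifts (positive
  = anterior movement), inter-domain overlaps, and the time class at
  which two datasets' boundaries first converge persistently.
- **RNAi scoring.** A wild-type envelope (median ± 2 × variability) turns
  per-embryo boundary sets into phenotype labels (expansions,
  displacements, retraction failures, reduction, absence), penetrance
  tables, and severity-ordered allelic series; per knock-down→stained
  pair the evidence condenses into repression/activation edges classed
  strong/weak (median severity ≥ 5 %EL with penetrance ≥ 50% is strong).

## Worked example

```python
import gapatlas as ga

# a central Kr domain spanning 40-63% A-P, rendered as an embryo image
prof, truth = ga.make_profile([ga.DomainSpec("Kr", "central", 40, 63)])
embryo = ga.make_embryo_image(prof, seed=1)

from gapatlas.profiles import EmbryoImage, extract_profile
image = EmbryoImage(pixels=embryo.image, mask=embryo.mask, gene="Kr")
(domain,) = ga.fit_profile(extract_profile(image), gene="Kr")
print(f"{domain.a_position:.2f} {domain.p_position:.2f} "
      f"width {domain.p_position - domain.a_position:.2f}")
```

prints

```
39.95 63.06 width 23.10
```

— the full render → strip → fit chain recovers the generating edges to a
few hundredths of a percent egg length, and the recovered width matches
the 23 %EL of the early central *Kr* domain. Running the packaged
perturbation study end to end:

```sh
gapatlas study --seed 0 --out study/
```

prints `{"posterior_bias": 2.0, "n_edges": 12, "seed": 0}` and writes the
atlas, penetrance table and the inferred network (`network.tsv`,
`network.dot`): all six generated strong interactions are recovered at
the correct sign, and the positive `posterior_bias` reflects the
built-in asymmetry of repression acting from posterior onto anterior
neighbouring domains.

The CLI also exposes `simulate`, `extract`, `aggregate`, `plot` and `run`
(full pipeline over a manifest TSV of images plus a YAML config); every
output table carries a provenance header (package version, config hash,
seed) and reruns are byte-identical.

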