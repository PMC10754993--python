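# gpcochlea

Guinea-pig scala tympani (ST) volumetry and cochlear-implant (CI) dosing
toolkit.

The guinea pig is the standard animal model for inner-ear pharmacotherapy,
yet drug doses are usually planned against a single textbook perilymph
volume even though individual ST volumes vary by ~15% (relative standard
deviation). Because intracochlear drug concentration is set by the
perilymph volume — further reduced by the volume a CI electrode array
displaces — that variability translates directly into dose variability.
This package implements an estimation chain that replaces full manual μCT
segmentation with two easily measured footprint parameters, plus the
geometry pipeline to derive everything from segmentation contours when you
do have them.

## The model

For a cochlea with basal footprint diameter *A* and width *B* (mm):

1. **Basal turn length** via the elliptic-circular approximation (ECA):
   `BTL = 1.18·A + 2.69·B − 0.72·√(A·B)`  (the product-form cross term is
   available as a variant; see `ECACoefficients`).
2. **Basal-turn volume**: `V(360°) = 1.38·BTL − 8.36` μL.
3. **Full profile** `V(θ)`, θ ∈ [0°, 1080°], by one of three methods:
   * `mean` — a packaged canonical mean profile (anchored at 4.4 μL at
     360° and 5.3 μL at 1080°; the basal turn holds 83% of the total),
     ignoring the individual footprint;
   * `log` — a logarithmic curve `a·ln(1 + θ/b)` rescaled to the
     individual V(360°);
   * `scaling` (recommended) — the normalized mean profile rescaled to the
     individual V(360°).

Around an inserted electrode (tapered frustum, tip-first; insertion depth ↔
insertion angle by linear regression) the perilymph is partitioned into
volumes **basal** to the implant (cochleostomy pocket), **surrounding** it,
and **apical** to it, with the array's displaced volume (optionally
including a coating) accounted separately. Dosing helpers convert target
concentrations into drug masses and bolus volumes.

The geometry pipeline consumes midmodiolar segmentation contours (22.5°
angular stations about the modiolar axis), computes cross-sectional areas
(shoelace), the cumulative volume by the conical-frustum rule
`d·(Aᵢ + Aᵢ₊₁ + √(AᵢAᵢ₊₁))/3` along the centroid path, the lateral-wall
curve, and extracts *A*/*B* from the basal-turn wall projection.

Everything is testable without real scans: `gpcochlea.synthetic` generates
helical cochleae with analytically known volume and footprint, cohorts
matching the published population statistics, and insertion datasets.

## Worked example

```sh
$ gpcochlea volume --A 3.8 --B 2.8 --method scaling --out vol.json
BTL = 9.667 mm, V(360°) = 4.981 μL, V(1080°) = 6.000 μL → vol.json
```

A mean-sized footprint (A = 3.8 mm, B = 2.8 mm) gives a basal turn of
9.67 mm, a basal-turn perilymph volume of 4.98 μL and a three-turn total
of 6.00 μL. Insert the default array (5 mm long, 0.3/0.6 mm diameters)
through the round window to 360°:

```sh
$ gpcochlea implant-plan --A 3.8 --B 2.8 --eid 5 --ia 360 --out part.json
basal 0.0000 | surrounding 4.1564 | apical 1.0189 | implant 0.8247 (total 5.9999 μL)
```

The array displaces 0.82 μL, leaving 4.16 μL of perilymph alongside it and
1.02 μL beyond the tip. To reach 100 μM dexamethasone (392.46 g/mol) in the
surrounding volume:

```sh
$ gpcochlea dose --concentration 0.0001 --volume 4.1564 --molar-mass 392.46
required drug amount: 0.163122 μg
```

The same computations are available as library calls
(`gpcochlea.estimate_profile`, `gpcochlea.partition_perilymph`,
`gpcochlea.required_drug_amount`, …); `segment-analyze`, `simulate`,
`loocv` and `compare-groups` subcommands cover the segmentation-driven and
evaluation workflows.

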