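# ecoloc

Ecological measurement of immune–cancer cell colocalization in digital
pathology, and its prognostic evaluation.

## The problem

Immune cell *abundance* in tumors is a well-established prognostic signal,
but abundance ignores geography: two tumors with identical lymphocyte
fractions can have their immune cells packed against the cancer cells or
segregated into distant stroma. `ecoloc` treats a classified cell map of a
tumor section (cancer / immune / stromal-other cells at μm coordinates, as
produced by any upstream H&E image classifier) as a two-species ecological
community and asks how strongly the two species share space.

The section window is divided into non-overlapping polygons — 250 μm × 250 μm
squares by default (on the order of effective cell–cell communication
distances), or a Voronoi tessellation — and the cancer count `x_i` and immune
count `y_i` are recorded per polygon `i`, excluding polygons with too little
tissue. Colocalization is the Morisita–Horn similarity of the two count
vectors:

```
MH = 2 Σᵢ xᵢyᵢ / ( (Σᵢxᵢ²/X² + Σᵢyᵢ²/Y²) · X · Y ),   X = Σᵢxᵢ, Y = Σᵢyᵢ
```

`MH = 1` when the two populations have identical relative spatial
distributions (e.g. equal numbers of cancer and immune cells in every
square) and `MH = 0` when they never co-occupy a polygon. It is symmetric
and invariant to the overall abundance of either species, so it isolates
*where* the immune cells are from *how many* there are. Pearson correlation
of the paired counts and the plain immune-abundance fraction (dichotomized
at 8 %) are computed alongside as comparators.

Prognostic value is quantified with the standard discovery/validation
biomarker protocol: the continuous score is dichotomized at the cutoff with
the smallest log-rank p among the discovery cohort's 20th–80th score
percentiles in steps of 1.5 (41 candidates); the winning cutoff is frozen
and applied unchanged to the validation cohort, where Kaplan–Meier curves,
log-rank tests and Cox proportional-hazards models (univariate, and
multivariate with lymph-node status, tumor size and grade; Efron ties)
measure the effect. Follow-up is administratively censored at 120 months.
Robustness is probed by patient-level bootstrap (fraction of subsample
replicates retaining p < 0.05) and by recomputing the index on 75/50/25 %
contiguous portions of the tissue.

Because the clinical data this analysis was designed for are
controlled-access, the package ships a first-class synthetic generator: a
Thomas cluster process in which a dial ρ ∈ [0, 1] moves immune cells from
independent immune-only clusters (segregated, low MH) onto the cancer-cell
clusters (colocalized, high MH), linked to Weibull proportional-hazards
survival in which crossing a ρ threshold confers a protective hazard ratio.

## Worked example

```
$ ecoloc simulate --n-discovery 100 --n-validation 100 --sections 1 \
    --effect-hr 0.25 --seed 11 --out-cells cells.csv --out-clinical clinical.csv
wrote 870269 cells for 200 patients

$ ecoloc score cells.csv --out scores.csv
scored 200 patients -> scores.csv

$ ecoloc cutoff scores.csv clinical.csv
{
  "measure": "morisita",
  "chosen_cutoff": 0.7115749572731678,
  "chosen_percentile": 42.5,
  "n_candidates": 41
}

$ ecoloc survive scores.csv clinical.csv --cutoff 0.7115749572731678
{
  "cohort": "validation",
  "cutoff": 0.7115749572731678,
  "n_high": 61,
  "n_low": 39,
  "logrank_p": 0.030175313352842723,
  "hr": 0.4027644570257618,
  "ci": [0.17204029364792053, 0.942914037191993],
  "cox_p": 0.03613524297922721
}
```

Reading the numbers: the generator gave each patient a colocalization level
ρ ~ U(0, 1) and a four-fold hazard reduction above ρ = 0.5. The cutoff
search, seeing only the discovery half, picked the Morisita value 0.71 (the
42.5th score percentile) — close to the generative change-point. Applied
unchanged to the held-out validation half, the high-colocalization group
has hazard ratio 0.40 (95 % CI 0.17–0.94, log-rank p = 0.030): high
immune–cancer colocalization predicts better survival, and the frozen-cutoff
protocol detects it out of sample.

The same stages are available as library functions
(`ecoloc.morisita_horn`, `ecoloc.optimal_cutoff_search`,
`ecoloc.cox_fit`, …), and `ecoloc run config.yaml` chains the full
pipeline — subtype and treatment strata, measure comparison, bootstrap and
tissue-subsampling robustness — writing `report.json`, per-term Cox tables
and exported KM curves.

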