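# neuroenergetics

Regional analysis of brain energetics from simultaneous PET/MRI: relative
energy production (rEP) and relative aerobic glycolysis (rAG) metrics,
cross-validated age-related spatial covariance patterns, and comparison with
neurodegenerative disease-related metabolic patterns.

## Who this is for

Imaging neuroscientists with regional tables of cerebral glucose metabolism
(CMRglu, from dynamic FDG-PET) and cerebral blood flow (CBF, from arterial
spin labelling) across a cohort spanning a broad age range, who want to ask:
*which regions restructure their energy production with age, and does that
topography resemble known disease patterns?*

## The method

**Energetics metrics.** Within each subject, regional CMRglu and CBF are
z-scored across regions and rotated 45° in the (z(CBF), z(CMRglu)) plane:

    rEP = (z(CBF) + z(CMRglu)) / √2        (concurrence: energy production)
    rAG = (z(CMRglu) − z(CBF)) / √2        (discordance: aerobic glycolysis)

rEP is the projection onto the line of unity — regions where relative flow
and metabolism are concurrently high produce relatively more energy.  rAG
measures the orthogonal departure: relative glucose use exceeding relative
flow suggests a glycolytic preference, and — because regional CMRO₂ tracks
CBF under spatially uniform oxygen extraction — relatively elevated aerobic
glycolysis.  Both are purely *spatial* measures, invariant to each subject's
global scale.

**Age-related patterns (SSM-PCA).** A subjects × regions metric matrix is
double-demeaned (Scaled Subprofile Model residual profile), decomposed by
PCA into spatial patterns with subject scores, and the components (filtered
at >5% variance accounted for and younger/older score separation p<0.2) are
recombined by AIC-guided forward-stepwise logistic regression into one
pattern whose expression maximally separates younger (≤60 y) from older
(>60 y) subjects.  500 iterations of stratified five-fold cross-validation
give the final weights (mean across folds) and their stability (SD across
folds); final scores project the full-cohort residual profile onto the
pattern.

**PLSC validation.** Partial Least Squares Correlation — SVD of the
correlation matrix between regional values and clinical variables (age,
sex) — provides an independent route to the same topography, with
permutation significance and bootstrap stability.

**Disease-pattern comparison.** Subject expression of external patterns
(e.g. PDRP/PDCP/ADRP region weights with a group mean profile) is scored by
a regionalized Topographic Profile Rating, `rSRP = log rCMRglu − rGMR −
rGMP` projected onto the pattern weights; spatial similarity uses Spearman
ρ, expression similarity Pearson ρ, with Bonferroni adjustment over the
comparison family.

A kinetic front-end (Patlak graphical estimation of the FDG net uptake rate
Ki, CMRglu = Ki·Cglu/LC with LC = 0.65, simplified image-derived input
function, ROI aggregation, anterior/middle/posterior putamen subdivision)
turns dynamic and volumetric inputs into the regional tables, and a
synthetic-cohort generator provides statistically faithful test data, since
no subject data ships with the package.

## Worked example

```bash
neuroenergetics simulate --out cohort
neuroenergetics derive-pattern --in cohort --metric rep --iters 500 --seed 11 --out rep_pattern.json
neuroenergetics derive-pattern --in cohort --metric rag --iters 500 --seed 11 --out rag_pattern.json
neuroenergetics plsc --in cohort --metric rep --seed 11 --out plsc_rep.json
```

prints

```
wrote cohort (24 subjects x 97 regions) to cohort
rep pattern: separation p=7.8e-11, d=4.73, age r2=0.98
rag pattern: separation p=8.7e-07, d=2.76, age r2=0.57
LV1: sigma=5.579, p=0.0010
```

The simulated cohort (24 subjects, ages 35–80, 97 regions) carries a
*concordant* planted pattern whose expression grows with age, i.e. an
energy-production effect.  Accordingly the rEP pattern separates younger
from older subjects decisively (Cohen's d = 4.73) and its expression tracks
age almost linearly (r² = 0.98), while the rAG analysis — the metric blind
to concordant changes — finds only the weaker residual structure.  The PLSC
first latent variable is significant by permutation (p = 0.001) and its
region weights agree with the SSM-PCA pattern.

The same stages are available as library functions
(`generate_regional_cohort`, `build_energetics_table`,
`crossvalidate_pattern`, `plsc_fit`, `tpr_scores`, …), and
`neuroenergetics run --out DIR` executes the whole pipeline with a manifest
that makes every stochastic stage reproducible from its seed.

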