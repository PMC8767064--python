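# embryoeffect

Tools for quantifying the effect of a developing embryo on endosperm
metabolism from compartment-dissected seed omics.

## The problem

Grain chalkiness — the opaque, loosely packed region of a rice endosperm —
is a major quality defect. A notched-belly (NB) rice mutant develops a
notched line that splits the endosperm into a translucent upper part (EnU)
and a chalky bottom part (EnB) next to the embryo, and the notch blocks
nutrient and signal movement between the two halves. This traps the
embryo's influence in the bottom half and makes a clean two-factor
comparison possible against the wild type (WT), whose halves communicate
freely. Sampling both genotypes at 10, 20 and 30 days after fertilization
(DAF), with the embryo (E) and the two endosperm halves dissected apart,
yields a 2 genotype × 3 tissue × 3 stage factorial design (six metabolome
replicates and three transcriptome replicates per cell).

For every metabolite (or gene) and stage, three quantities are estimated
from median-scaled intensities:

* **position effect** — WT_EnB vs WT_EnU, a Duncan multiple-range
  comparison at α = 0.05: whatever differs between the endosperm halves
  for purely positional reasons;
* **compound effect** — NB_EnB vs NB_EnU, the same comparison in the
  mutant: position *plus* embryo;
* **embryo effect** — the ratio of ratios

  ```
  R = (NB_EnB / NB_EnU) / (WT_EnB / WT_EnU)
  ```

  where each term is a replicate mean. Anything applied equally to the
  bottom half of both genotypes cancels, so R isolates the embryo's
  contribution. A marked difference is declared at R ≤ 0.95
  (downregulation) or R ≥ 1.05 (upregulation), boundaries inclusive.

Around this core the package provides median scaling, imputation and
FPKM/DEG filters, a PCA distance trajectory between the endosperm halves
(the WT shows a monotone decline across stages; the NB a "V-type" pattern
— largest at 10 DAF, smallest at 20, recovering at 30), K-means
coexpression modules DP1–DP6 on Z-scored profiles with hypergeometric
pathway enrichment, and a fully parameterised synthetic-data generator
with ground truth, so every stage of the pipeline is testable without
access to the original measurements.

## Worked example

```python
import embryoeffect as ee

cfg = ee.GeneratorConfig(seed=0)          # the default 634-metabolite study
catalog = ee.generate_catalog(cfg)
matrix, truth, records = ee.simulate_metabolome(cfg, catalog)
scaled = ee.median_scale(matrix)

calls = ee.decompose_all(scaled)          # one row per endosperm feature x stage
print(calls.head(6).to_string(index=False))
```

```
feature_id  stage position_dir  position_p compound_dir  compound_p        R embryo_class  welch_p  welch_p_adj
     M0001     10           ns    0.773398           ns    0.829961 0.928471         down 0.938089     0.974958
     M0001     20           ns    0.420357           ns    0.174356 1.045730           ns 0.328454     0.835602
     M0001     30           ns    0.408977           ns    0.270303 0.756043         down 0.008789     0.059643
     M0002     10           ns    0.930133           up    0.001496 2.874619           up 0.012733     0.079929
     M0002     20           ns    0.487084           up    0.030960 1.114653           up 0.187655     0.741182
     M0002     30           ns    0.946849           up    0.000010 2.631815           up 0.000027     0.003572
```

`M0002` carries a planted embryo effect: its compound call is up while its
position call stays ns, and R ≈ 2.9 at 10 DAF weakens at 20 DAF and
returns at 30 DAF, following the stage profile of the planted effect.
The `welch_p`/`welch_p_adj` columns (NB_EnB vs WT_EnB, BH-adjusted within
stage) are the significance overlay used when rendering per-feature call
tables; the class itself follows R alone.

The distance trajectory between the endosperm halves reproduces the two
genotypes' signatures:

```python
traj, pca = ee.endosperm_trajectories(scaled)
print(traj.to_string(index=False))
```

```
genotype       d10      d20      d30          pattern
      WT  7.794819 4.571099 2.312459 monotone_decline
      NB 15.137010 6.703656 8.336175           v_type
```

The same pipeline is scriptable from the shell
(`embryoeffect run-all --outdir out --seed 0`), which also writes module
assignments, class-level enrichment and a provenance record.

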