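# eclascreen

Screening analysis for reverse-phase *E. coli* lysate arrays (ECLAs) and
forward-phase proteome microarrays: spot quantification, array quality
control, three-criterion candidate-kinase calling with two-antibody
intersection, ±ATP substrate calling, and a seeded synthetic-array
simulator with planted ground truth.

## The problem

Bacterial tyrosine kinases (BY-kinases) regulate biofilm and capsule
formation, but sequence search finds few of them — in *E. coli* only two
(etk, wzc) were known. A reverse-phase lysate array turns the problem into
a screen: thousands of IPTG-induced overexpression clone lysates are
printed in duplicate on coated slides and probed with
anti-phosphotyrosine antibodies. If an overexpressed protein is a tyrosine
kinase, its lysate spot lights up: the lysate supplies both the enzyme and
its substrates. A forward-phase array of purified proteins then maps the
substrates of a purified kinase via an in-vitro reaction with and without
ATP.

## The statistics

Per spot, the net signal is foreground minus background median,
`x = F − B` (negative values retained). Duplicate spots are averaged per
clone and assay. A clone *c* is a **candidate kinase** for antibody *a*
when all three hold:

1. `p < 0.05` — two-tailed pooled Student's *t* between the clone's
   per-assay means in the experiment scans and in the secondary-only
   blanks (3 vs 3 assays);
2. `z_wt > 1.5` — where `z_wt = (x̄_c − μ_WT) / σ_WT`, with `μ_WT, σ_WT`
   the mean and SD of WT-lysate spot net intensities pooled over the
   experiment scans (WT clones carry no overexpression, hence baseline
   phosphorylation);
3. the clone is called by **both** antibodies (P-Tyr-100 and PY20).

Hits are ranked by descending `z_wt`. On the proteome array, a protein is
a **substrate** when `p < 0.05` (±ATP replicate assays) and
`Δ = x̄₊ − x̄₋ > 1 × SD₋`, ranked by descending Δ. Array QC reports the
fraction of lysate spots above the buffer-spot mean (total-protein stain),
the fraction above the WT mean (anti-His stain), and the inter-batch
squared Pearson correlation R².

## Worked example

Simulate a 500-clone two-antibody screen with three planted kinases, run
QC and the screen. `screen.yaml`:

```yaml
n_clones: 500
n_blocks: 12
block_columns: 12
planted_kinases:
  etk:  {pTyr100: 12.0, PY20: 11.0}
  wzc:  {pTyr100: 10.0, PY20: 9.0}
  nrdD: {pTyr100: 8.0,  PY20: 7.5}
seed: 42
```

```sh
$ ecla simulate ecla --config screen.yaml --out scans --verbose
wrote 16 scans (500 clones, 1096 spots each) to scans
$ ecla qc --scans scans
 NHS_ester  fraction_above_buffer    0.9950
 NHS_ester  fraction_above_buffer    0.9920
 NHS_ester  r_squared_batches        0.8881
   antiHis  fraction_above_wt        0.9740
   antiHis  fraction_above_wt        0.9660
   antiHis  r_squared_batches        0.9244
$ ecla screen --scans scans --out screen --verbose
screened 500 clones: hits per antibody {'pTyr100': 3, 'PY20': 3}, intersection 3
$ cat screen/intersection.tsv
clone
etk
wzc
nrdD
```

`hits_pTyr100.tsv` carries the per-clone statistics; for example the
planted 12-WT-SD clone:

```text
clone  antibody  p_value      z_wt    exp_mean  pass_p  pass_sd  hit   rank
etk    pTyr100   3.73587e-05  12.087  8083.5    True    True     True  1
```

`z_wt = 12.1` means etk's mean experiment signal sits 12 WT standard
deviations above the WT baseline; with `p < 0.05` against the blanks and a
call from both antibodies it is a candidate kinase. The same workflow in
Python, through the scikit-learn-style estimators:

```python
import eclascreen as ec

cfg = ec.SimConfig(n_clones=500, n_blocks=12, block_columns=12, seed=42,
                   planted_kinases={"etk": {"pTyr100": 12.0, "PY20": 11.0}})
sim = ec.simulate_ecla(cfg)
est = ec.EclaScreen(alpha=0.05, k=1.5).fit(sim.scans, sim.layout)
est.intersection_        # ['etk']
est.per_antibody_hits_   # per-antibody ranked statistics (DataFrames)
```

`SubstrateCaller` mirrors this for ±ATP proteome-array scans, and
`biofilm_index` computes the crystal-violet OD540/OD600 statistic with its
unpaired two-tailed *t* test.

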