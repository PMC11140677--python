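# Methods

## Screening model

The package analyses two array designs built from the same ordered
overexpression clone collection:

* **Reverse-phase lysate array (ECLA).** Each IPTG-induced clone lysate is
  printed in duplicate; one control row per print block holds WT lysate,
  lysis buffer, BSA, poly-L-lysine, Protein A, anti-human antibody and a
  fluorescent landmark. Anti-phosphotyrosine staining (P-Tyr-100, PY20) is
  read against secondary-antibody-only blanks; total-protein (NHS ester)
  and anti-His stains serve QC.
* **Forward-phase proteome array.** Purified proteins probed after an
  in-vitro kinase reaction with and without ATP, duplicate assays per
  condition.

All statistics operate on net intensities `x = F − B` (scanner foreground
minus background medians). Negative nets are retained — clipping would
truncate the null distribution the *t*-test assumes; an explicit
`clip_negative` opt-in exists. Duplicates are averaged per clone and assay
*before* any testing (with two spots, median and mean coincide anyway);
a GenePix-convention negative flag removes a spot from every aggregate,
and a clone with both duplicates flagged is missing, never imputed.

### Candidate-kinase calling

Per antibody, a clone needs (i) two-tailed pooled Student's *t* between
its experiment-assay means and its blank-assay means with `p < α = 0.05`
(the replicate unit is the assay, n = 3 vs 3 — assays are the independent
unit, spots within an assay share a slide); and (ii)
`z_wt = (x̄ − μ_WT)/σ_WT > k = 1.5`, strict. `μ_WT, σ_WT` pool the WT
spots of all experiment scans of that antibody: the pooled SD absorbs both
spot noise and slide-to-slide scale, which is the spread the threshold is
meant to be measured against. Only elevations are called — kinase
overexpression raises phosphotyrosine; symmetrically low clones
(phosphatase-like behaviour) are out of scope. The cross-antibody
intersection orders clones by their better per-antibody rank (ties: worse
rank, then name). Degenerate *t* conventions: identical zero-variance
groups give p = 1, separated zero-variance groups p = 0 (the vanishing
within-group-variance limit); a zero σ_WT maps any elevation to +∞ SDs.
No multiple-testing correction by default (raw p < 0.05 is the screening
rule); Benjamini–Hochberg and Welch variants sit behind flags.

### Substrate calling

Per protein, `p < 0.05` between +ATP and −ATP assay means and
`Δ = x̄₊ − x̄₋ > k × SD_ref` with `k = 1`, `SD_ref` the protein's own
−ATP replicate SD (the no-kinase baseline; the array-wide SD of the Δ
distribution is available via `sd_reference="delta_pool"`). Hits are
ranked by descending Δ.

A structural note worth knowing: with n replicate assays per condition,
`p < α` already implies `Δ > k·SD_ref` whenever `t_crit(α, 2n−2) > k√n`
— true at n = 2 (4.30 > 1.41) and n = 4 (2.45 > 2.0). The SD gate is
therefore redundant given a significant positive *t*, and the caller's
null pass rate is the *t*-test's one-sided α/2 ≈ 2.5%. Two consequences,
both verified by simulation here: at array scale (~4000 proteins) a
duplicate-assay experiment carries an *expectation* of ~100 null calls,
and at df = 2 the *t*-test misses even arbitrarily large effects ~10–15%
of the time (the pooled SD is estimated from ~1 effective degree of
freedom of the high-variance +ATP pair). Exact recovery of a planted
substrate set is thus not an expectation of this design, unlike the
lysate screen, where the blank contrast makes `pass_p` nearly certain for
every clone and the stable pooled-WT z-gate does the selecting.

## Synthetic data generator

For every spot the scanner foreground is

```
F = round( B_true + b · L(role, clone, channel) · ε ),    B_col = round(B̄)
```

with `b` one log-normal scale factor per scan (`batch_scale_sd`), `ε`
mean-one log-normal spot noise (`spot_cv`), `B_true ~ N(B̄, background_sd)`
truncated at 0, and `B_col` the reported background median — so net
intensities carry the background noise. Values are rounded to integer
scanner counts. Channel levels `L`:

| channel              | lysate clone                     | WT    | buffer | blanks' floor |
|----------------------|----------------------------------|-------|--------|---------------|
| anti-pTyr experiment | `base·(1 + e·u)`                 | base  | 5% base| 5% base (all) |
| NHS ester (total)    | `base·a_c`                       | base  | 10% base | —           |
| anti-His             | `base·a_c` if expressor, else 2% | 2% base | 2% base | —          |
| proteome ±ATP        | `floor·(1 + e·u)` in +ATP only   | —     | 20% floor | —          |

where `u = sqrt(spot_cv² + batch_scale_sd²)` is the relative pooled
WT-spot SD, so a planted effect `e` is expressed directly in WT-SD units
and the 1.5-SD criterion is exercisable by construction; `a_c` is a fixed
per-clone log-normal abundance (`abundance_cv`) shared across scans —
what makes two QC batches correlate at R² < 1; the landmark is bright in
every channel (it is a fluorophore). All randomness flows from one seed
through per-scan substreams: identical (config, seed) gives byte-identical
scans.

### Defaults and their calibration

| parameter | default | why |
|---|---|---|
| `n_clones`, `n_blocks` | 4126, 48 | array scale; 48-pin print head |
| `n_replicate_assays` | 3 (ECLA), 2 (proteome) | assays per condition in the screen design |
| `baseline_mean` | 2000 AU | mid-range 16-bit scanner counts |
| `spot_cv` | 0.2 | typical printed-spot CV for lysate arrays |
| `batch_scale_sd` | 0.15 | 10–20% slide-to-slide staining scale drift |
| `background_mean/sd` | 100 / 20 AU | low, stable local background |
| `abundance_cv` | 0.8 | calibrated (loosely, jointly with `buffer_protein_frac` = 0.1) so inter-batch R² ≈ 0.92 and ~99% of lysate spots clear the buffer reference — the published QC regime |
| `his_positive_fraction` | 0.938 | observed fraction of clones with detectable overexpression |
| `blank_floor_frac` | 0.05 | nonzero secondary-antibody floor visible in blank scans |
| `his_floor_frac` | 0.02 | anti-His background on His-negative spots (~40 AU) |

### What the generator does and does not emulate

Emulated: duplicate printing with control rows, per-scan scale (batch)
effects, heavy-tailed abundance across clones in protein-stain channels,
nonzero blank floors, seeded planted kinase/substrate effects in SD
units, integer scanner counts. Not emulated: spatial artifacts
(gradients, scratches, pin effects), saturation, spot-size variation,
carry-over, and — importantly — any coupling between a clone's printed
protein amount and its basal phosphotyrosine signal: the pTyr baseline is
homogeneous across clones here. Passing tests therefore demonstrate the
statistics are implemented and calibrated correctly, not that the screen
is robust to abundance-correlated phosphosignal on real arrays. One
measurable consequence: under noise the anti-His QC fraction sits ~3
points above the true expressor proportion (the non-expressors straddle
the WT mean), so equality holds exactly only in the noise-free limit.

## Numerical and design choices

* Strict inequalities at both gates (`z_wt > k`, `Δ > k·SD_ref`,
  `net > reference` in QC fractions): a spot exactly at the reference is
  not "above" it.
* Ranking tie-breaks are total and deterministic (z then p then name;
  Δ then name).
* QC references are means of pooled control spots; R² is computed on raw
  net intensities (linear-scale batch plots), with a log10 option.
* No cross-array normalization by default; optional per-array WT-median
  scaling exists, and the screening statistics are invariant to a common
  positive rescaling regardless.
* Grid geometry (blocks, columns per block) is configuration, not a
  constant — the print format is not fixed by the assay.
* Layout construction is a pure function; capacity violations report the
  number of blocks actually needed.

## Problem sizes used by the test suite and acceptance script

The recovery experiments run at 1000 unplanted clones + 33 planted
(two antibodies, 3+3 assays each) and 4126 proteins (duplicate ±ATP);
null calibration uses 200 zero-effect simulations of 50 clones/proteins;
the *t* oracle covers 100 random small-sample cases against numerical
integration of a hand-written t density. Monte-Carlo property checks
(power, monotonicity, R²-vs-noise) use 200–800 clones per simulation.

## Known limitations

* The substrate caller's duplicate-assay design has the power ceiling and
  null floor derived above; treat its hit list as a ranking to verify, not
  a count.
* The 1.5-SD gate on ~10³–10⁴ clones leaves an expected O(0.1–0.5)
  borderline null crossings per antibody per experiment (log-normal right
  tail); the two-antibody intersection is far more stable than either
  per-antibody count.
* Per-clone statistics assume duplicate-averaged means; spot-level
  modelling (mixed effects across slides) is out of scope.
* QC fractions compare against pooled-mean references; max-based or
  quantile references would shift the printed percentages.
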