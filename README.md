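# invkit

Quantitative analysis of **in-cell vesicle capture ("knocksideways") assays**,
autophagosome puncta and vesicle-proteome enrichment — the analysis chain used
to decide whether one population of small uncoated transport vesicles is a
subtype of another.

## The scientific problem

Intracellular nanovesicles (INVs) are ~35 nm uncoated transport vesicles
marked by TPD52-family proteins (TPD54 is the standard marker).  ATG9A
vesicles are small uncoated vesicles carrying the lipid scramblase ATG9A that
seed autophagosome formation.  Are ATG9A vesicles a *flavor* of INV?

The assay that answers this traps vesicles on mitochondria: an FKBP-tagged
marker heterodimerizes with a mitochondrially anchored FRB domain (MitoTrap)
when rapalog is added, dragging the whole vesicle — and any other protein
riding it — onto the mitochondrial network.  Relocalization of the tagged
marker and *co-relocation* of a second marker are read out per cell from
mask-arithmetic fluorescence ratios:

- `F_mito`, `F_cyto` — background-subtracted summed fluorescence in the
  mitochondrial mask and in a surrounding "cytoplasm" ring (the mito mask
  dilated eight times, mito excluded); `F_total = F_mito + F_cyto`.
- fixed cells: `F_mito / F_total`;  live cells: `F_post / F_pre` in the mito
  region.  Cells with `F_mito / F_cyto < 1` in the FKBP channel
  post-treatment failed to respond and are excluded.
- capture kinetics follow a delayed mono-exponential
  `F(t) = F_plateau − (F_plateau − F_base)·exp(−(t − t_on)/τ)`; matched τ
  between two channels (through-origin regression, uncentered R²) indicates
  the two markers ride the same vesicles.

The size of the relocalizable vesicle pool of a marker is the relative loss
of its cytoplasmic fraction, `loss = 1 − (F_cyto/F_total)_treated /
(F_cyto/F_total)_reference`.  The headline statistic is the **subset share**

```
share = co-relocated loss / maximal direct loss
```

e.g. a 71.5% cytoplasmic loss of the INV marker under direct INV capture
versus a 14.5% loss of the same marker when ATG9A vesicles are captured gives
`14.5 / 71.5 ≈ 0.20`: about 20% of the INV pool is ATG9A-flavor, while the
reciprocal ratio (43.1 / 41.0 ≥ 1) means essentially the entire ATG9A-vesicle
pool is INV.

Around this core, the package also provides:

- a **synthetic-data generator** (`invkit.synthetic_data`) producing capture
  fields, time lapses, 3D puncta stacks and label-free quantification (LFQ)
  protein tables with exact ground truth — every quantification step is
  validated by recovery against it;
- **3D puncta volumetrics** (`invkit.puncta_golgi`): isotropic rescaling,
  26-connected labeling and a strict `> 0.012 µm³` volume rule for LC3B
  autophagosome puncta, plus TGN-mask intensity measurements;
- **proteome enrichment statistics** (`invkit.proteomics_enrichment`):
  MaxQuant-style protein-group IO, downshifted-normal imputation, Welch
  tests with the four-color volcano classification (enriched = fold change
  > 2 and P < 0.05), multi-experiment consolidation, Pearson chi-squared 2×2
  annotation/overlap tests and Spearman rank correlation;
- **replicate-aware reporting** (`invkit.reporting`): superplot summaries
  with two-way ANOVA + Tukey HSD computed on replicate means, never on
  pooled cells;
- a **CLI and pipeline driver** (`invkit` / `invkit.pipeline`).

## Worked example

```python
from invkit.kinetics_pools import pool_shares
from invkit.pipeline import run_subset_share_study

est = pool_shares(max_loss=71.5, co_loss=14.5)
print(f"subset share: {est.subset_share_raw:.3f}  ->  {est.render()}")
recip = pool_shares(max_loss=41.0, co_loss=43.1)
print(f"reciprocal:   {recip.subset_share_raw:.3f}  ->  {recip.render()}")

study = run_subset_share_study(n_cells=12, n_seeds=3, base_seed=1)
print(f"simulated recovery: max loss {study.max_loss.grand_mean:.1f}%, "
      f"co-loss {study.co_loss.grand_mean:.1f}%, "
      f"share {study.subset_share:.3f} ({study.n_cells} cells)")
```

prints

```
subset share: 0.203  ->  ∼20%
reciprocal:   1.051  ->  full capture (entire pool trapped)
simulated recovery: max loss 69.7%, co-loss 14.4%, share 0.207 (42 cells)
```

The first two lines evaluate the subset-share statistic on measured
cytoplasmic-loss percentages: ~20% of INVs carry the ATG9A marker, whereas
the reciprocal ratio exceeds 1 and is flagged as capture of the entire pool.
The last line repeats the whole experiment *in silico*: three replicate
seeds of reciprocal capture fields (12 cells each) are simulated, segmented
(Gaussian smooth + Otsu on the MitoTrap channel), measured, responder
filtered and reduced to losses — recovering the configured ~70% pool and the
~0.20 share from pixels alone.

The same pipeline is scriptable from the shell:

```sh
invkit pools --max-loss 71.5 --co-loss 14.5
invkit run --config src/invkit/data/demo_config.yaml --outdir demo_out
```

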