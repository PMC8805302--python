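# emvalidate

Validation of atomic models built into cryo-EM density maps.

Models refined against 3–5 Å cryo-EM reconstructions routinely contain
regions where the chain was traced through noise, residues drifted out of
density, or B factors were never refined. `emvalidate` scores a model (PDB or
mmCIF) against its map (MRC/CCP4) globally and per residue, runs
map-independent sanity checks, and condenses every flagged residue into a
spatially clustered, ranked to-do list.

## Scores

**Global fit to map** — a theoretical map is computed from the model
(Gaussian atoms: each atom contributes a normalized isotropic Gaussian with
real-space variance σ² = B/8π², amplitude ∝ occupancy × Z, band-limited at
the nominal resolution) and compared with the experimental map by:

- **FSC / FSCavg** — Fourier shell correlation per frequency shell;
  FSCavg = Σₖ nₖ FSCₖ / Σₖ nₖ over shells up to the reported resolution
  limit, weighted by the structure-factor count nₖ per shell.
- **CCC** — Pearson cross-correlation over above-contour voxels.
- **MI** — mutual information (nats) of the joint binned density histogram.
- **OV** — overlap of the above-contour voxel sets, normalized by the
  smaller set.
- With ≥ 3 models, the ensemble-combined **CCC_OV** and **MI_OV** scores
  (z-rescaled CCC or MI plus z-rescaled OV) rank the candidates; a second
  (half) map supports an FSCavg-difference overfitting check.
- Default contour level: 1.5 σ above the background peak of the value
  histogram; an explicit contour always wins.

**Per-residue fit** —

- **SMOC** — segment-based Manders' overlap coefficient
  Σ(s·e)/√(Σs²·Σe²) between simulated (s) and experimental (e) density over
  the residue's voxel footprint; outliers are residues whose Z-score against
  the residues within 12 Å falls below −1.5.
- **FDR-backbone score** — background noise is estimated from the map
  periphery, per-voxel p-values under the noise Gaussian are FDR-adjusted
  (Benjamini–Yekutieli) over a small resolution scan, and each residue gets
  the fraction of its backbone atoms in confident (1 − q ≥ 0.99) volume.
  Residues scoring below 0.9 are flagged; the fraction of residues scoring
  above 0.9 summarizes the model. Requires an **unmasked** map.

**Model-only checks** — B-factor distribution (multimodality and
unrefined-B warnings) and a simplified van-der-Waals clash count per 1000
atoms (a lightweight stand-in for a full MolProbity clashscore, labelled as
such in the report).

**Outlier clustering** — all flagged residues are joined by single-linkage
connectivity of their Cα atoms at 7 Å; clusters are ranked by size, and
residues in no cluster form a final "unclustered" row.

## Worked example

Generate a synthetic 20-residue polyalanine helix with a simulated 3 Å map
(Gaussian background noise at 20% of peak) and validate it:

```bash
emvalidate fixtures --out fx
emvalidate run --model fx/model.pdb --map fx/noisy.mrc --resolution 3.0 --out val
```

`val/report.json` then holds (this exact run):

```
global_scores: ccc 0.312  fsc_avg 0.399  mi 0.152  ov 0.312
               contour_exp 0.362 (auto, 1.5 sigma)  contour_model 0.012
overall_fdr_backbone: 1.0
bfactor: one peak at 29.5 Å², no multimodality warning
clash rate: 0.0 per 1000 atoms
outlier_clusters: one "unclustered" row (terminal residues 1 and 20, smoc_z)
```

Reading: every backbone atom sits in statistically confident density
(overall FDR-backbone metric 1.0), geometry is clean, and the moderate
global scores reflect the 20% map noise rather than model error. The two
terminal residues carry slightly depressed SMOC Z-scores — a known edge
effect at chain termini (see `docs/methods.md`) — and land in the
unclustered row rather than forming a problem region. `val/` also contains
the FSC curve (CSV + plot), the per-residue score table, diagnostic plots
and `outliers.txt`, a navigation list ordered by cluster rank.

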