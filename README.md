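# mietox

QSTR (quantitative structure–toxicity relationship) classifiers for the
59 Tox21 molecular-initiating-event (MIE) assay targets — nuclear-receptor
agonists/antagonists and stress-response pathway activators — built from
qHTS activity scores and chemical structures, with Youden-calibrated
prediction scores and applicability-domain (AD) reliability.

It is aimed at computational toxicologists and cheminformaticians who want
to (re)train per-assay activity classifiers from compound × assay activity
score tables and SMILES/SDF structures, and to screen new compounds against
all trained targets in one batch.

## The method

**Labels.** qHTS outcomes are PubChem-style activity scores in [0, 100]
(raw plate signals normalize as
`activity = (V_compound − V_DMSO)/(V_pos − V_DMSO) × 100`). Two binary
teacher-label criteria are supported: *criterion 40* (active iff
score ≥ 40; the inconclusive 5–30 band counts as inactive) and
*criterion 1* (active iff score ≥ 1; inconclusives count as active).
Compounds without a score for an assay are excluded from that assay only.

**Structures → features.** SMILES are standardized (largest organic
fragment, charge neutralization, explicit H); up to 200 random 3D conformer
candidates are MMFF94-minimized and the minimum-energy one kept (a single
ETKDG embedding is the fallback when the candidate path exceeds a
per-molecule time budget). RDKit 2D + 3D descriptors are computed per
conformer; training fixes a cleaned descriptor schema (no non-finite or
constant columns) that prediction-time matrices are aligned and
mean-imputed to.

**Models.** Per target × criterion: 10 % of compounds are held out as the
test set; the development rest is partitioned into three disjoint
out-of-fold (OOF) thirds. A *validator* grid-trains an XGBoost classifier
at 100 learning rates (0.01·i, i = 0…99) per OOF allocation; a *recorder*
keeps all 300 fitted models with validation ROC-AUCs; a *filter* drops
learning rates whose across-fold AUC standard deviation exceeds 0.05 and
selects the best surviving model. The operating cutoff *c* maximizes the
Youden index J = SE + SP − 1 on the test ROC curve, and raw probabilities
x_u are displayed as x_n = x_u^(−log_c 2), which maps 0 → 0, c → 0.5,
1 → 1 (call = active iff x_n ≥ 0.5; display bins: high > 0.6, low < 0.4).

**Reliability.** Each query's mean log Euclidean distance to its 5 nearest
training molecules (z-scored descriptor space) is mapped onto [0, 1] using
the training leave-one-out range — 1 ≈ training-like chemistry, 0 ≈ far
outside the domain — with a 2-component PCA scatter for visual inspection.

## Worked example

Train on the packaged toy molecule set with a synthetic score table, then
predict two query structures:

```sh
mietox synth molecules --out mols.smi
mietox synth scores --n 24 --active-ratio 0.4 --aids 720516 --criterion 40 --seed 5 --out scores.csv
# (embed mols.smi to confs.sdf with mietox/structprep, or bring your own 3D SDF)
mietox train --scores scores.csv --sdf confs.sdf --aid 720516 --criterion both --seed 5 --out models/
printf 'CCO\tethanol\nc1ccncc1\tpyridine\n' > query.smi
mietox predict --in query.smi --bundle models/ --out report.csv --seed 5
```

`report.csv` (one row per compound × target × criterion):

```
compound_id,aid,abbreviation,criterion,probability,normalized_score,call,display_bin,reliability,conformer_method,error
ethanol,720516,ATAD5_ind,1,0.1651782...,0.1997853...,inactive,low,1.0,random-candidate,
pyridine,720516,ATAD5_ind,1,0.8417083...,0.8571703...,active,high,0.5133260...,random-candidate,
```

Reading a row: the ATAD5 genotoxicity model gives pyridine a raw
probability of 0.84, i.e. a normalized score of 0.86 (> 0.5 ⇒ called
active, > 0.6 ⇒ binned "high"), and a reliability of 0.51 — the query sits
midway between training-like chemistry and the edge of the applicability
domain. Ethanol is itself in this toy training set, hence reliability 1.0.
(Labels here are synthetic, so the calls illustrate the format, not real
toxicology.) With a full bundle — 59 targets × 2 criteria — each valid
compound receives 118 such rows.

Retraining at full scale needs the Tox21 assay tables (one CSV of activity
scores per the registry's 59 AIDs, downloadable from PubChem) and the
corresponding structures; the pipeline is the same `mietox train` loop over
`mietox.predictor.enumerate_model_slots()`.

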