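# igocsvm

Single-reference classification of protein–ligand binding modes. The package
encodes the interactions of a receptor–ligand conformational ensemble as
complete, labeled, distance-weighted **interaction graphs** (IGs) over
interaction pseudo-atoms (IPAs), compares graphs with a **shortest-path
kernel**, and learns a one-class definition of the reference binding mode
with a **ν-OCSVM** whose ν is set by either of two heuristics (QMS2 /
kneedle-knee pruning, or a median-absolute-deviation outlier fraction).
Docking poses scoring non-negatively under the model reproduce the reference
binding mode; a molecule is classified as a binder of the reference class
when at least one of its poses is an inlier.

Supporting machinery covers binding-site definition and RMSD-based
conformer clustering (average-linkage hierarchical and PAM k-medoids with
silhouette / Dunn / Davies–Bouldin model selection), a binary
interaction-fingerprint (IFP) Tanimoto baseline with an F1-maximising
threshold sweep, precision/recall/F1 evaluation, and a fully seeded
synthetic-data generator so the entire pipeline runs without external data.

## Layout

| module | role |
|---|---|
| `igocsvm.structio` | TRIPOS MOL2 I/O, chemical feature perception (rule table in `chem_rules`) |
| `igocsvm.interactions` | geometric detection of the 7 interaction types → IPA triplets |
| `igocsvm.iggraph` | IG construction (deci-Å integer weights), Polar variant, IPA file I/O |
| `igocsvm.spkernel` | shortest-path fingerprints, vocabularies, cosine/dot Gram matrices |
| `igocsvm.occlass` | KNN profile, kneedle knee, QMS2 / MAD ν heuristics, OCSVM training & scoring |
| `igocsvm.conformers` | binding sites, pairwise RMSD, clustering, medoid representatives |
| `igocsvm.screen` | pose→molecule decisions, metrics, IFP baseline, threshold sweep |
| `igocsvm.synthdata` | seeded templates, trajectories, decoys, geometric micro-fixtures |

## CLI

```sh
igocsvm simulate --frames 500 --sigma 0.5 --seed 7 -o frames/   # synthetic IPA frames
igocsvm inspect protein.mol2                                    # atom/feature summary
igocsvm detect --protein p.mol2 --ligand l.mol2 --d-ar 5.0 -o pose_ipa.mol2
igocsvm graph pose_ipa.mol2 [--polar] -o graph.json
igocsvm kernel --train frames/ --mode normalized -o gram.csv
igocsvm train --ipa-dir frames/ --interactions polar --method qms2 -o model.json
igocsvm score --model model.json --poses poses_ipa/ -o scores.csv
igocsvm screen --model model.json --manifest poses.tsv --labels labels.csv -o report/
igocsvm cluster --manifest frames.tsv --method kmedoids --k auto --seed 7
```

`--method nn` trains on the non-normalized (dot-product) kernel with QMS2
selection; `qms2`/`mad` use the normalized (cosine) kernel.

## Notes

- All graph edge weights and path lengths are exact deci-Å integers
  (distances rounded half-up to the nearest Å; overlapping IPAs get a
  0.1 Å edge), so kernel features never suffer float drift.
- The chemical typing rule table (`igocsvm/chem_rules.py`) is a frozen,
  documented approximation; detection thresholds are configurable
  (`GeometryConfig`), with `GeometryConfig.reference()` enabling the
  extended 5.0 Å aromatic cutoff used in the reference pipeline.
- kneedle knee detection and PAM k-medoids are implemented in-package.
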