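# dockjury

Consensus (jury) quality assessment for pools of docked protein–protein
complex models.

Rigid-body docking engines (MEGADOCK, FRODOCK, PatchDock, ZDOCK, ...)
produce pools of alternative quaternary-structure models of the same
target, and the practical problem is picking the best one without knowing
the native structure. `dockjury` ranks such a pool by **consensus**: a
model is trusted to the extent that it agrees with the rest of the
ensemble, both globally (pairwise structure similarity) and locally (does
each interface residue sit where the other models put it?).

## Scores

For a pool of *n* ≥ 2 models sharing chain ids and residue numbering:

* **QSscoreJury / DockQJury** — the mean QS-score / DockQ of a model
  against every *other* model in the pool.  QS-score is the symmetric
  weighted overlap of inter-chain residue contacts (Cβ, 12 Å horizon,
  weight 1 up to 5 Å then a Gaussian decay of width 4.28 Å).  DockQ is the
  canonical composite `(fnat + 1/(1+(iRMS/1.5)²) + 1/(1+(LRMS/8.5)²))/3`
  with fnat at a 5 Å heavy-atom contact cutoff and the iRMS interface
  defined at 10 Å.
* **ModFOLDIA** — per-residue interface accuracy.  An interface residue is
  one with a heavy atom ≤ 5 Å from a different chain; its minimum
  inter-chain distance is *Dmin*, and the mean of that distance for the
  equivalent residue over all other models is *MeanDmin*.  Both are mapped
  through the contact sigmoid `S = 1/(1+(D/20)²)` and

  ```
  IA = 1 − |Si − MeanSi|
  ```

  The global ModFOLDIA score is Σ IA over the model's interface residues,
  normalised by `max(n_interface, mean n_interface across the pool)`.
* **ModFOLDdock global** — the unweighted mean of the available component
  scores: the three internal ones above plus, when supplied as TSV files,
  external per-model scorers such as ProQDock (averaged over chain pairs)
  and VoroMQA.  Models are ranked by this score.

A seeded synthetic decoy generator (ideal two-helix poly-Ala dimers with
rigid-body perturbed ligand chains and known ground-truth DockQ) makes the
whole protocol testable end to end without any external data.

## Worked example

Generate a 10-decoy pool and rank it:

```bash
dockjury simulate --n 10 --seed 7 --out pool --log-level WARNING
dockjury score pool/decoy_*.pdb --out scores --log-level WARNING
```

which prints the ranked list (rank, model, ModFOLDdock global score):

```
   1  decoy_004  0.5880
   2  decoy_002  0.5824
   3  decoy_001  0.5813
   4  decoy_003  0.5250
   5  decoy_007  0.4907
   6  decoy_006  0.3781
   7  decoy_010  0.3619
   8  decoy_008  0.2980
   9  decoy_009  0.2083
  10  decoy_005  0.0525
```

The generator's manifest (`pool/manifest.tsv`) records the ground truth:
decoys 001–004 are the near-native ones (ligand perturbed by ≤ 5° / ≤ 1 Å,
DockQ vs reference 0.83–0.99), and they occupy the top four ranks — the
jury finds them purely from mutual agreement, never seeing the reference.
`scores/scores.tsv` holds the per-model components (for decoy_004:
QSscoreJury 0.422, DockQJury 0.402, ModFOLDIA 0.939, global 0.588 — jury
components sit well below 1 here because the 10-model pool is 60% junk),
`scores/residue_ia.tsv` the per-residue IA values, and
`scores/scores.caspqa.txt` the same in CASP-QA-style text.  `dockjury
pairwise a.pdb b.pdb` prints the raw QS/DockQ/fnat/iRMS/LRMS of one pair.

External scorer files are joined in with
`--external-scores proqdock.tsv` (columns `method`, `model_id`, optional
`chain_a`/`chain_b`, `score`), restoring the five-component mean.

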