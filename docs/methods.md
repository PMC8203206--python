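# Methods

## The consensus model

`dockjury` estimates the quality of each member of a pool of docked
protein-complex models without a native structure, on the assumption that
drives all jury/consensus EMA methods: correct binding modes recur across
independent docking runs, while errors scatter.  Under that assumption a
model's mean similarity to the rest of the pool is a proxy for its
similarity to the (unknown) native complex, and residues whose interface
geometry matches the ensemble consensus are the trustworthy parts of the
interface.  The assumption fails when the pool is systematically biased
(e.g. every engine funnels into the same wrong site); nothing in a
consensus score can detect that failure mode, and users should treat
scores as relative within a pool, not as calibrated accuracies.

## Pipeline and definitions

1. **Input models** are PDB files of the same target sharing chain ids and
   author residue numbering.  Only heavy atoms (element ≠ H/D) of ATOM
   records in the first MODEL block are kept; HETATM records (including
   waters) are dropped; for altloc duplicates the highest-occupancy
   conformer wins, ties resolved by file order.  Residue equivalence across
   models is keyed by `(chain_id, seq_num, icode)`; no sequence-alignment
   fallback is attempted (a limitation: renumbered pools must be fixed
   upstream).
2. **Interface profile.** For every residue, `Dmin` = minimum heavy-atom
   distance to the union of all other chains (for > 2 chains, the minimum
   over all foreign chains).  Interface membership is `Dmin ≤ 5 Å`,
   inclusive.  `Dmin` is stored uncapped for *all* residues, because the
   consensus average below includes equivalent residues that are not
   interface in some models.  The search uses exact k-d-tree
   nearest-neighbour queries; a brute-force O(N²) implementation is kept
   and tested to produce identical arithmetic.
3. **Per-residue interface accuracy (ModFOLDIA).** For each interface
   residue of the scored model, `MeanDmin` is the arithmetic mean of that
   residue's `Dmin` over all other models that contain it — raw,
   uncapped distances, whether or not the residue is interface there (the
   inclusive choice; capping far distances would soften the penalty for
   models that strand a residue far from any chain).  Then
   `S = 1/(1+(D/20)²)` maps distances to (0,1] — 1 in contact, 0.5 at
   20 Å — and `IA = 1 − |Si − MeanSi|`.  The global score is
   `Σ IA / max(n_interface, mean n_interface over the pool)`; the
   normaliser stops a model scoring highly by predicting a tiny interface.
   Residues present in no other model get an undefined IA (reported as
   missing) and contribute 0 to the numerator while still counting in
   `n_interface` — the conservative choice, since shrinking the normaliser
   instead would reward dropping residues.  An empty interface scores 0.
4. **Jury scores.** QS-score and DockQ of the model against every other
   model, averaged; self-comparison excluded, so pools need n ≥ 2.
   DockQ uses the published constants (fnat cutoff 5 Å, iRMS interface at
   10 Å, scalings d2 = 1.5 Å and d1 = 8.5 Å) and the two-chain
   receptor/ligand formulation: receptor = larger chain by residue count,
   ties by chain-id sort.  Backbone atoms for RMSD terms are N, CA, C, O;
   residues or atoms missing from either model drop out pairwise.
   QS-score uses Cβ (Cα for Gly, with a Cα fallback when Cβ is absent),
   a 12 Å contact horizon, weight 1 up to 5 Å and
   `exp(−(d−5)²/(2·4.28²))` beyond; the score is
   `Σ_shared min(w_a, w_b) / Σ_union max-available weight`.
5. **Aggregation.** The global score is the unweighted mean of the
   components available per model: the three internal ones, plus external
   per-model scores ingested from TSV (per-chain-pair rows are averaged
   first).  The external scorers themselves (ProQDock, VoroMQA) are not
   re-implemented; without them the documented 3-component mode applies
   and is logged.  Ranking is by global score descending, ties broken by
   model id so output is deterministic.

## Edge cases and numerical choices

* A jury DockQ comparison whose pairwise *reference* has no inter-chain
  contacts at 5 Å is undefined (fnat has an empty denominator); the jury
  records that pair's DockQ as 0.0 — no interface agreement is
  demonstrable — with NaN RMSD components in the pairwise table.  The same
  convention gives QS = 0 when neither model has any contact.  This
  penalises exploded decoys symmetrically but means two models that agree
  on *having no interface* still score 0 with each other.
* Kabsch superposition uses the SVD formulation with determinant-sign
  correction, so reflections are never returned; self-comparisons give
  RMSD at machine precision (~1e-15 Å) and identities are asserted at
  1e-9 Å in tests.
* The interface cutoff test is inclusive (`≤ 5 Å`) and exact-distance
  cases are tested at the boundary.
* PDB writing refuses residue numbers > 9999 rather than switching to
  hybrid-36, since docking pools realistically stay far below the limit.
* Malformed ATOM records are detected by a pre-parse scan of the
  fixed-width numeric fields (reporting the line number) because the
  underlying parser zero-fills unparsable numbers silently.

## The synthetic decoy generator

The generator stands in for docking-engine output.  A reference dimer is
two parallel ideal poly-alanine α-helices (rise 1.5 Å and twist 100° per
residue; N/CA/C/O/Cβ placed on coaxial helices with fixed radial, phase
and axial offsets giving plausible bond lengths), axes 9 Å apart with the
Cβ faces opposed, which guarantees a non-empty 5 Å interface; a 0.02 Å
seeded coordinate jitter makes distinct seeds give distinct references.
Decoys rigidly rotate/translate the ligand helix about its centroid and
add per-atom Gaussian noise.  Defaults model a plausible docking-pool
composition: 30 decoys, 40% near-native (rotation ≤ 5°, translation
≤ 1 Å), the rest drawn from a broad continuum (rotation U(0°, 60°),
translation U(2 Å, 20 Å)) so pool quality spans near-perfect to
interface-destroying, and jitter sd 0.2 Å emulating coordinate noise.
Each decoy's RNG stream is split by counter (`default_rng([seed, i])`), so
extending a pool never changes earlier decoys; ground-truth DockQ against
the unperturbed reference is computed at generation time.

What the generator does **not** emulate: side-chain packing and real
rotamers, sequence diversity, backbone flexibility, clashes and physical
plausibility, multimeric (> 2 chain) assemblies, and — most importantly —
correlated errors between decoys.  Its perturbations are independent, so
the consensus assumption holds by construction; passing the
ranking-recovery test therefore shows the machinery is correct, not that
consensus scoring succeeds on adversarial real pools.

## Problem sizes used in checks

The automated checks run on 30-residue-per-chain dimers (300 heavy atoms),
pools of up to 30 decoys, 20-seed brute-force/tree equivalence sweeps, and
a 21-step 0–40 Å translation scan; these sizes make every property
(identities, oracle equivalence, monotone decay, ranking recovery with
Spearman ρ ≥ 0.8) measurable in seconds while exercising the same code
paths as production-sized pools.

## Known limitations

* Two-chain DockQ only; for > 2-chain models the jury would need a
  chain-pair averaging extension (the interface/IA machinery already
  handles any chain count).
* Residue correspondence trusts author numbering; no alignment rescue.
* External scorer values are trusted as given (only range-checked).
* CASP-style output uses score-valued per-residue fields (IA in [0,1]),
  not distance-valued error estimates.
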