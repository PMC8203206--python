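"""Seeded synthetic decoy pools with known ground-truth quality.

Real inputs to the consensus scorer are pools of rigid-body docking
outputs.  This module emulates them without any download: a reference
two-helix poly-alanine dimer (the shape of a coiled-coil pairing) plus
decoys obtained by rigidly rotating/translating the ligand chain and
optionally jittering its atoms.  Every decoy's true quality (DockQ against
the unperturbed reference) is computed at generation time, which is what
makes ranking-recovery tests possible.

Helix geometry is ideal and parametric -- 1.5 A rise and 100 deg twist per
residue, backbone and Cbeta atoms placed on coaxial helices with fixed
radial/phase/axial offsets chosen to give plausible bond lengths.  Only a
plausible, reproducible interface is needed, not biophysical realism.

Reproducibility: one RNG stream per pool, split per decoy by counter
(``default_rng([seed, i])``), so extending a pool never reshuffles earlier
decoys.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .similarity_metrics import dockq
from .structure_io import Atom, ComplexModel, ModelPool, Residue, build_pool, write_pdb

logger = logging.getLogger("dockjury")

HELIX_RISE = 1.5        # A per residue
HELIX_TWIST = 100.0     # deg per residue
AXIS_SEPARATION = 9.0   # A between the two helix axes

# atom name -> (radius A, phase offset deg, axial offset A) on the helix
_ATOM_HELIX = {
    "N": (1.86, -28.9, -0.93),
    "CA": (2.30, 0.0, 0.0),
    "C": (1.66, 26.7, 1.10),
    "O": (2.00, 40.0, 2.10),
    "CB": (3.20, -24.0, -0.63),
}
_COORD_JITTER_SD = 0.02  # A, tiny seeded roughness so references differ by seed


@dataclass
class DecoySpec:
    """Parameters of one synthetic decoy pool.

    Near-native decoys get rotations <= 5 deg and translations <= 1 A of
    the ligand chain; the remainder draw from a broad continuum (up to
    ``rotation_max`` / ``translation_max``) emulating the quality spread of
    rigid-body docking output.
    """

    n_decoys: int = 30
    rotation_max: float = 60.0       # deg
    translation_max: float = 20.0    # A
    jitter_sd: float = 0.2           # A per-atom Gaussian noise
    seed: int = 0
    fraction_near_native: float = 0.4
    n_res_per_chain: int = 30

    def validate(self) -> None:
        if self.n_decoys < 2:
            raise ValueError("pool must allow a jury: n_decoys >= 2")
        for name in ("rotation_max", "translation_max", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.fraction_near_native <= 1.0:
            raise ValueError("fraction_near_native must be in [0, 1]")
        if self.n_res_per_chain < 5:
            raise ValueError("n_res_per_chain must be >= 5")


def _helix_chain(
    chain_id: str, n_res: int, phase_deg: float, origin: np.ndarray,
    rng: np.random.Generator,
) -> list[Residue]:
    residues = []
    for i in range(n_res):
        atoms = []
        for name, (radius, dphase, dz) in _ATOM_HELIX.items():
            theta = math.radians(HELIX_TWIST * i + phase_deg + dphase)
            pos = origin + np.array(
                [radius * math.cos(theta), radius * math.sin(theta),
                 HELIX_RISE * i + dz]
            )
            pos = pos + rng.normal(0.0, _COORD_JITTER_SD, size=3)
            atoms.append(Atom(name=name, element=name[0], coords=pos))
        residues.append(
            Residue(chain_id=chain_id, seq_num=i + 1, icode="", res_name="ALA",
                    atoms=atoms)
        )
    return residues


def make_reference_dimer(
    n_res_per_chain: int = 30, seed: int = 0, model_id: str = "reference"
) -> ComplexModel:
    """Two parallel ideal poly-Ala helices, axes 9 A apart, facing each other.

    The geometry guarantees a non-empty interface at the 5 A cutoff; a tiny
    seeded coordinate jitter (sd 0.02 A) makes distinct seeds produce
    distinct but equally valid references.  Deterministic per seed.
    """
    if n_res_per_chain < 5:
        raise ValueError("n_res_per_chain must be >= 5")
    rng = np.random.default_rng(seed)
    chain_a = _helix_chain("A", n_res_per_chain, 0.0, np.zeros(3), rng)
    chain_b = _helix_chain(
        "B", n_res_per_chain, 180.0, np.array([AXIS_SEPARATION, 0.0, 0.0]), rng
    )
    return ComplexModel(model_id=model_id, chains={"A": chain_a, "B": chain_b})


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def perturb_model(
    reference: ComplexModel,
    rotation: float = 0.0,
    translation: float = 0.0,
    jitter_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    axis: np.ndarray | None = None,
    model_id: str | None = None,
) -> ComplexModel:
    """Rigid-body perturbation of chain B; chain A and residue keys untouched.

    Chain B is rotated by ``rotation`` degrees about its centroid (random
    seeded axis), translated by ``translation`` A along a seeded random
    direction (or along ``axis`` when given -- the fixed-axis mode used for
    monotone-decay checks), then optionally jittered per atom.  Zero
    magnitudes are exact no-ops, so (0, 0, 0) reproduces the reference
    coordinates bit for bit.
    """
    for name, v in (("rotation", rotation), ("translation", translation),
                    ("jitter_sd", jitter_sd)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rot_axis = _unit_vector(rng)
    direction = _unit_vector(rng) if axis is None else (
        np.asarray(axis, dtype=float) / np.linalg.norm(axis)
    )
    chain_ids = reference.chain_ids
    moving = chain_ids[-1]  # ligand chain; "B" for generated dimers

    coords = np.array(
        [a.coords for res in reference.chains[moving] for a in res.atoms]
    )
    if rotation > 0:
        centroid = coords.mean(axis=0)
        rot = Rotation.from_rotvec(math.radians(rotation) * rot_axis)
        coords = rot.apply(coords - centroid) + centroid
    if translation > 0:
        coords = coords + translation * direction
    if jitter_sd > 0:
        coords = coords + rng.normal(0.0, jitter_sd, size=coords.shape)

    new_chains: dict[str, list[Residue]] = {}
    for cid in chain_ids:
        if cid != moving:
            new_chains[cid] = [
                Residue(res.chain_id, res.seq_num, res.icode, res.res_name,
                        [Atom(a.name, a.element, a.coords.copy(), a.occupancy,
                              a.altloc) for a in res.atoms])
                for res in reference.chains[cid]
            ]
    k = 0
    moved: list[Residue] = []
    for res in reference.chains[moving]:
        atoms = []
        for a in res.atoms:
            atoms.append(Atom(a.name, a.element, coords[k].copy(), a.occupancy,
                              a.altloc))
            k += 1
        moved.append(Residue(res.chain_id, res.seq_num, res.icode, res.res_name,
                             atoms))
    new_chains[moving] = moved
    ordered = {cid: new_chains[cid] for cid in chain_ids}
    return ComplexModel(
        model_id=model_id or f"{reference.model_id}_perturbed", chains=ordered
    )


def _generate(
    spec: DecoySpec, reference: ComplexModel | None = None
) -> tuple[ModelPool, dict[str, float], pd.DataFrame]:
    spec.validate()
    if reference is None:
        reference = make_reference_dimer(spec.n_res_per_chain, seed=spec.seed)
    n_near = round(spec.fraction_near_native * spec.n_decoys)
    decoys: list[ComplexModel] = []
    rows = []
    ground_truth: dict[str, float] = {}
    for i in range(spec.n_decoys):
        rng = np.random.default_rng([spec.seed, i + 1])
        near = i < n_near
        if near:
            rot = rng.uniform(0.0, min(5.0, spec.rotation_max))
            trans = rng.uniform(0.0, min(1.0, spec.translation_max))
        else:
            rot = rng.uniform(0.0, spec.rotation_max)
            trans = rng.uniform(min(2.0, spec.translation_max), spec.translation_max)
        mid = f"decoy_{i + 1:03d}"
        decoy = perturb_model(reference, rotation=rot, translation=trans,
                              jitter_sd=spec.jitter_sd, seed=rng, model_id=mid)
        gt = dockq(decoy, reference).dockq
        decoys.append(decoy)
        ground_truth[mid] = gt
        rows.append(
            {"model_id": mid, "is_near_native": near,
             "rotation_deg": rot, "translation_ang": trans,
             "jitter_sd": spec.jitter_sd, "dockq_vs_reference": gt}
        )
    pool = build_pool(decoys, target_id=f"synthetic_seed{spec.seed}")
    return pool, ground_truth, pd.DataFrame(rows)


def generate_pool(
    spec: DecoySpec, reference: ComplexModel | None = None
) -> tuple[ModelPool, dict[str, float]]:
    """Generate a decoy pool and its ground-truth DockQ-vs-reference map.

    Fully reproducible from the spec (seed included); decoy i depends only
    on (seed, i).
    """
    pool, ground_truth, _ = _generate(spec, reference)
    return pool, ground_truth


def write_pool(spec: DecoySpec, outdir: str | Path) -> Path:
    """Write the pool as numbered PDB files plus a manifest TSV; returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pool, _, manifest = _generate(spec)
    for model in pool.models:
        write_pdb(model, outdir / f"{model.model_id}.pdb")
    manifest_path = outdir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False, float_format="%.6f")
    logger.info("wrote %d decoys + manifest to %s", len(pool), outdir)
    return manifest_path
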