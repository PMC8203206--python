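"""Pairwise model-vs-model similarity kernels: Kabsch, DockQ and QS-score.

These are the kernels the jury consensus consumes.  DockQ combines the
fraction of native residue-residue contacts (fnat, 5 A heavy-atom cutoff)
with interface and ligand backbone RMSDs, each mapped to (0,1] by
``1/(1+(rmsd/d)^2)`` with the published scaling constants d1 = 8.5 A (LRMS)
and d2 = 1.5 A (iRMS); the interface for the iRMS term is defined at a
10 A heavy-atom cutoff on the reference.  QS-score is a symmetric weighted
contact-overlap: inter-chain residue contacts on Cbeta (Calpha for Gly)
within 12 A, weighted 1 up to 5 A and by a Gaussian decay
``exp(-(d-5)^2 / (2 * 4.28^2))`` beyond.

DockQ here follows the canonical two-chain receptor/ligand formulation
(receptor = larger chain by residue count, ties broken by chain-id order);
residues or backbone atoms missing from either model are dropped pairwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import ComplexModel, DockjuryError, ResidueKey

logger = logging.getLogger("dockjury")

BACKBONE_ATOMS = ("N", "CA", "C", "O")

FNAT_CUTOFF = 5.0      # A, native-contact definition
IRMS_CUTOFF = 10.0     # A, interface definition for the iRMS term
LRMS_SCALE = 8.5       # A, d1
IRMS_SCALE = 1.5       # A, d2
QS_CONTACT_CUTOFF = 12.0  # A, Cbeta contact horizon
QS_FLAT_CUTOFF = 5.0      # A, weight 1 below this
QS_GAUSS_SD = 4.28        # A, decay width beyond the flat region


class MetricError(DockjuryError):
    """A pairwise comparison cannot be formed (e.g. no native interface)."""


@dataclass
class Superposition:
    """Optimal proper rigid-body fit of one coordinate set onto another."""

    rotation: np.ndarray   # 3x3, det = +1
    translation: np.ndarray  # 3-vector, A
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class PairwiseSimilarity:
    """QS and DockQ (with components) for an ordered (model, reference) pair."""

    model_a: str
    model_b: str
    qs: float
    dockq: float
    fnat: float
    irms: float
    lrms: float


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(ref_coords: np.ndarray, mov_coords: np.ndarray) -> Superposition:
    """Least-squares optimal rotation + translation of ``mov`` onto ``ref``.

    Uses the SVD formulation with determinant sign correction, so the result
    is always a proper rotation (no reflection).
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {mov.shape}")
    if ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] < 3:
        raise ValueError("need two (N, 3) arrays with N >= 3")
    cm_ref = ref.mean(axis=0)
    cm_mov = mov.mean(axis=0)
    h = (mov - cm_mov).T @ (ref - cm_ref)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cm_ref - rot @ cm_mov
    moved = mov @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


# ---------------------------------------------------------------------------
# Residue-residue contacts
# ---------------------------------------------------------------------------

def _ordered_pair(ka: ResidueKey, kb: ResidueKey) -> tuple[ResidueKey, ResidueKey]:
    return (ka, kb) if ka[0] < kb[0] else (kb, ka)


def heavy_contact_distances(
    model: ComplexModel, cutoff: float
) -> dict[tuple[ResidueKey, ResidueKey], float]:
    """Min heavy-atom distance per inter-chain residue pair within ``cutoff``.

    Pairs are keyed with the lexicographically smaller chain first, so the
    result is comparable across models of the same target.
    """
    out: dict[tuple[ResidueKey, ResidueKey], float] = {}
    cids = model.chain_ids
    arrays = {cid: model.chain_arrays(cid) for cid in cids}
    for i, ca in enumerate(cids):
        coords_a, ridx_a, keys_a = arrays[ca]
        for cb in cids[i + 1:]:
            coords_b, ridx_b, keys_b = arrays[cb]
            dist = cdist(coords_a, coords_b)
            ii, jj = np.nonzero(dist <= cutoff)
            if ii.size == 0:
                continue
            flat = ridx_a[ii] * len(keys_b) + ridx_b[jj]
            for f in np.unique(flat):
                sel = flat == f
                ra, rb = divmod(int(f), len(keys_b))
                out[_ordered_pair(keys_a[ra], keys_b[rb])] = float(dist[ii[sel], jj[sel]].min())
    return out


def _bead_coords(model: ComplexModel) -> dict[ResidueKey, np.ndarray]:
    """One coordinate per residue for QS contacts: CB, or CA for glycine.

    Residues lacking both are skipped with a warning, per the QS contract.
    """
    beads: dict[ResidueKey, np.ndarray] = {}
    for _, res in model.iter_residues():
        atom = res.get_atom("CA") if res.res_name == "GLY" else res.get_atom("CB")
        if atom is None:
            atom = res.get_atom("CA")
        if atom is None:
            logger.warning(
                "model %s: residue %s has no CB/CA; skipped for QS",
                model.model_id, res.key,
            )
            continue
        beads[res.key] = atom.coords
    return beads


def _qs_contact_weights(model: ComplexModel) -> dict[tuple[ResidueKey, ResidueKey], float]:
    beads = _bead_coords(model)
    by_chain: dict[str, tuple[list[ResidueKey], np.ndarray]] = {}
    for cid in model.chain_ids:
        keys = [r.key for r in model.chains[cid] if r.key in beads]
        if keys:
            by_chain[cid] = (keys, np.array([beads[k] for k in keys]))
    weights: dict[tuple[ResidueKey, ResidueKey], float] = {}
    cids = list(by_chain)
    for i, ca in enumerate(cids):
        keys_a, coords_a = by_chain[ca]
        for cb in cids[i + 1:]:
            keys_b, coords_b = by_chain[cb]
            dist = cdist(coords_a, coords_b)
            ii, jj = np.nonzero(dist <= QS_CONTACT_CUTOFF)
            for a, b in zip(ii, jj):
                d = dist[a, b]
                w = 1.0 if d <= QS_FLAT_CUTOFF else math.exp(
                    -((d - QS_FLAT_CUTOFF) ** 2) / (2.0 * QS_GAUSS_SD**2)
                )
                weights[_ordered_pair(keys_a[a], keys_b[b])] = w
    return weights


# ---------------------------------------------------------------------------
# fnat / DockQ
# ---------------------------------------------------------------------------

def fnat(
    model: ComplexModel,
    reference: ComplexModel,
    contact_cutoff: float = FNAT_CUTOFF,
) -> float:
    """Fraction of the reference's inter-chain residue contacts present in the model."""
    ref_contacts = set(heavy_contact_distances(reference, contact_cutoff))
    if not ref_contacts:
        raise MetricError(
            f"reference {reference.model_id!r} has no native interface "
            f"(no inter-chain contacts at {contact_cutoff} A)"
        )
    model_contacts = set(heavy_contact_distances(model, contact_cutoff))
    return len(ref_contacts & model_contacts) / len(ref_contacts)


def _receptor_ligand(reference: ComplexModel) -> tuple[str, str]:
    """Receptor = larger chain by residue count; ties by chain-id sort order."""
    sizes = sorted(
        ((len(reference.chains[cid]), cid) for cid in reference.chain_ids),
        key=lambda t: (-t[0], t[1]),
    )
    return sizes[0][1], sizes[1][1]


def _shared_backbone(
    model: ComplexModel,
    reference: ComplexModel,
    keys: list[ResidueKey],
) -> tuple[np.ndarray, np.ndarray]:
    """Matched (reference, model) backbone coordinates over ``keys``.

    Residues missing from either model, and backbone atoms missing from
    either copy of a residue, are dropped pairwise.
    """
    ref_pts: list[np.ndarray] = []
    mov_pts: list[np.ndarray] = []
    for key in keys:
        rres = reference.get_residue(key)
        mres = model.get_residue(key)
        if rres is None or mres is None:
            continue
        for name in BACKBONE_ATOMS:
            ra, ma = rres.get_atom(name), mres.get_atom(name)
            if ra is not None and ma is not None:
                ref_pts.append(ra.coords)
                mov_pts.append(ma.coords)
    if not ref_pts:
        return np.empty((0, 3)), np.empty((0, 3))
    return np.array(ref_pts), np.array(mov_pts)


def dockq(model: ComplexModel, reference: ComplexModel) -> PairwiseSimilarity:
    """DockQ of ``model`` against ``reference`` (two-chain comparison).

    DockQ = (fnat + 1/(1+(iRMS/1.5)^2) + 1/(1+(LRMS/8.5)^2)) / 3, where
    iRMS is the backbone RMSD over the reference's 10 A interface residues
    after superposing on those residues, and LRMS is the ligand backbone
    RMSD after superposing the receptors.  The returned record also carries
    the (symmetric) QS-score of the pair.
    """
    if len(model.chains) != 2 or len(reference.chains) != 2:
        raise MetricError("DockQ is defined here for two-chain models only")
    if set(model.chain_ids) != set(reference.chain_ids):
        raise MetricError(
            f"chain sets differ: {sorted(model.chain_ids)} vs {sorted(reference.chain_ids)}"
        )
    receptor, ligand = _receptor_ligand(reference)

    fnat_val = fnat(model, reference)

    # iRMS: reference interface at 10 A, both chains' residues
    iface_contacts = heavy_contact_distances(reference, IRMS_CUTOFF)
    iface_keys = sorted({k for pair in iface_contacts for k in pair})
    ref_i, mov_i = _shared_backbone(model, reference, iface_keys)
    if len(ref_i) < 3:
        raise MetricError("fewer than 3 shared interface backbone atoms for iRMS")
    irms = kabsch_superpose(ref_i, mov_i).rmsd

    # LRMS: superpose receptors, measure ligand backbone deviation
    rec_keys = [r.key for r in reference.chains[receptor]]
    lig_keys = [r.key for r in reference.chains[ligand]]
    ref_r, mov_r = _shared_backbone(model, reference, rec_keys)
    ref_l, mov_l = _shared_backbone(model, reference, lig_keys)
    if len(ref_r) < 3 or len(ref_l) < 1:
        raise MetricError("insufficient shared backbone atoms for LRMS")
    sup = kabsch_superpose(ref_r, mov_r)
    moved_l = sup.apply(mov_l)
    lrms = float(np.sqrt(np.mean(np.sum((moved_l - ref_l) ** 2, axis=1))))

    dockq_val = (
        fnat_val
        + 1.0 / (1.0 + (irms / IRMS_SCALE) ** 2)
        + 1.0 / (1.0 + (lrms / LRMS_SCALE) ** 2)
    ) / 3.0
    return PairwiseSimilarity(
        model_a=model.model_id,
        model_b=reference.model_id,
        qs=qs_score(model, reference),
        dockq=dockq_val,
        fnat=fnat_val,
        irms=irms,
        lrms=lrms,
    )


# ---------------------------------------------------------------------------
# QS-score
# ---------------------------------------------------------------------------

def qs_score(model_a: ComplexModel, model_b: ComplexModel) -> float:
    """Symmetric weighted contact-overlap between two models of one target.

    QS = sum over shared contacts of min(w_a, w_b) divided by the sum over
    the union of contacts of the larger available weight; 1 for identical
    models, 0 for disjoint interfaces.
    """
    wa = _qs_contact_weights(model_a)
    wb = _qs_contact_weights(model_b)
    num = 0.0
    den = 0.0
    for pair in set(wa) | set(wb):
        a = wa.get(pair)
        b = wb.get(pair)
        if a is not None and b is not None:
            num += min(a, b)
            den += max(a, b)
        else:
            den += a if a is not None else b  # type: ignore[operator]
    if den == 0.0:
        logger.warning(
            "QS undefined: neither %s nor %s has inter-chain contacts; returning 0",
            model_a.model_id, model_b.model_id,
        )
        return 0.0
    return num / den
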