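"""Inter-chain interface detection and per-residue minimum contact distances.

For every residue the quantity of interest is ``Dmin``: the minimum
Euclidean distance from any of its heavy atoms to any heavy atom in a
*different* chain.  A residue is an interface residue when Dmin <= cutoff
(5.0 A by default, inclusive).  Dmin is recorded for every residue, not
only interface ones, because the consensus stage averages these distances
for equivalent residues across the whole pool regardless of their interface
status in each individual model.

The default path accelerates the search with a k-d tree (scipy cKDTree
nearest-neighbour queries are exact Euclidean distances, so it matches the
brute-force all-pairs computation to machine arithmetic); a brute-force
implementation is kept as the oracle/fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structure_io import ComplexModel, ModelPool, NotAComplexError, Residue, ResidueKey

logger = logging.getLogger("dockjury")

DEFAULT_CUTOFF = 5.0  # A, inclusive


@dataclass
class InterfaceProfile:
    """Per-residue minimum inter-chain heavy-atom distances of one model."""

    model_id: str
    dmin: dict[ResidueKey, float]
    cutoff: float = DEFAULT_CUTOFF

    @property
    def interface_set(self) -> frozenset[ResidueKey]:
        return frozenset(k for k, d in self.dmin.items() if d <= self.cutoff)

    @property
    def n_interface(self) -> int:
        return len(self.interface_set)


def residue_min_distance(res_a: Residue, res_b: Residue) -> float:
    """Minimum heavy-atom pair distance between two residues (symmetric)."""
    if not res_a.atoms or not res_b.atoms:
        raise ValueError("residue without heavy atoms")
    return float(cdist(res_a.coord_array(), res_b.coord_array()).min())


def _profile_kdtree(model: ComplexModel, cutoff: float) -> dict[ResidueKey, float]:
    dmin: dict[ResidueKey, float] = {}
    arrays = {cid: model.chain_arrays(cid) for cid in model.chain_ids}
    for cid in model.chain_ids:
        coords, res_idx, keys = arrays[cid]
        other = np.concatenate(
            [arrays[c][0] for c in model.chain_ids if c != cid], axis=0
        )
        dist, _ = cKDTree(other).query(coords)
        per_res = np.full(len(keys), np.inf)
        np.minimum.at(per_res, res_idx, dist)
        for k, d in zip(keys, per_res):
            dmin[k] = float(d)
    return dmin


def _profile_bruteforce(model: ComplexModel, cutoff: float) -> dict[ResidueKey, float]:
    """O(N^2) atom-pair reference implementation (oracle for the tree path)."""
    dmin: dict[ResidueKey, float] = {}
    arrays = {cid: model.chain_arrays(cid) for cid in model.chain_ids}
    for cid in model.chain_ids:
        coords, res_idx, keys = arrays[cid]
        other = np.concatenate(
            [arrays[c][0] for c in model.chain_ids if c != cid], axis=0
        )
        dist = cdist(coords, other).min(axis=1)
        per_res = np.full(len(keys), np.inf)
        np.minimum.at(per_res, res_idx, dist)
        for k, d in zip(keys, per_res):
            dmin[k] = float(d)
    return dmin


def interface_profile(
    model: ComplexModel, cutoff: float = DEFAULT_CUTOFF, method: str = "kdtree"
) -> InterfaceProfile:
    """Compute Dmin for every residue of ``model`` against all other chains.

    Parameters
    ----------
    cutoff
        Interface membership threshold in A; the test is inclusive (<=).
    method
        ``"kdtree"`` (default) or ``"bruteforce"`` -- identical results,
        the latter exists as a verification oracle.
    """
    if len(model.chains) < 2:
        raise NotAComplexError(f"model {model.model_id!r} has fewer than two chains")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    impl = {"kdtree": _profile_kdtree, "bruteforce": _profile_bruteforce}[method]
    return InterfaceProfile(model_id=model.model_id, dmin=impl(model, cutoff), cutoff=cutoff)


def pool_dmin_table(
    pool: ModelPool, cutoff: float = DEFAULT_CUTOFF, method: str = "kdtree"
) -> dict[str, InterfaceProfile]:
    """One :class:`InterfaceProfile` per pool model, keyed by model id."""
    return {
        m.model_id: interface_profile(m, cutoff=cutoff, method=method)
        for m in pool.models
    }


def profile_to_rows(model: ComplexModel, profile: InterfaceProfile) -> list[dict]:
    """Flatten a profile for TSV export, in the model's residue order."""
    rows = []
    iface = profile.interface_set
    for cid, res in model.iter_residues():
        rows.append(
            {
                "model_id": profile.model_id,
                "chain": cid,
                "seq_num": res.seq_num,
                "icode": res.icode,
                "res_name": res.res_name,
                "dmin": profile.dmin[res.key],
                "is_interface": res.key in iface,
            }
        )
    return rows
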