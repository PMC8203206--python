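"""Reading, writing and pooling of multi-chain structural models.

Models are held as plain dataclasses (:class:`Atom`, :class:`Residue`,
:class:`ComplexModel`) carrying only what downstream scoring needs: heavy
atoms with Cartesian coordinates in Angstroms, keyed by author chain id,
residue number and insertion code.  A :class:`ModelPool` groups >= 2 models
of the same target and records which models contain each residue key, the
correspondence used by the consensus scores.

PDB input/output is delegated to gemmi; this module applies the filtering
policy on top: heavy atoms only (no H/D), first MODEL block only, no
HETATM/waters, highest-occupancy altloc conformer kept (ties broken by file
order).  Residue equivalence across models is keyed by
``(chain_id, seq_num, icode)`` -- a pool derives from a single target
sequence, so author numbering is trusted and no alignment fallback is
attempted.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

logger = logging.getLogger("dockjury")

#: (chain_id, author seq number, insertion code) -- the residue identity
#: shared across all models of one target.
ResidueKey = tuple[str, int, str]


class DockjuryError(Exception):
    """Base class for all errors raised by this package."""


class PDBParseError(DockjuryError):
    """A structure file could not be parsed."""


class NotAComplexError(DockjuryError):
    """A model has fewer than two chains after filtering."""


class PoolError(DockjuryError):
    """A model pool violates its preconditions."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """One heavy atom: name, element symbol and Cartesian coordinates (A)."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: empty element symbol")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: list[Atom]

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.icode)

    def coord_array(self) -> np.ndarray:
        """(n_atoms, 3) array of heavy-atom coordinates."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ComplexModel:
    """A multi-chain model of one target: chains -> residues -> heavy atoms."""

    model_id: str
    chains: dict[str, list[Residue]]
    source: str = "synthetic"
    _index: dict[ResidueKey, Residue] = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.chains) < 2:
            raise NotAComplexError(
                f"model {self.model_id!r}: not a complex "
                f"({len(self.chains)} chain(s) after filtering; need >= 2)"
            )
        seen: set[ResidueKey] = set()
        for cid, residues in self.chains.items():
            for res in residues:
                if res.chain_id != cid:
                    raise ValueError(
                        f"model {self.model_id!r}: residue {res.key} filed under chain {cid!r}"
                    )
                if res.key in seen:
                    raise ValueError(f"model {self.model_id!r}: duplicate residue key {res.key}")
                if not res.atoms:
                    raise ValueError(f"model {self.model_id!r}: residue {res.key} has no heavy atoms")
                seen.add(res.key)
        self._index = {r.key: r for _, r in self.iter_residues()}

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def iter_residues(self) -> Iterator[tuple[str, Residue]]:
        """Yield (chain_id, residue) in file/chain order."""
        for cid, residues in self.chains.items():
            for res in residues:
                yield cid, res

    def residue_keys(self) -> list[ResidueKey]:
        return [r.key for _, r in self.iter_residues()]

    def get_residue(self, key: ResidueKey) -> Residue | None:
        return self._index.get(key)

    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def n_atoms(self) -> int:
        return sum(len(res.atoms) for _, res in self.iter_residues())

    def chain_arrays(self, chain_id: str) -> tuple[np.ndarray, np.ndarray, list[ResidueKey]]:
        """Flattened per-chain geometry: (coords (N,3), residue index per atom, keys).

        ``res_idx[i]`` indexes into ``keys`` for atom ``i``; used by the
        neighbour-search kernels.
        """
        residues = self.chains[chain_id]
        coords = np.concatenate([r.coord_array() for r in residues], axis=0)
        res_idx = np.repeat(np.arange(len(residues)), [len(r.atoms) for r in residues])
        return coords, res_idx, [r.key for r in residues]


@dataclass
class ModelPool:
    """>= 2 models of one target plus the residue-key correspondence."""

    target_id: str
    models: list[ComplexModel]
    correspondence: dict[ResidueKey, frozenset[str]]

    @property
    def model_ids(self) -> list[str]:
        return [m.model_id for m in self.models]

    def get_model(self, model_id: str) -> ComplexModel:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise PoolError(f"model {model_id!r} not in pool {self.target_id!r}")

    def __len__(self) -> int:
        return len(self.models)


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _validate_atom_records(path: Path) -> None:
    """Check fixed-width numeric fields of ATOM records before handing the
    file to gemmi, which silently zero-fills malformed numbers."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"{path}: line {lineno}: truncated ATOM record")
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"{path}: line {lineno}: unparsable {what} coordinate "
                        f"{line[lo:hi].strip()!r}"
                    ) from None
            occ = line[54:60].strip()
            if occ:
                try:
                    float(occ)
                except ValueError:
                    raise PDBParseError(
                        f"{path}: line {lineno}: unparsable occupancy {occ!r}"
                    ) from None


def _select_altloc(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties -> first seen."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [best[n] for n in order]


def read_pdb(path: str | Path, model_id: str | None = None) -> ComplexModel:
    """Read a PDB file (optionally .gz) into a heavy-atom :class:`ComplexModel`.

    Only ATOM records of the first MODEL block are kept; hydrogens/deuteriums,
    HETATM records and waters are discarded; for altloc duplicates the
    highest-occupancy conformer wins (ties broken by file order).

    Raises
    ------
    PDBParseError
        Missing file or an unparsable ATOM record (the message names the line).
    NotAComplexError
        Fewer than two chains remain after filtering.
    """
    path = Path(path)
    if not path.exists():
        raise PDBParseError(f"no such file: {path}")
    if model_id is None:
        model_id = path.name.removesuffix(".gz").removesuffix(".pdb")
    _validate_atom_records(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise NotAComplexError(f"{path}: no coordinate model found")
    if len(st) > 1:
        logger.info("%s: multi-model file; keeping first MODEL block only", path)

    chains: dict[str, list[Residue]] = {}
    for gchain in st[0]:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.het_flag == "H":  # HETATM: ligands, waters
                continue
            atoms: list[Atom] = []
            for gat in gres:
                if gat.element.is_hydrogen:  # H and D
                    continue
                element = gat.element.name or gat.name[:1]
                atoms.append(
                    Atom(
                        name=gat.name,
                        element=element,
                        coords=np.array([gat.pos.x, gat.pos.y, gat.pos.z]),
                        occupancy=gat.occ,
                        altloc=gat.altloc if gat.altloc != "\x00" else "",
                    )
                )
            atoms = _select_altloc(atoms)
            if not atoms:
                continue
            icode = gres.seqid.icode.strip()
            key = (gchain.name, gres.seqid.num, icode)
            if any(r.key == key for r in residues):
                logger.warning("%s: duplicate residue %s; keeping first", path, key)
                continue
            residues.append(
                Residue(
                    chain_id=gchain.name,
                    seq_num=gres.seqid.num,
                    icode=icode,
                    res_name=gres.name,
                    atoms=atoms,
                )
            )
        if residues:
            chains[gchain.name] = residues

    if len(chains) < 2:
        raise NotAComplexError(
            f"{path}: not a complex ({len(chains)} chain(s) with heavy atoms after filtering)"
        )
    return ComplexModel(model_id=model_id, chains=chains, source=str(path))


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def write_pdb(model: ComplexModel, path: str | Path) -> None:
    """Write a model as fixed-width PDB ATOM records (via gemmi).

    Residue numbers above 9999 do not fit the format and raise ``ValueError``.
    """
    path = Path(path)
    st = gemmi.Structure()
    st.name = model.model_id
    gmodel = gemmi.Model(1)
    for cid, residues in model.chains.items():
        gchain = gemmi.Chain(cid)
        for res in residues:
            if res.seq_num > 9999 or res.seq_num < -999:
                raise ValueError(
                    f"residue number {res.seq_num} does not fit fixed-width PDB format"
                )
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_num, res.icode or " ")
            gres.het_flag = "A"
            for atom in res.atoms:
                gat = gemmi.Atom()
                gat.name = atom.name
                gat.pos = gemmi.Position(*atom.coords)
                gat.occ = atom.occupancy
                gat.b_iso = 0.0
                gat.element = gemmi.Element(atom.element)
                gres.add_atom(gat)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise DockjuryError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Pool construction
# ---------------------------------------------------------------------------

def build_pool(models: list[ComplexModel], target_id: str = "target") -> ModelPool:
    """Group models of one target and build the residue-key correspondence.

    All models must share the same chain-id set.  The correspondence maps
    every residue key present in *any* model to the frozenset of model ids
    containing it; keys absent from some model are logged (scoring treats
    them per the documented missing-residue policy).
    """
    if len(models) < 2:
        raise PoolError(f"jury requires >= 2 models (got {len(models)})")
    ids = [m.model_id for m in models]
    if len(set(ids)) != len(ids):
        raise PoolError(f"duplicate model ids in pool: {sorted(ids)}")
    chain_sets = {m.model_id: frozenset(m.chain_ids) for m in models}
    ref_chains = chain_sets[models[0].model_id]
    for mid, cs in chain_sets.items():
        if cs != ref_chains:
            missing = sorted(ref_chains - cs)
            extra = sorted(cs - ref_chains)
            raise PoolError(
                f"model {mid!r} chain set {sorted(cs)} differs from "
                f"{sorted(ref_chains)} (missing {missing}, extra {extra})"
            )
    correspondence: dict[ResidueKey, set[str]] = {}
    for m in models:
        for key in m.residue_keys():
            correspondence.setdefault(key, set()).add(m.model_id)
    frozen = {k: frozenset(v) for k, v in sorted(correspondence.items())}
    n_models = len(models)
    for key, present in frozen.items():
        if len(present) < n_models:
            absent = sorted(set(ids) - present)
            logger.warning("residue %s absent from model(s) %s", key, ", ".join(absent))
    return ModelPool(target_id=target_id, models=list(models), correspondence=frozen)
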