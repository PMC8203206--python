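"""Consensus (jury) scoring of a docking model pool.

The protocol produces, for every model in a pool of alternative quaternary
structure models of one target:

* **QSscoreJury / DockQJury** -- the mean QS-score / DockQ of the model
  against every *other* model in the pool (self-comparison excluded).  A
  model scores highly when it agrees with the ensemble.
* **ModFOLDIA** -- a per-residue interface-accuracy estimate.  For each
  interface residue (Dmin <= 5 A) of the scored model, the equivalent
  residue's minimum inter-chain distances in all other models are averaged
  (MeanDmin), both distances are squashed through the sigmoid
  ``S = 1/(1+(D/20)^2)``, and ``IA = 1 - |Si - MeanSi|``.  The global
  ModFOLDIA score is the sum of IA over the model's interface residues,
  normalised by ``max(n_interface, mean n_interface across the pool)`` so
  that models cannot inflate their score by predicting tiny interfaces.
* **ModFOLDdock global** -- the unweighted mean of the available component
  scores: the three internal ones above, plus any externally supplied
  per-model scores (e.g. ProQDock- or VoroMQA-style files), which are
  averaged over chain pairs when given per chain pair.

Models are ranked by the global score, descending, ties broken by model id.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .interface_analysis import DEFAULT_CUTOFF, InterfaceProfile, pool_dmin_table
from .similarity_metrics import MetricError, PairwiseSimilarity, dockq, qs_score
from .structure_io import DockjuryError, ModelPool, PoolError, ResidueKey

logger = logging.getLogger("dockjury")

SI_HALF_DISTANCE = 20.0  # A: distance at which the contact sigmoid equals 0.5
INTERNAL_COMPONENTS = ("qs_jury", "dockq_jury", "modfoldia_global")


# ---------------------------------------------------------------------------
# Per-residue formulas
# ---------------------------------------------------------------------------

def si_score(dmin: float) -> float:
    """Contact sigmoid S = 1/(1+(Dmin/20)^2); 1 at contact, 0.5 at 20 A."""
    if dmin < 0:
        raise ValueError(f"negative distance: {dmin}")
    return 1.0 / (1.0 + (dmin / SI_HALF_DISTANCE) ** 2)


def ia_score(si: float, mean_si: float) -> float:
    """Interface accuracy IA = 1 - |Si - MeanSi|, in [0, 1]."""
    for name, v in (("si", si), ("mean_si", mean_si)):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"{name}={v} outside (0, 1]")
    return 1.0 - abs(si - mean_si)


@dataclass
class ResidueIA:
    """Interface-accuracy record for one interface residue of one model."""

    key: ResidueKey
    dmin: float
    si: float
    mean_dmin: float | None
    mean_si: float | None
    ia: float | None

    @property
    def missing(self) -> bool:
        """True when the residue exists in no other pool model."""
        return self.ia is None


# ---------------------------------------------------------------------------
# ModFOLDIA local and global
# ---------------------------------------------------------------------------

def modfoldia_local(
    pool: ModelPool,
    model_id: str,
    cutoff: float = DEFAULT_CUTOFF,
    profiles: dict[str, InterfaceProfile] | None = None,
) -> list[ResidueIA]:
    """Per-residue IA for every interface residue of ``model_id``.

    MeanDmin averages the residue's Dmin over all *other* models containing
    it (uncapped distances; interface status in the other model is
    irrelevant).  Residues absent from every other model are returned with
    ``ia=None`` and a warning.
    """
    if len(pool) < 2:
        raise PoolError("jury requires >= 2 models")
    model = pool.get_model(model_id)
    if profiles is None:
        profiles = pool_dmin_table(pool, cutoff=cutoff)
    prof = profiles[model_id]
    iface = prof.interface_set
    out: list[ResidueIA] = []
    for _, res in model.iter_residues():
        key = res.key
        if key not in iface:
            continue
        d = prof.dmin[key]
        si = si_score(d)
        others = [
            profiles[mid].dmin[key]
            for mid in pool.model_ids
            if mid != model_id and key in profiles[mid].dmin
        ]
        if not others:
            logger.warning(
                "model %s: interface residue %s missing from all other models; "
                "IA undefined", model_id, key,
            )
            out.append(ResidueIA(key=key, dmin=d, si=si, mean_dmin=None,
                                 mean_si=None, ia=None))
            continue
        mean_dmin = float(np.mean(others))
        mean_si = si_score(mean_dmin)
        out.append(ResidueIA(key=key, dmin=d, si=si, mean_dmin=mean_dmin,
                             mean_si=mean_si, ia=ia_score(si, mean_si)))
    return out


def modfoldia_global(
    pool: ModelPool,
    model_id: str,
    cutoff: float = DEFAULT_CUTOFF,
    profiles: dict[str, InterfaceProfile] | None = None,
    local: list[ResidueIA] | None = None,
) -> float:
    """Sum of per-residue IA, normalised by
    ``max(n_interface(model), mean n_interface over the pool)``.

    Residues with undefined IA (absent from every other model) contribute 0
    to the numerator but still count in ``n_interface``; an empty interface
    scores 0.
    """
    if profiles is None:
        profiles = pool_dmin_table(pool, cutoff=cutoff)
    if local is None:
        local = modfoldia_local(pool, model_id, cutoff=cutoff, profiles=profiles)
    n_iface = profiles[model_id].n_interface
    if n_iface == 0:
        return 0.0
    mean_n = float(np.mean([profiles[mid].n_interface for mid in pool.model_ids]))
    total = sum(r.ia for r in local if r.ia is not None)
    return total / max(n_iface, mean_n)


# ---------------------------------------------------------------------------
# Jury scores
# ---------------------------------------------------------------------------

def pairwise_scores(pool: ModelPool) -> dict[tuple[str, str], PairwiseSimilarity]:
    """All ordered pairwise similarities (model, reference) in the pool.

    QS is symmetric and computed once per unordered pair.  DockQ is
    directional (the second model is the reference); when a reference has
    no inter-chain contacts at all, that direction's DockQ is recorded as
    0.0 (no interface agreement is possible) with NaN RMSD components.
    """
    table: dict[tuple[str, str], PairwiseSimilarity] = {}
    for a, b in combinations(pool.models, 2):
        try:
            rec_ab = dockq(a, b)
        except MetricError as exc:
            logger.debug("dockq(%s, %s) undefined: %s", a.model_id, b.model_id, exc)
            rec_ab = None
        try:
            rec_ba = dockq(b, a)
        except MetricError as exc:
            logger.debug("dockq(%s, %s) undefined: %s", b.model_id, a.model_id, exc)
            rec_ba = None
        if rec_ab is not None:
            qs = rec_ab.qs
        elif rec_ba is not None:
            qs = rec_ba.qs
        else:
            qs = qs_score(a, b)
        if rec_ab is None:
            rec_ab = PairwiseSimilarity(a.model_id, b.model_id, qs=qs, dockq=0.0,
                                        fnat=0.0, irms=math.nan, lrms=math.nan)
        if rec_ba is None:
            rec_ba = PairwiseSimilarity(b.model_id, a.model_id, qs=qs, dockq=0.0,
                                        fnat=0.0, irms=math.nan, lrms=math.nan)
        table[(a.model_id, b.model_id)] = rec_ab
        table[(b.model_id, a.model_id)] = rec_ba
    return table


def jury_score(
    pool: ModelPool,
    model_id: str,
    metric: str = "qs",
    table: dict[tuple[str, str], PairwiseSimilarity] | None = None,
) -> float:
    """Mean pairwise ``metric`` ('qs' or 'dockq') of a model against every
    other model in the pool; self-comparison excluded."""
    if metric not in ("qs", "dockq"):
        raise ValueError(f"metric must be 'qs' or 'dockq', got {metric!r}")
    if len(pool) < 2:
        raise PoolError("jury requires >= 2 models")
    pool.get_model(model_id)  # existence check
    if table is None:
        table = pairwise_scores(pool)
    vals = [
        getattr(table[(model_id, other)], metric)
        for other in pool.model_ids
        if other != model_id
    ]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# External scores
# ---------------------------------------------------------------------------

def average_chain_pair_scores(per_pair: dict[tuple[str, str], float]) -> float:
    """Mean of per-chain-pair scores, producing one global value per model."""
    if not per_pair:
        raise ValueError("no chain-pair scores to average")
    for pair, v in per_pair.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"chain pair {pair}: score {v} outside [0, 1]")
    return float(np.mean(list(per_pair.values())))


def read_external_scores(
    path: str | Path, pool: ModelPool | None = None
) -> dict[str, dict[str, float]]:
    """Read a TSV of external per-model (or per-chain-pair) scores.

    Columns: ``method``, ``model_id``, optional ``chain_a``/``chain_b``,
    ``score``.  Rows carrying chain pairs are averaged per model.  Returns
    ``{method: {model_id: score}}``; scores are validated to [0, 1] and,
    when a pool is given, model ids must exist in it.
    """
    df = pd.read_csv(path, sep="\t", dtype={"model_id": str})
    required = {"method", "model_id", "score"}
    if not required.issubset(df.columns):
        raise DockjuryError(
            f"{path}: external score file needs columns {sorted(required)}"
        )
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        bad = df[(df["score"] < 0) | (df["score"] > 1)].iloc[0]
        raise DockjuryError(
            f"{path}: score {bad['score']} for model {bad['model_id']!r} outside [0, 1]"
        )
    out: dict[str, dict[str, float]] = {}
    has_pairs = "chain_a" in df.columns and "chain_b" in df.columns
    for (method, model_id), grp in df.groupby(["method", "model_id"], sort=True):
        if pool is not None and model_id not in pool.model_ids:
            raise DockjuryError(
                f"{path}: external score for unknown model {model_id!r}"
            )
        if has_pairs and grp["chain_a"].notna().any():
            per_pair = {
                (str(r.chain_a), str(r.chain_b)): float(r.score)
                for r in grp.itertuples()
            }
            value = average_chain_pair_scores(per_pair)
        else:
            if len(grp) != 1:
                raise DockjuryError(
                    f"{path}: multiple global rows for method {method!r}, "
                    f"model {model_id!r}"
                )
            value = float(grp["score"].iloc[0])
        out.setdefault(str(method), {})[str(model_id)] = value
    return out


# ---------------------------------------------------------------------------
# Aggregation and ranking
# ---------------------------------------------------------------------------

@dataclass
class ModelConsensus:
    """All consensus scores for one model."""

    model_id: str
    qs_jury: float
    dockq_jury: float
    modfoldia_global: float
    external: dict[str, float] = field(default_factory=dict)
    modfolddock_global: float = 0.0
    residues: list[ResidueIA] = field(default_factory=list)


@dataclass
class ConsensusScores:
    """Consensus scores for a whole pool, with the descending ranking."""

    target_id: str
    models: dict[str, ModelConsensus]
    ranking: list[str]


def aggregate_modfolddock(
    components: dict[str, dict[str, float]],
    per_residue: dict[str, list[ResidueIA]] | None = None,
    target_id: str = "target",
) -> ConsensusScores:
    """Combine per-model component scores into the global score and ranking.

    ``components`` maps model id -> {component name: value}; the three
    internal components (qs_jury, dockq_jury, modfoldia_global) are
    mandatory, external ones optional.  The global score is the unweighted
    mean over the components present for that model.  Ties in the ranking
    break by model id for determinism.
    """
    models: dict[str, ModelConsensus] = {}
    for model_id in sorted(components):
        comp = components[model_id]
        for name in INTERNAL_COMPONENTS:
            if name not in comp:
                raise DockjuryError(
                    f"model {model_id!r}: missing internal component {name!r}"
                )
        for name, v in comp.items():
            if not 0.0 <= v <= 1.0:
                raise DockjuryError(
                    f"model {model_id!r}: component {name}={v} outside [0, 1]"
                )
        external = {k: v for k, v in comp.items() if k not in INTERNAL_COMPONENTS}
        global_score = float(np.mean(list(comp.values())))
        if not external:
            logger.info(
                "model %s: 3-component aggregate (no external scores supplied)",
                model_id,
            )
        models[model_id] = ModelConsensus(
            model_id=model_id,
            qs_jury=comp["qs_jury"],
            dockq_jury=comp["dockq_jury"],
            modfoldia_global=comp["modfoldia_global"],
            external=external,
            modfolddock_global=global_score,
            residues=(per_residue or {}).get(model_id, []),
        )
    ranking = sorted(models, key=lambda mid: (-models[mid].modfolddock_global, mid))
    return ConsensusScores(target_id=target_id, models=models, ranking=ranking)


def score_pool(
    pool: ModelPool,
    external: dict[str, dict[str, float]] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> ConsensusScores:
    """Run the full consensus protocol on a pool: profiles, jury table,
    per-residue IA, aggregation and ranking."""
    if len(pool) < 2:
        raise PoolError("jury requires >= 2 models")
    profiles = pool_dmin_table(pool, cutoff=cutoff)
    table = pairwise_scores(pool)
    components: dict[str, dict[str, float]] = {}
    per_residue: dict[str, list[ResidueIA]] = {}
    for mid in pool.model_ids:
        local = modfoldia_local(pool, mid, cutoff=cutoff, profiles=profiles)
        per_residue[mid] = local
        comp = {
            "qs_jury": jury_score(pool, mid, "qs", table=table),
            "dockq_jury": jury_score(pool, mid, "dockq", table=table),
            "modfoldia_global": modfoldia_global(
                pool, mid, cutoff=cutoff, profiles=profiles, local=local
            ),
        }
        for method, scores in (external or {}).items():
            if mid in scores:
                comp[method] = scores[mid]
        components[mid] = comp
    return aggregate_modfolddock(components, per_residue=per_residue,
                                 target_id=pool.target_id)


# ---------------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------------

def scores_frame(scores: ConsensusScores) -> pd.DataFrame:
    """Ranked per-model score table as a DataFrame."""
    ext_names = sorted({k for m in scores.models.values() for k in m.external})
    rows = []
    for rank, mid in enumerate(scores.ranking, start=1):
        m = scores.models[mid]
        row = {
            "rank": rank,
            "model_id": mid,
            "qs_jury": m.qs_jury,
            "dockq_jury": m.dockq_jury,
            "modfoldia_global": m.modfoldia_global,
        }
        for name in ext_names:
            row[name] = m.external.get(name, math.nan)
        row["modfolddock_global"] = m.modfolddock_global
        rows.append(row)
    return pd.DataFrame(rows)


def write_scores_tsv(scores: ConsensusScores, path: str | Path) -> None:
    scores_frame(scores).to_csv(path, sep="\t", index=False, float_format="%.6f")


def residue_frame(scores: ConsensusScores) -> pd.DataFrame:
    """Per-residue IA table (interface residues of every model)."""
    rows = []
    for mid in scores.ranking:
        for r in scores.models[mid].residues:
            rows.append(
                {
                    "model_id": mid,
                    "chain": r.key[0],
                    "seq_num": r.key[1],
                    "icode": r.key[2],
                    "dmin": r.dmin,
                    "si": r.si,
                    "mean_dmin": r.mean_dmin,
                    "mean_si": r.mean_si,
                    "ia": r.ia,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["model_id", "chain", "seq_num", "icode", "dmin", "si",
                 "mean_dmin", "mean_si", "ia"],
    )


def write_residue_tsv(scores: ConsensusScores, path: str | Path) -> None:
    residue_frame(scores).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_caspqa(scores: ConsensusScores, pool: ModelPool, path: str | Path) -> None:
    """CASP-QA-style text: header block, then per model one line with the
    global score followed by per-residue scores in PDB numbering order
    ('X' for residues without an IA value)."""
    lines = [
        "PFRMAT QA",
        f"TARGET {scores.target_id}",
        "AUTHOR dockjury",
        "METHOD Consensus jury scoring: QS-score jury, DockQ jury and",
        "METHOD per-residue interface accuracy (IA), aggregated as an",
        "METHOD unweighted mean of available component scores.",
        "MODEL 1",
        "QMODE 2",
    ]
    for mid in scores.ranking:
        m = scores.models[mid]
        by_key = {r.key: r for r in m.residues}
        model = pool.get_model(mid)
        fields = [mid, f"{m.modfolddock_global:.4f}"]
        for _, res in model.iter_residues():
            r = by_key.get(res.key)
            fields.append("X" if r is None or r.ia is None else f"{r.ia:.4f}")
        lines.append(" ".join(fields))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pairwise_tsv(
    table: dict[tuple[str, str], PairwiseSimilarity], path: str | Path
) -> None:
    rows = [
        {
            "model_a": rec.model_a,
            "model_b": rec.model_b,
            "qs": rec.qs,
            "dockq": rec.dockq,
            "fnat": rec.fnat,
            "irms": rec.irms,
            "lrms": rec.lrms,
        }
        for rec in (table[k] for k in sorted(table))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")
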