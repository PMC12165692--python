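"""Phenotype algebra: rank tumor subpopulations by survival risk.

The idea: average the embeddings-side representation of the whole tumor
(pseudo-bulk "T") and of each phenotype group, embed them jointly with a
bulk RNA-seq survival cohort through the same trained model, and score
"removal" queries ``delta = E(T) - E(P)`` with a random survival forest
(RSF) trained on the bulk embeddings.  A query whose removal yields the
*lowest* predicted risk marks the subtracted phenotype as the *most
aggressive* — taking it out of the tumor improves prognosis the most.

The protocol bootstraps the RSF: 50 models by default, each trained on an
80% subsample (without replacement) of the bulk cohort, 1000 trees each;
queries are ranked by the median of their bootstrap risk scores.
"""

from __future__ import annotations

import json
import logging
import re
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors
from sksurv.ensemble import RandomSurvivalForest
from sksurv.util import Surv

from .corpus import build_documents
from .embed import EmbeddingMatrix, EmbeddingModel, cosine_similarity, infer_vectors
from .matrix import ExpressionMatrix
from .preprocess import minmax_scale_int, normalize_cpm_log, zscore_scale

logger = logging.getLogger(__name__)

REFERENCE_NAME = "T"


# ---------------------------------------------------------------------------
# Survival cohort
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCohort:
    """Bulk expression (genes x samples) paired with right-censored outcomes.

    ``time`` is the non-negative follow-up duration in days and ``event``
    is 1/True for death (event observed) and 0/False for censoring.
    """

    expression: ExpressionMatrix
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        n = self.expression.n_cells
        if len(self.time) != n or len(self.event) != n:
            raise ValueError("time/event must align with expression samples")
        if np.any(~np.isfinite(self.time)) or np.any(self.time < 0):
            raise ValueError("follow-up times must be finite and >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.cell_ids

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @classmethod
    def from_table(cls, expression: ExpressionMatrix, table: pd.DataFrame) -> "SurvivalCohort":
        """Pair expression with a (sample_id, time, event) table, dropping
        samples that lack follow-up time, status, or expression."""
        t = table.copy()
        t.columns = [c.lower() for c in t.columns]
        t = t.set_index(t.columns[0]) if "sample_id" not in t.columns else t.set_index("sample_id")
        t.index = t.index.astype(str)
        keep = [
            s for s in expression.cell_ids
            if s in t.index and np.isfinite(t.loc[s, "time"]) and not pd.isna(t.loc[s, "event"])
        ]
        dropped = expression.n_cells - len(keep)
        if dropped:
            logger.info("SurvivalCohort: excluded %d sample(s) without follow-up "
                        "time, survival status, or expression", dropped)
        if not keep:
            raise ValueError("no samples with both expression and survival information")
        sub = expression.subset_cells(keep)
        return cls(sub, t.loc[keep, "time"].to_numpy(float), t.loc[keep, "event"].to_numpy())


# ---------------------------------------------------------------------------
# Class balancing (SMOTE-style oversampling)
# ---------------------------------------------------------------------------

def balance_classes(
    E_trg: ExpressionMatrix,
    labels: pd.Series,
    seed: int,
    k_neighbors: int = 5,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Oversample minority groups to the majority size by interpolation.

    Each synthetic cell is ``x + u * (x_nn - x)`` for a real cell x, one of
    its ``k`` nearest same-group neighbors x_nn (k reduced to group_size - 1
    when the group is small), and u ~ Uniform(0, 1).  Real cells are
    preserved verbatim; synthetic columns are appended after them.
    """
    labels = pd.Series(labels)
    if not labels.index.is_unique or set(labels.index) != set(E_trg.cell_ids):
        labels = pd.Series(np.asarray(labels), index=E_trg.cell_ids)
    labels = labels.loc[E_trg.cell_ids].astype(str)
    sizes = labels.value_counts()
    if len(sizes) < 2:
        raise ValueError("balance_classes needs >= 2 groups")
    singletons = sizes[sizes < 2]
    if len(singletons):
        raise ValueError(
            f"group(s) of size 1 cannot be oversampled: {list(singletons.index)}; "
            "merge them with a related group or exclude them"
        )
    target = int(sizes.max())
    new_cols, new_ids, new_labels = [], [], []
    for group in sorted(sizes.index):
        size = int(sizes[group])
        need = target - size
        if need == 0:
            continue
        idx = np.flatnonzero((labels == group).to_numpy())
        X = E_trg.values[:, idx].T  # cells x genes within the group
        kk = min(k_neighbors, size - 1)
        nn = NearestNeighbors(n_neighbors=kk + 1).fit(X)
        _, nbrs = nn.kneighbors(X)
        rng = np.random.default_rng([seed, zlib.crc32(group.encode()) & 0x7FFFFFFF])
        base = rng.integers(0, size, need)
        pick = rng.integers(0, kk, need)
        u = rng.random(need)
        for i in range(need):
            x = X[base[i]]
            xn = X[nbrs[base[i], pick[i] + 1]]
            new_cols.append(x + u[i] * (xn - x))
            new_ids.append(f"{group}__synth{i}")
            new_labels.append(group)
    if not new_cols:
        return E_trg, labels
    values = np.hstack([E_trg.values, np.array(new_cols).T])
    out = ExpressionMatrix(values, list(E_trg.gene_ids), E_trg.cell_ids + new_ids,
                           layer=E_trg.layer, unit=E_trg.unit)
    out_labels = pd.concat([labels, pd.Series(new_labels, index=new_ids)])
    logger.info("balance_classes: %d groups balanced to %d cells each "
                "(%d synthetic cells added)", len(sizes), target, len(new_ids))
    return out, out_labels


# ---------------------------------------------------------------------------
# Pseudo-bulk vectors and the query grammar
# ---------------------------------------------------------------------------

@dataclass
class PseudoBulkVector:
    name: str                      # canonical query name, e.g. "T-(MES+CLA)"
    gene_profile: np.ndarray       # per-gene mean expression of the subtracted set
    gene_ids: list[str]
    role: str                      # reference | phenotype | combination
    groups: list[str] = field(default_factory=list)


def parse_query(query: str) -> list[str]:
    """Parse an algebra expression into the list of subtracted groups.

    Grammar: ``T`` alone (the reference), ``T - G`` for one group, or
    ``T - (G1 + G2 [+ ...])`` for a combination.  ``-`` may appear once at
    top level; ``+`` only inside the parentheses.
    """
    s = query.strip()
    if s == REFERENCE_NAME:
        return []
    m = re.fullmatch(r"T\s*-\s*(.+)", s)
    if not m:
        raise ValueError(f"cannot parse algebra expression {query!r}; "
                         "expected 'T', 'T - G' or 'T - (G1 + G2)'")
    rest = m.group(1).strip()
    if rest.startswith("("):
        if not rest.endswith(")"):
            raise ValueError(f"unbalanced parentheses in {query!r}")
        groups = [g.strip() for g in rest[1:-1].split("+")]
    else:
        if "+" in rest or "(" in rest or ")" in rest or "-" in rest:
            raise ValueError(f"'+' is only allowed inside parentheses: {query!r}")
        groups = [rest]
    if any(not g for g in groups):
        raise ValueError(f"empty group name in {query!r}")
    return groups


def canonical_name(groups: list[str]) -> str:
    if not groups:
        return REFERENCE_NAME
    if len(groups) == 1:
        return f"T-{groups[0]}"
    return "T-(" + "+".join(groups) + ")"


def make_pseudobulk(
    E_trg: ExpressionMatrix,
    labels: pd.Series,
    queries: list[str],
) -> list[PseudoBulkVector]:
    """Build the reference pseudo-bulk T and one per algebra query.

    T is the mean expression over all cells; a single-group query carries
    the mean over that group's cells; a combination ``(P_a + P_b)`` the mean
    over the union of the groups' cells (so the listed order of a and b is
    irrelevant).
    """
    labels = pd.Series(labels).loc[E_trg.cell_ids].astype(str)
    available = sorted(labels.unique())
    out = [PseudoBulkVector(REFERENCE_NAME, E_trg.values.mean(axis=1),
                            list(E_trg.gene_ids), "reference")]
    seen = {REFERENCE_NAME}
    for q in queries:
        groups = parse_query(q)
        if not groups:
            continue  # reference is always present
        unknown = [g for g in groups if g not in available]
        if unknown:
            raise ValueError(f"unknown group(s) {unknown} in query {q!r}; "
                             f"available groups: {available}")
        name = canonical_name(groups)
        if name in seen:
            continue
        seen.add(name)
        mask = labels.isin(groups).to_numpy()
        profile = E_trg.values[:, mask].mean(axis=1)
        role = "phenotype" if len(groups) == 1 else "combination"
        out.append(PseudoBulkVector(name, profile, list(E_trg.gene_ids), role, groups))
    return out


# ---------------------------------------------------------------------------
# Joint embedding of bulk cohort + pseudo-bulks
# ---------------------------------------------------------------------------

def joint_embed(
    cohort: SurvivalCohort,
    pseudobulks: list[PseudoBulkVector],
    model: EmbeddingModel,
    seed: int,
    infer_epochs: int = 50,
    min_common_genes: int = 50,
) -> tuple[EmbeddingMatrix, dict[str, str]]:
    """Embed bulk samples and pseudo-bulk vectors in one shared pass.

    The cohort and pseudo-bulk profiles are restricted to common genes,
    the bulk matrix is depth-normalized (CPM + log; skipped for TPM/FPKM
    or pre-normalized input), each gene is z-scored across the *combined*
    columns (absorbing bulk-vs-pseudo-bulk scale differences), rescaled to
    [0, 10] integers, encoded as documents, and inferred through the same
    trained model so all vectors share one latent space.

    Returns the embedding matrix (bulk samples first, then pseudo-bulks)
    and a role tag per id (``bulk`` or the pseudo-bulk role).
    """
    if not model.is_trained:
        raise ValueError("joint_embed requires a trained model")
    if not pseudobulks:
        raise ValueError("no pseudo-bulk vectors given")
    pb_genes = pseudobulks[0].gene_ids
    for pb in pseudobulks[1:]:
        if pb.gene_ids != pb_genes:
            raise ValueError("pseudo-bulk vectors must share one gene set")
    common = [g for g in cohort.expression.gene_ids if g in set(pb_genes)]
    if len(common) < min_common_genes:
        raise ValueError(
            f"only {len(common)} genes shared between cohort and target "
            f"(< {min_common_genes}): insufficient shared features"
        )
    bulk = cohort.expression.subset_genes(common)
    if bulk.layer == "raw":
        bulk = normalize_cpm_log(bulk)
    pb_idx = [pb_genes.index(g) for g in common]
    pb_mat = np.column_stack([pb.gene_profile[pb_idx] for pb in pseudobulks])
    names = [pb.name for pb in pseudobulks]
    if set(names) & set(bulk.cell_ids):
        raise ValueError("pseudo-bulk names collide with bulk sample ids")
    combined = ExpressionMatrix(
        np.hstack([bulk.values, pb_mat]), common, bulk.cell_ids + names,
        layer="normalized", unit=bulk.unit,
    )
    scaled = minmax_scale_int(zscore_scale(combined, common))
    corpus = build_documents(scaled, seed=seed, stream_by="content")
    emb = infer_vectors(model, corpus, infer_epochs=infer_epochs, seed=seed)
    roles = {s: "bulk" for s in bulk.cell_ids}
    roles.update({pb.name: pb.role for pb in pseudobulks})
    return emb, roles


def delta_embedding(ref: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Removal query: componentwise ``E(T) - E(P)``."""
    ref = np.asarray(ref, dtype=float).ravel()
    query = np.asarray(query, dtype=float).ravel()
    if ref.shape != query.shape:
        raise ValueError(f"dimension mismatch: {ref.shape} vs {query.shape}")
    return ref - query


# ---------------------------------------------------------------------------
# Random survival forest and the bootstrap protocol
# ---------------------------------------------------------------------------

def train_rsf(
    bulk_embeddings: EmbeddingMatrix,
    cohort: SurvivalCohort,
    n_estimators: int = 1000,
    seed: int = 0,
    min_samples_leaf: int = 20,
    **rsf_params,
) -> RandomSurvivalForest:
    """Fit a right-censored random survival forest on bulk embeddings."""
    if list(bulk_embeddings.ids) != list(cohort.sample_ids):
        bulk_embeddings = bulk_embeddings.subset(cohort.sample_ids)
    if cohort.n_events == 0:
        raise ValueError("cannot fit a survival forest on a cohort with zero events")
    if cohort.n_events < 2:
        raise ValueError("need >= 2 observed events to fit a survival forest")
    y = Surv.from_arrays(event=cohort.event, time=cohort.time)
    rsf = RandomSurvivalForest(
        n_estimators=n_estimators,
        min_samples_leaf=min_samples_leaf,
        random_state=int(seed) % (2**31),
        n_jobs=1,
        **rsf_params,
    )
    rsf.fit(bulk_embeddings.vectors, y)
    return rsf


def eval_survival(fn, times: np.ndarray) -> np.ndarray:
    """Evaluate a fitted step function S(t) on arbitrary non-negative times.

    Before the first observed event time S(t) = 1 (no event can have
    occurred yet); beyond the last knot the final value is carried forward.
    """
    times = np.asarray(times, dtype=float)
    lo, hi = fn.x[0], fn.x[-1]
    out = np.empty(times.shape[0])
    below = times < lo
    above = times > hi
    mid = ~(below | above)
    out[below] = 1.0
    out[above] = fn.y[-1]
    if mid.any():
        out[mid] = fn(times[mid])
    return out


@dataclass
class RiskReport:
    """Bootstrap risk distributions and the aggressiveness ranking."""

    queries: list[str]
    boot_scores: np.ndarray            # queries x n_boot
    median_risk: dict[str, float]
    survival_curves: dict[str, tuple[np.ndarray, np.ndarray]]  # name -> (t, S)
    ranking: list[str]                 # ascending median risk
    n_boot: int
    seed: int
    cosine_to_reference: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.boot_scores = np.asarray(self.boot_scores, dtype=float)
        if self.boot_scores.shape != (len(self.queries), self.n_boot):
            raise ValueError("boot_scores must be (n_queries, n_boot)")
        if sorted(self.ranking) != sorted(self.queries):
            raise ValueError("ranking must be a permutation of queries")
        for name, (t, s) in self.survival_curves.items():
            s = np.asarray(s)
            if np.any(s < -1e-9) or np.any(s > 1 + 1e-9) or np.any(np.diff(s) > 1e-9):
                raise ValueError(f"survival curve for {name!r} is not a valid "
                                 "non-increasing function in [0, 1]")

    @property
    def most_aggressive(self) -> str:
        """The query whose removal yields the lowest median risk; its
        subtracted phenotype is the most aggressive."""
        return self.ranking[0]

    def to_dict(self) -> dict:
        return {
            "queries": self.queries,
            "boot_scores": self.boot_scores.tolist(),
            "median_risk": self.median_risk,
            "ranking": self.ranking,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "cosine_to_reference": self.cosine_to_reference,
            "survival_curves": {
                k: {"time": t.tolist(), "S": np.asarray(s).tolist()}
                for k, (t, s) in self.survival_curves.items()
            },
            "interpretation": (
                "queries sorted by ascending median bootstrap risk; the "
                "subtracted phenotype of the lowest-scoring query is the "
                "most aggressive"
            ),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))


def bootstrap_risk(
    queries: EmbeddingMatrix,
    bulk_embeddings: EmbeddingMatrix,
    cohort: SurvivalCohort,
    n_boot: int = 50,
    train_frac: float = 0.8,
    seed: int = 0,
    n_estimators: int = 1000,
    min_samples_leaf: int = 20,
    cosine_to_reference: dict[str, float] | None = None,
) -> RiskReport:
    """Bootstrap the RSF and rank removal queries by median risk.

    For each of ``n_boot`` iterations a fraction ``train_frac`` of the bulk
    cohort is subsampled *without replacement* with a seed-derived stream,
    an RSF is fitted, and every query (a delta embedding) is scored.  The
    per-query survival curve is the pointwise mean of the bootstrap models'
    step functions on the union time grid.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if list(bulk_embeddings.ids) != list(cohort.sample_ids):
        bulk_embeddings = bulk_embeddings.subset(cohort.sample_ids)
    n = len(cohort.sample_ids)
    m = max(2, int(np.floor(train_frac * n)))
    X = bulk_embeddings.vectors
    Q = queries.vectors
    scores = np.empty((len(queries.ids), n_boot))
    curves = [[] for _ in queries.ids]
    grids = []
    for b in range(n_boot):
        rng = np.random.default_rng([seed, 101, b])
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = SurvivalCohort(
            cohort.expression.subset_cells([cohort.sample_ids[i] for i in idx]),
            cohort.time[idx], cohort.event[idx],
        )
        if sub.n_events < 2:
            raise ValueError(f"bootstrap subsample {b} has < 2 events; "
                             "increase cohort size or event rate")
        y = Surv.from_arrays(event=sub.event, time=sub.time)
        rs = int(np.random.default_rng([seed, 202, b]).integers(2**31))
        rsf = RandomSurvivalForest(
            n_estimators=n_estimators, min_samples_leaf=min_samples_leaf,
            random_state=rs, n_jobs=1,
        )
        rsf.fit(X[idx], y)
        scores[:, b] = rsf.predict(Q)
        fns = rsf.predict_survival_function(Q)
        grids.append(np.asarray(rsf.unique_times_))
        for qi, fn in enumerate(fns):
            curves[qi].append(fn)
    grid = np.unique(np.concatenate([[0.0]] + grids))
    surv = {
        name: (grid, np.mean([eval_survival(fn, grid) for fn in curves[qi]], axis=0))
        for qi, name in enumerate(queries.ids)
    }
    med = {name: float(np.median(scores[qi])) for qi, name in enumerate(queries.ids)}
    ranking = sorted(queries.ids, key=lambda q: (med[q], q))
    return RiskReport(
        queries=list(queries.ids), boot_scores=scores, median_risk=med,
        survival_curves=surv, ranking=ranking, n_boot=n_boot, seed=seed,
        cosine_to_reference=cosine_to_reference or {},
    )


def rank_report(report: RiskReport, outdir: str | Path | None = None) -> pd.DataFrame:
    """Human-readable aggressiveness ranking (and TSV export).

    Rank 1 is the query with the lowest median risk; its subtracted
    phenotype is called the most aggressive.  Queries with exactly equal
    medians share the interpretation and are flagged ``tied``.
    """
    med = report.median_risk
    counts = pd.Series(list(med.values())).value_counts()
    rows = []
    for rank, name in enumerate(report.ranking, start=1):
        rows.append({
            "rank": rank,
            "query": name,
            "median_risk": med[name],
            "mean_risk": float(report.boot_scores[report.queries.index(name)].mean()),
            "tied": bool(counts.get(med[name], 0) > 1),
            "cosine_to_reference": report.cosine_to_reference.get(name, float("nan")),
            "interpretation": (
                "subtracted phenotype most aggressive" if rank == 1
                else "subtracted phenotype least aggressive" if rank == len(report.ranking)
                else ""
            ),
        })
    table = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "ranking.tsv", sep="\t", index=False)
        curve_rows = []
        for name, (t, s) in report.survival_curves.items():
            curve_rows.append(pd.DataFrame({"query": name, "time": t, "S": s}))
        pd.concat(curve_rows).to_csv(outdir / "survival_curves.tsv", sep="\t", index=False)
    return table
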