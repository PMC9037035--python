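"""Iterative Stochastic Elimination (ISE) filter-ensemble classification.

The classifier is an ensemble of *filters*: conjunctions of descriptor-range
clauses.  A molecule passes a filter when every clause interval contains its
descriptor value.  Training proceeds by iterated stochastic search over a
pool of (descriptor, bin) values:

1. descriptors are split into equal-frequency bins on the training set;
2. each iteration draws a batch of random candidate filters (1..max_clauses
   clauses, each a contiguous bin range of one descriptor) and scores each
   by its training Matthews correlation coefficient (MCC), treating "passes
   the filter" as a Best prediction;
3. (descriptor, bin) values over-represented among the bottom-scoring
   candidates are eliminated from the pool, shrinking the search space;
4. the loop runs a fixed number of iterations; once the pool is stable the
   later iterations sample the narrowed space.  Candidates that ever reached
   the MCC floor survive and are greedily deduplicated.

Scoring a molecule against a model yields the molecular index
(n_pass - n_fail) / n_filters in [-1, 1].  Stratified k-fold cross-validation
scores every molecule exactly once as test data and merges the per-fold
filter sets into one final model.  An enrichment curve (true/false positives
above each index threshold) then fixes the screening cutoff.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .criteria import BEST, WORST
from .descriptors import DescriptorTable, manifest_hash
from .errors import ConfigurationError, ModelingError

log = logging.getLogger("ppiscreen.ise")

# ---------------------------------------------------------------------------
# parameters and model types


@dataclass(frozen=True)
class ISEParams:
    """Hyperparameters of the ISE search.

    n_bins: equal-frequency bins per descriptor.
    max_clauses: maximum clauses per candidate filter.
    n_candidates: candidates drawn per iteration.
    max_iterations: iteration cap; the loop also stops when no elimination
        occurs.
    worst_fraction: bottom fraction of candidates inspected for elimination.
    over_representation: elimination requires a (descriptor, bin) to appear
        in the bottom fraction at >= this multiple of its expected share.
    min_total_count: minimum appearances before a value may be eliminated.
    mcc_floor: training MCC a filter must reach to survive.
    dedup_max_overlap: greedy deduplication drops a filter whose clause-set
        Jaccard overlap with an already kept filter reaches this value.
    max_filters: cap on surviving filters per training run.
    mcc_weighted_index: weight each filter vote by its training MCC.
    """

    n_bins: int = 10
    max_clauses: int = 4
    n_candidates: int = 2000
    max_iterations: int = 50
    worst_fraction: float = 0.25
    over_representation: float = 2.0
    min_total_count: int = 8
    mcc_floor: float = 0.7
    dedup_max_overlap: float = 0.5
    max_filters: int = 1000
    mcc_weighted_index: bool = False

    def __post_init__(self) -> None:
        if self.n_bins < 2 or self.max_clauses < 1 or self.n_candidates < 1:
            raise ConfigurationError("invalid ISE search sizes")
        if not (0 < self.worst_fraction < 1):
            raise ConfigurationError("worst_fraction must be in (0, 1)")
        if not (-1.0 <= self.mcc_floor <= 1.0):
            raise ConfigurationError("mcc_floor must lie in [-1, 1]")


@dataclass(frozen=True)
class Clause:
    """One descriptor-range condition: lower < value <= upper.

    Infinite bounds mark ranges open at the training extremes, so unseen
    values beyond the training range still satisfy the outermost bins.
    """

    descriptor: str
    lower: float  # -inf allowed
    upper: float  # +inf allowed

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ConfigurationError(f"clause bounds must satisfy lower < upper "
                                     f"({self.descriptor}: {self.lower}, {self.upper})")

    def contains(self, value: float) -> bool:
        return self.lower < value <= self.upper


@dataclass(frozen=True)
class DescriptorFilter:
    clauses: tuple[Clause, ...]
    train_mcc: float

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ConfigurationError("a filter needs at least one clause")
        if not -1.0 <= self.train_mcc <= 1.0:
            raise ConfigurationError("train_mcc outside [-1, 1]")

    def passes(self, row) -> bool:
        return all(c.contains(float(row[c.descriptor])) for c in self.clauses)


@dataclass
class ISEModel:
    """Trained ensemble: filters sorted by training MCC, plus provenance."""

    filters: list[DescriptorFilter]
    descriptor_names: list[str]
    descriptor_hash: str
    params: ISEParams
    seed: int

    def to_json(self) -> str:
        def enc(x):
            if x == math.inf:
                return None
            if x == -math.inf:
                return None
            return x

        payload = {
            "format_version": 1,
            "descriptor_hash": self.descriptor_hash,
            "descriptor_names": self.descriptor_names,
            "params": asdict(self.params),
            "seed": self.seed,
            "filters": [
                {
                    "train_mcc": f.train_mcc,
                    "clauses": [
                        {"descriptor": c.descriptor,
                         "lower": enc(c.lower),
                         "upper": enc(c.upper)}
                        for c in f.clauses
                    ],
                }
                for f in self.filters
            ],
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ISEModel":
        payload = json.loads(text)
        filters = [
            DescriptorFilter(
                clauses=tuple(
                    Clause(c["descriptor"],
                           -math.inf if c["lower"] is None else c["lower"],
                           math.inf if c["upper"] is None else c["upper"])
                    for c in f["clauses"]
                ),
                train_mcc=f["train_mcc"],
            )
            for f in payload["filters"]
        ]
        return cls(filters, payload["descriptor_names"], payload["descriptor_hash"],
                   ISEParams(**payload["params"]), payload["seed"])


@dataclass(frozen=True)
class IndexScore:
    molecule_id: str
    index: float
    n_pass: int
    n_fail: int


@dataclass
class EnrichmentCurve:
    """TP/FP counts of molecules scoring at or above each index threshold."""

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    ratio: np.ndarray  # tp/fp, np.inf where fp == 0


# ---------------------------------------------------------------------------
# binning


@dataclass
class Binning:
    """Equal-frequency bin edges per descriptor, fitted on training data only."""

    descriptor_names: list[str]
    edges: list[np.ndarray]  # interior edges; len(edges[d]) + 1 bins

    @property
    def n_bins(self) -> list[int]:
        return [len(e) + 1 for e in self.edges]

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Map a (molecules, descriptors) matrix to integer bin indices."""
        out = np.empty(values.shape, dtype=np.int32)
        for d, e in enumerate(self.edges):
            out[:, d] = np.searchsorted(e, values[:, d], side="left")
        return out


def bin_descriptors(table: DescriptorTable | pd.DataFrame, n_bins: int = 10) -> Binning:
    """Equal-frequency bin edges for every descriptor of the (training) table.

    Edges sit at the k/n_bins quantiles.  Descriptors with fewer distinct
    values than bins get fewer bins; constant columns collapse to a single
    bin with a warning.
    """
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")
    frame = table.values if isinstance(table, DescriptorTable) else table
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = []
    for name in frame.columns:
        col = frame[name].to_numpy(dtype=float)
        e = np.unique(np.quantile(col, qs))
        e = e[(e > col.min()) & (e <= col.max())]  # drop degenerate outer edges
        if len(e) == 0:
            warnings.warn(f"descriptor {name!r} has a single bin", stacklevel=2)
        edges.append(e)
    return Binning(list(frame.columns), edges)


# ---------------------------------------------------------------------------
# MCC


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    if min(tp, fp, tn, fn) < 0:
        raise ConfigurationError("confusion counts must be non-negative")
    if tp + fp + tn + fn == 0:
        raise ConfigurationError("empty confusion matrix")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _mcc_vector(tp, fp, tn, fn) -> np.ndarray:
    tp = tp.astype(float)
    fp = fp.astype(float)
    tn = tn.astype(float)
    fn = fn.astype(float)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out = np.zeros_like(tp)
    ok = denom > 0
    out[ok] = (tp[ok] * tn[ok] - fp[ok] * fn[ok]) / np.sqrt(denom[ok])
    return out


# ---------------------------------------------------------------------------
# training


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) runs of True values."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def _require_labels(table: DescriptorTable) -> np.ndarray:
    if table.labels is None:
        raise ModelingError("descriptor table carries no Best/Worst labels")
    lab = table.labels
    n_best = int((lab == BEST).sum())
    n_worst = int((lab == WORST).sum())
    if n_best < 5 or n_worst < 5:
        raise ModelingError(
            f"need >= 5 molecules per class, got Best={n_best} Worst={n_worst}")
    return (lab == BEST).to_numpy()


def train_ise(table: DescriptorTable, params: ISEParams = ISEParams(),
              seed: int = 0) -> ISEModel:
    """Train an ISE filter ensemble on a labeled descriptor table.

    Deterministic given the seed.  Returns only filters whose training MCC
    reaches ``params.mcc_floor``; an empty ensemble (nothing separable)
    triggers a warning but is returned so callers can inspect the failure.
    """
    y = _require_labels(table)
    X = table.values.to_numpy(dtype=float)
    n, d = X.shape
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-bin warnings handled via pool
        binning = bin_descriptors(table, params.n_bins)
    B = binning.assign(X)
    nb = np.array(binning.n_bins)
    max_nb = int(nb.max())

    # pool[d, b]: (descriptor, bin) still available to the sampler
    pool = np.zeros((d, max_nb), dtype=bool)
    for j in range(d):
        if nb[j] > 1:  # constant columns never enter the pool
            pool[j, : nb[j]] = True

    n_best = int(y.sum())
    n_worst = n - n_best
    survivors: dict[tuple, float] = {}
    C = params.max_clauses
    K = params.n_candidates
    n_bottom = max(1, int(K * params.worst_fraction))

    for _ in range(params.max_iterations):
        usable = np.flatnonzero(pool.any(axis=1))
        if len(usable) == 0:
            break
        # run lookup tables: for each pooled (d, b), the containing run
        run_start = np.full((d, max_nb), -1, dtype=np.int32)
        run_end = np.full((d, max_nb), -1, dtype=np.int32)
        pooled_bins = np.full((d, max_nb), -1, dtype=np.int32)
        n_pooled = np.zeros(d, dtype=np.int32)
        for j in usable:
            bins = np.flatnonzero(pool[j])
            n_pooled[j] = len(bins)
            pooled_bins[j, : len(bins)] = bins
            for s, e in _contiguous_runs(pool[j]):
                run_start[j, s : e + 1] = s
                run_end[j, s : e + 1] = e

        # --- sample K candidates, vectorized ------------------------------
        n_clauses = rng.integers(1, C + 1, size=K)
        # distinct descriptors per candidate via random keys
        keys = rng.random((K, len(usable)))
        order = np.argsort(keys, axis=1)[:, :C]
        dsel = usable[order]  # (K, C)
        active = np.arange(C)[None, :] < n_clauses[:, None]
        # anchor bin uniform over pooled bins of each chosen descriptor
        u = rng.random((K, C))
        anchor_pos = np.minimum((u * n_pooled[dsel]).astype(np.int64),
                                n_pooled[dsel] - 1)
        anchor = pooled_bins[dsel, anchor_pos]
        s = run_start[dsel, anchor]
        e = run_end[dsel, anchor]
        lo = s + np.minimum((rng.random((K, C)) * (anchor - s + 1)).astype(np.int64),
                            anchor - s)
        hi = anchor + np.minimum((rng.random((K, C)) * (e - anchor + 1)).astype(np.int64),
                                 e - anchor)

        # --- evaluate ------------------------------------------------------
        cols = B[:, dsel]  # (n, K, C)
        ok = (cols >= lo[None]) & (cols <= hi[None])
        ok |= ~active[None]
        passed = ok.all(axis=2)  # (n, K)
        tp = passed[y].sum(axis=0)
        fp = passed[~y].sum(axis=0)
        scores = _mcc_vector(tp, fp, n_worst - fp, n_best - tp)

        # --- record survivors ---------------------------------------------
        for k in np.flatnonzero(scores >= params.mcc_floor):
            clauses = tuple(sorted(
                (int(dsel[k, c]), int(lo[k, c]), int(hi[k, c]))
                for c in range(C) if active[k, c]
            ))
            if scores[k] > survivors.get(clauses, -2.0):
                survivors[clauses] = float(scores[k])

        # --- eliminate over-represented (descriptor, bin) values -----------
        bottom = np.argsort(scores, kind="stable")[:n_bottom]
        bottom_mask = np.zeros(K, dtype=bool)
        bottom_mask[bottom] = True
        total = np.zeros((d, max_nb), dtype=np.int64)
        bot = np.zeros((d, max_nb), dtype=np.int64)
        for c in range(C):
            act = active[:, c]
            for b in range(max_nb):
                covered = act & (lo[:, c] <= b) & (hi[:, c] >= b)
                np.add.at(total, (dsel[covered, c], b), 1)
                covered_bot = covered & bottom_mask
                np.add.at(bot, (dsel[covered_bot, c], b), 1)
        expected = total * params.worst_fraction
        eliminate = (pool & (total >= params.min_total_count)
                     & (bot >= params.over_representation * expected)
                     & (expected > 0))
        log.debug("iteration: pool=%d survivors=%d best_mcc=%.3f eliminate=%d",
                  pool.sum(), len(survivors), scores.max(), eliminate.sum())
        # once the pool is stable the remaining iterations keep sampling the
        # narrowed space, which is where most surviving filters come from
        pool &= ~eliminate

    # --- deduplicate greedily by clause overlap ----------------------------
    ranked = sorted(survivors.items(), key=lambda kv: (-kv[1], kv[0]))
    kept: list[tuple] = []
    kept_mcc: list[float] = []
    for clauses, score in ranked:
        cset = set(clauses)
        dup = any(
            len(cset & set(other)) / len(cset | set(other)) >= params.dedup_max_overlap
            for other in kept
        )
        if not dup:
            kept.append(clauses)
            kept_mcc.append(score)
        if len(kept) >= params.max_filters:
            break

    filters = []
    for clauses, score in zip(kept, kept_mcc):
        built = []
        for j, blo, bhi in clauses:
            e = binning.edges[j]
            lower = -math.inf if blo == 0 else float(e[blo - 1])
            upper = math.inf if bhi >= len(e) else float(e[bhi])
            built.append(Clause(binning.descriptor_names[j], lower, upper))
        filters.append(DescriptorFilter(tuple(built), score))
    filters.sort(key=lambda f: (-f.train_mcc,
                                tuple((c.descriptor, c.lower, c.upper)
                                      for c in f.clauses)))
    if not filters:
        warnings.warn("ISE training produced no filter at the MCC floor; "
                      "the classes are not separable at these settings",
                      stacklevel=2)
    return ISEModel(
        filters=filters,
        descriptor_names=list(table.values.columns),
        descriptor_hash=table.hash,
        params=params,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# scoring


def score_index(model: ISEModel, row) -> IndexScore:
    """Molecular index of one molecule: (n_pass - n_fail) / n_filters.

    ``row`` maps descriptor names to values (a dict or pandas Series whose
    name, if any, becomes the molecule id).  A missing descriptor raises.
    """
    if not model.filters:
        raise ModelingError("model has no filters to score against")
    needed = {c.descriptor for f in model.filters for c in f.clauses}
    missing = sorted(k for k in needed if k not in row)
    if missing:
        raise ModelingError(f"row lacks descriptor(s): {', '.join(missing)}")
    if model.params.mcc_weighted_index:
        w = np.array([f.train_mcc for f in model.filters])
        votes = np.array([1.0 if f.passes(row) else -1.0 for f in model.filters])
        n_pass = int((votes > 0).sum())
        index = float(np.dot(w, votes) / w.sum()) if w.sum() else 0.0
    else:
        n_pass = sum(1 for f in model.filters if f.passes(row))
        index = (2 * n_pass - len(model.filters)) / len(model.filters)
    mol_id = str(getattr(row, "name", "") or "")
    return IndexScore(mol_id, index, n_pass, len(model.filters) - n_pass)


def score_table(model: ISEModel, frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorized index scores for every row of a descriptor frame."""
    if not model.filters:
        raise ModelingError("model has no filters to score against")
    needed = sorted({c.descriptor for f in model.filters for c in f.clauses})
    missing = [k for k in needed if k not in frame.columns]
    if missing:
        raise ModelingError(f"table lacks descriptor(s): {', '.join(missing)}")
    n = len(frame)
    passes = np.ones((n, len(model.filters)), dtype=bool)
    for j, f in enumerate(model.filters):
        for c in f.clauses:
            v = frame[c.descriptor].to_numpy(dtype=float)
            passes[:, j] &= (v > c.lower) & (v <= c.upper)
    n_pass = passes.sum(axis=1)
    n_fail = len(model.filters) - n_pass
    if model.params.mcc_weighted_index:
        w = np.array([f.train_mcc for f in model.filters])
        index = (np.where(passes, 1.0, -1.0) @ w) / w.sum()
    else:
        index = (n_pass - n_fail) / len(model.filters)
    return pd.DataFrame(
        {"index": index, "n_pass": n_pass, "n_fail": n_fail}, index=frame.index
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CrossValidationResult:
    fold_models: list[ISEModel]
    scores: pd.DataFrame  # index: molecule id; columns: index, n_pass, n_fail, label, fold
    final_model: ISEModel


def cross_validate(table: DescriptorTable, k: int = 5,
                   params: ISEParams = ISEParams(), seed: int = 0
                   ) -> CrossValidationResult:
    """Stratified k-fold protocol: train on k-1 folds, score the held-out fold.

    Every molecule is scored exactly once as test data; the final model is
    the deduplicated union of the per-fold filter sets, sorted by MCC.
    """
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    y = _require_labels(table)
    if min(int(y.sum()), int((~y).sum())) < k:
        raise ModelingError(f"each class needs >= {k} molecules for {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    fold_models: list[ISEModel] = []
    pieces = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(table.values, y)):
        sub = DescriptorTable(
            values=table.values.iloc[train_idx],
            labels=table.labels.iloc[train_idx],
        )
        fold_seed = (int(seed) * 1000003 + 7919 * fold + 1) % (2**31)
        model = train_ise(sub, params, fold_seed)
        fold_models.append(model)
        test_frame = table.values.iloc[test_idx]
        if model.filters:
            scored = score_table(model, test_frame)
        else:
            scored = pd.DataFrame(
                {"index": 0.0, "n_pass": 0, "n_fail": 0}, index=test_frame.index
            )
        scored["label"] = table.labels.iloc[test_idx].to_numpy()
        scored["fold"] = fold
        pieces.append(scored)

    scores = pd.concat(pieces).loc[table.values.index]
    seen: dict[tuple, DescriptorFilter] = {}
    for model in fold_models:
        for f in model.filters:
            key = tuple((c.descriptor, c.lower, c.upper) for c in f.clauses)
            if key not in seen or f.train_mcc > seen[key].train_mcc:
                seen[key] = f
    merged = sorted(seen.values(),
                    key=lambda f: (-f.train_mcc,
                                   tuple((c.descriptor, c.lower, c.upper)
                                         for c in f.clauses)))
    final = ISEModel(
        filters=merged,
        descriptor_names=list(table.values.columns),
        descriptor_hash=table.hash,
        params=params,
        seed=int(seed),
    )
    return CrossValidationResult(fold_models, scores, final)


# ---------------------------------------------------------------------------
# enrichment


def enrichment_curve(indexes, labels) -> EnrichmentCurve:
    """TP/FP above each index threshold, positives being Best molecules.

    ``labels`` may be booleans or the Best/Worst strings.  Thresholds are the
    sorted unique observed indexes together with -1; at each threshold t,
    tp counts positives with index >= t and fp negatives with index >= t.
    """
    idx = np.asarray(indexes, dtype=float)
    lab = np.asarray(labels)
    if lab.dtype.kind in "USO":
        pos = lab == BEST
    else:
        pos = lab.astype(bool)
    if idx.shape != pos.shape:
        raise ConfigurationError("indexes and labels differ in length")
    if not pos.any():
        raise ModelingError("no positive (Best) molecules in the label set")
    thresholds = np.unique(np.concatenate(([-1.0], idx)))
    tp = np.array([(pos & (idx >= t)).sum() for t in thresholds])
    fp = np.array([(~pos & (idx >= t)).sum() for t in thresholds])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fp > 0, tp / np.maximum(fp, 1), np.inf)
    return EnrichmentCurve(thresholds, tp, fp, ratio)


def select_cutoff(curve: EnrichmentCurve, min_ratio: float) -> float:
    """Smallest index threshold whose TP/FP ratio reaches ``min_ratio``.

    Infinite ratios (no false positives) qualify.  Raises when no threshold
    attains the requested enrichment, reporting the maximum achievable.
    """
    if len(curve.thresholds) == 0:
        raise ConfigurationError("empty enrichment curve")
    ok = np.flatnonzero(curve.ratio >= min_ratio)
    if len(ok) == 0:
        best = curve.ratio.max()
        raise ModelingError(
            f"no threshold reaches TP/FP {min_ratio}; maximum achievable is {best}")
    return float(curve.thresholds[ok[0]])
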