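"""Network fingerprint: PCA/UMAP and stable/variable parameter selection.

The fingerprint of a culture is its multi-parameter activity profile. The
analysis z-scores the feature table, runs PCA, retains the components
explaining more than a variance threshold (2.5% for MEA network parameters,
5% for single-cell intrinsic-property tables), embeds the retained scores in
2-D with UMAP, and isolates parameters by their loadings:

* variable parameters — the top-k (default 10) largest-|loading| parameters
  of each of the first two retained PCs (greatest variance);
* stable parameters — the top-k of each of the last two retained PCs (least
  variance among retained);
* parameters stable across several datasets are intersected, and those
  contributing exclusively to the stable PCs (never to the variable ones) are
  reported as the robust, condition-insensitive parameter set.

All selection steps are deterministic: ties in |loading| break by catalogue
(column) order, and row order never affects the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import reduce
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FingerprintConfig",
    "FingerprintResult",
    "scale_features",
    "run_pca",
    "select_pcs",
    "embed_umap",
    "top_loading_parameters",
    "variable_stable_sets",
    "stable_across_datasets",
    "exclusive_selection",
    "variable_in_one_not_other",
    "fingerprint",
]


@dataclass(frozen=True)
class FingerprintConfig:
    variance_threshold: float = 0.025  # 0.05 for single-cell property tables
    top_k: int = 10
    n_variable_pcs: int = 2
    n_stable_pcs: int = 2
    umap_neighbors: int = 15
    umap_min_dist: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.variance_threshold < 1:
            raise ValueError("variance_threshold must lie in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be at least 1")


@dataclass
class FingerprintResult:
    parameters: list[str]
    loadings: np.ndarray  # parameters x PCs
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # rows x PCs
    retained_pcs: list[int] = field(default_factory=list)
    embedding: np.ndarray | None = None
    variable_set: set[str] = field(default_factory=set)
    stable_set: set[str] = field(default_factory=set)
    row_index: pd.Index | None = None


def scale_features(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column (mean 0, SD 1 with ddof=0).

    Rows containing any missing value are dropped first, then zero-variance
    columns; both removals are logged with counts. Raises if fewer than two
    complete rows remain.
    """
    numeric = table.select_dtypes(include=[np.number])
    complete = numeric.dropna(axis=0)
    n_dropped_rows = len(numeric) - len(complete)
    if n_dropped_rows:
        logger.info("dropped %d rows with missing values", n_dropped_rows)
    if len(complete) < 2:
        raise ValueError("fewer than 2 complete rows remain after dropping missing values")
    sd = complete.std(ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        logger.info("dropped %d zero-variance columns: %s", len(constant), constant)
    kept = complete.drop(columns=constant)
    if kept.shape[1] == 0:
        raise ValueError("no variable columns remain")
    return (kept - kept.mean()) / kept.std(ddof=0)


def run_pca(scaled: pd.DataFrame) -> FingerprintResult:
    """Centered SVD-based PCA of the scaled table.

    Loadings columns are unit-norm PC directions with a fixed sign convention:
    the largest-|loading| entry of each PC is positive. Explained-variance
    ratios are non-increasing, and the scaled matrix is exactly reconstructed
    from all PCs.
    """
    X = np.asarray(scaled, dtype=float)
    X = X - X.mean(axis=0)
    n = X.shape[0]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-|loading| entry of each PC positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    var = S**2 / max(n - 1, 1)
    ratio = var / var.sum() if var.sum() > 0 else var
    return FingerprintResult(
        parameters=list(scaled.columns),
        loadings=Vt.T,
        explained_variance_ratio=ratio,
        scores=U * S,
        row_index=scaled.index,
    )


def select_pcs(ratios: np.ndarray, variance_threshold: float) -> list[int]:
    """Indices of PCs explaining strictly more than the threshold fraction."""
    retained = [i for i, r in enumerate(ratios) if r > variance_threshold]
    if not retained:
        raise ValueError(
            f"no principal component exceeds the {variance_threshold:.1%} variance threshold"
        )
    return retained


def embed_umap(scores: np.ndarray, config: FingerprintConfig = FingerprintConfig()) -> np.ndarray:
    """2-D UMAP embedding of the retained-PC scores, deterministic per seed."""
    import umap  # deferred: heavy import

    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] < config.umap_neighbors + 1:
        raise ValueError(
            f"need at least umap_neighbors+1={config.umap_neighbors + 1} rows, got {scores.shape[0]}"
        )
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=config.umap_neighbors,
        min_dist=config.umap_min_dist,
        random_state=config.seed,
    )
    return np.asarray(reducer.fit_transform(scores), dtype=float)


def top_loading_parameters(
    result: FingerprintResult, pc: int, top_k: int = 10
) -> list[str]:
    """Parameter names with the largest |loading| on one PC, descending.

    Ties break by catalogue (column) order, so the output is stable across
    runs and row permutations. If ``top_k`` exceeds the parameter count, all
    parameters are returned with a log note.
    """
    if not 0 <= pc < result.loadings.shape[1]:
        raise IndexError(f"PC {pc} out of range")
    mag = np.abs(result.loadings[:, pc])
    if top_k > mag.size:
        logger.info("top_k=%d exceeds %d parameters; returning all", top_k, mag.size)
        top_k = mag.size
    # stable sort on -|loading| keeps catalogue order among exact ties
    order = np.argsort(-mag, kind="stable")[:top_k]
    return [result.parameters[i] for i in order]


def variable_stable_sets(
    result: FingerprintResult, config: FingerprintConfig = FingerprintConfig()
) -> tuple[set[str], set[str]]:
    """Union of top-k parameters of the first/last retained PCs.

    Variable parameters load on the first ``n_variable_pcs`` retained PCs;
    stable parameters load on the last ``n_stable_pcs`` retained PCs. Requires
    at least four retained PCs so the two groups cannot overlap trivially.
    """
    retained = result.retained_pcs
    if len(retained) < config.n_variable_pcs + config.n_stable_pcs:
        raise ValueError(
            f"need at least {config.n_variable_pcs + config.n_stable_pcs} retained PCs, "
            f"got {len(retained)}"
        )
    variable: set[str] = set()
    for pc in retained[: config.n_variable_pcs]:
        variable.update(top_loading_parameters(result, pc, config.top_k))
    stable: set[str] = set()
    for pc in retained[-config.n_stable_pcs:]:
        stable.update(top_loading_parameters(result, pc, config.top_k))
    return variable, stable


def stable_across_datasets(stable_sets: Sequence[set[str]]) -> set[str]:
    """Parameters stable in every dataset (set intersection, >=2 sets)."""
    if len(stable_sets) < 2:
        raise ValueError("need stable sets from at least two datasets")
    out = reduce(set.intersection, (set(s) for s in stable_sets))
    if not out:
        logger.warning("no parameter is stable across all %d datasets", len(stable_sets))
    return out


def exclusive_selection(stable_set: set[str], variable_set: set[str]) -> set[str]:
    """Parameters contributing only to the stable PCs, never the variable ones."""
    return set(stable_set) - set(variable_set)


def variable_in_one_not_other(variable_a: set[str], variable_b: set[str]) -> set[str]:
    """Parameters variable in dataset A but not in dataset B."""
    return set(variable_a) - set(variable_b)


def fingerprint(
    table: pd.DataFrame,
    config: FingerprintConfig = FingerprintConfig(),
    embed: bool = True,
) -> FingerprintResult:
    """Full fingerprint analysis: scale -> PCA -> retain -> UMAP -> select."""
    scaled = scale_features(table)
    result = run_pca(scaled)
    result.retained_pcs = select_pcs(result.explained_variance_ratio, config.variance_threshold)
    if embed and scaled.shape[0] >= config.umap_neighbors + 1:
        result.embedding = embed_umap(result.scores[:, result.retained_pcs], config)
    elif embed:
        logger.info("too few rows for UMAP (%d); skipping embedding", scaled.shape[0])
    try:
        result.variable_set, result.stable_set = variable_stable_sets(result, config)
    except ValueError as exc:
        logger.info("parameter selection skipped: %s", exc)
    return result
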