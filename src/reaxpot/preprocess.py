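"""Preprocessing of intensity/abundance matrices.

The fixed pipeline order is: half-missing filter -> per-feature minimum
imputation -> quantile normalization -> enzyme-activity aggregation (gene or
protein matrices only) -> log2(x + 1). The order is enforced through a state
flag on :class:`AbundanceMatrix` that only moves raw -> normalized -> log2.

Enzyme activity follows the limiting-subunit / additive-isoenzyme model: per
sample, an isoenzyme is as abundant as its scarcest measured subunit, and
isoenzyme activities add.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .network import EnzymeDefinition

__all__ = [
    "AbundanceMatrix",
    "PreprocessError",
    "filter_missing",
    "impute_min",
    "quantile_normalize",
    "log_transform",
    "aggregate_enzyme_activity",
    "pca_summary",
    "preprocess_pipeline",
]

REFERENCE = "reference"
TEST = "test"

_STATES = ("raw", "normalized", "log2")


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class AbundanceMatrix:
    """A features x samples matrix with a two-group design.

    ``data`` rows are features, columns are samples. ``groups`` maps each
    sample id to ``"reference"`` or ``"test"``; both groups need at least two
    samples. ``state`` tracks the preprocessing stage.
    """

    data: pd.DataFrame
    groups: dict[str, str]
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise PreprocessError(f"unknown state {self.state!r}")
        missing = [s for s in self.data.columns if s not in self.groups]
        if missing:
            raise PreprocessError(f"samples without group label: {missing}")
        bad = sorted({g for g in self.groups.values()} - {REFERENCE, TEST})
        if bad:
            raise PreprocessError(f"group labels must be reference/test, got {bad}")
        counts = pd.Series([self.groups[s] for s in self.data.columns]).value_counts()
        if counts.get(REFERENCE, 0) < 2 or counts.get(TEST, 0) < 2:
            raise PreprocessError("both groups need >= 2 samples")
        if not self.data.index.is_unique:
            raise PreprocessError("duplicate feature ids")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.data.columns if self.groups[s] == group]

    def _with(self, data: pd.DataFrame, state: str | None = None) -> "AbundanceMatrix":
        return replace(self, data=data, state=state or self.state)


def _require_state(m: AbundanceMatrix, *states: str, op: str) -> None:
    if m.state not in states:
        raise PreprocessError(f"{op}: expected state in {states}, got {m.state!r}")


def filter_missing(m: AbundanceMatrix) -> AbundanceMatrix:
    """Drop features with more than half of the sample values missing.

    A feature survives iff its number of missing values is at most
    floor(n_samples / 2); order is preserved.
    """
    _require_state(m, "raw", op="filter_missing")
    n = m.data.shape[1]
    keep = m.data.isna().sum(axis=1) <= n // 2
    if not keep.any():
        raise PreprocessError("filter_missing removed every feature")
    return m._with(m.data.loc[keep])


def impute_min(m: AbundanceMatrix) -> AbundanceMatrix:
    """Replace remaining missing values by the feature's minimum observed value.

    Missingness is read as concentrations below the detection limit, so the
    smallest observed value of the same feature is the natural stand-in.
    """
    _require_state(m, "raw", op="impute_min")
    if m.data.isna().all(axis=1).any():
        raise PreprocessError("impute_min: feature with no observed values (run filter_missing)")
    mins = m.data.min(axis=1, skipna=True)
    return m._with(m.data.mask(m.data.isna(), mins, axis=0))


def quantile_normalize(m: AbundanceMatrix) -> AbundanceMatrix:
    """Force every sample onto the common distribution of mean order statistics.

    Ties within a sample receive the mean of the reference quantiles they
    span, so within-sample rank order is preserved up to ties.
    """
    _require_state(m, "raw", op="quantile_normalize")
    if m.data.isna().any().any():
        raise PreprocessError("quantile_normalize needs a complete matrix (impute first)")
    values = m.data.to_numpy(dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty_like(ref)
        mapped[order] = ref
        # average the reference values across tied positions
        out[:, j] = pd.Series(mapped).groupby(pd.Series(col)).transform("mean").to_numpy()
    return m._with(pd.DataFrame(out, index=m.data.index, columns=m.data.columns), "normalized")


def log_transform(m: AbundanceMatrix, pseudo_count: float = 1.0) -> AbundanceMatrix:
    """log2(value + pseudo_count); the default pseudo count of 1 maps 0 to 0."""
    _require_state(m, "normalized", "raw", op="log_transform")
    if (m.data.to_numpy() < 0).any():
        raise PreprocessError("log_transform: negative values")
    return m._with(np.log2(m.data + pseudo_count), "log2")


def aggregate_enzyme_activity(
    genes: AbundanceMatrix, definitions: dict[str, EnzymeDefinition]
) -> AbundanceMatrix:
    """Aggregate gene/protein abundances into per-enzyme activities.

    Per sample: isoenzyme activity = min over its *measured* subunit genes;
    enzyme activity = sum over isoenzymes that have at least one measured
    subunit. Enzymes with no measured subunit anywhere are absent from the
    output. Aggregation runs on the pre-log (linear) scale.
    """
    if not definitions:
        raise PreprocessError("empty enzyme definition map")
    _require_state(genes, "raw", "normalized", op="aggregate_enzyme_activity")
    measured = set(genes.data.index)
    rows: dict[str, np.ndarray] = {}
    for eid, enz in definitions.items():
        total: np.ndarray | None = None
        for iso in enz.isoenzymes:
            present = [g for g in iso if g in measured]
            if not present:
                continue
            activity = genes.data.loc[present].min(axis=0).to_numpy(dtype=float)
            total = activity if total is None else total + activity
        if total is not None:
            rows[eid] = total
    if not rows:
        raise PreprocessError("no enzyme has a measured subunit")
    data = pd.DataFrame.from_dict(rows, orient="index", columns=genes.data.columns)
    return replace(genes, data=data)


def pca_summary(
    m: AbundanceMatrix, top_fraction: float = 0.10, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample scores of the leading principal components.

    Selects the ``ceil(top_fraction * n_features)`` most variable features
    (pass ``top_fraction=1.0`` for metabolite matrices, which use every
    feature), centers each feature, and returns (scores, explained-variance
    fractions). Features are centered but not scaled.
    """
    _require_state(m, "log2", op="pca_summary")
    if m.data.shape[0] < 3 or m.data.shape[1] < 3:
        raise PreprocessError("pca_summary needs >= 3 features and >= 3 samples")
    if not 0 < top_fraction <= 1:
        raise PreprocessError("top_fraction must be in (0, 1]")
    n_top = math.ceil(top_fraction * m.data.shape[0])
    variances = m.data.var(axis=1)
    top = variances.sort_values(ascending=False, kind="mergesort").index[:n_top]
    sub = m.data.loc[m.data.index.isin(set(top))]
    x = sub.to_numpy(dtype=float).T  # samples x features
    k = min(n_components, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x - x.mean(axis=0))
    frame = pd.DataFrame(
        scores, index=m.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    frame["group"] = [m.groups[s] for s in m.sample_ids]
    return frame, pca.explained_variance_ratio_


def preprocess_pipeline(
    m: AbundanceMatrix,
    enzyme_definitions: dict[str, EnzymeDefinition] | None = None,
    quantile: bool = True,
    pseudo_count: float = 1.0,
) -> AbundanceMatrix:
    """Run the full fixed-order pipeline on one matrix.

    When ``enzyme_definitions`` is given the matrix is treated as a gene or
    protein matrix and aggregated to enzyme activities before the log
    transform.
    """
    m = impute_min(filter_missing(m))
    if quantile:
        m = quantile_normalize(m)
    if enzyme_definitions is not None:
        m = aggregate_enzyme_activity(m, enzyme_definitions)
    return log_transform(m, pseudo_count=pseudo_count)
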