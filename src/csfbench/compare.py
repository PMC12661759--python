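"""Cross-workflow detection, overlap, reproducibility and ordination.

All operations take :class:`~csfbench.assembly.QuantMatrix` inputs where
"detected" means non-missing (the parser already maps zero intensity to
absent). Outputs are plain DataFrames, written as TSV by the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .assembly import QuantMatrix
from .stats import spearman

__all__ = [
    "MembershipSets",
    "detection_counts",
    "membership_sets",
    "detection_tiers",
    "correlation_matrix",
    "pca_scores",
    "rank_abundance",
]

#: detection-frequency tier boundaries, features binned into (lower, upper]
DEFAULT_TIER_CUTS = (0.9, 0.5, 0.1)


@dataclass
class MembershipSets:
    """Per-workflow feature universes and exclusive-region counts."""

    universes: dict[str, set[str]]
    region_counts: dict[frozenset, int]

    @property
    def union_size(self) -> int:
        return len(set().union(*self.universes.values()))


def detection_counts(matrices: dict[str, QuantMatrix]) -> pd.DataFrame:
    """Non-missing feature count per sample, with per-workflow medians.

    Returns a tidy frame (workflow, sample, patient, n_detected,
    workflow_median); all-missing samples are listed with count 0.
    """
    rows = []
    for workflow in sorted(matrices):
        matrix = matrices[workflow]
        counts = matrix.detected().sum(axis=0)
        median = float(np.median(counts.to_numpy())) if len(counts) else np.nan
        for sample in matrix.samples:
            rows.append(
                {
                    "workflow": workflow,
                    "sample": sample,
                    "patient": matrix.patient_of(sample),
                    "n_detected": int(counts[sample]),
                    "workflow_median": median,
                }
            )
    return pd.DataFrame(rows)


def membership_sets(matrices: dict[str, QuantMatrix]) -> MembershipSets:
    """Exact exclusive-intersection (UpSet) counts across workflows.

    A feature's universe membership is detection in >= 1 sample of the
    workflow; each feature lands in exactly one of the 2^k - 1 regions.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two workflows")
    universes = {
        w: {
            f
            for f, hit in matrices[w].detected().any(axis=1).items()
            if hit
        }
        for w in matrices
    }
    region_counts: dict[frozenset, int] = {}
    for feature in set().union(*universes.values()):
        region = frozenset(w for w, u in universes.items() if feature in u)
        region_counts[region] = region_counts.get(region, 0) + 1
    return MembershipSets(universes=universes, region_counts=region_counts)


def membership_table(sets: MembershipSets) -> pd.DataFrame:
    """Region counts as a tidy frame, exclusive (single-workflow) rows first."""
    rows = []
    for region, count in sets.region_counts.items():
        rows.append(
            {
                "workflows": "&".join(sorted(region)),
                "degree": len(region),
                "count": count,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["degree", "workflows"])
        .reset_index(drop=True)
    )


def detection_tiers(
    matrix: QuantMatrix, cuts: tuple[float, ...] = DEFAULT_TIER_CUTS
) -> pd.DataFrame:
    """Bin features by detection frequency into half-open (lower, upper] tiers.

    With the default cuts the tiers are (0.9, 1], (0.5, 0.9], (0.1, 0.5]
    and (0, 0.1]; the three displayed in typical reproducibility charts
    plus the explicit (0.5, 0.9] class so the tiers partition the
    universe.
    """
    if not matrix.samples:
        raise ValueError("matrix has no samples")
    freq = matrix.detected().sum(axis=1) / len(matrix.samples)
    freq = freq[freq > 0]
    edges = [0.0] + sorted(cuts) + [1.0]
    labels = [f"({edges[i]:g},{edges[i + 1]:g}]" for i in range(len(edges) - 1)]
    rows = []
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        count = int(((freq > lo) & (freq <= hi)).sum())
        rows.append({"tier": labels[i], "lower": lo, "upper": hi, "count": count})
    out = pd.DataFrame(rows)[::-1].reset_index(drop=True)  # top tier first
    assert out["count"].sum() == len(freq)
    return out


def correlation_matrix(
    matrix: QuantMatrix, min_shared: int = 3
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise-complete Spearman correlation between samples.

    Pairs sharing fewer than ``min_shared`` features are NaN. The second
    return value is the sample display order from average-linkage
    hierarchical clustering on distance 1 - r (NaN treated as distance 1).
    """
    samples = matrix.samples
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    values = matrix.values
    n = len(samples)
    corr = np.ones((n, n))
    for i, j in combinations(range(n), 2):
        x = values.iloc[:, i].to_numpy()
        y = values.iloc[:, j].to_numpy()
        shared = (~np.isnan(x)) & (~np.isnan(y))
        r = spearman(x[shared], y[shared]) if shared.sum() >= min_shared else np.nan
        corr[i, j] = corr[j, i] = r
    frame = pd.DataFrame(corr, index=samples, columns=samples)
    distance = np.clip(1.0 - np.nan_to_num(corr, nan=0.0), 0.0, 2.0)
    np.fill_diagonal(distance, 0.0)
    distance = 0.5 * (distance + distance.T)  # guard fp asymmetry
    order = [samples[i] for i in leaves_list(average(squareform(distance)))]
    return frame, order


def pca_scores(matrix: QuantMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample PCA of complete features (no imputation), centered, via SVD.

    Returns sample scores (rows = samples, columns = PC1..) and the
    explained-variance fractions, which sum to 1.
    """
    if len(matrix.samples) < 3:
        raise ValueError("need at least three samples")
    complete = matrix.values.dropna(axis=0, how="any")
    if len(complete) < 2:
        raise ValueError("fewer than two complete features")
    X = complete.to_numpy().T  # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U * s
    variance = s**2
    fractions = variance / variance.sum() if variance.sum() > 0 else variance
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    frame = pd.DataFrame(scores, index=matrix.samples, columns=cols)
    frame.insert(0, "method", [matrix.method_of(s_) for s_ in matrix.samples])
    frame.insert(1, "patient", [matrix.patient_of(s_) for s_ in matrix.samples])
    return frame, fractions


def rank_abundance(
    matrix: QuantMatrix, marker_panel: list[str] | None = None
) -> pd.DataFrame:
    """Features ranked by descending median intensity across samples.

    Medians are over observed values only; ties break lexicographically by
    feature id. Marker-panel members absent from the matrix are appended
    with detection fraction 0 and no rank.
    """
    marker_panel = list(marker_panel or [])
    med = matrix.values.median(axis=1, skipna=True)
    det = matrix.detected().sum(axis=1) / max(1, len(matrix.samples))
    frame = pd.DataFrame(
        {"feature": matrix.features, "median_log2": med, "detection_fraction": det}
    )
    frame = frame.sort_values(
        ["median_log2", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    panel = set(marker_panel)
    frame["is_marker"] = frame["feature"].isin(panel)
    missing = [m for m in sorted(panel) if m not in set(matrix.features)]
    if missing:
        extra = pd.DataFrame(
            {
                "feature": missing,
                "median_log2": np.nan,
                "detection_fraction": 0.0,
                "rank": np.nan,
                "is_marker": True,
            }
        )
        frame = pd.concat([frame, extra], ignore_index=True)
    return frame
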