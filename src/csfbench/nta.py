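"""Nanoparticle-tracking-analysis size-distribution processing.

Instrument exports ("...-ExperimentSummary.csv") hold one row per size
bin with the bin center (nm) and one particle-concentration column per
30-second video capture. Counts are multiplied by the sample's dilution
factor (4 for the 150,000 x g pellet, 5 for the 20,000 x g pellet in the
default configuration), then summarized per bin as the mean and standard
error (sd / sqrt(n_videos), n-1 denominator) across the technical
replicate videos. Two fractions are merged by exact bin-center match
(outer join) for side-by-side comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FormatError, get_logger

__all__ = [
    "SizeDistribution",
    "load_nta",
    "normalize_and_summarize",
    "merge_distributions",
]

BIN_MATCH_TOL = 1e-9  # nm; instrument grids are fixed, no interpolation


@dataclass
class SizeDistribution:
    fraction: str
    dilution_factor: float
    table: pd.DataFrame  # columns: bin_center_nm, mean, se (NaN if 1 video)

    @property
    def total_concentration(self) -> float:
        return float(self.table["mean"].sum())


def load_nta(path) -> pd.DataFrame:
    """Read a raw NTA export into a bins x videos concentration matrix.

    The first column is the bin center; every remaining column is one
    video capture. Bin centers must increase strictly; non-numeric cells
    are errors with coordinates.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError("NTA file needs a bin column and >= 1 video column")
    bin_col = df.columns[0]
    matrix = pd.DataFrame(index=df.index)
    for col in df.columns:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise FormatError(
                f"non-numeric cell at row {row}, column {col!r}: {df[col][row]!r}"
            )
        matrix[col] = parsed
    centers = matrix[bin_col].to_numpy()
    if np.any(np.isnan(centers)) or np.any(np.diff(centers) <= 0):
        raise FormatError("bin centers must be strictly increasing")
    matrix = matrix.rename(columns={bin_col: "bin_center_nm"})
    return matrix


def normalize_and_summarize(
    raw: pd.DataFrame, dilution_factor: float, fraction: str = ""
) -> SizeDistribution:
    """Dilution-normalize video counts and average them per bin."""
    if dilution_factor <= 0:
        raise ValueError("dilution factor must be positive")
    videos = [c for c in raw.columns if c != "bin_center_nm"]
    counts = raw[videos].to_numpy(dtype=float) * dilution_factor
    mean = counts.mean(axis=1)
    if len(videos) > 1:
        se = counts.std(axis=1, ddof=1) / np.sqrt(len(videos))
    else:
        se = np.full(len(raw), np.nan)
    table = pd.DataFrame(
        {
            "bin_center_nm": raw["bin_center_nm"].to_numpy(),
            "mean": mean,
            "se": se,
        }
    )
    return SizeDistribution(fraction=fraction, dilution_factor=dilution_factor, table=table)


def merge_distributions(a: SizeDistribution, b: SizeDistribution) -> pd.DataFrame:
    """Outer-join two size distributions on (exactly matching) bin centers."""
    ta = a.table.rename(
        columns={"mean": f"mean_{a.fraction}", "se": f"se_{a.fraction}"}
    ).copy()
    tb = b.table.rename(
        columns={"mean": f"mean_{b.fraction}", "se": f"se_{b.fraction}"}
    ).copy()
    # quantize centers so "exact match" tolerates fp noise below BIN_MATCH_TOL
    ta["_key"] = np.round(ta["bin_center_nm"] / BIN_MATCH_TOL).astype(np.int64)
    tb["_key"] = np.round(tb["bin_center_nm"] / BIN_MATCH_TOL).astype(np.int64)
    shared = set(ta["_key"]) & set(tb["_key"])
    if not shared:
        get_logger().warning(
            "merge_distributions: no shared bins between %s and %s",
            a.fraction,
            b.fraction,
        )
    merged = ta.merge(tb.drop(columns=["bin_center_nm"]), on="_key", how="outer")
    centers_b = dict(zip(tb["_key"], tb["bin_center_nm"]))
    merged["bin_center_nm"] = [
        c if not np.isnan(c) else centers_b[k]
        for c, k in zip(merged["bin_center_nm"], merged["_key"])
    ]
    merged = merged.drop(columns=["_key"]).sort_values("bin_center_nm")
    return merged.reset_index(drop=True)
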