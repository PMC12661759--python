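"""N-glycosite calling from deamidation evidence.

PNGase F converts a glycosylated asparagine to aspartate, so a confidently
localized deamidation inside the canonical sequon N-[!P]-[S/T/C] marks a
former N-glycosite. Sites are retained when the localization probability
strictly exceeds the threshold (default 0.8) AND the protein position sits
in a sequon of the reference sequence. Glycoprotein quantification sums
raw site intensities per protein before the log2 transform; single-site
proteins are kept (no two-peptide rule at this level).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SiteTable
from .assembly import QuantMatrix

__all__ = [
    "GlycoSite",
    "GlycoSiteSet",
    "scan_sequons",
    "call_glycosites",
    "quantify_glycoproteins",
]

_SEQON_THIRD = frozenset("STC")


@dataclass
class GlycoSite:
    accession: str
    position: int  # 1-based asparagine index in the protein
    sequon: str
    localization_probability: float
    intensities: dict[str, float] = field(default_factory=dict)


@dataclass
class GlycoSiteSet:
    sites: list[GlycoSite]
    threshold: float
    rejected: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sites)


def scan_sequons(protein_sequence: str) -> list[int]:
    """All 1-based positions of N in N-[!P]-[S/T/C] sequons.

    Overlapping sequons are all reported; the last two residues of the
    protein cannot start a sequon.
    """
    seq = protein_sequence
    positions = []
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in _SEQON_THIRD:
            positions.append(i + 1)
    return positions


def call_glycosites(
    sites: SiteTable,
    proteome: dict[str, str],
    threshold: float = 0.8,
) -> GlycoSiteSet:
    """Retain deamidation sites that are confident, in-sequon glycosites.

    A site passes when ``localization_probability > threshold`` (strict)
    and its protein position is a sequon start in the reference sequence.
    Positions beyond the protein length and accessions absent from the
    proteome are hard errors; duplicate (accession, position) records have
    their intensities summed and their highest localization kept.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold outside [0, 1]: {threshold}")
    sequon_cache: dict[str, frozenset[int]] = {}
    retained: dict[tuple[str, int], GlycoSite] = {}
    rejected = {"low_localization": 0, "not_in_sequon": 0}
    for rec in sites.records:
        seq = proteome.get(rec.accession)
        if seq is None:
            raise KeyError(f"accession {rec.accession} missing from proteome")
        if rec.position > len(seq):
            raise ValueError(
                f"site {rec.accession}:{rec.position} beyond protein length "
                f"{len(seq)}"
            )
        if rec.localization_probability <= threshold:
            rejected["low_localization"] += 1
            continue
        if rec.accession not in sequon_cache:
            sequon_cache[rec.accession] = frozenset(scan_sequons(seq))
        if rec.position not in sequon_cache[rec.accession]:
            rejected["not_in_sequon"] += 1
            continue
        key = (rec.accession, rec.position)
        if key in retained:
            site = retained[key]
            site.localization_probability = max(
                site.localization_probability, rec.localization_probability
            )
            for s, v in rec.intensities.items():
                site.intensities[s] = site.intensities.get(s, 0.0) + v
        else:
            retained[key] = GlycoSite(
                accession=rec.accession,
                position=rec.position,
                sequon=seq[rec.position - 1 : rec.position + 2],
                localization_probability=rec.localization_probability,
                intensities=dict(rec.intensities),
            )
    ordered = [retained[k] for k in sorted(retained)]
    return GlycoSiteSet(sites=ordered, threshold=threshold, rejected=rejected)


def quantify_glycoproteins(siteset: GlycoSiteSet, sheet) -> QuantMatrix:
    """Per-protein log2 of summed raw glycosite intensities.

    ``sheet`` is the run SampleSheet; columns are restricted to samples
    carrying intensity in at least one site unless listed there.
    """
    if not siteset.sites:
        raise ValueError("empty glycosite set")
    raw: dict[str, dict[str, float]] = {}
    observed_samples: set[str] = set()
    for site in siteset.sites:
        bucket = raw.setdefault(site.accession, {})
        for sample, value in site.intensities.items():
            bucket[sample] = bucket.get(sample, 0.0) + value
            observed_samples.add(sample)
    observed_methods = {
        sheet.samples[s]["method"] for s in observed_samples if s in sheet.samples
    }
    # all sheet samples of the workflow(s) carrying sites, so unobserved
    # samples show up as missing rather than vanishing
    samples = sorted(
        s
        for s in sheet.samples
        if sheet.samples[s]["method"] in observed_methods
    )
    samples += sorted(observed_samples - set(samples) - set(sheet.samples))
    meta = {
        s: sheet.samples.get(s, {"method": "unknown", "patient": "unknown"})
        for s in samples
    }
    df = pd.DataFrame(
        [
            [
                math.log2(raw[acc][s]) if s in raw[acc] else np.nan
                for s in samples
            ]
            for acc in sorted(raw)
        ],
        index=sorted(raw),
        columns=samples,
        dtype=float,
    )
    return QuantMatrix(values=df, sample_meta=meta)


def siteset_to_frame(siteset: GlycoSiteSet) -> pd.DataFrame:
    """Tidy per-site table with per-sample log2 intensities (for TSV export)."""
    samples = sorted({s for site in siteset.sites for s in site.intensities})
    rows = []
    for site in siteset.sites:
        row = {
            "accession": site.accession,
            "position": site.position,
            "sequon": site.sequon,
            "localization_probability": site.localization_probability,
        }
        for s in samples:
            v = site.intensities.get(s)
            row[f"log2_{s}"] = math.log2(v) if v else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
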