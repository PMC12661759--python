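"""Protein-group assembly and intensity quantification.

Peptide evidence is assembled into parsimonious protein groups:

1. proteins with identical observed peptide sets are merged into one group;
2. proteins whose peptide set is a strict subset of another's are absorbed
   (subsumption);
3. peptides still shared between surviving groups are assigned to the group
   with the most distinct candidate peptides, ties broken lexicographically
   by group id;
4. groups retaining fewer than two assigned peptides are removed.

Group quantification sums raw peptide intensities per sample before the
global log2 transform (log of sums, not sum of logs); samples where no
assigned peptide was observed are missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PeptideTable, SampleSheet

__all__ = [
    "ProteinGroup",
    "QuantMatrix",
    "group_peptides",
    "quantify_groups",
    "peptide_matrix",
]


@dataclass
class ProteinGroup:
    group_id: str
    members: frozenset[str]
    peptides: frozenset[str]
    intensities: dict[str, float] = field(default_factory=dict)


@dataclass
class QuantMatrix:
    """Feature x sample log2-intensity matrix with explicit missingness.

    ``values`` is a pandas DataFrame (rows = feature ids, columns =
    sample ids, NaN = missing); ``sample_meta`` maps sample id ->
    {method, patient}.
    """

    values: pd.DataFrame
    sample_meta: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for s in self.values.columns:
            meta = self.sample_meta.get(s)
            if not meta or not meta.get("method") or not meta.get("patient"):
                raise ValueError(f"sample {s} lacks method/patient metadata")
        finite = np.isfinite(self.values.to_numpy(dtype=float))
        missing = self.values.isna().to_numpy()
        if not np.all(finite | missing):
            raise ValueError("matrix contains non-finite stored values")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask (non-missing)."""
        return self.values.notna()

    def method_of(self, sample_id: str) -> str:
        return self.sample_meta[sample_id]["method"]

    def patient_of(self, sample_id: str) -> str:
        return self.sample_meta[sample_id]["patient"]

    @classmethod
    def from_dict(
        cls,
        values: dict[str, dict[str, float]],
        sample_meta: dict[str, dict[str, str]],
        sample_order=None,
    ) -> "QuantMatrix":
        samples = list(sample_order) if sample_order is not None else sorted(
            {s for row in values.values() for s in row}
        )
        df = pd.DataFrame(
            [
                [values[f].get(s, np.nan) for s in samples]
                for f in sorted(values)
            ],
            index=sorted(values),
            columns=samples,
            dtype=float,
        )
        return cls(values=df, sample_meta=sample_meta)


def peptide_matrix(table: PeptideTable, sheet: SampleSheet) -> QuantMatrix:
    """Peptide-level log2 matrix (rows = peptide sequences).

    Rows with the same sequence have their raw intensities summed per
    sample before the log2 transform.
    """
    raw: dict[str, dict[str, float]] = {}
    for rec in table.records:
        bucket = raw.setdefault(rec.sequence, {})
        for sample, value in rec.intensities.items():
            bucket[sample] = bucket.get(sample, 0.0) + value
    samples = sorted(
        s for s in sheet.samples
        if table.workflow is None or sheet.method_of(s) == table.workflow
    ) or sorted(sheet.samples)
    df = pd.DataFrame(
        [
            [math.log2(raw[p][s]) if s in raw[p] else np.nan for s in samples]
            for p in sorted(raw)
        ],
        index=sorted(raw),
        columns=samples,
        dtype=float,
    )
    return QuantMatrix(values=df, sample_meta={s: sheet.samples[s] for s in samples})


def _observed_peptides_by_protein(table: PeptideTable) -> dict[str, frozenset[str]]:
    by_protein: dict[str, set[str]] = {}
    for rec in table.records:
        for accession in rec.accessions:
            by_protein.setdefault(accession, set()).add(rec.sequence)
    return {acc: frozenset(peps) for acc, peps in by_protein.items()}


def group_peptides(table: PeptideTable, min_peptides: int = 2) -> list[ProteinGroup]:
    """Assemble peptide evidence into protein groups (see module docstring).

    The result is deterministic and independent of input row order.
    """
    by_protein = _observed_peptides_by_protein(table)
    if not by_protein:
        return []

    # 1. merge proteins with identical observed peptide sets
    by_pepset: dict[frozenset[str], set[str]] = {}
    for accession, peps in by_protein.items():
        by_pepset.setdefault(peps, set()).add(accession)
    proto = [
        {"members": set(members), "peptides": set(peps)}
        for peps, members in by_pepset.items()
    ]

    # 2. absorb strict-subset groups into their superset; when several
    # supersets exist, the largest peptide set wins, ties lexicographic
    proto.sort(key=lambda g: (-len(g["peptides"]), min(g["members"])))
    survivors: list[dict] = []
    for group in proto:
        host = None
        for candidate in survivors:
            if group["peptides"] < candidate["peptides"]:
                host = candidate
                break  # survivors sorted: first hit is the preferred host
        if host is not None:
            host["members"] |= group["members"]
        else:
            survivors.append(group)

    # 3. greedy assignment of shared peptides
    peptide_owners: dict[str, list[dict]] = {}
    for group in survivors:
        for pep in group["peptides"]:
            peptide_owners.setdefault(pep, []).append(group)
    for group in survivors:
        group["assigned"] = set()
    for pep, owners in peptide_owners.items():
        winner = min(
            owners, key=lambda g: (-len(g["peptides"]), min(g["members"]))
        )
        winner["assigned"].add(pep)

    # 4. two-peptide threshold
    out = []
    for group in survivors:
        if len(group["assigned"]) >= min_peptides:
            out.append(
                ProteinGroup(
                    group_id=min(group["members"]),
                    members=frozenset(group["members"]),
                    peptides=frozenset(group["assigned"]),
                )
            )
    out.sort(key=lambda g: g.group_id)
    return out


def quantify_groups(
    groups: list[ProteinGroup],
    table: PeptideTable,
    sheet: SampleSheet,
) -> QuantMatrix:
    """Quantify protein groups by summing raw peptide intensities per sample.

    Matrix entries are log2 of the summed raw intensity; a sample in which
    no assigned peptide was observed is missing. Raises if a group refers
    to a peptide sequence absent from the table.
    """
    intensity_by_peptide: dict[str, dict[str, float]] = {}
    for rec in table.records:
        bucket = intensity_by_peptide.setdefault(rec.sequence, {})
        for sample, value in rec.intensities.items():
            bucket[sample] = bucket.get(sample, 0.0) + value

    known = set(intensity_by_peptide)
    samples = sorted(
        s for s in sheet.samples if table.workflow is None
        or sheet.method_of(s) == table.workflow
    ) or sorted(sheet.samples)

    values: dict[str, dict[str, float]] = {}
    for group in groups:
        unknown = group.peptides - known
        if unknown:
            raise ValueError(
                f"group {group.group_id} references peptides not in the table: "
                + ", ".join(sorted(unknown)[:5])
            )
        raw: dict[str, float] = {}
        for pep in group.peptides:
            for sample, value in intensity_by_peptide[pep].items():
                raw[sample] = raw.get(sample, 0.0) + value
        group.intensities = dict(sorted(raw.items()))
        values[group.group_id] = {
            s: math.log2(v) for s, v in raw.items() if v > 0
        }

    meta = {s: sheet.samples[s] for s in samples}
    df = pd.DataFrame(
        [[values.get(g.group_id, {}).get(s, np.nan) for s in samples] for g in groups],
        index=[g.group_id for g in groups],
        columns=samples,
        dtype=float,
    )
    return QuantMatrix(values=df, sample_meta=meta)
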