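"""File dialects, configuration and domain containers.

The pipeline consumes search-engine style peptide tables (generic TSV or
MaxQuant ``peptides.txt`` column subsets), deamidation site tables, a
reference proteome in FASTA, annotation TSV/GMT files and a YAML run
configuration. Zero intensity is treated as "not detected" throughout,
matching search-engine convention, and decoy / contaminant / spike-in
standard accessions are stripped at parse time.
"""

from __future__ import annotations

import json
import logging
import re
import sys
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "FormatError",
    "PeptideRecord",
    "PeptideTable",
    "SiteRecord",
    "SiteTable",
    "SampleSheet",
    "AnnotationMap",
    "read_peptide_table",
    "write_peptide_table",
    "read_site_table",
    "write_site_table",
    "read_fasta",
    "write_fasta",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_annotation",
    "read_config",
    "write_matrix_tsv",
    "write_json_summary",
    "get_logger",
    "stage_timer",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_SEQ_RE = re.compile(rf"^[{AA_ALPHABET}]+$")

#: accession prefixes removed at parse time (reverse decoys, contaminants)
DEFAULT_EXCLUDED_PREFIXES = ("REV__", "CON__")
#: spike-in process standards removed at parse time
DEFAULT_EXCLUDED_ACCESSIONS = ("P00724", "SUC2", "iRT", "Biognosys_iRT")


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# logging
# ---------------------------------------------------------------------------

def get_logger(name: str = "csfbench") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


@contextmanager
def stage_timer(stage: str, logger: logging.Logger | None = None):
    """Log wall-clock duration of a pipeline stage to stderr."""
    logger = logger or get_logger()
    t0 = time.perf_counter()
    logger.info("stage %s started", stage)
    try:
        yield
    finally:
        logger.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class PeptideRecord:
    sequence: str
    accessions: tuple[str, ...]
    intensities: dict[str, float]
    modifications: tuple[tuple[int, str], ...] = ()

    def validate(self) -> None:
        if not _SEQ_RE.match(self.sequence):
            raise FormatError(f"invalid peptide sequence: {self.sequence!r}")
        if not self.accessions:
            raise FormatError("peptide record without accessions")
        for pos, _name in self.modifications:
            if not (1 <= pos <= len(self.sequence)):
                raise FormatError(
                    f"modification position {pos} outside 1..{len(self.sequence)}"
                )
        for sample, value in self.intensities.items():
            if not (value > 0 and np.isfinite(value)):
                raise FormatError(
                    f"non-positive or non-finite intensity for sample {sample}"
                )


@dataclass
class PeptideTable:
    records: list[PeptideRecord]
    workflow: str | None = None

    def __len__(self) -> int:
        return len(self.records)

    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            for s in rec.intensities:
                seen.setdefault(s, None)
        return sorted(seen)


@dataclass
class SiteRecord:
    accession: str
    position: int  # 1-based index in the protein
    localization_probability: float
    sequence_window: str
    intensities: dict[str, float]

    def validate(self) -> None:
        if self.position < 1:
            raise FormatError(f"site position must be >= 1, got {self.position}")
        if not (0.0 <= self.localization_probability <= 1.0):
            raise FormatError(
                f"localization probability outside [0, 1]: "
                f"{self.localization_probability}"
            )


@dataclass
class SiteTable:
    records: list[SiteRecord]
    workflow: str | None = None

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SampleSheet:
    """sample_id -> (method, patient) assignment for the whole run."""

    samples: dict[str, dict[str, str]]

    def methods(self) -> list[str]:
        return sorted({v["method"] for v in self.samples.values()})

    def patients(self) -> list[str]:
        return sorted({v["patient"] for v in self.samples.values()})

    def samples_for_method(self, method: str) -> list[str]:
        return sorted(
            s for s, v in self.samples.items() if v["method"] == method
        )

    def method_of(self, sample_id: str) -> str:
        return self.samples[sample_id]["method"]

    def patient_of(self, sample_id: str) -> str:
        return self.samples[sample_id]["patient"]

    def validate(self) -> None:
        for sid, v in self.samples.items():
            if not v.get("method") or not v.get("patient"):
                raise FormatError(f"sample {sid}: empty method or patient label")


@dataclass
class AnnotationMap:
    """id -> label set, for subcellular locations, gene lists or GMT sets.

    ``kind`` is one of ``subcellular``, ``gene_list``, ``gene_sets``. For
    ``gene_sets`` the mapping is gene -> set names; set descriptions are
    kept in ``set_descriptions``.
    """

    kind: str
    mapping: dict[str, set[str]]
    set_descriptions: dict[str, str] = field(default_factory=dict)

    def labels_of(self, key: str) -> set[str]:
        return self.mapping.get(key, set())


# ---------------------------------------------------------------------------
# peptide / site tables
# ---------------------------------------------------------------------------

def _is_excluded(accession: str, prefixes, excluded) -> bool:
    return accession.startswith(tuple(prefixes)) or accession in set(excluded)


def _intensity_columns(columns, dialect: str) -> dict[str, str]:
    """Map intensity column name -> sample id for the given dialect."""
    out: dict[str, str] = {}
    for col in columns:
        if dialect == "maxquant" and col.startswith("Intensity "):
            out[col] = col[len("Intensity ") :]
        elif dialect == "generic_tsv" and col.startswith("Intensity."):
            out[col] = col[len("Intensity.") :]
    return out


def _parse_intensity(raw, column: str, row_index: int) -> float | None:
    """Parse one intensity cell; 0/empty means absent, NaN is an error."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return None
    try:
        value = float(raw)
    except (TypeError, ValueError) as exc:
        raise FormatError(
            f"row {row_index}: unparseable intensity {raw!r} in column {column}"
        ) from exc
    if np.isnan(value):
        raise FormatError(
            f"row {row_index}: NaN intensity in column {column}"
        )
    if value < 0:
        raise FormatError(
            f"row {row_index}: negative intensity {value} in column {column}"
        )
    return value if value > 0 else None


def read_peptide_table(
    path,
    dialect: str = "generic_tsv",
    workflow: str | None = None,
    excluded_prefixes=DEFAULT_EXCLUDED_PREFIXES,
    excluded_accessions=DEFAULT_EXCLUDED_ACCESSIONS,
) -> PeptideTable:
    """Read a peptide quantification table (``peptides.txt``-style TSV).

    Mandatory columns: ``Sequence``, ``Proteins``; intensity columns are
    ``Intensity.<sample>`` (generic_tsv) or ``Intensity <sample>``
    (maxquant). Rows whose accessions are all decoy/contaminant/standard
    entries are dropped; zero intensities become "absent".
    """
    if dialect not in ("generic_tsv", "maxquant"):
        raise ValueError(f"unknown dialect: {dialect}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("Sequence", "Proteins"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col}")
    intensity_cols = _intensity_columns(df.columns, dialect)
    if not intensity_cols:
        raise FormatError("no intensity columns found for dialect " + dialect)

    records: list[PeptideRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        accessions = tuple(
            a
            for a in str(rowd["Proteins"]).split(";")
            if a and not _is_excluded(a, excluded_prefixes, excluded_accessions)
        )
        if not accessions:
            continue
        intensities: dict[str, float] = {}
        for col, sample in intensity_cols.items():
            value = _parse_intensity(rowd[col], col, i)
            if value is not None:
                intensities[sample] = value
        mods: tuple[tuple[int, str], ...] = ()
        if "Modifications" in rowd and rowd["Modifications"]:
            parsed = []
            for token in str(rowd["Modifications"]).split(";"):
                pos_s, _, name = token.partition(":")
                parsed.append((int(pos_s), name))
            mods = tuple(parsed)
        rec = PeptideRecord(
            sequence=str(rowd["Sequence"]).upper(),
            accessions=accessions,
            intensities=intensities,
            modifications=mods,
        )
        rec.validate()
        records.append(rec)
    return PeptideTable(records=records, workflow=workflow)


def write_peptide_table(table: PeptideTable, path) -> None:
    """Write a PeptideTable in the generic_tsv dialect (round-trippable)."""
    samples = table.sample_ids()
    rows = []
    for rec in table.records:
        row = {
            "Sequence": rec.sequence,
            "Proteins": ";".join(rec.accessions),
            "Modifications": ";".join(f"{p}:{n}" for p, n in rec.modifications),
        }
        for s in samples:
            value = rec.intensities.get(s)
            row[f"Intensity.{s}"] = "" if value is None else repr(value)
        rows.append(row)
    cols = ["Sequence", "Proteins", "Modifications"] + [
        f"Intensity.{s}" for s in samples
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_site_table(path, workflow: str | None = None) -> SiteTable:
    """Read a deamidation site table.

    Mandatory columns: ``Protein``, ``Position``, ``Localization prob``;
    intensity columns ``Intensity.<sample>``; optional ``Sequence window``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("Protein", "Position", "Localization prob"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col}")
    intensity_cols = _intensity_columns(df.columns, "generic_tsv")
    records: list[SiteRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        intensities: dict[str, float] = {}
        for col, sample in intensity_cols.items():
            value = _parse_intensity(rowd[col], col, i)
            if value is not None:
                intensities[sample] = value
        rec = SiteRecord(
            accession=str(rowd["Protein"]),
            position=int(rowd["Position"]),
            localization_probability=float(rowd["Localization prob"]),
            sequence_window=str(rowd.get("Sequence window", "")),
            intensities=intensities,
        )
        rec.validate()
        records.append(rec)
    return SiteTable(records=records, workflow=workflow)


def write_site_table(table: SiteTable, path) -> None:
    samples: list[str] = sorted(
        {s for rec in table.records for s in rec.intensities}
    )
    rows = []
    for rec in table.records:
        row = {
            "Protein": rec.accession,
            "Position": rec.position,
            "Localization prob": repr(rec.localization_probability),
            "Sequence window": rec.sequence_window,
        }
        for s in samples:
            value = rec.intensities.get(s)
            row[f"Intensity.{s}"] = "" if value is None else repr(value)
        rows.append(row)
    cols = ["Protein", "Position", "Localization prob", "Sequence window"] + [
        f"Intensity.{s}" for s in samples
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _accession_from_header(header: str) -> str:
    token = header.split()[0]
    if token.startswith(("sp|", "tr|")):
        parts = token.split("|")
        if len(parts) >= 2 and parts[1]:
            return parts[1]
    return token


def read_fasta(path) -> dict[str, str]:
    """Read a protein FASTA into accession -> uppercase sequence.

    UniProt ``sp|ACC|NAME`` headers are unwrapped to the accession.
    Duplicate accessions and empty sequences are errors.
    """
    proteome: dict[str, str] = {}
    duplicates: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        accession = _accession_from_header(record.description or record.id)
        sequence = str(record.seq).upper().replace(" ", "")
        if not sequence:
            raise FormatError(f"empty sequence for accession {accession}")
        if accession in proteome:
            duplicates.append(accession)
        proteome[accession] = sequence
    if duplicates:
        raise FormatError("duplicate accessions: " + ", ".join(sorted(set(duplicates))))
    if not proteome:
        raise FormatError(f"no FASTA records found in {path}")
    return proteome


def write_fasta(proteome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for accession in proteome:
            fh.write(f">{accession}\n")
            seq = proteome[accession]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# sample sheet, annotations, config
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "method", "patient"):
        if col not in df.columns:
            raise FormatError(f"sample sheet missing column: {col}")
    sheet = SampleSheet(
        samples={
            r.sample_id: {"method": r.method, "patient": r.patient}
            for r in df.itertuples(index=False)
        }
    )
    sheet.validate()
    return sheet


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    rows = [
        {"sample_id": s, "method": v["method"], "patient": v["patient"]}
        for s, v in sorted(sheet.samples.items())
    ]
    pd.DataFrame(rows, columns=["sample_id", "method", "patient"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotation(path, kind: str) -> AnnotationMap:
    """Read annotation files.

    * ``subcellular`` / ``gene_list``: two-column TSV (id, label), labels
      ``;``-separated, multi-line ids unioned. ``gene_list`` files may be a
      single column of ids (label defaults to the list membership flag).
    * ``gene_sets``: GMT (set name, description, members...).
    """
    if kind not in ("subcellular", "gene_list", "gene_sets"):
        raise ValueError(f"unknown annotation kind: {kind}")
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"empty annotation file: {path}")

    mapping: dict[str, set[str]] = {}
    if kind == "gene_sets":
        descriptions: dict[str, str] = {}
        for lineno, line in enumerate(lines, start=1):
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: malformed GMT line {lineno} (<3 fields)"
                )
            set_name, description, *members = fields
            descriptions[set_name] = description
            for gene in members:
                if gene:
                    mapping.setdefault(gene, set()).add(set_name)
        return AnnotationMap(kind=kind, mapping=mapping, set_descriptions=descriptions)

    for line in lines:
        fields = line.split("\t")
        key = fields[0]
        if kind == "gene_list" and len(fields) == 1:
            labels = ["member"]
        else:
            if len(fields) < 2:
                raise FormatError(f"{path}: expected two columns, got {line!r}")
            labels = [lab for lab in fields[1].split(";") if lab.strip()]
        mapping.setdefault(key, set()).update(lab.strip() for lab in labels)
    return AnnotationMap(kind=kind, mapping=mapping)


DEFAULT_CONFIG = {
    "workflows": ["MStern", "Seer", "N-Gp", "P20-EV", "P150-EV"],
    "glyco_workflow": "N-Gp",
    "localization_threshold": 0.8,
    "min_peptides_per_group": 2,
    "min_detect_fraction": 0.5,
    "alpha": 0.05,
    "digest": {"max_missed": 2, "proline_rule": True, "length_range": [7, 35]},
    "nta_dilution_factors": {"P150-EV": 4.0, "P20-EV": 5.0},
    "seed": 0,
}


def read_config(path) -> dict:
    """Read the YAML run configuration, filling in documented defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


# ---------------------------------------------------------------------------
# generic writers
# ---------------------------------------------------------------------------

def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "feature") -> None:
    """Write a feature x sample table; missing values as empty fields."""
    df.to_csv(path, sep="\t", index=True, index_label=index_label, na_rep="")


def write_json_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
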