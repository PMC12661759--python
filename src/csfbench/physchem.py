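"""In-silico tryptic digestion and peptide/protein physicochemical profiles.

Molecular weight is the sum of monoisotopic residue masses plus one water;
GRAVY is the arithmetic mean of Kyte-Doolittle hydropathy values (the
definition of the score); the isoelectric point is the pH at which the
Henderson-Hasselbalch net charge over the termini and the D, E, C, Y, H,
K, R side chains crosses zero, located by bisection on [0, 14]. The pKa
table defaults to Bjellqvist values and can be swapped. All three constant
tables ship with the package as TSV files.

Trypsin cleaves C-terminal to K or R; the classic proline rule (no
cleavage before P) is on by default and can be disabled, since search
engines differ.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_adjust, wilcoxon_rank_sum

__all__ = [
    "DigestPeptide",
    "PhyschemProfile",
    "WATER_MONO",
    "load_constant_table",
    "digest",
    "peptide_properties",
    "net_charge",
    "reference_distribution",
    "compare_distributions",
]

WATER_MONO = 18.01056
PI_TOLERANCE = 1e-6  # bisection width on the pH axis


def load_constant_table(name: str) -> pd.DataFrame:
    """Load a packaged constants TSV (masses, hydropathy or pKa)."""
    ref = resources.files("csfbench.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def _mass_table() -> dict[str, float]:
    df = load_constant_table("monoisotopic_masses.tsv")
    return dict(zip(df["residue"], df["monoisotopic_mass_da"]))


def _hydropathy_table() -> dict[str, float]:
    df = load_constant_table("kyte_doolittle.tsv")
    return dict(zip(df["residue"], df["hydropathy"]))


def _pka_table() -> dict[str, tuple[float, int]]:
    df = load_constant_table("pka_bjellqvist.tsv")
    return {
        row.group: (float(row.pka), 1 if int(row.charge_sign) > 0 else -1)
        for row in df.itertuples(index=False)
    }


MONO_MASS = _mass_table()
HYDROPATHY = _hydropathy_table()
DEFAULT_PKA = _pka_table()


@dataclass(frozen=True)
class DigestPeptide:
    sequence: str
    parent: str
    missed_cleavages: int
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive


@dataclass(frozen=True)
class PhyschemProfile:
    molecular_weight: float
    gravy: float
    isoelectric_point: float


def _check_sequence(sequence: str) -> None:
    for i, residue in enumerate(sequence):
        if residue not in MONO_MASS:
            raise ValueError(f"invalid residue {residue!r} at position {i + 1}")


def digest(
    sequence: str,
    parent: str = "",
    max_missed: int = 2,
    proline_rule: bool = True,
) -> list[DigestPeptide]:
    """Tryptic digest with up to ``max_missed`` missed cleavages.

    A sequence without cut sites yields itself as a single peptide.
    Products are emitted in order of start coordinate, then length.
    """
    _check_sequence(sequence)
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    n = len(sequence)
    # boundaries: 0-based index i means a cut between residues i-1 and i
    cuts = [0]
    for i in range(n - 1):
        if sequence[i] in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            cuts.append(i + 1)
    cuts.append(n)
    fragments = [(cuts[j], cuts[j + 1]) for j in range(len(cuts) - 1)]

    peptides: list[DigestPeptide] = []
    for j in range(len(fragments)):
        for k in range(j, min(j + max_missed + 1, len(fragments))):
            start, end = fragments[j][0], fragments[k][1]
            peptides.append(
                DigestPeptide(
                    sequence=sequence[start:end],
                    parent=parent,
                    missed_cleavages=k - j,
                    start=start + 1,
                    end=end,
                )
            )
    return peptides


def net_charge(sequence: str, ph: float, pka=None) -> float:
    """Henderson-Hasselbalch net charge of a peptide at the given pH."""
    pka = pka or DEFAULT_PKA
    charge = 0.0
    groups = [("n_terminus", 1), ("c_terminus", 1)]
    for residue in set(sequence) & set("DECYHKR"):
        groups.append((residue, sequence.count(residue)))
    for group, count in groups:
        if group not in pka:
            continue
        value, sign = pka[group]
        if sign > 0:
            charge += count / (1.0 + 10.0 ** (ph - value))
        else:
            charge -= count / (1.0 + 10.0 ** (value - ph))
    return charge


def isoelectric_point(sequence: str, pka=None) -> float:
    """pH of zero net charge, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    while hi - lo > PI_TOLERANCE:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def peptide_properties(sequence: str, pka=None) -> PhyschemProfile:
    """Monoisotopic MW (Da), GRAVY and predicted pI of a sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    _check_sequence(sequence)
    mw = sum(MONO_MASS[r] for r in sequence) + WATER_MONO
    gravy = sum(HYDROPATHY[r] for r in sequence) / len(sequence)
    pi = isoelectric_point(sequence, pka)
    return PhyschemProfile(molecular_weight=mw, gravy=gravy, isoelectric_point=pi)


def reference_distribution(
    proteome: dict[str, str],
    max_missed: int = 2,
    proline_rule: bool = True,
    length_range: tuple[int, int] = (7, 35),
    unique_only: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Digest a proteome and profile its peptides and proteins.

    Returns ``(peptide_table, protein_table)``: the peptide table has one
    row per digest product inside the length window (deduplicated
    proteome-wide when ``unique_only``); the protein table has exactly one
    row per input accession, with properties computed on the full
    sequence.
    """
    if not proteome:
        raise ValueError("empty proteome")
    lo, hi = length_range
    pep_rows = []
    seen: set[str] = set()
    for accession in sorted(proteome):
        for pep in digest(proteome[accession], accession, max_missed, proline_rule):
            if not (lo <= len(pep.sequence) <= hi):
                continue
            if unique_only:
                if pep.sequence in seen:
                    continue
                seen.add(pep.sequence)
            prof = peptide_properties(pep.sequence)
            pep_rows.append(
                {
                    "sequence": pep.sequence,
                    "parent": pep.parent,
                    "missed_cleavages": pep.missed_cleavages,
                    "mw": prof.molecular_weight,
                    "gravy": prof.gravy,
                    "pi": prof.isoelectric_point,
                }
            )
    prot_rows = []
    for accession in sorted(proteome):
        prof = peptide_properties(proteome[accession])
        prot_rows.append(
            {
                "accession": accession,
                "length": len(proteome[accession]),
                "mw": prof.molecular_weight,
                "gravy": prof.gravy,
                "pi": prof.isoelectric_point,
            }
        )
    return pd.DataFrame(pep_rows), pd.DataFrame(prot_rows)


def compare_distributions(
    observed: dict[str, pd.DataFrame],
    reference: pd.DataFrame,
    properties: tuple[str, ...] = ("mw", "gravy", "pi"),
) -> pd.DataFrame:
    """Rank-sum comparison of per-method property distributions.

    For each property and method, the method's values are tested against
    the pooled values of all other methods (``vs_rest``) and against the
    in-silico reference digest (``vs_reference``); the shift estimate is
    the difference of medians. BH adjustment spans the whole comparison
    family. Degenerate groups (fewer than 3 values) are flagged with NaN p
    rather than raising.
    """
    rows = []
    for prop in properties:
        for method in sorted(observed):
            values = observed[method][prop].dropna().to_numpy()
            rest = np.concatenate(
                [
                    observed[other][prop].dropna().to_numpy()
                    for other in observed
                    if other != method
                ]
            ) if len(observed) > 1 else np.array([])
            ref_values = reference[prop].dropna().to_numpy()
            for contrast, other_values in (
                ("vs_rest", rest),
                ("vs_reference", ref_values),
            ):
                row = {
                    "property": prop,
                    "method": method,
                    "contrast": contrast,
                    "n": len(values),
                    "n_other": len(other_values),
                    "median": float(np.median(values)) if len(values) else np.nan,
                    "median_other": (
                        float(np.median(other_values)) if len(other_values) else np.nan
                    ),
                }
                if len(values) >= 3 and len(other_values) >= 3:
                    result = wilcoxon_rank_sum(values, other_values)
                    row["p"] = result.p_value
                    row["shift"] = row["median"] - row["median_other"]
                else:
                    row["p"] = np.nan
                    row["shift"] = np.nan
                rows.append(row)
    table = pd.DataFrame(rows)
    mask = table["p"].notna()
    adjusted = pd.Series(np.nan, index=table.index)
    if mask.any():
        adjusted[mask] = bh_adjust(table.loc[mask, "p"].tolist())
    table["adjusted_p"] = adjusted
    return table
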