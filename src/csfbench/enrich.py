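"""Fraction-unique / fraction-elevated classification and over-representation.

A protein is *unique* to a workflow when it is detected (in >= 1 sample)
in that workflow and no other. It is *elevated* in a workflow when, for
every other workflow, the patient-paired two-tailed Wilcoxon signed-rank
test on log2 intensities is significant after BH adjustment (family = all
proteins tested within that workflow pair) with a positive mean paired
log2 difference. Only proteins detected in at least ``min_detect`` of the
samples of both workflows in a comparison enter that comparison; a
comparison with fewer than 4 complete patient pairs is untestable and
blocks the elevated call. The *enriched* set of a workflow is the union
of its unique and elevated proteins.

Over-representation of a protein set against a background uses Fisher's
exact test per category with conditional-MLE odds ratios (direction: OR >
1 over-, OR < 1 under-represented) and BH across categories. Subcellular
raw labels are first consolidated into the packaged category scheme
(Nucleus, Cytoskeleton, Cell division, Centrosome cilium, Cell adhesion
and Cytoplasmic bodies each absorb their constituent structures;
top-level labels map to themselves; unmapped labels are dropped with a
logged count).
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import QuantMatrix
from .io import AnnotationMap, get_logger
from .stats import bh_adjust, fisher_2x2, wilcoxon_signed_rank

__all__ = [
    "ComparisonRecord",
    "EnrichmentCall",
    "load_consolidation_scheme",
    "classify_fraction_proteins",
    "consolidate_locations",
    "ora",
    "ANALYZED_CATEGORIES",
]

#: the eleven consolidated subcellular categories entering the ORA
ANALYZED_CATEGORIES = (
    "Vesicles",
    "Plasma membrane",
    "Nucleus",
    "Mitochondria",
    "Lysosomes",
    "Golgi apparatus",
    "Endoplasmic reticulum",
    "Cytosol",
    "Cell adhesion",
    "Cytoskeleton",
    "Cytoplasmic bodies",
)

MIN_COMPLETE_PAIRS = 4


@dataclass
class ComparisonRecord:
    other_method: str
    log2_fc: float
    p: float
    adjusted_p: float
    n_pairs: int
    testable: bool


@dataclass
class EnrichmentCall:
    protein: str
    workflow: str
    classification: str  # unique | elevated | none
    comparisons: list[ComparisonRecord] = field(default_factory=list)


def load_consolidation_scheme() -> dict[str, str]:
    """Packaged raw-label -> consolidated-category mapping."""
    ref = resources.files("csfbench.data").joinpath("subcellular_consolidation.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df["raw_label"], df["category"]))


def consolidate_locations(
    raw_annotations: AnnotationMap, scheme: dict[str, str] | None = None
) -> dict[str, set[str]]:
    """Map each protein's raw location labels to consolidated categories."""
    scheme = scheme or load_consolidation_scheme()
    out: dict[str, set[str]] = {}
    dropped = 0
    for protein, labels in raw_annotations.mapping.items():
        categories = set()
        for label in labels:
            if label in scheme:
                categories.add(scheme[label])
            else:
                dropped += 1
        if categories:
            out[protein] = categories
    if dropped:
        get_logger().info("consolidate_locations: dropped %d unmapped labels", dropped)
    return out


def _paired_differences(
    matrix_a: QuantMatrix, matrix_b: QuantMatrix, protein: str
) -> np.ndarray:
    """Per-patient log2 differences (a - b); patients missing either side drop."""
    by_patient_a = {
        matrix_a.patient_of(s): matrix_a.values.at[protein, s]
        for s in matrix_a.samples
    }
    by_patient_b = {
        matrix_b.patient_of(s): matrix_b.values.at[protein, s]
        for s in matrix_b.samples
    }
    diffs = []
    for patient in sorted(set(by_patient_a) & set(by_patient_b)):
        a, b = by_patient_a[patient], by_patient_b[patient]
        if not (np.isnan(a) or np.isnan(b)):
            diffs.append(a - b)
    return np.asarray(diffs, dtype=float)


def classify_fraction_proteins(
    matrices: dict[str, QuantMatrix],
    alpha: float = 0.05,
    min_detect: float = 0.5,
) -> list[EnrichmentCall]:
    """Classify every detected protein as unique / elevated / none per workflow."""
    if len(matrices) < 2:
        raise ValueError("need at least two workflows")
    workflows = sorted(matrices)
    detected_in: dict[str, set[str]] = {
        w: {f for f, hit in matrices[w].detected().any(axis=1).items() if hit}
        for w in workflows
    }
    detect_freq: dict[str, pd.Series] = {
        w: matrices[w].detected().sum(axis=1) / len(matrices[w].samples)
        for w in workflows
    }

    # pairwise testing with BH per ordered workflow pair (family = proteins)
    pair_results: dict[tuple[str, str], dict[str, ComparisonRecord]] = {}
    for w in workflows:
        for v in workflows:
            if v == w:
                continue
            candidates = sorted(
                p
                for p in detected_in[w] & detected_in[v]
                if detect_freq[w].get(p, 0) >= min_detect
                and detect_freq[v].get(p, 0) >= min_detect
            )
            records: dict[str, ComparisonRecord] = {}
            testable_p: list[str] = []
            pvals: list[float] = []
            for protein in candidates:
                diffs = _paired_differences(matrices[w], matrices[v], protein)
                if len(diffs) < MIN_COMPLETE_PAIRS or np.all(diffs == 0):
                    records[protein] = ComparisonRecord(
                        other_method=v,
                        log2_fc=float(np.mean(diffs)) if len(diffs) else np.nan,
                        p=np.nan,
                        adjusted_p=np.nan,
                        n_pairs=len(diffs),
                        testable=False,
                    )
                    continue
                result = wilcoxon_signed_rank(diffs)
                records[protein] = ComparisonRecord(
                    other_method=v,
                    log2_fc=float(np.mean(diffs)),
                    p=result.p_value,
                    adjusted_p=np.nan,
                    n_pairs=len(diffs),
                    testable=True,
                )
                testable_p.append(protein)
                pvals.append(result.p_value)
            if pvals:
                for protein, q in zip(testable_p, bh_adjust(pvals)):
                    records[protein].adjusted_p = q
            pair_results[(w, v)] = records

    calls: list[EnrichmentCall] = []
    all_proteins = sorted(set().union(*detected_in.values()))
    for w in workflows:
        others = [v for v in workflows if v != w]
        for protein in all_proteins:
            if protein not in detected_in[w]:
                continue
            if all(protein not in detected_in[v] for v in others):
                calls.append(EnrichmentCall(protein, w, "unique"))
                continue
            comparisons = []
            elevated = True
            for v in others:
                rec = pair_results[(w, v)].get(protein)
                if rec is None:
                    rec = ComparisonRecord(v, np.nan, np.nan, np.nan, 0, False)
                comparisons.append(rec)
                if not (
                    rec.testable
                    and rec.log2_fc > 0
                    and rec.adjusted_p < alpha
                ):
                    elevated = False
            calls.append(
                EnrichmentCall(
                    protein, w, "elevated" if elevated else "none", comparisons
                )
            )
    return calls


def enriched_sets(calls: list[EnrichmentCall]) -> dict[str, set[str]]:
    """Per-workflow union of unique and elevated proteins."""
    out: dict[str, set[str]] = {}
    for call in calls:
        if call.classification in ("unique", "elevated"):
            out.setdefault(call.workflow, set()).add(call.protein)
    return out


def ora(
    protein_set: set[str],
    background: set[str],
    categories: dict[str, set[str]],
    category_names=None,
) -> pd.DataFrame:
    """Fisher's-exact over/under-representation of a set per category.

    ``categories`` maps protein -> consolidated category set; the 2x2
    table per category is (in set & in category, in set & not, out of set
    & in category, out of set & not). Categories with zero annotated
    background members are skipped with a log entry.
    """
    if not protein_set:
        raise ValueError("empty protein set")
    if not protein_set <= background:
        raise ValueError("protein set must be a subset of the background")
    if category_names is None:
        category_names = sorted(
            {c for p in background for c in categories.get(p, set())}
        )
    rows = []
    for category in category_names:
        members = {p for p in background if category in categories.get(p, set())}
        if not members:
            get_logger().info("ora: category %s has no background members", category)
            continue
        a = len(protein_set & members)
        b = len(protein_set) - a
        c = len(members) - a
        d = len(background) - len(protein_set) - c
        if c + d == 0 or b + d == 0:
            # only one table is possible given the margins (e.g. the set is
            # the whole background): no evidence either way
            oddsr, log2_or, p = 1.0, 0.0, 1.0
        else:
            result = fisher_2x2(a, b, c, d)
            oddsr, log2_or, p = (
                result.odds_ratio,
                result.log2_odds_ratio,
                result.p_value,
            )
        rows.append(
            {
                "category": category,
                "set_in": a,
                "set_out": b,
                "bg_in": c,
                "bg_out": d,
                "odds_ratio": oddsr,
                "log2_odds_ratio": log2_or,
                "p": p,
                "direction": "over" if oddsr > 1 else (
                    "under" if oddsr < 1 else "none"
                ),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["adjusted_p"] = bh_adjust(table["p"].tolist())
    return table


def calls_to_frame(calls: list[EnrichmentCall]) -> pd.DataFrame:
    rows = []
    for call in calls:
        if not call.comparisons:
            rows.append(
                {
                    "protein": call.protein,
                    "workflow": call.workflow,
                    "class": call.classification,
                    "other_method": "",
                    "log2_fc": np.nan,
                    "p": np.nan,
                    "adjusted_p": np.nan,
                    "n_pairs": 0,
                }
            )
        for rec in call.comparisons:
            rows.append(
                {
                    "protein": call.protein,
                    "workflow": call.workflow,
                    "class": call.classification,
                    "other_method": rec.other_method,
                    "log2_fc": rec.log2_fc,
                    "p": rec.p,
                    "adjusted_p": rec.adjusted_p,
                    "n_pairs": rec.n_pairs,
                }
            )
    return pd.DataFrame(rows)
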