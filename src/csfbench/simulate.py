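"""Synthetic multi-workflow CSF proteomics cohorts with known ground truth.

The generator emulates the data structures the analysis stages consume:

* a random proteome with controlled tryptic-site (K/R) density and planted
  N-glycosylation sequons, annotated with subcellular categories (raw
  Human-Protein-Atlas-style labels), a brain-enriched-style gene list and
  GMT gene sets;
* per-workflow peptide tables whose intensities follow a crossed
  random-effects model on the log2 scale, y = mu_p + a_method + b_patient
  + delta_planted + eps, with the three variance components drawn to match
  configured fractions, peptide intensities as Dirichlet shares of the
  protein's raw intensity over its in-range tryptic peptides, and
  missing-not-at-random dropout via a logistic function of log2 intensity;
* a deamidation site table for the glyco workflow, with localization
  probabilities drawn from a high ~Beta(20, 1) / low ~Beta(2, 2) mixture
  and non-sequon decoy sites;
* NTA bin-count CSVs with known true concentrations and dilution factors.

All randomness flows from a single seed through ``SeedSequence.spawn``
(one child stream per artifact), so the same seed reproduces every file
byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly import QuantMatrix
from .glyco import scan_sequons
from .io import (
    AnnotationMap,
    PeptideRecord,
    PeptideTable,
    SampleSheet,
    SiteRecord,
    SiteTable,
    write_fasta,
    write_peptide_table,
    write_sample_sheet,
    write_site_table,
)
from .physchem import digest
from .enrich import ANALYZED_CATEGORIES, load_consolidation_scheme

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_proteome",
    "generate_protein_matrices",
    "generate_cohort",
    "generate_nta",
    "write_cohort",
    "null_config",
    "planted_config",
    "recovery_config",
]

DEFAULT_WORKFLOWS = ("MStern", "Seer", "N-Gp", "P20-EV", "P150-EV")

#: amino-acid sampling weights: ~10% K+R so tryptic sites land roughly
#: every 10 residues on average; modest P and N frequencies
AA_WEIGHTS = {
    "A": 8.0, "C": 1.5, "D": 5.5, "E": 6.5, "F": 4.0, "G": 7.0, "H": 2.5,
    "I": 5.5, "K": 5.5, "L": 9.5, "M": 2.5, "N": 4.0, "P": 4.5, "Q": 4.0,
    "R": 4.5, "S": 7.0, "T": 5.5, "V": 6.5, "W": 1.5, "Y": 3.0,
}


@dataclass
class SimConfig:
    """All tunable knobs of the generator (defaults = study conditions)."""

    n_proteins: int = 200
    n_patients: int = 19
    workflows: tuple[str, ...] = DEFAULT_WORKFLOWS
    glyco_workflow: str = "N-Gp"
    # log2-scale abundance model
    variance_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    within_variance: float = 1.0  # total method+patient+residual variance
    baseline_mean: float = 25.0   # mean protein log2 abundance
    baseline_sd: float = 2.0
    # planted method-elevated proteins
    planted_fraction: float = 0.0
    planted_effect: float = 1.5   # log2 units
    # missing-not-at-random dropout on peptide log2 intensity
    dropout_midpoint: float | None = 18.0
    dropout_steepness: float = 1.0
    # per-workflow capture probability by subcellular category:
    # {workflow: {category: probability}}; None = everything captured.
    # A protein that a workflow fails to capture is absent from all of
    # that workflow's samples, which is what drives workflow-specific
    # subcellular signatures.
    capture_bias: dict | None = None
    # proteome
    protein_length_range: tuple[int, int] = (150, 400)
    sequon_density: float = 0.01  # planted sequons per residue
    glyco_decoy_sites: int = 40   # non-sequon deamidation decoys
    p_high_localization: float = 0.75  # mixture weight of Beta(20, 1)
    peptide_length_range: tuple[int, int] = (7, 35)
    digest_max_missed: int = 0
    # NTA
    nta_dilution_factors: dict = field(
        default_factory=lambda: {"P150-EV": 4.0, "P20-EV": 5.0}
    )
    nta_peak_nm: dict = field(
        default_factory=lambda: {"P150-EV": 110.0, "P20-EV": 140.0}
    )
    nta_total_particles: dict = field(
        default_factory=lambda: {"P150-EV": 2.0e8, "P20-EV": 9.0e8}
    )
    nta_videos: int = 3

    def __post_init__(self) -> None:
        fractions = np.asarray(self.variance_fractions, dtype=float)
        if np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-9:
            raise ValueError("variance fractions must be >= 0 and sum to 1")
        if not (0.0 <= self.planted_fraction <= 1.0):
            raise ValueError("planted_fraction outside [0, 1]")


def null_config(**overrides) -> SimConfig:
    """No planted effects and no systematic method component.

    This is the null for fraction-elevated calling: planted shifts are
    the only admissible source of method-level differential abundance, so
    the method variance component is zero and its share moves to patient
    and residual.
    """
    base = dict(
        variance_fractions=(0.0, 0.5, 0.5),
        within_variance=0.5,
        planted_fraction=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)


def planted_config(**overrides) -> SimConfig:
    """Planted-effect cohort: 10% of proteins elevated by 1.5 log2 units.

    Patient and residual components split a within-protein variance of
    0.5 (residual log2 sd ~0.5, a typical label-free replicate spread);
    planted shifts are the only method-level signal.
    """
    base = dict(
        variance_fractions=(0.0, 0.5, 0.5),
        within_variance=0.5,
        planted_fraction=0.1,
        planted_effect=1.5,
    )
    base.update(overrides)
    return SimConfig(**base)


def recovery_config(**overrides) -> SimConfig:
    """Balanced complete design for variance-component recovery."""
    base = dict(
        variance_fractions=(0.6, 0.2, 0.2),
        planted_fraction=0.0,
        dropout_midpoint=None,  # complete data: the design stays balanced
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class GroundTruth:
    variance_fractions: tuple[float, float, float]
    categories: dict[str, str]               # protein -> consolidated category
    raw_labels: dict[str, str]               # protein -> raw HPA-style label
    elevated: dict[str, str]                 # protein -> workflow (planted)
    sequon_positions: dict[str, list[int]]   # protein -> all sequon starts
    brain_enriched: list[str] = field(default_factory=list)
    nta_dilution_factors: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _protein_ids(n: int) -> list[str]:
    return [f"PR{i:04d}" for i in range(1, n + 1)]


def generate_proteome(
    config: SimConfig, seed: int
) -> tuple[dict[str, str], dict[str, AnnotationMap], GroundTruth]:
    """Random proteome, annotations and the proteome half of the truth.

    Sequons are planted at ``sequon_density`` per residue by overwriting
    N-X-[S/T] windows; the truth records *all* sequons of the final
    sequence, including chance-formed ones.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    letters = np.array(list(AA_WEIGHTS))
    weights = np.array(list(AA_WEIGHTS.values()), dtype=float)
    weights /= weights.sum()

    proteome: dict[str, str] = {}
    categories: dict[str, str] = {}
    raw_labels: dict[str, str] = {}
    sequons: dict[str, list[int]] = {}
    scheme = load_consolidation_scheme()
    members_by_category = {
        cat: sorted(raw for raw, c in scheme.items() if c == cat)
        for cat in ANALYZED_CATEGORIES
    }
    lo, hi = config.protein_length_range
    for protein in _protein_ids(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(letters, size=length, p=weights)
        n_sequons = rng.binomial(length, config.sequon_density)
        if n_sequons and length >= 3:
            starts = rng.choice(length - 2, size=n_sequons, replace=False)
            for s in starts:
                seq[s] = "N"
                if seq[s + 1] == "P":
                    seq[s + 1] = "A"
                seq[s + 2] = "S" if rng.random() < 0.5 else "T"
        sequence = "".join(seq)
        proteome[protein] = sequence
        sequons[protein] = scan_sequons(sequence)
        category = ANALYZED_CATEGORIES[int(rng.integers(len(ANALYZED_CATEGORIES)))]
        categories[protein] = category
        raw_labels[protein] = members_by_category[category][
            int(rng.integers(len(members_by_category[category])))
        ]

    brain = sorted(
        rng.choice(
            _protein_ids(config.n_proteins),
            size=max(1, config.n_proteins // 10),
            replace=False,
        ).tolist()
    )
    subcellular = AnnotationMap(
        kind="subcellular", mapping={p: {raw_labels[p]} for p in proteome}
    )
    gene_list = AnnotationMap(kind="gene_list", mapping={g: {"member"} for g in brain})
    gene_sets = AnnotationMap(
        kind="gene_sets",
        mapping={
            p: {f"CAT_{categories[p].replace(' ', '_').upper()}"} for p in proteome
        },
        set_descriptions={
            f"CAT_{cat.replace(' ', '_').upper()}": f"synthetic {cat} set"
            for cat in ANALYZED_CATEGORIES
        },
    )
    truth = GroundTruth(
        variance_fractions=config.variance_fractions,
        categories=categories,
        raw_labels=raw_labels,
        elevated={},
        sequon_positions=sequons,
        brain_enriched=brain,
        nta_dilution_factors=dict(config.nta_dilution_factors),
    )
    return proteome, {
        "subcellular": subcellular,
        "gene_list": gene_list,
        "gene_sets": gene_sets,
    }, truth


def _patients(config: SimConfig) -> list[str]:
    return [f"PT{i:02d}" for i in range(1, config.n_patients + 1)]


def _sample_id(workflow: str, patient: str) -> str:
    return f"{workflow}.{patient}"


def _draw_abundance(
    config: SimConfig, protein_ids: list[str], rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, str]]:
    """Protein x (workflow x patient) log2 abundances plus planted truth."""
    n_p = len(protein_ids)
    n_w = len(config.workflows)
    n_i = config.n_patients
    f_m, f_i, f_e = config.variance_fractions
    total = config.within_variance
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n_p)
    a = rng.normal(0.0, np.sqrt(f_m * total), size=(n_p, n_w))
    b = rng.normal(0.0, np.sqrt(f_i * total), size=(n_p, n_i))
    eps = rng.normal(0.0, np.sqrt(f_e * total), size=(n_p, n_w, n_i))
    y = mu[:, None, None] + a[:, :, None] + b[:, None, :] + eps

    elevated: dict[str, str] = {}
    n_planted = int(round(config.planted_fraction * n_p))
    if n_planted:
        chosen = rng.choice(n_p, size=n_planted, replace=False)
        for rank, idx in enumerate(sorted(chosen)):
            workflow_idx = rank % n_w
            y[idx, workflow_idx, :] += config.planted_effect
            elevated[protein_ids[idx]] = config.workflows[workflow_idx]
    return y, elevated


def _capture_mask(
    config: SimConfig,
    protein_ids: list[str],
    categories: dict[str, str] | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """proteins x workflows boolean mask of per-workflow capture."""
    n_p, n_w = len(protein_ids), len(config.workflows)
    if config.capture_bias is None:
        return np.ones((n_p, n_w), dtype=bool)
    if categories is None:
        categories = {
            p: ANALYZED_CATEGORIES[int(rng.integers(len(ANALYZED_CATEGORIES)))]
            for p in protein_ids
        }
    mask = np.ones((n_p, n_w), dtype=bool)
    for wi, workflow in enumerate(config.workflows):
        by_category = config.capture_bias.get(workflow, {})
        for pi, protein in enumerate(protein_ids):
            prob = by_category.get(categories[protein], 1.0)
            if prob < 1.0:
                mask[pi, wi] = rng.random() < prob
    return mask


def _dropout_keep(
    log2_intensity: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """MNAR detection mask: logistic detection probability in log2 units."""
    if config.dropout_midpoint is None:
        return np.ones_like(log2_intensity, dtype=bool)
    p_detect = 1.0 / (
        1.0
        + np.exp(
            -config.dropout_steepness * (log2_intensity - config.dropout_midpoint)
        )
    )
    return rng.random(log2_intensity.shape) < p_detect


def generate_protein_matrices(
    config: SimConfig, seed: int, categories: dict[str, str] | None = None
) -> tuple[dict[str, QuantMatrix], SampleSheet, dict[str, str]]:
    """Protein-level log2 matrices per workflow, without peptide emission.

    Used wherever only the abundance model matters (variance recovery,
    null calibration); dropout is applied at the protein level here.
    Returns (matrices, sample sheet, planted-elevated truth).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    protein_ids = _protein_ids(config.n_proteins)
    patients = _patients(config)
    y, elevated = _draw_abundance(config, protein_ids, rng)
    keep = _dropout_keep(y, config, rng)
    keep &= _capture_mask(config, protein_ids, categories, rng)[:, :, None]

    sheet = SampleSheet(
        samples={
            _sample_id(w, p): {"method": w, "patient": p}
            for w in config.workflows
            for p in patients
        }
    )
    matrices: dict[str, QuantMatrix] = {}
    for wi, workflow in enumerate(config.workflows):
        samples = [_sample_id(workflow, p) for p in patients]
        data = np.where(keep[:, wi, :], y[:, wi, :], np.nan)
        df = pd.DataFrame(data, index=protein_ids, columns=samples, dtype=float)
        matrices[workflow] = QuantMatrix(
            values=df, sample_meta={s: sheet.samples[s] for s in samples}
        )
    return matrices, sheet, elevated


def generate_cohort(
    config: SimConfig,
    proteome: dict[str, str],
    truth: GroundTruth,
    seed: int,
) -> tuple[dict[str, PeptideTable], SiteTable, SampleSheet]:
    """Emit per-workflow peptide tables, the glyco site table and the sheet.

    Peptide intensities are Dirichlet shares of the protein's raw
    intensity over its in-range tryptic peptides, so summation recovers
    the protein exactly in the noise-free limit; dropout then thins
    observations as a logistic function of peptide log2 intensity.
    """
    streams = np.random.SeedSequence(seed).spawn(3)
    rng = np.random.default_rng(streams[0])
    protein_ids = sorted(proteome)
    patients = _patients(config)
    y, elevated = _draw_abundance(config, protein_ids, rng)
    truth.elevated = elevated
    captured = _capture_mask(config, protein_ids, truth.categories, rng)

    lo, hi = config.peptide_length_range
    peptides_of: dict[str, list[str]] = {}
    shares_of: dict[str, np.ndarray] = {}
    for protein in protein_ids:
        peps = [
            p.sequence
            for p in digest(
                proteome[protein],
                protein,
                max_missed=config.digest_max_missed,
            )
            if lo <= len(p.sequence) <= hi
        ]
        peptides_of[protein] = peps
        if peps:
            shares_of[protein] = rng.dirichlet(np.ones(len(peps)))

    sheet = SampleSheet(
        samples={
            _sample_id(w, p): {"method": w, "patient": p}
            for w in config.workflows
            for p in patients
        }
    )

    tables: dict[str, PeptideTable] = {}
    for wi, workflow in enumerate(config.workflows):
        samples = [_sample_id(workflow, p) for p in patients]
        records: list[PeptideRecord] = []
        for pi, protein in enumerate(protein_ids):
            peps = peptides_of[protein]
            if not peps or not captured[pi, wi]:
                continue
            raw_protein = 2.0 ** y[pi, wi, :]  # per patient
            intensity = raw_protein[None, :] * shares_of[protein][:, None]
            keep = _dropout_keep(np.log2(intensity), config, rng)
            for j, pep in enumerate(peps):
                intensities = {
                    samples[k]: float(intensity[j, k])
                    for k in range(len(samples))
                    if keep[j, k]
                }
                if intensities:
                    records.append(
                        PeptideRecord(
                            sequence=pep,
                            accessions=(protein,),
                            intensities=intensities,
                        )
                    )
        tables[workflow] = PeptideTable(records=records, workflow=workflow)

    site_table = _generate_sites(
        config, proteome, truth, y, protein_ids, captured, streams[1]
    )
    return tables, site_table, sheet


def _generate_sites(
    config: SimConfig,
    proteome: dict[str, str],
    truth: GroundTruth,
    y: np.ndarray,
    protein_ids: list[str],
    captured: np.ndarray,
    stream,
) -> SiteTable:
    """Deamidation evidence: sequon sites plus non-sequon decoys."""
    rng = np.random.default_rng(stream)
    patients = _patients(config)
    try:
        wi = list(config.workflows).index(config.glyco_workflow)
    except ValueError:
        wi = 0
    workflow = config.workflows[wi]
    samples = [_sample_id(workflow, p) for p in patients]
    records: list[SiteRecord] = []

    def emit(protein_idx: int, protein: str, position: int, p_loc: float) -> None:
        raw = 2.0 ** y[protein_idx, wi, :] * rng.uniform(0.05, 0.3)
        keep = _dropout_keep(np.log2(raw), config, rng)
        intensities = {
            samples[k]: float(raw[k]) for k in range(len(samples)) if keep[k]
        }
        seq = proteome[protein]
        window = seq[max(0, position - 6) : position + 5]
        records.append(
            SiteRecord(
                accession=protein,
                position=position,
                localization_probability=round(float(p_loc), 6),
                sequence_window=window,
                intensities=intensities,
            )
        )

    for pi, protein in enumerate(protein_ids):
        if not captured[pi, wi]:
            continue
        for position in truth.sequon_positions.get(protein, []):
            if rng.random() < config.p_high_localization:
                p_loc = rng.beta(20.0, 1.0)
            else:
                p_loc = rng.beta(2.0, 2.0)
            emit(pi, protein, position, p_loc)

    # decoys: deamidation at asparagines outside any sequon
    sequon_sets = {p: set(truth.sequon_positions.get(p, [])) for p in protein_ids}
    emitted = 0
    order = rng.permutation(len(protein_ids))
    for pi in order:
        if emitted >= config.glyco_decoy_sites:
            break
        if not captured[pi, wi]:
            continue
        protein = protein_ids[pi]
        seq = proteome[protein]
        candidates = [
            i + 1
            for i, residue in enumerate(seq)
            if residue == "N" and (i + 1) not in sequon_sets[protein]
        ]
        if not candidates:
            continue
        position = int(candidates[int(rng.integers(len(candidates)))])
        emit(pi, protein, position, rng.beta(2.0, 2.0))
        emitted += 1
    return SiteTable(records=records, workflow=workflow)


def generate_nta(config: SimConfig, seed: int) -> dict[str, pd.DataFrame]:
    """Raw (pre-dilution) NTA export frames per EV fraction.

    Bin centers run 10-990 nm in 10 nm steps; the true size distribution
    is log-normal around the fraction's peak; per-video counts add
    multiplicative log-normal noise. The stored values are the *diluted*
    instrument readings, so multiplying by the dilution factor recovers
    the configured totals in expectation.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    centers = np.arange(10.0, 1000.0, 10.0)
    out: dict[str, pd.DataFrame] = {}
    for fraction in sorted(config.nta_dilution_factors):
        peak = config.nta_peak_nm[fraction]
        total = config.nta_total_particles[fraction]
        sigma = 0.35
        density = np.exp(
            -((np.log(centers) - np.log(peak)) ** 2) / (2 * sigma**2)
        ) / centers
        density /= density.sum()
        truth_counts = total * density / config.nta_dilution_factors[fraction]
        frame = pd.DataFrame({"bin_center_nm": centers})
        for v in range(1, config.nta_videos + 1):
            noise = rng.lognormal(mean=0.0, sigma=0.1, size=len(centers))
            frame[f"video_{v}"] = truth_counts * noise
        out[fraction] = frame
    return out


def write_cohort(config: SimConfig, seed: int, outdir) -> dict:
    """Generate a full cohort and write every artifact to ``outdir``.

    Returns a manifest of the files written. Same seed -> byte-identical
    outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(seed).spawn(2)
    proteome, annotations, truth = generate_proteome(config, seed)
    tables, site_table, sheet = generate_cohort(
        config, proteome, truth, int(streams[1].generate_state(1)[0] % (2**31))
    )
    nta = generate_nta(config, seed)

    write_fasta(proteome, outdir / "proteome.fasta")
    write_sample_sheet(sheet, outdir / "sample_sheet.tsv")
    manifest = {
        "fasta": "proteome.fasta",
        "sample_sheet": "sample_sheet.tsv",
        "peptide_tables": {},
        "site_table": "sites.N-Gp.tsv",
        "nta": {},
    }
    for workflow, table in tables.items():
        name = f"peptides.{workflow}.tsv"
        write_peptide_table(table, outdir / name)
        manifest["peptide_tables"][workflow] = name
    write_site_table(site_table, outdir / "sites.N-Gp.tsv")

    with open(outdir / "subcellular.tsv", "w") as fh:
        for protein in sorted(truth.raw_labels):
            fh.write(f"{protein}\t{truth.raw_labels[protein]}\n")
    with open(outdir / "brain_enriched.tsv", "w") as fh:
        for gene in truth.brain_enriched:
            fh.write(gene + "\n")
    with open(outdir / "gene_sets.gmt", "w") as fh:
        by_set: dict[str, list[str]] = {}
        for gene, sets in sorted(annotations["gene_sets"].mapping.items()):
            for s in sets:
                by_set.setdefault(s, []).append(gene)
        for set_name in sorted(by_set):
            description = annotations["gene_sets"].set_descriptions.get(set_name, "")
            fh.write("\t".join([set_name, description] + by_set[set_name]) + "\n")
    for fraction, frame in nta.items():
        name = f"{fraction}-ExperimentSummary.csv"
        frame.to_csv(outdir / name, index=False)
        manifest["nta"][fraction] = name
    truth.to_json(outdir / "ground_truth.json")
    manifest["ground_truth"] = "ground_truth.json"
    manifest["annotations"] = {
        "subcellular": "subcellular.tsv",
        "gene_list": "brain_enriched.tsv",
        "gene_sets": "gene_sets.gmt",
    }
    return manifest
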