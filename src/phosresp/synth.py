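"""Synthetic phosphoproteomics datasets with planted, recorded structure.

The generator emulates the statistical structure the downstream analyses
assume, so every stage of the pipeline is testable without external data:

* log-normal peptide intensities (MS peak intensities span orders of
  magnitude and are roughly log-normal), with multiplicative replicate
  noise of a stated coefficient of variation;
* a tumor-type classification design — by default three diseases (AML,
  lymphoma, myeloma) with three cell lines each in six replicates, giving a
  2,000 x 54 matrix — where a disjoint random subset of peptides per
  disease is multiplied by a planted fold in that disease's samples, and
  every cell line carries a smaller log-normal offset profile giving it an
  identity of its own;
* a drug-response design — by default seven AML lines in triplicate,
  2,000 x 21 — where planted resistance markers follow
  ``baseline * exp(marker_slope * viability)`` (sensitivity markers use the
  negated slope), implementing the exponential intensity-viability
  relationship as the generative truth, and motif-assigned peptides share
  an additive log-scale shift equal to their motif's latent per-cell-line
  kinase activity (one motif's activity is linked to viability; the rest
  are drawn from N(0, kinase_activity_sd)).

Everything planted is recorded in a truth object serialized alongside the
data, so tests never have to re-derive it. Identical configs (including the
seed) produce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import (
    IntensityMatrix,
    PhosphoSiteAnnotation,
    SampleMeta,
    ViabilityTable,
    write_fasta,
    write_intensity_matrix,
    write_sample_meta,
    write_site_annotations,
    write_viability,
)
from .motifs import AMINO_ACIDS, Motif, load_motif_library

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "SynthDataset",
    "drug_response_config",
    "default_viability_table",
    "generate_classification_dataset",
    "generate_drug_response_dataset",
    "generate_protein_db_and_sites",
    "write_dataset",
]

DEFAULT_DRUGS = ("PI-103", "MEK-i", "JAK-i")

#: Motifs auto-assigned to peptides in the drug-response design.
DEFAULT_ASSIGNED_MOTIFS = (
    "xRxxSx",
    "xRxSx",
    "xKxSx",
    "RxRxxSx",
    "xSPx",
    "SxxE",
    "SxxD",
    "LxRxxSx",
    "DxxSx",
    "pY",
)


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters. Log-scale parameters are natural-log."""

    n_peptides: int = 2000
    diseases: tuple[tuple[str, int], ...] = (("AML", 3), ("lymphoma", 3), ("myeloma", 3))
    replicates_per_line: int = 6
    baseline_log_mean: float = 14.0
    baseline_log_sd: float = 1.5
    disease_effect_fraction: float = 0.05
    disease_effect_fold: float = 2.0
    line_effect_sd: float = 0.15
    marker_count_per_direction: int = 10
    marker_slope: float = 0.05  # per %-viability exponential rate
    noise_cv: float = 0.2
    motif_assignments: Mapping[str, str] | None = None
    peptides_per_motif: int = 15
    assigned_motifs: tuple[str, ...] = DEFAULT_ASSIGNED_MOTIFS
    responsive_motif: str = "RxRxxSx"
    kinase_activity_sd: float = 0.5
    motif_response_slope: float = 0.02  # per %-viability, on the natural-log scale
    marker_drug: str | None = None
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peptides < 1 or self.replicates_per_line < 1:
            raise ValueError("all counts must be >= 1")
        if not self.diseases or any(count < 1 for _, count in self.diseases):
            raise ValueError("each disease needs at least one cell line")
        if self.disease_effect_fold <= 1:
            raise ValueError("disease_effect_fold must be > 1")
        if not 0 <= self.disease_effect_fraction <= 1:
            raise ValueError("disease_effect_fraction must be in [0, 1]")
        if self.noise_cv < 0 or self.line_effect_sd < 0 or self.kinase_activity_sd < 0:
            raise ValueError("spread parameters must be non-negative")
        if self.marker_count_per_direction < 0:
            raise ValueError("marker_count_per_direction must be >= 0")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")

    @property
    def cell_lines(self) -> tuple[tuple[str, str], ...]:
        """(line name, disease) pairs, in declaration order."""
        return tuple(
            (f"{disease}{i}", disease)
            for disease, count in self.diseases
            for i in range(1, count + 1)
        )

    @property
    def sample_ids(self) -> tuple[tuple[str, str, int], ...]:
        """(sample id, line, replicate index) triples."""
        return tuple(
            (f"{line}_r{rep}", line, rep)
            for line, _ in self.cell_lines
            for rep in range(1, self.replicates_per_line + 1)
        )

    @property
    def peptide_ids(self) -> tuple[str, ...]:
        return tuple(f"pep{i:04d}" for i in range(self.n_peptides))


def drug_response_config(**overrides) -> SynthConfig:
    """Config preset for the drug-response design: 7 AML lines x 3 replicates.

    Sets ``line_effect_sd`` to 0 so that, apart from the planted markers and
    motif-level kinase activities, peptides are independent of the cell line
    (and hence of viability), as the drug-response design assumes.
    """
    base = dict(diseases=(("AML", 7),), replicates_per_line=3, line_effect_sd=0.0)
    base.update(overrides)
    return SynthConfig(**base)


@dataclass(frozen=True)
class SynthTruth:
    """Record of everything planted by the generator."""

    disease_effect_peptides: dict[str, tuple[str, ...]] = field(default_factory=dict)
    resistance_markers: tuple[str, ...] = ()
    sensitivity_markers: tuple[str, ...] = ()
    marker_drug: str = ""
    motif_assignments: dict[str, str] = field(default_factory=dict)
    responsive_motif: str = ""
    kinase_activities: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SynthTruth":
        raw = json.loads(text)
        raw["disease_effect_peptides"] = {
            k: tuple(v) for k, v in raw.get("disease_effect_peptides", {}).items()
        }
        raw["resistance_markers"] = tuple(raw.get("resistance_markers", ()))
        raw["sensitivity_markers"] = tuple(raw.get("sensitivity_markers", ()))
        return cls(**raw)

    @property
    def all_peptides(self) -> set[str]:
        out: set[str] = set()
        for peptides in self.disease_effect_peptides.values():
            out |= set(peptides)
        out |= set(self.resistance_markers) | set(self.sensitivity_markers)
        out |= set(self.motif_assignments)
        return out


@dataclass(frozen=True)
class SynthDataset:
    intensities: IntensityMatrix
    meta: SampleMeta
    viability: ViabilityTable
    truth: SynthTruth

    def __post_init__(self) -> None:
        matrix_peptides = set(self.intensities.peptide_ids)
        stray = self.truth.all_peptides - matrix_peptides
        if stray:
            raise ValueError(f"truth references peptides absent from matrix: {sorted(stray)[:5]}")
        stray_samples = set(self.intensities.sample_ids) - set(self.meta.sample_ids)
        if stray_samples:
            raise ValueError(f"matrix samples absent from metadata: {sorted(stray_samples)[:5]}")


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _noise_log_sd(cv: float) -> float:
    # exact log-normal relation: CV^2 = exp(sigma^2) - 1
    return float(np.sqrt(np.log1p(cv**2)))


def _build_meta(cfg: SynthConfig, rng: np.random.Generator) -> SampleMeta:
    line_disease = dict(cfg.cell_lines)
    rows = []
    for sample_id, line, rep in cfg.sample_ids:
        rows.append(
            {
                "sample_id": sample_id,
                "cell_line": line,
                "disease": line_disease[line],
                "replicate": rep,
            }
        )
    df = pd.DataFrame(rows).set_index("sample_id")
    df["run_order"] = rng.permutation(len(df)) + 1  # random LC-MS/MS run order
    return SampleMeta(df)


def _apply_missing(
    log_int: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    if fraction <= 0:
        return log_int
    mask = rng.random(log_int.shape) < fraction
    out = log_int.copy()
    out[mask] = np.nan
    return out


def default_viability_table(
    cell_lines: Iterable[str],
    drugs: tuple[str, ...] = DEFAULT_DRUGS,
    seed: int = 0,
    low: float = 5.0,
    high: float = 95.0,
) -> ViabilityTable:
    """Evenly spread viabilities in [low, high], permuted per drug.

    Each drug assigns the same set of viability values to the cell lines in
    a different (seeded) order, so drugs have distinct response rankings.
    """
    lines = list(cell_lines)
    values = np.linspace(low, high, len(lines))
    rows = []
    for k, drug in enumerate(drugs):
        rng = np.random.default_rng([seed, 3, k])
        for line, v in zip(lines, values[rng.permutation(len(lines))]):
            rows.append({"cell_line": line, "drug": drug, "viability_percent": float(v)})
    return ViabilityTable(pd.DataFrame(rows))


def _empty_viability() -> ViabilityTable:
    return ViabilityTable(
        pd.DataFrame({"cell_line": [], "drug": [], "viability_percent": []})
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_classification_dataset(cfg: SynthConfig) -> SynthDataset:
    """Multi-disease dataset with planted per-disease fold shifts.

    For each disease, a disjoint random subset of
    ``disease_effect_fraction * n_peptides`` peptides is multiplied by
    ``disease_effect_fold`` in that disease's samples. Cell-line offset
    profiles (sd ``line_effect_sd`` on the log scale) are smaller than the
    disease shifts; replicate noise is multiplicative with CV ``noise_cv``.
    """
    if len(cfg.diseases) < 2 or any(count < 2 for _, count in cfg.diseases):
        raise ValueError("classification design needs >=2 diseases with >=2 cell lines each")
    rng = np.random.default_rng([cfg.seed, 0])
    peptides = cfg.peptide_ids
    meta = _build_meta(cfg, rng)

    n_eff = int(round(cfg.disease_effect_fraction * cfg.n_peptides))
    diseases = [d for d, _ in cfg.diseases]
    if n_eff * len(diseases) > cfg.n_peptides:
        raise ValueError(
            f"disjoint planted sets need {n_eff * len(diseases)} peptides "
            f"but only {cfg.n_peptides} exist"
        )
    chosen = rng.choice(cfg.n_peptides, size=n_eff * len(diseases), replace=False)
    effect_sets = {
        d: np.sort(chosen[i * n_eff : (i + 1) * n_eff]) for i, d in enumerate(diseases)
    }

    log_base = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_peptides)
    line_offsets = {
        line: rng.normal(0.0, cfg.line_effect_sd, cfg.n_peptides)
        for line, _ in cfg.cell_lines
    }
    log_fold = np.log(cfg.disease_effect_fold)
    sd = _noise_log_sd(cfg.noise_cv)
    line_disease = dict(cfg.cell_lines)

    columns = {}
    for sample_id, line, _rep in cfg.sample_ids:
        log_int = log_base + line_offsets[line] + rng.normal(0.0, sd, cfg.n_peptides)
        log_int[effect_sets[line_disease[line]]] += log_fold
        columns[sample_id] = log_int
    log_matrix = np.column_stack([columns[s] for s, _, _ in cfg.sample_ids])
    log_matrix = _apply_missing(log_matrix, cfg.missing_fraction, rng)
    matrix = IntensityMatrix(
        pd.DataFrame(
            np.exp(log_matrix),
            index=pd.Index(peptides, name="peptide_id"),
            columns=[s for s, _, _ in cfg.sample_ids],
        ),
        provenance=("synthetic:classification",),
    )
    truth = SynthTruth(
        disease_effect_peptides={
            d: tuple(peptides[i] for i in idx) for d, idx in effect_sets.items()
        }
    )
    return SynthDataset(intensities=matrix, meta=meta, viability=_empty_viability(), truth=truth)


def generate_drug_response_dataset(
    cfg: SynthConfig, viabilities: ViabilityTable
) -> SynthDataset:
    """Drug-response dataset with planted markers and motif-coherent shifts.

    Resistance markers follow ``baseline * exp(marker_slope * (viability -
    mean viability))`` under ``marker_drug`` (the first drug in the table
    when unset); sensitivity markers use the negated slope. Centering the
    exponent is the same exponential law with a rescaled baseline; it keeps
    marker intensities inside the normal dynamic range, so a handful of
    markers cannot dominate a sample's total chromatogram intensity (which
    would distort total-intensity normalization for every other peptide).
    Motif-assigned peptides additionally receive their
    motif's latent per-cell-line kinase activity on the log scale; the
    ``responsive_motif``'s activity is ``motif_response_slope *
    (viability - mean viability)``, all others are N(0, kinase_activity_sd)
    draws per cell line.
    """
    lines = [line for line, _ in cfg.cell_lines]
    missing = sorted(set(lines) - set(viabilities.cell_lines))
    if missing:
        raise ValueError(f"viability table missing cell lines: {missing}")
    drug = cfg.marker_drug or sorted(viabilities.drugs)[0]
    viab = viabilities.for_drug(drug)
    rng = np.random.default_rng([cfg.seed, 1])
    peptides = cfg.peptide_ids
    meta = _build_meta(cfg, rng)

    k = cfg.marker_count_per_direction
    if cfg.motif_assignments is not None:
        assignments = dict(cfg.motif_assignments)
        stray = sorted(set(assignments) - set(peptides))
        if stray:
            raise ValueError(f"motif_assignments reference unknown peptides: {stray[:5]}")
        n_motif = 0  # provided assignments may overlap markers; caller's choice
        pool = [i for i, p in enumerate(peptides) if p not in assignments]
        if 2 * k > len(pool):
            raise ValueError("not enough unassigned peptides for the requested marker counts")
        marker_idx = rng.choice(len(pool), size=2 * k, replace=False)
        marker_idx = np.array([pool[i] for i in marker_idx])
    else:
        n_motif = cfg.peptides_per_motif * len(cfg.assigned_motifs)
        if 2 * k + n_motif > cfg.n_peptides:
            raise ValueError(
                f"planted sets need {2 * k + n_motif} peptides but only "
                f"{cfg.n_peptides} exist"
            )
        chosen = rng.choice(cfg.n_peptides, size=2 * k + n_motif, replace=False)
        marker_idx = chosen[: 2 * k]
        motif_idx = chosen[2 * k :]
        assignments = {}
        for m, name in enumerate(cfg.assigned_motifs):
            for i in motif_idx[m * cfg.peptides_per_motif : (m + 1) * cfg.peptides_per_motif]:
                assignments[peptides[i]] = name
    res_idx, sens_idx = np.sort(marker_idx[:k]), np.sort(marker_idx[k:])

    motif_names = sorted(set(assignments.values()))
    activities: dict[str, dict[str, float]] = {}
    viab_mean = float(viab.loc[lines].mean())
    for name in motif_names:
        if name == cfg.responsive_motif:
            activities[name] = {
                line: cfg.motif_response_slope * (float(viab[line]) - viab_mean)
                for line in lines
            }
        else:
            draws = rng.normal(0.0, cfg.kinase_activity_sd, len(lines))
            activities[name] = {line: float(a) for line, a in zip(lines, draws)}

    log_base = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_peptides)
    line_offsets = {
        line: rng.normal(0.0, cfg.line_effect_sd, cfg.n_peptides) for line in lines
    }
    sd = _noise_log_sd(cfg.noise_cv)
    pep_index = {p: i for i, p in enumerate(peptides)}

    columns = {}
    for sample_id, line, _rep in cfg.sample_ids:
        v = float(viab[line]) - viab_mean
        log_int = log_base + line_offsets[line] + rng.normal(0.0, sd, cfg.n_peptides)
        log_int[res_idx] += cfg.marker_slope * v
        log_int[sens_idx] -= cfg.marker_slope * v
        for pep, name in assignments.items():
            log_int[pep_index[pep]] += activities[name][line]
        columns[sample_id] = log_int
    log_matrix = np.column_stack([columns[s] for s, _, _ in cfg.sample_ids])
    log_matrix = _apply_missing(log_matrix, cfg.missing_fraction, rng)
    matrix = IntensityMatrix(
        pd.DataFrame(
            np.exp(log_matrix),
            index=pd.Index(peptides, name="peptide_id"),
            columns=[s for s, _, _ in cfg.sample_ids],
        ),
        provenance=("synthetic:drug_response",),
    )
    truth = SynthTruth(
        resistance_markers=tuple(peptides[i] for i in res_idx),
        sensitivity_markers=tuple(peptides[i] for i in sens_idx),
        marker_drug=drug,
        motif_assignments=assignments,
        responsive_motif=cfg.responsive_motif if cfg.responsive_motif in motif_names else "",
        kinase_activities=activities,
    )
    return SynthDataset(intensities=matrix, meta=meta, viability=viabilities, truth=truth)


def generate_protein_db_and_sites(
    cfg: SynthConfig,
    motif_assignments: Mapping[str, str] | None = None,
    library: Iterable[Motif] | None = None,
) -> tuple[dict[str, str], list[PhosphoSiteAnnotation]]:
    """Synthetic protein sequences realizing each peptide's assigned motif.

    For every peptide a protein and a 1-based site position are generated so
    that the 15-mer window centered on the site satisfies the assigned motif
    pattern (wildcard positions are filled uniformly at random); peptides
    without an assignment get an unconstrained S/T/Y site. Constrained
    offsets are always placed inside the protein, so assigned motifs match
    regardless of terminal padding.
    """
    assignments = dict(motif_assignments) if motif_assignments is not None else None
    if assignments is None:
        if cfg.motif_assignments is None:
            raise ValueError(
                "motif_assignments required: pass the truth assignments of a "
                "generated dataset or set them in the config"
            )
        assignments = dict(cfg.motif_assignments)
    lib = {m.name: m for m in (library if library is not None else load_motif_library())}
    unknown = sorted(set(assignments.values()) - set(lib))
    if unknown:
        raise ValueError(f"assigned motifs missing from the library: {unknown}")
    rng = np.random.default_rng([cfg.seed, 2])
    aa = np.array(list(AMINO_ACIDS))
    proteins: dict[str, str] = {}
    sites: list[PhosphoSiteAnnotation] = []
    for pid in cfg.peptide_ids:
        length = int(rng.integers(24, 40))
        seq = rng.choice(aa, size=length)
        motif = lib.get(assignments.get(pid, ""))
        if motif is not None:
            offs = list(motif.offsets) or [0]
            lo = max(0, -min(offs + [0]))
            hi = min(length - 1, length - 1 - max(offs + [0]))
            if lo > hi:
                raise ValueError(
                    f"motif {motif.name!r} cannot be placed in a protein of length {length}"
                )
            pos0 = int(rng.integers(lo, hi + 1))
            center = "Y" if motif.acceptor_class == "Y" else str(rng.choice(["S", "T"]))
            seq[pos0] = center
            for off, residue in motif.offsets.items():
                seq[pos0 + off] = residue
        else:
            pos0 = int(rng.integers(0, length))
            center = str(rng.choice(["S", "T", "Y"]))
            seq[pos0] = center
        protein_id = f"PROT_{pid}"
        proteins[protein_id] = "".join(seq)
        sites.append(
            PhosphoSiteAnnotation(
                peptide_id=pid,
                protein_id=protein_id,
                position=pos0 + 1,
                residue=center,
                gene=pid.upper(),
            )
        )
    return proteins, sites


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_dataset(
    dataset: SynthDataset,
    directory: str | Path,
    proteins: Mapping[str, str] | None = None,
    sites: Iterable[PhosphoSiteAnnotation] | None = None,
) -> dict[str, Path]:
    """Write a dataset (and optionally its protein database) as TSV/FASTA/JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": directory / "intensity_matrix.tsv",
        "meta": directory / "sample_meta.tsv",
        "viability": directory / "viability.tsv",
        "truth": directory / "truth.json",
    }
    write_intensity_matrix(dataset.intensities, paths["intensities"])
    write_sample_meta(dataset.meta, paths["meta"])
    write_viability(dataset.viability, paths["viability"])
    paths["truth"].write_text(dataset.truth.to_json())
    if proteins is not None:
        paths["fasta"] = directory / "proteins.fasta"
        write_fasta(proteins, paths["fasta"])
    if sites is not None:
        paths["sites"] = directory / "sites.tsv"
        write_site_annotations(sites, paths["sites"])
    return paths
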