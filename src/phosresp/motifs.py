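"""Phosphosite sequence windows, motif matching, and motif-level correlation.

A phosphosite context is a 15-mer window: the phosphorylated residue in the
center flanked by seven residues on each side, with positions beyond a
protein terminus padded with ``_``. Motifs are wildcard patterns over the
window (``x`` matches anything, including padding; a residue constraint is
never satisfied by padding). No distinction is made between phospho-Ser and
phospho-Thr motifs — an ST-class motif's center matches S or T — while
tyrosine phosphosites are grouped under a single Y-class motif.

Motif-level drug-response correlation averages, per sample, the log2
normalized intensities of all peptides matching a motif (restricted by
default to peptides whose own semi-log correlation passes |R| >= 0.45) and
correlates that profile with viability; motifs are ranked by |R|.

A default library of common basophilic, proline-directed, acidophilic, and
hydrophobic-directed motifs plus the single pY class ships with the package
(``data/motif_library.tsv``); results should always report which library
was used.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import PhosphoSiteAnnotation, SampleMeta, ViabilityTable
from .markers import R_THRESHOLD_DEFAULT, correlate_peptides
from .preprocess import NormalizedMatrix

__all__ = [
    "AMINO_ACIDS",
    "PAD",
    "WINDOW_LENGTH",
    "SequenceWindow",
    "Motif",
    "MotifCorrelationResult",
    "parse_motif",
    "build_window",
    "match_motif",
    "load_motif_library",
    "motif_viability_correlation",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "_"
WINDOW_LENGTH = 15
CENTER = WINDOW_LENGTH // 2  # 0-based index 7 = 1-based position 8


@dataclass(frozen=True)
class SequenceWindow:
    """Phosphosite-centered 15-mer; ``_`` pads past the protein termini."""

    peptide_id: str
    window: str

    def __post_init__(self) -> None:
        w = self.window
        if len(w) != WINDOW_LENGTH:
            raise ValueError(f"window must be {WINDOW_LENGTH} characters, got {len(w)}")
        if w[CENTER] not in "STY":
            raise ValueError(f"center residue must be S/T/Y, got {w[CENTER]!r}")
        core = w.strip(PAD)
        if PAD in core:
            raise ValueError("padding must be contiguous at the window ends")
        bad = set(core) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"invalid residues in window: {sorted(bad)}")

    @property
    def center_residue(self) -> str:
        return self.window[CENTER]


@dataclass(frozen=True)
class Motif:
    """Wildcard motif with one phosphoacceptor position at the center.

    ``acceptor_class`` is ``"ST"`` (center matches S or T) or ``"Y"``.
    ``offsets`` maps center-relative positions (excluding 0) to required
    residues.
    """

    name: str
    pattern: str
    acceptor_class: str
    offsets: Mapping[int, str]
    family: str = ""

    def is_subset_of(self, other: "Motif") -> bool:
        """True if every constraint of self is also imposed by other."""
        if self.acceptor_class != other.acceptor_class:
            return False
        return all(other.offsets.get(k) == v for k, v in self.offsets.items())


def parse_motif(name: str, pattern: str, acceptor_class: str, family: str = "") -> Motif:
    """Parse a wildcard pattern, locating the phosphoacceptor.

    The acceptor is the lowercase ``s``/``t``/``y`` if one is present;
    otherwise the pattern must contain exactly one residue of the acceptor
    class (S/T for class ST, Y for class Y). Anything else is ambiguous and
    rejected.
    """
    acceptor_class = acceptor_class.upper()
    if acceptor_class not in ("ST", "Y"):
        raise ValueError(f"motif {name!r}: acceptor class must be ST or Y")
    if not 1 <= len(pattern) <= WINDOW_LENGTH:
        raise ValueError(f"motif {name!r}: pattern length must be 1..{WINDOW_LENGTH}")
    class_letters = set(acceptor_class)
    lower = [i for i, ch in enumerate(pattern) if ch in {c.lower() for c in class_letters}]
    if len(lower) > 1:
        raise ValueError(f"motif {name!r}: more than one acceptor mark in {pattern!r}")
    if lower:
        acceptor_idx = lower[0]
    else:
        candidates = [i for i, ch in enumerate(pattern) if ch in class_letters]
        if len(candidates) != 1:
            raise ValueError(
                f"motif {name!r}: pattern {pattern!r} has {len(candidates)} possible "
                f"acceptor positions; mark exactly one (lowercase)"
            )
        acceptor_idx = candidates[0]
    offsets: dict[int, str] = {}
    for i, ch in enumerate(pattern):
        if i == acceptor_idx or ch == "x":
            continue
        ch_up = ch.upper()
        if ch_up not in AMINO_ACIDS:
            raise ValueError(f"motif {name!r}: illegal character {ch!r} in pattern")
        off = i - acceptor_idx
        if not -CENTER <= off <= CENTER:
            raise ValueError(f"motif {name!r}: constraint at offset {off} falls outside the window")
        offsets[off] = ch_up
    return Motif(
        name=name,
        pattern=pattern,
        acceptor_class=acceptor_class,
        offsets=offsets,
        family=family,
    )


def build_window(site: PhosphoSiteAnnotation, proteins: Mapping[str, str]) -> SequenceWindow:
    """Extract the 15-mer centered on a phosphosite from its protein."""
    if site.protein_id not in proteins:
        raise KeyError(f"protein {site.protein_id!r} not in the supplied database")
    seq = proteins[site.protein_id]
    pos0 = site.position - 1
    if pos0 >= len(seq):
        raise ValueError(
            f"position {site.position} beyond end of protein {site.protein_id!r} "
            f"(length {len(seq)})"
        )
    if seq[pos0] != site.residue:
        raise ValueError(
            f"residue mismatch at {site.protein_id!r} position {site.position}: "
            f"annotation says {site.residue!r}, sequence has {seq[pos0]!r}"
        )
    left = max(0, pos0 - CENTER)
    right = min(len(seq), pos0 + CENTER + 1)
    window = (
        PAD * (CENTER - (pos0 - left)) + seq[left:right] + PAD * (CENTER - (right - 1 - pos0))
    )
    return SequenceWindow(peptide_id=site.peptide_id, window=window)


def match_motif(w: SequenceWindow, m: Motif) -> bool:
    """True iff the window satisfies every constraint of the motif."""
    center = w.window[CENTER]
    if m.acceptor_class == "ST":
        if center not in "ST":
            return False
    elif center != "Y":
        return False
    for off, residue in m.offsets.items():
        if w.window[CENTER + off] != residue:  # PAD never equals a residue
            return False
    return True


def load_motif_library(path: str | Path | None = None) -> list[Motif]:
    """Load a motif library TSV (columns name, pattern, class[, family]).

    With no path, the packaged default library is loaded.
    """
    if path is None:
        ref = resources.files("phosresp").joinpath("data/motif_library.tsv")
        lines = ref.read_text().splitlines()
        source = "packaged motif_library.tsv"
    else:
        lines = Path(path).read_text().splitlines()
        source = str(path)
    if not lines:
        raise ValueError(f"{source}: empty motif library")
    header = lines[0].rstrip("\n").split("\t")
    required = ["name", "pattern", "class"]
    if header[: len(required)] != required:
        raise ValueError(f"{source}: header must start with {required}, got {header}")
    has_family = "family" in header
    motifs: list[Motif] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{source} line {lineno}: expected >=3 tab-separated fields")
        name, pattern, cls = fields[0], fields[1], fields[2]
        family = fields[header.index("family")] if has_family and len(fields) > 3 else ""
        if name in seen:
            raise ValueError(f"{source} line {lineno}: duplicate motif name {name!r}")
        seen.add(name)
        try:
            motifs.append(parse_motif(name, pattern, cls, family=family))
        except ValueError as exc:
            raise ValueError(f"{source} line {lineno}: {exc}") from exc
    return motifs


@dataclass(frozen=True)
class MotifCorrelationResult:
    """Ranked motif-level correlations for one drug.

    ``table`` columns: motif, family, n_matched, r_log, rank (1 = largest
    |R|). ``unmatched`` lists motifs with zero contributing peptides;
    ``n_uncovered`` counts matrix peptides without a sequence window.
    """

    drug: str
    table: pd.DataFrame
    unmatched: tuple[str, ...]
    n_uncovered: int
    library_size: int
    profiles: pd.DataFrame  # motif x sample mean log2 intensity


def motif_viability_correlation(
    windows: Mapping[str, SequenceWindow] | Iterable[SequenceWindow],
    normm: NormalizedMatrix,
    meta: SampleMeta,
    viability: ViabilityTable,
    drug: str,
    library: Iterable[Motif] | None = None,
    r_peptide_threshold: float | None = R_THRESHOLD_DEFAULT,
) -> MotifCorrelationResult:
    """Correlate motif-averaged log2 intensities with viability.

    For each motif: collect matrix peptides whose window matches it (and,
    unless ``r_peptide_threshold`` is None, whose own |R_log| passes the
    threshold), average their log2 normalized intensities per sample
    (duplicate peptide ids collapse to one row), and correlate the profile
    with per-sample viability. Motifs matching zero peptides are listed
    separately instead of ranked.
    """
    if library is None:
        library = load_motif_library()
    library = list(library)
    if not library:
        raise ValueError("motif library is empty")
    if not isinstance(windows, Mapping):
        windows = {w.peptide_id: w for w in windows}
    df = normm.data[~normm.data.index.duplicated(keep="first")]
    normm = NormalizedMatrix(df, provenance=normm.provenance)
    peptides = list(df.index)
    covered = [p for p in peptides if p in windows]
    n_uncovered = len(peptides) - len(covered)

    if r_peptide_threshold is not None:
        records = correlate_peptides(normm, meta, viability, drug)
        rmap = records.set_index("peptide_id")
        eligible = [
            p
            for p in covered
            if bool(rmap.at[p, "valid"]) and abs(float(rmap.at[p, "r_log"])) >= r_peptide_threshold
        ]
    else:
        eligible = covered

    viab_map = viability.for_drug(drug)
    sample_lines = [meta.cell_line_of(s) for s in df.columns]
    missing = sorted(set(sample_lines) - set(viab_map.index))
    if missing:
        raise ValueError(f"no viability for drug {drug!r} in cell lines: {missing}")
    viab = np.array([viab_map[line] for line in sample_lines], dtype=float)
    log_df = np.log2(df.to_numpy(dtype=float).clip(min=np.finfo(float).tiny))
    row_of = {p: i for i, p in enumerate(peptides)}

    rows = []
    profiles = {}
    unmatched = []
    for motif in library:
        matched = [p for p in eligible if match_motif(windows[p], motif)]
        if not matched:
            unmatched.append(motif.name)
            continue
        profile = log_df[[row_of[p] for p in matched]].mean(axis=0)
        if np.ptp(profile) == 0 or np.ptp(viab) == 0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(profile, viab).statistic)
        rows.append(
            {"motif": motif.name, "family": motif.family, "n_matched": len(matched), "r_log": r}
        )
        profiles[motif.name] = profile
    table = pd.DataFrame(rows, columns=["motif", "family", "n_matched", "r_log"])
    if len(table):
        table = table.iloc[
            np.lexsort((table["motif"].to_numpy(), -np.abs(table["r_log"].to_numpy())))
        ].reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
    else:
        table["rank"] = pd.Series(dtype=int)
    profile_df = pd.DataFrame(profiles, index=df.columns).T
    return MotifCorrelationResult(
        drug=drug,
        table=table,
        unmatched=tuple(unmatched),
        n_uncovered=n_uncovered,
        library_size=len(library),
        profiles=profile_df,
    )
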