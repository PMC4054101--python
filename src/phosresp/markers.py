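"""Correlation-based resistance/sensitivity marker discovery.

Every replicate sample contributes one point: its peptide intensity paired
with its cell line's viability under the drug (replicates are not averaged
before correlating). Two Pearson coefficients are reported per peptide —
on linear relative intensities and on their log2 (the "semi-log" axis,
which is the default ranking scale because intensity-viability
relationships are typically exponential, hence linear in semi-log).

Marker groups are the top-k peptides by semi-log correlation: group 1
(resistance, R > 0) and group 2 (sensitivity, R < 0), with an |R| >= 0.45
qualification threshold applied by default. The group statistic of a sample
is the sum of its normalized (fold-over-mean) intensities over a group;
the ratio statistic sum1/sum2 is the headline classifier. ``fold`` compares
the cell-line mean of a statistic between the most drug-resistant line
(max mean viability) and the most drug-sensitive line (min mean viability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleMeta, ViabilityTable
from .preprocess import NormalizedMatrix

__all__ = [
    "CorrelationRecord",
    "MarkerGroups",
    "MarkerStatistic",
    "correlate_peptides",
    "select_marker_groups",
    "group_statistics",
    "cross_cohort_transfer",
]

R_THRESHOLD_DEFAULT = 0.45


@dataclass(frozen=True)
class MarkerGroups:
    group1: tuple[str, ...]  # resistance: largest R_log
    group2: tuple[str, ...]  # sensitivity: smallest R_log
    k: int
    r_threshold: float | None


@dataclass(frozen=True)
class MarkerStatistic:
    """Per-sample group sums, their ratio, and summary correlations/folds.

    ``per_sample`` columns: sample_id, cell_line, viability, sum1, sum2,
    ratio. ``r_log``/``fold`` map each statistic name to its semi-log
    Pearson R vs viability / resistant-over-sensitive cell-line-mean fold;
    undefined correlations (constant statistic) are NaN and flagged.
    """

    per_sample: pd.DataFrame
    r_log: dict[str, float]
    fold: dict[str, float]
    resistant_line: str
    sensitive_line: str
    flags: tuple[str, ...] = ()


def _viability_per_sample(
    normm: NormalizedMatrix, meta: SampleMeta, viability: ViabilityTable, drug: str
) -> tuple[np.ndarray, np.ndarray]:
    samples = list(normm.data.columns)
    viab = viability.for_drug(drug)
    lines = np.array([meta.cell_line_of(s) for s in samples])
    missing = sorted(set(lines) - set(viab.index))
    if missing:
        raise ValueError(f"no viability for drug {drug!r} in cell lines: {missing}")
    return lines, np.array([viab[line] for line in lines], dtype=float)


def _pearson_rows(values: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Pearson R of each row of ``values`` against ``x`` (NaN for flat rows)."""
    xc = x - x.mean()
    vc = values - values.mean(axis=1, keepdims=True)
    denom = np.sqrt((vc**2).sum(axis=1)) * np.sqrt((xc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc @ xc) / denom
    r[denom == 0] = np.nan
    return r


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson R via the t transform with n-2 df.

    Treats replicate samples as independent observations, which is the
    convention the sample count n implies.
    """
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    return 2 * stats.t.sf(t, n - 2)


def correlate_peptides(
    normm: NormalizedMatrix, meta: SampleMeta, viability: ViabilityTable, drug: str
) -> pd.DataFrame:
    """Per-peptide Pearson R (linear and log2 intensity) vs viability.

    Returns a DataFrame with columns peptide_id, r_linear, r_log, n_points,
    direction, valid; zero-variance peptides are flagged ``valid=False``
    and excluded from downstream ranking.
    """
    if normm.is_log:
        raise ValueError("correlate_peptides expects linear relative intensities")
    _, viab = _viability_per_sample(normm, meta, viability, drug)
    if len(viab) < 3:
        raise ValueError("need at least 3 samples to correlate")
    values = normm.data.to_numpy(dtype=float)
    r_linear = _pearson_rows(values, viab)
    with np.errstate(divide="ignore"):
        log_values = np.log2(values.clip(min=np.finfo(float).tiny))
    r_log = _pearson_rows(log_values, viab)
    valid = np.isfinite(r_log) & np.isfinite(r_linear)
    direction = np.where(r_log > 0, "resistance", "sensitivity")
    return pd.DataFrame(
        {
            "peptide_id": normm.data.index,
            "r_linear": r_linear,
            "r_log": r_log,
            "p_log": _pearson_p(r_log, len(viab)),
            "n_points": len(viab),
            "direction": direction,
            "valid": valid,
        }
    ).reset_index(drop=True)


def select_marker_groups(
    records: pd.DataFrame,
    k: int = 10,
    r_threshold: float | None = R_THRESHOLD_DEFAULT,
) -> MarkerGroups:
    """Top-k resistance and sensitivity peptides by semi-log correlation.

    Ties are broken by |R| (descending) then peptide id; peptides below the
    |R| threshold are excluded even when inside the top k
    (``r_threshold=None`` disables the threshold). Raises if either group
    would be empty.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    recs = records[records["valid"]].copy()
    pos = recs[recs["r_log"] > 0]
    neg = recs[recs["r_log"] < 0]
    if r_threshold is not None:
        pos = pos[pos["r_log"] >= r_threshold]
        neg = neg[neg["r_log"] <= -r_threshold]
    if pos.empty or neg.empty:
        raise ValueError(
            f"fewer than 1 qualifying peptide per group at |R| >= {r_threshold}"
        )
    pos = pos.sort_values(
        by=["r_log", "peptide_id"], ascending=[False, True], kind="mergesort"
    )
    neg = neg.sort_values(
        by=["r_log", "peptide_id"], ascending=[True, True], kind="mergesort"
    )
    return MarkerGroups(
        group1=tuple(pos["peptide_id"].head(k)),
        group2=tuple(neg["peptide_id"].head(k)),
        k=k,
        r_threshold=r_threshold,
    )


def _safe_pearson_log(stat: np.ndarray, viab: np.ndarray) -> float:
    logged = np.log2(stat)
    if np.ptp(logged) == 0 or np.ptp(viab) == 0:
        return float("nan")
    return float(stats.pearsonr(logged, viab).statistic)


def group_statistics(
    normm: NormalizedMatrix,
    meta: SampleMeta,
    viability: ViabilityTable,
    groups: MarkerGroups,
    drug: str,
) -> MarkerStatistic:
    """Per-sample sums of normalized intensities, their ratio, R and fold."""
    if normm.is_log:
        raise ValueError("group_statistics expects linear relative intensities")
    df = normm.data
    missing = sorted((set(groups.group1) | set(groups.group2)) - set(df.index))
    if missing:
        raise ValueError(f"marker peptides absent from matrix: {missing}")
    lines, viab = _viability_per_sample(normm, meta, viability, drug)
    sum1 = df.loc[list(groups.group1)].sum(axis=0).to_numpy()
    sum2 = df.loc[list(groups.group2)].sum(axis=0).to_numpy()
    if np.any(sum2 == 0):
        raise ValueError("group 2 sum is zero for at least one sample; ratio undefined")
    ratio = sum1 / sum2
    per_sample = pd.DataFrame(
        {
            "sample_id": df.columns,
            "cell_line": lines,
            "viability": viab,
            "sum1": sum1,
            "sum2": sum2,
            "ratio": ratio,
        }
    )
    line_means = per_sample.groupby("cell_line").mean(numeric_only=True)
    resistant = str(line_means["viability"].idxmax())
    sensitive = str(line_means["viability"].idxmin())
    flags: list[str] = []
    r_log: dict[str, float] = {}
    fold: dict[str, float] = {}
    for name in ("sum1", "sum2", "ratio"):
        r = _safe_pearson_log(per_sample[name].to_numpy(), viab)
        if np.isnan(r):
            flags.append(f"{name}: R undefined (constant)")
        r_log[name] = r
        fold[name] = float(line_means.at[resistant, name] / line_means.at[sensitive, name])
    return MarkerStatistic(
        per_sample=per_sample,
        r_log=r_log,
        fold=fold,
        resistant_line=resistant,
        sensitive_line=sensitive,
        flags=tuple(flags),
    )


def cross_cohort_transfer(
    marker_peptides,
    normm2: NormalizedMatrix,
    meta2: SampleMeta,
    viability2: ViabilityTable,
    drug: str,
) -> tuple[pd.DataFrame, list[str]]:
    """Recompute marker correlations on a second cohort (no re-selection).

    ``marker_peptides`` is an iterable of peptide ids or a
    :class:`MarkerGroups`. Returns (records for peptides present in the new
    cohort, list of missing peptide ids). Raises if nothing overlaps.
    """
    if isinstance(marker_peptides, MarkerGroups):
        peptides = list(marker_peptides.group1) + list(marker_peptides.group2)
    else:
        peptides = list(marker_peptides)
    present = [p for p in peptides if p in normm2.data.index]
    missing = [p for p in peptides if p not in normm2.data.index]
    if not present:
        raise ValueError("no marker peptides overlap the second cohort's matrix")
    records = correlate_peptides(normm2, meta2, viability2, drug)
    records = records[records["peptide_id"].isin(present)].reset_index(drop=True)
    return records, missing
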