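"""Per-protein decomposition of total variation into analytical and
inter-individual biological CVs from duplicate measurements.

Definitions (all CVs in percent):

- ``CV_total``: sample SD over all present relative abundances of a protein
  divided by their mean, times 100.
- ``CV_analytical``: the unweighted mean over subjects of the per-subject
  duplicate CV (pair SD / pair mean × 100). Subjects with fewer than two
  present replicates are excluded.
- ``CV_biological``: ``sqrt(CV_total² − CV_analytical²)``, clipped at zero
  (with a flag) when the analytical component exceeds the total.

Sample SDs use denominator ``n − 1`` throughout, including two-point
replicate pairs. The mean-duplicate-CV estimator therefore carries the
known ``sqrt(2/pi)`` downward bias of pair-based SDs; this is documented,
surfaced via :func:`duplicate_sd_bias_factor`, and deliberately not
corrected.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd

from plasmacv.datatypes import ReporterMatrix, SampleMap

logger = logging.getLogger(__name__)

__all__ = [
    "filter_by_completeness",
    "cv_analytical",
    "cv_total",
    "cv_biological",
    "variation_table",
    "summarize",
    "duplicate_sd_bias_factor",
]


def duplicate_sd_bias_factor() -> float:
    """Expected ratio E[pair SD] / sigma for normal duplicates: sqrt(2/pi)."""
    return math.sqrt(2.0 / math.pi)


def _sample_values(matrix: ReporterMatrix, sample_map: SampleMap) -> pd.DataFrame:
    cols = [c for c in sample_map.sample_columns if c in matrix.values.columns]
    return matrix.values[cols]


def filter_by_completeness(
    matrix: ReporterMatrix,
    sample_map: SampleMap,
    threshold: float = 0.5,
) -> ReporterMatrix:
    """Retain proteins quantified in at least ``threshold`` of the designed
    measurements (inclusive boundary; 42 of 84 survives at 0.5).

    The denominator is the designed measurement count from the sample map,
    not the per-protein observed maximum. Protein order is preserved.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    n_designed = sample_map.n_designed_measurements
    n_present = _sample_values(matrix, sample_map).notna().sum(axis=1)
    keep = n_present >= threshold * n_designed
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("completeness filter removed %d of %d proteins", n_removed, len(keep))
    return ReporterMatrix(matrix.values.loc[keep].copy(), dict(matrix.flags))


def cv_analytical(matrix: ReporterMatrix, sample_map: SampleMap) -> pd.DataFrame:
    """Mean per-subject duplicate CV for each protein.

    Returns a DataFrame with ``cv_analytical`` (percent; NaN when no subject
    has >= 2 present replicates) and ``n_pairs_used``.
    """
    values = matrix.values
    n_prot = len(values)
    cv_sum = np.zeros(n_prot)
    n_pairs = np.zeros(n_prot, dtype=int)
    for subject in sample_map.subjects:
        cols = [c for c in sample_map.replicate_columns(subject) if c in values.columns]
        if len(cols) < 2:
            continue
        block = values[cols].to_numpy()
        n_present = np.sum(~np.isnan(block), axis=1)
        usable = n_present >= 2
        if not usable.any():
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.nanmean(block[usable], axis=1)
            sd = np.nanstd(block[usable], axis=1, ddof=1)
            cv_pt = np.where(mean > 0, sd / mean * 100.0, np.nan)
        ok = np.isfinite(cv_pt)
        idx = np.nonzero(usable)[0][ok]
        cv_sum[idx] += cv_pt[ok]
        n_pairs[idx] += 1
    out = pd.DataFrame(index=values.index)
    with np.errstate(invalid="ignore"):
        out["cv_analytical"] = np.where(n_pairs > 0, cv_sum / np.maximum(n_pairs, 1), np.nan)
    out["n_pairs_used"] = n_pairs
    n_flagged = int((n_pairs == 0).sum())
    if n_flagged:
        logger.info("%d proteins have no complete replicate pair", n_flagged)
    return out


def cv_total(matrix: ReporterMatrix, sample_map: SampleMap, over: str = "samples") -> pd.DataFrame:
    """Mean, sample SD and CV of relative abundance per protein.

    ``over="samples"`` (default) pools all present measurements (both
    replicates of every subject, up to 84). ``over="subject-means"``
    averages each subject's replicates first and takes statistics over the
    subject means. Proteins with fewer than two contributing values get
    NaNs.
    """
    if over not in ("samples", "subject-means"):
        raise ValueError("over must be 'samples' or 'subject-means'")
    values = _sample_values(matrix, sample_map)
    if over == "subject-means":
        subject_of = sample_map.table.loc[values.columns, "subject_id"]
        values = values.T.groupby(subject_of).mean().T

    arr = values.to_numpy()
    n_present = np.sum(~np.isnan(arr), axis=1)
    mean = np.full(len(arr), np.nan)
    sd = np.full(len(arr), np.nan)
    m1 = n_present >= 1
    m2 = n_present >= 2
    if m1.any():
        mean[m1] = np.nanmean(arr[m1], axis=1)
    if m2.any():
        sd[m2] = np.nanstd(arr[m2], axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(m2 & (mean > 0), sd / mean * 100.0, np.nan)
    return pd.DataFrame(
        {"mean_total": mean, "sd_total": sd, "cv_total": cv, "n_stat": n_present},
        index=values.index,
    )


def cv_biological(cv_total_pct, cv_analytical_pct):
    """Inter-individual biological CV: sqrt(CV_total² − CV_analytical²).

    Accepts scalars or arrays (percent). When the analytical CV exceeds the
    total CV the result is clipped to 0 — the decomposition cannot be
    negative. Negative inputs are rejected; NaNs propagate.
    """
    cvt = np.asarray(cv_total_pct, dtype=float)
    cva = np.asarray(cv_analytical_pct, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(cvt < 0) or np.any(cva < 0):
            raise ValueError("CVs must be non-negative")
        diff = np.square(cvt) - np.square(cva)
        out = np.sqrt(np.clip(diff, 0.0, None))
        out = np.where(np.isnan(cvt) | np.isnan(cva), np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


def variation_table(
    matrix: ReporterMatrix,
    sample_map: SampleMap,
    threshold: float = 0.5,
    total_over: str = "samples",
) -> pd.DataFrame:
    """Completeness filter plus the full per-protein variation record.

    Columns: ``n_present``, ``completeness``, ``mean_total``, ``sd_total``,
    ``cv_total``, ``cv_analytical``, ``n_pairs_used``, ``cv_biological``,
    ``cv_bio_clipped``.
    """
    filtered = filter_by_completeness(matrix, sample_map, threshold)
    n_designed = sample_map.n_designed_measurements
    n_present = _sample_values(filtered, sample_map).notna().sum(axis=1)

    tot = cv_total(filtered, sample_map, over=total_over)
    ana = cv_analytical(filtered, sample_map)

    table = pd.DataFrame(index=filtered.values.index)
    table["n_present"] = n_present
    table["completeness"] = n_present / n_designed
    table["mean_total"] = tot["mean_total"]
    table["sd_total"] = tot["sd_total"]
    table["cv_total"] = tot["cv_total"]
    table["cv_analytical"] = ana["cv_analytical"]
    table["n_pairs_used"] = ana["n_pairs_used"]
    table["cv_biological"] = cv_biological(table["cv_total"], table["cv_analytical"])
    with np.errstate(invalid="ignore"):
        table["cv_bio_clipped"] = (
            table["cv_analytical"].to_numpy() > table["cv_total"].to_numpy()
        ) & table["cv_analytical"].notna().to_numpy()
    return table


def summarize(table: pd.DataFrame, bin_width: float = 5.0) -> dict:
    """Cohort summary: medians of the three CVs plus histogram counts.

    Returns ``{"medians": {...}, "n_proteins": int, "histogram": DataFrame}``
    where the histogram has per-bin and cumulative protein counts for each
    CV measure at ``bin_width`` percentage points.
    """
    if table.empty:
        raise ValueError("variation table is empty")
    measures = ("cv_total", "cv_analytical", "cv_biological")
    medians = {m: float(table[m].median(skipna=True)) for m in measures}

    top = float(np.nanmax(table[list(measures)].to_numpy()))
    n_bins = max(1, math.ceil(top / bin_width + 1e-12))
    edges = np.arange(n_bins + 1) * bin_width
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:]})
    for m in measures:
        vals = table[m].dropna().to_numpy()
        counts, _ = np.histogram(vals, bins=edges)
        hist[f"count_{m}"] = counts
        hist[f"cumulative_{m}"] = counts.cumsum()
    return {"medians": medians, "n_proteins": int(len(table)), "histogram": hist}
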