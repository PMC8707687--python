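"""Reporter-matrix processing chain.

Order of operations: impurity correction → global equal-sum normalization →
control scaling → relative abundance versus the pooled internal control.
The composed chain is invariant to rescaling any input column by a
constant.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from plasmacv.datatypes import POOL, ReporterMatrix, SampleMap
from plasmacv.impurity import ImpurityModel

logger = logging.getLogger(__name__)

__all__ = [
    "correct_impurities",
    "normalize_global_equal_sum",
    "scale_to_control",
    "relative_abundance",
    "process_pipeline",
]


def correct_impurities(
    matrix: ReporterMatrix,
    impurity: ImpurityModel,
    sample_map: SampleMap,
    cond_threshold: float = 1e8,
) -> ReporterMatrix:
    """Invert channel cross-talk per plex by solving the mixing system.

    Negative solutions (possible with noisy data) are clipped to zero and
    the clip count is logged and recorded in ``flags["impurity_clipped"]``.
    Missing cells are treated as zero during the solve and restored
    afterwards.
    """
    values = matrix.values.copy()
    n_clipped = 0
    for plex in sample_map.plexes:
        cols = [c for c in sample_map.plex_columns(plex) if c in values.columns]
        if not cols:
            continue
        sub = impurity.restrict([sample_map.table.loc[c, "channel"] for c in cols])
        try:
            block = values[cols].to_numpy()
            nan_mask = np.isnan(block)
            solved = sub.unmix(np.nan_to_num(block), cond_threshold=cond_threshold)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"plex {plex}: {exc}") from exc
        neg = solved < 0
        n_clipped += int(neg.sum())
        solved[neg] = 0.0
        solved[nan_mask] = np.nan
        values[cols] = solved
    if n_clipped:
        logger.info("impurity correction clipped %d negative values to 0", n_clipped)
    out = ReporterMatrix(values, dict(matrix.flags))
    out.flags["impurity_clipped"] = n_clipped
    return out


def normalize_global_equal_sum(matrix: ReporterMatrix) -> ReporterMatrix:
    """Equalize per-column sums across all channels and plexes.

    Each column is scaled so its sum over present values equals the mean of
    all column sums (the mean target preserves the global scale). Missing
    cells are excluded from the sums.
    """
    sums = matrix.values.sum(axis=0, skipna=True)
    empty = sums.index[matrix.values.notna().sum(axis=0) == 0]
    if len(empty):
        raise ValueError(f"cannot normalize all-missing column(s): {list(empty)}")
    target = sums.mean()
    return ReporterMatrix(matrix.values * (target / sums), dict(matrix.flags))


def scale_to_control(
    matrix: ReporterMatrix,
    sample_map: SampleMap,
    control_channel: str = "126",
    mode: str = "protein",
) -> ReporterMatrix:
    """Align plexes on the pooled control channel.

    ``mode="protein"`` (default) rescales each plex per protein so the
    plex's control value equals the protein's across-plex average control
    value. ``mode="global"`` applies one channel-wise factor per plex
    (ratio of the grand mean control column mean to the plex's control
    column mean). Proteins whose control is missing in a plex keep that
    plex's values unscaled; such (protein, plex) pairs are recorded in
    ``flags["unscaled"]``.
    """
    if mode not in ("protein", "global"):
        raise ValueError("mode must be 'protein' or 'global'")
    plexes = sample_map.plexes
    try:
        control_cols = {p: sample_map.control_column(p, control_channel) for p in plexes}
    except KeyError as exc:
        raise ValueError(f"control channel missing: {exc}") from exc

    values = matrix.values.copy()
    flags = dict(matrix.flags)
    if mode == "global":
        plex_means = {p: values[control_cols[p]].mean(skipna=True) for p in plexes}
        grand = float(np.mean(list(plex_means.values())))
        for p in plexes:
            values[sample_map.plex_columns(p)] *= grand / plex_means[p]
        return ReporterMatrix(values, flags)

    controls = values[[control_cols[p] for p in plexes]]
    controls.columns = plexes
    avg_control = controls.mean(axis=1, skipna=True)
    unscaled: list[tuple[str, str]] = []
    for p in plexes:
        factor = avg_control / controls[p]
        missing = ~np.isfinite(factor)
        if missing.any():
            unscaled.extend((acc, p) for acc in values.index[missing])
            factor = factor.where(~missing, 1.0)
        cols = sample_map.plex_columns(p)
        values[cols] = values[cols].mul(factor, axis=0)
    if unscaled:
        logger.info("control scaling left %d (protein, plex) blocks unscaled", len(unscaled))
    flags["unscaled"] = unscaled
    return ReporterMatrix(values, flags)


def relative_abundance(
    matrix: ReporterMatrix,
    sample_map: SampleMap,
    control_channel: str = "126",
    drop_controls: bool = True,
) -> ReporterMatrix:
    """Divide each measurement by its plex's control value per protein.

    Ratios against a zero or missing control are missing. Pooled control
    columns are dropped from the result unless ``drop_controls=False`` (the
    retained 131/126 pool ratio is a useful QC readout).
    """
    values = matrix.values.copy()
    for plex in sample_map.plexes:
        ctrl = values[sample_map.control_column(plex, control_channel)]
        denom = ctrl.where(ctrl > 0)
        cols = sample_map.plex_columns(plex)
        values[cols] = values[cols].div(denom, axis=0)
    if drop_controls:
        keep = [c for c in values.columns if c not in set(sample_map.control_columns)]
        values = values[keep]
    return ReporterMatrix(values, dict(matrix.flags))


def process_pipeline(
    matrix: ReporterMatrix,
    sample_map: SampleMap,
    impurity: ImpurityModel | None = None,
    control_channel: str = "126",
    scale_mode: str = "protein",
) -> ReporterMatrix:
    """Run correct → normalize → scale → ratio and return relative abundances."""
    matrix.validate_against(sample_map)
    if impurity is not None and not impurity.is_identity:
        matrix = correct_impurities(matrix, impurity, sample_map)
    matrix = normalize_global_equal_sum(matrix)
    matrix = scale_to_control(matrix, sample_map, control_channel, mode=scale_mode)
    return relative_abundance(matrix, sample_map, control_channel)
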