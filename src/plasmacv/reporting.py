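"""Report rendering and comparison against reference biological-variation
values.

A small reference table of inter-individual biological CVs for abundant
plasma proteins (sourced from the EFLM Biological Variation Database) ships
with the package, alongside a worked-example per-protein CV table for the
same proteins. Entries flagged ``comparable = False`` (one value orders of
magnitude below every other entry, suspected unit inconsistency upstream)
are kept in joins but excluded from summary statistics.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from plasmacv import variation as _variation
from plasmacv.power import SampleSizeGrid

__all__ = [
    "load_reference",
    "load_example_cv_table",
    "example_impurity_kit_path",
    "compare_to_reference",
    "render_tables",
]


def _data_path(name: str) -> Path:
    return Path(resources.files("plasmacv").joinpath("data", name))


def load_reference(path: str | Path | None = None) -> pd.DataFrame:
    """Reference biological-CV table, indexed by accession."""
    path = path or _data_path("eflm_reference_cv.tsv")
    df = pd.read_csv(path, sep="\t", index_col="accession")
    for col in ("meta_analysis", "comparable"):
        if col in df.columns and df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin(("true", "1", "yes"))
    if "comparable" not in df.columns:
        df["comparable"] = True
    if df.index.duplicated().any():
        raise ValueError("reference table has duplicated accessions")
    return df


def load_example_cv_table() -> pd.DataFrame:
    """Worked-example per-protein CV estimates for 17 plasma proteins."""
    return pd.read_csv(_data_path("plasma_cv_examples.tsv"), sep="\t", index_col="accession")


def example_impurity_kit_path() -> Path:
    """Path of the bundled kit-style impurity correction-factor table."""
    return _data_path("example_impurity_kit.tsv")


def compare_to_reference(
    variation: pd.DataFrame,
    reference: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Inner-join estimated vs reference biological CVs by accession.

    Returns the per-protein comparison table and a summary dict with
    ``n_overlap``, ``median_abs_difference`` and ``rank_correlation``
    (Spearman, over comparable entries only).
    """
    if reference is None:
        reference = load_reference()
    carry = [c for c in ("cv_total", "cv_analytical", "cv_biological") if c in variation.columns]
    est = variation[carry].rename(columns={"cv_biological": "estimated_cv_biological"})
    joined = est.join(reference, how="inner")
    if joined.empty:
        warnings.warn("no accessions overlap between variation table and reference")
        return joined, {"n_overlap": 0, "median_abs_difference": np.nan, "rank_correlation": np.nan}
    joined["reference_cv_biological"] = joined["eflm_cv_biological"]
    joined["abs_difference"] = (
        joined["estimated_cv_biological"] - joined["reference_cv_biological"]
    ).abs()
    joined["rel_difference"] = joined["abs_difference"] / joined["reference_cv_biological"]
    comp = joined[joined["comparable"]]
    if len(comp) >= 2:
        rho = float(stats.spearmanr(comp["estimated_cv_biological"], comp["reference_cv_biological"]).statistic)
    else:
        rho = np.nan
    summary = {
        "n_overlap": int(len(joined)),
        "median_abs_difference": float(comp["abs_difference"].median()) if len(comp) else np.nan,
        "rank_correlation": rho,
    }
    return joined, summary


def _five_number(series: pd.Series) -> dict:
    v = series.dropna()
    return {
        "min": v.min(),
        "q1": v.quantile(0.25),
        "median": v.median(),
        "q3": v.quantile(0.75),
        "max": v.max(),
    }


def render_tables(
    outdir: str | Path,
    variation: pd.DataFrame | None = None,
    grid: SampleSizeGrid | None = None,
    comparison: pd.DataFrame | None = None,
    bin_width: float = 5.0,
) -> dict[str, Path]:
    """Write deterministic TSV reports; returns a name → path map.

    Outputs (those whose input is provided): the per-protein variation
    table, five-number CV summaries, CV histogram counts, the sample-size
    grid with ``n (lo–hi)`` cells, and the reference comparison with CVs at
    one decimal.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if variation is not None:
        p = outdir / "variation_table.tsv"
        variation.to_csv(p, sep="\t", float_format="%.6g")
        written["variation_table"] = p

        summary = _variation.summarize(variation, bin_width=bin_width)
        fn = pd.DataFrame(
            {m: _five_number(variation[m]) for m in ("cv_total", "cv_analytical", "cv_biological")}
        ).T
        fn.index.name = "measure"
        p = outdir / "cv_five_number_summary.tsv"
        fn.to_csv(p, sep="\t", float_format="%.1f")
        written["cv_five_number_summary"] = p

        p = outdir / "cv_histogram.tsv"
        summary["histogram"].to_csv(p, sep="\t", index=False)
        written["cv_histogram"] = p

    if grid is not None:
        p = outdir / "sample_size_grid.tsv"
        grid.to_tsv(p)
        written["sample_size_grid"] = p

    if comparison is not None:
        p = outdir / "reference_comparison.tsv"
        cols = [
            c
            for c in (
                "description",
                "cv_total",
                "cv_analytical",
                "estimated_cv_biological",
                "reference_cv_biological",
                "abs_difference",
                "meta_analysis",
                "comparable",
            )
            if c in comparison.columns
        ]
        out = comparison[cols].copy()
        for c in ("cv_total", "cv_analytical", "estimated_cv_biological",
                  "reference_cv_biological", "abs_difference"):
            if c in out.columns:
                out[c] = out[c].map(lambda x: f"{x:.1f}" if pd.notna(x) else "")
        out.to_csv(p, sep="\t")
        written["reference_comparison"] = p

    return written
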