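"""Sample-size grids over effect sizes and variance percentiles.

The per-group sample size for a two-group comparison is

    n = ceil( 2 (z_{alpha/2} + z_{1-beta})^2 sigma^2 / delta^2 )

with sigma the per-protein SD of relative abundance and delta the absolute
between-group difference. Fold changes are mapped to delta via
``delta = (fold - 1) * mean_ref``; in the default CV formulation relative
abundances are centred at 1, so sigma is CV/100 and mean_ref is 1, making
n a function of CV alone. With the default alpha = 0.05 and power = 0.80
the multiplier 2 (z_a + z_b)^2 is about 15.698.

Percentile columns use linear-interpolation empirical percentiles of the
per-protein variation; the distinguished "max" column uses the sample
maximum. Confidence intervals come from a seeded percentile bootstrap over
proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PowerParams", "SampleSizeGrid", "sample_size", "effect_to_delta",
           "sample_size_grid", "sample_size_ci", "empirical_power"]

MAX_LABEL = "max"


@dataclass(frozen=True)
class PowerParams:
    """Knobs of the sample-size computation."""

    alpha: float = 0.05
    power: float = 0.80
    effect_sizes: tuple[float, ...] = (1.1, 1.2, 1.5, 2.0)
    percentiles: tuple[float, ...] = (70.0, 75.0, 80.0, 85.0)
    include_max: bool = True
    basis: str = "cv"  # "cv": percentiles over CV_total, mean_ref = 1
    bootstrap_reps: int = 1000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if any(f <= 1 for f in self.effect_sizes):
            raise ValueError("fold changes must be > 1")
        if any(not 0 < q <= 100 for q in self.percentiles):
            raise ValueError("percentiles must lie in (0, 100]")
        if self.basis not in ("cv", "sd"):
            raise ValueError("basis must be 'cv' or 'sd'")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")

    @property
    def z_alpha(self) -> float:
        """Two-sided alpha quantile (1.96 at alpha = 0.05)."""
        return float(stats.norm.ppf(1 - self.alpha / 2))

    @property
    def z_beta(self) -> float:
        """Power quantile (0.8416 at 80%)."""
        return float(stats.norm.ppf(self.power))

    @property
    def z_multiplier(self) -> float:
        return 2.0 * (self.z_alpha + self.z_beta) ** 2

    @property
    def column_labels(self) -> list[str]:
        labels = [f"{q:g}" for q in self.percentiles]
        if self.include_max:
            labels.append(MAX_LABEL)
        return labels


@dataclass
class SampleSizeGrid:
    """Required per-group n across (effect size × variance percentile).

    ``n`` holds the ceiled sample sizes (rows = fold changes, columns =
    percentile labels plus ``max``); ``ci_low``/``ci_high`` are the
    bootstrap interval bounds (None without a CI run); ``raw`` keeps the
    pre-ceiling values for scaling diagnostics.
    """

    n: pd.DataFrame
    raw: pd.DataFrame
    ci_low: pd.DataFrame | None = None
    ci_high: pd.DataFrame | None = None
    params: PowerParams | None = None

    def render(self) -> pd.DataFrame:
        """Cells formatted ``n (lo–hi)`` when intervals are available."""
        if self.ci_low is None:
            return self.n.astype(int)
        out = self.n.copy().astype(object)
        for r in out.index:
            for c in out.columns:
                out.loc[r, c] = (
                    f"{int(self.n.loc[r, c])} "
                    f"({int(self.ci_low.loc[r, c])}–{int(self.ci_high.loc[r, c])})"
                )
        return out

    def to_tsv(self, path) -> None:
        rendered = self.render()
        rendered.index.name = "effect_size"
        rendered.to_csv(path, sep="\t")


def sample_size(sigma: float, delta: float, params: PowerParams | None = None, *, ceil: bool = True):
    """Per-group n for detecting an absolute difference ``delta`` at SD ``sigma``."""
    params = params or PowerParams()
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    raw = params.z_multiplier * (sigma / delta) ** 2
    return math.ceil(raw) if ceil else raw


def effect_to_delta(fold: float, mean_ref: float = 1.0) -> float:
    """Absolute effect on the relative-abundance scale for a fold change."""
    if fold <= 1:
        raise ValueError("fold change must be > 1")
    if mean_ref <= 0:
        raise ValueError("mean_ref must be > 0")
    return (fold - 1.0) * mean_ref


def _sigma_values(variation: pd.DataFrame, params: PowerParams) -> np.ndarray:
    """Per-protein sigma on the scale used by the grid."""
    if params.basis == "cv":
        vals = variation["cv_total"].dropna().to_numpy() / 100.0
    else:
        vals = variation["sd_total"].dropna().to_numpy()
    if len(vals) < 2:
        raise ValueError("need at least 2 proteins with defined variation")
    return vals


def _grid_from_sigmas(sigmas: np.ndarray, params: PowerParams) -> np.ndarray:
    """Pre-ceiling n per (fold, percentile-column); vectorized over bootstrap."""
    sig_cols = [np.percentile(sigmas, q, axis=-1) for q in params.percentiles]
    if params.include_max:
        sig_cols.append(np.max(sigmas, axis=-1))
    sig = np.stack(sig_cols, axis=-1)  # (..., n_cols)
    deltas = np.array([effect_to_delta(f) for f in params.effect_sizes])
    return params.z_multiplier * (sig[..., None, :] / deltas[:, None]) ** 2


def sample_size_grid(variation: pd.DataFrame, params: PowerParams | None = None) -> SampleSizeGrid:
    """Point-estimate grid from a variation table (no intervals)."""
    params = params or PowerParams()
    sigmas = _sigma_values(variation, params)
    raw = _grid_from_sigmas(sigmas, params)
    labels = params.column_labels
    index = pd.Index(params.effect_sizes, name="effect_size")
    raw_df = pd.DataFrame(raw, index=index, columns=labels)
    n_df = pd.DataFrame(np.ceil(raw).astype(int), index=index, columns=labels)
    return SampleSizeGrid(n=n_df, raw=raw_df, params=params)


def sample_size_ci(variation: pd.DataFrame, params: PowerParams | None = None) -> SampleSizeGrid:
    """Grid with percentile-bootstrap confidence intervals over proteins."""
    params = params or PowerParams()
    if params.bootstrap_reps < 100:
        raise ValueError("bootstrap_reps must be >= 100")
    grid = sample_size_grid(variation, params)
    sigmas = _sigma_values(variation, params)
    rng = np.random.default_rng(params.seed)
    resampled = rng.choice(sigmas, size=(params.bootstrap_reps, len(sigmas)), replace=True)
    boot_raw = _grid_from_sigmas(resampled, params)  # (reps, folds, cols)
    tail = (1.0 - params.ci_level) / 2.0
    lo = np.ceil(np.quantile(boot_raw, tail, axis=0)).astype(int)
    hi = np.ceil(np.quantile(boot_raw, 1.0 - tail, axis=0)).astype(int)
    # Clamp so the point estimate always lies inside its interval.
    n = grid.n.to_numpy()
    lo = np.minimum(lo, n)
    hi = np.maximum(hi, n)
    grid.ci_low = pd.DataFrame(lo, index=grid.n.index, columns=grid.n.columns)
    grid.ci_high = pd.DataFrame(hi, index=grid.n.index, columns=grid.n.columns)
    return grid


def empirical_power(
    n: int,
    sigma: float,
    delta: float,
    alpha: float = 0.05,
    reps: int = 10_000,
    seed: int = 0,
    test: str = "z",
) -> float:
    """Monte-Carlo two-sample power check at the returned sample size.

    Simulates ``reps`` two-sample normal experiments (group means 0 and
    ``delta``, common SD ``sigma``, ``n`` per group) and returns the
    rejection fraction at two-sided ``alpha``. ``test="z"`` (default) uses
    the known-variance normal test — the sampling model behind the
    normal-quantile sample-size formula; ``test="t"`` uses Welch's t-test,
    which at very small n is conservative relative to the formula.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sigma, size=(reps, n))
    b = rng.normal(delta, sigma, size=(reps, n))
    if test == "z":
        z = (b.mean(axis=1) - a.mean(axis=1)) / (sigma * math.sqrt(2.0 / n))
        p = 2.0 * stats.norm.sf(np.abs(z))
    elif test == "t":
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    else:
        raise ValueError("test must be 'z' or 't'")
    return float(np.mean(p < alpha))
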