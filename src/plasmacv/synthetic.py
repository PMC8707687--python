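"""Synthetic duplicate-design multiplexed reporter data with known truth.

The generative model is multiplicative throughout: per protein ``p`` and
subject ``i`` the latent abundance is ``A_pi = mu_p * L_pi`` with ``L_pi``
log-normal with unit mean and the requested biological CV; each measurement
multiplies an independent unit-mean log-normal analytical error. Pooled
control channels carry the arithmetic mean of all subject-measurement true
abundances, with their own analytical error per channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from plasmacv.datatypes import CHANNELS_10PLEX, POOL, ReporterMatrix, SampleMap, column_key
from plasmacv.impurity import ImpurityModel

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_dataset", "apply_impurity_mixing"]

_LAYOUTS = ("random", "same_plex", "cross_plex")


def _as_cv_array(spec, n: int, rng: np.random.Generator, name: str) -> np.ndarray:
    """Resolve a CV specification (scalar %, sequence, or rng-callable)."""
    if callable(spec):
        out = np.asarray(spec(rng, n), dtype=float)
    elif np.isscalar(spec):
        out = np.full(n, float(spec))
    else:
        out = np.asarray(spec, dtype=float)
    if out.shape != (n,):
        raise ValueError(f"{name} must resolve to {n} values, got shape {out.shape}")
    if (out < 0).any():
        raise ValueError(f"{name} values must be >= 0 (percent)")
    return out


def _lognormal_unit_mean(rng: np.random.Generator, cv_fraction: np.ndarray, size) -> np.ndarray:
    """Unit-mean log-normal draws with per-row CV given as a fraction.

    sigma_log = sqrt(ln(1 + cv^2)); the mean-correcting location is
    -sigma_log^2 / 2 so the requested CV is the distribution's true CV.
    """
    sigma2 = np.log1p(np.square(cv_fraction))
    sigma = np.sqrt(sigma2)
    z = rng.standard_normal(size)
    return np.exp(z * sigma - sigma2 / 2.0)


@dataclass
class SimulationConfig:
    """Parameters of the duplicate-design generator.

    CV parameters are in percent and may be a scalar (shared by all
    proteins), a length-``n_proteins`` sequence, or a callable
    ``f(rng, n) -> array``.
    """

    n_proteins: int
    n_subjects: int = 42
    n_replicates: int = 2
    channels_per_plex: int = 10
    control_channels: tuple[str, ...] = ("126", "131")
    cv_biological: object = 20.0
    cv_analytical: object = 5.0
    missing_rate: float = 0.0
    mean_log10_range: tuple[float, float] = (1.0, 4.0)
    duplicate_layout: str = "random"
    plex_factors: Optional[Sequence[float]] = None
    impurity: Optional[ImpurityModel] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("at least 1 protein is required")
        if self.n_replicates < 2:
            raise ValueError("duplicate analysis requires n_replicates >= 2")
        if self.channels_per_plex != 10:
            raise ValueError("the default layout requires exactly 10 channels per plex")
        if not set(self.control_channels) <= set(CHANNELS_10PLEX):
            raise ValueError(f"control channels must be among {CHANNELS_10PLEX}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.duplicate_layout not in _LAYOUTS:
            raise ValueError(f"duplicate_layout must be one of {_LAYOUTS}")

    @property
    def sample_channels(self) -> tuple[str, ...]:
        return tuple(c for c in CHANNELS_10PLEX if c not in self.control_channels)

    @property
    def n_measurements(self) -> int:
        return self.n_subjects * self.n_replicates

    @property
    def n_plexes(self) -> int:
        return math.ceil(self.n_measurements / len(self.sample_channels))

    def to_text(self) -> str:
        """Key-value rendering of the configuration (all fields)."""
        lines = []
        for key in (
            "n_proteins", "n_subjects", "n_replicates", "channels_per_plex",
            "control_channels", "cv_biological", "cv_analytical", "missing_rate",
            "mean_log10_range", "duplicate_layout", "plex_factors", "seed",
        ):
            val = getattr(self, key)
            if isinstance(val, (tuple, list)):
                val = ",".join(str(v) for v in val)
            lines.append(f"{key}\t{val}")
        return "\n".join(lines) + "\n"


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset.

    ``table`` has one row per protein (true mean, true CVs in percent,
    missing rate); ``subject_abundance`` holds the latent per-subject true
    abundances ``A_pi`` used to generate every measurement.
    """

    table: pd.DataFrame
    subject_abundance: pd.DataFrame = field(repr=False, default=None)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimulationTruth":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def _assign_layout(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign (subject, replicate) measurements to (plex, channel) slots."""
    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    plexes = [f"P{i + 1:02d}" for i in range(config.n_plexes)]
    sample_channels = config.sample_channels
    slots = [(p, c) for p in plexes for c in sample_channels][: config.n_measurements]

    measurements = [(s, r + 1) for s in subjects for r in range(config.n_replicates)]
    layout = config.duplicate_layout
    if layout == "same_plex":
        order = [m for s in rng.permutation(subjects)
                 for m in ((s, r + 1) for r in range(config.n_replicates))]
    else:
        order = [measurements[i] for i in rng.permutation(len(measurements))]
        if layout == "cross_plex":
            order = _repair_cross_plex(order, slots, rng)

    rows = [
        {"plex": p, "channel": c, "subject_id": s, "replicate": r}
        for (p, c), (s, r) in zip(slots, order)
    ]
    for plex in plexes:
        for ctrl in config.control_channels:
            rows.append({"plex": plex, "channel": ctrl, "subject_id": POOL, "replicate": 0})
    table = pd.DataFrame(rows)
    order_key = {c: i for i, c in enumerate(CHANNELS_10PLEX)}
    table = table.sort_values(
        ["plex", "channel"], key=lambda s: s.map(order_key) if s.name == "channel" else s
    ).reset_index(drop=True)
    return table


def _repair_cross_plex(order, slots, rng, max_rounds: int = 100):
    """Swap measurements until no subject has two replicates in one plex."""
    order = list(order)
    plex_of = [p for p, _ in slots]
    for _ in range(max_rounds):
        seen: dict[tuple[str, str], int] = {}
        conflict = None
        for i, (s, _) in enumerate(order):
            key = (s, plex_of[i])
            if key in seen:
                conflict = i
                break
            seen[key] = i
        if conflict is None:
            return order
        candidates = [
            j for j in range(len(order))
            if plex_of[j] != plex_of[conflict] and order[j][0] != order[conflict][0]
        ]
        j = int(rng.choice(candidates))
        order[conflict], order[j] = order[j], order[conflict]
    raise RuntimeError("failed to find a cross-plex layout")  # pragma: no cover


def simulate_dataset(config: SimulationConfig) -> tuple[ReporterMatrix, SampleMap, SimulationTruth]:
    """Generate a reporter matrix, sample map and ground truth.

    Reproducible given ``config.seed``; see the module docstring for the
    generative model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_prot = config.n_proteins

    cv_bio = _as_cv_array(config.cv_biological, n_prot, rng, "cv_biological")
    cv_ana = _as_cv_array(config.cv_analytical, n_prot, rng, "cv_analytical")

    lo, hi = config.mean_log10_range
    mu = 10.0 ** rng.uniform(lo, hi, size=n_prot)

    accessions = [f"SIM{i + 1:05d}" for i in range(n_prot)]
    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]

    # Latent subject abundances A_pi = mu_p * L_pi.
    L = _lognormal_unit_mean(rng, (cv_bio / 100.0)[:, None], (n_prot, config.n_subjects))
    A = mu[:, None] * L

    map_table = _assign_layout(config, rng)
    sample_map = SampleMap(map_table)

    # Pool value: arithmetic mean of all subject-measurement true abundances.
    # Each subject contributes n_replicates identical true values, so this
    # equals the across-subject mean of A.
    pool_true = A.mean(axis=1)

    subj_index = {s: i for i, s in enumerate(subjects)}
    cv_ana_frac = (cv_ana / 100.0)[:, None]
    columns: dict[str, np.ndarray] = {}
    for key, row in sample_map.table.iterrows():
        true = pool_true if row["subject_id"] == POOL else A[:, subj_index[row["subject_id"]]]
        noise = _lognormal_unit_mean(rng, cv_ana_frac, (n_prot, 1))[:, 0]
        columns[key] = true * noise

    values = pd.DataFrame(columns, index=pd.Index(accessions, name="accession"))

    if config.plex_factors is not None:
        plexes = sample_map.plexes
        if len(config.plex_factors) != len(plexes):
            raise ValueError(f"plex_factors must have {len(plexes)} entries")
        for plex, factor in zip(plexes, config.plex_factors):
            values[sample_map.plex_columns(plex)] *= float(factor)

    matrix = ReporterMatrix(values)
    if config.impurity is not None:
        matrix = apply_impurity_mixing(matrix, config.impurity, sample_map)

    if config.missing_rate > 0:
        mask = rng.random(matrix.values.shape) < config.missing_rate
        masked = matrix.values.to_numpy(copy=True)
        masked[mask] = np.nan
        matrix = ReporterMatrix(
            pd.DataFrame(masked, index=matrix.values.index, columns=matrix.values.columns)
        )

    truth = SimulationTruth(
        table=pd.DataFrame(
            {
                "true_mean": mu,
                "true_cv_bio": cv_bio,
                "true_cv_analytical": cv_ana,
                "missing_rate": config.missing_rate,
            },
            index=pd.Index(accessions, name="accession"),
        ),
        subject_abundance=pd.DataFrame(
            A, index=pd.Index(accessions, name="accession"), columns=subjects
        ),
    )
    return matrix, sample_map, truth


def apply_impurity_mixing(
    matrix: ReporterMatrix,
    impurity: ImpurityModel,
    sample_map: SampleMap,
) -> ReporterMatrix:
    """Forward-mix each plex's channels with the impurity model.

    The inverse operation is
    :func:`plasmacv.processing.correct_impurities`. Missing cells are
    treated as zero signal during mixing and restored afterwards.
    """
    values = matrix.values.copy()
    for plex in sample_map.plexes:
        cols = [c for c in sample_map.plex_columns(plex) if c in values.columns]
        if not cols:
            continue
        sub = impurity.restrict([sample_map.table.loc[c, "channel"] for c in cols])
        block = values[cols].to_numpy()
        nan_mask = np.isnan(block)
        mixed = sub.mix(np.nan_to_num(block))
        mixed[nan_mask] = np.nan
        values[cols] = mixed
    return ReporterMatrix(values, dict(matrix.flags))
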