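"""Reporter-channel isotope-impurity model.

The observed reporter vector per plex is modelled as a linear mixture of the
true channel intensities: ``observed = M @ true`` where column ``j`` of the
mixing matrix ``M`` gives the destinations of channel ``j``'s signal. Leakage
targeted outside the plex's channel range is lost, so column sums are at
most 1. Correction inverts the mixture per plex.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from plasmacv.datatypes import CHANNELS_10PLEX

_TOL = 1e-9


@dataclass(frozen=True)
class ImpurityModel:
    """Column-stochastic channel cross-talk specification.

    Attributes
    ----------
    channels
        Channel labels, in the order of the matrix axes.
    matrix
        Square mixing matrix; ``matrix[i, j]`` is the fraction of channel
        ``j``'s signal observed in channel ``i``.
    """

    channels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.channels), len(self.channels)):
            raise ValueError("mixing matrix shape does not match channel count")
        if (m < -_TOL).any():
            raise ValueError("impurity fractions must be non-negative")
        colsums = m.sum(axis=0)
        if (colsums > 1 + 1e-6).any():
            bad = [self.channels[j] for j in np.nonzero(colsums > 1 + 1e-6)[0]]
            raise ValueError(f"impurity fractions exceed 100% for channels: {bad}")
        object.__setattr__(self, "matrix", m)

    # -- constructors ------------------------------------------------------

    @classmethod
    def identity(cls, channels: tuple[str, ...] = CHANNELS_10PLEX) -> "ImpurityModel":
        return cls(tuple(channels), np.eye(len(channels)))

    @classmethod
    def symmetric_leak(cls, channels: tuple[str, ...], leak: float) -> "ImpurityModel":
        """Each channel leaks ``leak`` fraction to each adjacent channel."""
        n = len(channels)
        m = np.zeros((n, n))
        for j in range(n):
            neighbours = [i for i in (j - 1, j + 1) if 0 <= i < n]
            for i in neighbours:
                m[i, j] = leak
            m[j, j] = 1.0 - leak * 2  # out-of-range leakage is lost
        return cls(tuple(channels), m)

    @classmethod
    def from_kit_table(cls, table: pd.DataFrame, channels: tuple[str, ...] = CHANNELS_10PLEX) -> "ImpurityModel":
        """Build the model from a kit-style correction-factor table.

        ``table`` needs columns ``channel``, ``minus2``, ``minus1``,
        ``plus1``, ``plus2`` with leakage given in percent of the channel's
        signal; offsets are positions in ``channels`` order. The retained
        fraction is 100 minus the total leakage, including leakage lost
        outside the plex range.
        """
        t = table.set_index(table["channel"].astype(str))
        n = len(channels)
        m = np.zeros((n, n))
        offsets = {"minus2": -2, "minus1": -1, "plus1": 1, "plus2": 2}
        for j, ch in enumerate(channels):
            if ch not in t.index:
                raise ValueError(f"kit table missing channel {ch!r}")
            row = t.loc[ch]
            total_leak = 0.0
            for col, off in offsets.items():
                frac = float(row.get(col, 0.0) or 0.0) / 100.0
                if frac < 0:
                    raise ValueError(f"negative impurity fraction for channel {ch!r}")
                total_leak += frac
                i = j + off
                if 0 <= i < n:
                    m[i, j] = frac
            if total_leak > 1:
                raise ValueError(f"impurity fractions exceed 100% for channel {ch!r}")
            m[j, j] = 1.0 - total_leak
        return cls(tuple(channels), m)

    @classmethod
    def from_kit_tsv(cls, path: str | Path, channels: tuple[str, ...] = CHANNELS_10PLEX) -> "ImpurityModel":
        return cls.from_kit_table(pd.read_csv(path, sep="\t", dtype={"channel": str}), channels)

    # -- operations --------------------------------------------------------

    def restrict(self, channels: list[str]) -> "ImpurityModel":
        """Sub-model over the channels actually present in a plex.

        Cross-talk to or from absent channels is dropped (absent channels
        carry no signal in the forward model, and leakage into them is
        unobserved).
        """
        idx = [self.channels.index(c) for c in channels]
        return ImpurityModel(tuple(channels), self.matrix[np.ix_(idx, idx)])

    @property
    def is_identity(self) -> bool:
        return bool(np.allclose(self.matrix, np.eye(len(self.channels))))

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def mix(self, true_values: np.ndarray) -> np.ndarray:
        """Forward mixing; ``true_values`` has channels on the last axis."""
        return np.asarray(true_values) @ self.matrix.T

    def unmix(self, observed: np.ndarray, cond_threshold: float = 1e8) -> np.ndarray:
        """Solve the mixing system for the true intensities.

        Raises ``np.linalg.LinAlgError`` if the matrix condition number
        exceeds ``cond_threshold``.
        """
        cond = self.condition_number()
        if not np.isfinite(cond) or cond > cond_threshold:
            raise np.linalg.LinAlgError(
                f"impurity matrix ill-conditioned (cond={cond:.3g} > {cond_threshold:.3g})"
            )
        obs = np.asarray(observed, dtype=float)
        return np.linalg.solve(self.matrix, obs.T).T
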