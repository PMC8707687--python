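"""Core data containers: the reporter abundance matrix and the sample map.

Both are thin wrappers around :class:`pandas.DataFrame` with validation and
TSV round-trip support. Matrix columns are keyed ``<plex>_<channel>``
(e.g. ``P01_126``); missing cells are ``NaN`` in memory and empty fields on
disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical 10-plex reporter channel labels, in nominal mass order.
CHANNELS_10PLEX: tuple[str, ...] = (
    "126",
    "127N",
    "127C",
    "128N",
    "128C",
    "129N",
    "129C",
    "130N",
    "130C",
    "131",
)

#: Marker used in the sample map for pooled internal-control channels.
POOL = "POOL"


def column_key(plex: str, channel: str) -> str:
    """Build the matrix column key for a (plex, channel) pair."""
    return f"{plex}_{channel}"


def split_column_key(key: str) -> tuple[str, str]:
    """Invert :func:`column_key`; channel labels never contain ``_``."""
    plex, _, channel = key.rpartition("_")
    if not plex or not channel:
        raise ValueError(f"malformed column key {key!r}; expected '<plex>_<channel>'")
    return plex, channel


@dataclass
class SampleMap:
    """Per-column annotation linking matrix columns to the study design.

    Parameters
    ----------
    table
        DataFrame with columns ``plex``, ``channel``, ``subject_id``,
        ``replicate``. Pooled control columns use ``subject_id == "POOL"``
        and ``replicate == 0``. The index is the matrix column key.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"plex", "channel", "subject_id", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample map missing columns: {sorted(missing)}")
        t = self.table
        if t.index.name != "column":
            t = t.copy()
            t.index = pd.Index(
                [column_key(p, c) for p, c in zip(t["plex"], t["channel"])],
                name="column",
            )
            self.table = t
        dup = t.groupby(["plex", "channel"]).size()
        if (dup > 1).any():
            bad = dup[dup > 1].index.tolist()
            raise ValueError(f"duplicate (plex, channel) assignments: {bad}")
        samples = t[t["subject_id"] != POOL]
        pair_counts = samples.groupby(["subject_id", "replicate"]).size()
        if (pair_counts > 1).any():
            bad = pair_counts[pair_counts > 1].index.tolist()
            raise ValueError(f"(subject, replicate) mapped to multiple columns: {bad}")

    # -- selection helpers -------------------------------------------------

    @property
    def plexes(self) -> list[str]:
        return list(dict.fromkeys(self.table["plex"]))

    @property
    def sample_columns(self) -> list[str]:
        """Column keys carrying subject measurements (non-pool)."""
        return list(self.table.index[self.table["subject_id"] != POOL])

    @property
    def control_columns(self) -> list[str]:
        return list(self.table.index[self.table["subject_id"] == POOL])

    @property
    def n_designed_measurements(self) -> int:
        """Number of designed subject measurements (84 in the default layout)."""
        return len(self.sample_columns)

    @property
    def subjects(self) -> list[str]:
        s = self.table.loc[self.table["subject_id"] != POOL, "subject_id"]
        return list(dict.fromkeys(s))

    def plex_columns(self, plex: str) -> list[str]:
        return list(self.table.index[self.table["plex"] == plex])

    def plex_channels(self, plex: str) -> list[str]:
        return list(self.table.loc[self.table["plex"] == plex, "channel"])

    def control_column(self, plex: str, channel: str) -> str:
        """Column key of ``channel`` within ``plex``; KeyError if absent."""
        sel = self.table[(self.table["plex"] == plex) & (self.table["channel"] == channel)]
        if sel.empty:
            raise KeyError(f"plex {plex!r} has no channel {channel!r}")
        return sel.index[0]

    def replicate_columns(self, subject_id: str) -> list[str]:
        sel = self.table[self.table["subject_id"] == subject_id].sort_values("replicate")
        return list(sel.index)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.reset_index(drop=True)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleMap":
        t = pd.read_csv(path, sep="\t", dtype={"plex": str, "channel": str, "subject_id": str})
        t["replicate"] = t["replicate"].astype(int)
        return cls(t)


@dataclass
class ReporterMatrix:
    """Protein × measurement abundance grid.

    ``values`` is indexed by protein accession; columns are matrix column
    keys. Values are non-negative floats, ``NaN`` marking missing cells.
    """

    values: pd.DataFrame
    flags: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.values.index.name is None:
            self.values.index.name = "accession"
        present = self.values.to_numpy()
        with np.errstate(invalid="ignore"):
            if np.any(present[~np.isnan(present)] < 0):
                raise ValueError("reporter abundances must be non-negative")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def validate_against(self, sample_map: SampleMap) -> None:
        """Check every matrix column resolves in the sample map."""
        unknown = set(self.columns) - set(sample_map.table.index)
        if unknown:
            raise ValueError(f"matrix columns absent from sample map: {sorted(unknown)}")

    def copy(self) -> "ReporterMatrix":
        return ReporterMatrix(self.values.copy(), dict(self.flags))

    def subset(self, proteins: Iterable[str] | None = None, columns: Sequence[str] | None = None) -> "ReporterMatrix":
        v = self.values
        if proteins is not None:
            v = v.loc[list(proteins)]
        if columns is not None:
            v = v[list(columns)]
        return ReporterMatrix(v.copy(), dict(self.flags))

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReporterMatrix":
        v = pd.read_csv(path, sep="\t", index_col=0)
        v.index = v.index.astype(str)
        v.index.name = "accession"
        return cls(v.astype(float))
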