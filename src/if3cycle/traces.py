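"""Stopped-flow time-course container and CSV interchange.

A :class:`Trace` is one fluorescence time course as recorded by a
stopped-flow photomultiplier: a time axis in seconds and a fluorescence
signal in instrument volts, plus the metadata needed to group traces into
replicates and titration series (titrant name, titrant concentration in
micromolar, replicate index).

The on-disk format is long-format CSV with the header
``time_s,fluorescence_V,replicate,titrant,conc_uM``; a single file may hold
one trace or a whole titration series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CSV_COLUMNS = ["time_s", "fluorescence_V", "replicate", "titrant", "conc_uM"]


@dataclass
class Trace:
    """One stopped-flow fluorescence time course.

    Parameters
    ----------
    time : ndarray
        Sample times in seconds, non-decreasing, starting at mixing (t=0).
    fluorescence : ndarray
        Donor fluorescence in instrument volts, same length as ``time``.
    titrant : str, optional
        Name of the titrated ligand (e.g. ``"30S"``, ``"IF2"``).
    conc_uM : float, optional
        Titrant concentration in micromolar.
    replicate : int, optional
        Replicate index within a reaction.
    n_averaged : int
        Number of raw replicates averaged into this trace (1 = raw).
    """

    time: np.ndarray
    fluorescence: np.ndarray
    titrant: str | None = None
    conc_uM: float | None = None
    replicate: int | None = None
    n_averaged: int = 1

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.ndim != 1 or self.fluorescence.ndim != 1:
            raise ValueError("time and fluorescence must be 1-D arrays")
        if self.time.shape != self.fluorescence.shape:
            raise ValueError(
                f"time ({self.time.size}) and fluorescence "
                f"({self.fluorescence.size}) length mismatch"
            )
        if not np.all(np.isfinite(self.time)):
            raise ValueError("non-finite time values")

    def __len__(self) -> int:
        return self.time.size

    def with_fluorescence(self, f: np.ndarray, **meta) -> "Trace":
        """Copy of this trace with a new signal (and optional new metadata)."""
        return replace(self, fluorescence=np.asarray(f, dtype=float), **meta)

    def baseline_removed(self) -> "Trace":
        """Subtract the long-time plateau (median of the final 2% of points)."""
        tail = max(2, int(0.02 * len(self)))
        return self.with_fluorescence(self.fluorescence - np.median(self.fluorescence[-tail:]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "fluorescence_V": self.fluorescence,
                "replicate": self.replicate if self.replicate is not None else 0,
                "titrant": self.titrant if self.titrant is not None else "",
                "conc_uM": self.conc_uM if self.conc_uM is not None else np.nan,
            }
        )


def write_traces_csv(traces: list[Trace] | Trace, path) -> None:
    """Write one or many traces to a long-format CSV file."""
    if isinstance(traces, Trace):
        traces = [traces]
    pd.concat([t.to_frame() for t in traces], ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path) -> list[Trace]:
    """Read a long-format trace CSV back into a list of traces.

    Traces are split on the (titrant, conc_uM, replicate) triple and
    returned sorted by concentration then replicate.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV missing columns: {missing}")
    df["titrant"] = df["titrant"].fillna("")
    out: list[Trace] = []
    for (titrant, conc, rep), grp in df.groupby(["titrant", "conc_uM", "replicate"], dropna=False, sort=True):
        out.append(
            Trace(
                time=grp["time_s"].to_numpy(),
                fluorescence=grp["fluorescence_V"].to_numpy(),
                titrant=titrant or None,
                conc_uM=None if pd.isna(conc) else float(conc),
                replicate=int(rep),
            )
        )
    return out


def group_by_concentration(traces: list[Trace]) -> dict[float, list[Trace]]:
    """Group traces into a {concentration: [replicates]} mapping."""
    groups: dict[float, list[Trace]] = {}
    for t in traces:
        if t.conc_uM is None:
            raise ValueError("trace without conc_uM cannot be grouped")
        groups.setdefault(float(t.conc_uM), []).append(t)
    return dict(sorted(groups.items()))
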