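"""Time-trace container and its on-disk TSV format.

A trace is one bead trajectory sampled at the camera rate, with the applied
force and magnet-turn protocol channels alongside.  On disk a trace is a
tab-separated file with ``#``-prefixed ``key = value`` metadata header lines
followed by the columns ``time_s, extension_nm, force_pN, turns``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

COLUMNS = ("time_s", "extension_nm", "force_pN", "turns")


class TraceFormatError(ValueError):
    """Raised when a trace file violates the TSV schema."""


@dataclass
class TimeTrace:
    """A sampled bead trajectory with protocol channels and metadata.

    time (s), extension (nm), force (pN) and turns all have equal length;
    time is strictly increasing.  ``metadata`` carries acquisition context
    (concentration, nucleotide condition, seed, ...) and, for synthetic
    traces, the ground-truth record and phase boundaries.
    """

    time: np.ndarray
    extension: np.ndarray
    force: np.ndarray
    turns: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.turns = np.asarray(self.turns, dtype=float)
        n = self.time.size
        if not (self.extension.size == self.force.size == self.turns.size == n):
            raise ValueError("all trace channels must have equal length")
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.extension)):
            raise ValueError("extension must be finite")

    def __len__(self) -> int:
        return self.time.size

    @property
    def sample_rate(self) -> float:
        """Mean sampling frequency in Hz."""
        if len(self) < 2:
            return float("nan")
        return 1.0 / float(np.mean(np.diff(self.time)))

    def slice_time(self, t0: float, t1: float) -> "TimeTrace":
        """Sub-trace with t0 <= time <= t1 (metadata shared)."""
        m = (self.time >= t0) & (self.time <= t1)
        return TimeTrace(self.time[m], self.extension[m], self.force[m],
                         self.turns[m], dict(self.metadata))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time,
            "extension_nm": self.extension,
            "force_pN": self.force,
            "turns": self.turns,
        })


def _format_meta_value(v) -> str:
    if isinstance(v, (np.floating, np.integer)):
        v = v.item()
    return repr(v) if isinstance(v, (dict, list, tuple)) else str(v)


def _parse_meta_value(s: str):
    s = s.strip()
    for parser in (int, float):
        try:
            return parser(s)
        except ValueError:
            pass
    if s in ("True", "False"):
        return s == "True"
    if s == "None":
        return None
    if s and s[0] in "[{(":
        import ast
        try:
            return ast.literal_eval(s)
        except (ValueError, SyntaxError):
            return s
    return s


def write_trace(trace: TimeTrace, path: str | Path) -> None:
    """Write a trace to TSV with ``# key = value`` metadata headers."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in trace.metadata.items():
            fh.write(f"# {key} = {_format_meta_value(value)}\n")
        fh.write("\t".join(COLUMNS) + "\n")
        np.savetxt(fh, np.column_stack([trace.time, trace.extension,
                                        trace.force, trace.turns]),
                   delimiter="\t", fmt="%.10g")


def read_trace(path: str | Path) -> TimeTrace:
    """Read a TSV trace, restoring metadata; schema errors carry line numbers."""
    path = Path(path)
    metadata: dict = {}
    header_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if "=" not in body:
                raise TraceFormatError(
                    f"{path}:{lineno}: malformed metadata header {body!r} "
                    "(expected '# key = value')")
            key, _, value = body.partition("=")
            metadata[key.strip()] = _parse_meta_value(value)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(
            f"{path}:{header_lines + 1}: missing required column(s) {missing}")
    time = df["time_s"].to_numpy()
    if time.size > 1 and not np.all(np.diff(time) > 0):
        raise TraceFormatError(f"{path}: time_s is not strictly increasing")
    return TimeTrace(time, df["extension_nm"].to_numpy(),
                     df["force_pN"].to_numpy(), df["turns"].to_numpy(), metadata)
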