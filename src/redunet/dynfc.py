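"""Sliding-window dynamic functional connectivity.

Turns a parcellated regional BOLD timeseries (volumes x regions) into an
ordered stack of symmetric Pearson correlation matrices, one per sliding
window.  The default window is 50 volumes with a step of 1 volume; at a
repetition time (TR) of 3 s that is a 150 s window, long enough to capture
the slowest BOLD frequencies of interest (~0.01 Hz) while remaining short
enough to resolve temporal dynamics.  A 100-volume window is supported for
sensitivity analyses.

No detrending, filtering or global-signal regression is applied inside
windows: the input timeseries is assumed to be fully denoised upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_WINDOW = 50
DEFAULT_STEP = 1
DEFAULT_DROP_INITIAL = 4


class DegenerateWindowError(ValueError):
    """A region is constant (zero variance) within a correlation window."""


@dataclass(frozen=True)
class RegionalTimeseries:
    """Per-session regional BOLD-like timeseries.

    Parameters
    ----------
    values
        Array of shape (n_volumes, n_regions); arbitrary BOLD units.
    tr_seconds
        Repetition time in seconds (time between successive volumes).
    subject_id, session_id
        Identifiers carried through the pipeline.
    region_ids
        Optional region names; defaults to ``r000, r001, ...``.
    """

    values: np.ndarray
    tr_seconds: float = 3.0
    subject_id: str = "sub-01"
    session_id: str = "ses-01"
    region_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("timeseries must be 2-D (volumes x regions)")
        if values.shape[0] < 2:
            raise ValueError("timeseries needs at least 2 volumes")
        if values.shape[1] < 2:
            raise ValueError("timeseries needs at least 2 regions")
        if not np.all(np.isfinite(values)):
            raise ValueError("timeseries contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "values", values)
        if not self.region_ids:
            object.__setattr__(
                self,
                "region_ids",
                tuple(f"r{i:03d}" for i in range(values.shape[1])),
            )
        elif len(self.region_ids) != values.shape[1]:
            raise ValueError("region_ids length must match region count")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class DynFCStack:
    """Ordered stack of sliding-window correlation matrices for one session.

    ``matrices[k]`` is the regions x regions Pearson correlation over volumes
    ``[window_start_indices[k], window_start_indices[k] + window_volumes)``.
    """

    matrices: np.ndarray  # (n_windows, n_regions, n_regions)
    window_volumes: int
    step_volumes: int
    window_start_indices: tuple[int, ...]
    tr_seconds: float = 3.0
    subject_id: str = "sub-01"
    session_id: str = "ses-01"
    region_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]

    @property
    def window_seconds(self) -> float:
        """Window duration in seconds (window_volumes x TR)."""
        return self.window_volumes * self.tr_seconds


def drop_initial_volumes(
    ts: RegionalTimeseries, k: int = DEFAULT_DROP_INITIAL
) -> RegionalTimeseries:
    """Remove the first ``k`` volumes (pre-steady-state scrubbing).

    The scanner's first few volumes precede magnetization steady state and
    are conventionally discarded; the default removes 4.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= ts.n_volumes:
        raise ValueError(
            f"cannot drop {k} volumes from a {ts.n_volumes}-volume session"
        )
    if k == 0:
        return ts
    return replace(ts, values=ts.values[k:])


def enumerate_windows(n_volumes: int, window: int, step: int = 1) -> tuple[int, ...]:
    """Start indices of all full sliding windows.

    Returns ``0, step, 2*step, ...`` while ``start + window <= n_volumes``;
    the count is ``floor((n_volumes - window) / step) + 1``.
    """
    if window < 2:
        raise ValueError("window must be at least 2 volumes")
    if step < 1:
        raise ValueError("step must be at least 1")
    if window > n_volumes:
        raise ValueError(
            f"window of {window} volumes exceeds session length {n_volumes}"
        )
    return tuple(range(0, n_volumes - window + 1, step))


def window_correlation(
    ts: RegionalTimeseries, start: int, window: int
) -> np.ndarray:
    """Pearson correlation matrix over one window of the timeseries.

    Raises :class:`DegenerateWindowError` naming the first constant region,
    rather than silently emitting NaNs that would corrupt downstream
    proportional thresholding.
    """
    if start < 0:
        raise ValueError("start must be non-negative")
    if start + window > ts.n_volumes:
        raise ValueError("window extends past the end of the timeseries")
    chunk = ts.values[start : start + window]
    sd = chunk.std(axis=0)
    if np.any(sd == 0):
        region = int(np.flatnonzero(sd == 0)[0])
        raise DegenerateWindowError(
            f"region {ts.region_ids[region]!r} (index {region}) is constant in "
            f"window [{start}, {start + window})"
        )
    corr = np.corrcoef(chunk, rowvar=False)
    # enforce exact symmetry/unit diagonal against floating-point asymmetry
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def build_stack(
    ts: RegionalTimeseries,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> DynFCStack:
    """Compute the full dynamic FC stack for one session."""
    starts = enumerate_windows(ts.n_volumes, window, step)
    matrices = np.stack([window_correlation(ts, s, window) for s in starts])
    return DynFCStack(
        matrices=matrices,
        window_volumes=window,
        step_volumes=step,
        window_start_indices=starts,
        tr_seconds=ts.tr_seconds,
        subject_id=ts.subject_id,
        session_id=ts.session_id,
        region_ids=ts.region_ids,
    )
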