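"""Takens delay embedding with strict segment bookkeeping.

Series from different individuals are physically distinct trajectories of
the same attractor, so no lag vector may span two individuals.  Each
embedding therefore records, per vector, the segment (individual) it came
from and its time index within that segment; neighbor exclusion windows and
forecast targets respect segment boundaries throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class EmbeddingError(ValueError):
    """Series too short for the requested embedding."""


@dataclass(frozen=True)
class DelayEmbedding:
    """Lagged state vectors pooled over one or more segments.

    Attributes
    ----------
    E, tau :
        Embedding dimension and lag.
    vectors :
        ``(n_vectors, E)`` array; row built at segment time t is
        ``(x_t, x_{t-tau}, ..., x_{t-(E-1)tau})``.
    times :
        Time index of each vector within its own segment.
    segments :
        Integer segment id per vector.
    segment_values :
        The raw segment series, for future lookups when forecasting.
    segment_ids :
        Names of the segments, aligned with the integer ids.
    """

    E: int
    tau: int
    vectors: np.ndarray
    times: np.ndarray
    segments: np.ndarray
    segment_values: tuple[np.ndarray, ...]
    segment_ids: tuple[str, ...]

    @property
    def n_vectors(self) -> int:
        return len(self.vectors)

    def future(self, tp: int) -> tuple[np.ndarray, np.ndarray]:
        """Values ``x(t + tp)`` per vector and a validity mask.

        A future is valid only when ``t + tp`` stays inside the vector's
        own segment.
        """
        n = self.n_vectors
        vals = np.zeros(n)
        ok = np.zeros(n, dtype=bool)
        for i in range(n):
            t = self.times[i] + tp
            seg = self.segment_values[self.segments[i]]
            if 0 <= t < len(seg):
                vals[i] = seg[t]
                ok[i] = True
        return vals, ok

    def values_at(self, series_by_segment: dict[str, np.ndarray] | list[np.ndarray],
                  tp: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """Another variable's values aligned to each vector time (+ tp).

        Used by cross mapping: neighbors found in *this* embedding predict
        the other variable at the same (or shifted) time.
        """
        if isinstance(series_by_segment, dict):
            series = [np.asarray(series_by_segment[s], dtype=float)
                      for s in self.segment_ids]
        else:
            series = [np.asarray(s, dtype=float) for s in series_by_segment]
        n = self.n_vectors
        vals = np.zeros(n)
        ok = np.zeros(n, dtype=bool)
        for i in range(n):
            t = self.times[i] + tp
            seg = series[self.segments[i]]
            if 0 <= t < len(seg):
                vals[i] = seg[t]
                ok[i] = True
        return vals, ok


def expected_vector_count(segment_lengths, E: int, tau: int = 1) -> int:
    """Closed-form count: sum over segments of max(0, L - (E-1)*tau)."""
    return int(sum(max(0, L - (E - 1) * tau) for L in segment_lengths))


def embed(
    series,
    E: int,
    tau: int = 1,
    segment_ids: tuple[str, ...] | None = None,
) -> DelayEmbedding:
    """Build a delay embedding from one series or several segments.

    ``series`` may be a single 1-D array, a list of per-segment arrays, or
    a dict mapping segment name to array (iterated in sorted-key order so
    the embedding is deterministic).
    """
    if E < 1 or tau < 1:
        raise EmbeddingError(f"E and tau must be >= 1 (got E={E}, tau={tau})")
    if isinstance(series, dict):
        keys = sorted(series)
        seg_arrays = [np.asarray(series[k], dtype=float) for k in keys]
        segment_ids = tuple(keys)
    elif isinstance(series, (list, tuple)) and len(series) and np.ndim(series[0]) == 1:
        seg_arrays = [np.asarray(s, dtype=float) for s in series]
    else:
        seg_arrays = [np.asarray(series, dtype=float)]
    if segment_ids is None:
        segment_ids = tuple(f"seg{i}" for i in range(len(seg_arrays)))

    vecs, times, segs = [], [], []
    span = (E - 1) * tau
    for si, x in enumerate(seg_arrays):
        for t in range(span, len(x)):
            vecs.append([x[t - k * tau] for k in range(E)])
            times.append(t)
            segs.append(si)
    if not vecs:
        raise EmbeddingError(
            f"series too short for E={E}, tau={tau}: no valid vectors"
        )
    return DelayEmbedding(
        E=E,
        tau=tau,
        vectors=np.asarray(vecs, dtype=float),
        times=np.asarray(times, dtype=int),
        segments=np.asarray(segs, dtype=int),
        segment_values=tuple(seg_arrays),
        segment_ids=segment_ids,
    )


def exclusion_matrix(embedding: DelayEmbedding, theiler: int = 1) -> np.ndarray:
    """Boolean (n, n) matrix: True where vector j may NOT serve as a
    neighbor for target i (self, or within the Theiler window in the same
    segment).  Cross-segment pairs are always eligible."""
    t = embedding.times
    s = embedding.segments
    same_seg = s[:, None] == s[None, :]
    close = np.abs(t[:, None] - t[None, :]) <= theiler
    return same_seg & close


__all__ = [
    "DelayEmbedding",
    "EmbeddingError",
    "embed",
    "expected_vector_count",
    "exclusion_matrix",
]
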