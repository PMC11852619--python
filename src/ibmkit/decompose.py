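"""Singular spectrum analysis (SSA) trend decomposition.

SSA embeds a length-n series into an L x K Hankel trajectory matrix
(K = n - L + 1), takes its singular value decomposition, and reconstructs
each rank-one term back into a length-n elementary series by averaging over
anti-diagonals. Summing every elementary series recovers the input exactly,
so any partition of the components yields an additive decomposition

    A = L + S + R

with L the long-term trend (components whose dominant frequency falls below
a cutoff), S the dominant oscillatory part (remaining components carrying at
least a floor fraction of the total energy), and R the remainder.

Anti-diagonal averaging of the outer product sigma * u v^T is computed as a
linear convolution of u and v divided by the anti-diagonal lengths, which
avoids materializing the rank-one matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.signal import fftconvolve

from .preprocess import UniformSeries


@dataclass(frozen=True)
class SSAResult:
    """Additive decomposition A = L + S + R of a uniform series.

    ``eigenvalues`` are the squared singular values of the trajectory matrix,
    descending. ``grouping`` maps each elementary-component index to one of
    "L", "S", "R".
    """

    L: UniformSeries
    S: UniformSeries
    R: UniformSeries
    window_len: int
    eigenvalues: np.ndarray
    grouping: Dict[int, str]

    def reconstruct(self) -> UniformSeries:
        return self.L.replace(values=self.L.values + self.S.values + self.R.values)


def ssa_decompose(
    series: UniformSeries, window_len: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Elementary SSA components and eigenvalues of a series.

    Returns ``(components, eigenvalues)`` where ``components`` has shape
    (d, n) with d = min(window_len, n - window_len + 1); the rows sum to the
    input series exactly (to floating tolerance), and ``eigenvalues`` are the
    squared singular values, descending.
    """
    x = np.asarray(series.values, dtype=float)
    n = x.size
    if not 2 <= window_len <= n // 2:
        raise ValueError(
            f"window_len must satisfy 2 <= window_len <= n/2 = {n // 2}, got {window_len}"
        )
    L = int(window_len)
    K = n - L + 1
    # trajectory (Hankel) matrix: column j is x[j : j + L]
    traj = np.lib.stride_tricks.sliding_window_view(x, L).T  # L x K
    u, s, vt = np.linalg.svd(traj, full_matrices=False)
    d = s.size
    # anti-diagonal counts: number of (i, j), i + j = k, 0<=i<L, 0<=j<K
    counts = np.minimum(np.minimum(np.arange(1, n + 1), n - np.arange(n)), min(L, K))
    components = np.empty((d, n))
    for i in range(d):
        components[i] = s[i] * fftconvolve(u[:, i], vt[i]) / counts
    return components, s**2


def group_components(
    components: np.ndarray,
    eigenvalues: np.ndarray,
    rate: float,
    trend_cutoff: float = 0.1,
    energy_floor: float = 0.05,
    t0: float = 0.0,
) -> SSAResult:
    """Group elementary components into trend, oscillatory, and remainder parts.

    A component joins the trend L when the frequency of its largest FFT
    magnitude lies below ``trend_cutoff`` (Hz); otherwise it joins the
    oscillatory part S when its eigenvalue is at least ``energy_floor`` of the
    eigenvalue total, and the remainder R if not.
    """
    components = np.atleast_2d(np.asarray(components, dtype=float))
    if components.size == 0:
        raise ValueError("no components to group")
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    n = components.shape[1]
    total = float(eigenvalues.sum())
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)

    grouping: Dict[int, str] = {}
    sums = {"L": np.zeros(n), "S": np.zeros(n), "R": np.zeros(n)}
    for i, comp in enumerate(components):
        dom = float(freqs[np.argmax(np.abs(np.fft.rfft(comp)))])
        if dom < trend_cutoff:
            label = "L"
        elif total > 0 and eigenvalues[i] >= energy_floor * total:
            label = "S"
        else:
            label = "R"
        grouping[i] = label
        sums[label] += comp

    return SSAResult(
        L=UniformSeries(sums["L"], rate, t0),
        S=UniformSeries(sums["S"], rate, t0),
        R=UniformSeries(sums["R"], rate, t0),
        window_len=components.shape[0] if components.shape[0] < n else n,
        eigenvalues=eigenvalues,
        grouping=grouping,
    )


def ssa(
    series: UniformSeries,
    window_len: int | None = None,
    trend_cutoff: float = 0.1,
    energy_floor: float = 0.05,
) -> SSAResult:
    """Full SSA decomposition with automatic grouping.

    ``window_len`` defaults to 20 s of samples, capped at half the series
    length — the embedding must span several IBM periods for the trend to
    separate from the burst oscillations.
    """
    if window_len is None:
        window_len = min(round(series.rate * 20.0), len(series) // 2)
        window_len = max(window_len, 2)
    components, eigenvalues = ssa_decompose(series, window_len)
    result = group_components(
        components,
        eigenvalues,
        rate=series.rate,
        trend_cutoff=trend_cutoff,
        energy_floor=energy_floor,
        t0=series.t0,
    )
    return SSAResult(
        L=result.L,
        S=result.S,
        R=result.R,
        window_len=int(window_len),
        eigenvalues=eigenvalues,
        grouping=result.grouping,
    )


def trend_of(
    series: UniformSeries,
    window_len: int | None = None,
    trend_cutoff: float = 0.1,
    energy_floor: float = 0.05,
) -> UniformSeries:
    """Convenience: the long-term trend L of the SSA decomposition."""
    return ssa(series, window_len, trend_cutoff, energy_floor).L
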