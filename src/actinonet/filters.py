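"""Spectrum cleanup and blank-derived exclusion lists.

Two cleanup steps precede all scoring, mirroring classical molecular
networking: removal of fragment ions near the precursor (which carry no
structural information and inflate self-similarity) and a windowed
intensity filter that keeps only the locally strongest peaks.

Exclusion lists emulate, in software, the acquisition-side practice of
suppressing culture-media ions: precursors observed in blank injections are
deduplicated into a list, and any sample spectrum whose precursor falls on
the list is dropped.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .spectra import NetworkingParams, Spectrum

__all__ = [
    "remove_precursor_region",
    "window_filter_top_peaks",
    "preprocess_spectrum",
    "build_exclusion_list",
    "apply_exclusion_list",
]


def remove_precursor_region(s: Spectrum, window: float = 17.0) -> Spectrum:
    """Drop every fragment within ``window`` Da of the precursor m/z.

    The boundary is inclusive: a peak at exactly ``precursor_mz - window``
    is removed. An empty result is allowed (the caller flags such spectra
    for exclusion downstream).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    keep = np.abs(s.mz - s.precursor_mz) > window
    return s.with_peaks(s.mz[keep], s.intensity[keep])


def window_filter_top_peaks(s: Spectrum, k: int = 6, width: float = 50.0) -> Spectrum:
    """Keep a peak only if it ranks in the top ``k`` by intensity within
    ±``width`` Da of its own m/z.

    The neighbourhood is evaluated per peak (a sliding window centred on
    each peak, not disjoint bins). Intensity ties rank the lower-m/z peak
    higher, making the filter deterministic. The operation is idempotent:
    removing a peak can only shrink its neighbours' competition.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if width <= 0:
        raise ValueError("width must be > 0")
    n = s.n_peaks
    if n == 0:
        return s
    mz, inten = s.mz, s.intensity
    lo = np.searchsorted(mz, mz - width, side="left")
    hi = np.searchsorted(mz, mz + width, side="right")
    keep = np.zeros(n, dtype=bool)
    for i in range(n):
        nb = slice(lo[i], hi[i])
        stronger = np.count_nonzero(
            (inten[nb] > inten[i]) | ((inten[nb] == inten[i]) & (mz[nb] < mz[i]))
        )
        keep[i] = stronger < k
    return s.with_peaks(mz[keep], inten[keep])


def preprocess_spectrum(s: Spectrum, params: NetworkingParams) -> Spectrum:
    """Apply the standard cleanup chain: precursor-region removal then the
    windowed top-k filter."""
    s = remove_precursor_region(s, params.precursor_region_window)
    return window_filter_top_peaks(s, params.window_filter_k, params.window_filter_width)


def build_exclusion_list(blank_spectra: Sequence[Spectrum], mz_tol: float = 0.01) -> list[float]:
    """Deduplicate blank precursor m/z values into a sorted exclusion list.

    Precursors are grouped by single linkage (consecutive sorted values
    within ``mz_tol`` join one group); each group contributes the mean of
    its members. Returns an empty list for no blanks.
    """
    if mz_tol <= 0:
        raise ValueError("mz_tol must be > 0")
    values = np.sort(np.asarray([s.precursor_mz for s in blank_spectra], dtype=float))
    if values.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(values) > mz_tol) + 1
    return [float(g.mean()) for g in np.split(values, breaks)]


def apply_exclusion_list(
    spectra: Sequence[Spectrum], exclusion: Sequence[float], mz_tol: float = 0.01
) -> list[Spectrum]:
    """Remove spectra whose precursor lies within ``mz_tol`` of any entry."""
    if not exclusion:
        return list(spectra)
    excl = np.asarray(sorted(exclusion), dtype=float)
    kept = []
    for s in spectra:
        idx = np.searchsorted(excl, s.precursor_mz)
        near = False
        if idx < excl.size and abs(excl[idx] - s.precursor_mz) <= mz_tol:
            near = True
        if idx > 0 and abs(excl[idx - 1] - s.precursor_mz) <= mz_tol:
            near = True
        if not near:
            kept.append(s)
    return kept
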