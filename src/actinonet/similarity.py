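"""Modified-cosine spectral similarity.

The modified cosine extends the dot-product similarity between two MS/MS
spectra by allowing a fragment of one spectrum to match a fragment of the
other either directly (|m/z difference| <= tol) or offset by the precursor
mass difference Δ = precursor(b) − precursor(a). It is the edge kernel of
classical molecular networking: two ions of structurally related molecules
(e.g. an analog carrying one extra residue) share many fragments, some
unshifted and some shifted by exactly Δ.

Intensities are square-root transformed and each spectrum's transformed
vector is scaled to unit Euclidean norm, so the score of a spectrum with
itself is 1. Each peak may participate in at most one matched pair; the
score is the maximum total product weight over all one-to-one assignments,
solved exactly as a maximum-weight bipartite matching
(:func:`scipy.optimize.linear_sum_assignment`). A greedy fallback
(descending pair weight) is available for speed; it lower-bounds the exact
score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .spectra import Spectrum

__all__ = ["PeakMatch", "Alignment", "align_spectra", "modified_cosine"]


@dataclass(frozen=True)
class PeakMatch:
    """One matched peak pair of an alignment (indices into each spectrum)."""

    index_a: int
    index_b: int
    mz_a: float
    mz_b: float
    weight: float
    shifted: bool  # matched via the Δ-shifted condition (and not directly)


@dataclass(frozen=True)
class Alignment:
    score: float
    n_matched: int
    matches: tuple[PeakMatch, ...]


def _unit_sqrt(intensity: np.ndarray) -> np.ndarray:
    w = np.sqrt(intensity)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def _pairs_within(mz_a: np.ndarray, mz_b: np.ndarray, shift: float, tol: float):
    """Index pairs (i, j) with |mz_a[i] + shift − mz_b[j]| <= tol.

    Both arrays are sorted ascending, so each i maps to a contiguous j range.
    """
    shifted = mz_a + shift
    lo = np.searchsorted(mz_b, shifted - tol, side="left")
    hi = np.searchsorted(mz_b, shifted + tol, side="right")
    return [(i, j) for i in range(mz_a.size) for j in range(lo[i], hi[i])]


def align_spectra(a: Spectrum, b: Spectrum, fragment_tol: float = 0.02) -> Alignment:
    """Exact modified-cosine alignment of two spectra.

    Returns the optimal one-to-one peak assignment together with its score
    and the number of positive-weight matched pairs. Symmetric in its
    arguments. Spectra with empty peak lists score 0 with no matches.
    """
    if fragment_tol <= 0:
        raise ValueError("fragment_tol must be > 0")
    if a.n_peaks == 0 or b.n_peaks == 0:
        return Alignment(0.0, 0, ())

    delta = b.precursor_mz - a.precursor_mz
    direct = set(_pairs_within(a.mz, b.mz, 0.0, fragment_tol))
    shifted = set(_pairs_within(a.mz, b.mz, delta, fragment_tol))
    candidates = direct | shifted
    if not candidates:
        return Alignment(0.0, 0, ())

    wa = _unit_sqrt(a.intensity)
    wb = _unit_sqrt(b.intensity)

    # Restrict the assignment problem to peaks that occur in some candidate
    # pair; everything else can never contribute weight.
    ia = sorted({i for i, _ in candidates})
    jb = sorted({j for _, j in candidates})
    pos_a = {i: r for r, i in enumerate(ia)}
    pos_b = {j: c for c, j in enumerate(jb)}
    weights = np.zeros((len(ia), len(jb)))
    for i, j in candidates:
        weights[pos_a[i], pos_b[j]] = wa[i] * wb[j]

    rows, cols = linear_sum_assignment(weights, maximize=True)
    matches = []
    for r, c in zip(rows, cols):
        if weights[r, c] <= 0:
            continue
        i, j = ia[r], jb[c]
        matches.append(
            PeakMatch(
                index_a=i,
                index_b=j,
                mz_a=float(a.mz[i]),
                mz_b=float(b.mz[j]),
                weight=float(weights[r, c]),
                shifted=(i, j) not in direct,
            )
        )
    matches.sort(key=lambda m: (m.mz_a, m.mz_b))
    score = float(sum(m.weight for m in matches))
    return Alignment(score, len(matches), tuple(matches))


def modified_cosine(
    a: Spectrum, b: Spectrum, fragment_tol: float = 0.02, *, method: str = "exact"
) -> tuple[float, int]:
    """Modified-cosine score and matched-peak count for two spectra.

    ``method="exact"`` (default) solves the maximum-weight bipartite
    matching; ``method="greedy"`` accepts candidate pairs in descending
    weight order, each peak at most once — faster but a lower bound.
    """
    if method == "exact":
        al = align_spectra(a, b, fragment_tol)
        return al.score, al.n_matched
    if method != "greedy":
        raise ValueError(f"unknown method {method!r}")
    if a.n_peaks == 0 or b.n_peaks == 0:
        return 0.0, 0
    delta = b.precursor_mz - a.precursor_mz
    candidates = set(_pairs_within(a.mz, b.mz, 0.0, fragment_tol))
    candidates |= set(_pairs_within(a.mz, b.mz, delta, fragment_tol))
    if not candidates:
        return 0.0, 0
    wa = _unit_sqrt(a.intensity)
    wb = _unit_sqrt(b.intensity)
    ranked = sorted(candidates, key=lambda ij: (-wa[ij[0]] * wb[ij[1]], ij))
    used_a: set[int] = set()
    used_b: set[int] = set()
    score = 0.0
    n = 0
    for i, j in ranked:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += wa[i] * wb[j]
        n += 1
    return float(score), n
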