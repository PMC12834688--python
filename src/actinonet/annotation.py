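"""Spectral-library dereplication and analog (propagated) annotation.

Exact dereplication matches a consensus spectrum against library entries
whose precursor agrees within the precursor tolerance; analog ("suspect")
annotation extends this to entries whose precursor differs by up to
``analog_max_delta`` Da — the modified cosine absorbs the shift — giving
propagated annotations for modified or homologous compounds never
deposited themselves. Library spectra are filtered with exactly the same
cleanup as the query data before scoring.

:func:`localize_mass_shift` is a deliberately simplified fragment-level
localisation of the modification implied by an analog match: it partitions
the matched peak pairs into shift-carrying and unshifted sets and reports
the smallest shifted fragment, the tightest bound on where along the
fragment series the modification resides. It does not attempt atom-level
placement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .clustering import ConsensusSpectrum
from .filters import preprocess_spectrum
from .io import read_mgf
from .networking import MolecularFamily
from .similarity import align_spectra
from .spectra import NetworkingParams, Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "LibraryEntry",
    "Annotation",
    "ShiftedFragmentReport",
    "read_library_mgf",
    "prepare_library",
    "exact_library_search",
    "analog_library_search",
    "localize_mass_shift",
    "propagate_family_annotations",
    "write_annotations",
]


@dataclass(frozen=True)
class LibraryEntry:
    entry_id: str
    compound_name: str
    spectrum: Spectrum
    pathway: str | None = None

    def __post_init__(self) -> None:
        if not self.compound_name:
            raise ValueError(f"library entry {self.entry_id} lacks a compound name")
        if self.spectrum.n_peaks == 0:
            raise ValueError(f"library entry {self.entry_id} has an empty peak list")


@dataclass(frozen=True)
class ShiftedFragmentReport:
    """Partition of an analog match's peak pairs into direct and shifted."""

    delta: float
    direct_pairs: tuple[tuple[float, float], ...]  # (query m/z, library m/z)
    shifted_pairs: tuple[tuple[float, float], ...]
    smallest_shifted_mz: float | None  # query-side; None if nothing shifted

    @property
    def all_shifted(self) -> bool:
        return bool(self.shifted_pairs) and not self.direct_pairs


@dataclass(frozen=True)
class Annotation:
    consensus_id: str
    entry_id: str
    compound_name: str
    cosine: float
    n_matched: int
    precursor_delta: float  # query precursor − library precursor
    mode: str  # "exact" | "analog"
    pathway: str | None = None
    shifted_fragment_report: ShiftedFragmentReport | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "analog"):
            raise ValueError(f"unknown annotation mode {self.mode!r}")


def read_library_mgf(path: str | Path) -> list[LibraryEntry]:
    """Load a reference library MGF carrying NAME= and optional PATHWAY=."""
    params: list[dict] = []
    spectra = read_mgf(path, extra_params=params)
    entries = []
    for spec, p in zip(spectra, params):
        name = p.get("name") or spec.spectrum_id
        pathway = p.get("pathway")
        entries.append(LibraryEntry(spec.spectrum_id, str(name), spec, pathway))
    return entries


def prepare_library(entries: Sequence[LibraryEntry], params: NetworkingParams) -> list[LibraryEntry]:
    """Filter library spectra in the same manner as the input data."""
    out = []
    for e in entries:
        spec = preprocess_spectrum(e.spectrum, params)
        if spec.n_peaks == 0:
            logger.warning("library entry %s empty after preprocessing; dropped", e.entry_id)
            continue
        out.append(LibraryEntry(e.entry_id, e.compound_name, spec, e.pathway))
    return out


def _best_hit(
    query: ConsensusSpectrum,
    candidates: Sequence[LibraryEntry],
    params: NetworkingParams,
) -> tuple[LibraryEntry, float, int] | None:
    best: tuple[LibraryEntry, float, int] | None = None
    for entry in candidates:
        al = align_spectra(entry.spectrum, query.spectrum, params.fragment_tol)
        if al.score < params.library_min_cosine or al.n_matched < params.library_min_matched:
            continue
        # higher cosine, then more matched peaks, then lexically first entry
        if (
            best is None
            or (al.score, al.n_matched) > (best[1], best[2])
            or ((al.score, al.n_matched) == (best[1], best[2]) and entry.entry_id < best[0].entry_id)
        ):
            best = (entry, al.score, al.n_matched)
    return best


def exact_library_search(
    consensus: Sequence[ConsensusSpectrum],
    library: Sequence[LibraryEntry],
    params: NetworkingParams,
) -> list[Annotation]:
    """Best exact library hit per consensus (at most one annotation each).

    A hit requires |precursor delta| <= ``precursor_tol``, cosine >=
    ``library_min_cosine`` and matched peaks >= ``library_min_matched``;
    ties resolve by higher cosine, then matched peaks, then entry id.
    """
    if not library:
        logger.warning("exact library search against an empty library")
        return []
    out = []
    for c in consensus:
        candidates = [
            e for e in library if abs(c.precursor_mz - e.spectrum.precursor_mz) <= params.precursor_tol
        ]
        hit = _best_hit(c, candidates, params)
        if hit is None:
            continue
        entry, score, n_matched = hit
        out.append(
            Annotation(
                consensus_id=c.consensus_id,
                entry_id=entry.entry_id,
                compound_name=entry.compound_name,
                cosine=score,
                n_matched=n_matched,
                precursor_delta=c.precursor_mz - entry.spectrum.precursor_mz,
                mode="exact",
                pathway=entry.pathway,
            )
        )
    return out


def analog_library_search(
    consensus: Sequence[ConsensusSpectrum],
    library: Sequence[LibraryEntry],
    params: NetworkingParams,
    exact: Sequence[Annotation] = (),
) -> list[Annotation]:
    """Propagated (suspect-style) annotation for unannotated consensus.

    Only consensus without an exact annotation are considered; a hit
    requires ``precursor_tol`` < |Δ| <= ``analog_max_delta`` at the same
    cosine/matched thresholds. Each analog annotation carries a
    :class:`ShiftedFragmentReport` localising the mass shift.
    """
    already = {a.consensus_id for a in exact}
    out = []
    for c in consensus:
        if c.consensus_id in already:
            continue
        candidates = [
            e
            for e in library
            if params.precursor_tol < abs(c.precursor_mz - e.spectrum.precursor_mz) <= params.analog_max_delta
        ]
        hit = _best_hit(c, candidates, params)
        if hit is None:
            continue
        entry, score, n_matched = hit
        delta = c.precursor_mz - entry.spectrum.precursor_mz
        report = localize_mass_shift(c.spectrum, entry.spectrum, delta, params)
        out.append(
            Annotation(
                consensus_id=c.consensus_id,
                entry_id=entry.entry_id,
                compound_name=entry.compound_name,
                cosine=score,
                n_matched=n_matched,
                precursor_delta=delta,
                mode="analog",
                pathway=entry.pathway,
                shifted_fragment_report=report,
            )
        )
    return out


def localize_mass_shift(
    query: Spectrum,
    entry: Spectrum,
    delta: float,
    params: NetworkingParams,
) -> ShiftedFragmentReport:
    """Partition matched peak pairs of an analog match into direct and
    Δ-shifted sets.

    The smallest shifted query-side fragment bounds where the modification
    can reside along the fragment series. Rejects |Δ| within the exact
    precursor tolerance (such matches are exact, not analogs). Zero
    matched pairs yield an empty report.
    """
    if abs(delta) <= params.precursor_tol:
        raise ValueError("localization applies to analog matches only (|delta| > precursor_tol)")
    al = align_spectra(entry, query, params.fragment_tol)  # a=entry so Δ matches query−entry
    direct, shifted = [], []
    for m in al.matches:
        pair = (m.mz_b, m.mz_a)  # (query m/z, library m/z)
        (shifted if m.shifted else direct).append(pair)
    smallest = min((q for q, _ in shifted), default=None)
    return ShiftedFragmentReport(
        delta=delta,
        direct_pairs=tuple(direct),
        shifted_pairs=tuple(shifted),
        smallest_shifted_mz=smallest,
    )


def propagate_family_annotations(
    families: Sequence[MolecularFamily], annotations: Sequence[Annotation]
) -> pd.DataFrame:
    """Label each molecular family annotated iff >= 1 member has a hit.

    Returns a table (family_id, size, annotated, compound_names) where
    compound_names joins the distinct names contributed by member hits.
    """
    by_node: dict[str, Annotation] = {a.consensus_id: a for a in annotations}
    rows = []
    for f in families:
        hits = [by_node[n] for n in f.nodes if n in by_node]
        names = sorted({a.compound_name for a in hits})
        rows.append(
            {
                "family_id": f.family_id,
                "size": f.size,
                "annotated": bool(hits),
                "compound_names": ";".join(names),
            }
        )
    return pd.DataFrame(rows, columns=["family_id", "size", "annotated", "compound_names"])


def write_annotations(annotations: Sequence[Annotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "consensus_id": a.consensus_id,
                "entry_id": a.entry_id,
                "name": a.compound_name,
                "mode": a.mode,
                "cosine": round(a.cosine, 6),
                "n_matched": a.n_matched,
                "delta": round(a.precursor_delta, 5),
                "pathway": a.pathway or "",
            }
            for a in annotations
        ],
        columns=["consensus_id", "entry_id", "name", "mode", "cosine", "n_matched", "delta", "pathway"],
    ).to_csv(path, sep="\t", index=False)
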