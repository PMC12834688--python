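"""Core data model: MS/MS spectra, sample metadata, and networking parameters.

A :class:`Spectrum` is one product-ion (MS/MS) scan: a precursor m/z (and
charge), an optional retention time, and a centroided peak list. Peak lists
are normalised on construction — sorted ascending in m/z, zero/negative
intensities dropped, and peaks at exactly equal m/z merged by intensity sum —
so every downstream operation can rely on a strictly increasing m/z axis.

:class:`NetworkingParams` collects every threshold of the classical
molecular-networking workflow (spectrum cleanup, pairwise scoring, edge and
family filtering, library search) in one frozen record so a whole run is
reproducible from a single parameter set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MEDIA",
    "SAMPLE_TYPES",
    "Spectrum",
    "SampleRecord",
    "NetworkingParams",
]

#: The five culture media of the strains x media design.
MEDIA = ("ISP2", "ISP4", "TSA", "NSG", "CZP")

SAMPLE_TYPES = ("sample", "blank", "qc")


def _normalise_peaks(peaks: Iterable[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    """Sort peaks by m/z, drop non-positive intensities, merge equal m/z."""
    arr = np.asarray(list(peaks), dtype=float)
    if arr.size == 0:
        return np.empty(0), np.empty(0)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("peaks must be (m/z, intensity) pairs")
    arr = arr[arr[:, 1] > 0]
    if arr.shape[0] == 0:
        return np.empty(0), np.empty(0)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    mz, inv = np.unique(arr[:, 0], return_inverse=True)
    intensity = np.bincount(inv, weights=arr[:, 1])
    return mz, intensity


@dataclass(frozen=True)
class Spectrum:
    """One MS/MS scan with a normalised peak list.

    ``mz`` is strictly increasing and ``intensity`` strictly positive;
    construct through :meth:`from_peaks` (or I/O) to guarantee this.
    A precursor larger than every fragment is *not* required: in-source
    fragments promoted to precursors legitimately violate it.
    """

    spectrum_id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor_charge: int = 1
    retention_time: float | None = None
    source_file: str = ""
    scan_index: int = 0

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"precursor_mz must be > 0, got {self.precursor_mz}")
        if self.precursor_charge < 1:
            raise ValueError("precursor_charge must be >= 1")

    @classmethod
    def from_peaks(
        cls,
        spectrum_id: str,
        precursor_mz: float,
        peaks: Iterable[tuple[float, float]],
        **kwargs,
    ) -> "Spectrum":
        mz, intensity = _normalise_peaks(peaks)
        return cls(spectrum_id, precursor_mz, mz, intensity, **kwargs)

    @property
    def n_peaks(self) -> int:
        return int(self.mz.shape[0])

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def with_peaks(self, mz: np.ndarray, intensity: np.ndarray) -> "Spectrum":
        """Return a copy carrying a new (already normalised) peak list."""
        return dataclasses.replace(self, mz=np.asarray(mz, float), intensity=np.asarray(intensity, float))

    def __eq__(self, other: object) -> bool:  # arrays break the generated __eq__
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.spectrum_id == other.spectrum_id
            and self.precursor_mz == other.precursor_mz
            and self.precursor_charge == other.precursor_charge
            and np.array_equal(self.mz, other.mz)
            and np.array_equal(self.intensity, other.intensity)
        )

    __hash__ = None  # type: ignore[assignment]


def normalise_media(token: str) -> str:
    """Map media spellings like ``ISP-2`` onto the canonical enum token."""
    return token.strip().upper().replace("-", "").replace("_", "")


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one acquired LC-MS/MS file."""

    filename: str
    strain_id: str
    genus: str
    media: str | None
    sample_type: str

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample_type {self.sample_type!r} for {self.filename}")
        if self.sample_type == "sample" and self.media is None:
            raise ValueError(f"media required for sample {self.filename}")
        if self.media is not None and self.media not in MEDIA:
            raise ValueError(f"unknown media {self.media!r} for {self.filename}")

    @property
    def is_blank(self) -> bool:
        return self.sample_type == "blank"


@dataclass(frozen=True)
class NetworkingParams:
    """Thresholds of the molecular-networking workflow.

    Defaults follow standard classical-networking practice on Orbitrap data:
    fragment ions within ±17 Da of the precursor removed, only the top 6
    peaks in every ±50 Da window kept, 0.02 Da precursor/fragment tolerance,
    edges at cosine ≥ 0.7 with ≥ 6 matched peaks, mutual top-10 neighbours,
    molecular families capped at 100 nodes, and library matches at the same
    cosine / matched-peak thresholds.

    ``min_matched_peaks`` is applied inclusively (>=). Workflow descriptions
    alternate between "more than 6" and "at least 6"; the inclusive reading
    is used for both the network and the library search, and the value is
    configurable either way.
    """

    precursor_region_window: float = 17.0
    window_filter_k: int = 6
    window_filter_width: float = 50.0
    precursor_tol: float = 0.02
    fragment_tol: float = 0.02
    min_cosine: float = 0.7
    min_matched_peaks: int = 6
    top_k: int = 10
    max_family_size: int = 100
    library_min_cosine: float = 0.7
    library_min_matched: int = 6
    analog_max_delta: float = 200.0
    cluster_precursor_tol: float = 0.02
    cluster_min_cosine: float = 0.7
    exclusion_mz_tol: float = 0.01

    def __post_init__(self) -> None:
        positive = (
            "precursor_region_window window_filter_k window_filter_width "
            "precursor_tol fragment_tol min_matched_peaks top_k "
            "library_min_matched analog_max_delta cluster_precursor_tol "
            "exclusion_mz_tol"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("min_cosine", "library_min_cosine", "cluster_min_cosine"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.max_family_size < 2:
            raise ValueError("max_family_size must be >= 2")

    def replace(self, **kwargs) -> "NetworkingParams":
        return dataclasses.replace(self, **kwargs)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkingParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown networking parameter(s): {sorted(unknown)}")
        return cls(**d)
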