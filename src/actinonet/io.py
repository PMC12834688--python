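"""Reading and writing the study's file formats.

MGF (Mascot generic format) is the primary spectrum container, handled via
:mod:`pyteomics.mgf`; sample metadata and exclusion lists are plain TSV.
Reference libraries are MGF blocks carrying extra ``NAME=`` and optional
``PATHWAY=`` headers.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .spectra import MEDIA, SAMPLE_TYPES, SampleRecord, Spectrum, normalise_media

logger = logging.getLogger(__name__)

__all__ = [
    "read_mgf",
    "write_mgf",
    "load_sample_table",
    "write_sample_table",
    "read_exclusion_list",
    "write_exclusion_list",
]

_SAMPLE_COLUMNS = ["filename", "strain_id", "genus", "media", "sample_type"]


def read_mgf(path: str | os.PathLike, *, extra_params: list[dict] | None = None) -> list[Spectrum]:
    """Parse an MGF file into :class:`Spectrum` objects.

    One spectrum per ``BEGIN IONS`` block. ``spectrum_id`` is the TITLE
    when present, otherwise ``"<basename>:<block ordinal>"``. Peak lists are
    normalised (sorted, equal-m/z merged). An empty file yields an empty
    list with a logged warning; a malformed block raises ``ValueError``
    naming the file and block ordinal.

    If ``extra_params`` is a list, the raw header dict of each block is
    appended to it (used by the library reader).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    ordinal = 0
    reader = _mgf.MGF(str(path), convert_arrays=1, read_charges=True)
    try:
        while True:
            ordinal += 1
            try:
                entry = next(reader)
            except StopIteration:
                ordinal -= 1
                break
            except Exception as exc:  # non-numeric peak line etc.
                raise ValueError(f"{path.name}: malformed MGF block {ordinal}: {exc}") from exc
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise ValueError(f"{path.name}: MGF block {ordinal} lacks PEPMASS")
            precursor_mz = float(pepmass[0])
            charge_list = params.get("charge")
            charge = int(charge_list[0]) if charge_list else 1
            rt = params.get("rtinseconds")
            title = params.get("title")
            spectrum_id = str(title) if title else f"{path.name}:{ordinal}"
            spectra.append(
                Spectrum.from_peaks(
                    spectrum_id=spectrum_id,
                    precursor_mz=precursor_mz,
                    peaks=zip(entry["m/z array"], entry["intensity array"]),
                    precursor_charge=max(charge, 1),
                    retention_time=float(rt) if rt is not None else None,
                    source_file=path.name,
                    scan_index=ordinal - 1,
                )
            )
            if extra_params is not None:
                extra_params.append(dict(params))
    finally:
        reader.close()
    if not spectra:
        logger.warning("MGF file %s contains no spectra", path)
    return spectra


def write_mgf(
    spectra: Sequence[Spectrum],
    path: str | os.PathLike,
    *,
    extra_params: Sequence[dict] | None = None,
) -> None:
    """Write spectra as MGF, one BEGIN IONS block per spectrum, in order.

    Round-trips through :func:`read_mgf` to within float print precision.
    ``extra_params`` supplies per-spectrum additional headers (e.g. NAME=).
    """
    entries = []
    for i, s in enumerate(spectra):
        params: dict = {
            "title": s.spectrum_id,
            "pepmass": (s.precursor_mz,),
            "charge": f"{s.precursor_charge}+",
            "scans": s.scan_index,
        }
        if s.retention_time is not None:
            params["rtinseconds"] = round(s.retention_time, 3)
        if extra_params is not None:
            params.update(extra_params[i])
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": params,
            }
        )
    with open(path, "w") as fh:
        _mgf.write(entries, fh, key_order=["title", "pepmass", "charge", "scans", "rtinseconds"])


def load_sample_table(path: str | os.PathLike) -> list[SampleRecord]:
    """Load the metadata TSV (filename, strain_id, genus, media, sample_type).

    Media tokens are normalised (``ISP-2`` -> ``ISP2``) and validated against
    the five-media enum; unknown media or duplicate filenames raise with the
    offenders listed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table {path} missing column(s): {missing}")
    dupes = df["filename"][df["filename"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate filename(s) in sample table: {sorted(set(dupes))}")
    bad_media = []
    records = []
    for row in df.itertuples(index=False):
        media = normalise_media(row.media) if row.media else None
        if media is not None and media not in MEDIA:
            bad_media.append(row.media)
            continue
        if row.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample_type {row.sample_type!r} for {row.filename}")
        records.append(
            SampleRecord(
                filename=row.filename,
                strain_id=row.strain_id,
                genus=row.genus,
                media=media,
                sample_type=row.sample_type,
            )
        )
    if bad_media:
        raise ValueError(f"unknown media token(s) in sample table: {sorted(set(bad_media))}")
    return records


def write_sample_table(records: Sequence[SampleRecord], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "filename": r.filename,
                "strain_id": r.strain_id,
                "genus": r.genus,
                "media": r.media or "",
                "sample_type": r.sample_type,
            }
            for r in records
        ],
        columns=_SAMPLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_exclusion_list(path: str | os.PathLike) -> list[float]:
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                values.append(float(line.split("\t")[0]))
    return sorted(values)


def write_exclusion_list(entries: Sequence[float], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for mz in entries:
            fh.write(f"{mz:.5f}\n")
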