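"""Consensus clustering of near-identical MS/MS spectra.

The same ion, detected across many files, yields many near-identical
spectra; counting chemistry requires merging them into consensus spectra
("unique MS/MS"). Spectra are joinable when their precursors agree within
``cluster_precursor_tol`` and their cosine similarity reaches
``cluster_min_cosine`` (the precursor delta is ~0 inside a cluster, so the
modified cosine degenerates to a plain cosine). Clusters are the
single-linkage transitive closure of joinable pairs — a deterministic,
order-independent simplification of the multi-round heuristic clusterers
used by large-scale workflows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import write_mgf
from .similarity import modified_cosine
from .spectra import NetworkingParams, SampleRecord, Spectrum

__all__ = [
    "ConsensusSpectrum",
    "cluster_spectra",
    "build_consensus",
    "attach_provenance",
    "remove_blank_clusters",
    "write_consensus_outputs",
]


@dataclass(frozen=True)
class ConsensusSpectrum:
    """Merged representative of a cluster of near-identical spectra.

    ``strain_set``/``media_set``/``blank_member_count`` are empty until
    :func:`attach_provenance` joins the members against sample metadata.
    """

    consensus_id: str
    spectrum: Spectrum
    members: tuple[tuple[str, str], ...]  # (spectrum_id, source_file)
    strain_set: frozenset[str] = frozenset()
    media_set: frozenset[str] = frozenset()
    blank_member_count: int = 0

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def precursor_mz(self) -> float:
        return self.spectrum.precursor_mz


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_consensus(members: Sequence[Spectrum], fragment_tol: float = 0.02) -> Spectrum:
    """Merge member spectra into one consensus spectrum.

    Member peaks are pooled and grouped by single linkage within
    ``fragment_tol``; each group emits its intensity-weighted mean m/z and
    summed intensity, and the result is rescaled to a base peak of 1000.
    The consensus precursor m/z is the TIC-weighted mean of the member
    precursors. A single-member cluster keeps its peaks (rescaled only).
    """
    if not members:
        raise ValueError("consensus requires >= 1 member")
    tics = np.array([s.intensity.sum() if s.n_peaks else 0.0 for s in members])
    precs = np.array([s.precursor_mz for s in members])
    precursor = float(np.average(precs, weights=tics)) if tics.sum() > 0 else float(precs.mean())

    pooled_mz = np.concatenate([s.mz for s in members]) if any(s.n_peaks for s in members) else np.empty(0)
    pooled_int = np.concatenate([s.intensity for s in members]) if pooled_mz.size else np.empty(0)
    rep = members[0]
    if pooled_mz.size == 0:
        return replace(rep, precursor_mz=precursor, mz=pooled_mz, intensity=pooled_int)

    order = np.argsort(pooled_mz, kind="stable")
    pooled_mz, pooled_int = pooled_mz[order], pooled_int[order]
    breaks = np.flatnonzero(np.diff(pooled_mz) > fragment_tol) + 1
    group_mz, group_int = [], []
    for g_mz, g_int in zip(np.split(pooled_mz, breaks), np.split(pooled_int, breaks)):
        group_mz.append(float(np.average(g_mz, weights=g_int)))
        group_int.append(float(g_int.sum()))
    inten = np.asarray(group_int)
    inten = inten / inten.max() * 1000.0
    rts = [s.retention_time for s in members if s.retention_time is not None]
    return replace(
        rep,
        precursor_mz=precursor,
        mz=np.asarray(group_mz),
        intensity=inten,
        retention_time=float(np.mean(rts)) if rts else None,
    )


def cluster_spectra(spectra: Sequence[Spectrum], params: NetworkingParams) -> list[ConsensusSpectrum]:
    """Greedy single-linkage clustering within precursor buckets.

    Two spectra are joinable iff |Δprecursor| <= ``cluster_precursor_tol``
    and cosine >= ``cluster_min_cosine``; clusters are the transitive
    closure of joinable pairs. Spectra are processed sorted by
    (precursor m/z, spectrum_id) so the output (ids, ordering) is
    deterministic; the partition itself is order-independent.
    """
    order = sorted(range(len(spectra)), key=lambda i: (spectra[i].precursor_mz, spectra[i].spectrum_id))
    precs = [spectra[i].precursor_mz for i in order]
    uf = _UnionFind(len(order))
    for a in range(len(order)):
        b = a - 1
        while b >= 0 and precs[a] - precs[b] <= params.cluster_precursor_tol:
            if uf.find(a) != uf.find(b):
                score, _ = modified_cosine(
                    spectra[order[a]], spectra[order[b]], params.fragment_tol
                )
                if score >= params.cluster_min_cosine:
                    uf.union(a, b)
            b -= 1

    groups: dict[int, list[int]] = {}
    for pos in range(len(order)):
        groups.setdefault(uf.find(pos), []).append(pos)

    clusters = sorted(groups.values(), key=lambda g: (precs[g[0]], spectra[order[g[0]]].spectrum_id))
    out = []
    for idx, positions in enumerate(clusters):
        members = [spectra[order[p]] for p in positions]
        consensus = build_consensus(members, params.fragment_tol)
        out.append(
            ConsensusSpectrum(
                consensus_id=f"C{idx:05d}",
                spectrum=replace(consensus, spectrum_id=f"C{idx:05d}"),
                members=tuple((s.spectrum_id, s.source_file) for s in members),
            )
        )
    return out


def attach_provenance(
    consensus: Sequence[ConsensusSpectrum], records: Sequence[SampleRecord]
) -> list[ConsensusSpectrum]:
    """Fill strain/media/blank provenance from sample metadata.

    Raises ``KeyError`` naming the first member file absent from the
    metadata.
    """
    by_file = {r.filename: r for r in records}
    out = []
    for c in consensus:
        strains, media = set(), set()
        blanks = 0
        for _, source_file in c.members:
            rec = by_file.get(source_file)
            if rec is None:
                raise KeyError(f"member file {source_file!r} missing from sample metadata")
            if rec.is_blank:
                blanks += 1
            else:
                if rec.strain_id:
                    strains.add(rec.strain_id)
                if rec.media:
                    media.add(rec.media)
        out.append(
            replace(c, strain_set=frozenset(strains), media_set=frozenset(media), blank_member_count=blanks)
        )
    return out


def remove_blank_clusters(
    consensus: Sequence[ConsensusSpectrum],
    records: Sequence[SampleRecord],
    max_blank_fraction: float = 0.0,
) -> list[ConsensusSpectrum]:
    """Drop consensus spectra dominated by blank injections.

    A consensus is removed iff blank_members / members >
    ``max_blank_fraction``; the strict default 0.0 removes any consensus
    with blank membership at all. Provenance is (re)attached from
    ``records``.
    """
    attached = attach_provenance(consensus, records)
    return [c for c in attached if c.blank_member_count / c.n_members <= max_blank_fraction]


def write_consensus_outputs(
    consensus: Sequence[ConsensusSpectrum], mgf_path: str | Path, info_path: str | Path
) -> None:
    """Export consensus spectra (MGF) and a cluster-info TSV."""
    write_mgf([c.spectrum for c in consensus], mgf_path)
    pd.DataFrame(
        [
            {
                "consensus_id": c.consensus_id,
                "precursor_mz": round(c.precursor_mz, 5),
                "n_members": c.n_members,
                "files": ";".join(sorted({f for _, f in c.members})),
                "strains": ";".join(sorted(c.strain_set)),
                "media": ";".join(sorted(c.media_set)),
                "blank_members": c.blank_member_count,
            }
            for c in consensus
        ]
    ).to_csv(info_path, sep="\t", index=False)
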