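"""Discovery-potential statistics.

Everything here reduces the networking output to the bookkeeping that
quantifies how much detected chemistry remains unannotated:

* an incidence matrix (item x strain presence) over consensus spectra or
  molecular families;
* rarefaction/accumulation curves over strains — both permutation-averaged
  and via the closed-form hypergeometric expectation
  ``E[S(k)] = Σ_i (1 − C(N−n_i, k) / C(N, k))`` where ``n_i`` is the number
  of strains in which item *i* occurs;
* UpSet-style media-overlap counts (exclusive counts per media combination
  plus per-media set sizes);
* annotation-rate summaries at both the raw-spectrum and the consensus
  denominator (studies quote either, so both are reported, labelled); and
* the pathway x media matrix of annotated-spectrum counts, normalised to
  the maximum within each pathway.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .annotation import Annotation
from .clustering import ConsensusSpectrum
from .networking import MolecularFamily

__all__ = [
    "IncidenceMatrix",
    "RarefactionCurve",
    "build_incidence",
    "rarefaction_curve",
    "expected_rarefaction",
    "media_overlap_counts",
    "annotation_rate_summary",
    "pathway_media_matrix",
]


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary item x unit presence table.

    ``matrix`` is a boolean DataFrame indexed by item id with one column
    per unit (strain); ``annotated`` flags items, aligned to the index.
    All-zero item rows are disallowed: an item that occurs nowhere was
    never observed.
    """

    matrix: pd.DataFrame
    annotated: pd.Series

    def __post_init__(self) -> None:
        if (~self.matrix.any(axis=1)).any():
            bad = self.matrix.index[~self.matrix.any(axis=1)].tolist()
            raise ValueError(f"all-zero incidence rows: {bad[:5]}")
        if not self.matrix.index.equals(self.annotated.index):
            raise ValueError("annotated flags misaligned with incidence index")

    @property
    def n_items(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_units(self) -> int:
        return int(self.matrix.shape[1])

    def subset(self, stratum: str) -> "IncidenceMatrix":
        """Restrict to 'all', 'annotated' or 'unannotated' items."""
        if stratum == "all":
            return self
        if stratum == "annotated":
            mask = self.annotated.astype(bool)
        elif stratum == "unannotated":
            mask = ~self.annotated.astype(bool)
        else:
            raise ValueError(f"unknown stratum {stratum!r}")
        return IncidenceMatrix(self.matrix.loc[mask], self.annotated.loc[mask])


@dataclass(frozen=True)
class RarefactionCurve:
    k: np.ndarray            # 1..N units accumulated
    mean: np.ndarray         # permutation mean of distinct items
    sd: np.ndarray
    expected: np.ndarray     # closed-form hypergeometric expectation
    stratum: str
    n_permutations: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "mean": self.mean,
                "sd": self.sd,
                "expected": self.expected,
                "stratum": self.stratum,
            }
        )


def build_incidence(
    items: Sequence[ConsensusSpectrum] | Sequence[MolecularFamily],
    strains: Sequence[str],
    annotations: Sequence[Annotation] = (),
    consensus_by_id: Mapping[str, ConsensusSpectrum] | None = None,
) -> IncidenceMatrix:
    """Incidence of consensus spectra (or families) across strains.

    A consensus is present in a strain iff one of its member spectra came
    from that strain's files; a family's incidence is the union over its
    member nodes (``consensus_by_id`` required for families). Items with
    no strain provenance (e.g. blank-only) are dropped. Unknown strains
    raise.
    """
    strain_list = list(dict.fromkeys(strains))
    strain_pos = {s: i for i, s in enumerate(strain_list)}
    annotated_ids = {a.consensus_id for a in annotations}

    ids, rows, flags = [], [], []
    for item in items:
        if isinstance(item, MolecularFamily):
            if consensus_by_id is None:
                raise ValueError("family incidence requires consensus_by_id")
            strain_set: set[str] = set()
            for node in item.nodes:
                strain_set |= set(consensus_by_id[node].strain_set)
            item_id = item.family_id
            is_annot = any(node in annotated_ids for node in item.nodes)
        else:
            strain_set = set(item.strain_set)
            item_id = item.consensus_id
            is_annot = item_id in annotated_ids
        unknown = strain_set - strain_pos.keys()
        if unknown:
            raise KeyError(f"strain(s) {sorted(unknown)} not in the provided strain list")
        if not strain_set:
            continue
        row = np.zeros(len(strain_list), dtype=bool)
        for s in strain_set:
            row[strain_pos[s]] = True
        ids.append(item_id)
        rows.append(row)
        flags.append(is_annot)

    matrix = pd.DataFrame(np.array(rows, dtype=bool).reshape(len(ids), len(strain_list)),
                          index=ids, columns=strain_list)
    return IncidenceMatrix(matrix, pd.Series(flags, index=ids, dtype=bool))


def expected_rarefaction(incidence: np.ndarray) -> np.ndarray:
    """Closed-form expected accumulation curve.

    For item i present in n_i of N units, the chance it is missed by a
    uniformly random subset of k units is C(N−n_i, k)/C(N, k); summing the
    complements over items gives E[S(k)] for k = 1..N. Computed in log
    space via ``gammaln`` for numerical range.
    """
    inc = np.asarray(incidence, dtype=bool)
    n_items, n_units = inc.shape
    n_i = inc.sum(axis=1).astype(float)
    k = np.arange(1, n_units + 1, dtype=float)

    def log_comb(n: np.ndarray, r: np.ndarray) -> np.ndarray:
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    # P(miss item i with k units): 0 whenever k > N − n_i
    miss = np.zeros((n_items, n_units))
    for j, kk in enumerate(k):
        avail = n_units - n_i
        ok = avail >= kk
        miss[ok, j] = np.exp(log_comb(avail[ok], kk) - log_comb(float(n_units), kk))
    return (1.0 - miss).sum(axis=0)


def rarefaction_curve(
    m: IncidenceMatrix,
    n_permutations: int = 100,
    seed: int | None = 0,
    stratum: str = "all",
    order: Sequence[str] | None = None,
) -> RarefactionCurve:
    """Accumulation curve of distinct items as units are added.

    Averages ``n_permutations`` random unit orderings (seeded); pass
    ``order`` to instead use one fixed unit ordering (n_permutations then
    ignored, sd is zero). The closed-form expectation is always attached.
    Each permuted curve is monotone non-decreasing and ends at the
    stratum's total item count.
    """
    sub = m.subset(stratum)
    inc = sub.matrix.to_numpy()
    if inc.size == 0:
        if sub.n_items == 0 and m.n_units > 0:
            # an empty stratum accumulates nothing, but the curve is defined
            n = m.n_units
            z = np.zeros(n)
            return RarefactionCurve(np.arange(1, n + 1), z, z.copy(), z.copy(), stratum, 0, seed)
        raise ValueError("empty incidence matrix")
    n_items, n_units = inc.shape

    if order is not None:
        cols = [sub.matrix.columns.get_loc(u) for u in order]
        if len(cols) != n_units:
            raise ValueError("fixed order must list every unit exactly once")
        perms = np.asarray([cols])
    else:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        perms = np.asarray([rng.permutation(n_units) for _ in range(n_permutations)])

    curves = np.empty((perms.shape[0], n_units))
    for p, perm in enumerate(perms):
        permuted = inc[:, perm]
        first = permuted.argmax(axis=1)  # unit position of first occurrence
        counts = np.bincount(first, minlength=n_units)
        curves[p] = np.cumsum(counts)

    return RarefactionCurve(
        k=np.arange(1, n_units + 1),
        mean=curves.mean(axis=0),
        sd=curves.std(axis=0, ddof=0),
        expected=expected_rarefaction(inc),
        stratum=stratum,
        n_permutations=perms.shape[0],
        seed=seed,
    )


def media_overlap_counts(consensus: Sequence[ConsensusSpectrum]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """UpSet-style media overlap bookkeeping.

    Returns ``(exclusive, set_sizes)``: ``exclusive`` has one row per
    observed media combination with the count of items whose media set is
    exactly that combination (rows partition the items); ``set_sizes``
    counts, per media, the items observed in that media regardless of
    overlap. Items with an empty media set raise.
    """
    combos: dict[frozenset[str], int] = {}
    media_seen: dict[str, int] = {}
    for c in consensus:
        if not c.media_set:
            raise ValueError(f"consensus {c.consensus_id} has an empty media set")
        key = frozenset(c.media_set)
        combos[key] = combos.get(key, 0) + 1
        for m in c.media_set:
            media_seen[m] = media_seen.get(m, 0) + 1

    exclusive = pd.DataFrame(
        [
            {"media_combination": "+".join(sorted(k)), "n_media": len(k), "exclusive_count": v}
            for k, v in combos.items()
        ]
    ).sort_values(["n_media", "media_combination"]).reset_index(drop=True)
    set_sizes = (
        pd.DataFrame([{"media": m, "set_size": n} for m, n in media_seen.items()])
        .sort_values("media")
        .reset_index(drop=True)
    )
    return exclusive, set_sizes


def annotation_rate_summary(
    consensus: Sequence[ConsensusSpectrum],
    annotations: Sequence[Annotation],
    families: Sequence[MolecularFamily],
    total_raw_spectra: int | None = None,
) -> dict:
    """Annotation-rate bookkeeping at both denominators.

    ``total_raw_spectra`` defaults to the summed member counts of the
    consensus list (i.e. spectra surviving preprocessing); pass the
    pre-filter count to report rates against everything acquired.
    """
    member_spectra = sum(c.n_members for c in consensus)
    if total_raw_spectra is None:
        total_raw_spectra = member_spectra
    by_mode = {"exact": set(), "analog": set()}
    for a in annotations:
        by_mode[a.mode].add(a.consensus_id)
    annotated_ids = by_mode["exact"] | by_mode["analog"]
    annotated_members = sum(c.n_members for c in consensus if c.consensus_id in annotated_ids)
    fam_annotated = sum(
        1 for f in families if any(n in annotated_ids for n in f.nodes)
    )
    n_consensus = len(consensus)
    return {
        "total_raw_spectra": int(total_raw_spectra),
        "clustered_spectra": int(member_spectra),
        "total_consensus": n_consensus,
        "annotated_consensus_exact": len(by_mode["exact"]),
        "annotated_consensus_analog": len(by_mode["analog"]),
        "annotated_consensus_combined": len(annotated_ids),
        "annotated_raw_spectra": int(annotated_members),
        "annotation_rate_raw_spectra": annotated_members / total_raw_spectra if total_raw_spectra else 0.0,
        "annotation_rate_consensus": len(annotated_ids) / n_consensus if n_consensus else 0.0,
        "total_families": len(families),
        "annotated_families": fam_annotated,
        "unannotated_families": len(families) - fam_annotated,
    }


def pathway_media_matrix(
    annotations: Sequence[Annotation],
    consensus: Sequence[ConsensusSpectrum],
    media_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pathway x media counts of annotated consensus spectra, normalised to
    each pathway's row maximum.

    An annotated consensus contributes one count to every media in which
    it was observed. All-zero pathway rows are dropped; every retained
    row has maximum 1.0.
    """
    by_id = {c.consensus_id: c for c in consensus}
    counts: dict[str, dict[str, int]] = {}
    media_seen: list[str] = list(media_order) if media_order else []
    for a in annotations:
        if not a.pathway:
            continue
        c = by_id.get(a.consensus_id)
        if c is None:
            continue
        for m in sorted(c.media_set):
            if m not in media_seen:
                media_seen.append(m)
            counts.setdefault(a.pathway, {})[m] = counts.get(a.pathway, {}).get(m, 0) + 1
    if not counts:
        return pd.DataFrame(columns=media_seen)
    df = pd.DataFrame.from_dict(counts, orient="index").reindex(columns=media_seen).fillna(0.0)
    df = df.loc[df.max(axis=1) > 0]
    normalised = df.div(df.max(axis=1), axis=0)
    return normalised.sort_index()
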