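"""Consensus clustering and molecular networking on a synthetic study.

Reads the study written by 02_simulate_study.py (re-generating it if
absent), merges near-identical spectra into consensus spectra, then builds
the molecular network and extracts families.
"""

from pathlib import Path

from actinonet import (
    NetworkingParams,
    StudyDesign,
    build_graph,
    cluster_spectra,
    enforce_family_size_cap,
    extract_families,
    load_sample_table,
    mutual_topk_filter,
    preprocess_spectrum,
    read_mgf,
    remove_blank_clusters,
    score_all_pairs,
    simulate_study,
)

study = Path("scratch_study")
if not (study / "metadata.tsv").exists():
    simulate_study(StudyDesign(n_strains=5, n_molecules=20, n_families=5, seed=7), study)

params = NetworkingParams()
records = load_sample_table(study / "metadata.tsv")

spectra = []
for mgf in sorted((study / "spectra").glob("*.mgf")):
    spectra.extend(preprocess_spectrum(s, params) for s in read_mgf(mgf))
spectra = [s for s in spectra if s.n_peaks]
print(f"{len(spectra)} spectra after cleanup")

consensus = remove_blank_clusters(cluster_spectra(spectra, params), records)
print(f"{len(consensus)} consensus spectra after blank removal")

edges = mutual_topk_filter(score_all_pairs(consensus, params), params.top_k)
graph = enforce_family_size_cap(
    build_graph([c.consensus_id for c in consensus], edges), params.max_family_size
)
families = extract_families(graph)
multi = [f for f in families if not f.is_singleton]
print(f"{graph.number_of_edges()} edges; {len(multi)} multi-node families "
      f"(sizes {sorted((f.size for f in multi), reverse=True)}) "
      f"+ {len(families) - len(multi)} singletons")

# Each multi-node family groups ion forms and structural analogs of related
# ground-truth molecules; singletons are ions with no sufficiently similar
# partner at cosine >= 0.7 and >= 6 matched peaks.
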