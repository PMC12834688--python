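"""End-to-end orchestration of the networking and discovery-stats workflow.

``run_pipeline`` executes, in order: (optional) study simulation → spectrum
ingestion → blank-derived exclusion → spectrum cleanup → consensus
clustering → blank-cluster removal → molecular networking → library
annotation (exact, then analog) → discovery statistics. Every stage's
outputs are written under the run directory and a manifest echoes the full
parameter set, seeds, package versions and output checksums, so a rerun
with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation import (
    analog_library_search,
    exact_library_search,
    prepare_library,
    propagate_family_annotations,
    read_library_mgf,
    write_annotations,
)
from .clustering import cluster_spectra, remove_blank_clusters, write_consensus_outputs
from .filters import apply_exclusion_list, build_exclusion_list, preprocess_spectrum
from .io import load_sample_table, read_mgf, write_exclusion_list
from .networking import (
    build_graph,
    enforce_family_size_cap,
    extract_families,
    export_network,
    mutual_topk_filter,
    score_all_pairs,
)
from .spectra import NetworkingParams
from .stats import (
    annotation_rate_summary,
    build_incidence,
    media_overlap_counts,
    pathway_media_matrix,
    rarefaction_curve,
)
from .synthetic import StudyDesign, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """One run's complete configuration.

    Exactly one of ``simulate`` (a :class:`StudyDesign`) or the three
    input paths (``spectra_dir``, ``metadata_path``, ``library_path``)
    must be provided.
    """

    out_dir: Path
    simulate: StudyDesign | None = None
    spectra_dir: Path | None = None
    metadata_path: Path | None = None
    library_path: Path | None = None
    params: NetworkingParams = field(default_factory=NetworkingParams)
    seed: int = 0
    n_permutations: int = 100
    max_blank_fraction: float = 0.0
    make_plots: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_input = any(p is not None for p in (self.spectra_dir, self.metadata_path, self.library_path))
        if self.simulate is not None and has_input:
            raise ValueError("config must specify either a simulate block or input paths, not both")
        if self.simulate is None:
            if not all(p is not None for p in (self.spectra_dir, self.metadata_path, self.library_path)):
                raise ValueError("config needs either a simulate block or all three input paths")
            for p in (self.spectra_dir, self.metadata_path, self.library_path):
                if not Path(p).exists():
                    raise ValueError(f"input path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            if "media_list" in sim:
                sim["media_list"] = tuple(sim["media_list"])
            if "ion_form_probs" in sim:
                sim["ion_form_probs"] = dict(sim["ion_form_probs"])
            kwargs["simulate"] = StudyDesign(**sim)
        if "input" in raw and raw["input"] is not None:
            inp = raw["input"]
            kwargs["spectra_dir"] = Path(inp["spectra_dir"])
            kwargs["metadata_path"] = Path(inp["metadata"])
            kwargs["library_path"] = Path(inp["library"])
        if "params" in raw and raw["params"] is not None:
            kwargs["params"] = NetworkingParams.from_dict(raw["params"])
        for key in ("seed", "n_permutations", "max_blank_fraction", "make_plots", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(out_dir=Path(raw["out_dir"]), **kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; return (and write) the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    logging.getLogger().addHandler(fh)
    params = config.params
    outputs: dict[str, Path] = {}

    try:
        # -- inputs -------------------------------------------------------
        if config.simulate is not None:
            manifest_in = _stage("simulate")(simulate_study, config.simulate, out_dir / "study")
            spectra_dir = manifest_in.out_dir / "spectra"
            metadata_path = manifest_in.metadata_path
            library_path = manifest_in.library_path
        else:
            spectra_dir = Path(config.spectra_dir)
            metadata_path = Path(config.metadata_path)
            library_path = Path(config.library_path)

        records = _stage("metadata")(load_sample_table, metadata_path)
        by_file = {r.filename: r for r in records}

        def read_all():
            sample_spectra, blank_spectra = [], []
            for mgf_path in sorted(spectra_dir.glob("*.mgf")):
                rec = by_file.get(mgf_path.name)
                if rec is None:
                    raise KeyError(f"spectra file {mgf_path.name} missing from metadata")
                spectra = read_mgf(mgf_path)
                (blank_spectra if rec.is_blank else sample_spectra).extend(spectra)
            return sample_spectra, blank_spectra

        sample_spectra, blank_spectra = _stage("read")(read_all)
        n_input = len(sample_spectra)
        logger.info("read %d sample and %d blank spectra", n_input, len(blank_spectra))

        # -- exclusion ------------------------------------------------------
        def exclusion():
            entries = build_exclusion_list(blank_spectra, params.exclusion_mz_tol)
            write_exclusion_list(entries, out_dir / "exclusion_list.tsv")
            return entries, apply_exclusion_list(sample_spectra, entries, params.exclusion_mz_tol)

        exclusion_entries, sample_spectra = _stage("exclusion")(exclusion)
        outputs["exclusion_list"] = out_dir / "exclusion_list.tsv"

        # -- preprocess -----------------------------------------------------
        def preprocess():
            cleaned = []
            dropped = 0
            for s in sample_spectra + blank_spectra:
                c = preprocess_spectrum(s, params)
                if c.n_peaks == 0:
                    dropped += 1
                    continue
                cleaned.append(c)
            logger.info("preprocessing dropped %d empty spectra", dropped)
            return cleaned

        cleaned = _stage("preprocess")(preprocess)

        # -- cluster + blank removal ---------------------------------------
        consensus_all = _stage("cluster")(cluster_spectra, cleaned, params)
        consensus = _stage("blank_removal")(
            remove_blank_clusters, consensus_all, records, config.max_blank_fraction
        )
        write_consensus_outputs(consensus, out_dir / "consensus.mgf", out_dir / "clusterinfo.tsv")
        outputs["consensus_mgf"] = out_dir / "consensus.mgf"
        outputs["clusterinfo"] = out_dir / "clusterinfo.tsv"

        # -- network ---------------------------------------------------------
        def network():
            edges = score_all_pairs(consensus, params)
            kept = mutual_topk_filter(edges, params.top_k)
            graph = build_graph([c.consensus_id for c in consensus], kept)
            graph = enforce_family_size_cap(graph, params.max_family_size)
            return graph, extract_families(graph)

        graph, families = _stage("network")(network)

        # -- annotate ---------------------------------------------------------
        def annotate():
            library = prepare_library(read_library_mgf(library_path), params)
            exact = exact_library_search(consensus, library, params)
            analog = analog_library_search(consensus, library, params, exact)
            return exact + analog

        annotations = _stage("annotate")(annotate)
        write_annotations(annotations, out_dir / "annotations.tsv")
        outputs["annotations"] = out_dir / "annotations.tsv"
        fam_table = propagate_family_annotations(families, annotations)
        fam_table.to_csv(out_dir / "family_annotations.tsv", sep="\t", index=False)
        outputs["family_annotations"] = out_dir / "family_annotations.tsv"

        net_paths = export_network(
            graph, families, consensus, out_dir,
            annotations={a.consensus_id: a.compound_name for a in annotations},
        )
        outputs.update({f"network_{k}": v for k, v in net_paths.items()})

        # -- stats -------------------------------------------------------------
        def stats():
            strains = sorted({r.strain_id for r in records if r.sample_type == "sample" and r.strain_id})
            consensus_by_id = {c.consensus_id: c for c in consensus}
            inc_c = build_incidence(consensus, strains, annotations)
            inc_f = build_incidence(families, strains, annotations, consensus_by_id)
            frames = []
            for level, inc in (("spectra", inc_c), ("families", inc_f)):
                for stratum in ("all", "annotated", "unannotated"):
                    curve = rarefaction_curve(inc, config.n_permutations, config.seed, stratum)
                    frame = curve.to_frame()
                    frame["level"] = level
                    frames.append(frame)
            import pandas as pd

            rarefaction = pd.concat(frames, ignore_index=True)
            rarefaction.to_csv(out_dir / "rarefaction.tsv", sep="\t", index=False)

            exclusive, set_sizes = media_overlap_counts(consensus)
            exclusive.to_csv(out_dir / "upset_exclusive.tsv", sep="\t", index=False)
            set_sizes.to_csv(out_dir / "upset_set_sizes.tsv", sep="\t", index=False)

            matrix = pathway_media_matrix(annotations, consensus)
            matrix.to_csv(out_dir / "pathway_media.tsv", sep="\t")

            summary = annotation_rate_summary(consensus, annotations, families, total_raw_spectra=n_input)
            summary["spectra_after_exclusion"] = len(sample_spectra)
            summary["n_network_edges"] = graph.number_of_edges()
            summary["consensus_per_media"] = {
                row.media: int(row.set_size) for row in set_sizes.itertuples(index=False)
            }
            all_media = frozenset(m for c in consensus for m in c.media_set)
            summary["consensus_shared_all_media"] = int(
                sum(1 for c in consensus if c.media_set == all_media and len(all_media) > 1)
            )
            with open(out_dir / "summary.json", "w") as fh_json:
                json.dump(summary, fh_json, indent=2, sort_keys=True)
            if config.make_plots:
                from .plots import plot_media_overlap, plot_pathway_media, plot_rarefaction

                curves = [
                    rarefaction_curve(inc_c, config.n_permutations, config.seed, s)
                    for s in ("all", "annotated", "unannotated")
                ]
                plot_rarefaction(curves, out_dir / "rarefaction.png")
                plot_media_overlap(exclusive, set_sizes, out_dir / "media_overlap.png")
                if not matrix.empty:
                    plot_pathway_media(matrix, out_dir / "pathway_media.png")
            return summary

        summary = _stage("stats")(stats)
        for name in ("rarefaction", "upset_exclusive", "upset_set_sizes", "pathway_media", "summary"):
            ext = "json" if name == "summary" else "tsv"
            outputs[name] = out_dir / f"{name}.{ext}"

        manifest = {
            "actinonet_version": __version__,
            "config": {
                "seed": config.seed,
                "n_permutations": config.n_permutations,
                "max_blank_fraction": config.max_blank_fraction,
                "simulate": dataclasses.asdict(config.simulate) if config.simulate else None,
                "input": None
                if config.simulate
                else {
                    "spectra_dir": str(spectra_dir),
                    "metadata": str(metadata_path),
                    "library": str(library_path),
                },
            },
            "params": params.as_dict(),
            "summary": summary,
            "outputs": {k: str(v) for k, v in outputs.items()},
            "checksums": {k: _sha256(v) for k, v in sorted(outputs.items()) if v.exists()},
        }
        with open(out_dir / "manifest.json", "w") as fh_json:
            json.dump(manifest, fh_json, indent=2, sort_keys=True)
        return manifest
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()
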