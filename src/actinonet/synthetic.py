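"""Synthetic strains x media study generator with full ground truth.

Emulates the statistical structure of a large OSMAC-style screen
(many strains cultured on up to five media, profiled by untargeted
LC-MS/MS) without any real data: ground-truth molecules are grouped into
structural families related by biochemical mass offsets, produced
media-dependently, observed as redundant ion forms ([M+H]+, [M+Na]+,
[2M+H]+, in-source fragments), measured with ppm-scale m/z error and
additive noise peaks, and accompanied by blank injections that carry the
culture-media background. Only a configurable fraction of the true
molecules (default 13%) is present in the reference library, emulating the
low annotation-rate regime of microbial metabolomics.

It does not attempt realistic fragmentation chemistry, isotope envelopes,
chromatographic co-elution or ion suppression; retention times are
uninformative placeholders.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import write_mgf, write_sample_table
from .spectra import MEDIA, SampleRecord, Spectrum

__all__ = [
    "PROTON_MASS",
    "SODIUM_ADDUCT_MASS",
    "ION_FORMS",
    "PATHWAYS",
    "GroundTruthMolecule",
    "StudyDesign",
    "StudyManifest",
    "generate_ground_truth",
    "sample_ion_forms",
    "render_ion_spectrum",
    "render_ion_spectra",
    "simulate_study",
]

PROTON_MASS = 1.007276
SODIUM_ADDUCT_MASS = 22.989218  # Na+ replacing nothing: [M+Na]+ = M + this
SODIUM_FOR_PROTON = SODIUM_ADDUCT_MASS - PROTON_MASS  # 21.981942

ION_FORMS = ("[M+H]+", "[M+Na]+", "[2M+H]+", "insource")

#: Seven biosynthetic-pathway labels in the NPClassifier style.
PATHWAYS = (
    "Alkaloids",
    "Amino acids and Peptides",
    "Carbohydrates",
    "Fatty acids",
    "Polyketides",
    "Shikimates and Phenylpropanoids",
    "Terpenoids",
)

# Common biochemical mass deltas (CH2, H2O, Gly, C2H4, ketene, C2H2, O, Ala)
# used as within-family offsets so analog search against the library is
# meaningful.
FAMILY_DELTAS = (
    14.01565,
    18.010565,
    57.02146,
    28.0313,
    42.010565,
    26.01565,
    15.994915,
    71.03711,
)


@dataclass(frozen=True)
class GroundTruthMolecule:
    molecule_id: str
    family_id: str
    monoisotopic_mass: float
    base_fragments: tuple[tuple[float, float], ...]  # (m/z, relative intensity)
    pathway: str
    in_library: bool
    media_production_prob: Mapping[str, float]
    compound_name: str = ""
    is_background: bool = False

    def __post_init__(self) -> None:
        if len(self.base_fragments) < 5:
            raise ValueError(f"{self.molecule_id}: need >= 5 base fragments")
        if any(mz >= self.monoisotopic_mass for mz, _ in self.base_fragments):
            raise ValueError(f"{self.molecule_id}: fragment m/z above molecular mass")


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of one simulated study.

    Defaults give a desk-scale replica of a strains x five-media screen:
    20 strains, 60 molecules in 15 structural families, ~3 ion forms per
    detected molecule, 5 ppm m/z error, a Poisson(3) noise-peak count, and
    13% of molecules present in the reference library.
    """

    n_strains: int = 20
    media_list: tuple[str, ...] = MEDIA
    n_molecules: int = 60
    n_families: int = 15
    ion_form_probs: Mapping[str, float] = field(
        default_factory=lambda: {"[M+H]+": 1.0, "[M+Na]+": 0.7, "[2M+H]+": 0.5, "insource": 0.7}
    )
    library_fraction: float = 0.13
    noise_peaks_lambda: float = 3.0
    mz_error_ppm: float = 5.0
    blank_background_molecules: int = 8
    background_in_samples: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_families > self.n_molecules:
            raise ValueError("n_families may not exceed n_molecules")
        if not (0 <= self.library_fraction <= 1):
            raise ValueError("library_fraction must lie in [0, 1]")
        unknown = [m for m in self.media_list if m not in MEDIA]
        if unknown:
            raise ValueError(f"unknown media in design: {unknown}")
        bad = [f for f in self.ion_form_probs if f not in ION_FORMS]
        if bad:
            raise ValueError(f"unknown ion form(s): {bad}")

    def replace(self, **kwargs) -> "StudyDesign":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class StudyManifest:
    out_dir: Path
    sample_files: tuple[Path, ...]
    blank_files: tuple[Path, ...]
    metadata_path: Path
    library_path: Path
    truth_spectra_path: Path
    truth_molecules_path: Path
    n_spectra: int


def _family_sizes(n_molecules: int, n_families: int) -> list[int]:
    base, extra = divmod(n_molecules, n_families)
    return [base + (1 if i < extra else 0) for i in range(n_families)]


def _draw_media_probs(rng: np.random.Generator, media_list: Sequence[str]) -> dict[str, float]:
    n_prod = int(rng.integers(1, len(media_list) + 1))
    producing = rng.choice(len(media_list), size=n_prod, replace=False)
    probs = {m: 0.0 for m in media_list}
    for idx in producing:
        probs[media_list[int(idx)]] = float(rng.uniform(0.4, 0.9))
    return probs


def generate_ground_truth(design: StudyDesign) -> list[GroundTruthMolecule]:
    """Draw the study's true molecules, grouped into structural families.

    Family members differ by cumulative sums of common biochemical mass
    deltas; each member keeps >= 45% of the family's base fragments at
    their original m/z and shifts the remainder (the high-m/z fragments,
    as if the modification sits in the larger substructure) by its own
    constant offset. Exactly ``round(library_fraction * n_molecules)``
    molecules are flagged as library members. Deterministic given the seed.
    """
    rng = np.random.default_rng([design.seed, 0])
    sizes = _family_sizes(design.n_molecules, design.n_families)
    molecules: list[GroundTruthMolecule] = []
    mol_idx = 0
    for fam_idx, size in enumerate(sizes):
        family_id = f"F{fam_idx:03d}"
        pathway = str(rng.choice(PATHWAYS))
        # leave headroom for up to `size` cumulative offsets below 1800
        base_mass = float(rng.uniform(200.0, 1800.0 - 80.0 * size))
        n_frag = int(rng.integers(8, 41))
        frag_mz = np.sort(rng.uniform(50.0, base_mass - 30.0, size=n_frag))
        frag_int = rng.lognormal(mean=0.0, sigma=1.0, size=n_frag)
        offsets = np.concatenate([[0.0], np.cumsum(rng.choice(FAMILY_DELTAS, size=size - 1))])
        for k in range(size):
            offset = float(offsets[k])
            if k == 0:
                member_mz = frag_mz
            else:
                shift_frac = float(rng.uniform(0.30, 0.55))
                cut = int(np.ceil(n_frag * (1 - shift_frac)))
                member_mz = frag_mz.copy()
                member_mz[cut:] = member_mz[cut:] + offset
            fragments = tuple(zip(member_mz.tolist(), frag_int.tolist()))
            molecule_id = f"M{mol_idx:04d}"
            molecules.append(
                GroundTruthMolecule(
                    molecule_id=molecule_id,
                    family_id=family_id,
                    monoisotopic_mass=base_mass + offset,
                    base_fragments=fragments,
                    pathway=pathway,
                    in_library=False,  # assigned below
                    media_production_prob=_draw_media_probs(rng, design.media_list),
                    compound_name=f"synthcmpd_{molecule_id}",
                )
            )
            mol_idx += 1
    n_lib = round(design.library_fraction * design.n_molecules)
    lib_idx = set(rng.choice(design.n_molecules, size=n_lib, replace=False).tolist())
    return [
        dataclasses.replace(m, in_library=(i in lib_idx)) for i, m in enumerate(molecules)
    ]


def generate_background_molecules(design: StudyDesign) -> list[GroundTruthMolecule]:
    """Culture-media/solvent background molecules that appear in blanks.

    Low-mass (150-500 Da) singleton 'families', never in the library,
    produced in every media with probability 1.
    """
    rng = np.random.default_rng([design.seed, 1])
    out = []
    for i in range(design.blank_background_molecules):
        mass = float(rng.uniform(150.0, 500.0))
        n_frag = int(rng.integers(8, 21))
        frag_mz = np.sort(rng.uniform(50.0, mass - 30.0, size=n_frag))
        frag_int = rng.lognormal(0.0, 1.0, size=n_frag)
        out.append(
            GroundTruthMolecule(
                molecule_id=f"BG{i:03d}",
                family_id=f"BGF{i:03d}",
                monoisotopic_mass=mass,
                base_fragments=tuple(zip(frag_mz.tolist(), frag_int.tolist())),
                pathway="Carbohydrates",
                in_library=False,
                media_production_prob={m: 1.0 for m in design.media_list},
                compound_name=f"background_{i:03d}",
                is_background=True,
            )
        )
    return out


def sample_ion_forms(design: StudyDesign, rng: np.random.Generator) -> list[str]:
    """Sample the ion forms one detection event produces.

    [M+H]+ is always emitted; each additional form is an independent
    Bernoulli draw with its configured probability.
    """
    forms = ["[M+H]+"]
    for form in ION_FORMS[1:]:
        p = float(design.ion_form_probs.get(form, 0.0))
        if p > 0 and rng.random() < p:
            forms.append(form)
    return forms


def _clean_form_peaks(mol: GroundTruthMolecule, form: str) -> tuple[float, list[tuple[float, float]]] | None:
    """Noise-free precursor m/z and fragment list for one ion form.

    Returns None when the form is not constructible for this molecule
    (e.g. no suitable fragment to promote as an in-source precursor).
    """
    m = mol.monoisotopic_mass
    frags = list(mol.base_fragments)
    if form == "[M+H]+":
        return m + PROTON_MASS, frags
    if form == "[M+Na]+":
        mzs = np.array([mz for mz, _ in frags])
        median = float(np.median(mzs))
        out = [
            (mz + SODIUM_FOR_PROTON, inten) if mz > median else (mz, inten)
            for mz, inten in frags
        ]
        return m + SODIUM_ADDUCT_MASS, out
    if form == "[2M+H]+":
        max_int = max(inten for _, inten in frags)
        return 2 * m + PROTON_MASS, frags + [(m + PROTON_MASS, max_int)]
    if form == "insource":
        eligible = [(mz, inten) for mz, inten in frags if mz >= 150.0]
        if not eligible:
            return None
        pre_mz = max(eligible, key=lambda p: (p[1], p[0]))[0]
        sub = [(mz, inten) for mz, inten in frags if mz < pre_mz - 0.5]
        if len(sub) < 3:
            return None
        return pre_mz, sub
    raise ValueError(f"unknown ion form {form!r}")


def render_ion_spectrum(
    mol: GroundTruthMolecule,
    form: str,
    design: StudyDesign,
    rng: np.random.Generator | None = None,
    spectrum_id: str = "",
) -> Spectrum | None:
    """Render one ion form of a molecule as a :class:`Spectrum`.

    With ``rng=None`` the spectrum is clean (no m/z jitter, no noise
    peaks); otherwise every m/z receives Gaussian relative error of
    ``mz_error_ppm`` ppm and Poisson(``noise_peaks_lambda``) uniform noise
    peaks at 1-5% of the base-peak intensity are added.
    """
    clean = _clean_form_peaks(mol, form)
    if clean is None:
        return None
    precursor, peaks = clean
    mz = np.array([p[0] for p in peaks], dtype=float)
    inten = np.array([p[1] for p in peaks], dtype=float)
    rt = None
    if rng is not None:
        ppm = design.mz_error_ppm * 1e-6
        precursor = precursor * (1.0 + float(rng.normal(0.0, ppm)))
        mz = mz * (1.0 + rng.normal(0.0, ppm, size=mz.size))
        n_noise = int(rng.poisson(design.noise_peaks_lambda))
        if n_noise:
            noise_mz = rng.uniform(50.0, precursor, size=n_noise)
            noise_int = rng.uniform(0.01, 0.05, size=n_noise) * inten.max()
            mz = np.concatenate([mz, noise_mz])
            inten = np.concatenate([inten, noise_int])
        rt = float(rng.uniform(30.0, 600.0))
    return Spectrum.from_peaks(
        spectrum_id=spectrum_id or f"{mol.molecule_id}:{form}",
        precursor_mz=float(precursor),
        peaks=zip(mz, inten),
        retention_time=rt,
    )


def render_ion_spectra(
    mol: GroundTruthMolecule,
    design: StudyDesign,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, Spectrum]]:
    """Sample ion forms for one detection event and render each.

    With ``rng=None`` all constructible forms are rendered clean.
    """
    if rng is None:
        forms = list(ION_FORMS)
    else:
        forms = sample_ion_forms(design, rng)
    out = []
    for form in forms:
        spec = render_ion_spectrum(mol, form, design, rng)
        if spec is not None:
            out.append((form, spec))
    return out


def _genus_for(rng: np.random.Generator) -> str:
    return str(rng.choice(["Streptomyces", "Streptomyces", "Streptomyces", "Micromonospora", "Nocardia"]))


def simulate_study(design: StudyDesign, out_dir: str | Path) -> StudyManifest:
    """Write a complete synthetic study to ``out_dir``.

    Produces one MGF per strain x media (a molecule appears iff its
    per-media Bernoulli production succeeds), one blank MGF per media
    carrying the background molecules in all their ion forms, the sample
    metadata TSV, the partial reference library MGF (clean [M+H]+ spectra
    of the in-library molecules, with NAME=/PATHWAY= headers), and two
    ground-truth TSVs mapping every emitted spectrum and every molecule.
    Fully reproducible from ``design.seed``.
    """
    out_dir = Path(out_dir)
    spectra_dir = out_dir / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)

    molecules = generate_ground_truth(design)
    background = generate_background_molecules(design)
    rng = np.random.default_rng([design.seed, 2])

    strains = [f"S{i:03d}" for i in range(design.n_strains)]
    genera = {s: _genus_for(rng) for s in strains}

    records: list[SampleRecord] = []
    truth_rows: list[dict] = []
    sample_files: list[Path] = []
    blank_files: list[Path] = []
    n_spectra = 0

    def emit_file(filename: str, mols_forms: list[tuple[GroundTruthMolecule, list[str]]],
                  strain: str, media: str, sample_type: str) -> Path:
        nonlocal n_spectra
        path = spectra_dir / filename
        spectra = []
        scan = 0
        for mol, forms in mols_forms:
            for form in forms:
                sid = f"{filename}:scan{scan}"
                spec = render_ion_spectrum(mol, form, design, rng, spectrum_id=sid)
                if spec is None:
                    continue
                spec = dataclasses.replace(spec, source_file=filename, scan_index=scan)
                spectra.append(spec)
                truth_rows.append(
                    {
                        "spectrum_id": sid,
                        "filename": filename,
                        "molecule_id": mol.molecule_id,
                        "family_id": mol.family_id,
                        "ion_form": form,
                        "strain": strain,
                        "media": media,
                        "sample_type": sample_type,
                        "is_background": mol.is_background,
                    }
                )
                scan += 1
        write_mgf(spectra, path)
        n_spectra += len(spectra)
        return path

    for strain in strains:
        for media in design.media_list:
            filename = f"{strain}_{media}.mgf"
            present: list[tuple[GroundTruthMolecule, list[str]]] = []
            for mol in molecules:
                if rng.random() < mol.media_production_prob.get(media, 0.0):
                    present.append((mol, sample_ion_forms(design, rng)))
            if design.background_in_samples > 0:
                for mol in background:
                    if rng.random() < design.background_in_samples:
                        present.append((mol, sample_ion_forms(design, rng)))
            sample_files.append(emit_file(filename, present, strain, media, "sample"))
            records.append(SampleRecord(filename, strain, genera[strain], media, "sample"))

    for media in design.media_list:
        filename = f"BLANK_{media}.mgf"
        present = [(mol, list(ION_FORMS)) for mol in background]
        blank_files.append(emit_file(filename, present, "", media, "blank"))
        records.append(SampleRecord(filename, "", "", media, "blank"))

    metadata_path = out_dir / "metadata.tsv"
    write_sample_table(records, metadata_path)

    library_path = out_dir / "library.mgf"
    lib_spectra, lib_params = [], []
    for mol in molecules:
        if not mol.in_library:
            continue
        spec = render_ion_spectrum(mol, "[M+H]+", design, rng=None, spectrum_id=f"LIB_{mol.molecule_id}")
        lib_spectra.append(spec)
        lib_params.append({"name": mol.compound_name, "pathway": mol.pathway})
    write_mgf(lib_spectra, library_path, extra_params=lib_params)

    truth_spectra_path = out_dir / "truth_spectra.tsv"
    pd.DataFrame(
        truth_rows,
        columns=[
            "spectrum_id", "filename", "molecule_id", "family_id", "ion_form",
            "strain", "media", "sample_type", "is_background",
        ],
    ).to_csv(truth_spectra_path, sep="\t", index=False)

    truth_molecules_path = out_dir / "truth_molecules.tsv"
    pd.DataFrame(
        [
            {
                "molecule_id": m.molecule_id,
                "family_id": m.family_id,
                "compound_name": m.compound_name,
                "monoisotopic_mass": round(m.monoisotopic_mass, 6),
                "pathway": m.pathway,
                "in_library": m.in_library,
                "is_background": m.is_background,
                **{f"prob_{k}": round(v, 4) for k, v in m.media_production_prob.items()},
            }
            for m in molecules + background
        ]
    ).to_csv(truth_molecules_path, sep="\t", index=False)

    return StudyManifest(
        out_dir=out_dir,
        sample_files=tuple(sample_files),
        blank_files=tuple(blank_files),
        metadata_path=metadata_path,
        library_path=library_path,
        truth_spectra_path=truth_spectra_path,
        truth_molecules_path=truth_molecules_path,
        n_spectra=n_spectra,
    )
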