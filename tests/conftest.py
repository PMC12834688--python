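from __future__ import annotations

from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from actinonet import (
    NetworkingParams,
    PipelineConfig,
    Spectrum,
    StudyDesign,
    run_pipeline,
)


def make_spectrum(rng: np.random.Generator, n_peaks: int, precursor: float | None = None,
                  mz_lo: float = 50.0, mz_hi: float = 500.0, spectrum_id: str = "s") -> Spectrum:
    mz = np.sort(rng.uniform(mz_lo, mz_hi, size=n_peaks))
    intensity = rng.uniform(0.1, 100.0, size=n_peaks)
    if precursor is None:
        precursor = float(rng.uniform(mz_hi, mz_hi + 400.0))
    return Spectrum.from_peaks(spectrum_id, precursor, zip(mz, intensity))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def params() -> NetworkingParams:
    return NetworkingParams()


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory) -> SimpleNamespace:
    """One full pipeline run on the default demo study (20 strains x 5
    media, 60 molecules, library fraction 0.13, seed 42), shared across
    tests that audit its outputs."""
    out_dir = tmp_path_factory.mktemp("demo") / "run"
    config = PipelineConfig(out_dir=out_dir, simulate=StudyDesign(), seed=42, n_permutations=50)
    manifest = run_pipeline(config)
    truth = pd.read_csv(out_dir / "study" / "truth_spectra.tsv", sep="\t")
    return SimpleNamespace(config=config, manifest=manifest, out_dir=out_dir, truth=truth)
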