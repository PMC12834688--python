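"""Generate a small synthetic strains x media study with ground truth.

Writes per-sample MGF files, blanks, sample metadata, a partial reference
library (13% of the true molecules) and truth tables into ./scratch_study.
"""

import pandas as pd

from actinonet import StudyDesign, simulate_study

design = StudyDesign(n_strains=5, n_molecules=20, n_families=5, seed=7)
manifest = simulate_study(design, "scratch_study")

print(f"sample files : {len(manifest.sample_files)}  (5 strains x 5 media)")
print(f"blank files  : {len(manifest.blank_files)}  (one per media)")
print(f"spectra total: {manifest.n_spectra}")

truth = pd.read_csv(manifest.truth_spectra_path, sep="\t")
print("\nion-form redundancy (spectra per form):")
print(truth[truth.sample_type == "sample"].ion_form.value_counts().to_string())

# Every emitted spectrum is listed in the truth table with its molecule,
# family, ion form, strain and media — the ground truth the test suite
# audits recovery against.
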