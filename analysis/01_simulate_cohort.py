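#!/usr/bin/env python
"""Simulate the study cohort: 25 cancer + 25 normal sputum donors, triplicate
FTIR spectra each, with the six class-differential fingerprint bands planted.

Writes the raw wide-format cohort matrix (bulky) under scratch/analysis/ and
a small composition summary under results/.
"""

from pathlib import Path

import pandas as pd

import ftir_sputum as fs

SEED = 1
SCRATCH = Path("scratch/analysis")
RESULTS = Path("results")


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    config = fs.CohortConfig(seed=SEED)
    cohort = fs.generate_cohort(config)
    fs.write_cohort_matrix(cohort, SCRATCH / "cohort.csv", "wide_csv")

    per_subject = cohort.meta.drop_duplicates("sample_id")
    summary = (per_subject.groupby("class")
               .agg(subjects=("sample_id", "nunique"),
                    smokers=("smoking_status", lambda s: (s == "smoker").sum()),
                    ex_smokers=("smoking_status", lambda s: (s == "ex_smoker").sum()),
                    never_smokers=("smoking_status", lambda s: (s == "never_smoker").sum()),
                    prior_cancer=("prior_cancer", "sum"),
                    cough=("cough", "sum"))
               .reset_index())
    summary.to_csv(RESULTS / "cohort_composition.csv", index=False)

    print(f"simulated {cohort.n_spectra} spectra "
          f"({len(cohort.sample_ids)} subjects x {config.replicates} replicates, "
          f"seed {SEED}) on a {len(cohort.grid)}-point raw grid")
    print(summary.to_string(index=False))
    print(f"raw matrix -> {SCRATCH / 'cohort.csv'}")


if __name__ == "__main__":
    main()
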