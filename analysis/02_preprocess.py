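#!/usr/bin/env python
"""Preprocess the simulated cohort: two-point baseline correction (900/1850),
crop to the 442-point fingerprint region, vector normalisation, 9-point
Savitzky-Golay second derivative, then per-subject replicate medians.

Writes the per-subject second-derivative matrix (bulky) under scratch/ and
the cancer/normal median second-derivative spectra under results/.
"""

from pathlib import Path

import pandas as pd

import ftir_sputum as fs

SCRATCH = Path("scratch/analysis")
RESULTS = Path("results")


def main() -> None:
    source = SCRATCH / "cohort.csv"
    if not source.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    cohort = fs.read_cohort_matrix(source, "wide_csv")
    processed = fs.preprocess_cohort(cohort)
    per_subject = fs.aggregate_replicates(processed)
    fs.write_cohort_matrix(per_subject, SCRATCH / "processed_per_subject.csv",
                           "wide_csv")

    medians = {lab: fs.group_median_spectrum(per_subject, lab)
               for lab in ("cancer", "normal")}
    table = pd.DataFrame({"wavenumber": per_subject.grid.values,
                          **{f"{lab}_median_d2": m.absorbance
                             for lab, m in medians.items()}})
    table.to_csv(RESULTS / "group_median_second_derivative.csv", index=False,
                 float_format="%.6g")

    print(f"preprocessed {cohort.n_spectra} spectra -> "
          f"{per_subject.n_spectra} per-subject second-derivative spectra "
          f"({len(per_subject.grid)} fingerprint points)")
    print(f"group medians -> {RESULTS / 'group_median_second_derivative.csv'}")


if __name__ == "__main__":
    main()
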