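#!/usr/bin/env python
"""Annotate the top-ranked differential peaks.

For each top peak: check 13C isotope-partner presence in the annotation
table, collect the correlated co-eluting group as candidate in-source
fragments, and decompose parent minus aglycone into an ordered chain of
sugar/acyl neutral losses. Writes the annotation table and an MSP library
of the named spectra.
"""

import argparse
from pathlib import Path

import pandas as pd

from grassmet.annotate import annotate_peaks
from grassmet.msp import Spectrum, write_msp
from grassmet.peaks import read_peak_table, read_sample_meta

ap = argparse.ArgumentParser()
ap.add_argument("--survey", type=Path, default=Path("results/survey"))
ap.add_argument("--peaks", type=Path,
                default=Path("results/deisotoped/peak_table_deisotoped.tsv"))
ap.add_argument("--top", type=Path,
                default=Path("results/differential/top_peaks.csv"))
ap.add_argument("--out", type=Path, default=Path("results/annotation"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

matrix, annot = read_peak_table(args.peaks)
meta = read_sample_meta(args.survey / "sample_meta.tsv")
top = pd.read_csv(args.top, index_col=0)
targets = [pid for pid in top.index if pid in matrix.index]

adduct = "[M+H]+" if meta["ion_mode"].iloc[0] == "positive" else "[M-H]-"
table = annotate_peaks(matrix, annot, peak_ids=targets, adduct=adduct)
table.to_csv(args.out / "annotations.csv", index=False)

ann_idx = annot.set_index("peak_id")
spectra = []
for _, row in table.iterrows():
    if not isinstance(row["name"], str):
        continue
    spectra.append(Spectrum(
        name=row["name"],
        precursor_mz=float(ann_idx.at[row["peak_id"], "mz"]),
        ions=[(float(ann_idx.at[row["peak_id"], "mz"]), 100.0)],
        metadata={"Comment": f"peak={row['peak_id']} "
                             f"residual_ppm={row['residual_ppm']:.2f}"},
    ))
(args.out / "annotated_library.msp").write_text(write_msp(spectra))

named = table[table["name"].notna()]
print(f"{len(named)}/{len(table)} top peaks annotated:")
for _, row in named.iterrows():
    print(f"  {row['peak_id']}: {row['name']}"
          + (f" (ambiguous with {row['ambiguous_aglycones']})"
             if isinstance(row["ambiguous_aglycones"], str)
             and row["ambiguous_aglycones"] else ""))
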