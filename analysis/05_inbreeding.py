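#!/usr/bin/env python
"""Four genomic inbreeding coefficients and their correlations.

F_ROH from the detected segments over the marker-covered autosome
length; F_GRM, F_HOM and F_UNI from per-breed allele frequencies.
Writes the per-animal table, the breed-level means with dispersion, and
the Pearson correlations of each weighted estimator with F_ROH.
"""

from pathlib import Path

import pandas as pd

from rohscan.genotype_io import read_panel
from rohscan.inbreeding import correlate_estimators, inbreeding_table, summarise_inbreeding
from rohscan.roh_detection import ROHSegment

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    panel = read_panel(ROOT / "scratch" / "cohort_final", "bed")
    l_aut = float(panel.markers.groupby("chromosome")["position_bp"].max().sum())
    seg_df = pd.read_csv(ROOT / "scratch" / "roh_segments.tsv", sep="\t")
    segments = [
        ROHSegment(
            str(r.sample_id), str(r.chromosome), int(r.start_bp), int(r.end_bp),
            int(r.n_snps), int(r.n_het), int(r.n_missing),
        )
        for r in seg_df.itertuples(index=False)
    ]
    records = inbreeding_table(panel, segments, l_aut=l_aut)
    records.to_csv(ROOT / "results" / "inbreeding.tsv", sep="\t", index=False)
    summary = summarise_inbreeding(records)
    summary.round(4).to_csv(ROOT / "results" / "inbreeding_summary.tsv", sep="\t", index=False)
    corr = correlate_estimators(records)
    corr.round(3).to_csv(ROOT / "results" / "inbreeding_correlations.tsv", sep="\t", index=False)
    print(summary.round(3).to_string(index=False))
    print(corr.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
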