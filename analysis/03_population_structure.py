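#!/usr/bin/env python
"""Population structure of the QC-passing cohort.

Identity-by-state similarity, classical-MDS principal components and
centroid-rule cluster outliers. Writes PC coordinates (with outlier
flags) and per-component variance to results/; the outlier-free panel,
used by all downstream stages, goes to scratch/.
"""

from pathlib import Path

import pandas as pd

from rohscan.genotype_io import read_panel, write_panel
from rohscan.popstruct import flag_cluster_outliers, ibs_similarity, pca_from_similarity

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    panel = read_panel(ROOT / "scratch" / "cohort_qc", "bed")
    sim = ibs_similarity(panel)
    pcs = pca_from_similarity(sim, 10)
    labels = panel.samples.set_index("sample_id")["population"]
    flagged = flag_cluster_outliers(pcs, labels, n_sd=3.0)

    df = pcs.to_frame()
    df.insert(1, "population", labels.loc[df["sample_id"]].to_numpy())
    df["outlier"] = df["sample_id"].isin(flagged)
    df.to_csv(ROOT / "results" / "pca_coordinates.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(10)],
            "variance_explained": pcs.variance_explained,
        }
    ).to_csv(ROOT / "results" / "pca_variance.tsv", sep="\t", index=False)

    keep = ~panel.samples["sample_id"].isin(flagged).to_numpy()
    write_panel(panel.subset(sample_mask=keep), ROOT / "scratch" / "cohort_final", "bed")
    ve = pcs.variance_explained
    print(f"PC1 and PC2 explain {100 * ve[0]:.2f}% and {100 * ve[1]:.2f}% of the variance")
    print(f"flagged {len(flagged)} cluster outliers: {flagged}")


if __name__ == "__main__":
    main()
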