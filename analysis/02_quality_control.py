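#!/usr/bin/env python
"""Quality-control filtration of the simulated cohort.

Applies the fixed filter order (sample missingness > 5% -> unmapped/sex
markers -> SNP missingness > 5% -> MAF < 2% -> HWE p < 1e-6) and writes
the filtered panel to scratch/ plus the removal report to results/.
"""

from pathlib import Path

from rohscan.genotype_io import QCConfig, apply_qc, read_panel, write_panel

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    panel = read_panel(ROOT / "scratch" / "cohort", "bed")
    filtered, report = apply_qc(panel, QCConfig())
    write_panel(filtered, ROOT / "scratch" / "cohort_qc", "bed")
    report.to_frame().to_csv(ROOT / "results" / "qc_report.tsv", sep="\t", index=False)
    print(
        f"kept {report.n_samples_out}/{report.n_samples_in} samples and "
        f"{report.n_snps_out}/{report.n_snps_in} SNPs "
        f"(mean call rate {report.mean_call_rate:.4f})"
    )
    for k, v in report.removed.items():
        print(f"  removed {k}: {v}")


if __name__ == "__main__":
    main()
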