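"""Read/write PLINK-format genotype panels and quality-control filtration.

A panel is a diploid dosage matrix (samples x SNPs) over ``{0, 1, 2,
MISSING}``, where the dosage counts copies of ``allele_b`` (the "B" / A2
allele), together with a marker map and per-sample population labels.

Two on-disk representations are supported:

* PED/MAP — whitespace-delimited text, one sample per PED line (six
  pedigree columns then two allele characters per SNP, ``0 0`` = missing).
* BED/BIM/FAM — PLINK 1 binary: magic bytes ``0x6C 0x1B``, SNP-major mode
  byte ``0x01``, then one 2-bit code per genotype packed four per byte
  (``00``=hom A1, ``01``=missing, ``10``=het, ``11``=hom A2), little-endian
  within each byte.

PED files do not record the identity of an allele that never appears in the
data, so a SNP at which only ``allele_a`` is observed cannot round-trip
orientation through PED; BIM stores both alleles and BED round-trips are
always exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats

#: Sentinel for a missing genotype call in the dosage matrix.
MISSING: int = -1

#: Chromosome labels treated as sex/mitochondrial when ``drop_sex_chromosomes``.
SEX_CHROMOSOMES = frozenset({"X", "Y", "XY", "MT", "M"})

MARKER_COLUMNS = ["snp_id", "chromosome", "position_bp", "allele_a", "allele_b"]
SAMPLE_COLUMNS = ["sample_id", "population"]


class PanelFormatError(ValueError):
    """Malformed on-disk panel (bad magic bytes, ragged records...)."""


class PanelIntegrityError(ValueError):
    """Companion files disagree on sample/marker counts."""


class EmptyPanelError(ValueError):
    """Quality control removed every sample or every SNP."""


def _chrom_sort_key(label: str) -> tuple[int, float, str]:
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, np.inf, str(label))


@dataclass
class GenotypePanel:
    """Samples x SNPs dosage matrix plus marker map and sample labels.

    ``dosages`` is an ``int8`` array with values in ``{0, 1, 2, MISSING}``.
    ``samples`` has columns ``sample_id``/``population``; ``markers`` has
    ``snp_id``/``chromosome``/``position_bp``/``allele_a``/``allele_b``.
    """

    dosages: np.ndarray
    samples: pd.DataFrame
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.samples = self.samples.reset_index(drop=True)
        self.markers = self.markers.reset_index(drop=True)
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        if self.dosages.ndim != 2:
            raise PanelIntegrityError("dosage matrix must be 2-D")
        if self.dosages.shape != (len(self.samples), len(self.markers)):
            raise PanelIntegrityError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise PanelIntegrityError(
                f"{int(bad.sum())} dosage cells outside {{0,1,2,MISSING}}"
            )
        if self.markers["snp_id"].duplicated().any():
            raise PanelIntegrityError("duplicate snp_id in marker map")

    def subset(
        self,
        sample_mask: np.ndarray | None = None,
        snp_mask: np.ndarray | None = None,
    ) -> "GenotypePanel":
        d = self.dosages
        s = self.samples
        m = self.markers
        if sample_mask is not None:
            d = d[np.asarray(sample_mask)]
            s = s.loc[np.asarray(sample_mask)]
        if snp_mask is not None:
            d = d[:, np.asarray(snp_mask)]
            m = m.loc[np.asarray(snp_mask)]
        return GenotypePanel(d.copy(), s.reset_index(drop=True), m.reset_index(drop=True))

    def sort_markers(self) -> "GenotypePanel":
        """Return a panel with markers ordered by (chromosome, position)."""
        key = self.markers["chromosome"].map(_chrom_sort_key)
        order = pd.DataFrame(
            {"k": key, "pos": self.markers["position_bp"]}
        ).sort_values(["k", "pos"], kind="stable").index.to_numpy()
        return self.subset(snp_mask=None).subset(snp_mask=order)

    def markers_sorted(self) -> bool:
        grp = self.markers.groupby("chromosome", sort=False)["position_bp"]
        if not grp.apply(lambda s: bool(s.is_monotonic_increasing)).all():
            return False
        # chromosome blocks must be contiguous
        chrom = self.markers["chromosome"].to_numpy()
        seen: set[str] = set()
        prev = None
        for c in chrom:
            if c != prev:
                if c in seen:
                    return False
                seen.add(c)
                prev = c
        return True

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP frequency of allele_b among non-missing calls (NaN if none)."""
        d = self.dosages
        obs = d != MISSING
        n = obs.sum(axis=0)
        tot = np.where(obs, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, tot / (2.0 * n), np.nan)


@dataclass
class QCConfig:
    """Thresholds for panel filtration.

    Defaults follow the usual SNP-array practice for livestock panels:
    drop samples with > 5% missing calls, then unmapped and sex-chromosome
    markers, then SNPs with > 5% missing calls, minor allele frequency
    below 2%, or a Hardy–Weinberg chi-square p-value below 1e-6.
    """

    max_sample_missing: float = 0.05
    max_snp_missing: float = 0.05
    min_maf: float = 0.02
    hwe_p_min: float = 1e-6
    drop_sex_chromosomes: bool = True
    drop_unmapped: bool = True
    per_population: bool = False

    def __post_init__(self) -> None:
        for name in ("max_sample_missing", "max_snp_missing", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.hwe_p_min <= 1.0:
            raise ValueError("hwe_p_min outside [0, 1]")


@dataclass
class QCReport:
    n_samples_in: int
    n_samples_out: int
    n_snps_in: int
    n_snps_out: int
    removed: dict[str, int] = field(default_factory=dict)
    mean_call_rate: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("samples_in", self.n_samples_in),
            ("samples_out", self.n_samples_out),
            ("snps_in", self.n_snps_in),
            ("snps_out", self.n_snps_out),
            *((f"removed_{k}", v) for k, v in self.removed.items()),
            ("mean_call_rate", round(self.mean_call_rate, 6)),
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])


# ---------------------------------------------------------------------------
# Hardy–Weinberg chi-square
# ---------------------------------------------------------------------------

def hwe_chisq_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Upper-tail p of the 1-df chi-square goodness-of-fit test against
    Hardy–Weinberg genotype proportions.

    Expected counts derive from the sample allele frequency; a monomorphic
    input (one allele absent) returns ``p = 1`` by convention — such SNPs
    are the MAF filter's job, not this test's.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no observed genotypes")
    p = (2 * n_aa + n_ab) / (2.0 * n)  # frequency of allele a
    if p == 0.0 or p == 1.0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_p_per_snp(dosages: np.ndarray) -> np.ndarray:
    """Vectorised HWE p-value per SNP column (same test as hwe_chisq_p)."""
    n_bb = (dosages == 2).sum(axis=0).astype(float)
    n_ab = (dosages == 1).sum(axis=0).astype(float)
    n_aa = (dosages == 0).sum(axis=0).astype(float)
    n = n_aa + n_ab + n_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n_aa + n_ab) / (2 * n)
        e_aa = n * p * p
        e_ab = 2 * n * p * (1 - p)
        e_bb = n * (1 - p) ** 2
        chi2 = (
            (n_aa - e_aa) ** 2 / e_aa
            + (n_ab - e_ab) ** 2 / e_ab
            + (n_bb - e_bb) ** 2 / e_bb
        )
    pval = stats.chi2.sf(chi2, df=1)
    mono = (n == 0) | (p <= 0) | (p >= 1)
    return np.where(mono, 1.0, pval)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def apply_qc(panel: GenotypePanel, cfg: QCConfig | None = None) -> tuple[GenotypePanel, QCReport]:
    """Filter a panel in the fixed order: sample missingness -> unmapped /
    sex-chromosome markers -> SNP missingness -> MAF -> HWE.

    Marker-level statistics (missingness, MAF, HWE) are computed on the
    cohort remaining after sample removal. With ``cfg.per_population`` the
    MAF and HWE filters remove a SNP if it fails in *any* population.
    """
    cfg = cfg or QCConfig()
    if panel.n_samples == 0 or panel.n_snps == 0:
        raise EmptyPanelError("input panel is empty")
    removed: dict[str, int] = {}

    # 1. sample missingness (strict >)
    miss_frac = (panel.dosages == MISSING).mean(axis=1)
    keep_samples = miss_frac <= cfg.max_sample_missing
    removed["samples_missing"] = int((~keep_samples).sum())
    panel = panel.subset(sample_mask=keep_samples)
    if panel.n_samples == 0:
        raise EmptyPanelError("sample-missingness filter removed every sample")
    n_in_samples = len(keep_samples)

    chrom = panel.markers["chromosome"].astype(str)
    pos = panel.markers["position_bp"].to_numpy()
    keep = np.ones(panel.n_snps, dtype=bool)
    # 2. unmapped / sex chromosomes
    if cfg.drop_unmapped:
        unmapped = (chrom == "0").to_numpy() | (pos <= 0)
        removed["snps_unmapped"] = int((keep & unmapped).sum())
        keep &= ~unmapped
    if cfg.drop_sex_chromosomes:
        sex = chrom.str.upper().isin(SEX_CHROMOSOMES).to_numpy()
        removed["snps_sex_chromosome"] = int((keep & sex).sum())
        keep &= ~sex
    panel_kept = panel.subset(snp_mask=keep)

    # 3. SNP missingness (strict >)
    snp_miss = (panel_kept.dosages == MISSING).mean(axis=0)
    drop = snp_miss > cfg.max_snp_missing
    removed["snps_missing"] = int(drop.sum())
    panel_kept = panel_kept.subset(snp_mask=~drop)

    groups: list[np.ndarray]
    if cfg.per_population:
        pops = panel_kept.samples["population"].to_numpy()
        groups = [pops == p for p in pd.unique(pops)]
    else:
        groups = [np.ones(panel_kept.n_samples, dtype=bool)]

    # 4. MAF (strict <)
    drop = np.zeros(panel_kept.n_snps, dtype=bool)
    for g in groups:
        freq = panel_kept.subset(sample_mask=g).allele_frequencies()
        maf = np.minimum(freq, 1 - freq)
        drop |= np.isnan(maf) | (maf < cfg.min_maf)
    removed["snps_maf"] = int(drop.sum())
    panel_kept = panel_kept.subset(snp_mask=~drop)

    # 5. HWE (strict <)
    drop = np.zeros(panel_kept.n_snps, dtype=bool)
    for g in groups:
        masked = np.where(g[:, None], panel_kept.dosages, MISSING)
        drop |= _hwe_p_per_snp(masked) < cfg.hwe_p_min
    removed["snps_hwe"] = int(drop.sum())
    panel_kept = panel_kept.subset(snp_mask=~drop)

    if panel_kept.n_snps == 0:
        raise EmptyPanelError("SNP filters removed every marker")

    call_rate = float((panel_kept.dosages != MISSING).mean())
    report = QCReport(
        n_samples_in=n_in_samples,
        n_samples_out=panel_kept.n_samples,
        n_snps_in=panel.n_snps,
        n_snps_out=panel_kept.n_snps,
        removed=removed,
        mean_call_rate=call_rate,
    )
    return panel_kept, report


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

def _write_map(markers: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        for row in markers.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.snp_id}\t0\t{row.position_bp}\n")


def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PanelFormatError(f"MAP line has {len(parts)} fields, expected 4")
            rows.append((parts[1], parts[0], int(parts[3])))
    return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_bp"])


def write_panel(panel: GenotypePanel, prefix: str | Path, fmt: str = "bed") -> None:
    """Write a panel as ``prefix.ped/.map`` or ``prefix.bed/.bim/.fam``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "ped":
        _write_map(panel.markers, prefix.with_suffix(".map"))
        a = panel.markers["allele_a"].to_numpy()
        b = panel.markers["allele_b"].to_numpy()
        with open(prefix.with_suffix(".ped"), "w") as fh:
            for i, row in enumerate(panel.samples.itertuples(index=False)):
                fields = [str(row.population), str(row.sample_id), "0", "0", "0", "-9"]
                d = panel.dosages[i]
                for j in range(panel.n_snps):
                    x = d[j]
                    if x == MISSING:
                        fields += ["0", "0"]
                    elif x == 0:
                        fields += [a[j], a[j]]
                    elif x == 1:
                        fields += [a[j], b[j]]
                    else:
                        fields += [b[j], b[j]]
                fh.write(" ".join(fields) + "\n")
    elif fmt == "bed":
        with open(prefix.with_suffix(".bim"), "w") as fh:
            for row in panel.markers.itertuples(index=False):
                fh.write(
                    f"{row.chromosome}\t{row.snp_id}\t0\t{row.position_bp}"
                    f"\t{row.allele_a}\t{row.allele_b}\n"
                )
        with open(prefix.with_suffix(".fam"), "w") as fh:
            for row in panel.samples.itertuples(index=False):
                fh.write(f"{row.population} {row.sample_id} 0 0 0 -9\n")
        with open(prefix.with_suffix(".bed"), "wb") as fh:
            fh.write(bytes([0x6C, 0x1B, 0x01]))
            fh.write(_pack_bed(panel.dosages))
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'ped' or 'bed')")


# 2-bit codes per dosage (copies of allele_b): 0 -> 0b00, MISSING -> 0b01,
# 1 -> 0b10, 2 -> 0b11.
_DOSAGE_TO_CODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)


def _pack_bed(dosages: np.ndarray) -> bytes:
    n, m = dosages.shape
    codes = np.empty((m, n), dtype=np.uint8)  # SNP-major
    d = dosages.T
    codes[d == 0] = 0b00
    codes[d == MISSING] = 0b01
    codes[d == 1] = 0b10
    codes[d == 2] = 0b11
    n_bytes = (n + 3) // 4
    padded = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    shaped = padded.reshape(m, n_bytes, 4)
    packed = (
        shaped[:, :, 0]
        | (shaped[:, :, 1] << 2)
        | (shaped[:, :, 2] << 4)
        | (shaped[:, :, 3] << 6)
    ).astype(np.uint8)
    return packed.tobytes()


def _unpack_bed(raw: bytes, n_samples: int, n_snps: int) -> np.ndarray:
    n_bytes = (n_samples + 3) // 4
    arr = np.frombuffer(raw, dtype=np.uint8)
    if arr.size != n_bytes * n_snps:
        raise PanelIntegrityError(
            f"BED payload of {arr.size} bytes does not match "
            f"{n_snps} SNPs x {n_samples} samples"
        )
    arr = arr.reshape(n_snps, n_bytes)
    codes = np.empty((n_snps, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = arr & 0b11
    codes[:, 1::4] = (arr >> 2) & 0b11
    codes[:, 2::4] = (arr >> 4) & 0b11
    codes[:, 3::4] = (arr >> 6) & 0b11
    return _CODE_TO_DOSAGE[codes[:, :n_samples]].T.copy()


def read_panel(prefix: str | Path, fmt: str = "bed") -> GenotypePanel:
    """Read ``prefix.{ped,map}`` or ``prefix.{bed,bim,fam}`` into a panel.

    The FAM/PED family-ID column is taken as the population label.
    """
    prefix = Path(prefix)
    if fmt == "bed":
        bim = pd.read_csv(
            prefix.with_suffix(".bim"),
            sep=r"\s+",
            header=None,
            names=["chromosome", "snp_id", "cm", "position_bp", "allele_a", "allele_b"],
            dtype={"chromosome": str, "snp_id": str, "allele_a": str, "allele_b": str},
        )
        fam = pd.read_csv(
            prefix.with_suffix(".fam"),
            sep=r"\s+",
            header=None,
            names=["population", "sample_id", "pat", "mat", "sex", "pheno"],
            dtype={"population": str, "sample_id": str},
        )
        with open(prefix.with_suffix(".bed"), "rb") as fh:
            header = fh.read(3)
            if len(header) != 3 or header[0] != 0x6C or header[1] != 0x1B:
                raise PanelFormatError("bad BED magic bytes")
            if header[2] != 0x01:
                raise PanelFormatError("only SNP-major BED (mode 0x01) is supported")
            dosages = _unpack_bed(fh.read(), len(fam), len(bim))
        markers = bim[["snp_id", "chromosome", "position_bp", "allele_a", "allele_b"]]
        samples = fam[["sample_id", "population"]]
        return GenotypePanel(dosages, samples, markers)
    if fmt == "ped":
        markers = _read_map(prefix.with_suffix(".map"))
        m = len(markers)
        sample_rows = []
        geno_rows = []
        with open(prefix.with_suffix(".ped")) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if len(parts) != 6 + 2 * m:
                    raise PanelIntegrityError(
                        f"PED record has {len(parts)} fields, expected {6 + 2 * m}"
                    )
                sample_rows.append((parts[1], parts[0]))
                geno_rows.append(parts[6:])
        alleles = np.array(geno_rows, dtype="U1").reshape(len(geno_rows), m, 2)
        allele_a = np.empty(m, dtype="U1")
        allele_b = np.empty(m, dtype="U1")
        dosages = np.empty((len(geno_rows), m), dtype=np.int8)
        for j in range(m):
            col = alleles[:, j, :]
            seen = sorted(set(col.ravel()) - {"0"})
            if len(seen) > 2:
                raise PanelFormatError(
                    f"marker {markers['snp_id'].iloc[j]} shows >2 alleles: {seen}"
                )
            if len(seen) == 2:
                allele_a[j], allele_b[j] = seen
            elif len(seen) == 1:
                allele_a[j], allele_b[j] = "0", seen[0]
            else:
                allele_a[j], allele_b[j] = "0", "0"
            miss = (col == "0").any(axis=1)
            nb = (col == allele_b[j]).sum(axis=1)
            dosages[:, j] = np.where(miss, MISSING, nb)
        markers = markers.assign(allele_a=allele_a, allele_b=allele_b)
        samples = pd.DataFrame(sample_rows, columns=["sample_id", "population"])
        return GenotypePanel(dosages, samples, markers[MARKER_COLUMNS])
    raise ValueError(f"unknown format {fmt!r} (expected 'ped' or 'bed')")
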