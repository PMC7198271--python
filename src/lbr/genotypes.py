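"""Genotype and phenotype containers plus PLINK 1 binary input/output.

The central container is :class:`GenotypePanel`, an n x p allele-dosage
matrix with SNP metadata (chromosome, base-pair position) and per-individual
sex labels.  Dosages count copies of the BIM A1 allele, following the PLINK 1
convention; missing genotypes are stored as NaN until :func:`impute_missing`
replaces them with the per-SNP mean computed over both sexes pooled.

Phenotypes are scaled to unit pooled variance (no centering — the model's
sex-specific intercepts absorb the means), so downstream window variances
read directly as proportions of phenotypic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "PhenotypeVector",
    "PlinkFormatError",
    "UnknownSexError",
    "read_plink",
    "write_plink",
    "read_phenotype_tsv",
    "impute_missing",
    "scale_phenotype",
]

MALE = "male"
FEMALE = "female"

_BED_MAGIC = bytes([0x6C, 0x1B])
_MODE_VARIANT_MAJOR = 0x01
# 2-bit code -> dosage of the A1 allele (PLINK 1 spec); 0b01 is missing.
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class PlinkFormatError(ValueError):
    """Raised when a PLINK file violates the binary/text format."""


class UnknownSexError(ValueError):
    """Raised when a FAM file carries a sex code other than 1 (male) or 2 (female)."""


@dataclass
class GenotypePanel:
    """n x p dosage matrix with SNP and individual metadata.

    Attributes
    ----------
    dosages
        Float array, entries in {0, 1, 2} or NaN (missing).
    snp_ids, chrom, bp
        Per-SNP identifier, chromosome label and 1-based position; positions
        must be strictly increasing within each chromosome.
    individual_ids, sex
        Per-individual identifier and label in {"male", "female"}.
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    bp: np.ndarray
    individual_ids: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if not np.issubdtype(self.dosages.dtype, np.floating):
            self.dosages = self.dosages.astype(np.float64)
        self.snp_ids = np.asarray(self.snp_ids)
        self.chrom = np.asarray(self.chrom)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.individual_ids = np.asarray(self.individual_ids)
        self.sex = np.asarray(self.sex)
        n, p = self.dosages.shape
        if not (len(self.snp_ids) == len(self.chrom) == len(self.bp) == p):
            raise ValueError("SNP metadata length does not match dosage columns")
        if not (len(self.individual_ids) == len(self.sex) == n):
            raise ValueError("individual metadata length does not match dosage rows")
        bad_sex = ~np.isin(self.sex, [MALE, FEMALE])
        if bad_sex.any():
            raise UnknownSexError(
                f"unrecognised sex labels: {set(self.sex[bad_sex])!r}"
            )
        for c in pd.unique(self.chrom):
            pos = self.bp[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"bp not strictly increasing on chromosome {c}")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    @property
    def is_male(self) -> np.ndarray:
        return self.sex == MALE

    @property
    def is_female(self) -> np.ndarray:
        return self.sex == FEMALE

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def subset_snps(self, idx: np.ndarray) -> "GenotypePanel":
        """Panel restricted to the given SNP indices (order preserved)."""
        idx = np.asarray(idx)
        return GenotypePanel(
            dosages=self.dosages[:, idx],
            snp_ids=self.snp_ids[idx],
            chrom=self.chrom[idx],
            bp=self.bp[idx],
            individual_ids=self.individual_ids,
            sex=self.sex,
        )


@dataclass
class PhenotypeVector:
    """Phenotype values with a flag recording unit-variance scaling."""

    values: np.ndarray
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scaled:
            v = self.values.var(ddof=1)
            if abs(v - 1.0) > 1e-8:
                raise ValueError(f"scaled flag set but variance is {v}")


def read_plink(bed_path, bim_path=None, fam_path=None, *, drop_unknown_sex: bool = False) -> GenotypePanel:
    """Read a PLINK 1 binary triplet into a :class:`GenotypePanel`.

    ``bim_path``/``fam_path`` default to ``bed_path`` with the extension
    swapped.  Sex is decoded from FAM column 5 (1=male, 2=female); any other
    code raises :class:`UnknownSexError` unless ``drop_unknown_sex`` is set,
    in which case those individuals are removed.
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path is not None else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path is not None else bed_path.with_suffix(".fam")

    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "bp", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex_code", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, p = len(fam), len(bim)

    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes {raw[:2]!r}")
    if raw[2] != _MODE_VARIANT_MAJOR:
        raise PlinkFormatError(f"{bed_path}: only variant-major (SNP-major) mode supported")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * p:
        raise PlinkFormatError(
            f"{bed_path}: expected {bytes_per_snp * p} data bytes for n={n}, p={p}, got {body.size}"
        )
    blocks = body.reshape(p, bytes_per_snp)
    # unpack 2-bit codes, low-order bits first within each byte
    codes = np.empty((p, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # -> n x p

    sex_code = fam["sex_code"].to_numpy()
    known = np.isin(sex_code, [1, 2])
    if not known.all():
        if not drop_unknown_sex:
            raise UnknownSexError(
                f"{fam_path}: sex codes {sorted(set(sex_code[~known]))} "
                "(use drop_unknown_sex=True to remove these individuals)"
            )
        dosages = dosages[known]
        fam = fam.loc[known].reset_index(drop=True)
        sex_code = sex_code[known]
    sex = np.where(sex_code == 1, MALE, FEMALE)

    return GenotypePanel(
        dosages=dosages,
        snp_ids=bim["snp_id"].to_numpy(),
        chrom=bim["chrom"].to_numpy(),
        bp=bim["bp"].to_numpy(),
        individual_ids=fam["iid"].to_numpy(),
        sex=sex,
    )


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write ``panel`` as PLINK 1 ``prefix.bed/.bim/.fam``.

    Dosages must be in {0, 1, 2} or NaN; fractional (imputed) dosages cannot
    be represented in the 2-bit encoding and raise ``ValueError``.
    """
    prefix = Path(prefix)
    d = panel.dosages
    ok = np.isnan(d) | np.isin(d, [0.0, 1.0, 2.0])
    if not ok.all():
        raise ValueError("write_plink requires dosages in {0,1,2} or NaN")

    n, p = d.shape
    code = np.full(d.shape, 0b01, dtype=np.uint8)  # missing
    code[d == 2.0] = 0b00
    code[d == 1.0] = 0b10
    code[d == 0.0] = 0b11
    pad = (-n) % 4
    if pad:
        code = np.concatenate([code, np.full((pad, p), 0b01, np.uint8)], axis=0)
    quads = code.T.reshape(p, -1, 4)
    packed = (
        quads[:, :, 0] | (quads[:, :, 1] << 2) | (quads[:, :, 2] << 4) | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_MODE_VARIANT_MAJOR]))
        fh.write(packed.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": panel.chrom,
            "snp_id": panel.snp_ids,
            "cm": 0,
            "bp": panel.bp,
            "a1": "A",
            "a2": "G",
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": panel.individual_ids,
            "iid": panel.individual_ids,
            "father": 0,
            "mother": 0,
            "sex_code": np.where(panel.sex == MALE, 1, 2),
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_phenotype_tsv(path, panel: GenotypePanel) -> np.ndarray:
    """Read a phenotype TSV (columns individual_id, phenotype) aligned to ``panel``.

    Every panel individual must be present exactly once in the file; extra
    rows are ignored.
    """
    df = pd.read_csv(path, sep="\t")
    if not {"individual_id", "phenotype"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns individual_id, phenotype")
    lookup = df.drop_duplicates("individual_id").set_index("individual_id")["phenotype"]
    ids = pd.Index(panel.individual_ids.astype(lookup.index.dtype, copy=False))
    missing = ids.difference(lookup.index)
    if len(missing):
        raise ValueError(f"{path}: no phenotype for individuals {list(missing[:5])} ...")
    return lookup.reindex(ids).to_numpy(dtype=float)


def impute_missing(panel: GenotypePanel) -> GenotypePanel:
    """Replace missing dosages by the per-SNP mean over non-missing individuals.

    Means are pooled across sexes, preserving per-SNP allele frequency.
    Non-missing entries are untouched.  A SNP with every entry missing is an
    error (its frequency is undefined).
    """
    d = panel.dosages
    nan_mask = np.isnan(d)
    if not nan_mask.any():
        return panel
    all_missing = nan_mask.all(axis=0)
    if all_missing.any():
        bad = panel.snp_ids[all_missing]
        raise ValueError(f"SNP(s) with all dosages missing: {list(bad[:5])}")
    col_means = np.nanmean(d, axis=0)
    filled = np.where(nan_mask, col_means[np.newaxis, :], d)
    return replace(panel, dosages=filled)


def scale_phenotype(y) -> PhenotypeVector:
    """Scale a phenotype to unit pooled sample variance (no centering).

    The model's sex-specific intercepts absorb the (sex) means, so only the
    scale is normalised; after scaling, genetic window variances are
    proportions of total phenotypic variance.  Idempotent within 1e-12.
    """
    if isinstance(y, PhenotypeVector):
        y = y.values
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two phenotype values")
    sd = y.std(ddof=1)
    if sd == 0:
        raise ValueError("phenotype is constant; cannot scale to unit variance")
    return PhenotypeVector(values=y / sd, scaled=True)
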