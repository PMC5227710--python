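"""Genotype and phenotype containers.

Genotype calls are stored as the count of *major* alleles per (individual,
SNP): 2 = major homozygote QQ, 1 = heterozygote Qq, 0 = minor homozygote qq,
-1 = missing.  This orientation matches the effect coding used by the full
genetic model, where the major homozygote carries the +1 additive
coefficient.  The single-locus baseline converts to minor-allele dosage
itself (see :mod:`fullgwas.single_locus`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: ethnic group labels in model order (group codes 1..4)
GROUP_LABELS = ("E-A", "C-A", "A-A", "H-A")
N_GROUPS = 4

SNP_META_COLUMNS = ["chrom", "id", "pos", "major", "minor"]


class CodingError(ValueError):
    """A genotype value outside {0, 1, 2, missing} was encountered."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs matrix of major-allele counts.

    Parameters
    ----------
    samples
        Ordered individual ids (unique).
    snps
        Per-SNP metadata frame with columns ``chrom, id, pos, major, minor``.
    calls
        ``int8`` array of shape ``(n_samples, n_snps)`` with values in
        ``{0, 1, 2}`` or ``-1`` for missing.
    """

    samples: np.ndarray
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids are not unique")
        ids = self.snps["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate SNP id {dup!r}")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CodingError(
                f"invalid call {self.calls[i, j]} for SNP "
                f"{self.snps['id'].iloc[j]!r}, sample {self.samples[i]!r}"
            )
        self.snps = self.snps.reset_index(drop=True)
        self._snp_index = {s: k for k, s in enumerate(self.snps["id"])}
        self._sample_index = {s: k for k, s in enumerate(self.samples)}

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_position(self, snp_id: str) -> int:
        try:
            return self._snp_index[snp_id]
        except KeyError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None

    def sample_position(self, sample_id) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def column(self, snp_id: str) -> np.ndarray:
        """Major-allele counts for one SNP across all samples."""
        return self.calls[:, self.snp_position(snp_id)]

    # -- summaries -------------------------------------------------------

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        return (self.calls != MISSING).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP (folded: always <= 0.5).

        SNPs with no observed calls get MAF 0.
        """
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        tot = np.where(self.calls == MISSING, 0, self.calls).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_major = np.where(n_obs > 0, tot / (2.0 * n_obs), 1.0)
        return np.minimum(p_major, 1.0 - p_major)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to a boolean mask or index array of SNPs."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=self.samples,
            snps=self.snps.iloc[keep].reset_index(drop=True),
            calls=self.calls[:, keep],
        )


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    n_fail_maf: int
    n_fail_call_rate: int
    maf_min: float
    call_rate_min: float


def qc_filter(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs with MAF or call rate below threshold.

    Exclusion is strict (``< threshold``): a SNP exactly at the boundary is
    retained.  No Hardy-Weinberg test is applied, because the populations
    handled here are ethnically heterogeneous and HWE is not expected to
    hold in the pooled sample.
    """
    if not (0.0 <= maf_min <= 1.0 and 0.0 <= call_rate_min <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    maf = genotypes.maf()
    cr = genotypes.call_rate()
    fail_maf = maf < maf_min
    fail_cr = cr < call_rate_min
    keep = ~(fail_maf | fail_cr)
    report = QCReport(
        n_input=genotypes.n_snps,
        n_kept=int(keep.sum()),
        n_fail_maf=int(fail_maf.sum()),
        n_fail_call_rate=int(fail_cr.sum()),
        maf_min=maf_min,
        call_rate_min=call_rate_min,
    )
    if report.n_kept == 0:
        import warnings

        warnings.warn("QC filter removed every SNP", stacklevel=2)
    return genotypes.subset_snps(keep), report


@dataclass
class PhenotypeTable:
    """Stacked phenotype records: one row per (individual, exam).

    Columns: ``iid`` (individual id), ``sex`` (0 female / 1 male),
    ``ethnicity`` (1=E-A, 2=C-A, 3=A-A, 4=H-A), ``exam`` (replication
    label), ``value`` (trait value, arbitrary units).  Repeated exam
    records of one individual are treated as replications by the mixed
    model; sex and ethnicity must be constant within individual.
    """

    records: pd.DataFrame = field(repr=False)

    REQUIRED = ("iid", "sex", "ethnicity", "exam", "value")

    def __post_init__(self) -> None:
        df = self.records
        missing_cols = [c for c in self.REQUIRED if c not in df.columns]
        if missing_cols:
            raise ValueError(f"phenotype table lacks columns {missing_cols}")
        df = df.reset_index(drop=True)
        if df.duplicated(subset=["iid", "exam"]).any():
            raise ValueError("duplicate (individual, exam) record")
        if not df["sex"].isin([0, 1]).all():
            raise ValueError("sex must be coded 0 (female) / 1 (male)")
        if not df["ethnicity"].isin([1, 2, 3, 4]).all():
            raise ValueError("ethnicity must be coded 1..4")
        per_ind = df.groupby("iid")[["sex", "ethnicity"]].nunique()
        if (per_ind > 1).any().any():
            raise ValueError("sex/ethnicity not constant within individual")
        if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite trait value")
        self.records = df

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def individuals(self) -> np.ndarray:
        """Unique individual ids in first-appearance order."""
        return self.records["iid"].drop_duplicates().to_numpy()

    def values(self) -> np.ndarray:
        return self.records["value"].to_numpy(dtype=float)

    def drop_records(self, mask: np.ndarray) -> "PhenotypeTable":
        """New table without the records flagged True in ``mask``."""
        return PhenotypeTable(self.records.loc[~np.asarray(mask)].reset_index(drop=True))
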