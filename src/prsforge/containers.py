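"""Core in-memory containers shared across the pipeline.

Genotypes are kept as an additive dosage matrix (samples x SNPs) counting
copies of the effect allele, which by convention is the minor allele in the
control stratum of the cohort that defined the panel.  Missing calls are
``NaN``.  Phenotypes and covariates live in a plain :class:`pandas.DataFrame`
with a documented column set (:data:`SAMPLE_COLUMNS`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical column set of a sample table.  ``status`` is "case"/"control";
#: ``er_status`` is "positive"/"negative" for cases and "unknown" for controls;
#: ``external_5yr_risk`` holds an externally computed 5-year absolute risk
#: (e.g. Gail-2 output) and may be NaN; ``pc1``/``pc2`` are filled in by
#: :func:`prsforge.prsmodels.compute_pcs`.
SAMPLE_COLUMNS = [
    "sample_id",
    "status",
    "er_status",
    "age",
    "bmi",
    "age_menarche",
    "live_births",
    "family_history",
    "menopausal",
    "external_5yr_risk",
    "pc1",
    "pc2",
]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive dosage matrix with per-SNP metadata.

    ``dosages`` is a float array; entries are 0/1/2 counts of the effect
    allele or NaN for missing calls (fractional values appear only after
    mean imputation).
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    effect_alleles: list[str]
    other_alleles: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValueError(
                f"dosage matrix is {self.dosages.shape} but there are "
                f"{len(self.sample_ids)} samples and {len(self.snp_ids)} SNPs"
            )
        if len(self.effect_alleles) != m or len(self.other_alleles) != m:
            raise ValueError("allele metadata length does not match SNP count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    @property
    def maf_observed(self) -> np.ndarray:
        """Per-SNP effect-allele frequency among observed calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask.mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask.mean(axis=1)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            list(self.snp_ids),
            self.dosages.copy(),
            list(self.effect_alleles),
            list(self.other_alleles),
        )

    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        snp_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        ki = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in si],
            [self.snp_ids[k] for k in ki],
            self.dosages[np.ix_(si, ki)],
            [self.effect_alleles[k] for k in ki],
            [self.other_alleles[k] for k in ki],
        )

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None


def empty_sample_table() -> pd.DataFrame:
    return pd.DataFrame(columns=SAMPLE_COLUMNS)


def validate_sample_table(t: pd.DataFrame) -> None:
    """Check the sample-table contract (columns, status/ER coding)."""
    missing = [c for c in ("sample_id", "status") if c not in t.columns]
    if missing:
        raise ValueError(f"sample table is missing columns {missing}")
    bad = set(t["status"].unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"unexpected status values {sorted(bad)}")
    if "er_status" in t.columns:
        ctrl = t.loc[t["status"] == "control", "er_status"]
        if not (ctrl.isin(["unknown"]) | ctrl.isna()).all():
            raise ValueError("controls must have er_status 'unknown'")


def status_to_binary(t: pd.DataFrame) -> np.ndarray:
    """0/1 vector (1 = case), aligned with the table's row order."""
    return (t["status"].to_numpy() == "case").astype(float)
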