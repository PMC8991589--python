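"""Genotype quality control for array-scale and small-panel cohorts.

Two regimes are covered by the same machinery and differ only in thresholds:

* array QC for a GWAS training cohort — SNP/sample call rate >= 99%,
  MAF >= 1%, stratified HWE exact test (P >= 1e-6 in controls, >= 1e-10 in
  cases), KING-robust kinship exclusion at phi > 0.0884;
* panel QC for a genotyped validation cohort — call rate >= 98%, blind
  duplicate concordance >= 99%, HWE P >= 0.05 in controls, monomorphic SNP
  removal, exclusion of samples with >= 3 failed (no-call) SNPs, and
  population-mean imputation of the surviving sporadic missingness.

Filters run in a fixed order and per-SNP statistics are recomputed after
every sample-removal step; imputation is strictly the final step and all
statistics are computed on observed (hard 0/1/2) calls only, which makes
:func:`apply_qc` idempotent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "array_thresholds",
    "panel_thresholds",
    "hwe_exact_test",
    "king_kinship",
    "king_kinship_matrix",
    "duplicate_concordance",
    "mean_impute",
    "apply_qc",
]


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; ``None`` disables the corresponding filter."""

    snp_call_rate_min: float | None = None
    sample_call_rate_min: float | None = None
    maf_min: float | None = None
    hwe_p_min_controls: float | None = None
    hwe_p_min_cases: float | None = None
    kinship_max: float | None = None
    duplicate_concordance_min: float | None = None
    max_failed_snps_per_sample: int | None = None
    drop_monomorphic: bool = False

    def __post_init__(self) -> None:
        for name in (
            "snp_call_rate_min",
            "sample_call_rate_min",
            "maf_min",
            "hwe_p_min_controls",
            "hwe_p_min_cases",
            "duplicate_concordance_min",
        ):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.kinship_max is not None and self.kinship_max < 0:
            raise ValueError("kinship_max must be >= 0")


def array_thresholds() -> QCThresholds:
    """GWAS-array regime: call rate 99%, MAF 1%, stratified HWE, kinship."""
    return QCThresholds(
        snp_call_rate_min=0.99,
        sample_call_rate_min=0.99,
        maf_min=0.01,
        hwe_p_min_controls=1e-6,
        hwe_p_min_cases=1e-10,
        kinship_max=0.0884,
    )


def panel_thresholds() -> QCThresholds:
    """Validation-panel regime: call rate 98%, duplicate concordance 99%,
    HWE P 0.05 in controls, monomorphic removal, >=3 failed SNPs per sample."""
    return QCThresholds(
        snp_call_rate_min=0.98,
        hwe_p_min_controls=0.05,
        duplicate_concordance_min=0.99,
        max_failed_snps_per_sample=3,
        drop_monomorphic=True,
    )


@dataclass
class QCReport:
    snp_decisions: pd.DataFrame
    sample_decisions: pd.DataFrame
    kinship_pairs: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def n_removed_snps(self) -> int:
        return int((~self.snp_decisions["pass"]).sum())

    def n_removed_samples(self) -> int:
        return int((~self.sample_decisions["pass"]).sum())


# ---------------------------------------------------------------------------
# primitives


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test P-value.

    Conditions on the observed allele counts and sums, over all heterozygote
    counts of the same parity, the hypergeometric probabilities of every
    genotype configuration no more probable than the observed one.  Returns a
    value in (0, 1]; monomorphic tables have a single attainable
    configuration and return 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count must be > 0")
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if rare == 0:
        return 1.0

    def log_prob(het: int) -> float:
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        return (
            gammaln(n + 1)
            - gammaln(hom_rare + 1)
            - gammaln(het + 1)
            - gammaln(hom_common + 1)
            + het * math.log(2.0)
            + gammaln(rare + 1)
            + gammaln(2 * n - rare + 1)
            - gammaln(2 * n + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    logs = np.array([log_prob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = (n_Aa - rare % 2) // 2
    p = float(probs[probs <= probs[obs] * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def _genotype_classes(dosages: np.ndarray) -> tuple[np.ndarray, ...]:
    """Boolean masks for hard genotype calls (fractional/imputed entries are
    not counted in any class)."""
    with np.errstate(invalid="ignore"):
        hom0 = dosages == 0.0
        het = dosages == 1.0
        hom2 = dosages == 2.0
    return hom0, het, hom2


def king_kinship(dos_i: np.ndarray, dos_j: np.ndarray) -> float:
    """KING-robust between-family kinship estimate for one sample pair.

    phi = (N_AaAa - 2 N_opp) / (N_Aa(i) + N_Aa(j)) over loci non-missing in
    both samples; NaN when neither sample has a heterozygous locus there.
    """
    a = np.asarray(dos_i, dtype=float)
    b = np.asarray(dos_j, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have the same length")
    mask = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[mask], b[mask]
    het_i = a == 1.0
    het_j = b == 1.0
    n_het_het = int(np.sum(het_i & het_j))
    n_opp = int(np.sum(((a == 0.0) & (b == 2.0)) | ((a == 2.0) & (b == 0.0))))
    denom = int(het_i.sum()) + int(het_j.sum())
    if denom == 0:
        return float("nan")
    return (n_het_het - 2.0 * n_opp) / denom


def king_kinship_matrix(g: GenotypeMatrix) -> np.ndarray:
    """All-pairs KING-robust kinship (NaN where not evaluable)."""
    hom0, het, hom2 = _genotype_classes(g.dosages)
    obs = ~g.missing_mask
    H = het.astype(float)
    n_het_het = H @ H.T
    n_opp = hom0.astype(float) @ hom2.astype(float).T
    n_opp = n_opp + n_opp.T
    het_in_obs = H @ obs.astype(float).T  # het loci of i that are observed in j
    denom = het_in_obs + het_in_obs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (n_het_het - 2.0 * n_opp) / denom
    phi[denom == 0] = np.nan
    return phi


def duplicate_concordance(dos_a: np.ndarray, dos_b: np.ndarray) -> np.ndarray:
    """Per-SNP concordance across blind-duplicate pairs.

    Inputs are (n_pairs, n_snps) dosage arrays (a 1-D pair is promoted);
    returns the fraction of jointly non-missing calls that agree, NaN where a
    SNP has no evaluable pair.
    """
    a = np.atleast_2d(np.asarray(dos_a, dtype=float))
    b = np.atleast_2d(np.asarray(dos_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("duplicate arrays must have the same shape")
    ok = ~np.isnan(a) & ~np.isnan(b)
    agree = (a == b) & ok
    n_ok = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = agree.sum(axis=0) / n_ok
    conc = np.asarray(conc, dtype=float)
    conc[n_ok == 0] = np.nan
    return conc


def mean_impute(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the SNP's mean observed dosage (cases and
    controls combined); imputed values may be fractional."""
    out = g.copy()
    miss = out.missing_mask
    if not miss.any():
        return out
    if miss.all(axis=0).any():
        bad = [out.snp_ids[k] for k in np.flatnonzero(miss.all(axis=0))]
        raise ValueError(f"all-missing SNPs cannot be imputed: {bad}")
    col_mean = np.nanmean(out.dosages, axis=0)
    rows, cols = np.nonzero(miss)
    out.dosages[rows, cols] = col_mean[cols]
    return out


# ---------------------------------------------------------------------------
# the QC pipeline


def _hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    hom0, het, hom2 = _genotype_classes(dosages)
    out = np.empty(dosages.shape[1])
    for k in range(dosages.shape[1]):
        n0, n1, n2 = int(hom0[:, k].sum()), int(het[:, k].sum()), int(hom2[:, k].sum())
        out[k] = hwe_exact_test(n0, n1, n2) if (n0 + n1 + n2) else 1.0
    return out


def apply_qc(
    g: GenotypeMatrix,
    t: pd.DataFrame,
    thresholds: QCThresholds,
    duplicates: list[tuple[str, str]] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, QCReport]:
    """Run the ordered QC filter cascade and return the cleaned cohort.

    Order: SNP call rate -> sample call rate -> MAF -> HWE (controls, then
    cases stratum) -> duplicate concordance -> monomorphic -> kinship ->
    failed-SNP-count sample exclusion -> mean imputation.  ``duplicates``
    lists blind-duplicate sample-id pairs; the second member of each pair is
    removed after the concordance filter.  Raises if any filter empties the
    cohort.
    """
    th = thresholds
    snp_ids = list(g.snp_ids)
    sample_ids = list(g.sample_ids)
    snp_reasons: dict[str, list[str]] = {s: [] for s in snp_ids}
    sample_reasons: dict[str, list[str]] = {s: [] for s in sample_ids}
    snp_metrics: dict[str, dict] = {s: {} for s in snp_ids}
    sample_metrics: dict[str, dict] = {s: {} for s in sample_ids}

    work = g.copy()
    pheno = t.set_index("sample_id", drop=False)

    def drop_snps(mask_fail: np.ndarray, reason: str, values: np.ndarray) -> None:
        nonlocal work
        for k in np.flatnonzero(mask_fail):
            sid = work.snp_ids[k]
            snp_reasons[sid].append(reason)
            snp_metrics[sid][reason] = float(values[k])
        if mask_fail.any():
            work = work.subset(snp_idx=np.flatnonzero(~mask_fail))
        if work.n_snps == 0:
            raise RuntimeError(f"QC filter {reason!r} removed every SNP")

    def drop_samples(fail_ids: list[str], reason: str, values: dict[str, float]) -> None:
        nonlocal work
        for sid in fail_ids:
            sample_reasons[sid].append(reason)
            if sid in values:
                sample_metrics[sid][reason] = float(values[sid])
        if fail_ids:
            keep = [i for i, sid in enumerate(work.sample_ids) if sid not in set(fail_ids)]
            work = work.subset(sample_idx=keep)
        if work.n_samples == 0:
            raise RuntimeError(f"QC filter {reason!r} removed every sample")

    # 1. SNP call rate
    if th.snp_call_rate_min is not None:
        cr = work.snp_call_rate()
        drop_snps(cr < th.snp_call_rate_min, "call_rate", cr)

    # 2. sample call rate
    if th.sample_call_rate_min is not None:
        cr = work.sample_call_rate()
        fail = [work.sample_ids[i] for i in np.flatnonzero(cr < th.sample_call_rate_min)]
        drop_samples(fail, "call_rate", dict(zip(work.sample_ids, cr)))

    # 3. MAF
    if th.maf_min is not None:
        maf = np.minimum(work.maf_observed, 1.0 - work.maf_observed)
        drop_snps(maf < th.maf_min, "maf", maf)

    # 4. HWE, stratified
    status = pheno.loc[work.sample_ids, "status"].to_numpy()
    for stratum, pmin, reason in (
        ("control", th.hwe_p_min_controls, "hwe_controls"),
        ("case", th.hwe_p_min_cases, "hwe_cases"),
    ):
        if pmin is None:
            continue
        rows = np.flatnonzero(status == stratum)
        if len(rows) == 0:
            continue
        pvals = _hwe_pvalues(work.dosages[rows])
        drop_snps(pvals < pmin, reason, pvals)
        status = pheno.loc[work.sample_ids, "status"].to_numpy()

    # 5. duplicate concordance
    dup_second = []
    if th.duplicate_concordance_min is not None:
        pairs = [
            (a, b)
            for a, b in (duplicates or [])
            if a in work.sample_ids and b in work.sample_ids
        ]
        if not pairs:
            warnings.warn(
                "duplicate-concordance filter requested but no duplicate "
                "pairs supplied; filter skipped",
                stacklevel=2,
            )
        else:
            ia = [work.sample_ids.index(a) for a, _ in pairs]
            ib = [work.sample_ids.index(b) for _, b in pairs]
            conc = duplicate_concordance(work.dosages[ia], work.dosages[ib])
            fail = ~np.isnan(conc) & (conc < th.duplicate_concordance_min)
            drop_snps(fail, "duplicate_concordance", np.where(np.isnan(conc), 1.0, conc))
            dup_second = [b for _, b in pairs]
            drop_samples(dup_second, "blind_duplicate", {})

    # 6. monomorphic
    if th.drop_monomorphic:
        hom0, het, hom2 = _genotype_classes(work.dosages)
        counts = np.stack([hom0.sum(0), het.sum(0), hom2.sum(0)])
        mono = (counts > 0).sum(axis=0) <= 1
        drop_snps(mono, "monomorphic", mono.astype(float))

    # 7. kinship
    kin_rows = []
    if th.kinship_max is not None and work.n_samples > 1:
        phi = king_kinship_matrix(work)
        call = work.sample_call_rate()
        flagged = []
        iu, ju = np.triu_indices(work.n_samples, k=1)
        hit = ~np.isnan(phi[iu, ju]) & (phi[iu, ju] > th.kinship_max)
        for i, j in zip(iu[hit], ju[hit]):
            flagged.append((i, j, phi[i, j]))
            kin_rows.append((work.sample_ids[i], work.sample_ids[j], float(phi[i, j])))
        removed: set[str] = set()
        for i, j, ph in flagged:
            sid_i, sid_j = work.sample_ids[i], work.sample_ids[j]
            if sid_i in removed or sid_j in removed:
                continue
            # remove the lower-call-rate member; ties keep the earlier sample
            victim = sid_j if call[j] <= call[i] else sid_i
            removed.add(victim)
        drop_samples(sorted(removed, key=work.sample_ids.index), "kinship",
                     {})

    # 8. failed-SNP count per sample (no-calls among surviving SNPs)
    if th.max_failed_snps_per_sample is not None:
        n_fail = work.missing_mask.sum(axis=1)
        fail = [
            work.sample_ids[i]
            for i in np.flatnonzero(n_fail >= th.max_failed_snps_per_sample)
        ]
        drop_samples(fail, "failed_snps", dict(zip(work.sample_ids, n_fail.astype(float))))

    # 9. mean imputation of surviving sporadic missingness
    if work.missing_mask.any():
        work = mean_impute(work)

    snp_df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "pass": [not snp_reasons[s] for s in snp_ids],
            "reasons": [",".join(snp_reasons[s]) for s in snp_ids],
            "metrics": [snp_metrics[s] for s in snp_ids],
        }
    )
    sample_df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "pass": [not sample_reasons[s] for s in sample_ids],
            "reasons": [",".join(sample_reasons[s]) for s in sample_ids],
            "metrics": [sample_metrics[s] for s in sample_ids],
        }
    )
    kin_df = pd.DataFrame(kin_rows, columns=["sample_i", "sample_j", "phi"])
    report = QCReport(
        snp_decisions=snp_df,
        sample_decisions=sample_df,
        kinship_pairs=kin_df,
        summary={
            "snps_in": len(snp_ids),
            "snps_out": work.n_snps,
            "samples_in": len(sample_ids),
            "samples_out": work.n_samples,
        },
    )
    t_out = pheno.loc[work.sample_ids].reset_index(drop=True)
    return work, t_out, report
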