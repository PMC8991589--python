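"""Synthetic GWAS-like training and case-control validation cohorts.

The generator emulates the statistical structure a small-panel breast-cancer
PRS analysis assumes: SNP dosages drawn in Hardy-Weinberg equilibrium with
optional block LD at a target composite r-squared, disease status from an
additive logistic liability with per-SNP log odds ratios, covariate effects
and optional pairwise SNP x SNP interaction terms, estrogen-receptor subtype
labels for cases, sporadic missingness, and planted duplicate / related
sample pairs for relatedness QC.

LD construction
---------------
Within an LD block each haplotype carries a shared latent Bernoulli allele
``Z ~ Bern(p0)`` (``p0`` = block mean MAF).  Each SNP copies ``Z`` with
probability ``c`` and otherwise redraws an independent allele whose frequency
is adjusted so the SNP's marginal MAF is preserved exactly.  The haplotype
correlation between two block members is then ``c**2 * p0*(1-p0) /
sqrt(v_i*v_j)`` and the dosage (composite) correlation equals the haplotype
correlation, so ``c`` is solved from the target r-squared in closed form; for
equal MAFs ``c = target_r2 ** 0.25``.

Case-control ascertainment
--------------------------
The liability intercept ``alpha`` is calibrated by bisection (tolerance 1e-4
on the prevalence scale) so the expected case probability over a simulated
reference pool matches ``n_cases / (n_cases + n_controls)``; samples are then
drawn in batches and kept until exactly the requested numbers of cases and
controls are collected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SAMPLE_COLUMNS, GenotypeMatrix

__all__ = [
    "SNPSpec",
    "SimulationConfig",
    "simulate_cohort",
    "inject_missingness",
    "add_related_samples",
    "default_panel",
    "two_population_genotypes",
]

#: Reference values subtracted from covariates before applying log-OR effects,
#: so the calibrated intercept corresponds to a typical participant.
COVARIATE_REFERENCE = {
    "age": 52.5,
    "bmi": 23.5,
    "age_menarche": 14.0,
    "live_births": 1.2,
    "family_history": 0.0,
    "menopausal": 0.0,
    "external_5yr_risk": 0.0054,
}

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


@dataclass(frozen=True)
class SNPSpec:
    """One simulated SNP: identifier, minor-allele frequency, per-allele
    log odds ratio, and optional LD-block membership ``(block_id, target_r2)``."""

    snp_id: str
    maf: float
    log_or: float = 0.0
    ld_block: tuple[object, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf must be in (0, 0.5], got {self.maf}")
        if self.ld_block is not None:
            r2 = self.ld_block[1]
            if not (0.0 <= r2 <= 1.0):
                raise ValueError(f"{self.snp_id}: target_r2 must be in [0,1], got {r2}")


@dataclass
class SimulationConfig:
    n_cases: int
    n_controls: int
    snps: list[SNPSpec]
    covariate_effects: dict[str, float] = field(default_factory=dict)
    interaction_terms: list[tuple[str, str, float]] = field(default_factory=list)
    er_pos_fraction: float = 0.66
    subtype_effect_overrides: dict[str, tuple[float, float]] | None = None
    missing_rate: float = 0.0
    n_duplicate_pairs: int = 0
    n_related_pairs: int = 0
    related_degree: str = "parent_offspring"
    genotype_covariate_corr: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("counts must be >= 0")
        if self.n_cases + self.n_controls == 0:
            raise ValueError("cohort must contain at least one sample")
        if not self.snps:
            raise ValueError("at least one SNP is required")
        if not (0.0 < self.er_pos_fraction <= 1.0):
            raise ValueError("er_pos_fraction must be in (0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_duplicate_pairs < 0 or self.n_related_pairs < 0:
            raise ValueError("pair counts must be >= 0")
        ids = {s.snp_id for s in self.snps}
        if len(ids) != len(self.snps):
            raise ValueError("duplicate snp_id in panel")
        for a, b, _ in self.interaction_terms:
            if a not in ids or b not in ids:
                raise ValueError(f"interaction SNPs ({a}, {b}) must be in the panel")
        unknown = set(self.covariate_effects) - set(COVARIATE_REFERENCE)
        if unknown:
            raise ValueError(f"unknown covariates {sorted(unknown)}")


def default_panel(
    n_snps: int = 24,
    seed: int = 7,
    effect_scale: float = 0.12,
    n_ld_blocks: int = 2,
    block_r2: float = 0.8,
) -> list[SNPSpec]:
    """A realistic demo panel: MAFs uniform on (0.05, 0.45), log-ORs
    N(0, effect_scale), and ``n_ld_blocks`` two-SNP blocks at ``block_r2``."""
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(0.05, 0.45, n_snps)
    lors = rng.normal(0.0, effect_scale, n_snps)
    specs = []
    for k in range(n_snps):
        block = None
        if k < 2 * n_ld_blocks:
            block = (f"blk{k // 2}", block_r2)
            # members of a block share the block-leader MAF so the target
            # composite r2 is attainable exactly
            mafs[k] = mafs[2 * (k // 2)]
        specs.append(SNPSpec(f"rs{1000 + k}", float(mafs[k]), float(lors[k]), block))
    return specs


# ---------------------------------------------------------------------------
# genotype drawing


def _block_copy_prob(mafs: np.ndarray, target_r2: float) -> tuple[float, float]:
    """Solve the latent-copy probability for a block: returns (p0, c)."""
    p0 = float(np.mean(mafs))
    if target_r2 <= 0.0:
        return p0, 0.0
    v0 = p0 * (1.0 - p0)
    vbar = float(np.exp(np.mean(np.log(mafs * (1.0 - mafs)))))  # geometric mean var
    c2 = math.sqrt(target_r2) * math.sqrt(vbar) * math.sqrt(vbar) / v0
    # equal-MAF case reduces to c = target_r2 ** 0.25
    c = min(1.0, math.sqrt(c2))
    return p0, c


def _draw_block_haplotype(
    rng: np.random.Generator, n: int, mafs: np.ndarray, p0: float, c: float
) -> np.ndarray:
    z = rng.random(n) < p0
    out = np.empty((n, len(mafs)), dtype=bool)
    for j, p in enumerate(mafs):
        if c >= 1.0:
            out[:, j] = z
            continue
        p_adj = (p - c * p0) / (1.0 - c)
        p_adj = min(1.0, max(0.0, p_adj))
        copy = rng.random(n) < c
        fresh = rng.random(n) < p_adj
        out[:, j] = np.where(copy, z, fresh)
    return out


def _draw_dosages(specs: list[SNPSpec], n: int, rng: np.random.Generator) -> np.ndarray:
    m = len(specs)
    dos = np.empty((n, m), dtype=float)
    blocks: dict[object, list[int]] = {}
    for k, s in enumerate(specs):
        if s.ld_block is None:
            p = s.maf
            dos[:, k] = (rng.random(n) < p).astype(float) + (rng.random(n) < p)
        else:
            blocks.setdefault(s.ld_block[0], []).append(k)
    for block_id, idx in blocks.items():
        mafs = np.array([specs[k].maf for k in idx])
        target = specs[idx[0]].ld_block[1]
        p0, c = _block_copy_prob(mafs, target)
        h1 = _draw_block_haplotype(rng, n, mafs, p0, c)
        h2 = _draw_block_haplotype(rng, n, mafs, p0, c)
        dos[:, idx] = h1.astype(float) + h2.astype(float)
    return dos


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = rng.uniform(35.0, 70.0, n)
    bmi = np.clip(rng.normal(23.5, 3.0, n), 15.0, 40.0)
    menarche = np.clip(np.round(rng.normal(14.0, 1.5, n)), 10, 18)
    births = np.clip(rng.poisson(1.2, n), 0, 6)
    famhist = rng.random(n) < 0.02
    menopausal = age > rng.normal(49.5, 2.0, n)
    risk = np.clip(np.exp(rng.normal(np.log(0.0054), 0.4, n)), 1e-4, 0.2)
    return pd.DataFrame(
        {
            "age": age,
            "bmi": bmi,
            "age_menarche": menarche,
            "live_births": births.astype(float),
            "family_history": famhist,
            "menopausal": menopausal,
            "external_5yr_risk": risk,
        }
    )


def _covariate_liability(cov: pd.DataFrame, effects: dict[str, float]) -> np.ndarray:
    eta = np.zeros(len(cov))
    for name, beta in effects.items():
        x = cov[name].to_numpy(dtype=float)
        eta += beta * (x - COVARIATE_REFERENCE[name])
    return eta


def _genetic_liability(
    dos: np.ndarray,
    betas: np.ndarray,
    interactions: list[tuple[int, int, float]],
) -> np.ndarray:
    eta = dos @ betas
    for i, j, delta in interactions:
        eta = eta + delta * dos[:, i] * dos[:, j]
    return eta


def _calibrate_alpha(eta_pool: np.ndarray, target: float, tol: float = 1e-4) -> float:
    """Bisection on the intercept so mean sigmoid(alpha + eta) == target."""

    def prev(alpha: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + eta_pool)))))

    lo, hi = -40.0, 40.0
    if prev(lo) > target or prev(hi) < target:
        raise RuntimeError("target case fraction unreachable for this liability model")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if prev(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    alpha = 0.5 * (lo + hi)
    if abs(prev(alpha) - target) > tol:
        raise RuntimeError("intercept calibration did not converge")
    return alpha


def simulate_cohort(config: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw a case-control cohort with exactly the configured class sizes.

    Returns the dosage matrix and a sample table with phenotype, ER subtype
    and covariates.  Fully reproducible from ``config.seed``.
    """
    config.validate()
    specs = config.snps
    m = len(specs)
    idx = {s.snp_id: k for k, s in enumerate(specs)}
    interactions = [(idx[a], idx[b], d) for a, b, d in config.interaction_terms]
    betas = np.array([s.log_or for s in specs])

    ss = np.random.SeedSequence(config.seed)
    rng_cal, rng_draw, rng_sub, rng_rel, rng_miss = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]

    n_cases, n_controls = config.n_cases, config.n_controls
    n_total = n_cases + n_controls
    target = n_cases / n_total

    subtype_mode = config.subtype_effect_overrides is not None
    if subtype_mode:
        betas_pos = betas.copy()
        betas_neg = betas.copy()
        for snp_id, (b_pos, b_neg) in config.subtype_effect_overrides.items():
            if snp_id not in idx:
                raise ValueError(f"override SNP {snp_id!r} not in panel")
            betas_pos[idx[snp_id]] = b_pos
            betas_neg[idx[snp_id]] = b_neg

    # calibration pool
    n_pool = int(min(50_000, max(5_000, 2 * n_total)))
    pool_dos = _draw_dosages(specs, n_pool, rng_cal)
    pool_cov = _draw_covariates(n_pool, rng_cal)
    eta_cov = _covariate_liability(pool_cov, config.covariate_effects)
    if subtype_mode:
        eta_pos = _genetic_liability(pool_dos, betas_pos, interactions) + eta_cov
        eta_neg = _genetic_liability(pool_dos, betas_neg, interactions) + eta_cov
        alpha_pos = _calibrate_alpha(eta_pos, target * config.er_pos_fraction)
        alpha_neg = _calibrate_alpha(eta_neg, target * (1.0 - config.er_pos_fraction)) \
            if config.er_pos_fraction < 1.0 else -np.inf
    else:
        eta = _genetic_liability(pool_dos, betas, interactions) + eta_cov
        alpha = _calibrate_alpha(eta, target)

    # rejection sampling until both strata are full
    case_dos, case_cov, case_er = [], [], []
    ctrl_dos, ctrl_cov = [], []
    got_cases = got_controls = 0
    batch = int(min(100_000, max(2048, 2 * n_total)))
    for _ in range(2000):
        if got_cases >= n_cases and got_controls >= n_controls:
            break
        dos = _draw_dosages(specs, batch, rng_draw)
        cov = _draw_covariates(batch, rng_draw)
        ec = _covariate_liability(cov, config.covariate_effects)
        if subtype_mode:
            pp = 1.0 / (1.0 + np.exp(-(alpha_pos + _genetic_liability(dos, betas_pos, interactions) + ec)))
            pn = (
                1.0 / (1.0 + np.exp(-(alpha_neg + _genetic_liability(dos, betas_neg, interactions) + ec)))
                if np.isfinite(alpha_neg)
                else np.zeros(batch)
            )
            p_case = 1.0 - (1.0 - pp) * (1.0 - pn)
            is_case = rng_draw.random(batch) < p_case
            with np.errstate(invalid="ignore", divide="ignore"):
                frac_pos = np.where(pp + pn > 0, pp / np.maximum(pp + pn, 1e-300), 1.0)
            er_pos = rng_draw.random(batch) < frac_pos
        else:
            p_case = 1.0 / (1.0 + np.exp(-(alpha + _genetic_liability(dos, betas, interactions) + ec)))
            is_case = rng_draw.random(batch) < p_case
            er_pos = np.zeros(batch, dtype=bool)  # assigned by thinning below
        for stratum, take in (("case", is_case), ("control", ~is_case)):
            if stratum == "case" and got_cases < n_cases:
                sel = np.flatnonzero(take)[: n_cases - got_cases]
                case_dos.append(dos[sel])
                case_cov.append(cov.iloc[sel])
                case_er.append(er_pos[sel])
                got_cases += len(sel)
            elif stratum == "control" and got_controls < n_controls:
                sel = np.flatnonzero(take)[: n_controls - got_controls]
                ctrl_dos.append(dos[sel])
                ctrl_cov.append(cov.iloc[sel])
                got_controls += len(sel)
    if got_cases < n_cases or got_controls < n_controls:
        raise RuntimeError(
            f"could not collect {n_cases} cases / {n_controls} controls; "
            "the liability model makes the case fraction unreachable"
        )

    dos = np.vstack([a for part in (case_dos, ctrl_dos) for a in part]) if n_total else np.empty((0, m))
    cov = pd.concat(
        [c for part in (case_cov, ctrl_cov) for c in part], ignore_index=True
    )
    if config.genotype_covariate_corr:
        # robustness switch: tilt age along the first SNP's standardized dosage
        x0 = dos[:, 0]
        sd = x0.std() or 1.0
        cov["age"] = cov["age"].to_numpy() + (
            config.genotype_covariate_corr * 10.0 * (x0 - x0.mean()) / sd
        )
    status = np.array(["case"] * n_cases + ["control"] * n_controls)
    if subtype_mode:
        er_case = np.concatenate(case_er) if n_cases else np.array([], dtype=bool)
    else:
        er_case = rng_sub.random(n_cases) < config.er_pos_fraction
    er = np.full(n_total, "unknown", dtype=object)
    er[:n_cases] = np.where(er_case, "positive", "negative")

    # shuffle rows so case/control order carries no information
    perm = rng_sub.permutation(n_total)
    dos = dos[perm]
    cov = cov.iloc[perm].reset_index(drop=True)
    status = status[perm]
    er = er[perm]

    sample_ids = [f"S{i:06d}" for i in range(n_total)]
    alleles = [_ALLELE_PAIRS[k % len(_ALLELE_PAIRS)] for k in range(m)]
    g = GenotypeMatrix(
        sample_ids,
        [s.snp_id for s in specs],
        dos,
        [a for a, _ in alleles],
        [b for _, b in alleles],
    )
    t = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "status": status,
            "er_status": er,
            **{c: cov[c].to_numpy() for c in cov.columns},
            "pc1": np.nan,
            "pc2": np.nan,
        }
    )[SAMPLE_COLUMNS]

    if config.n_duplicate_pairs:
        g, t = add_related_samples(
            g, t, "duplicate", config.n_duplicate_pairs,
            seed=int(rng_rel.integers(2**31)),
        )
    if config.n_related_pairs:
        g, t = add_related_samples(
            g, t, config.related_degree, config.n_related_pairs,
            seed=int(rng_rel.integers(2**31)),
        )
    if config.missing_rate > 0:
        g = inject_missingness(g, config.missing_rate, seed=int(rng_miss.integers(2**31)))
    return g, t


def inject_missingness(g: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set each dosage to missing independently with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    out = g.copy()
    if rate > 0.0:
        rng = np.random.default_rng(seed)
        mask = rng.random(out.dosages.shape) < rate
        out.dosages[mask] = np.nan
    return out


def two_population_genotypes(
    n_per_pop: int,
    n_snps: int,
    maf_shift: float = 0.1,
    seed: int = 0,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Two subpopulations with shifted MAFs, for population-structure tests.

    Population 0 draws SNP k at frequency ``p_k``; population 1 at
    ``p_k + maf_shift`` (clipped).  Returns the matrix and the 0/1
    subpopulation labels.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.1, 0.4, n_snps)
    labels = np.repeat([0, 1], n_per_pop)
    dos = np.empty((2 * n_per_pop, n_snps))
    for pop, shift in ((0, 0.0), (1, maf_shift)):
        p = np.clip(base + shift, 0.01, 0.99)
        rows = slice(pop * n_per_pop, (pop + 1) * n_per_pop)
        dos[rows] = (rng.random((n_per_pop, n_snps)) < p).astype(float) + (
            rng.random((n_per_pop, n_snps)) < p
        )
    alleles = [_ALLELE_PAIRS[k % len(_ALLELE_PAIRS)] for k in range(n_snps)]
    g = GenotypeMatrix(
        [f"P{l}S{i:05d}" for i, l in enumerate(labels)],
        [f"ps{k}" for k in range(n_snps)],
        dos,
        [a for a, _ in alleles],
        [b for _, b in alleles],
    )
    return g, labels


_RELATION_SUFFIX = {"duplicate": "dup", "parent_offspring": "off", "second_degree": "sd"}


def add_related_samples(
    g: GenotypeMatrix,
    t: pd.DataFrame,
    relationship: str,
    n_pairs: int,
    seed: int,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Append samples genetically related to existing cohort members.

    ``duplicate`` copies dosages exactly; ``parent_offspring`` transmits one
    allele per locus from the base sample (the other drawn at the population
    frequency); ``second_degree`` transmits with probability 1/2 per locus
    (kinship 1/8).  New samples copy the base member's phenotype row under a
    fresh sample id.
    """
    if relationship not in _RELATION_SUFFIX:
        raise ValueError(f"unknown relationship {relationship!r}")
    if g.n_samples == 0:
        raise ValueError("base cohort is empty")
    rng = np.random.default_rng(seed)
    base_idx = rng.choice(g.n_samples, size=n_pairs, replace=n_pairs > g.n_samples)
    p = np.clip(g.maf_observed, 1e-6, 1 - 1e-6)
    new_rows, new_ids = [], []
    suffix = _RELATION_SUFFIX[relationship]
    for i, b in enumerate(base_idx):
        base = g.dosages[b]
        obs = np.where(np.isnan(base), 2 * p, base)  # transmit from imputed freq if missing
        if relationship == "duplicate":
            row = base.copy()
        else:
            transmitted = (rng.random(g.n_snps) < obs / 2.0).astype(float)
            if relationship == "second_degree":
                pop = (rng.random(g.n_snps) < p).astype(float)
                path = rng.random(g.n_snps) < 0.5
                transmitted = np.where(path, transmitted, pop)
            other = (rng.random(g.n_snps) < p).astype(float)
            row = transmitted + other
        new_rows.append(row)
        new_ids.append(f"{g.sample_ids[b]}_{suffix}{i}")
    out = GenotypeMatrix(
        g.sample_ids + new_ids,
        list(g.snp_ids),
        np.vstack([g.dosages, np.array(new_rows)]) if n_pairs else g.dosages.copy(),
        list(g.effect_alleles),
        list(g.other_alleles),
    )
    extra = t.iloc[base_idx].copy()
    extra["sample_id"] = new_ids
    t_out = pd.concat([t, extra], ignore_index=True)
    return out, t_out
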