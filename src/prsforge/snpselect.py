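"""SNP selection: composite LD, proxy substitution, tight-LD pruning,
genome-wide significance screening and cross-dataset direction concordance.

LD is measured as the squared Pearson correlation of dosage vectors
(composite LD), the appropriate measure when phase is unobserved; values
from haplotype-based reference tools can differ slightly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import GenotypeMatrix, status_to_binary

__all__ = [
    "LDMatrix",
    "SelectionDecision",
    "ld_r2",
    "ld_matrix",
    "find_proxy",
    "prune_tight_ld",
    "significance_filter",
    "direction_concordance",
]


@dataclass
class LDMatrix:
    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.snp_ids)
        if self.r2.shape != (m, m):
            raise ValueError("r2 matrix shape does not match snp_ids")

    def lookup(self, a: str, b: str) -> float:
        i = self.snp_ids.index(a)
        j = self.snp_ids.index(b)
        return float(self.r2[i, j])


@dataclass(frozen=True)
class SelectionDecision:
    snp_id: str
    action: str  # keep|drop_ld|replace_with_proxy|drop_no_proxy|drop_discordant|drop_not_significant
    detail: str = ""


def ld_r2(dos_i: np.ndarray, dos_j: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation over jointly observed
    samples; NaN when either SNP is monomorphic on that subset."""
    a = np.asarray(dos_i, dtype=float)
    b = np.asarray(dos_j, dtype=float)
    mask = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[mask], b[mask]
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_matrix(g: GenotypeMatrix) -> LDMatrix:
    m = g.n_snps
    r2 = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            r2[i, j] = r2[j, i] = ld_r2(g.dosages[:, i], g.dosages[:, j])
    return LDMatrix(list(g.snp_ids), r2)


def find_proxy(
    target: str,
    candidates: list[str],
    ld: LDMatrix,
    r2_min: float = 0.9,
) -> str | None:
    """Best available proxy: the candidate with maximal r2 to ``target``
    among those with r2 strictly above ``r2_min``; ties break to the
    lexicographically smallest snp_id.  ``None`` when nothing qualifies."""
    if target not in ld.snp_ids:
        raise KeyError(f"target {target!r} absent from LD matrix")
    best: tuple[float, str] | None = None
    for cand in candidates:
        if cand == target:
            raise ValueError("target must not be among candidates")
        r2 = ld.lookup(target, cand)
        if np.isnan(r2) or r2 <= r2_min:
            continue
        if best is None or r2 > best[0] or (r2 == best[0] and cand < best[1]):
            best = (r2, cand)
    return None if best is None else best[1]


def prune_tight_ld(
    snps: list[str], ld: LDMatrix, r2_max: float = 0.8
) -> list[SelectionDecision]:
    """Greedy input-order pruning: drop any SNP in LD (r2 > r2_max) with an
    already-kept SNP.  Deterministic given the input order."""
    kept: list[str] = []
    out: list[SelectionDecision] = []
    for s in snps:
        partner = None
        for k in kept:
            r2 = ld.lookup(s, k)
            if not np.isnan(r2) and r2 > r2_max:
                partner = k
                break
        if partner is None:
            kept.append(s)
            out.append(SelectionDecision(s, "keep"))
        else:
            out.append(SelectionDecision(s, "drop_ld", partner))
    return out


def _wald_p_1snp(y: np.ndarray, x: np.ndarray) -> tuple[float, float, bool]:
    """Univariate logistic Wald P for the dosage term; likelihood-ratio
    fallback (flagged) under separation/non-convergence."""
    X = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        if np.isfinite(fit.bse[1]) and fit.mle_retvals.get("converged", True):
            return float(fit.pvalues[1]), float(fit.params[1]), False
    except Exception:
        pass
    # LR fallback
    with np.errstate(all="ignore"):
        ll0 = sm.Logit(y, np.ones_like(y)[:, None]).fit(disp=0).llf
        fit = sm.Logit(y, X).fit_regularized(disp=0, alpha=1e-6, maxiter=200)
        ll1 = sm.Logit(y, X).loglike(np.asarray(fit.params))
    lr = max(0.0, 2.0 * (ll1 - ll0))
    return float(stats.chi2.sf(lr, 1)), float(np.asarray(fit.params)[1]), True


def significance_filter(
    g: GenotypeMatrix,
    t: pd.DataFrame,
    alpha_gw: float = 5e-8,
) -> list[SelectionDecision]:
    """Keep SNPs whose univariate logistic Wald P is strictly below
    ``alpha_gw`` (genome-wide significance screen)."""
    y = status_to_binary(t)
    out = []
    for k, sid in enumerate(g.snp_ids):
        p, _, flagged = _wald_p_1snp(y, g.dosages[:, k])
        detail = f"p={p:.3g}" + ("|lr_fallback" if flagged else "")
        action = "keep" if p < alpha_gw else "drop_not_significant"
        out.append(SelectionDecision(sid, action, detail))
    return out


def direction_concordance(weights_a, weights_b) -> list[SelectionDecision]:
    """Keep SNPs whose univariate effect estimates agree in sign across the
    two datasets; an exactly-zero estimate demonstrates no effect and drops."""
    if list(weights_a.snp_ids) != list(weights_b.snp_ids):
        raise ValueError("weight sets must cover the same SNP panel in order")
    out = []
    for sid, ba, bb in zip(weights_a.snp_ids, weights_a.betas, weights_b.betas):
        if ba == 0.0 or bb == 0.0:
            out.append(SelectionDecision(sid, "drop_discordant", "zero_effect"))
        elif np.sign(ba) == np.sign(bb):
            out.append(SelectionDecision(sid, "keep", f"{ba:+.3f}/{bb:+.3f}"))
        else:
            out.append(SelectionDecision(sid, "drop_discordant", f"{ba:+.3f}/{bb:+.3f}"))
    return out
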