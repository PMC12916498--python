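"""LD score regression: SNP-heritability, genetic correlation, and the
fraction of heritability carried by a variant subset.

Under a polygenic model, the expected association chi-square of variant
``j`` grows linearly with its LD score ``l_j`` (the sum of squared
correlations with surrounding variants, including itself):

    E[chi2_j] = 1 + a + N * h2 * l_j / M,

so the regression slope of chi-square on ``N l / M`` estimates the
observed-scale SNP-heritability and the intercept captures confounding
and uncorrected sample structure.  The cross-trait analogue regresses
``Z1 * Z2`` on the scores and estimates the genetic covariance; its free
intercept absorbs sample overlap.  Standard errors come from a 20-block
jackknife over position-ordered variants.

The concordant/all heritability partition divides the subset-restricted
estimate (with the subset's own variant count and subset-restricted LD
scores) by the all-variant estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from crossmeta.errors import ConfigError, UsageError
from crossmeta.simulate import GenotypeMatrix

log = logging.getLogger(__name__)

MIN_VARIANTS = 200
N_JACKKNIFE_BLOCKS = 20


def ld_scores(panel: GenotypeMatrix, window_bp: int = 1_000_000,
              subset: set[str] | None = None) -> pd.DataFrame:
    """Per-variant LD scores from a reference panel.

    ``l_j = sum_k r2_adj(j, k)`` over variants ``k`` within ``window_bp``
    (including ``j`` itself), with the small-sample bias adjustment
    ``r2_adj = r2 - (1 - r2) / (n - 2)``.  When ``subset`` is given, the
    sum runs over subset variants only (the regressor for a partitioned
    estimate) while scores are still reported for the same variants.
    """
    n = panel.n_individuals
    if n <= 2:
        raise ConfigError("panel too small for the r2 bias adjustment")
    order = panel.variants["BP"].to_numpy().argsort(kind="mergesort")
    meta = panel.variants.iloc[order].reset_index(drop=True)
    G = panel.dosages[:, order]
    bp = meta["BP"].to_numpy(np.int64)
    snps = meta["SNP"].to_numpy()
    X = G.astype(np.float64)
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    in_sum = np.ones(len(snps), dtype=bool) if subset is None \
        else np.array([s in subset for s in snps])
    m = len(snps)
    ell = np.zeros(m)
    chunk = 512
    for start in range(0, m, chunk):
        stop = min(start + chunk, m)
        lo = np.searchsorted(bp, bp[start] - window_bp)
        hi = np.searchsorted(bp, bp[stop - 1] + window_bp, side="right")
        r = (X[:, start:stop].T @ X[:, lo:hi]) / n
        r2 = r * r
        r2_adj = r2 - (1.0 - r2) / (n - 2)
        # the self term contributes exactly 1 (diagonal r2 is 1, the bias
        # adjustment vanishes there)
        ell[start:stop] = r2_adj[:, in_sum[lo:hi]].sum(axis=1)
    out = pd.DataFrame({"SNP": snps, "BP": bp, "L2": ell})
    if subset is not None:
        out = out[in_sum].reset_index(drop=True)
    return out


@dataclass
class H2Estimate:
    """Observed-scale SNP-heritability with jackknife uncertainty."""

    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    n_variants: int
    M: int
    mean_chi2: float

    def summary(self) -> str:
        return (f"h2 = {self.h2:.4f} (SE {self.h2_se:.4f}), "
                f"intercept = {self.intercept:.3f} "
                f"(SE {self.intercept_se:.3f}), "
                f"{self.n_variants} variants, M = {self.M}, "
                f"mean chi2 = {self.mean_chi2:.3f}")


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray,
         fixed_intercept: float | None = None):
    if fixed_intercept is not None:
        slope = float((w * x) @ (y - fixed_intercept) / ((w * x) @ x))
        return np.array([fixed_intercept, slope])
    X = np.column_stack([np.ones_like(x), x])
    Xw = X * w[:, None]
    beta = np.linalg.solve(X.T @ Xw, Xw.T @ y)
    return beta  # [intercept, slope]


def _jackknife(x, y, w, n_blocks, fixed_intercept=None):
    m = x.size
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    thetas = []
    for b in range(n_blocks):
        keep = np.ones(m, dtype=bool)
        keep[edges[b]:edges[b + 1]] = False
        thetas.append(_wls(x[keep], y[keep], w[keep], fixed_intercept))
    thetas = np.array(thetas)
    mean = thetas.mean(axis=0)
    se = np.sqrt((n_blocks - 1) / n_blocks
                 * ((thetas - mean) ** 2).sum(axis=0))
    return se


def ldsc_h2(sumstats: pd.DataFrame, scores: pd.DataFrame,
            M: int | None = None,
            n_blocks: int = N_JACKKNIFE_BLOCKS,
            intercept_free: bool = True) -> H2Estimate:
    """Weighted LD score regression of chi-square on the scores.

    Weights follow the standard heteroskedasticity form
    ``1 / (l_j * (1 + N h0 l_j / M)^2)`` with ``h0`` from an unweighted
    pilot fit (one reweighting iteration).  ``intercept_free=False``
    constrains the intercept to 1 (no confounding assumed), trading
    robustness for a markedly tighter slope.  A negative fitted slope is
    reported as is, with a warning, never clipped.
    """
    merged = sumstats.merge(scores[["SNP", "L2"]], on="SNP")
    merged = merged[np.isfinite(merged["Z"])]
    if len(merged) < MIN_VARIANTS:
        raise UsageError(
            f"only {len(merged)} variants matched the LD scores "
            f"(need >= {MIN_VARIANTS})")
    merged = merged.sort_values("BP").reset_index(drop=True)
    if M is None:
        M = len(scores)
    chi2 = merged["Z"].to_numpy() ** 2
    ell = merged["L2"].to_numpy()
    N = merged["N"].to_numpy(dtype=float)
    x = N * ell / M
    pilot = _wls(x, chi2, np.ones_like(x))
    h0 = float(np.clip(pilot[1], 0.0, 1.0))
    ell_w = np.maximum(ell, 1.0)
    w = 1.0 / (ell_w * (1.0 + N * h0 * ell_w / M) ** 2)
    fixed = None if intercept_free else 1.0
    intercept, slope = _wls(x, chi2, w, fixed)
    se_int, se_slope = _jackknife(x, chi2, w, n_blocks, fixed)
    if slope < 0:
        log.warning("ldsc_h2: negative fitted slope (h2 = %.4g); reported "
                    "as is", slope)
    return H2Estimate(h2=float(slope), h2_se=float(se_slope),
                      intercept=float(intercept),
                      intercept_se=float(se_int),
                      n_variants=len(merged), M=int(M),
                      mean_chi2=float(chi2.mean()))


def ldsc_h2_stratified(sumstats: pd.DataFrame,
                       score_sets: dict[str, pd.DataFrame],
                       Ms: dict[str, int],
                       n_blocks: int = N_JACKKNIFE_BLOCKS) -> dict:
    """Two-or-more-category LD score regression.

    Each category supplies partial LD scores (sum of r2 to that
    category's variants only); the joint fit

        E[chi2_j] = 1 + N * sum_c (h2_c / M_c) * l_{c,j}

    attributes signal to the category that tags it, which a
    single-category fit on a variant subset cannot do when causal
    variants outside the subset are in LD with it.  Returns per-category
    heritabilities with jackknife SEs and the intercept.
    """
    names = list(score_sets)
    merged = sumstats[["SNP", "BP", "Z", "N"]].copy()
    for name in names:
        sc = score_sets[name][["SNP", "L2"]].rename(columns={"L2": f"L2_{name}"})
        merged = merged.merge(sc, on="SNP", how="left")
        merged[f"L2_{name}"] = merged[f"L2_{name}"].fillna(0.0)
    merged = merged[np.isfinite(merged["Z"])]
    merged = merged.sort_values("BP").reset_index(drop=True)
    if len(merged) < MIN_VARIANTS:
        raise UsageError("too few variants for stratified regression")
    chi2 = merged["Z"].to_numpy() ** 2
    N = merged["N"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(merged))] + [
        N * merged[f"L2_{name}"].to_numpy() / Ms[name] for name in names])
    ell_tot = sum(merged[f"L2_{name}"].to_numpy() for name in names)
    ell_w = np.maximum(ell_tot, 1.0)
    pilot = np.linalg.lstsq(X, chi2, rcond=None)[0]
    h0 = float(np.clip(sum(pilot[1:]), 0.0, 1.0))
    M_tot = sum(Ms.values())
    w = 1.0 / (ell_w * (1.0 + N * h0 * ell_w / M_tot) ** 2)
    Xw = X * w[:, None]
    beta = np.linalg.solve(X.T @ Xw, Xw.T @ chi2)
    m = len(merged)
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    thetas = []
    for b in range(n_blocks):
        keep = np.ones(m, dtype=bool)
        keep[edges[b]:edges[b + 1]] = False
        Xk = X[keep]
        Xkw = Xk * w[keep][:, None]
        thetas.append(np.linalg.solve(Xk.T @ Xkw, Xkw.T @ chi2[keep]))
    thetas = np.array(thetas)
    se = np.sqrt((n_blocks - 1) / n_blocks
                 * ((thetas - thetas.mean(axis=0)) ** 2).sum(axis=0))
    out = {"intercept": float(beta[0]), "intercept_se": float(se[0])}
    for i, name in enumerate(names):
        out[f"h2_{name}"] = float(beta[i + 1])
        out[f"h2_{name}_se"] = float(se[i + 1])
    return out


@dataclass
class RgEstimate:
    """Cross-trait genetic correlation from LD score regression."""

    rg: float
    rg_se: float
    gencov: float
    intercept: float
    h2_1: float
    h2_2: float
    n_variants: int
    defined: bool


def ldsc_rg(s1: pd.DataFrame, s2: pd.DataFrame, scores: pd.DataFrame,
            M: int | None = None,
            n_blocks: int = N_JACKKNIFE_BLOCKS,
            overlap_intercept_free: bool = True) -> RgEstimate:
    """Genetic correlation: regress ``Z1 * Z2`` on the LD scores.

    By default the intercept is left free, absorbing any shared-sample
    covariance; with ``overlap_intercept_free=False`` (cohorts known to
    be disjoint) the cross-score intercept is pinned at 0 and the
    per-trait intercepts at 1, which substantially tightens the
    estimate.  ``rg = gencov / sqrt(h2_1 * h2_2)``; when either
    heritability is nonpositive the correlation is undefined and
    flagged.
    """
    merged = s1.merge(s2, on="SNP", suffixes=("_1", "_2"))
    merged = merged.merge(scores[["SNP", "L2"]], on="SNP")
    merged = merged[np.isfinite(merged["Z_1"]) & np.isfinite(merged["Z_2"])]
    if len(merged) < MIN_VARIANTS:
        raise UsageError("too few shared variants for genetic correlation")
    merged = merged.sort_values("BP_1").reset_index(drop=True)
    if M is None:
        M = len(scores)
    h1 = ldsc_h2(s1, scores, M=M, n_blocks=n_blocks,
                 intercept_free=overlap_intercept_free)
    h2 = ldsc_h2(s2, scores, M=M, n_blocks=n_blocks,
                 intercept_free=overlap_intercept_free)
    y = merged["Z_1"].to_numpy() * merged["Z_2"].to_numpy()
    ell = merged["L2"].to_numpy()
    Ng = np.sqrt(merged["N_1"].to_numpy() * merged["N_2"].to_numpy())
    x = Ng * ell / M
    ell_w = np.maximum(ell, 1.0)
    w = 1.0 / (ell_w ** 2)
    fixed = None if overlap_intercept_free else 0.0
    intercept, slope = _wls(x, y, w, fixed)
    defined = h1.h2 > 0 and h2.h2 > 0
    if not defined:
        log.warning("ldsc_rg: nonpositive heritability; rg undefined")
        return RgEstimate(rg=np.nan, rg_se=np.nan, gencov=float(slope),
                          intercept=float(intercept), h2_1=h1.h2, h2_2=h2.h2,
                          n_variants=len(merged), defined=False)
    rg = float(slope / np.sqrt(h1.h2 * h2.h2))
    _, se_slope = _jackknife(x, y, w, n_blocks, fixed)
    rg_se = float(se_slope / np.sqrt(h1.h2 * h2.h2))
    return RgEstimate(rg=rg, rg_se=rg_se, gencov=float(slope),
                      intercept=float(intercept), h2_1=h1.h2, h2_2=h2.h2,
                      n_variants=len(merged), defined=defined)


def h2_fraction(sumstats: pd.DataFrame, concordant_ids,
                panel: GenotypeMatrix, window_bp: int = 1_000_000,
                fixed_M: bool = False) -> dict:
    """Fraction of SNP-heritability carried by the concordant subset.

    The denominator is the standard all-variant estimate.  The numerator
    comes from a two-category stratified fit (concordant vs remainder,
    each with its own partial LD scores and, by default, its own M):
    restricting the regression to the subset alone would credit the
    subset with signal from causal variants outside it that happen to be
    in LD with it.  A nonpositive all-variant estimate leaves the
    fraction undefined (NaN, flagged).
    """
    concordant = set(concordant_ids)
    unknown = concordant - set(sumstats["SNP"])
    if unknown:
        raise UsageError("concordant ids missing from the summary "
                         f"statistics: {sorted(unknown)[:5]}")
    scores_all = ld_scores(panel, window_bp)
    est_all = ldsc_h2(sumstats, scores_all)
    scores_sub = ld_scores(panel, window_bp, subset=concordant)
    complement = set(scores_all["SNP"]) - concordant
    if not complement:
        # trivial partition: the subset is everything
        return {"fraction": 1.0, "h2_all": est_all, "h2_concordant": est_all,
                "stratified": None}
    scores_comp = ld_scores(panel, window_bp, subset=complement)
    M = len(scores_all)
    Ms = {"concordant": M if fixed_M else len(scores_sub),
          "rest": M if fixed_M else len(scores_comp)}
    strat = ldsc_h2_stratified(
        sumstats, {"concordant": scores_sub, "rest": scores_comp}, Ms)
    est_sub = H2Estimate(
        h2=strat["h2_concordant"], h2_se=strat["h2_concordant_se"],
        intercept=strat["intercept"], intercept_se=strat["intercept_se"],
        n_variants=len(sumstats), M=Ms["concordant"],
        mean_chi2=float((sumstats["Z"] ** 2).mean()))
    total = strat["h2_concordant"] + strat["h2_rest"]
    if total <= 0:
        log.warning("h2_fraction: total heritability <= 0; "
                    "fraction undefined")
        frac = float("nan")
    else:
        # both terms come from one joint fit, so realization noise in the
        # genome-wide signal cancels out of the ratio
        frac = strat["h2_concordant"] / total
    return {"fraction": frac, "h2_all": est_all, "h2_concordant": est_sub,
            "stratified": strat}
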