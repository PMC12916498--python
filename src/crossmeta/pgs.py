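"""Polygenic scoring and top-decile risk stratification.

A polygenic score is the dosage-weighted sum of per-allele effects;
missing genotypes are imputed as twice the effect-allele frequency.  Risk
stratification compares the 10% of individuals with the highest score to
the remaining 90% by logistic regression of case status on the top-decile
indicator plus covariates (sex, age, genetic principal components, and an
optional genotyping-array indicator), overall and sex-stratified.  Odds
ratios from independent target cohorts combine by fixed-effect
inverse-variance meta-analysis on the log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from crossmeta.errors import ConfigError, UsageError
from crossmeta.loci import LDMatrix, select_leads

log = logging.getLogger(__name__)

TOP_FRACTION = 0.1
P_THRESHOLDS = (5e-8, 1e-6, 1e-4)


@dataclass
class CohortData:
    """Target cohort: dosages, phenotype and covariates, row-aligned.

    ``dosages`` is individuals x variants in [0, 2] with NaN for missing
    genotypes; ``variants`` carries SNP/A1/A2 (and optionally FRQ);
    ``covariates`` holds sex, age, principal components and any array
    indicator.  Age follows the usual EHR contract (age at first
    diagnosis for cases, at last record for controls) as an input column,
    not something computed here.  Individuals are assumed unrelated.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    phenotype: np.ndarray
    covariates: pd.DataFrame | None = None
    label: str = "cohort"

    def __post_init__(self):
        n = self.dosages.shape[0]
        if len(self.phenotype) != n:
            raise ConfigError("phenotype length does not match genotypes")
        if self.covariates is not None and len(self.covariates) != n:
            raise ConfigError("covariate rows do not match genotypes")
        uniq = set(np.unique(self.phenotype))
        if not uniq <= {0, 1}:
            raise ConfigError("phenotype must be binary 0/1")


def score(cohort: CohortData, weights: pd.DataFrame) -> np.ndarray:
    """Additive polygenic score per individual.

    ``weights`` carries SNP, A1, A2, WEIGHT and optionally FRQ.  Alleles
    are aligned to the cohort (swapped orientation flips the weight's
    sign); missing dosages are imputed as ``2 * FRQ``; weight variants
    absent from the cohort contribute the constant ``2 * FRQ * WEIGHT``
    (logged — a uniform shift that cannot change ranks).
    """
    cv = cohort.variants.reset_index(drop=True)
    col_of = {s: i for i, s in enumerate(cv["SNP"])}
    n = cohort.dosages.shape[0]
    total = np.zeros(n)
    shift = 0.0
    n_absent = 0
    for row in weights.itertuples(index=False):
        freq = getattr(row, "FRQ", None)
        j = col_of.get(row.SNP)
        if j is None:
            if freq is None or not np.isfinite(freq):
                raise UsageError(
                    f"weight variant {row.SNP} absent from the cohort and "
                    "has no allele frequency")
            shift += 2.0 * freq * row.WEIGHT
            n_absent += 1
            continue
        a1, a2 = cv.at[j, "A1"], cv.at[j, "A2"]
        if (row.A1, row.A2) == (a1, a2):
            w = row.WEIGHT
            f = freq
        elif (row.A1, row.A2) == (a2, a1):
            w = -row.WEIGHT
            f = None if freq is None else 1.0 - freq
        else:
            log.warning("weight variant %s: alleles do not match the "
                        "cohort; skipped", row.SNP)
            continue
        d = cohort.dosages[:, j].astype(float)
        missing = ~np.isfinite(d)
        if missing.any():
            if f is None or not np.isfinite(f):
                raise UsageError(
                    f"variant {row.SNP} has missing dosages and no allele "
                    "frequency for mean imputation")
            d = np.where(missing, 2.0 * f, d)
        total += w * d
    if n_absent:
        log.info("score: %d weight variants absent from the cohort "
                 "(constant shift %.4g applied)", n_absent, shift)
    return total + shift


@dataclass
class ORResult:
    """Odds ratio for top-decile vs remainder, with a 95% CI."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or_se: float
    stratum: str
    cohort: str
    n_cases: int
    n_controls: int
    estimable: bool = True

    @property
    def log_or(self) -> float:
        return float(np.log(self.odds_ratio))


def top_decile_or(scores: np.ndarray, cohort: CohortData,
                  stratum: str = "combined",
                  covariate_columns: list[str] | None = None,
                  top_fraction: float = TOP_FRACTION,
                  min_per_class: int = 20) -> ORResult:
    """Logistic top-decile odds ratio within a stratum.

    ``stratum`` is ``combined`` or a value of the cohort's ``sex``
    covariate (rows are restricted *before* the percentile is taken).
    Individuals at or above the ``1 - top_fraction`` quantile form the
    top group.  With ``covariate_columns=None`` all covariates except
    ``sex`` in sex-stratified runs are used; pass ``[]`` for the
    covariate-free model, which reproduces the closed-form 2x2 odds
    ratio.  Complete separation is flagged as non-estimable.
    """
    scores = np.asarray(scores, dtype=float)
    mask = np.ones(len(scores), dtype=bool)
    if stratum != "combined":
        if cohort.covariates is None or "sex" not in cohort.covariates:
            raise UsageError("sex-stratified analysis needs a sex covariate")
        mask = (cohort.covariates["sex"].to_numpy() == stratum)
    s = scores[mask]
    y = np.asarray(cohort.phenotype)[mask].astype(float)
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    if n_cases < min_per_class or n_controls < min_per_class:
        raise UsageError(
            f"stratum {stratum!r}: need >= {min_per_class} cases and "
            f"controls (got {n_cases}/{n_controls})")
    cut = np.quantile(s, 1.0 - top_fraction)
    top = (s >= cut).astype(float)
    X = pd.DataFrame({"top_decile": top})
    if cohort.covariates is not None:
        cols = covariate_columns
        if cols is None:
            cols = [c for c in cohort.covariates.columns
                    if not (c == "sex" and stratum != "combined")]
        for c in cols:
            X[c] = cohort.covariates.loc[mask, c].to_numpy(dtype=float)
    X = sm.add_constant(X, prepend=True)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200, tol=1e-10)
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:  # separation or singular design
        converged = False
        fit = None
    if fit is None or not converged or not np.isfinite(
            fit.bse["top_decile"]) or fit.bse["top_decile"] > 50:
        log.warning("top_decile_or: separation or non-convergence in "
                    "stratum %r; OR non-estimable", stratum)
        return ORResult(np.nan, np.nan, np.nan, np.nan, stratum,
                        cohort.label, n_cases, n_controls, estimable=False)
    b = float(fit.params["top_decile"])
    se = float(fit.bse["top_decile"])
    return ORResult(odds_ratio=float(np.exp(b)),
                    ci_low=float(np.exp(b - 1.96 * se)),
                    ci_high=float(np.exp(b + 1.96 * se)),
                    log_or_se=se, stratum=stratum, cohort=cohort.label,
                    n_cases=n_cases, n_controls=n_controls)


def meta_or(results: list[ORResult], weighting: str = "inverse_variance",
            allow_single: bool = False) -> ORResult:
    """Fixed-effect combination of log odds ratios across cohorts.

    ``inverse_variance`` weights by ``1 / SE^2`` (the default reading of
    "weighted by the inverse of standard error"); ``inverse_se`` weights
    by ``1 / SE`` for comparison.  All inputs must share a stratum.
    """
    results = [r for r in results if r.estimable]
    if len(results) < (1 if allow_single else 2):
        raise UsageError("need at least two estimable results to combine")
    strata = {r.stratum for r in results}
    if len(strata) != 1:
        raise UsageError(f"mismatched strata: {sorted(strata)}")
    logs = np.array([r.log_or for r in results])
    ses = np.array([r.log_or_se for r in results])
    if weighting == "inverse_variance":
        w = 1.0 / ses ** 2
        se = float(1.0 / np.sqrt(w.sum()))
    elif weighting == "inverse_se":
        w = 1.0 / ses
        se = float(np.sqrt((w ** 2 @ ses ** 2)) / w.sum())
    else:
        raise UsageError(f"unknown weighting {weighting!r}")
    pooled = float((w @ logs) / w.sum())
    return ORResult(odds_ratio=float(np.exp(pooled)),
                    ci_low=float(np.exp(pooled - 1.96 * se)),
                    ci_high=float(np.exp(pooled + 1.96 * se)),
                    log_or_se=se, stratum=results[0].stratum,
                    cohort="meta(" + "+".join(r.cohort for r in results) + ")",
                    n_cases=sum(r.n_cases for r in results),
                    n_controls=sum(r.n_controls for r in results))


def fallback_weights(result: pd.DataFrame, ld: LDMatrix,
                     p_thresholds=P_THRESHOLDS,
                     tuning: tuple[CohortData, np.ndarray] | None = None
                     ) -> pd.DataFrame:
    """Clump-and-threshold weights from a concordant meta-analysis.

    For each P threshold, independent leads (pairwise r2 < 0.1) are
    retained with weight ``Z / sqrt(N)``.  With a tuning cohort the
    threshold maximizing the score/phenotype correlation is kept,
    otherwise the strictest threshold.  A stand-in for posterior-effect
    weight files, which are accepted as input wherever weights are used.
    """
    candidates = {}
    for p in sorted(p_thresholds):
        leads = select_leads(result, ld, gws_p=p)
        if leads.empty:
            continue
        w = leads[["SNP", "A1", "A2"]].copy()
        w["WEIGHT"] = leads["Z"].to_numpy() / np.sqrt(leads["N"].to_numpy())
        if "FRQ" in leads.columns:
            w["FRQ"] = leads["FRQ"].to_numpy()
        candidates[p] = w.reset_index(drop=True)
    if not candidates:
        return pd.DataFrame(columns=["SNP", "A1", "A2", "WEIGHT"])
    if tuning is None:
        return candidates[min(candidates)]
    cohort, pheno = tuning
    best, best_r = None, -np.inf
    for p, w in sorted(candidates.items()):
        s = score(cohort, w)
        if np.std(s) == 0:
            continue
        r = abs(float(np.corrcoef(s, pheno)[0, 1]))
        if r > best_r:
            best, best_r = p, r
    return candidates[best if best is not None else min(candidates)]


def read_weights(path) -> pd.DataFrame:
    """Read a tab-delimited weight file (SNP, A1, A2, WEIGHT[, FRQ])."""
    df = pd.read_csv(path, sep="\t")
    for col in ("SNP", "A1", "A2", "WEIGHT"):
        if col not in df.columns:
            raise UsageError(f"weight file missing column {col!r}")
    return df


def write_weights(weights: pd.DataFrame, path) -> None:
    weights.to_csv(path, sep="\t", index=False)
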