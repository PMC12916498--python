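"""Gene-based association: brain-expression filter, top-chi-square test,
cross-population gene meta-analysis.

The gene statistic is the maximum squared Z over the variants mapped to a
gene (gene body plus a flanking margin).  Its null distribution under LD
is the maximum of squared draws from a zero-mean multivariate normal with
the variants' correlation structure; the gene P-value is the Monte-Carlo
tail probability with the add-one correction
``P = (1 + #exceed) / (n_mc + 1)``.  Gene P-values are converted to Z by
the probit, ``Z = Phi^{-1}(1 - P)``, and combined across populations by a
sqrt-N-weighted Stouffer sum; genes present in only one population are
excluded from the cross-population table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from crossmeta.errors import UsageError
from crossmeta.loci import LDMatrix

log = logging.getLogger(__name__)

GENE_MARGIN_BP = 10_000
LD_SHRINK = 0.05
N_MC = 100_000
N_MC_ESCALATED = 1_000_000


def brain_expressed_filter(genes: list[str] | pd.Series,
                           tissue_expression: pd.DataFrame) -> list[str]:
    """Genes with expression > 0 in at least one tissue column.

    ``tissue_expression`` is a genes x tissues matrix indexed by gene id
    (median TPM across donors in the motivating use).  Genes missing from
    the matrix are excluded with a warning.
    """
    keep = []
    missing = 0
    expressed = (tissue_expression > 0).any(axis=1)
    for g in genes:
        if g not in expressed.index:
            missing += 1
            continue
        if bool(expressed.loc[g]):
            keep.append(g)
    if missing:
        log.warning("brain_expressed_filter: %d genes absent from the "
                    "expression matrix were excluded", missing)
    return keep


def _null_max_chi2(corr: np.ndarray, observed: float, n_mc: int,
                   rng: np.random.Generator, batch: int = 200_000) -> int:
    """Count Monte-Carlo null draws whose max squared component exceeds
    the observed statistic."""
    m = corr.shape[0]
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        # PSD but rank-deficient (e.g. perfect LD): eigen factor instead
        vals, vecs = np.linalg.eigh(corr)
        if vals.min() < -1e-8:
            raise UsageError(
                "gene LD matrix indefinite after regularization")
        L = vecs * np.sqrt(np.clip(vals, 0.0, None))
    exceed = 0
    done = 0
    while done < n_mc:
        b = min(batch, n_mc - done)
        draws = rng.standard_normal((b, m)) @ L.T
        exceed += int((np.max(draws * draws, axis=1) > observed).sum())
        done += b
    return exceed


def gene_top_chi2(result: pd.DataFrame, gene: pd.Series, ld: LDMatrix,
                  margin_bp: int = GENE_MARGIN_BP, n_mc: int = N_MC,
                  seed: int = 0, shrink: float = LD_SHRINK,
                  escalate_below: float = 1e-3) -> dict | None:
    """Top-chi-square statistic and Monte-Carlo P for one gene.

    ``gene`` carries GENE, CHR, START, END.  Variants within
    ``[START - margin, END + margin]`` are mapped to the gene; the LD
    correlation of the mapped variants is shrunk toward the identity with
    weight ``shrink`` before sampling (reference panels make raw matrices
    indefinite).  When the first-pass P falls below ``escalate_below`` the
    draw count is escalated tenfold.  Returns None when no variant maps.
    """
    sel = result[(result["CHR"].astype(str) == str(gene["CHR"]))
                 & (result["BP"] >= gene["START"] - margin_bp)
                 & (result["BP"] <= gene["END"] + margin_bp)]
    sel = sel[sel["SNP"].isin(ld.index)]
    sel = sel[np.isfinite(sel["Z"])]
    if sel.empty:
        return None
    snps = sel["SNP"].tolist()
    z = sel["Z"].to_numpy()
    observed = float(np.max(z * z))
    idx = [ld.index[s] for s in snps]
    r2 = ld.r2[np.ix_(idx, idx)]
    corr = np.sqrt(r2)  # magnitude is all the max-of-squares null needs
    corr = (1.0 - shrink) * corr + shrink * np.eye(len(snps))
    np.fill_diagonal(corr, 1.0)
    rng = np.random.default_rng(seed)
    exceed = _null_max_chi2(corr, observed, n_mc, rng)
    p = (1 + exceed) / (n_mc + 1)
    if p < escalate_below and n_mc < N_MC_ESCALATED:
        exceed = _null_max_chi2(corr, observed, N_MC_ESCALATED, rng)
        n_mc = N_MC_ESCALATED
        p = (1 + exceed) / (n_mc + 1)
    return {
        "GENE": gene["GENE"], "CHR": gene["CHR"],
        "START": int(gene["START"]), "END": int(gene["END"]),
        "N_SNPS": len(snps), "TOP_CHI2": observed,
        "P": float(p), "ZSTAT": float(stats.norm.isf(p)),
        "N_MC": n_mc,
    }


def gene_scan(result: pd.DataFrame, genes: pd.DataFrame, ld: LDMatrix,
              expressed: set[str] | None = None, seed: int = 0,
              **kwargs) -> pd.DataFrame:
    """Run the top-chi-square test over a gene annotation table."""
    rows = []
    for k, (_, gene) in enumerate(genes.iterrows()):
        if expressed is not None and gene["GENE"] not in expressed:
            continue
        res = gene_top_chi2(result, gene, ld, seed=seed + k, **kwargs)
        if res is not None:
            rows.append(res)
    return pd.DataFrame(rows, columns=[
        "GENE", "CHR", "START", "END", "N_SNPS", "TOP_CHI2", "P", "ZSTAT",
        "N_MC"])


def gene_meta(results: dict[str, pd.DataFrame],
              n_eff: dict[str, float]) -> pd.DataFrame:
    """Sqrt-N-weighted Stouffer meta-analysis of per-population gene Z.

    ``meta Z = sum_k sqrt(N_k) Z_k / sqrt(sum_k N_k)`` over the
    populations where the gene is present; ``meta P = 1 - Phi(Z)``
    (one-sided, matching the probit convention).  Genes present in a
    single population are excluded.
    """
    frames = []
    for pop, df in results.items():
        frames.append(df.set_index("GENE")["ZSTAT"].rename(pop))
    merged = pd.concat(frames, axis=1, join="outer")
    pops = list(results)
    Z = merged[pops].to_numpy()
    present = np.isfinite(Z)
    multi = present.sum(axis=1) >= 2
    w = np.sqrt(np.array([n_eff[p] for p in pops]))
    W = np.where(present, w[np.newaxis, :], 0.0)
    num = (W * np.where(present, Z, 0.0)).sum(axis=1)
    denom = np.sqrt((W * W).sum(axis=1))
    with np.errstate(invalid="ignore"):
        z_meta = num / denom
    out = pd.DataFrame({
        "GENE": merged.index,
        "ZSTAT": z_meta,
        "P": stats.norm.sf(z_meta),
        "N_POPULATIONS": present.sum(axis=1),
    })
    for p in pops:
        out[f"PRESENT_{p}"] = np.isfinite(merged[p].to_numpy())
    return out[multi].reset_index(drop=True)
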