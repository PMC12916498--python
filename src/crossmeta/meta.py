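"""Overlap-corrected weighted-Z meta-analysis and concordance filtering.

When cohorts share participants, their association Z-scores are correlated
and a naive weighted-Z combination is anticonservative.  The correction
estimates the pairwise Z-score correlation matrix ``C`` from null variants
and combines studies as

    Z_meta = sum_i w_i Z_i / sqrt(sum_ij w_i w_j c_ij),   w_i = sqrt(N_i),

which is exactly standard normal under the null for jointly normal Z with
correlation ``C``.  For two studies of the same trait sharing ``n_s`` of
``n_1``/``n_2`` participants, ``c_12 ~= n_s / sqrt(n_1 n_2)``.

The concordance filter implements the cross-disorder sharing definition:
a variant is retained iff its effect direction is identical across every
contributing study in which it is present (with a minimum-presence
policy), which under four independent null traits retains 1/8 of variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from crossmeta.errors import ConfigError, UsageError
from crossmeta.sumstats import z_to_p

log = logging.getLogger(__name__)

GWS_P = 5e-8  #: genome-wide significance threshold


@dataclass
class OverlapModel:
    """Pairwise Z-score correlations among studies, plus sqrt-N weights."""

    labels: list[str]
    C: np.ndarray
    w: np.ndarray = field(default=None)

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        k = len(self.labels)
        if self.C.shape != (k, k):
            raise ConfigError("correlation matrix shape mismatch")
        if self.w is None:
            self.w = np.ones(k)

    def submodel(self, labels: list[str]) -> "OverlapModel":
        idx = [self.labels.index(l) for l in labels]
        return OverlapModel(labels=list(labels), C=self.C[np.ix_(idx, idx)],
                            w=self.w[idx])


def repair_psd(C: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Floor eigenvalues and rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(C)
    if vals.min() >= floor:
        return C
    vals = np.maximum(vals, floor)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


@lru_cache(maxsize=None)
def _truncation_table(z_max: float, n_grid: int = 60, n_nodes: int = 120):
    """Map true correlation -> correlation of the doubly truncated pair.

    Restricting a bivariate normal to the box ``|x|,|y| < z_max`` shrinks
    the sample correlation; this table (built by Gauss-Legendre quadrature
    of the truncated density) lets the estimator invert that shrinkage.
    """
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    x = nodes * z_max
    w = weights * z_max
    X, Y = np.meshgrid(x, x, indexing="ij")
    W = np.outer(w, w)
    rhos = np.linspace(0.0, 0.999, n_grid)
    out = np.empty(n_grid)
    for i, rho in enumerate(rhos):
        det = 1.0 - rho * rho
        pdf = np.exp(-(X * X - 2 * rho * X * Y + Y * Y) / (2 * det))
        pdf /= 2 * np.pi * np.sqrt(det)
        mass = float((W * pdf).sum())
        exy = float((W * pdf * X * Y).sum()) / mass
        exx = float((W * pdf * X * X).sum()) / mass
        out[i] = exy / exx  # symmetric box: means 0, var(x) = var(y)
    return rhos, out

def _deattenuate(c_obs: float, z_max: float) -> float:
    rhos, truncated = _truncation_table(z_max)
    sign = 1.0 if c_obs >= 0 else -1.0
    mag = min(abs(c_obs), truncated[-1])
    return sign * float(np.interp(mag, truncated, rhos))


def estimate_z_correlation(studies: dict[str, pd.DataFrame],
                           min_shared: int = 1000,
                           z_max: float = 1.96,
                           truncate_negative: bool = True,
                           deattenuate: bool = True,
                           psd_floor: float = 1e-6) -> OverlapModel:
    """Estimate the pairwise Z-score correlation matrix from null variants.

    For every study pair, the Pearson correlation of Z is computed over
    shared variants with ``|Z| < z_max`` in both studies (so true shared
    signal does not inflate the estimate) and corrected for the shrinkage
    the truncation itself induces.  Pairs with fewer than ``min_shared``
    usable variants get ``c = 0`` with a warning.  Negative estimates are
    truncated at 0 by default (participant overlap cannot be negative),
    and the matrix is repaired to positive semi-definiteness.
    """
    if len(studies) < 2:
        raise UsageError("need at least two studies to estimate overlap")
    labels = list(studies)
    k = len(labels)
    zmat = {}
    nbar = np.empty(k)
    for i, name in enumerate(labels):
        df = studies[name]
        zmat[name] = df.set_index("SNP")["Z"]
        nbar[i] = float(df["N"].mean())
    C = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            zi, zj = zmat[labels[i]], zmat[labels[j]]
            both = zi.index.intersection(zj.index)
            a = zi.reindex(both).to_numpy()
            b = zj.reindex(both).to_numpy()
            ok = (np.abs(a) < z_max) & (np.abs(b) < z_max)
            ok &= np.isfinite(a) & np.isfinite(b)
            if ok.sum() < min_shared:
                log.warning("pair (%s, %s): only %d usable shared variants "
                            "(< %d); setting c = 0",
                            labels[i], labels[j], int(ok.sum()), min_shared)
                c = 0.0
            else:
                c = float(np.corrcoef(a[ok], b[ok])[0, 1])
                if deattenuate:
                    c = _deattenuate(c, z_max)
                if truncate_negative and c < 0:
                    c = 0.0
            C[i, j] = C[j, i] = c
    C = repair_psd(C, psd_floor)
    return OverlapModel(labels=labels, C=C, w=np.sqrt(nbar))


def effective_sample_size(Ns, model: OverlapModel) -> float:
    """Size of one independent study carrying the same information.

    ``N_eff = (sum_i N_i)^2 / sum_ij sqrt(N_i N_j) c_ij``; with no overlap
    this is the plain sum, with complete duplication it collapses to a
    single cohort.
    """
    Ns = np.asarray(Ns, dtype=float)
    if np.any(Ns <= 0):
        raise ConfigError("sample sizes must be positive")
    w = np.sqrt(Ns)
    denom = float(w @ model.C @ w)
    if denom <= 0:
        raise ConfigError("overlap model denominator <= 0 (PSD repair failed)")
    return float(Ns.sum() ** 2 / denom)


def meta_weighted_z(studies: dict[str, pd.DataFrame],
                    model: OverlapModel | None = None) -> pd.DataFrame:
    """Overlap-corrected weighted-Z meta-analysis over harmonized studies.

    Per variant, only the subset of studies where it is present (finite Z)
    contributes; weights are sqrt of the per-variant N.  The result table
    carries ``Z``, ``P``, the per-variant effective sample size ``N``,
    the contributing-study count and one ``SIGN_<study>`` column per
    study (0 for Z exactly 0, NaN where absent).
    """
    if model is None:
        model = estimate_z_correlation(studies)
    labels = model.labels
    if set(labels) != set(studies):
        raise UsageError("overlap model labels do not match the studies")
    k = len(labels)
    frames = []
    for name in labels:
        df = studies[name]
        frames.append(df.set_index("SNP")[["Z", "N"]].rename(
            columns={"Z": f"Z_{name}", "N": f"N_{name}"}))
    merged = pd.concat(frames, axis=1, join="outer")
    meta_cols = ["CHR", "BP", "A1", "A2"]
    coords = pd.concat(
        [studies[name].set_index("SNP")[meta_cols] for name in labels])
    coords = coords[~coords.index.duplicated(keep="first")]
    Zs = merged[[f"Z_{n}" for n in labels]].to_numpy()
    Ns = merged[[f"N_{n}" for n in labels]].to_numpy()
    present = np.isfinite(Zs)
    W = np.where(present, np.sqrt(np.where(present, Ns, 0.0)), 0.0)
    Z0 = np.where(present, Zs, 0.0)
    num = (W * Z0).sum(axis=1)
    denom = np.einsum("mi,ij,mj->m", W, model.C, W)
    any_present = present.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_meta = np.where(any_present, num / np.sqrt(denom), np.nan)
        n_eff = np.where(any_present,
                         np.where(present, Ns, 0.0).sum(axis=1) ** 2 / denom,
                         np.nan)
    out = pd.DataFrame(index=merged.index)
    out = out.join(coords)
    out["Z"] = z_meta
    out["P"] = z_to_p(z_meta)
    out["N"] = n_eff
    out["N_STUDIES"] = present.sum(axis=1)
    for i, name in enumerate(labels):
        sign = np.where(present[:, i], np.sign(Zs[:, i]), np.nan)
        out[f"SIGN_{name}"] = sign
    out = out[any_present]
    out = out.reset_index().rename(columns={"index": "SNP"})
    return out.sort_values(["CHR", "BP", "SNP"],
                           key=_natural_sort_key).reset_index(drop=True)


def _natural_sort_key(col: pd.Series) -> pd.Series:
    if col.name == "CHR":
        return pd.to_numeric(col, errors="coerce").fillna(1e9)
    return col


def sign_columns(result: pd.DataFrame) -> list[str]:
    return [c for c in result.columns if c.startswith("SIGN_")]


def concordance_filter(result: pd.DataFrame, columns: list[str] | None = None,
                       min_present: int = 2) -> pd.DataFrame:
    """Retain variants whose effect direction agrees across studies.

    A variant passes iff it is present in at least ``min_present`` of the
    named sign columns and every present nonzero sign is identical; a Z of
    exactly 0 neither confirms nor breaks concordance, but a variant with
    no nonzero sign carries no direction and is removed.
    """
    if columns is None:
        columns = sign_columns(result)
    signs = result[columns].to_numpy()
    present = np.isfinite(signs)
    nonzero = present & (signs != 0)
    pos = (np.where(nonzero, signs, 0) > 0).sum(axis=1)
    neg = (np.where(nonzero, signs, 0) < 0).sum(axis=1)
    ok = (present.sum(axis=1) >= min_present) \
        & ((pos == 0) | (neg == 0)) & (pos + neg > 0)
    out = result[ok].reset_index(drop=True)
    log.info("concordance filter: retained %d / %d variants",
             len(out), len(result))
    return out


def _plan_order(plan: dict[str, list[str]], leaves: set[str]) -> list[str]:
    """Topological order of internal plan nodes; rejects cycles."""
    state: dict[str, int] = {}
    order: list[str] = []

    def visit(node: str):
        if node in leaves and node not in plan:
            return
        if state.get(node) == 1:
            raise ConfigError(f"cyclic meta-analysis plan at node {node!r}")
        if state.get(node) == 2:
            return
        if node not in plan:
            raise ConfigError(f"plan node {node!r} is neither a study "
                              "nor an internal node")
        state[node] = 1
        for child in plan[node]:
            visit(child)
        state[node] = 2
        order.append(node)

    for node in plan:
        visit(node)
    return order


def nested_meta(plan: dict[str, list[str]], studies: dict[str, pd.DataFrame],
                min_shared: int = 1000,
                models: dict[str, OverlapModel] | None = None,
                **overlap_kwargs) -> dict[str, pd.DataFrame]:
    """Hierarchical meta-analysis: children before parents.

    ``plan`` maps each internal node to its direct inputs (study names or
    other internal nodes); every internal node re-estimates its overlap
    model over its direct inputs.  A single-child node passes its input
    through unchanged.  Internal results re-enter parent analyses with
    ``N`` set to their per-variant effective sample size.  Returns one
    result table per internal node.
    """
    order = _plan_order(plan, set(studies))
    results: dict[str, pd.DataFrame] = {}
    pool: dict[str, pd.DataFrame] = dict(studies)
    for node in order:
        children = plan[node]
        inputs = {c: pool[c] for c in children}
        if len(inputs) == 1:
            out = next(iter(inputs.values())).copy()
            if "N_STUDIES" not in out.columns:
                out["N_STUDIES"] = 1
                sign = np.sign(out["Z"].to_numpy())
                out[f"SIGN_{children[0]}"] = sign
        else:
            if models is not None and node in models:
                model = models[node]
            else:
                model = estimate_z_correlation(inputs, min_shared=min_shared,
                                               **overlap_kwargs)
            out = meta_weighted_z(inputs, model)
        results[node] = out
        pool[node] = out
    return results
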