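"""Lead-variant selection and genomic risk locus definition.

Follows the standard post-GWAS convention: independent lead variants are
genome-wide significant variants chosen greedily by ascending P-value
subject to pairwise LD r^2 < 0.1; each lead's locus spans all variants
with r^2 > 0.6 to it; same-chromosome loci closer than 250 kb are merged
transitively.  Coordinates are 1-based inclusive in the result tables;
BED export converts to 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crossmeta.meta import GWS_P
from crossmeta.simulate import GenotypeMatrix

log = logging.getLogger(__name__)

LEAD_R2 = 0.1
BORDER_R2 = 0.6
MERGE_GAP_BP = 250_000
LD_WINDOW_BP = 1_000_000


@dataclass
class LDMatrix:
    """Pairwise squared dosage correlations among a set of variants."""

    snps: list[str]
    r2: np.ndarray
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.index = {s: i for i, s in enumerate(self.snps)}

    def pair(self, a: str, b: str) -> float:
        return float(self.r2[self.index[a], self.index[b]])


def compute_ld(panel: GenotypeMatrix, snps: list[str] | None = None,
               window_bp: int = LD_WINDOW_BP) -> LDMatrix:
    """Squared Pearson correlation of dosages from a reference panel.

    Pairs farther apart than ``window_bp`` (or on different chromosomes)
    are set to 0.  Monomorphic variants get r^2 = 0 with every other
    variant (their own diagonal stays 1) and a warning.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    meta = panel.variants
    if snps is None:
        snps = meta["SNP"].tolist()
    pos = meta.set_index("SNP")
    idx = [int(pos.index.get_indexer([s])[0]) for s in snps]
    G = panel.dosages[:, idx].astype(np.float64)
    Gc = G - G.mean(axis=0)
    sd = Gc.std(axis=0)
    mono = sd == 0.0
    if mono.any():
        log.warning("compute_ld: %d monomorphic variants (r2 set to 0)",
                    int(mono.sum()))
    sd_safe = np.where(mono, 1.0, sd)
    X = Gc / sd_safe
    r = (X.T @ X) / G.shape[0]
    r2 = r * r
    r2[mono, :] = 0.0
    r2[:, mono] = 0.0
    np.fill_diagonal(r2, 1.0)
    bp = pos["BP"].reindex(snps).to_numpy(dtype=np.int64)
    chrom = pos["CHR"].reindex(snps).to_numpy()
    far = np.abs(bp[:, None] - bp[None, :]) > window_bp
    far |= chrom[:, None] != chrom[None, :]
    np.fill_diagonal(far, False)
    r2[far] = 0.0
    return LDMatrix(snps=list(snps), r2=r2)


def _tie_sorted(result: pd.DataFrame) -> pd.DataFrame:
    # deterministic order: ascending P, ties by (CHR, BP, SNP)
    return result.sort_values(["P", "CHR", "BP", "SNP"], kind="mergesort")


def select_leads(result: pd.DataFrame, ld: LDMatrix,
                 gws_p: float = GWS_P) -> pd.DataFrame:
    """Greedy independent lead variants among GWS variants.

    Scanning variants with ``P < gws_p`` by ascending P, a variant becomes
    a lead iff its r^2 with every previously accepted lead is below 0.1.
    """
    gws = _tie_sorted(result[result["P"] < gws_p])
    leads = []
    for row in gws.itertuples(index=False):
        if row.SNP not in ld.index:
            continue
        if all(ld.pair(row.SNP, l.SNP) < LEAD_R2 for l in leads):
            leads.append(row)
    return pd.DataFrame(leads, columns=gws.columns)


def define_loci(leads: pd.DataFrame, result: pd.DataFrame, ld: LDMatrix,
                gws_p: float = GWS_P) -> pd.DataFrame:
    """One locus per lead: the span of its r^2 > 0.6 partners.

    ``N_GWS`` counts GWS variants inside the interval; ``LD_SUPPORTED`` is
    true when at least two GWS variants fall in the locus (a single
    unsupported variant is a likely false positive).
    """
    rows = []
    res = result.set_index("SNP")
    for lead in leads.itertuples(index=False):
        i = ld.index[lead.SNP]
        partners = [ld.snps[j] for j in np.flatnonzero(ld.r2[i] > BORDER_R2)]
        members = {lead.SNP} | set(partners)
        bps = res["BP"].reindex([m for m in members if m in res.index])
        bps = bps.dropna()
        start = int(min(bps.min(), lead.BP))
        end = int(max(bps.max(), lead.BP))
        inside = res[(res["CHR"] == lead.CHR) & (res["BP"] >= start)
                     & (res["BP"] <= end)]
        n_gws = int((inside["P"] < gws_p).sum())
        rows.append({
            "CHR": lead.CHR, "START": start, "END": end,
            "LEADS": (lead.SNP,), "LEAD_Z": (float(lead.Z),),
            "LEAD_P": (float(lead.P),), "N_GWS": n_gws,
            "LD_SUPPORTED": n_gws >= 2,
        })
    cols = ["CHR", "START", "END", "LEADS", "LEAD_Z", "LEAD_P", "N_GWS",
            "LD_SUPPORTED"]
    return pd.DataFrame(rows, columns=cols)


def merge_loci(loci: pd.DataFrame,
               max_gap_bp: int = MERGE_GAP_BP) -> pd.DataFrame:
    """Merge same-chromosome loci whose gap is strictly below the cutoff.

    The merge relation is closed transitively (a chain A-B-C collapses to
    one locus even when A and C alone would not merge); merged loci span
    the union, pool their leads and sum their GWS counts.
    """
    if loci.empty:
        return loci.copy()
    df = loci.sort_values(["CHR", "START", "END"],
                          kind="mergesort").reset_index(drop=True)
    rows = []
    cur = df.iloc[0].to_dict()
    for _, row in df.iloc[1:].iterrows():
        gap = row["START"] - cur["END"] - 1
        if row["CHR"] == cur["CHR"] and gap < max_gap_bp:
            cur["END"] = max(cur["END"], row["END"])
            cur["LEADS"] = tuple(cur["LEADS"]) + tuple(row["LEADS"])
            cur["LEAD_Z"] = tuple(cur["LEAD_Z"]) + tuple(row["LEAD_Z"])
            cur["LEAD_P"] = tuple(cur["LEAD_P"]) + tuple(row["LEAD_P"])
            cur["N_GWS"] = cur["N_GWS"] + row["N_GWS"]
            cur["LD_SUPPORTED"] = bool(cur["LD_SUPPORTED"] or row["LD_SUPPORTED"])
        else:
            rows.append(cur)
            cur = row.to_dict()
    rows.append(cur)
    return pd.DataFrame(rows, columns=df.columns).reset_index(drop=True)


def annotate_novel(loci: pd.DataFrame, known: pd.DataFrame) -> pd.DataFrame:
    """Flag loci with no overlap with any known interval or variant.

    ``known`` carries CHR plus either START/END intervals or BP positions
    (1-based inclusive, matching the locus convention).  A 1-bp overlap
    already disqualifies novelty.
    """
    out = loci.copy()
    if known is None or known.empty:
        out["NOVEL"] = True
        return out
    if "START" in known.columns:
        ks, ke = known["START"].to_numpy(), known["END"].to_numpy()
    else:
        ks = ke = known["BP"].to_numpy()
    kc = known["CHR"].astype(str).to_numpy()
    novel = []
    for row in out.itertuples(index=False):
        same = kc == str(row.CHR)
        hit = same & (ks <= row.END) & (ke >= row.START)
        novel.append(not bool(hit.any()))
    out["NOVEL"] = novel
    return out


def loci_to_bed(loci: pd.DataFrame) -> pd.DataFrame:
    """0-based half-open BED export of a locus table."""
    return pd.DataFrame({
        "chrom": loci["CHR"],
        "chromStart": loci["START"] - 1,
        "chromEnd": loci["END"],
        "name": ["|".join(l) for l in loci["LEADS"]],
    })


def region_dump(result: pd.DataFrame, locus: pd.Series) -> pd.DataFrame:
    """Plain-text region table (variants of one locus, by position)."""
    sel = result[(result["CHR"] == locus["CHR"])
                 & (result["BP"] >= locus["START"])
                 & (result["BP"] <= locus["END"])]
    return sel.sort_values("BP").reset_index(drop=True)
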