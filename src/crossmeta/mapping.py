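"""Variant-to-gene mapping and evidence-based gene prioritization.

Significant concordant variants are mapped to genes three ways —
positionally (gene body +- 10 kb), through cis-eQTL records, and through
chromatin loops (variant in one anchor, gene overlapping the other,
anchors within 2 Mb) — and the union of mapped genes plus significant
gene-based genes is prioritized by four evidence rules: membership in a
curated pathway, shared gene family with a pathway member, a high-
confidence interaction with a pathway member, or a prior association with
psychiatric or brain-related traits.  All evidence sources are offline
flat tables; coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

POSITIONAL_MARGIN_BP = 10_000
LOOP_MAX_SPAN_BP = 2_000_000
INTERACTION_SCORE_MIN = 0.7
TRUSTED_EVIDENCE = {"experimental", "database"}
BRAIN_TRAIT_CLASSES = {"psychiatric", "brain-measurement", "brain-function"}


def map_positional(variants: pd.DataFrame, genes: pd.DataFrame,
                   margin_bp: int = POSITIONAL_MARGIN_BP) -> pd.DataFrame:
    """(variant, gene) pairs with the variant inside gene +- margin."""
    rows = []
    for gene in genes.itertuples(index=False):
        sel = variants[(variants["CHR"].astype(str) == str(gene.CHR))
                       & (variants["BP"] >= gene.START - margin_bp)
                       & (variants["BP"] <= gene.END + margin_bp)]
        for snp in sel["SNP"]:
            rows.append({"SNP": snp, "GENE": gene.GENE, "SOURCE": "positional"})
    return pd.DataFrame(rows, columns=["SNP", "GENE", "SOURCE"])


def map_eqtl(variants: pd.DataFrame, eqtls: pd.DataFrame) -> pd.DataFrame:
    """(variant, gene) pairs present in the cis-eQTL lookup table."""
    hits = eqtls[eqtls["SNP"].isin(set(variants["SNP"]))]
    out = hits[["SNP", "GENE"]].drop_duplicates().copy()
    out["SOURCE"] = "eqtl"
    return out.reset_index(drop=True)


def map_chromatin(variants: pd.DataFrame, loops: pd.DataFrame,
                  genes: pd.DataFrame,
                  max_span_bp: int = LOOP_MAX_SPAN_BP) -> pd.DataFrame:
    """(variant, gene) pairs connected by a chromatin loop.

    A pair is emitted when the variant lies in one anchor, the gene
    interval overlaps the other anchor, and the outermost anchor span is
    at most ``max_span_bp``.
    """
    rows = []
    for loop in loops.itertuples(index=False):
        span = loop.END2 - loop.START1
        if span > max_span_bp:
            continue
        vsel = variants[variants["CHR"].astype(str) == str(loop.CHR)]
        gsel = genes[genes["CHR"].astype(str) == str(loop.CHR)]
        in1 = vsel[(vsel["BP"] >= loop.START1) & (vsel["BP"] <= loop.END1)]
        in2 = vsel[(vsel["BP"] >= loop.START2) & (vsel["BP"] <= loop.END2)]
        g1 = gsel[(gsel["START"] <= loop.END1) & (gsel["END"] >= loop.START1)]
        g2 = gsel[(gsel["START"] <= loop.END2) & (gsel["END"] >= loop.START2)]
        for snps, gs in ((in1, g2), (in2, g1)):
            for snp in snps["SNP"]:
                for gene in gs["GENE"]:
                    rows.append({"SNP": snp, "GENE": gene,
                                 "SOURCE": "chromatin"})
    out = pd.DataFrame(rows, columns=["SNP", "GENE", "SOURCE"])
    return out.drop_duplicates().reset_index(drop=True)


@dataclass
class EvidenceTables:
    """Offline evidence for prioritization.

    ``pathways`` maps pathway name -> gene set; ``families`` has columns
    GENE/FAMILY; ``interactions`` GENE1/GENE2/SCORE/EVIDENCE;
    ``trait_classes`` GENE/TRAIT_CLASS.
    """

    pathways: dict[str, set[str]] = field(default_factory=dict)
    families: pd.DataFrame | None = None
    interactions: pd.DataFrame | None = None
    trait_classes: pd.DataFrame | None = None

    def pathway_members(self) -> set[str]:
        out: set[str] = set()
        for members in self.pathways.values():
            out |= set(members)
        return out


def prioritize(candidates: list[str] | set[str],
               tables: EvidenceTables) -> pd.DataFrame:
    """Evidence-based prioritization of candidate genes.

    A candidate is prioritized when any rule fires: (a) pathway member;
    (b) same family as a pathway member; (c) interaction with a pathway
    member at score >= 0.7 or with trusted (experimental/database)
    evidence; (d) trait class among the psychiatric/brain categories.
    All firing reasons are recorded.  Returns one row per candidate with
    a PRIORITIZED flag and a REASONS tuple.
    """
    members = tables.pathway_members()
    fam_of: dict[str, str] = {}
    pathway_families: set[str] = set()
    if tables.families is not None and len(tables.families):
        fam_of = dict(zip(tables.families["GENE"], tables.families["FAMILY"]))
        pathway_families = {fam_of[g] for g in members if g in fam_of}
    partners: dict[str, set[str]] = {}
    if tables.interactions is not None and len(tables.interactions):
        inter = tables.interactions
        strong = (inter["SCORE"] >= INTERACTION_SCORE_MIN) | \
            inter["EVIDENCE"].isin(TRUSTED_EVIDENCE)
        for row in inter[strong].itertuples(index=False):
            partners.setdefault(row.GENE1, set()).add(row.GENE2)
            partners.setdefault(row.GENE2, set()).add(row.GENE1)
    trait_of: dict[str, str] = {}
    if tables.trait_classes is not None and len(tables.trait_classes):
        trait_of = dict(zip(tables.trait_classes["GENE"],
                            tables.trait_classes["TRAIT_CLASS"]))
    rows = []
    for gene in sorted(set(candidates)):
        reasons = []
        if gene in members:
            reasons.append("pathway")
        if gene not in members and fam_of.get(gene) in pathway_families:
            reasons.append("family")
        if partners.get(gene, set()) & members:
            reasons.append("interaction")
        if trait_of.get(gene) in BRAIN_TRAIT_CLASSES:
            reasons.append("trait")
        rows.append({"GENE": gene, "PRIORITIZED": bool(reasons),
                     "REASONS": tuple(reasons)})
    return pd.DataFrame(rows, columns=["GENE", "PRIORITIZED", "REASONS"])


def candidate_genes(mapped: pd.DataFrame, gene_based: pd.DataFrame,
                    expressed: set[str] | None = None,
                    gene_alpha: float = 0.05) -> set[str]:
    """Union of mapped genes (brain-expressed only) and significant
    gene-based genes (Bonferroni within the gene table)."""
    out = set(mapped["GENE"]) if len(mapped) else set()
    if expressed is not None:
        out &= expressed
    if len(gene_based):
        cutoff = gene_alpha / len(gene_based)
        out |= set(gene_based.loc[gene_based["P"] < cutoff, "GENE"])
    return out
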