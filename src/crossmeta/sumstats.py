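"""Reading, harmonization and writing of GWAS summary statistics.

The canonical in-memory container is a :class:`pandas.DataFrame` with the
columns

======  =====================================================
SNP     variant identifier (rs-style string)
CHR     chromosome label
BP      1-based base-pair position
A1      effect allele
A2      non-effect allele
Z       signed association statistic
P       two-sided P-value, ``P = 2 * Phi(-|Z|)``
N       per-variant sample size
======  =====================================================

plus the optional columns FRQ (effect-allele frequency), BETA and SE.
Files are tab-delimited text with a header; gzip is handled transparently
by pandas.  Arbitrary source headers are supported through ``column_map``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from crossmeta.errors import FormatError

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "Z"]
CANONICAL_COLUMNS = REQUIRED_COLUMNS + ["P", "N", "FRQ", "BETA", "SE"]

#: allele pairs that cannot be resolved across genotyping strands
STRAND_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


def z_to_p(z):
    """Two-sided P-value of a Z statistic, ``2 * Phi(-|Z|)``."""
    return 2.0 * stats.norm.sf(np.abs(z))


def p_to_z(p):
    """Magnitude of the Z statistic with two-sided P-value ``p``."""
    return stats.norm.isf(np.asarray(p) / 2.0)


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    dup = df["SNP"].duplicated()
    if dup.any():
        first = df.loc[dup, "SNP"].iloc[0]
        raise FormatError(f"duplicate variant id {first!r} in summary statistics")
    if "P" not in df.columns or df["P"].isna().all():
        df["P"] = z_to_p(df["Z"].to_numpy())
    else:
        missing = df["P"].isna()
        if missing.any():
            df.loc[missing, "P"] = z_to_p(df.loc[missing, "Z"].to_numpy())
    return df


def read_sumstats(path, column_map: dict | None = None,
                  malformed_tolerance: float = 0.01) -> pd.DataFrame:
    """Read a tab-delimited summary-statistics file.

    ``column_map`` maps canonical names to source header names, e.g.
    ``{"SNP": "rsid", "Z": "zscore"}``.  Rows whose numeric fields fail to
    parse are counted and dropped; more than ``malformed_tolerance`` of
    malformed rows is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        df = df.rename(columns=rename)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"required column {col!r} missing from {path}")
    n_raw = len(df)
    for col in ("BP", "Z", "P", "N", "FRQ", "BETA", "SE"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df["BP"].isna() | df["Z"].isna() | df["SNP"].isna()
    n_bad = int(bad.sum())
    if n_raw and n_bad / n_raw > malformed_tolerance:
        raise FormatError(
            f"{n_bad}/{n_raw} malformed rows in {path} "
            f"(tolerance {malformed_tolerance:.1%})")
    if n_bad:
        log.warning("dropped %d malformed rows while reading %s", n_bad, path)
        df = df[~bad]
    df = df.reset_index(drop=True)
    df["BP"] = df["BP"].astype(np.int64)
    if "N" in df.columns:
        df["N"] = df["N"].astype(float)
    return _validate(df)


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write summary statistics in the canonical tab-delimited dialect."""
    cols = [c for c in CANONICAL_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def remove_strand_ambiguous(df: pd.DataFrame) -> pd.DataFrame:
    """Drop variants whose allele pair is A/T or C/G.

    Such variants cannot be oriented unambiguously between genotyping
    strands and are removed before harmonization.
    """
    pairs = [frozenset((a1, a2)) for a1, a2 in zip(df["A1"], df["A2"])]
    keep = np.array([p not in STRAND_AMBIGUOUS for p in pairs])
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("removed %d strand-ambiguous variants", n_removed)
    return df[keep].reset_index(drop=True)


def harmonize(df: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Align a study to a reference variant table by id and allele pair.

    ``reference`` carries SNP, A1, A2 (and optionally CHR/BP, which, when
    present, overwrite the study's coordinates).  Records absent from the
    reference are dropped; records matching with swapped alleles have Z
    (and BETA, and FRQ) flipped; records whose allele pair cannot be
    reconciled are dropped.  Strand-ambiguous variants must have been
    removed beforehand.  The output allele orientation matches the
    reference exactly, so the operation is idempotent.
    """
    ref = reference.set_index("SNP")
    present = df["SNP"].isin(ref.index)
    dropped_absent = int((~present).sum())
    out = df[present].copy()
    ra1 = ref["A1"].reindex(out["SNP"]).to_numpy()
    ra2 = ref["A2"].reindex(out["SNP"]).to_numpy()
    a1 = out["A1"].to_numpy()
    a2 = out["A2"].to_numpy()
    same = (a1 == ra1) & (a2 == ra2)
    swapped = (a1 == ra2) & (a2 == ra1)
    out = out[same | swapped].copy()
    flip = swapped[same | swapped]
    n_mismatch = int((~(same | swapped)).sum())
    out.loc[flip, "Z"] = -out.loc[flip, "Z"]
    if "BETA" in out.columns:
        out.loc[flip, "BETA"] = -out.loc[flip, "BETA"]
    if "FRQ" in out.columns:
        out.loc[flip, "FRQ"] = 1.0 - out.loc[flip, "FRQ"]
    out.loc[flip, "A1"] = ra1[same | swapped][flip]
    out.loc[flip, "A2"] = ra2[same | swapped][flip]
    if dropped_absent or n_mismatch:
        log.info("harmonize: dropped %d variants absent from reference, "
                 "%d with irreconcilable alleles; flipped %d",
                 dropped_absent, n_mismatch, int(flip.sum()))
    if "CHR" in reference.columns and "BP" in reference.columns:
        out["CHR"] = ref["CHR"].reindex(out["SNP"]).to_numpy()
        out["BP"] = ref["BP"].reindex(out["SNP"]).to_numpy()
    return out.reset_index(drop=True)
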