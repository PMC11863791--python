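"""Gene-window annotation of instrumental variables and overlap sets.

A surviving IV is assigned to every named gene whose interval, extended by
a symmetric window (default 1000 bp, inclusive at both boundaries), contains
the SNP position.  Coordinates are 1-based with inclusive gene ends; strand
is ignored.  Cross-exposure overlap sets summarise which candidate genes are
shared between exposures (the partition a Venn diagram displays).
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 1000


def annotate_ivs(
    iv_table: pd.DataFrame,
    gene_intervals: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Assign each IV to genes within ``window_bp`` of its position.

    ``iv_table`` needs columns ``SNP, Chr, bp`` (extra columns such as
    ``exposure``/``outcome`` are carried through); ``gene_intervals`` needs
    ``chrom, start, end, symbol`` (1-based inclusive).  A SNP at position b
    hits gene [s, e] iff ``s - window_bp <= b <= e + window_bp``.  Rows with
    empty symbols are ignored; malformed intervals (start > end) are
    rejected with their line numbers logged.
    """
    genes = gene_intervals.reset_index(drop=True)
    bad = genes["start"] > genes["end"]
    if bad.any():
        for ln in genes.index[bad]:
            logger.warning("annotate_ivs: rejecting malformed interval at row %d (start > end)", ln)
        genes = genes[~bad]
    genes = genes[genes["symbol"].astype(str).str.strip().ne("")]

    carry = [c for c in iv_table.columns if c not in ("SNP", "Chr", "bp")]
    rows = []
    for chrom, snps in iv_table.groupby("Chr"):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        starts = g["start"].to_numpy(np.int64)
        ends = g["end"].to_numpy(np.int64)
        for _, snp in snps.iterrows():
            b = int(snp["bp"])
            hit = (starts - window_bp <= b) & (b <= ends + window_bp)
            for gi in np.flatnonzero(hit):
                s, e = int(starts[gi]), int(ends[gi])
                dist = 0 if s <= b <= e else (b - e if b > e else b - s)
                row = {
                    "SNP": snp["SNP"], "Chr": chrom, "bp": b,
                    "symbol": g["symbol"].iloc[gi], "gene_start": s, "gene_end": e,
                    "distance": dist,
                }
                row.update({c: snp[c] for c in carry})
                rows.append(row)
    cols = ["SNP", "Chr", "bp", "symbol", "gene_start", "gene_end", "distance", *carry]
    return pd.DataFrame(rows, columns=cols)


def overlap_sets(genehits_by_exposure: dict[str, pd.DataFrame | set]) -> tuple[pd.DataFrame, dict]:
    """Cross-exposure gene membership and exact-region counts.

    Accepts per-exposure annotation tables (their ``symbol`` columns) or
    plain gene-symbol sets.  Returns (membership, region_counts): membership
    is a boolean genes x exposures table; region_counts maps each non-empty
    exposure combination (a sorted tuple) to the number of genes belonging
    to exactly that combination — the counts of a Venn partition.
    """
    if len(genehits_by_exposure) < 2:
        raise ValueError("overlap_sets needs at least 2 exposures")
    sets = {
        exp: set(v["symbol"]) if isinstance(v, pd.DataFrame) else set(v)
        for exp, v in genehits_by_exposure.items()
    }
    exposures = sorted(sets)
    union = sorted(set().union(*sets.values()))
    membership = pd.DataFrame(
        {exp: [g in sets[exp] for g in union] for exp in exposures},
        index=pd.Index(union, name="symbol"),
    )
    counts = {}
    for r in range(1, len(exposures) + 1):
        for combo in combinations(exposures, r):
            inset = set(combo)
            exact = [
                g for g in union
                if all(g in sets[e] for e in combo)
                and all(g not in sets[e] for e in exposures if e not in inset)
            ]
            counts[tuple(combo)] = len(exact)
    return membership, counts
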