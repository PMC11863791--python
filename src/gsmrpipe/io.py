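"""Readers and writers for the pipeline's file formats.

Genotypes travel as PLINK bed/bim/fam triplets (SNP-major bed, 1-based bim
positions) or an equivalent transparent gzip-TSV dialect; phenotypes as
3-column TSV (FID, IID, value) per trait; summary statistics in the
GCTA-COJO ``.ma`` layout (SNP A1 A2 freq b se p N); GRMs in the GCTA
gzip-text format; gene intervals from GFF3 (``gene`` features with a
``gene_name``/``Name`` attribute) or 4-column BED + symbol.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import GenotypePanel, TruthRecord

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes -> A1 dosage: 00 hom A1 = 2, 10 het = 1, 11 hom A2 = 0,
# 01 missing = -1 (mean-imputed on read)
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11}

_BYTE_LUT = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _i in range(4):
        _BYTE_LUT[_b, _i] = _CODE_TO_DOSAGE[(_b >> (2 * _i)) & 0b11]


def _ext(prefix: Path, suffix: str) -> Path:
    return prefix.parent / (prefix.name + suffix)


class FormatError(ValueError):
    """Raised when an on-disk file does not match its declared format."""


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as PLINK bed/bim/fam (SNP-major)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mk = panel.markers
    bim = pd.DataFrame(
        {"chrom": mk["chrom"], "id": mk["id"], "cm": 0, "bp": mk["bp"],
         "a1": mk["a1"], "a2": mk["a2"]}
    )
    bim.to_csv(_ext(prefix, ".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": panel.samples, "iid": panel.samples, "pat": 0, "mat": 0, "sex": 0, "phe": -9}
    )
    fam.to_csv(_ext(prefix, ".fam"), sep="\t", header=False, index=False)

    n = panel.n_samples
    n_bytes = (n + 3) // 4
    with open(_ext(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        codes = np.zeros((panel.n_snps, n_bytes * 4), dtype=np.uint8)
        dos = panel.dosages
        for val, code in _DOSAGE_TO_CODE.items():
            codes[:, :n][dos.T == val] = code
        packed = (
            codes[:, 0::4]
            | (codes[:, 1::4] << 2)
            | (codes[:, 2::4] << 4)
            | (codes[:, 3::4] << 6)
        ).astype(np.uint8)
        fh.write(packed.tobytes())


def read_plink(prefix: str | Path, maf_filter: float | None = None,
               x_chrom: int | None = None) -> GenotypePanel:
    """Read a bed/bim/fam triplet into a :class:`GenotypePanel`.

    Missing genotypes are mean-imputed per SNP (rounded to the nearest
    dosage; count logged).  With ``maf_filter`` set, SNPs below that minor
    allele frequency are removed.  ``x_chrom`` flags the chromosome code to
    treat as X.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        _ext(prefix, ".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "bp", "a1", "a2"],
    )
    fam = pd.read_csv(
        _ext(prefix, ".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "phe"], dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(_ext(prefix, ".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{_ext(prefix, '.bed')}: bad magic bytes (not SNP-major PLINK bed)")
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != m * n_bytes:
        raise FormatError(
            f"{_ext(prefix, '.bed')}: expected {m * n_bytes} genotype bytes "
            f"for {n} samples x {m} SNPs, found {body.size}"
        )
    dos = _BYTE_LUT[body.reshape(m, n_bytes)].reshape(m, n_bytes * 4)[:, :n].T.copy()
    miss = dos < 0
    if miss.any():
        n_miss = int(miss.sum())
        logger.info("read_plink: mean-imputing %d missing genotypes", n_miss)
        col_mean = np.where(miss, 0, dos).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1)
        fill = np.clip(np.rint(col_mean), 0, 2).astype(np.int8)
        dos = np.where(miss, fill[None, :], dos)
    markers = bim[["id", "chrom", "bp", "a1", "a2"]].copy()
    markers["freq"] = dos.mean(axis=0) / 2.0
    panel = GenotypePanel(
        dosages=dos.astype(np.int8), markers=markers,
        samples=fam["iid"].tolist(), x_chrom=x_chrom,
    )
    if maf_filter is not None:
        maf = np.minimum(markers["freq"], 1 - markers["freq"]).to_numpy()
        keep = maf >= maf_filter
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("read_plink: MAF filter removed %d of %d SNPs", n_drop, m)
            panel = panel.subset_snps(keep)
    return panel


# ---------------------------------------------------------------------------
# transparent TSV genotype dialect


def write_panel_tsv(panel: GenotypePanel, path: str | Path) -> None:
    """Gzip TSV: marker columns (id, chrom, bp, a1, a2) then one dosage
    column per sample."""
    df = panel.markers[["id", "chrom", "bp", "a1", "a2"]].copy()
    dos = pd.DataFrame(panel.dosages.T, columns=panel.samples)
    pd.concat([df.reset_index(drop=True), dos], axis=1).to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: str | Path, x_chrom: int | None = None) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t")
    meta = ["id", "chrom", "bp", "a1", "a2"]
    samples = [c for c in df.columns if c not in meta]
    dos = df[samples].to_numpy(dtype=np.int8).T
    markers = df[meta].copy()
    markers["freq"] = dos.mean(axis=0) / 2.0
    return GenotypePanel(dosages=dos, markers=markers, samples=samples, x_chrom=x_chrom)


# ---------------------------------------------------------------------------
# phenotypes, truth sidecar


def write_phenotype(trait: pd.Series, path: str | Path) -> None:
    """3-column TSV (FID, IID, value); FID repeats the IID."""
    pd.DataFrame({"fid": trait.index, "iid": trait.index, "value": trait.to_numpy()}).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_phenotype(path: str | Path, name: str = "trait") -> pd.Series:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["fid", "iid", "value"],
                     dtype={"iid": str})
    return pd.Series(df["value"].to_numpy(), index=df["iid"], name=name)


def write_truth(truth: TruthRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# b_xy_true\t{truth.b_xy_true}\n")
        truth.to_frame().to_csv(fh, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        df = pd.read_csv(fh, sep="\t")
    df.attrs["b_xy_true"] = float(header[1])
    return df


# ---------------------------------------------------------------------------
# summary statistics (.ma) and GRM text format


def write_ma(table: pd.DataFrame, path: str | Path) -> None:
    """GCTA-COJO .ma file: SNP A1 A2 freq b se p N."""
    out = table.rename(columns={"Freq": "freq", "n": "N"})
    out[["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]].to_csv(path, sep="\t", index=False)


def read_ma(path: str | Path, panel: GenotypePanel | None = None) -> pd.DataFrame:
    """Read a .ma file; with a reference panel, Chr/bp are merged in."""
    df = pd.read_csv(path, sep=r"\s+")
    df = df.rename(columns={"N": "n"})
    if panel is not None:
        mk = panel.markers[["id", "chrom", "bp"]].rename(
            columns={"id": "SNP", "chrom": "Chr"})
        df = df.merge(mk, on="SNP", how="left")
    return df


def write_grm_gcta(grm, prefix: str | Path) -> None:
    """GCTA gzip-text GRM: ``<prefix>.grm.gz`` (i j n_snps value, 1-based
    lower triangle) and ``<prefix>.grm.id``."""
    prefix = Path(prefix)
    ids = pd.DataFrame({"fid": grm.sample_ids, "iid": grm.sample_ids})
    ids.to_csv(f"{prefix}.grm.id", sep="\t", header=False, index=False)
    n = grm.n
    i, j = np.tril_indices(n)
    with gzip.open(f"{prefix}.grm.gz", "wt") as fh:
        for a, b in zip(i, j):
            fh.write(f"{a + 1}\t{b + 1}\t{grm.n_snps_used}\t{grm.matrix[a, b]:.8g}\n")


def read_grm_gcta(prefix: str | Path):
    from .relatedness import Grm

    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None, names=["fid", "iid"],
                      dtype={"iid": str})
    n = len(ids)
    tab = pd.read_csv(f"{prefix}.grm.gz", sep="\t", header=None,
                      names=["i", "j", "m", "val"])
    A = np.zeros((n, n))
    A[tab["i"] - 1, tab["j"] - 1] = tab["val"]
    A = A + np.tril(A, -1).T
    return Grm(matrix=A, sample_ids=ids["iid"].tolist(), n_snps_used=int(tab["m"].iloc[0]))


# ---------------------------------------------------------------------------
# gene intervals


def read_genes_gff3(path: str | Path, feature: str = "gene") -> pd.DataFrame:
    """Gene intervals from GFF3 (1-based inclusive); symbol from the
    ``gene_name`` or ``Name`` attribute.  Unnamed genes get an empty symbol
    (dropped at annotation time)."""
    import gffutils.iterators

    rows = []
    for f in gffutils.iterators.DataIterator(str(path)):
        if f.featuretype != feature:
            continue
        symbol = (f.attributes.get("gene_name") or f.attributes.get("Name") or [""])[0]
        chrom = f.seqid
        try:
            chrom = int(chrom)
        except ValueError:
            pass
        rows.append({"chrom": chrom, "start": f.start, "end": f.end, "symbol": symbol})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "symbol"])


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """4-column BED (chrom, start, end, symbol); 0-based half-open intervals
    are converted to 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "symbol"],
                     usecols=[0, 1, 2, 3])
    df["start"] = df["start"] + 1
    return df


def read_genes(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return read_genes_gff3(path)
    return read_genes_bed(path)
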