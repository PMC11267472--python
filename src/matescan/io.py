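"""Readers and writers for the on-disk formats.

All tables are plain text.  Genotypes travel as VCF (inbred GT calls,
read through cyvcf2) or as a dosage TSV (variant metadata columns
followed by one column per line); pooled counts as a sync-style TSV;
phenotypes and covariates as TSV.  Every writer emits a header comment
with the tool version and, when available, a config hash, and sorts rows
by (chrom, pos) so outputs are byte-reproducible.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import GenotypeMatrix, PoolCounts, validate_phenotypes

_VARIANT_COLS = ["chrom", "pos", "ref", "alt"]


def _header_comment(config_hash: str | None = None) -> str:
    h = f" config_hash={config_hash}" if config_hash else ""
    return f"# matescan v{__version__}{h}\n"


def write_table(df: pd.DataFrame, path: str, config_hash: str | None = None,
                sort_genomic: bool = True, index: bool = False) -> None:
    """TSV writer with a provenance header comment and deterministic order."""
    if sort_genomic and {"chrom", "pos"} <= set(df.columns):
        df = df.sort_values(["chrom", "pos"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str, het_policy: str = "missing") -> GenotypeMatrix:
    """Read a line x variant dosage matrix from VCF or dosage TSV.

    For VCF, inbred genotypes map 0/0 -> 0, 1/1 -> 2, ./. -> missing;
    heterozygous calls become missing under the default ``het_policy``
    (``'one'`` keeps them as dosage 1).
    """
    if path.endswith((".vcf", ".vcf.gz")):
        return _read_vcf(path, het_policy)
    return _read_dosage_tsv(path)


def _read_vcf(path: str, het_policy: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample names in VCF")
    rows, dosages = [], []
    for i, rec in enumerate(vcf):
        try:
            rows.append(
                {"chrom": rec.CHROM, "pos": rec.POS, "ref": rec.REF,
                 "alt": rec.ALT[0] if rec.ALT else "."}
            )
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = rec.gt_types
        except Exception as exc:  # pragma: no cover - cyvcf2 raises rarely
            raise ValueError(f"malformed VCF record at line {i + 1}: {exc}") from exc
        d = np.full(len(samples), np.nan)
        d[gt == 0] = 0.0
        d[gt == 3] = 2.0
        if het_policy == "one":
            d[gt == 1] = 1.0
        elif het_policy != "missing":
            raise ValueError(f"unknown het_policy {het_policy!r}")
        dosages.append(d)
    variants = pd.DataFrame(rows)
    dosage = np.array(dosages, dtype=float).T if dosages else np.empty((len(samples), 0))
    return GenotypeMatrix(line_ids=samples, variants=variants, dosage=dosage)


def _read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = read_table(path)
    missing = [c for c in _VARIANT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"dosage TSV missing columns {missing}")
    line_cols = [c for c in df.columns if c not in _VARIANT_COLS and c != "af"]
    keep = _VARIANT_COLS + (["af"] if "af" in df.columns else [])
    variants = df[keep].reset_index(drop=True)
    dosage = df[line_cols].to_numpy(dtype=float).T
    return GenotypeMatrix(line_ids=line_cols, variants=variants, dosage=dosage)


def write_genotypes(g: GenotypeMatrix, path: str, config_hash: str | None = None) -> None:
    """Write genotypes as VCF (``.vcf`` suffix) or dosage TSV."""
    if path.endswith(".vcf"):
        _write_vcf(g, path, config_hash)
    else:
        df = g.variants.copy()
        for i, lid in enumerate(g.line_ids):
            df[lid] = g.dosage[i]
        write_table(df, path, config_hash)


def _write_vcf(g: GenotypeMatrix, path: str, config_hash: str | None) -> None:
    order = np.lexsort((g.variants["pos"].to_numpy(), g.variants["chrom"].to_numpy()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=matescan_v{__version__}")
        fh.write(f" config_hash={config_hash}\n" if config_hash else "\n")
        for chrom in pd.unique(g.variants["chrom"].to_numpy()[order]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.line_ids) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in order:
            row = g.variants.iloc[j]
            calls = [
                gt_map.get(g.dosage[i, j], "./.") if not np.isnan(g.dosage[i, j]) else "./."
                for i in range(g.n_lines)
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# pooled counts (sync-style TSV)
# ---------------------------------------------------------------------------

_POOL_COLS = ["chrom", "pos", "ref", "alt", "pool_id", "group", "replicate",
              "n_flies", "ref_count", "alt_count"]


def write_pool_counts(pools: Iterable[PoolCounts], path: str,
                      config_hash: str | None = None) -> None:
    frames = []
    for p in pools:
        df = p.variants[_VARIANT_COLS].copy()
        df["pool_id"] = p.pool_id
        df["group"] = p.group
        df["replicate"] = p.replicate
        df["n_flies"] = p.n_flies
        df["ref_count"] = p.ref_count
        df["alt_count"] = p.alt_count
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["pool_id", "chrom", "pos"], kind="mergesort")
    write_table(out, path, config_hash, sort_genomic=False)


def read_pool_counts(path: str) -> list[PoolCounts]:
    """Read sync-style pooled counts; one :class:`PoolCounts` per pool id."""
    df = read_table(path)
    missing = [c for c in _POOL_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"pool count TSV missing columns {missing}")
    if (df[["ref_count", "alt_count"]] < 0).any().any():
        raise ValueError("negative read counts")
    if not (df[["ref_count", "alt_count"]] == df[["ref_count", "alt_count"]].astype(int)).all().all():
        raise ValueError("read counts must be integral")
    pools = []
    for pid, sub in df.groupby("pool_id", sort=True):
        sub = sub.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        pools.append(
            PoolCounts(
                pool_id=str(pid),
                group=str(sub["group"].iloc[0]),
                replicate=int(sub["replicate"].iloc[0]),
                n_flies=int(sub["n_flies"].iloc[0]),
                variants=sub[_VARIANT_COLS].reset_index(drop=True),
                ref_count=sub["ref_count"].to_numpy(dtype=int),
                alt_count=sub["alt_count"].to_numpy(dtype=int),
            )
        )
    return pools


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_genes(path: str) -> pd.DataFrame:
    """Read gene intervals from BED or GFF3 into 1-based inclusive
    coordinates (columns gene_id, chrom, start, end).

    BED is 0-based half-open and converted at this boundary; GFF3 is
    already 1-based inclusive, and only ``gene`` features are kept (all
    features if none are typed ``gene``).
    """
    if path.endswith((".gff", ".gff3")):
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "source", "type", "start", "end", "score",
                   "strand", "frame", "attributes"],
        )
        genes = df[df["type"] == "gene"] if (df["type"] == "gene").any() else df
        ids = genes["attributes"].str.extract(r"(?:ID|gene_id)=([^;]+)")[0]
        ids = ids.fillna(pd.Series([f"gene{i}" for i in range(len(genes))],
                                   index=genes.index))
        out = pd.DataFrame({"gene_id": ids, "chrom": genes["chrom"],
                            "start": genes["start"], "end": genes["end"]})
    elif path.endswith(".bed"):
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
        out = pd.DataFrame({
            "gene_id": df[3] if df.shape[1] > 3 else [f"gene{i}" for i in range(len(df))],
            "chrom": df[0],
            "start": df[1] + 1,  # 0-based half-open -> 1-based inclusive
            "end": df[2],
        })
    else:
        raise ValueError("gene models must be .bed, .gff or .gff3")
    if (out["start"] > out["end"]).any():
        raise ValueError("malformed gene interval: start > end")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# phenotypes and covariates
# ---------------------------------------------------------------------------

def write_phenotypes(pheno: pd.DataFrame, path: str, config_hash: str | None = None) -> None:
    validate_phenotypes(pheno)
    write_table(pheno, path, config_hash, sort_genomic=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    return validate_phenotypes(read_table(path))


def write_covariates(cov: pd.DataFrame, path: str, config_hash: str | None = None) -> None:
    write_table(cov.reset_index(), path, config_hash, sort_genomic=False)


def read_covariates(path: str) -> pd.DataFrame:
    df = read_table(path)
    if "line" not in df.columns:
        raise ValueError("covariate TSV needs a 'line' column")
    return df.set_index("line")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
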