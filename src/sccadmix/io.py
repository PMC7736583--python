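"""File formats: VCF genotypes, tab-separated tables, YAML configuration.

Genotypes travel as uncompressed VCF (phased ``GT`` when haplotypes are
known, read back through :mod:`pysam`) or as a plain individuals × variants
dosage matrix.  All result tables are tab-separated with ``#``-prefixed
header lines recording the seed, package version and configuration hash so
any output can be traced to the run that produced it.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from . import __version__
from .data import GenotypeData
from .errors import InvalidArgumentError, ValidationError


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------
def write_vcf(genotypes: GenotypeData, path: str | Path) -> None:
    """Write genotypes as uncompressed VCF (phased GT when available)."""
    path = Path(path)
    var = genotypes.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(var["chrom"].astype(str)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        haps = genotypes.haplotypes
        for j in range(genotypes.n_variants):
            row = var.iloc[j]
            if haps is not None:
                cells = []
                for i in range(genotypes.n_samples):
                    a, b = haps[i, 0, j], haps[i, 1, j]
                    cells.append("./." if a < 0 or b < 0 else f"{a}|{b}")
            else:
                cells = []
                for d in genotypes.dosages[:, j]:
                    if not np.isfinite(d):
                        cells.append("./.")
                    else:
                        cells.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(round(d))])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeData:
    """Read an uncompressed VCF into a dosage matrix (+ haplotypes if the
    GT fields are phased).  Coordinates stay 1-based as in the file."""
    path = Path(path)
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if len(set(samples)) != len(samples):
            raise ValidationError("sample ids in VCF are not unique")
        records = list(vf)
    m, n = len(records), len(samples)
    dosages = np.full((n, m), np.nan)
    haplotypes = np.full((n, 2, m), -1, dtype=np.int8)
    phased_everywhere = True
    rows = []
    for j, rec in enumerate(records):
        if rec.alts is None or len(rec.alts) != 1:
            raise InvalidArgumentError(
                f"record {rec.id or rec.pos}: only biallelic sites are supported"
            )
        rows.append(
            {
                "variant_id": rec.id or f"{rec.chrom}:{rec.pos}",
                "chrom": str(rec.chrom),
                "pos": int(rec.pos),
                "ref": rec.ref,
                "alt": rec.alts[0],
            }
        )
        for i, s in enumerate(samples):
            sample = rec.samples[s]
            gt = sample.get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            if len(gt) != 2:
                raise InvalidArgumentError("mixed ploidy is unsupported")
            dosages[i, j] = sum(gt)
            if sample.phased:
                haplotypes[i, :, j] = gt
            else:
                phased_everywhere = False
    return GenotypeData(
        samples=samples,
        variants=pd.DataFrame(rows),
        dosages=dosages,
        haplotypes=haplotypes if phased_everywhere else None,
    )


# ---------------------------------------------------------------------------
# dosage matrix / tables
# ---------------------------------------------------------------------------
def write_dosage_tsv(genotypes: GenotypeData, path: str | Path, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        genotypes.dosages, columns=genotypes.variant_ids
    )
    df.insert(0, "individual_id", genotypes.samples)
    write_table(df, path, meta or {})


def read_dosage_tsv(path: str | Path, variants: pd.DataFrame | None = None) -> GenotypeData:
    df = read_table(path)
    samples = df["individual_id"].astype(str).tolist()
    ids = [c for c in df.columns if c != "individual_id"]
    if variants is None:
        variants = pd.DataFrame(
            {
                "variant_id": ids,
                "chrom": "1",
                "pos": np.arange(1, len(ids) + 1),
                "ref": "A",
                "alt": "G",
            }
        )
    return GenotypeData(
        samples=samples,
        variants=variants,
        dosages=df[ids].to_numpy(dtype=float),
    )


def read_genotypes(path: str | Path, fmt: str = "vcf") -> GenotypeData:
    """Load genotypes from ``vcf`` or ``dosage_tsv``."""
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "dosage_tsv":
        return read_dosage_tsv(path)
    raise InvalidArgumentError(f"unknown genotype format {fmt!r}")


def header_lines(meta: dict) -> list[str]:
    fields = {"version": __version__, **meta}
    return [f"# {k}={v}" for k, v in fields.items()]


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Tab-separated table with ``#`` metadata header lines."""
    buf = _io.StringIO()
    for line in header_lines(meta or {}):
        buf.write(line + "\n")
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidArgumentError("configuration file must hold a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
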