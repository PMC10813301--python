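"""Readers and writers for the pipeline's on-disk formats.

Formats: minimal genotype VCF (GT-only, one column per sample), a dosage
TSV dialect (``CHROM POS ID A1 A2`` then one column per sample, values
0/1/2/NA), phenotype TSV, summary-statistics TSV
(``CHR SNP BP A1 A2 MAF BETA SE P N TRAIT``), pairwise LD TSV
(``SNP_A SNP_B R2``) and the loci report TSV.

Scientific notation is accepted both in machine form (``3.68e-54``) and
in the typeset form tables are printed in (``3.68 × 10−54``, unicode
multiplication sign and minus, optional carets), as are digit-grouped
positions (``27,519,736``).
"""

from __future__ import annotations

import re
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .synthdata import MISSING, GenotypeMatrix

_SCI_RE = re.compile(
    r"^\s*([+-]?[\d.,]+)\s*[×x]\s*10\^?\s*([+-−–]?\s*\d+)\^?\s*$")


class SchemaError(ValueError):
    """A file is missing required columns or contains malformed rows."""


def parse_number(text) -> float:
    """Parse a number in machine or typeset scientific notation.

    Handles ``1.44e-8``, ``3.68 × 10−54``, ``1.02 × 10^8``, comma digit
    grouping and unicode minus signs.
    """
    if isinstance(text, (int, float, np.integer, np.floating)):
        return float(text)
    s = str(text).strip().replace("−", "-").replace("–", "-")
    m = _SCI_RE.match(s)
    if m:
        mantissa = float(m.group(1).replace(",", ""))
        exponent = int(m.group(2).replace(" ", ""))
        return mantissa * 10.0 ** exponent
    return float(s.replace(",", ""))


# ---------------------------------------------------------------- genotypes

def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write genotypes as a minimal VCF 4.2 (GT-only)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        for chrom in dict.fromkeys(G.snp_meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.sample_ids) + "\n")
        meta = G.snp_meta
        for j in range(G.n_snps):
            # a1 is the counted (effect) allele = ALT; a2 = REF
            row = [str(meta["chrom"].iloc[j]), str(int(meta["pos"].iloc[j])),
                   str(meta["id"].iloc[j]), str(meta["a2"].iloc[j]),
                   str(meta["a1"].iloc[j]), ".", "PASS", ".", "GT"]
            row += [gt_map[int(v)] for v in G.dosages[:, j]]
            fh.write("\t".join(row) + "\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a GT-only VCF into a GenotypeMatrix (ALT dosage counted).

    Non-diploid GT records are rejected with the offending file line
    number.
    """
    from cyvcf2 import VCF

    with open(path) as fh:
        n_header = 0
        for line in fh:
            n_header += 1
            if line.startswith("#CHROM"):
                break
    vcf = VCF(path)
    samples = list(vcf.samples)
    chroms, pos, ids, a1, a2, rows = [], [], [], [], [], []
    for k, var in enumerate(vcf):
        gts = var.genotypes  # [allele_a, allele_b, phased] per sample
        line_no = n_header + 1 + k
        if any(len(g) != 3 for g in gts):
            raise SchemaError(
                f"{path}: non-diploid GT at line {line_no} ({var.ID})")
        dos = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            alleles = g[:2]
            if -1 in alleles:
                dos[i] = MISSING
            else:
                dos[i] = int(alleles[0] > 0) + int(alleles[1] > 0)
        rows.append(dos)
        chroms.append(var.CHROM)
        pos.append(var.POS)
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        a2.append(var.REF)
        a1.append(var.ALT[0] if var.ALT else ".")
    meta = pd.DataFrame({"chrom": chroms, "pos": np.array(pos,
                                                          dtype=np.int64),
                         "id": ids, "a1": a1, "a2": a2})
    dosages = np.array(rows, dtype=np.int8).T if rows else \
        np.empty((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(dosages, meta, samples)


_DOSAGE_FIXED = ["CHROM", "POS", "ID", "A1", "A2"]


def write_dosage_tsv(G: GenotypeMatrix, path: str) -> None:
    """Write the dosage TSV dialect: one row per SNP, fixed metadata
    columns then one 0/1/2/NA column per sample."""
    meta = pd.DataFrame({"CHROM": G.snp_meta["chrom"],
                         "POS": G.snp_meta["pos"],
                         "ID": G.snp_meta["id"],
                         "A1": G.snp_meta["a1"],
                         "A2": G.snp_meta["a2"]})
    dos = G.dosages.T.astype(object)
    dos[dos == MISSING] = "NA"
    body = pd.DataFrame(dos, columns=list(G.sample_ids))
    pd.concat([meta, body], axis=1).to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    missing_cols = [c for c in _DOSAGE_FIXED if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing required columns "
                          f"{missing_cols}")
    samples = [c for c in df.columns if c not in _DOSAGE_FIXED]
    dos = df[samples].to_numpy()
    out = np.empty(dos.shape, dtype=np.int8)
    for (i, j), v in np.ndenumerate(dos):
        if pd.isna(v) or v == "NA":
            out[i, j] = MISSING
        else:
            iv = int(v)
            if iv not in (0, 1, 2):
                raise SchemaError(
                    f"{path}: bad dosage {v!r} at data row {i + 1}")
            out[i, j] = iv
    meta = pd.DataFrame({"chrom": df["CHROM"].astype(str),
                         "pos": df["POS"].astype(np.int64),
                         "id": df["ID"].astype(str),
                         "a1": df["A1"], "a2": df["A2"]})
    return GenotypeMatrix(out.T.copy(), meta, samples)


# --------------------------------------------------------------- phenotypes

def write_phenotypes(phenos: pd.DataFrame, path: str) -> None:
    phenos.to_csv(path, sep="\t", index=True, index_label="sample_id",
                  na_rep="NA")


def read_phenotypes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: missing required columns "
                          "['sample_id']")
    return df.set_index("sample_id")


# ----------------------------------------------------------- summary stats

_SUMSTAT_MAP = {"CHR": "chrom", "SNP": "id", "BP": "pos", "A1": "a1",
                "A2": "a2", "MAF": "maf", "BETA": "beta", "SE": "se",
                "P": "p", "N": "n", "TRAIT": "trait"}


def write_summary_stats(stats: pd.DataFrame, path: str) -> None:
    inv = {v: k for k, v in _SUMSTAT_MAP.items()}
    out = stats[[c for c in _SUMSTAT_MAP.values()
                 if c in stats.columns]].rename(columns=inv)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_summary_stats(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str},
                     na_values=["NA"])
    missing = [c for c in ("CHR", "SNP", "BP", "P") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    df = df.rename(columns=_SUMSTAT_MAP)
    df["p"] = [parse_number(v) for v in df["p"]]
    return df


# -------------------------------------------------------------- LD and loci

def write_ld_table(ld: pd.DataFrame, path: str) -> None:
    ld.rename(columns=str.upper)[["SNP_A", "SNP_B", "R2"]].to_csv(
        path, sep="\t", index=False)


def read_ld_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    missing = [c for c in ("snp_a", "snp_b", "r2") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


_LOCI_COLS = {"chrom": "CHR", "rsid": "RSID", "pos": "POS",
              "gene": "GENE", "p1": "P1", "trait2": "TRAIT2", "p2": "P2",
              "cfdr": "CFDR"}


def write_loci_table(loci: pd.DataFrame, path: str,
                     header_comment: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        loci.rename(columns=_LOCI_COLS).to_csv(fh, sep="\t", index=False)


def read_loci_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"CHR": str})
    inv = {v: k for k, v in _LOCI_COLS.items()}
    missing = [c for c in inv if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    df = df.rename(columns=inv)
    for col in ("p1", "p2", "cfdr"):
        df[col] = [parse_number(v) for v in df[col]]
    df["pos"] = [int(parse_number(v)) for v in df["pos"]]
    df["gene"] = df["gene"].fillna("")
    return df
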