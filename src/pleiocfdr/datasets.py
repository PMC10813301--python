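"""Packaged reference datasets.

Currently one: the published 39-locus report of shared genetics between
age at menarche and type-2-diabetes traits (Taiwan Biobank cohort),
packaged in its printed typeset notation and parsed through the same
number parser the pipeline uses for its own outputs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import parse_number

_COLUMNS = {"Chr": "chrom", "rs": "rsid", "Position (hg38)": "pos",
            "Gene": "gene", "p of Trait 1": "p1", "Trait 2": "trait2",
            "p of Trait 2": "p2", "cFDR": "cfdr"}


def load_reported_loci() -> pd.DataFrame:
    """Load the packaged 39-locus reference table.

    Returns one row per (index SNP, trait-2 phenotype) — 47 rows over 39
    unique index SNPs, since some loci reach cFDR < 0.05 for several
    metabolic traits.  Continuation rows in the printed layout (blank
    leading fields) are forward-filled from their index SNP.  All numbers
    are parsed from the printed notation (``3.68 × 10−54``, digit-grouped
    or power-of-ten positions).
    """
    ref = resources.files("pleiocfdr.data") / "reported_loci.tsv"
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
    df = df.rename(columns=_COLUMNS)
    for col in ("chrom", "rsid", "pos", "gene", "p1"):
        df[col] = df[col].ffill()
    out = pd.DataFrame({
        "chrom": df["chrom"].astype(str),
        "rsid": df["rsid"],
        "pos": [int(parse_number(v)) for v in df["pos"]],
        "gene": df["gene"],
        "p1": [parse_number(v) for v in df["p1"]],
        "trait2": df["trait2"],
        "p2": [parse_number(v) for v in df["p2"]],
        "cfdr": [parse_number(v) for v in df["cfdr"]],
    })
    return out
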