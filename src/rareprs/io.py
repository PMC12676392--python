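"""Plain-text fixture formats: dosage TSV, phenotype/covariate TSV,
relatedness TSV, MODY region TSV and a minimal VCF writer/reader.

Dosage TSV: individuals x variants, header row of ``chrom:pos:ref:alt``
variant IDs, first column ``ID``. Positions are 1-based as in VCF. MODY
region files are 4-column TSVs (chrom, start, end, gene) with 1-based
inclusive coordinates on both ends — deliberately not BED's 0-based
half-open convention, so the intervals compare directly against variant
keys.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .ldpanel import LDPanel, panel_from_dosages
from .sumstats import parse_variant_key

__all__ = [
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_relatedness_tsv",
    "read_relatedness_tsv",
    "write_mody_regions_tsv",
    "read_mody_regions_tsv",
    "write_vcf",
    "read_vcf",
]


def write_dosage_tsv(path, dosages: np.ndarray, variant_keys: Sequence[str],
                     individual_ids: Sequence[str]) -> None:
    df = pd.DataFrame(np.asarray(dosages, dtype=float), columns=list(variant_keys))
    df.insert(0, "ID", list(individual_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_dosage_tsv(path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    ids = df["ID"].astype(str).tolist()
    keys = [c for c in df.columns if c != "ID"]
    return df[keys].to_numpy(dtype=float), keys, ids


def read_panel_tsv(path) -> LDPanel:
    dosages, keys, ids = read_dosage_tsv(path)
    return panel_from_dosages(dosages, keys, ids)


def write_phenotypes_tsv(path, cohort) -> None:
    df = cohort.covariates.copy()
    df.insert(0, "ID", cohort.ids)
    df["phenotype"] = cohort.phenotype
    df["subpop"] = cohort.subpop
    df["age_at_onset"] = cohort.age_at_onset
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def read_phenotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_relatedness_tsv(path, pairs: Sequence[tuple[str, str, float]]) -> None:
    with open(path, "w") as fh:
        fh.write("ID1\tID2\tPI_HAT\n")
        for a, b, pihat in pairs:
            fh.write(f"{a}\t{b}\t{pihat:.6g}\n")


def read_relatedness_tsv(path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (str(r.ID1), str(r.ID2), float(r.PI_HAT)) for r in df.itertuples(index=False)
    ]


def write_mody_regions_tsv(path, regions: Sequence[tuple[str, int, int]],
                           genes: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tgene\n")
        for i, (chrom, start, end) in enumerate(regions):
            gene = genes[i] if genes else f"GENE{i+1}"
            fh.write(f"{chrom}\t{start}\t{end}\t{gene}\n")


def read_mody_regions_tsv(path) -> tuple[tuple[str, int, int], ...]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return tuple(
        (str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples(index=False)
    )


def write_vcf(path, dosages: np.ndarray, variant_keys: Sequence[str],
              individual_ids: Sequence[str]) -> None:
    """Write dosages as an uncompressed VCF with a DS FORMAT field."""
    dosages = np.asarray(dosages, dtype=float)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(individual_ids)
            + "\n"
        )
        for j, key in enumerate(variant_keys):
            chrom, pos, ref, alt = parse_variant_key(key)
            vals = "\t".join(
                "." if np.isnan(d) else f"{d:g}" for d in dosages[:, j]
            )
            fh.write(f"{chrom}\t{pos}\t{key}\t{ref}\t{alt}\t.\t.\t.\tDS\t{vals}\n")


def read_vcf(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read dosages from a VCF (DS field preferred, GT otherwise) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    keys: list[str] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else "."
        keys.append(f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}")
        if "DS" in (rec.FORMAT or []):
            ds = np.array(rec.format("DS"), dtype=float).ravel()
        else:
            gts = np.asarray(rec.genotype.array())[:, :2]
            ds = np.where((gts < 0).any(axis=1), np.nan, gts.clip(min=0).sum(axis=1))
        cols.append(ds)
    vcf.close()
    return np.column_stack(cols) if cols else np.empty((len(ids), 0)), keys, ids
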