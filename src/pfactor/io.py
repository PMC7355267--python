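"""Reading and writing the pipeline's on-disk formats.

Genotype panels travel as VCF with a DS (dosage) FORMAT field; summary
statistics as tab-delimited text with header SNP/CHR/BP/A1/A2/BETA/SE/P;
cohort and score tables as TSV; configuration as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import SUMSTAT_COLUMNS, GenotypePanel

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=pfactor-simulated
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">
"""


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write the panel as an uncompressed VCF (dosages in a DS field)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(VCF_HEADER)
        for c in sorted(panel.variants["CHR"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.person_ids)
            + "\n"
        )
        dosage = panel.dosages
        for j, var in enumerate(panel.variants.itertuples(index=False)):
            ds = "\t".join(
                "." if not np.isfinite(d) else f"{d:g}" for d in dosage[:, j]
            )
            fh.write(
                f"{var.CHR}\t{var.BP}\t{var.SNP}\t{var.REF}\t{var.ALT}\t.\tPASS\t"
                f"AF={var.AAF:.4f}\tDS\t{ds}\n"
            )


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a DS-dosage VCF into a GenotypePanel (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    person_ids = np.array(vcf.samples)
    records, dosage_rows = [], []
    for var in vcf:
        ds = np.asarray(var.format("DS"), dtype=float).ravel()
        records.append(
            {
                "SNP": var.ID,
                "CHR": int(var.CHROM),
                "BP": var.POS,
                "REF": var.REF,
                "ALT": var.ALT[0],
                "AAF": float(np.nanmean(ds)) / 2.0,
            }
        )
        dosage_rows.append(ds)
    vcf.close()
    variants = pd.DataFrame(records)
    variants["block"] = -1  # unknown for external panels
    variants["block_r"] = np.nan
    return GenotypePanel(
        person_ids=person_ids,
        variants=variants,
        dosages=np.asarray(dosage_rows).T,
    )


def write_sumstats(sumstats: pd.DataFrame, path: str | Path) -> None:
    sumstats[SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    missing = set(SUMSTAT_COLUMNS) - set(tab.columns)
    if missing:
        raise ValueError(f"summary statistics missing columns {sorted(missing)}")
    return tab


def write_table(frame: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None):
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def save_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
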