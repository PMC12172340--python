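"""Reading and writing the study's tabular formats.

All tables are TSV: cohort (one row per subject-visit with covariates),
analyte matrices (sample_id rows, analyte columns, empty cell = missing),
genotype dosages (subject rows, variant columns, with a companion variant
info table), and clinical indicators.  Genotypes can also be exchanged as a
minimal VCF (v4.x, GT field, one sample column per subject); FILTER and
QUAL are honoured on input when present.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .qc import QCReport
from .simulate import GenotypeData, GroundTruth

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_analytes",
    "write_analytes",
    "read_dosage",
    "write_dosage",
    "read_vcf",
    "write_vcf",
    "read_clinical",
    "write_qc_report",
    "write_ground_truth",
]

_GT_DOSAGE = {"0/0": 0.0, "0|0": 0.0, "0/1": 1.0, "1/0": 1.0, "0|1": 1.0,
              "1|0": 1.0, "1/1": 2.0, "1|1": 2.0}


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject", "visit", "month", "sex", "age", "bmi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    df.index = pd.Index(
        [f"{s}_v{v}" for s, v in zip(df["subject"], df["visit"])], name="sample_id"
    )
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_analytes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_analytes(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="sample_id")


def read_dosage(path, info_path=None) -> GenotypeData:
    dosage = pd.read_csv(path, sep="\t", index_col=0)
    dosage.index.name = "subject"
    dosage.columns.name = "variant_id"
    if info_path is not None:
        info = pd.read_csv(info_path, sep="\t", index_col=0)
    else:
        freq = dosage.mean(axis=0, skipna=True) / 2.0
        info = pd.DataFrame(
            {
                "chrom": 0,
                "pos": np.arange(1, dosage.shape[1] + 1),
                "maf": np.minimum(freq, 1 - freq),
            },
            index=dosage.columns,
        )
    return GenotypeData(dosage, info.loc[dosage.columns])


def write_dosage(genotypes: GenotypeData, path, info_path=None) -> None:
    genotypes.dosage.to_csv(path, sep="\t", index_label="subject")
    if info_path is not None:
        genotypes.info.to_csv(info_path, sep="\t", index_label="variant_id")


def read_vcf(path, min_qual: float = 30.0, require_pass: bool = True) -> GenotypeData:
    """Read a GT-field VCF into a dosage matrix.

    Honours FILTER (keep PASS or '.') and QUAL >= ``min_qual`` when those
    columns are populated.  Multi-allelic records are skipped.
    """
    subjects: list[str] = []
    rows = []
    info_rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                subjects = line.split("\t")[9:]
                continue
            f = line.split("\t")
            chrom, pos, vid, ref, alt, qual, filt = f[0], f[1], f[2], f[3], f[4], f[5], f[6]
            if "," in alt:
                continue
            if require_pass and filt not in (".", "PASS", ""):
                continue
            if qual not in (".", "") and float(qual) < min_qual:
                continue
            fmt = f[8].split(":")
            try:
                gi = fmt.index("GT")
            except ValueError:
                continue
            dose = [
                _GT_DOSAGE.get(s.split(":")[gi].replace("|", "/"), np.nan)
                for s in f[9:]
            ]
            rows.append(dose)
            info_rows.append(
                {"variant_id": vid if vid != "." else f"{chrom}:{pos}",
                 "chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt}
            )
    if not subjects:
        raise ValueError(f"no #CHROM header found in {path}")
    info = pd.DataFrame(info_rows).set_index("variant_id")
    dosage = pd.DataFrame(
        np.asarray(rows, dtype=float).T,
        index=pd.Index(subjects, name="subject"),
        columns=info.index,
    )
    freq = dosage.mean(axis=0, skipna=True) / 2.0
    info["maf"] = np.minimum(freq, 1 - freq)
    return GenotypeData(dosage, info)


def write_vcf(genotypes: GenotypeData, path) -> None:
    """Write a minimal GT-only VCF (one sample column per subject)."""
    dos = genotypes.dosage
    gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dos.index) + "\n")
        for vid in dos.columns:
            inf = genotypes.info.loc[vid]
            calls = "\t".join(
                gt.get(x, "./.") if not pd.isna(x) else "./." for x in dos[vid]
            )
            fh.write(
                f"{inf['chrom']}\t{int(inf['pos'])}\t{vid}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_qc_report(report: QCReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=str)


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Ground truth as JSON (tuple keys flattened to 'a|b')."""
    d = {
        "seasonal": {k: list(v) for k, v in truth.seasonal.items()},
        "mqtl_effects": [list(x) for x in truth.mqtl_effects],
        "pqtl_effects": [list(x) for x in truth.pqtl_effects],
        "causal_pm": {f"{p}|{m}": v for (p, m), v in truth.causal_pm.items()},
        "confounder_loadings": dict(truth.confounder_loadings),
        "covariate_effects": dict(truth.covariate_effects),
        "variance_shares": dict(truth.variance_shares),
        "risk_labels": dict(truth.risk_labels),
    }
    Path(path).write_text(json.dumps(d, indent=2))
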