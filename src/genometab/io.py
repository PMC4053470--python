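"""File-format layer: phenotype CSV, genotype ped/map and TSV, spectra TSV.

All tables are plain text, UTF-8, '.' decimal separator, header row
mandatory (ped/map excepted, which follow the PLINK text conventions:
whitespace-separated, two allele columns per SNP, missing allele '0').
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .genassoc import GenotypeMatrix
from .simulate.specs import MALB_THRESHOLD
from .spectra import Spectrum

PHENO_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "bmi",
    "sbp",
    "dbp",
    "glucose",
    "creatinine",
    "acr",
    "log_uae",
    "malb",
    "diabetes",
    "hypertension",
]

_REQUIRED_PHENO = {"subject_id", "age", "sex", "bmi", "sbp", "glucose"}


def read_phenotypes(path, malb_threshold: float = MALB_THRESHOLD) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a phenotype CSV.

    Derives ``log_uae`` = log10(ACR) and ``malb`` = ACR >= threshold when
    absent. Rows with non-positive ACR are rejected (log undefined) and
    returned in a second table with reasons — never silently dropped.
    """
    df = pd.read_csv(path)
    missing = _REQUIRED_PHENO - set(df.columns)
    if missing:
        raise SchemaError(f"phenotype CSV missing columns: {sorted(missing)}")
    if "acr" not in df.columns and "log_uae" not in df.columns:
        raise SchemaError("phenotype CSV needs an 'acr' or 'log_uae' column")
    rejected = pd.DataFrame(columns=list(df.columns) + ["reject_reason"])
    if "acr" in df.columns:
        bad = ~(df["acr"] > 0)
        if bad.any():
            rejected = df.loc[bad].copy()
            rejected["reject_reason"] = "acr <= 0: log UAE undefined"
            df = df.loc[~bad].copy()
        if "log_uae" not in df.columns:
            df["log_uae"] = np.log10(df["acr"])
    else:
        df["acr"] = 10.0 ** df["log_uae"]
    if "malb" not in df.columns:
        df["malb"] = (df["acr"] >= malb_threshold).astype(int)
    return df.set_index("subject_id"), rejected


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    out = pheno.reset_index()
    cols = [c for c in PHENO_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotypes


def write_genotypes_tsv(geno: GenotypeMatrix, path) -> None:
    """Simple dialect: rows = subjects, columns = SNPs, values AA/AB/BB/NA."""
    labels = {}
    for snp in geno.snp_ids:
        labels[snp] = geno.genotype_labels(snp)
    table = pd.DataFrame(labels, index=geno.sample_ids)
    table.index.name = "subject_id"
    table.fillna("NA").to_csv(path, sep="\t")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("subject_id")
    calls = {}
    alleles = {}
    for snp in df.columns:
        col = df[snp]
        observed = sorted({a for gt in col.dropna() if gt != "NA" for a in gt})
        if len(observed) > 2:
            raise SchemaError(f"{snp}: more than two alleles observed: {observed}")
        counts = {a: 0 for a in observed}
        for gt in col.dropna():
            if gt == "NA":
                continue
            for a in gt:
                counts[a] += 1
        if not counts:
            calls[snp] = pd.Series(np.nan, index=df.index)
            alleles[snp] = ("A", "B")
            continue
        # minor = lower frequency; ties broken lexicographically (smaller = minor)
        ordered = sorted(counts, key=lambda a: (counts[a], a))
        minor = ordered[0]
        major = ordered[-1] if len(ordered) > 1 else minor
        calls[snp] = col.map(
            lambda gt: np.nan if pd.isna(gt) or gt == "NA" else float(sum(a == minor for a in gt))
        )
        alleles[snp] = (major, minor)
    return GenotypeMatrix(pd.DataFrame(calls, index=df.index), alleles)


def write_ped_map(geno: GenotypeMatrix, ped_path, map_path) -> None:
    """PLINK-style text: .map (chrom, snp, cM, pos) and .ped rows."""
    with open(map_path, "w") as fh:
        for i, snp in enumerate(geno.snp_ids, start=1):
            fh.write(f"0\t{snp}\t0\t{i}\n")
    with open(ped_path, "w") as fh:
        for sid in geno.sample_ids:
            fields = [str(sid), str(sid), "0", "0", "0", "-9"]
            for snp in geno.snp_ids:
                major, minor = geno.alleles[snp]
                c = geno.calls.loc[sid, snp]
                if np.isnan(c):
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [major, major]
                elif c == 1:
                    fields += [major, minor]
                else:
                    fields += [minor, minor]
            fh.write(" ".join(fields) + "\n")


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK-style text genotypes; minor allele recomputed from data."""
    snps = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 2:
                raise SchemaError(f"bad .map line: {line!r}")
            snps.append(parts[1])
    sample_ids = []
    raw = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * len(snps):
                raise SchemaError(
                    f"ped row has {len(parts)} fields; expected {6 + 2 * len(snps)}"
                )
            sample_ids.append(parts[1])
            raw.append(parts[6:])
    calls = {}
    alleles = {}
    for j, snp in enumerate(snps):
        pairs = [(row[2 * j], row[2 * j + 1]) for row in raw]
        counts: dict[str, int] = {}
        for a1, a2 in pairs:
            for a in (a1, a2):
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise SchemaError(f"{snp}: more than two alleles in ped file")
        if not counts:
            calls[snp] = np.full(len(pairs), np.nan)
            alleles[snp] = ("A", "B")
            continue
        # same minor-allele convention as the TSV dialect
        ordered = sorted(counts, key=lambda a: (counts[a], a))
        minor = ordered[0]
        major = ordered[-1] if len(ordered) > 1 else minor
        col = np.full(len(pairs), np.nan)
        for i, (a1, a2) in enumerate(pairs):
            if a1 == "0" or a2 == "0":
                continue
            col[i] = float((a1 == minor) + (a2 == minor))
        calls[snp] = col
        alleles[snp] = (major, minor)
    return GenotypeMatrix(pd.DataFrame(calls, index=sample_ids), alleles)


# ---------------------------------------------------------------------------
# spectra


def write_spectra(spectra: list[Spectrum], out_dir, manifest_name: str = "manifest.csv") -> Path:
    """Per-sample two-column TSV (ppm, intensity) plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / manifest_name
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "path"])
        for spec in spectra:
            fname = f"{spec.sample_id}.tsv"
            pd.DataFrame({"ppm": spec.ppm, "intensity": spec.intensity}).to_csv(
                out_dir / fname, sep="\t", index=False
            )
            writer.writerow([spec.sample_id, fname])
    return manifest


def read_spectra(manifest_path) -> list[Spectrum]:
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    if not {"sample_id", "path"}.issubset(manifest.columns):
        raise SchemaError("spectra manifest needs 'sample_id' and 'path' columns")
    spectra = []
    for row in manifest.itertuples():
        df = pd.read_csv(manifest_path.parent / row.path, sep="\t")
        if not {"ppm", "intensity"}.issubset(df.columns):
            raise SchemaError(f"{row.path}: spectrum TSV needs 'ppm' and 'intensity' columns")
        spectra.append(
            Spectrum(df["ppm"].to_numpy(), df["intensity"].to_numpy(), sample_id=str(row.sample_id))
        )
    return spectra
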