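"""Readers, writers and run configuration.

File formats:

* phenotypes -- CSV with ``plot_id, genotype_id, year, treatment, block,
  date, gf`` (ISO-8601 dates, GF in [0, 1]);
* temperatures -- CSV with ``environment_id, date, tmean_c``; the first date
  of each environment is its sowing date, one row per day from sowing;
* genotypes -- VCF (biallelic SNPs, GT field) or a coded-matrix CSV with
  genotypes as rows and markers as columns, entries -1 (reference
  homozygote), 0 (heterozygote), +1 (alternative homozygote), blank missing;
* configuration -- YAML; run metadata sidecars -- JSON.

Readers validate loudly: out-of-range GF, duplicate observations and missing
columns are reported with row numbers rather than silently coerced.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
import pathlib

import numpy as np
import pandas as pd
import yaml

from .growth import ThermalTime

logger = logging.getLogger(__name__)

PHENO_COLUMNS = ["plot_id", "genotype_id", "year", "treatment", "block", "date", "gf"]
TEMP_COLUMNS = ["environment_id", "date", "tmean_c"]


def read_phenotypes(path) -> pd.DataFrame:
    """Read and validate the plot-level GF table; adds ``environment_id``."""
    df = pd.read_csv(path, dtype={"plot_id": str, "genotype_id": str, "block": str})
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file {path}: missing columns {missing}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.date
    except ValueError as exc:
        raise ValueError(f"phenotype file {path}: unparseable date ({exc})") from exc
    bad = df.index[(df["gf"] < 0) | (df["gf"] > 1) | df["gf"].isna()]
    if len(bad):
        raise ValueError(
            f"phenotype file {path}: gf outside [0, 1] at rows {list(bad[:10] + 2)}"
        )
    dup = df.duplicated(subset=["plot_id", "date"])
    if dup.any():
        raise ValueError(
            f"phenotype file {path}: duplicate (plot_id, date) at rows "
            f"{list(df.index[dup][:10] + 2)}"
        )
    df["environment_id"] = df["year"].astype(str) + "-" + df["treatment"].astype(str)
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    out = df[PHENO_COLUMNS].copy()
    out["date"] = out["date"].astype(str)
    out.to_csv(path, index=False)


def read_temperatures(path) -> tuple[pd.DataFrame, dict]:
    """Read daily temperatures; returns the table and env -> ThermalTime.

    Within each environment the rows must form a gap-free daily series whose
    first date is the sowing date.
    """
    df = pd.read_csv(path)
    missing = [c for c in TEMP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"temperature file {path}: missing columns {missing}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.date
    if df["tmean_c"].isna().any():
        raise ValueError(f"temperature file {path}: missing tmean_c values")
    thermal = {}
    for env, rows in df.groupby("environment_id", sort=True):
        rows = rows.sort_values("date")
        days = rows["date"].map(lambda d: (d - rows["date"].iloc[0]).days).to_numpy()
        if not np.array_equal(days, np.arange(len(rows))):
            raise ValueError(f"temperature file {path}: gaps in daily series for {env}")
        thermal[env] = ThermalTime(rows["date"].iloc[0], rows["tmean_c"].to_numpy(float))
    return df, thermal


def write_temperatures(df: pd.DataFrame, path) -> None:
    out = df[TEMP_COLUMNS].copy()
    out["date"] = out["date"].astype(str)
    out.to_csv(path, index=False)


def attach_gdd(pheno: pd.DataFrame, thermal: dict) -> pd.DataFrame:
    """Add days-after-sowing and degree-day columns to a phenotype table."""
    pheno = pheno.copy()
    pheno["date"] = pd.to_datetime(pheno["date"]).dt.date
    days, gdd = [], []
    for env, date in zip(pheno["environment_id"], pheno["date"]):
        tt = thermal[env]
        d = (date - tt.sowing_date).days
        days.append(d)
        gdd.append(float(tt.gdd_at(d)))
    pheno["days"] = days
    pheno["gdd"] = gdd
    return pheno


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes_vcf(path) -> pd.DataFrame:
    """Coded marker matrix from a VCF; multiallelic records are dropped.

    Codes follow the -1/0/+1 homozygote/heterozygote convention; missing
    calls become NaN.  Phasing is ignored.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    cols, names, n_multi = [], [], 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gt = rec.gt_types.astype(float)  # 0 hom-ref, 1 het, 2 hom-alt, 3 missing
        gt[gt == 3] = np.nan
        cols.append(gt - 1.0)
        names.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
    vcf.close()
    if n_multi:
        logger.info("dropped %d multiallelic records from %s", n_multi, path)
    if not cols:
        raise ValueError(f"no biallelic records in {path}")
    return pd.DataFrame(
        np.column_stack(cols), index=pd.Index(samples, name="genotype_id"), columns=names
    )


def write_vcf(codes: pd.DataFrame, path) -> None:
    """Write coded markers as a minimal single-chromosome VCF."""
    gmap = {-1.0: "0/0", 0.0: "0/1", 1.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in codes.index)
            + "\n"
        )
        M = codes.to_numpy(dtype=float)
        for j, marker in enumerate(codes.columns):
            calls = "\t".join(
                gmap.get(M[i, j], "./.") if np.isfinite(M[i, j]) else "./."
                for i in range(M.shape[0])
            )
            fh.write(f"1\t{j + 1}\t{marker}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def read_coded_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    vals = df.to_numpy(dtype=float)
    ok = np.isnan(vals) | np.isin(vals, (-1.0, 0.0, 1.0))
    if not ok.all():
        bad = np.argwhere(~ok)[0]
        raise ValueError(
            f"coded matrix {path}: invalid code at row {bad[0] + 2}, column {bad[1] + 2}"
        )
    df.index.name = "genotype_id"
    return df


def write_coded_matrix(codes: pd.DataFrame, path) -> None:
    codes.to_csv(path)


def write_grm(grm: pd.DataFrame, path) -> None:
    grm.to_csv(path)


def read_grm(path) -> pd.DataFrame:
    grm = pd.read_csv(path, index_col=0)
    grm.columns = grm.index
    return grm


# ---------------------------------------------------------------------------
# run configuration and metadata
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Validated YAML run configuration."""

    seed: int
    output_dir: str
    phenotypes: str | None = None
    temperatures: str | None = None
    genotypes: str | None = None
    raw: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError(f"config {path}: 'seed' is mandatory")
        paths = raw.get("paths", {})
        cfg = cls(
            seed=int(raw["seed"]),
            output_dir=str(raw.get("output_dir", "canopygp_out")),
            phenotypes=paths.get("phenotypes"),
            temperatures=paths.get("temperatures"),
            genotypes=paths.get("genotypes"),
            raw=raw,
        )
        return cfg

    def require(self, *names):
        for name in names:
            p = getattr(self, name)
            if p is None:
                raise ValueError(f"config: paths.{name} is required for this command")
            if not pathlib.Path(p).exists():
                raise FileNotFoundError(f"config: paths.{name} = {p} does not exist")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_sidecar(output_path, config: dict, seed: int, inputs=()) -> None:
    """JSON sidecar recording config, seed and input hashes for reproduction."""
    meta = {
        "output": str(output_path),
        "created": datetime.datetime.now().isoformat(timespec="seconds"),
        "seed": seed,
        "config": config,
        "inputs": {str(p): _sha256(p) for p in inputs if pathlib.Path(p).exists()},
    }
    with open(str(output_path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
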