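"""CSV (and optional VCF) ingestion and persistence for all pipeline tables.

All writers put a ``# statinpgx`` comment header (package version and seed)
on the first line; readers skip comment lines.  Below-LLOQ concentrations are
written as the token ``BLQ`` and read back as NaN.  Missing genotype calls
are written as ``.``.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from statinpgx.nca import ConcTimeProfile

BLQ_TOKEN = "BLQ"


def _write_with_header(df: pd.DataFrame, path, seed=None, index=False) -> None:
    from statinpgx import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# statinpgx v{__version__}"
                 + (f" seed={seed}" if seed is not None else "") + "\n")
        df.to_csv(fh, index=index)


def _read_csv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


def write_subjects_csv(subjects: pd.DataFrame, path, seed=None) -> None:
    _write_with_header(subjects, path, seed)


def read_subjects_csv(path) -> pd.DataFrame:
    df = _read_csv(path)
    required = {"subject_id", "sex", "weight_kg", "dose_mg", "trial_arm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subjects file {path}: missing columns {sorted(missing)}")
    return df


def write_genotypes_csv(genotypes: pd.DataFrame, path, seed=None) -> None:
    out = genotypes.copy()
    for col in ("allele1", "allele2"):
        out[col] = out[col].fillna(".")
    _write_with_header(out, path, seed)


def read_genotypes_csv(path) -> pd.DataFrame:
    df = _read_csv(path, dtype=str)
    required = {"subject_id", "gene", "rsid", "allele1", "allele2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"genotype file {path}: missing columns {sorted(missing)}")
    return df


def write_profiles_csv(profiles: list[ConcTimeProfile], path, seed=None) -> None:
    rows = []
    for p in profiles:
        for t, c in zip(p.times, p.concentrations):
            rows.append({"subject_id": p.subject_id,
                         "schedule_id": p.schedule_id, "time_h": t,
                         "conc_ng_ml": BLQ_TOKEN if np.isnan(c) else c,
                         "lloq": p.lloq})
    _write_with_header(pd.DataFrame(rows), path, seed)


def read_profiles_csv(path) -> list[ConcTimeProfile]:
    df = _read_csv(path)
    required = {"subject_id", "time_h", "conc_ng_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profiles file {path}: missing columns {sorted(missing)}")
    conc = pd.to_numeric(df["conc_ng_ml"].replace(BLQ_TOKEN, np.nan),
                         errors="coerce")
    df = df.assign(conc_ng_ml=conc)
    profiles = []
    for sid, sub in df.groupby("subject_id", sort=True):
        sub = sub.sort_values("time_h")
        profiles.append(ConcTimeProfile(
            subject_id=str(sid),
            schedule_id=str(sub["schedule_id"].iloc[0])
            if "schedule_id" in sub.columns else "",
            times=sub["time_h"].to_numpy(dtype=float),
            concentrations=sub["conc_ng_ml"].to_numpy(dtype=float),
            lloq=float(sub["lloq"].iloc[0]) if "lloq" in sub.columns else 0.0))
    return profiles


def write_phenotypes_csv(long: pd.DataFrame, path, seed=None) -> None:
    _write_with_header(long, path, seed)


def write_adr_csv(adr: pd.DataFrame, path, seed=None) -> None:
    _write_with_header(adr, path, seed)


def read_adr_csv(path) -> pd.DataFrame:
    df = _read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"ADR file {path}: missing subject_id column")
    return df


def read_genotypes_vcf(path, panel: pd.DataFrame) -> pd.DataFrame:
    """Long genotype table from a VCF (GT field only; unphased accepted).

    Records are matched to the panel by the ID column (rsid); sample
    genotypes are translated back to panel ref/alt allele strings.
    Requires ``cyvcf2``.
    """
    from cyvcf2 import VCF

    panel = panel.set_index("rsid")
    vcf = VCF(str(path))
    samples = vcf.samples
    rows = []
    for record in vcf:
        rsid = record.ID
        if rsid not in panel.index:
            continue
        ref = panel.loc[rsid, "ref"]
        alt = panel.loc[rsid, "alt"]
        gene = panel.loc[rsid, "gene"]
        for sample, gt in zip(samples, record.genotypes):
            a = []
            for allele_idx in gt[:2]:
                if allele_idx < 0:
                    a.append(".")
                else:
                    a.append(ref if allele_idx == 0 else alt)
            rows.append({"subject_id": sample, "gene": gene, "rsid": rsid,
                         "allele1": a[0], "allele2": a[1]})
    return pd.DataFrame(rows)


def sha256sum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
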