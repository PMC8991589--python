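"""Text-format readers and writers.

Genotypes round-trip through three dialects:

* PLINK ``.ped``/``.map`` — one sample per line (``FID IID PAT MAT SEX
  PHENOTYPE`` then two allele columns per SNP, ``0 0`` for a missing call);
* PLINK additive ``.raw`` — header ``FID IID PAT MAT SEX PHENOTYPE`` then
  ``<snp>_<effect-allele>`` dosage columns, ``NA`` for missing;
* plain TSV — ``sample_id`` then ``<snp>_<effect-allele>`` columns, empty
  cell for missing.

The PED dialect carries no allele-role metadata, so the reader re-derives
the effect allele as the observed minor allele (ties broken
lexicographically); the ``.raw`` and TSV dialects carry it in the header.
Sample tables and PRS weights are TSV; weight files use the de-facto
``snp_id / effect_allele / beta`` layout with a JSON sidecar for covariate
betas and metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SAMPLE_COLUMNS, GenotypeMatrix
from .prsmodels import PRSWeights

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_sample_table",
    "write_sample_table",
    "read_weights",
    "write_weights",
    "write_scores",
]

_VALID_ALLELES = {"A", "C", "G", "T", "0"}


def write_genotypes(g: GenotypeMatrix, prefix: str | Path, dialect: str = "raw") -> list[Path]:
    prefix = Path(prefix)
    if dialect == "ped":
        return _write_ped(g, prefix)
    if dialect == "raw":
        return [_write_raw(g, prefix.with_suffix(".raw"))]
    if dialect == "tsv":
        return [_write_tsv(g, prefix.with_suffix(".tsv"))]
    raise ValueError(f"unknown dialect {dialect!r}")


def read_genotypes(path: str | Path, dialect: str = "raw") -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Parse genotypes; returns the matrix and a stub sample table holding
    only sample ids (plus PED phenotype when present)."""
    path = Path(path)
    if dialect == "ped":
        return _read_ped(path)
    if dialect == "raw":
        return _read_raw(path)
    if dialect == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# -- PED/MAP ----------------------------------------------------------------


def _write_ped(g: GenotypeMatrix, prefix: Path) -> list[Path]:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with open(map_path, "w") as fh:
        for k, sid in enumerate(g.snp_ids):
            fh.write(f"1\t{sid}\t0\t{k + 1}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for k in range(g.n_snps):
                d = g.dosages[i, k]
                e, o = g.effect_alleles[k], g.other_alleles[k]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [o, o]
                elif d == 1:
                    fields += [e, o]
                elif d == 2:
                    fields += [e, e]
                else:
                    raise ValueError(
                        f"PED cannot encode fractional dosage {d} at {g.snp_ids[k]}"
                    )
            fh.write("\t".join(fields) + "\n")
    return [ped_path, map_path]


def _read_ped(ped_path: Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    map_path = ped_path.with_suffix(".map")
    snp_ids = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{map_path}:{lineno}: malformed map line")
            snp_ids.append(parts[1])
    m = len(snp_ids)
    sample_ids, phenos, allele_rows = [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            phenos.append(parts[5])
            alleles = parts[6:]
            bad = set(alleles) - _VALID_ALLELES
            if bad:
                raise ValueError(f"{ped_path}:{lineno}: invalid allele codes {sorted(bad)}")
            allele_rows.append(alleles)
    n = len(sample_ids)
    dosages = np.full((n, m), np.nan)
    effect_alleles, other_alleles = [], []
    for k in range(m):
        a1 = [row[2 * k] for row in allele_rows]
        a2 = [row[2 * k + 1] for row in allele_rows]
        counts: dict[str, int] = {}
        for a in a1 + a2:
            if a != "0":
                counts[a] = counts.get(a, 0) + 1
        if not counts:
            effect, other = "A", "G"  # all-missing column; placeholder labels
        elif len(counts) == 1:
            other = next(iter(counts))
            effect = "A" if other != "A" else "G"
        else:
            # minor allele = effect; ties broken lexicographically
            alleles_sorted = sorted(counts.items(), key=lambda kv: (kv[1], kv[0]))
            effect = alleles_sorted[0][0]
            other = alleles_sorted[-1][0]
        effect_alleles.append(effect)
        other_alleles.append(other)
        for i in range(n):
            if a1[i] == "0" or a2[i] == "0":
                continue
            dosages[i, k] = (a1[i] == effect) + (a2[i] == effect)
    g = GenotypeMatrix(sample_ids, snp_ids, dosages, effect_alleles, other_alleles)
    stub = pd.DataFrame({"sample_id": sample_ids, "ped_phenotype": phenos})
    return g, stub


# -- RAW --------------------------------------------------------------------


def _write_raw(g: GenotypeMatrix, path: Path) -> Path:
    cols = [f"{sid}_{ea}" for sid, ea in zip(g.snp_ids, g.effect_alleles)]
    with open(path, "w") as fh:
        fh.write(" ".join(["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"] + cols) + "\n")
        for i, sid in enumerate(g.sample_ids):
            vals = [
                "NA" if np.isnan(d) else (f"{d:g}")
                for d in g.dosages[i]
            ]
            fh.write(" ".join([sid, sid, "0", "0", "0", "-9"] + vals) + "\n")
    return path


def _read_raw(path: Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    with open(path) as fh:
        header = fh.readline().split()
        if header[:6] != ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]:
            raise ValueError(f"{path}:1: not a .raw header")
        snp_ids, effect_alleles = [], []
        for col in header[6:]:
            sid, _, allele = col.rpartition("_")
            if not sid:
                raise ValueError(f"{path}:1: column {col!r} lacks _ALLELE suffix")
            snp_ids.append(sid)
            effect_alleles.append(allele)
        sample_ids, rows = [], []
        for lineno, line in enumerate(fh, 2):
            parts = line.split()
            if len(parts) != len(header):
                raise ValueError(f"{path}:{lineno}: wrong field count")
            sample_ids.append(parts[1])
            rows.append([np.nan if v == "NA" else float(v) for v in parts[6:]])
    dosages = np.array(rows, dtype=float) if rows else np.empty((0, len(snp_ids)))
    other = ["G" if a != "G" else "A" for a in effect_alleles]  # not encoded in .raw
    g = GenotypeMatrix(sample_ids, snp_ids, dosages, effect_alleles, other)
    return g, pd.DataFrame({"sample_id": sample_ids})


# -- TSV --------------------------------------------------------------------


def _write_tsv(g: GenotypeMatrix, path: Path) -> Path:
    cols = [f"{sid}_{ea}" for sid, ea in zip(g.snp_ids, g.effect_alleles)]
    df = pd.DataFrame(g.dosages, columns=cols)
    df.insert(0, "sample_id", g.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="")
    return path


def _read_tsv(path: Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing sample_id column")
    snp_ids, effect_alleles = [], []
    for col in df.columns[1:]:
        sid, _, allele = col.rpartition("_")
        if not sid:
            raise ValueError(f"{path}: column {col!r} lacks _ALLELE suffix")
        snp_ids.append(sid)
        effect_alleles.append(allele)
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    other = ["G" if a != "G" else "A" for a in effect_alleles]
    g = GenotypeMatrix(list(df["sample_id"]), snp_ids, dosages, effect_alleles, other)
    return g, pd.DataFrame({"sample_id": g.sample_ids})


# -- sample tables, weights, scores -----------------------------------------


def write_sample_table(t: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    t.to_csv(path, sep="\t", index=False)
    return path


def read_sample_table(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in SAMPLE_COLUMNS:
        if col not in t.columns:
            t[col] = np.nan
    for col in ("family_history", "menopausal"):
        if t[col].dtype == object:
            t[col] = t[col].map({"True": True, "False": False}).fillna(t[col])
        t[col] = t[col].astype(bool)
    return t[SAMPLE_COLUMNS]


def write_weights(w: PRSWeights, prefix: str | Path) -> list[Path]:
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    pd.DataFrame(
        {"snp_id": w.snp_ids, "effect_allele": w.effect_alleles, "beta": w.betas}
    ).to_csv(tsv, sep="\t", index=False)
    sidecar = prefix.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "method": w.method,
                "covariate_betas": w.covariate_betas,
                "intercept": w.intercept,
                "lambda": w.lam,
                "training_case_set": w.training_case_set,
                "flags": w.flags,
            },
            fh,
            indent=2,
        )
    return [tsv, sidecar]


def read_weights(prefix: str | Path) -> PRSWeights:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return PRSWeights(
        method=meta["method"],
        snp_ids=list(df["snp_id"]),
        effect_alleles=list(df["effect_allele"]),
        betas=df["beta"].to_numpy(),
        covariate_betas=meta.get("covariate_betas"),
        intercept=meta.get("intercept", 0.0),
        lam=meta.get("lambda"),
        training_case_set=meta.get("training_case_set", "overall"),
        flags=meta.get("flags", {}),
    )


def write_scores(sample_ids: list[str], scores: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"sample_id": sample_ids, "prs": scores}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    return path
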