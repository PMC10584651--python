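"""Readers and writers for the text formats the tool consumes.

Genotypes arrive either as PLINK ``.raw`` recoded dosage files (header
``FID IID PAT MAT SEX PHENOTYPE SNP1_A ...``) or as a plain TSV matrix with
a header row of SNP ids.  The block map is a two-column TSV
(``snp_id<TAB>group_id``) or a PLINK ``.blocks.det``-style interval table
joined against a ``.bim``.  Survival outcomes are a TSV with columns
``sample_id``, ``time``, ``event`` (1 = observed, 0 = censored).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .model_core import Block, GroupedDesign, SurvivalData
from .synthetic_data import SimulatedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes_raw",
    "read_genotypes_tsv",
    "read_block_map",
    "read_blocks_det",
    "read_survival",
    "build_design",
    "write_dataset",
    "write_stage1_results",
    "write_stage2_results",
]

_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_genotypes_raw(path: str | Path) -> pd.DataFrame:
    """PLINK .raw additive dosage file -> subjects x SNPs DataFrame.

    SNP columns named ``rs123_A`` are stripped of the counted-allele suffix.
    """
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in _RAW_META if c not in df.columns]
    if missing:
        raise ValueError(f"not a PLINK .raw file: missing columns {missing}")
    ids = df["IID"].astype(str)
    geno = df.drop(columns=_RAW_META)
    geno.columns = [c.rsplit("_", 1)[0] if "_" in c else c for c in geno.columns]
    geno.index = ids
    return geno.astype(np.float64)


def read_genotypes_tsv(path: str | Path) -> pd.DataFrame:
    """Plain TSV: first column sample id, remaining columns SNP dosages."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(np.float64)


def read_block_map(path: str | Path) -> pd.DataFrame:
    """TSV with columns snp_id, group_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"snp_id", "group_id"} <= set(df.columns):
        raise ValueError("block map needs columns snp_id and group_id")
    return df[["snp_id", "group_id"]]


def read_blocks_det(det_path: str | Path, bim_path: str | Path) -> pd.DataFrame:
    """PLINK .blocks.det intervals joined against a .bim -> snp_id/group_id map.

    Interval coordinates are 1-based and inclusive on both ends.
    """
    det = pd.read_csv(det_path, sep=r"\s+")
    need = {"CHR", "BP1", "BP2"}
    if not need <= set(det.columns):
        raise ValueError(".blocks.det file needs columns CHR, BP1, BP2")
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "bp", "a1", "a2"],
                      dtype={"chrom": str})
    rows = []
    for i, blk in det.iterrows():
        hit = bim[(bim["chrom"] == str(blk["CHR"]))
                  & (bim["bp"] >= blk["BP1"]) & (bim["bp"] <= blk["BP2"])]
        gid = f"chr{blk['CHR']}:{int(blk['BP1'])}-{int(blk['BP2'])}"
        for snp in hit["snp_id"]:
            rows.append({"snp_id": snp, "group_id": gid})
    return pd.DataFrame(rows, columns=["snp_id", "group_id"])


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if not {"sample_id", "time", "event"} <= set(df.columns):
        raise ValueError("survival file needs columns sample_id, time, event")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def build_design(
    genotypes: pd.DataFrame,
    block_map: pd.DataFrame,
    survival: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    ridge: float = 1.0,
    min_group_size: int = 2,
) -> tuple[GroupedDesign, SurvivalData, list[str], list[str]]:
    """Align genotypes, block map and outcome into the model containers.

    Subjects are matched on sample id across files.  Constant SNP columns
    are dropped with a warning (upstream QC normally removes them), as are
    groups left with fewer than ``min_group_size`` members.  Returns the
    design, the survival data, the retained SNP ids and the group ids.
    """
    sids = survival["sample_id"].tolist()
    missing = [s for s in sids if s not in genotypes.index]
    if missing:
        raise ValueError(f"{len(missing)} survival subjects missing from "
                         f"genotypes (first: {missing[0]})")
    geno = genotypes.loc[sids]

    mapped = block_map[block_map["snp_id"].isin(geno.columns)]
    constant = [c for c in mapped["snp_id"] if geno[c].nunique() <= 1]
    if constant:
        logger.warning("dropping %d constant SNP columns", len(constant))
        mapped = mapped[~mapped["snp_id"].isin(constant)]
    counts = mapped.groupby("group_id")["snp_id"].count()
    small = counts[counts < min_group_size].index
    if len(small):
        logger.warning("dropping %d groups with fewer than %d SNPs",
                       len(small), min_group_size)
        mapped = mapped[~mapped["group_id"].isin(small)]
    if mapped.empty:
        raise ValueError("no SNP groups left after filtering")

    group_ids = sorted(mapped["group_id"].unique())
    snp_order: list[str] = []
    blocks = []
    X = geno.to_numpy(dtype=np.float64)
    col_of = {c: j for j, c in enumerate(geno.columns)}
    for gid in group_ids:
        snps = mapped.loc[mapped["group_id"] == gid, "snp_id"].tolist()
        idx = np.array([col_of[s] for s in snps], dtype=np.intp)
        blocks.append(Block(group_id=gid, member_index=idx, X=X[:, idx]))
        snp_order.extend(snps)

    n = len(sids)
    if covariates is not None:
        cov = covariates.loc[sids].to_numpy(dtype=np.float64)
        X0 = np.column_stack([np.ones(n), cov])
    else:
        X0 = np.ones((n, 1))
    design = GroupedDesign(X0=X0, blocks=blocks, ridge=ridge)
    surv = SurvivalData(t=survival["time"].to_numpy(np.float64),
                        nu=survival["event"].to_numpy(np.intp))
    return design, surv, snp_order, group_ids


def write_dataset(data: SimulatedDataset, out_dir: str | Path) -> None:
    """Dump one simulated replicate as genotype/block/survival/truth TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = data.genotypes.shape[0]
    sample_ids = [f"s{i}" for i in range(n)]
    geno = pd.DataFrame(data.genotypes, index=sample_ids, columns=data.snp_ids)
    geno.index.name = "sample_id"
    geno.to_csv(out / "genotypes.tsv", sep="\t")
    pd.DataFrame({
        "snp_id": data.snp_ids,
        "group_id": [data.group_ids[g] for g in data.group_of],
    }).to_csv(out / "blocks.tsv", sep="\t", index=False)
    pd.DataFrame({
        "sample_id": sample_ids,
        "time": data.survival.t,
        "event": data.survival.nu,
    }).to_csv(out / "survival.tsv", sep="\t", index=False,
              float_format="%.17g")  # exact float round-trip
    pd.DataFrame({
        "snp_id": data.snp_ids,
        "group_id": [data.group_ids[g] for g in data.group_of],
        "beta_true": data.true_beta,
        "causal": (data.true_beta != 0).astype(int),
    }).to_csv(out / "truth.tsv", sep="\t", index=False)


def write_stage1_results(out_dir: str | Path, group_ids: list[str],
                         pip: NDArray[np.float64], p_star: float,
                         selected: NDArray[np.intp],
                         w_tilde: NDArray[np.float64]) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sel = np.zeros(len(group_ids), dtype=int)
    sel[selected] = 1
    pd.DataFrame({
        "group_id": group_ids,
        "pip": pip,
        "qvalue": 1.0 - pip,
        "selected": sel,
    }).to_csv(out / "stage1_groups.tsv", sep="\t", index=False)
    pd.DataFrame({"w_tilde": w_tilde}).to_csv(out / "stage1_wtilde.tsv",
                                              sep="\t", index=False)
    (out / "stage1_threshold.txt").write_text(f"{p_star}\n")


def write_stage2_results(out_dir: str | Path, snp_ids: list[str],
                         group_of: list[str],
                         theta_median: NDArray[np.float64],
                         selected: NDArray[np.intp], H: int) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sel = np.zeros(len(snp_ids), dtype=int)
    sel[selected] = 1
    pd.DataFrame({
        "snp_id": snp_ids,
        "group_id": group_of,
        "theta_median": theta_median,
        "selected": sel,
    }).to_csv(out / "stage2_snps.tsv", sep="\t", index=False)
    (out / "stage2_H.txt").write_text(f"{H}\n")
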