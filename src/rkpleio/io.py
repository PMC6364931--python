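"""Tab-separated interchange formats.

Growth table: environment, genotype, replicate, time_h, cell_count (long).
Trait table:  environment, genotype, r, K, se_r, se_K, n_retained, R_g2.
Genotype matrix: snp_id, chrom, pos, then one 0/1/2/NA column per genotype.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import InputDataError
from .growth import GrowthCurve
from .qtl import GenotypeMatrix

GROWTH_COLUMNS = ["environment", "genotype", "replicate", "time_h", "cell_count"]
TRAIT_COLUMNS = ["environment", "genotype", "r", "K", "se_r", "se_K", "n_retained", "R_g2"]


def write_growth_table(curves: Iterable[GrowthCurve], path: str | Path) -> None:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "environment": c.environment,
                    "genotype": c.genotype,
                    "replicate": c.replicate,
                    "time_h": c.times,
                    "cell_count": c.counts,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_growth_table(path: str | Path) -> list[GrowthCurve]:
    df = pd.read_csv(path, sep="\t")
    missing = set(GROWTH_COLUMNS) - set(df.columns)
    if missing:
        raise InputDataError(f"growth table missing columns: {sorted(missing)}")
    out = []
    for (env, geno, rep), grp in df.groupby(
        ["environment", "genotype", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h")
        out.append(
            GrowthCurve(
                environment=str(env),
                genotype=str(geno),
                replicate=int(rep),
                times=grp["time_h"].to_numpy(dtype=float),
                counts=grp["cell_count"].to_numpy(dtype=float),
            )
        )
    return out


def write_trait_table(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, sep="\t", index=False)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRAIT_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise InputDataError(f"trait table missing columns: {sorted(missing)}")
    return df


def write_genotype_matrix(gm: GenotypeMatrix, path: str | Path) -> None:
    codes = pd.DataFrame(gm.codes, columns=gm.genotype_ids)
    codes = codes.astype("Int64")
    meta = pd.DataFrame(
        {"snp_id": gm.snp_ids, "chrom": gm.chromosomes, "pos": gm.positions}
    )
    pd.concat([meta, codes], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("snp_id", "chrom", "pos"):
        if col not in df.columns:
            raise InputDataError(f"genotype matrix missing column {col}")
    gen_cols = [c for c in df.columns if c not in ("snp_id", "chrom", "pos")]
    return GenotypeMatrix(
        snp_ids=df["snp_id"].to_numpy(dtype=object),
        chromosomes=df["chrom"].to_numpy(dtype=object),
        positions=df["pos"].to_numpy(),
        codes=df[gen_cols].to_numpy(dtype=float),
        genotype_ids=np.array(gen_cols, dtype=object),
    )
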