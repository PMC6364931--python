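"""End-to-end orchestration: fit -> QC -> aggregate -> correlate -> map -> classify -> cost model.

Stages run in dependency order and write their outputs as TSV/JSON into the
output directory.  Expensive stages record a hash of their inputs and
parameters in a manifest; a rerun with unchanged inputs reuses the cached
stage output instead of recomputing.  A machine-readable ``summary.json``
collects the headline statistics (one record each) together with the RNG
seed and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .correlation import (
    bin_by_r,
    cross_environment_trend,
    spearman,
    summaries_frame,
    summarize_environment,
    turning_point,
)
from .cost import CostParams, cost_curve, find_cost_minimum
from .exceptions import ConfigurationError
from .growth import aggregate_genotypes, fit_many, qc_filter
from .io import (
    read_genotype_matrix,
    read_growth_table,
    read_trait_table,
    write_trait_table,
)
from .qtl import (
    GenotypeMatrix,
    map_qtls,
    prune_complete_ld,
    prune_to_top_k,
    qtl_effects,
    records_frame,
)
from .simulate import (
    SimConfig,
    simulate_cross,
    simulate_growth_curves,
    simulate_phenotypes,
)

log = logging.getLogger("rkpleio")


@dataclass
class PipelineConfig:
    """Inputs, knobs and seed of a full run.

    Exactly one of (growth_table or trait_table) / simulation must be
    supplied: either paths to measured data or a SimConfig preset.
    """

    out_dir: Path
    seed: int
    growth_table: Optional[Path] = None
    trait_table: Optional[Path] = None
    genotype_matrix: Optional[Path] = None
    simulation: Optional[SimConfig] = None
    min_reps: int = 1
    bin_size: int = 500
    qtl_rounds: int = 6
    fdr: float = 0.05
    n_perm: int = 1000
    top_k: int = 36
    cost_params: CostParams = field(default_factory=CostParams)
    quiet: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        has_files = self.growth_table is not None or self.trait_table is not None
        if has_files == (self.simulation is not None):
            raise ConfigurationError(
                "supply exactly one of input paths or a simulation preset"
            )
        if self.simulation is not None and len(self.simulation.environments) == 0:
            raise ConfigurationError("simulation preset has an empty environment list")


def _hash_inputs(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, Path):
            h.update(p.read_bytes())
        else:
            h.update(str(p).encode())
    return h.hexdigest()


class _Stages:
    """Manifest-backed stage cache keyed by input hashes."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.manifest_path = out_dir / "stage_manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text()) if self.manifest_path.exists() else {}
        )

    def fresh(self, name: str, key: str, outputs: list[Path]) -> bool:
        return self.manifest.get(name) == key and all(p.exists() for p in outputs)

    def done(self, name: str, key: str) -> None:
        self.manifest[name] = key
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))


def _timed(name: str, summary: dict):
    def deco(fn):
        def wrapped(*a, **k):
            t0 = time.time()
            try:
                res = fn(*a, **k)
            except Exception as e:  # noqa: BLE001
                raise RuntimeError(f"stage '{name}' failed: {e}") from e
            log.info("[%s] %.1fs", name, time.time() - t0)
            summary["stages"].append(name)
            return res

        return wrapped

    return deco


def _fit_qc_aggregate(curves, min_reps: int) -> pd.DataFrame:
    fits = fit_many(curves)
    by_env: dict[str, list] = {}
    for f in fits:
        by_env.setdefault(f.environment, []).append(f)
    parts = [
        aggregate_genotypes(qc_filter(fs), min_reps=min_reps) for fs in by_env.values()
    ]
    return pd.concat(parts, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage the supplied inputs allow; return the summary record.

    A trait table without a genotype matrix means the correlation stages run
    and the QTL stages are skipped with an explicit notice.  Errors carry
    the stage name; no summary is written on failure.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    level = logging.WARNING if config.quiet else logging.INFO
    logging.basicConfig(stream=sys.stderr, level=level, format="%(message)s")
    stages = _Stages(out)
    rng_seq = np.random.SeedSequence(config.seed)
    summary: dict = {"seed": config.seed, "version": __version__, "stages": []}
    traits_path = out / "traits.tsv"

    # ---- stage: traits (and, for simulated runs, the genotype matrix) ----
    gm: Optional[GenotypeMatrix] = None

    @_timed("traits", summary)
    def stage_traits():
        nonlocal gm
        if config.trait_table is not None:
            return read_trait_table(config.trait_table)
        if config.growth_table is not None:
            key = _hash_inputs(config.growth_table, config.min_reps)
            if stages.fresh("traits", key, [traits_path]):
                log.info("[traits] cached")
                return read_trait_table(traits_path)
            traits = _fit_qc_aggregate(read_growth_table(config.growth_table), config.min_reps)
            write_trait_table(traits, traits_path)
            stages.done("traits", key)
            # downstream stages always consume the written file, so cached
            # and fresh runs see bit-identical numbers
            return read_trait_table(traits_path)
        sim = config.simulation
        # the cross and the latent phenotypes are cheap and deterministic,
        # so they are regenerated even on a cache hit; only the curve
        # simulation + fitting is skipped.
        rng = np.random.default_rng(rng_seq.spawn(1)[0])
        gm = simulate_cross(sim, rng)
        truth, _ = simulate_phenotypes(gm, sim, rng)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        key = _hash_inputs(repr(sim), config.min_reps, config.seed)
        if stages.fresh("traits", key, [traits_path]):
            log.info("[traits] cached")
            return read_trait_table(traits_path)
        curves = simulate_growth_curves(truth, sim, rng)
        traits = _fit_qc_aggregate(curves, config.min_reps)
        write_trait_table(traits, traits_path)
        stages.done("traits", key)
        return read_trait_table(traits_path)

    traits = stage_traits()
    if traits.empty:
        raise RuntimeError("stage 'traits' produced an empty trait table")

    # ---- stage: correlations -------------------------------------------
    @_timed("correlate", summary)
    def stage_correlate():
        sums = [
            summarize_environment(grp)
            for _, grp in traits.groupby("environment", sort=True)
        ]
        summaries_frame(sums).to_csv(out / "environment_summary.tsv", sep="\t", index=False)
        rec = {}
        if len(sums) >= 3:
            (rq, pq), (rk, pk) = cross_environment_trend(sums)
            rec.update(
                rho_Q_vs_rhoRK=rq,
                p_Q_vs_rhoRK=pq,
                rho_meanK_vs_rhoRK=rk,
                p_meanK_vs_rhoRK=pk,
            )
        bin_frames = [
            bin_by_r(grp, config.bin_size)
            for _, grp in traits.groupby("environment", sort=True)
            if len(grp) >= config.bin_size
        ]
        if bin_frames:
            bins = pd.concat(bin_frames, ignore_index=True)
            bins.to_csv(out / "bins.tsv", sep="\t", index=False)
            rec["r_tp"] = turning_point(bins).r_tp
        return rec

    summary.update(stage_correlate())

    # ---- stage: qtl ----------------------------------------------------
    if config.genotype_matrix is not None:
        gm = read_genotype_matrix(config.genotype_matrix)
    if gm is None:
        log.info("[qtl] skipped: no genotype matrix supplied")
        summary["qtl"] = "skipped (no genotype matrix)"
    else:

        @_timed("qtl", summary)
        def stage_qtl(gm):
            gm = prune_complete_ld(gm)
            id_pos = {g: i for i, g in enumerate(gm.genotype_ids)}
            all_records = []
            frac_rows = []
            env_count = traits["environment"].nunique()
            seeds = iter(rng_seq.spawn(2 * env_count))
            for env, grp in traits.groupby("environment", sort=True):
                grp = grp[grp["genotype"].isin(id_pos)]
                keep = np.array([id_pos[g] for g in grp["genotype"]], dtype=int)
                sub = GenotypeMatrix(
                    snp_ids=gm.snp_ids,
                    chromosomes=gm.chromosomes,
                    positions=gm.positions,
                    codes=gm.codes[:, keep],
                    genotype_ids=grp["genotype"].to_numpy(),
                )
                yr = grp["r"].to_numpy(dtype=float)
                yK = grp["K"].to_numpy(dtype=float)
                for trait, y in (("r", yr), ("K", yK)):
                    seed = int(np.random.default_rng(next(seeds)).integers(2**31))
                    recs = map_qtls(
                        y,
                        sub,
                        trait=trait,
                        environment=str(env),
                        max_rounds=config.qtl_rounds,
                        fdr=config.fdr,
                        n_perm=config.n_perm,
                        seed=seed,
                    )
                    if len(recs) > config.top_k:
                        recs = prune_to_top_k(recs, y, sub, k=config.top_k)
                    recs = qtl_effects(recs, yr, yK, sub)
                    all_records.extend(recs)
                    n_ant = sum(1 for q in recs if q.pleiotropy == "antagonistic")
                    n_cls = sum(1 for q in recs if q.pleiotropy != "null")
                    frac_rows.append(
                        {
                            "environment": str(env),
                            "trait": trait,
                            "n_qtls": len(recs),
                            "fraction_antagonistic": n_ant / n_cls if n_cls else np.nan,
                        }
                    )
            records_frame(all_records).to_csv(out / "qtls.tsv", sep="\t", index=False)
            fr = pd.DataFrame(frac_rows)
            fr.to_csv(out / "pleiotropy_fractions.tsv", sep="\t", index=False)
            rec = {}
            env_q = traits.groupby("environment", sort=True)["r"].mean().rename("Q")
            fr_r = fr[fr.trait == "r"].merge(env_q, on="environment")
            ok = fr_r.fraction_antagonistic.notna()
            if ok.sum() >= 3:
                rho, p = spearman(
                    fr_r.Q.to_numpy()[ok.to_numpy()],
                    fr_r.fraction_antagonistic.to_numpy()[ok.to_numpy()],
                )
                rec["rho_Q_vs_frac_antagonistic_rQTL"] = rho
                rec["p_Q_vs_frac_antagonistic_rQTL"] = p
            return rec

        summary.update(stage_qtl(gm))

    # ---- stage: cost model ---------------------------------------------
    @_timed("costmodel", summary)
    def stage_cost():
        r, f, C, dC = cost_curve(config.cost_params)
        pd.DataFrame({"r": r, "f": f, "C": C, "dCdr": dC}).to_csv(
            out / "cost_curve.tsv", sep="\t", index=False
        )
        return {"r_star": find_cost_minimum(config.cost_params)}

    summary.update(stage_cost())

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
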