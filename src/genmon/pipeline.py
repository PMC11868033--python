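"""End-to-end monitoring pipeline: simulate (or load), build baselines,
assign ancestry, compute diversity/divergence statistics and effective
sizes, and classify the traffic-light indicators, writing every artifact
into an output directory with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestry import (
    baseline_from_freq_table,
    detect_immigrants,
    estimate_q_supervised,
    introgression_rate,
    cline_correlation,
)
from .diversity import fis, heterozygosity, hwe_exact, paired_change_test
from .divergence import bootstrap_tree, nei_da, wc_fstats
from .effective_size import harmonic_mean_ne, ne_ld, ne_temporal
from .geno_io import GenotypeMatrix, allele_frequencies, write_genepop, write_csv_genotypes
from .indicators import delta_fst_classify, delta_h_classify, indicator_report, ne_classify
from .simulate import SimConfig, sample_population, simulate_release_and_spread

log = logging.getLogger("genmon")

__all__ = ["RunConfig", "run_monitoring", "stage_seed"]


@dataclass
class RunConfig:
    """Configuration of a full monitoring run over simulated data."""

    sim: SimConfig = field(default_factory=SimConfig)
    sample_size: int = 50
    seed: int = 0
    out_dir: str = "monitoring_run"
    n_bootstrap: int = 200
    n_permutations: int = 0
    anthropogenic_flag: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage child seed: global seed fanned out by hashing the
    stage name (reproducible under partial re-runs)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_monitoring(cfg: RunConfig) -> Path:
    """Run the whole workflow; returns the artifact directory.

    Stages: simulate -> baselines -> ancestry/introgression -> diversity ->
    divergence/tree -> effective size -> indicators.  Any stage failure
    aborts with the stage name; partial outputs are retained next to a
    FAILED marker.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = dict(version=__version__, seed=cfg.seed,
                          config=json.loads(json.dumps(asdict(cfg), default=str)),
                          stages={}, files={})
    stage = "simulate"
    try:
        t0 = time.time()
        sim_cfg = SimConfig(**{**asdict(cfg.sim),
                               "seed": stage_seed(cfg.seed, "simulate")})
        mid_gen = max(1, sim_cfg.generations - 2)
        state = simulate_release_and_spread(
            sim_cfg, archive_generations=(0, mid_gen, sim_cfg.generations))
        write_genepop(state.gm, out / "genotypes.gen")
        write_csv_genotypes(state.gm, out / "genotypes.csv")
        state.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        manifest["stages"][stage] = dict(
            n_ind=state.gm.n_ind, n_loci=state.gm.n_loci,
            elapsed_s=round(time.time() - t0, 2))

        stage = "baselines"
        t0 = time.time()
        baselines = [
            baseline_from_freq_table(state.founder_freqs, p, n_individuals=50)
            for p in state.founder_freqs.pops
        ]
        manifest["stages"][stage] = dict(k=len(baselines),
                                         elapsed_s=round(time.time() - t0, 2))

        stage = "ancestry"
        t0 = time.time()
        seed = stage_seed(cfg.seed, "sampling")
        lakes = [p for p in state.gm.pops if p.startswith("Lake")]
        q_frames = []
        lake_mean_qa = []
        for i, lake in enumerate(lakes):
            samp = sample_population(state, lake, sim_cfg.generations,
                                     min(cfg.sample_size, state.gm.by_pop(lake).n_ind),
                                     seed + i)
            res = estimate_q_supervised(samp, baselines[:2])
            df = res.to_frame()
            df.insert(1, "pop", lake)
            q_frames.append(df)
            lake_mean_qa.append(res.Q[:, 0].mean())
        creek_rows = []
        introg = {}
        for j, creek in enumerate(("CreekI", "CreekII")):
            samp = sample_population(state, creek, sim_cfg.generations,
                                     min(cfg.sample_size,
                                         state.gm.by_pop(creek).n_ind),
                                     seed + 100 + j)
            res = estimate_q_supervised(samp, baselines)
            calls = detect_immigrants(res, creek, creek_i_source="CreekI")
            introg[creek] = introgression_rate(res, calls)
            # simulation truth travels with the sample; record it alongside
            introg[creek]["true_alien_fraction"] = float(
                (samp.truth["Q_A"] + samp.truth["Q_B"]).mean())
            df = res.to_frame()
            df.insert(1, "pop", creek)
            df["group"] = [c.group for c in calls]
            creek_rows.append(df)
        pd.concat(q_frames + creek_rows).to_csv(out / "q_matrix.tsv",
                                                sep="\t", index=False)
        pd.concat(creek_rows)[["id", "pop", "group"]].to_csv(
            out / "group_calls.tsv", sep="\t", index=False)
        r, p = cline_correlation(lake_mean_qa, np.arange(1, len(lakes) + 1))
        with open(out / "introgression.json", "w") as fh:
            json.dump(dict(introgression=introg,
                           cline=dict(r=r, p=p)), fh, indent=1)
        manifest["stages"][stage] = dict(n_lakes=len(lakes), cline_r=round(r, 3),
                                         elapsed_s=round(time.time() - t0, 2))

        stage = "diversity"
        t0 = time.time()
        div = heterozygosity(state.gm)
        div.per_locus.to_csv(out / "diversity.tsv", sep="\t", index=False)
        f = fis(state.gm, n_permutations=cfg.n_permutations or 0,
                seed=stage_seed(cfg.seed, "fis"))
        f.drop(columns=["per_locus_f"]).to_csv(out / "fis.tsv", sep="\t",
                                               index=False)
        hwe = hwe_exact(state.gm)
        hwe.to_csv(out / "hwe.tsv", sep="\t", index=False)
        manifest["stages"][stage] = dict(elapsed_s=round(time.time() - t0, 2))

        stage = "divergence"
        t0 = time.time()
        fstats = wc_fstats(state.gm, pairwise=True,
                           n_permutations=cfg.n_permutations,
                           seed=stage_seed(cfg.seed, "fstats"))
        fstats.per_locus.to_csv(out / "fstats.tsv", sep="\t", index=False)
        fstats.pairwise_theta.to_csv(out / "pairwise_fst.tsv", sep="\t")
        tree = bootstrap_tree(state.gm, n_bootstrap=cfg.n_bootstrap,
                              seed=stage_seed(cfg.seed, "bootstrap"))
        (out / "tree.nwk").write_text(tree.newick + "\n")
        manifest["stages"][stage] = dict(theta=round(fstats.theta, 4),
                                         elapsed_s=round(time.time() - t0, 2))

        stage = "effective_size"
        t0 = time.time()
        ne_records = {}
        t_gens = sim_cfg.generations - mid_gen
        for creek in ("CreekI", "CreekII"):
            s0 = sample_population(state, creek, mid_gen,
                                   min(cfg.sample_size,
                                       state.history[(creek, mid_gen)][0].shape[0]),
                                   stage_seed(cfg.seed, f"ne0{creek}"))
            s1 = sample_population(state, creek, sim_cfg.generations,
                                   min(cfg.sample_size,
                                       state.gm.by_pop(creek).n_ind),
                                   stage_seed(cfg.seed, f"ne1{creek}"))
            temporal = ne_temporal(s0, s1, t_generations=t_gens)
            ld0, ld1 = ne_ld(s0), ne_ld(s1)
            hm = harmonic_mean_ne([ld0.point, ld1.point])
            ne_records[creek] = dict(
                temporal=dict(point=temporal.point, ci=temporal.ci,
                              **temporal.stats),
                ld=dict(points=[ld0.point, ld1.point],
                        harmonic_mean=hm.harmonic_mean),
            )
        with open(out / "ne.json", "w") as fh:
            json.dump(ne_records, fh, indent=1, default=str)
        manifest["stages"][stage] = dict(elapsed_s=round(time.time() - t0, 2))

        stage = "indicators"
        t0 = time.time()
        years = t_gens * sim_cfg.generation_length_years
        cells = {}
        for creek in ("CreekI", "CreekII"):
            s0 = sample_population(state, creek, mid_gen,
                                   min(cfg.sample_size,
                                       state.history[(creek, mid_gen)][0].shape[0]),
                                   stage_seed(cfg.seed, f"ind0{creek}"))
            s1 = sample_population(state, creek, sim_cfg.generations,
                                   min(cfg.sample_size,
                                       state.gm.by_pop(creek).n_ind),
                                   stage_seed(cfg.seed, f"ind1{creek}"))
            d0 = heterozygosity(s0).per_locus
            d1 = heterozygosity(s1).per_locus
            statuses = []
            for measure in ("He", "Ho", "Ar"):
                b = d0[measure].to_numpy()
                a = d1[measure].to_numpy()
                test = paired_change_test(b, a, measure=measure)
                statuses.append(delta_h_classify(
                    max(np.nanmean(b), 1e-9), max(np.nanmean(a), 1e-9),
                    years, test.significant, cfg.anthropogenic_flag, measure))
            rec = ne_records[creek]
            statuses.append(ne_classify(rec["temporal"]["point"],
                                        rec["ld"]["harmonic_mean"]))
            cells[(creek, f"g{mid_gen}-g{sim_cfg.generations}")] = statuses
        # dFST between the two creeks, before vs after
        s0s, s1s = [], []
        for creek in ("CreekI", "CreekII"):
            s0s.append(sample_population(
                state, creek, mid_gen,
                min(cfg.sample_size, state.history[(creek, mid_gen)][0].shape[0]),
                stage_seed(cfg.seed, f"fst0{creek}")))
            s1s.append(sample_population(
                state, creek, sim_cfg.generations,
                min(cfg.sample_size, state.gm.by_pop(creek).n_ind),
                stage_seed(cfg.seed, f"fst1{creek}")))
        fst0 = wc_fstats(_concat(*s0s), pairwise=False).theta
        fst1 = wc_fstats(_concat(*s1s), pairwise=False).theta
        if 0 < fst0 < 1 and 0 < fst1 < 1:
            comp0 = wc_fstats(_concat(*s0s), pairwise=False).per_locus["theta"]
            comp1 = wc_fstats(_concat(*s1s), pairwise=False).per_locus["theta"]
            keep = comp0.notna() & comp1.notna()
            sig = paired_change_test(comp0[keep], comp1[keep],
                                     measure="theta").significant
            cells[("CreekI-CreekII", f"g{mid_gen}-g{sim_cfg.generations}")] = [
                delta_fst_classify(fst0, fst1, sig)
            ]
        report = indicator_report(cells)
        report.to_tsv(out / "indicators.tsv")
        report.to_json(out / "indicators.json")
        manifest["stages"][stage] = dict(elapsed_s=round(time.time() - t0, 2))
    except Exception as e:
        (out / "FAILED").write_text(f"stage {stage}: {e}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _digest(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    log.info("monitoring run complete: %s", out)
    return out


def _concat(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    return GenotypeMatrix(
        a.individuals + b.individuals, list(a.loci),
        np.vstack([a.dosage, b.dosage]),
        a.pop_label + b.pop_label,
    )
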