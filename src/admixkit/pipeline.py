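"""End-to-end orchestration: simulate -> decode -> mask -> date -> ssPCA -> iHS.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence`` spawning, so any stage can be rerun in
isolation and the whole pipeline is bit-reproducible: identical config and
seed give byte-identical output checksums.  Every artifact lands in the
output directory and is listed, with its SHA-256, in ``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import simulate as sim
from .dating import DatingConfig, estimate_admixing_time
from .datamodel import write_ancestry_bed, write_phased_vcf
from .local_ancestry import decode_ancestry, estimate_hmm_params, global_ancestry_from_local
from .selection import IhsConfig, call_candidate_regions, ihs_scan, standardize_ihs
from .sspca import SsPcaConfig, fit_sspca, pcs_from_factors
from .virtual_genomes import extract_blocks, mask_to_virtual, select_individuals

logger = logging.getLogger("admixkit")


@dataclass
class PipelineConfig:
    out_dir: str = "admixkit_out"
    seed: int = 0
    # simulation stage
    M: int = 5000
    n_individuals: int = 60
    n_haps_per_source: int = 120
    K: int = 2
    fst: float = 0.15
    T: int = 12
    z_low: float = 0.2
    z_high: float = 0.8
    ld_rho: float = 0.3
    # analysis stages
    tau: float = 12.0
    markov_order: int = 0
    target_ancestry: str = "anc0"
    d: int = 2
    min_snps_block: int = 10
    run_selection: bool = True
    run_dating: bool = True
    run_sspca: bool = True

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Parse a simple ``key = value`` config file."""
        kwargs = {}
        fields = cls.__dataclass_fields__
        with open(path) as fh:
            for ln in fh:
                ln = ln.split("#")[0].strip()
                if not ln:
                    continue
                key, _, value = ln.partition("=")
                key = key.strip()
                if key not in fields:
                    raise ValueError(f"unknown config key {key!r}")
                typ = fields[key].type
                value = value.strip()
                if typ in ("int",):
                    kwargs[key] = int(value)
                elif typ in ("float",):
                    kwargs[key] = float(value)
                elif typ in ("bool",):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                else:
                    kwargs[key] = value
        return cls(**kwargs)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic-cohort pipeline; returns the output manifest.

    Stage failures propagate with the failing stage named; artifacts written
    before the failure are retained.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    logger.info("pipeline start: seed=%d config_hash=%s", config.seed, config.config_hash())
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
             for name, s in zip(
                 ["markers", "freqs", "sources", "admix", "sspca", "scan"], ss.spawn(6))}
    artifacts: list[str] = []

    def emit(name: str, writer) -> str:
        path = os.path.join(config.out_dir, name)
        writer(path)
        artifacts.append(path)
        return path

    stage = "simulate"
    try:
        rng = np.random.default_rng(seeds["markers"])
        markers = sim.simulate_markers(config.M, sim.DEFAULT_CHROM_LENGTHS_CM, rng)
        p_anc = np.random.default_rng(seeds["freqs"]).uniform(0.1, 0.9, size=config.M)
        freqs = sim.draw_population_freqs(p_anc, config.fst, config.K, seeds["freqs"])
        source_mats = sim.simulate_source_haplotypes(
            freqs, config.n_haps_per_source, config.ld_rho, markers, seeds["sources"])
        sim_cfg = sim.SimulationConfig(
            K=config.K, fst=config.fst, M=config.M, T=config.T,
            n_individuals=config.n_individuals, z_dist=(config.z_low, config.z_high),
            ld_rho=config.ld_rho, seed=seeds["admix"])
        sources = {f"anc{k}": source_mats[k] for k in range(config.K)}
        panel, truth, z, _info = sim.simulate_admixed_cohort(
            sim_cfg, sources, markers, rng=np.random.default_rng(seeds["admix"]))
        emit("cohort.vcf", lambda p: write_phased_vcf(panel, p, seed=config.seed))
        emit("truth_track.bed", lambda p: write_ancestry_bed(truth, panel, p, seed=config.seed))
        emit("true_z.tsv", lambda p: pd.DataFrame(
            {"sample_id": panel.sample_ids, "z": z}).to_csv(p, sep="\t", index=False))

        stage = "infer-ancestry"
        ref_mats = {f"anc{k}": source_mats[k].astype(float) for k in range(config.K)}
        params = estimate_hmm_params(ref_mats, q=np.full(config.K, 1 / config.K),
                                     tau=config.tau, markov_order=config.markov_order)
        track = decode_ancestry(panel, params)
        emit("track.bed", lambda p: write_ancestry_bed(track, panel, p, seed=config.seed))
        ga = global_ancestry_from_local(track)
        emit("global_ancestry.tsv", lambda p: pd.DataFrame(
            ga, columns=track.ancestry_names).assign(sample_id=panel.sample_ids)
            .to_csv(p, sep="\t", index=False))

        stage = "blocks-dating"
        if config.run_dating:
            blocks, counts = extract_blocks(track, panel.markers, config.min_snps_block)
            emit("blocks.tsv", lambda p: blocks.to_csv(p, sep="\t", index=False))
            k0 = track.ancestry_names.index(config.target_ancestry)
            res = estimate_admixing_time(ga[:, k0], counts,
                                         DatingConfig(L=float(sim.DEFAULT_CHROM_LENGTHS_CM.sum())))
            emit("dating.tsv", lambda p: res.profile.assign(T_hat=res.T_hat)
                 .to_csv(p, sep="\t", index=False))

        stage = "sspca"
        if config.run_sspca:
            pair = mask_to_virtual(panel, track, config.target_ancestry)
            keep = select_individuals(ga, track.ancestry_names.index(config.target_ancestry))
            model = fit_sspca(pair, SsPcaConfig(d=config.d, seed=seeds["sspca"]))
            scores, _ = pcs_from_factors(model)
            emit("pcs.tsv", lambda p: pd.DataFrame(
                scores, columns=[f"PC{j + 1}" for j in range(scores.shape[1])])
                .assign(sample_id=panel.sample_ids)
                .to_csv(p, sep="\t", index=False))

        stage = "selection"
        if config.run_selection:
            cfg = IhsConfig()
            raw = ihs_scan(panel, track, config.target_ancestry, cfg)
            std = standardize_ihs(raw, cfg)
            emit("ihs.tsv", lambda p: std.to_csv(p, sep="\t", index=False))
            regions = call_candidate_regions(std, cfg)
            emit("regions.tsv", lambda p: pd.DataFrame(
                [r.__dict__ for r in regions]).to_csv(p, sep="\t", index=False))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "artifacts": {os.path.basename(p): _sha256(p) for p in artifacts},
    }
    path = os.path.join(config.out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline done: %d artifacts", len(artifacts))
    return manifest
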