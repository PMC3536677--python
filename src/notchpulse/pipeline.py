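"""End-to-end orchestration: synthetic inputs through the integrated tables.

Stages run in dependency order — simulate, normalize, DE, clustering, peak
calling, Pol II classification, integration, motif scanning — each seeded
from a single global seed split deterministically per stage, so one seed
reproduces the whole run byte-for-byte.  A manifest records parameters,
seeds and input hashes for every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster, expression, integrate, io, motifs, peaks, polii, synth

logger = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "de", "cluster", "peaks", "polii", "integrate", "motifs")


@dataclass
class PipelineConfig:
    """Everything a full run needs: synthesis parameters, per-stage knobs,
    the global seed, and stage toggles."""

    outdir: str = "notchpulse_run"
    seed: int = 0
    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)
    enabled: dict = field(default_factory=lambda: {s: True for s in STAGES})
    de_q_cutoff: float = 0.05
    spline_df: int = 4
    loess_span: float = 0.4
    # desk-scale MCMC defaults; raise for production-size posterior summaries
    n_sweeps: int = 800
    burn_in: int = 200
    peak_threshold: float = 1.0
    min_run: int = 4
    merge_gap: int = 2
    promoter_window: int = 500
    suh_radius: int = integrate.DEFAULT_RADIUS
    motif_window: int = 5000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth_raw = raw.pop("synth", {})
        if "cluster_spec" in synth_raw:
            synth_raw["cluster_spec"] = tuple(tuple(x) for x in synth_raw["cluster_spec"])
        cfg = cls(**{k: v for k, v in raw.items() if k != "synth"})
        if synth_raw:
            cfg.synth = synth.SynthConfig(**synth_raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {
        s: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(STAGES, children)
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages and write the integrated outputs.

    Returns a run report with per-stage timings, headline numbers, and the
    paths written.  Identical config and seed give identical outputs.
    """
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report: dict = {"stages": {}, "outputs": {}, "seed": config.seed}
    enabled = {s: config.enabled.get(s, True) for s in STAGES}

    def fail(stage, exc):
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    cfg = dataclasses.replace(config.synth, seed=seeds["simulate"])
    # --- simulate ---
    stage_t = time.time()
    try:
        tc_true, expr_truth = synth.gen_expression(cfg)
        raw = synth.gen_raw_intensities(cfg, tc_true)
        transcripts, genome_length = synth.gen_gene_models(cfg)
        tracks, chip_truth = synth.gen_chip(cfg, transcripts, genome_length)
        wm_suh, wm_hairy = motifs.suh_matrix(), motifs.hairy_matrix()
        genome, motif_truth = synth.gen_genome_with_motifs(
            cfg, wm_suh, wm_hairy, genome_length=genome_length
        )
    except Exception as exc:  # noqa: BLE001
        fail("simulate", exc)
    report["stages"]["simulate"] = {"seconds": time.time() - stage_t}

    gene_of = pd.Series({tx.transcript_id: tx.gene_id for tx in transcripts})
    # expression rows are gene ids; analysis operates per transcript
    tx_of_gene = {tx.gene_id: tx for tx in transcripts}

    # --- normalize ---
    stage_t = time.time()
    if enabled["normalize"]:
        try:
            tc = expression.compute_ma(raw)
            tc = expression.normalize_within_array(tc, span=config.loess_span)
            logc0 = expression.compute_logC0(raw)
        except Exception as exc:  # noqa: BLE001
            fail("normalize", exc)
    else:
        tc, logc0 = tc_true, None
    report["stages"]["normalize"] = {"seconds": time.time() - stage_t}

    # --- differential expression ---
    stage_t = time.time()
    de_res = None
    if enabled["de"]:
        try:
            de_res = expression.timecourse_de(tc, spline_df=config.spline_df)
        except Exception as exc:  # noqa: BLE001
            fail("de", exc)
        n_de = len(de_res.significant(config.de_q_cutoff))
        report["stages"]["de"] = {"seconds": time.time() - stage_t, "n_de": n_de}
    else:
        report["stages"]["de"] = {"skipped": True}

    # --- clustering of DE profiles ---
    stage_t = time.time()
    summary = None
    if enabled["cluster"] and de_res is not None:
        de_ids = list(de_res.significant(config.de_q_cutoff))
        if len(de_ids) >= 2:
            try:
                profs = cluster.ProfileSet.from_timecourse(tc, transcripts=de_ids)
                samples = cluster.fit_dp(
                    profs,
                    n_sweeps=config.n_sweeps,
                    burn_in=config.burn_in,
                    seed=seeds["cluster"],
                )
                summary = cluster.summarize_clusters(samples, ids=profs.ids, times=profs.times)
            except Exception as exc:  # noqa: BLE001
                fail("cluster", exc)
            report["stages"]["cluster"] = {
                "seconds": time.time() - stage_t,
                "modal_K": summary.modal_K,
                "n_clustered": len(profs.ids),
            }
    if summary is None:
        report["stages"].setdefault("cluster", {"skipped": True})

    # --- peak calling ---
    stage_t = time.time()
    suh_peaks_by_time = {}
    if enabled["peaks"]:
        try:
            suh_peaks_by_time = peaks.call_peaks_all_times(
                tracks["SuH"],
                threshold=config.peak_threshold,
                min_run=config.min_run,
                merge_gap=config.merge_gap,
            )
            for t, plist in suh_peaks_by_time.items():
                io.write_peaks_bed(outdir / f"suh_peaks_{t:g}min.bed", plist)
        except Exception as exc:  # noqa: BLE001
            fail("peaks", exc)
        report["stages"]["peaks"] = {
            "seconds": time.time() - stage_t,
            "n_peaks": {f"{t:g}": len(v) for t, v in suh_peaks_by_time.items()},
        }
    else:
        report["stages"]["peaks"] = {"skipped": True}

    # --- Pol II classification ---
    stage_t = time.time()
    polii_table = None
    if enabled["polii"]:
        try:
            rows = {}
            track = tracks["PolII"]
            for tx in transcripts:
                states = {}
                for j, t in enumerate(track.times):
                    st = polii.classify_transcript(
                        track,
                        tx,
                        j,
                        promoter_window=config.promoter_window,
                        threshold=config.peak_threshold,
                        min_run=config.min_run,
                        merge_gap=config.merge_gap,
                    )
                    states[float(t)] = st.state
                rows[tx.gene_id] = states
            polii_table = pd.DataFrame(rows).T
        except Exception as exc:  # noqa: BLE001
            fail("polii", exc)
        report["stages"]["polii"] = {"seconds": time.time() - stage_t}
    else:
        report["stages"]["polii"] = {"skipped": True}

    # --- integration ---
    stage_t = time.time()
    master = None
    logistic_report = None
    if enabled["integrate"] and de_res is not None:
        try:
            suh_counts = None
            if suh_peaks_by_time:
                counts = {}
                for t, plist in suh_peaks_by_time.items():
                    ivals = [(p.start, p.end) for p in plist]
                    counts[t] = {
                        gid: integrate.count_peaks_within(
                            [(tx.start, tx.end)], ivals, radius=config.suh_radius
                        )
                        for gid, tx in tx_of_gene.items()
                    }
                suh_counts = pd.DataFrame(counts)
            cl_assign = summary.assignments if summary is not None else None
            master = integrate.build_master_table(
                de_table=de_res.table,
                transcript_gene=pd.Series({g: g for g in tc.transcripts}),
                median_m=tc.median_m(),
                cluster_assignments=cl_assign,
                polii_states=polii_table,
                suh_counts=suh_counts,
                logc0=logc0,
            )
            io.write_tsv(outdir / "master_table.tsv", master, index_label="transcript")
            # DE-odds logistic model at the 0 min timepoint
            if suh_counts is not None and polii_table is not None and logc0 is not None:
                t0 = sorted(suh_counts.columns)[0]
                tbl = pd.DataFrame(
                    {
                        "suh": (suh_counts[t0] >= 1).astype(int),
                        "P": (polii_table[0.0] == "P").astype(int),
                        "AP": (polii_table[0.0] == "AP").astype(int),
                        "AU": (polii_table[0.0] == "AU").astype(int),
                        "logC0": logc0.reindex(polii_table.index),
                        "de": (
                            de_res.table["q"].reindex(polii_table.index) < config.de_q_cutoff
                        ).astype(int),
                    }
                ).dropna()
                fit = integrate.fit_de_logistic(tbl)
                logistic_report = {
                    "params": fit.params.to_dict(),
                    "odds": fit.odds().to_dict(),
                    "adjusted_p": fit.adjusted_pvalues.to_dict(),
                    "significant": fit.significant.astype(bool).to_dict(),
                    "separation": fit.separation,
                }
                io.write_json(outdir / "model_report.json", logistic_report)
        except Exception as exc:  # noqa: BLE001
            fail("integrate", exc)
        report["stages"]["integrate"] = {"seconds": time.time() - stage_t}
        report["outputs"]["master_table"] = str(outdir / "master_table.tsv")
    else:
        report["stages"]["integrate"] = {"skipped": True}

    # --- motif scanning ---
    stage_t = time.time()
    if enabled["motifs"]:
        try:
            matches = motifs.scan_pwm(genome, wm_suh, chrom="chrS")
            matches += motifs.scan_pwm(genome, wm_hairy, chrom="chrS")
            suh_matches = [m for m in matches if m.matrix == "SuH"]
            sps = motifs.find_sps(suh_matches, motif_length=len(wm_suh))
            gene_extents = {tx.gene_id: (tx.start, tx.end) for tx in transcripts}
            counts = motifs.motif_gene_counts(
                gene_extents,
                [m for m in matches if m.matrix == "Hairy"],
                motif_length=len(wm_hairy),
                window=config.motif_window,
            )
            io.write_tsv(outdir / "hairy_gene_counts.tsv", counts, index_label="gene")
        except Exception as exc:  # noqa: BLE001
            fail("motifs", exc)
        report["stages"]["motifs"] = {
            "seconds": time.time() - stage_t,
            "n_matches": len(matches),
            "n_sps": len(sps),
        }
    else:
        report["stages"]["motifs"] = {"skipped": True}

    report["elapsed_seconds"] = time.time() - t_start
    manifest = {
        "config": _jsonable(config.to_dict()),
        "stage_seeds": seeds,
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    io.write_json(outdir / "manifest.json", manifest)
    io.write_json(outdir / "run_report.json", _jsonable(report))
    return report


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=_coerce))


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (tuple, set)):
        return list(o)
    return str(o)
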