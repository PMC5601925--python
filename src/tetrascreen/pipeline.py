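"""End-to-end driver: simulate -> normalize -> randomize zeros -> debarcode ->
gate -> decode -> profile -> differential, with a reproducibility manifest."""
from __future__ import annotations

import hashlib
import json
import logging
import platform
import time as _time
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, coding, synthetic
from .decode import DecodeParams, call_hits, compute_frequencies, concordance, decode_cells
from .differential import frequency_fold_change, summarize_markers, zscore
from .errors import ConfigurationError, TetraScreenError, ValidationError
from .events import EventTable
from .fcs import write_fcs
from .gating import apply_gate_tree, default_gate_tree, fit_gate_thresholds
from .preprocess import debarcode, identify_beads, normalize_beads, randomize_zeros
from .profiling import (CLUSTER_IDS, LogicleParams, ProfileParams, assign_rule_clusters,
                        cluster_embedding, cluster_profile, downsample, logicle_transform,
                        marker_matrix, run_tsne, transform_events)
from .synthetic import NoiseModel, archetype_thresholds

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Structured run configuration (YAML-serializable)."""

    seed: int = 1
    outdir: str = "tetrascreen_out"
    arms: list[str] = field(default_factory=lambda: ["isotype"])
    replicates: int = 1
    dual_config: bool = False
    tissue_cells: dict[str, int] = field(default_factory=lambda: {
        "tumour": 30_000, "spleen": 20_000, "dLN": 20_000, "ndLN": 60_000})
    noise: dict = field(default_factory=dict)
    logicle: dict = field(default_factory=dict)
    decode: dict = field(default_factory=dict)
    profile: dict = field(default_factory=dict)
    barcode_scheme: dict[str, list[str]] | str = "default"
    write_fcs: bool = False
    run_tsne: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for arm in self.arms:
            if arm != "isotype" and arm not in synthetic.TREATMENT_ARMS:
                raise ConfigurationError(f"unknown arm {arm!r}")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.barcode_scheme is None:
            raise ConfigurationError("config missing barcode scheme")
        self.noise_model()          # raises on bad noise parameters
        self.logicle_params()
        self.decode_params()

    def noise_model(self) -> NoiseModel:
        return NoiseModel(**self.noise)

    def logicle_params(self) -> LogicleParams:
        return LogicleParams(**self.logicle)

    def decode_params(self) -> DecodeParams:
        return DecodeParams(**self.decode)

    def profile_params(self) -> ProfileParams:
        allowed = {k: v for k, v in self.profile.items()
                   if k in ProfileParams.__dataclass_fields__}
        return ProfileParams(**allowed)


@dataclass
class RunManifest:
    config: dict
    version: str
    python: str
    stages: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)   # path -> sha256

    def record_output(self, path: Path) -> None:
        self.outputs[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "version": self.version, "python": self.python,
             "stages": self.stages, "outputs": self.outputs}, indent=2, sort_keys=True))


@contextmanager
def _stage(manifest: RunManifest, name: str):
    t0 = _time.perf_counter()
    try:
        yield
    except TetraScreenError as exc:
        exc.args = (f"[stage {name}] {exc.args[0] if exc.args else ''}",) + exc.args[1:]
        raise
    except Exception as exc:
        raise TetraScreenError(f"[stage {name}] {type(exc).__name__}: {exc}") from exc
    manifest.stages.append({"stage": name,
                            "seconds": round(_time.perf_counter() - t0, 3)})
    logger.info("stage %-12s done in %.2fs", name, manifest.stages[-1]["seconds"])


def preprocess_acquisition(pooled: EventTable, panel: coding.Panel,
                           barcodes: coding.BarcodeScheme, seed: int,
                           logicle: LogicleParams,
                           ) -> tuple[dict[str, EventTable], np.ndarray]:
    """Normalize on beads, randomize zeros, debarcode; split per sample."""
    bead_mask = identify_beads(pooled, panel.bead_labels, logicle=logicle)
    if bead_mask.sum() >= 2:
        pooled, _ = normalize_beads(pooled, bead_mask,
                                    bead_channels=panel.bead_labels)
    pooled = randomize_zeros(pooled, seed)
    cells = pooled.filter(~bead_mask)
    assign = debarcode(cells, barcodes, logicle=logicle)
    by_sample = {}
    for sid in barcodes.code_map:
        by_sample[sid] = cells.filter(assign.sample_ids == sid)
    return by_sample, bead_mask


def acquisition_gate_thresholds(pooled: EventTable, panel: coding.Panel,
                                logicle: LogicleParams) -> dict[str, float]:
    """Fit gate thresholds on a full acquisition (beads included)."""
    gate_channels = panel.bead_labels + [
        panel.label_for(m) for m in ("cisplatin", "DNA1", "CD45", "CD19",
                                     "TCRb", "CD90", "CD8", "CD4")]
    trans = transform_events(pooled, logicle, gate_channels)
    return fit_gate_thresholds(trans.intensities, panel)


def gate_cd8(events: EventTable, panel: coding.Panel, logicle: LogicleParams,
             overrides: dict[str, float] | None = None,
             ) -> tuple[EventTable, pd.DataFrame]:
    """Transform, fit thresholds, apply the live-CD8 tree; returns gated events."""
    gate_channels = panel.bead_labels + [
        panel.label_for(m) for m in ("cisplatin", "DNA1", "CD45", "CD19",
                                     "TCRb", "CD90", "CD8", "CD4")]
    trans = transform_events(events, logicle, gate_channels)
    thresholds = fit_gate_thresholds(trans.intensities, panel, overrides)
    tree = default_gate_tree(panel, thresholds)
    mask, counts = apply_gate_tree(trans, tree)
    return events.filter(mask), counts


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunManifest:
    """Execute the full synthetic screen described by ``config``."""
    config.validate()
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=__version__,
                           python=platform.python_version())

    panel = coding.default_channels()
    logicle = config.logicle_params()
    noise = config.noise_model()
    dec_params = config.decode_params()
    prof_params = config.profile_params()

    with _stage(manifest, "coding"):
        antigen_panel = coding.build_default_panel()
        scheme_a, scheme_b = coding.default_schemes(antigen_panel, panel,
                                                    seed=config.seed)
        if not config.dual_config:
            scheme_b = None
        coding.write_coding_table(out / "coding_table.tsv", antigen_panel,
                                  scheme_a, scheme_b)
        manifest.record_output(out / "coding_table.tsv")

    base_spec = synthetic.default_experiment(replicates=config.replicates,
                                             seed=config.seed,
                                             n_cells=config.tissue_cells)
    if config.barcode_scheme == "default":
        barcodes = coding.default_barcode_scheme(
            sorted(set(base_spec.barcode_assignment.values())), panel)
    else:
        barcodes = coding.BarcodeScheme(
            {k: tuple(v) for k, v in config.barcode_scheme.items()})

    screened = antigen_panel.screened_ids
    freq_rows: list[pd.DataFrame] = []
    decoded_cd8: dict[str, list[tuple[str, str, EventTable, np.ndarray]]] = {}

    for arm in config.arms:
        spec = synthetic.apply_treatment_effect(base_spec, arm)
        for rep in range(config.replicates):
            rep_seed = config.seed + 1000 * rep
            with _stage(manifest, f"simulate[{arm}/r{rep}]"):
                sim = synthetic.simulate_experiment(
                    spec, (scheme_a, scheme_b), noise, rep_seed, panel, barcodes)
            for cfg_id, per_tissue in sim.items():
                scheme = scheme_a if cfg_id == "A" else scheme_b
                with _stage(manifest, f"preprocess[{arm}/r{rep}/{cfg_id}]"):
                    pooled = EventTable.concat(list(per_tissue.values()))
                    pooled.time = np.arange(pooled.n_events, dtype=float)
                    by_sample, _ = preprocess_acquisition(
                        pooled, panel, barcodes, rep_seed, logicle)
                    # thresholds fitted on the whole acquisition: every gate
                    # channel is bimodal there (beads anchor DNA/CD45 lows)
                    gate_thresholds = acquisition_gate_thresholds(
                        pooled, panel, logicle)
                with _stage(manifest, f"gate+decode[{arm}/r{rep}/{cfg_id}]"):
                    for tissue in per_tissue:
                        sid = spec.barcode_assignment[tissue]
                        cd8, counts = gate_cd8(by_sample[sid], panel, logicle,
                                               overrides=gate_thresholds)
                        result = decode_cells(cd8, scheme, dec_params,
                                              panel.reporter_labels, logicle)
                        freqs = compute_frequencies(result, antigens=screened)
                        freqs["tissue"] = tissue
                        freqs["arm"] = arm
                        freqs["config"] = cfg_id
                        freqs["replicate"] = rep
                        freqs.attrs["n_cd8"] = cd8.n_events
                        freq_rows.append(freqs)
                        if cfg_id == "A" and tissue == "tumour":
                            decoded_cd8.setdefault(arm, []).append(
                                (arm, tissue, cd8, result.antigen))

    with _stage(manifest, "hits"):
        all_freqs = pd.concat(freq_rows, ignore_index=True)
        all_freqs.to_csv(out / "frequencies.csv", index=False)
        manifest.record_output(out / "frequencies.csv")
        hit_tables = {}
        for (arm, cfg_id), sub in all_freqs.groupby(["arm", "config"]):
            pooled_freq = (sub.groupby(["antigen", "tissue"])["frequency"]
                           .mean().reset_index())
            per_tissue = {
                t: tdf[["antigen", "frequency"]].assign(count=0)
                for t, tdf in pooled_freq.groupby("tissue")}
            hit_tables[(arm, cfg_id)] = call_hits(per_tissue, dec_params, arm)
        hits = pd.concat([df.assign(config=cfg) for (a, cfg), df in hit_tables.items()],
                         ignore_index=True)
        hits.to_csv(out / "hits.csv", index=False)
        manifest.record_output(out / "hits.csv")
        if config.dual_config:
            for arm in config.arms:
                conc = concordance(hit_tables[(arm, "A")], hit_tables[(arm, "B")])
                conc.to_csv(out / f"concordance_{arm}.csv", index=False)
                manifest.record_output(out / f"concordance_{arm}.csv")

    with _stage(manifest, "profile"):
        markers = list(prof_params.markers or synthetic.PHENOTYPE_MARKERS)
        markers = [m for m in markers if m not in set(prof_params.exclude_markers)]
        thresholds = archetype_thresholds(noise, logicle)
        pooled_cells = []
        for arm, entries in decoded_cd8.items():
            for _, tissue, cd8, antigen in entries:
                keep = np.isin(antigen, ["mLama4", "mAlg8"])
                sub = cd8.filter(keep)
                sub = transform_events(sub, logicle)
                mm = marker_matrix(sub, panel, markers)
                mm["arm"] = arm
                mm["antigen"] = antigen[keep]
                pooled_cells.append(mm)
        profile_rows = 0
        if pooled_cells:
            pool = pd.concat(pooled_cells, ignore_index=True)
            pool = downsample(pool, prof_params.downsample_cap, config.seed)
            rule_labels = assign_rule_clusters(pool[markers], thresholds)
            prof = cluster_profile(pool[markers], rule_labels,
                                   thresholds.positive, cluster_order=CLUSTER_IDS)
            prof.to_frame().to_csv(out / "cluster_profile.csv")
            manifest.record_output(out / "cluster_profile.csv")
            profile_rows = len(prof.n)
            if config.run_tsne and len(pool) >= prof_params.perplexity * 3 + 1:
                emb = run_tsne(pool[markers].to_numpy(), prof_params)
                model = cluster_embedding(emb.embedding, prof_params.k,
                                          prof_params.restarts, config.seed)
                edf = pd.DataFrame(emb.embedding, columns=["tsne1", "tsne2"])
                edf["kmeans"] = model.labels
                edf["rule"] = rule_labels
                edf.to_csv(out / "embedding.csv", index=False)
                manifest.record_output(out / "embedding.csv")
        logger.info("cluster profile rows: %d", profile_rows)

    with _stage(manifest, "differential"):
        treated_arms = [a for a in config.arms if a != "isotype"]
        if "isotype" in config.arms and treated_arms:
            iso = all_freqs[(all_freqs["arm"] == "isotype") & (all_freqs["config"] == "A")]
            for arm in treated_arms:
                trt = all_freqs[(all_freqs["arm"] == arm) & (all_freqs["config"] == "A")]
                fc = frequency_fold_change(
                    trt[["antigen", "tissue", "replicate", "frequency"]],
                    iso[["antigen", "tissue", "replicate", "frequency"]])
                fc.to_csv(out / f"fold_change_{arm}.csv", index=False)
                manifest.record_output(out / f"fold_change_{arm}.csv")

    manifest.write(out / "manifest.json")
    return manifest
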