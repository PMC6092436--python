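"""End-to-end orchestration of the abundant/rare biogeography analysis.

The full run mirrors the analysis workflow: rarefy to even depth, classify
OTUs by the dual thresholds, and then for each of the three datasets (all
OTUs, abundant, rare) compute alpha diversity, Bray-Curtis / NMDS / ANOSIM,
distance-decay, environmental and PCNM predictors, VIF filtering, forward
selection, the DCA-gated constrained ordination, variation partitioning and
Mantel / partial Mantel tests; the Sloan neutral model is fitted to the
entire community.  Every stage writes a labelled TSV into the output
directory and the run log records versions, seeds and parameters.

One master seed deterministically derives a seed per stage (by hashing the
stage name) so any stage can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, neutral, ordination, partition, spatial
from .distance import anosim, bray_curtis, mantel, nmds, partial_mantel
from .otu_io import (
    CountMatrix, DataError, SampleTable, read_count_table, read_sample_metadata,
    rarefy_even_depth, relative_abundance,
)

logger = logging.getLogger("abundrare")

SUBCOMMUNITIES = ("all", "abundant", "rare")


@dataclass
class PipelineConfig:
    """Workflow constants: inputs, depth, thresholds, permutations, seeds."""

    otu_table: str = ""
    metadata: str = ""
    output_dir: str = "results"
    rarefaction_depth: int = 28923
    thresholds: partition.ThresholdConfig = field(default_factory=partition.ThresholdConfig)
    transform: str = "sqrt"
    n_perm: int = 999
    seed: int = 0
    vif_threshold: float = 20.0
    alpha: float = 0.05
    env_variables: list[str] | None = None
    group_column: str = "bay"
    fit_ncm_per_subcommunity: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        thresholds = partition.ThresholdConfig(**doc.pop("thresholds", {}))
        cfg = cls(thresholds=thresholds, **doc)
        if cfg.n_perm < 1 or cfg.seed < 0:
            raise DataError("permutation count and seed must be positive")
        return cfg


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(master) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def run_full_analysis(
    cfg: PipelineConfig,
    cm: CountMatrix | None = None,
    meta: SampleTable | None = None,
) -> dict:
    """Run the whole workflow; returns a result bundle and writes TSV tables.

    ``cm`` and ``meta`` may be passed directly (e.g. from the simulator);
    otherwise they are read from the configured paths.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    bundle: dict = {}

    def save(name: str, frame) -> None:
        path = out / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
        manifest[name] = "ok"

    try:
        if cm is None:
            cm = read_count_table(cfg.otu_table)
        if meta is None:
            meta = read_sample_metadata(cfg.metadata)
        meta = meta.align_to(cm.sample_ids)

        cm = rarefy_even_depth(cm, cfg.rarefaction_depth,
                               stage_seed(cfg.seed, "rarefy"), prune_empty=True)
        ra = relative_abundance(cm)
        cls = partition.classify_otus(ra, cfg.thresholds)
        summary = partition.partition_summary(cls, cm)
        save("partition_summary", summary)
        bundle["partition_summary"] = summary

        groups = meta.groups(cfg.group_column)
        geo = spatial.haversine_matrix(meta)
        env_d = spatial.env_distance(meta, cfg.env_variables)
        env_frame = meta.env(cfg.env_variables)
        env_x = env_frame.copy()
        for c in env_x.columns:
            if c.lower() != "ph":
                env_x[c] = np.log1p(env_x[c])
        env_x = (env_x - env_x.mean()) / env_x.std(ddof=1).replace(0, 1)
        pcnm = spatial.pcnm_basis(geo)
        save("pcnm_axes", pcnm.to_frame().reset_index(names="sample_id"))

        ncm_fit = neutral.fit_ncm(cm)
        save("ncm_fit", pd.DataFrame([{
            "Nm": ncm_fit.Nm, "N": ncm_fit.N, "m": ncm_fit.m,
            "r_squared": ncm_fit.r_squared, "detection_limit": ncm_fit.detection_limit,
        }]))
        save("ncm_per_otu", ncm_fit.table)
        bundle["ncm"] = ncm_fit

        for level in SUBCOMMUNITIES:
            stage = f"level:{level}"
            if level == "all":
                sub_cm = cm
            else:
                keep = cls.otus_with_label(level)
                if len(keep) < 5:
                    logger.warning("%s: too few OTUs (%d); skipping", level, len(keep))
                    manifest[stage] = "skipped: too few OTUs"
                    continue
                sub_cm = cm.select_otus(keep)
            sub_ra = relative_abundance(sub_cm) if (sub_cm.sample_sums() > 0).all() else None
            if sub_ra is None:
                manifest[stage] = "skipped: empty sample after subsetting"
                continue

            alpha_tab = diversity.alpha_diversity_table(sub_cm)
            save(f"{level}_alpha", alpha_tab)

            bc = bray_curtis(sub_ra, transform=cfg.transform)
            save(f"{level}_bray_curtis", bc.to_frame().reset_index(names="sample_id"))
            nm = nmds(bc, seed=stage_seed(cfg.seed, stage + ":nmds"))
            coords = pd.DataFrame(nm.coordinates, columns=[f"NMDS{i+1}" for i in range(nm.coordinates.shape[1])])
            coords.insert(0, "sample_id", bc.labels)
            save(f"{level}_nmds", coords)
            an = anosim(bc, [groups[s] for s in bc.labels], cfg.n_perm,
                        stage_seed(cfg.seed, stage + ":anosim"))
            decay, slope = spatial.distance_decay(bc, geo, n_perm=cfg.n_perm,
                                                  seed=stage_seed(cfg.seed, stage + ":decay"))

            dca = ordination.dca_gradient_length(sub_ra)
            method = "cca" if dca.recommendation == "cca" else "rda"
            y = (ordination.community_matrix(sub_ra, "hellinger") if method == "rda"
                 else sub_cm.counts.T.astype(float))
            x_all = pd.concat([env_x.reset_index(drop=True),
                               pcnm.to_frame().reset_index(drop=True)], axis=1)
            x_filtered, dropped = ordination.vif_filter(x_all, cfg.vif_threshold)
            env_cols = [c for c in x_filtered.columns if not c.startswith("PCNM")]
            spa_cols = [c for c in x_filtered.columns if c.startswith("PCNM")]
            sel_env = ordination.forward_select(
                y, x_filtered[env_cols], method, cfg.alpha, cfg.n_perm,
                stage_seed(cfg.seed, stage + ":fsel_env")) if env_cols else None
            sel_spa = ordination.forward_select(
                y, x_filtered[spa_cols], method, cfg.alpha, cfg.n_perm,
                stage_seed(cfg.seed, stage + ":fsel_spa")) if spa_cols else None
            env_sel = (sel_env.selected if sel_env and sel_env.selected else env_cols)
            spa_sel = (sel_spa.selected if sel_spa and sel_spa.selected else spa_cols)
            vpa = ordination.variation_partition(
                y, x_filtered[env_sel], x_filtered[spa_sel], method="rda",
                n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, stage + ":vpa"))
            man_env = mantel(bc, env_d, n_perm=cfg.n_perm,
                             seed=stage_seed(cfg.seed, stage + ":mantel_env"))
            man_geo = mantel(bc, geo, n_perm=cfg.n_perm,
                             seed=stage_seed(cfg.seed, stage + ":mantel_geo"))
            pman_env = partial_mantel(bc, env_d, geo, n_perm=cfg.n_perm,
                                      seed=stage_seed(cfg.seed, stage + ":pmantel_env"))
            pman_geo = partial_mantel(bc, geo, env_d, n_perm=cfg.n_perm,
                                      seed=stage_seed(cfg.seed, stage + ":pmantel_geo"))
            stats_tab = pd.DataFrame([
                {"statistic": "anosim_R", "value": an.R, "p": an.p},
                {"statistic": "distance_decay_r", "value": decay.r, "p": decay.p},
                {"statistic": "distance_decay_slope", "value": slope, "p": np.nan},
                {"statistic": "dca_longest_gradient", "value": dca.axis_lengths.max(), "p": np.nan},
                {"statistic": "mantel_env_r", "value": man_env.r, "p": man_env.p},
                {"statistic": "mantel_geo_r", "value": man_geo.r, "p": man_geo.p},
                {"statistic": "partial_mantel_env_r", "value": pman_env.r, "p": pman_env.p},
                {"statistic": "partial_mantel_geo_r", "value": pman_geo.r, "p": pman_geo.p},
                {"statistic": "nmds_stress", "value": nm.stress, "p": np.nan},
                {"statistic": "vpa_pure_env", "value": vpa.pure_env, "p": vpa.p_pure_env},
                {"statistic": "vpa_pure_spatial", "value": vpa.pure_spatial, "p": vpa.p_pure_spatial},
                {"statistic": "vpa_shared", "value": vpa.shared, "p": np.nan},
                {"statistic": "vpa_residual", "value": vpa.residual, "p": np.nan},
            ])
            save(f"{level}_stats", stats_tab)
            sel_tab = pd.DataFrame([
                {"set": "env", "selected": ",".join(env_sel), "dropped_by_vif": ",".join(dropped)},
                {"set": "spatial", "selected": ",".join(spa_sel), "dropped_by_vif": ""},
            ])
            save(f"{level}_selection", sel_tab)
            bundle[level] = {
                "alpha": alpha_tab, "anosim": an, "decay": decay, "dca": dca,
                "vpa": vpa, "nmds": nm, "selection": {"env": env_sel, "spatial": spa_sel},
            }
            manifest[stage] = "ok"
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        raise
    manifest["status"] = "complete"
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
    log = {
        "seed": cfg.seed, "depth": cfg.rarefaction_depth, "n_perm": cfg.n_perm,
        "transform": cfg.transform, "numpy": np.__version__,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return bundle
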