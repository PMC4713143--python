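"""End-to-end orchestration: simulate -> preprocess -> connectivity ->
graph metrics -> PAC -> behaviour -> group statistics.

``run_pipeline`` executes the stages in their fixed order on a synthetic
cohort (or pre-simulated recordings), writes per-stage CSV/JSON outputs and
a manifest echoing every effective parameter and seed, and returns the
summary report.  Stage scale (channels, epochs, surrogates, densities) is
set by the config so the full pipeline stays tractable on one CPU.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behaviour import classify_responsiveness, median_split_predict
from .containers import LEVELS
from .graphs import surrogate_normalize
from .io import behaviour_to_frame
from .pac import pac_by_roi
from .preprocess import preprocess
from .spectral import BANDS, band_connectivity, dwpli, median_connectivity, tf_decompose
from .stats import make_long_table, mixed_anova_gg, pac_drug_correlation, pairwise_tukey
from .synth import CohortConfig, SimulationConfig, default_rois, simulate_cohort


@dataclass
class PipelineConfig:
    """Effective parameters of one pipeline run.

    Defaults use a reduced analysis scale (32 channels, 20 epochs, 5+5
    participants, 10 surrogates, coarse density grid) so a complete run
    finishes in minutes; the synthetic generator's own physiological
    defaults (sampling rate, bands, drug targets, group effects) are
    inherited from :class:`CohortConfig`.
    """

    out_dir: str = "sedanet_out"
    seed: int = 0
    n_channels: int = 32
    n_epochs: int = 20
    epoch_length: float = 10.0
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"responsive": 5, "drowsy": 5}
    )
    band: str = "alpha"
    densities: list[float] = field(
        default_factory=lambda: [0.10, 0.20, 0.30, 0.40, 0.50]
    )
    n_surrogates: int = 10
    louvain_reps: int = 10
    z_threshold: float = 3.0
    edge_trim: float = 1.0
    levels: list[str] = field(default_factory=lambda: list(LEVELS))
    stages: list[str] = field(
        default_factory=lambda: ["behaviour", "connectivity", "graphs", "pac", "stats"]
    )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _cohort_config(cfg: PipelineConfig) -> CohortConfig:
    base = SimulationConfig(
        n_channels=cfg.n_channels,
        n_epochs=cfg.n_epochs,
        epoch_length=cfg.epoch_length,
    )
    return CohortConfig(n_per_group=dict(cfg.n_per_group), base=base, seed=cfg.seed)


def run_pipeline(cfg: PipelineConfig, members=None) -> dict:
    """Run every enabled stage on a (simulated) cohort and write outputs.

    Returns the report dict; all tables land under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {"stages": {}, "warnings": []}

    cohort_cfg = _cohort_config(cfg)
    if members is None:
        members = simulate_cohort(cohort_cfg)
    rois = default_rois(cfg.n_channels)
    band = BANDS[cfg.band]
    rng = np.random.default_rng(cfg.seed + 1)

    # -- behaviour ---------------------------------------------------------
    if "behaviour" in cfg.stages:
        for m in members:
            m.record.group = classify_responsiveness(m.record)
        behav = behaviour_to_frame([m.record for m in members])
        behav["true_group"] = behav["participant"].map(
            {m.participant: m.true_group for m in members}
        )
        behav.to_csv(out / "behaviour.csv", index=False)
        report["stages"]["behaviour"] = {
            "n_participants": len(members),
            "n_drowsy": sum(m.record.group == "drowsy" for m in members),
        }

    # -- EEG stages --------------------------------------------------------
    long_rows = []
    pac_rows = []
    if {"connectivity", "graphs", "pac"} & set(cfg.stages):
        for m in members:
            for level in cfg.levels:
                rec = m.recordings[level]
                ep = preprocess(rec, z_threshold=cfg.z_threshold,
                                epoch_length=cfg.epoch_length)
                group = m.record.group
                if {"connectivity", "graphs"} & set(cfg.stages):
                    tf = tf_decompose(ep, fmax=band[1] + 5.0)
                    conn = dwpli(tf)
                    mat, _ = band_connectivity(conn, band)
                    long_rows.append(
                        (m.participant, group, level, "median_dwpli",
                         median_connectivity(mat))
                    )
                    if "graphs" in cfg.stages:
                        gm = surrogate_normalize(
                            tf,
                            band,
                            densities=np.asarray(cfg.densities),
                            n_surrogates=cfg.n_surrogates,
                            louvain_reps=cfg.louvain_reps,
                            seed=int(rng.integers(2**31 - 1)),
                            conn=conn,
                        )
                        report["warnings"].extend(gm.warnings)
                        for name, value in gm.summary().items():
                            long_rows.append(
                                (m.participant, group, level, name, value)
                            )
                if "pac" in cfg.stages:
                    res = pac_by_roi(ep, rois, edge_trim=cfg.edge_trim)
                    for roi, value in res.roi_mean.items():
                        pac_rows.append(
                            {
                                "participant": m.participant,
                                "group": group,
                                "level": level,
                                "roi": roi,
                                "pac": value,
                                "drug_ug_ml": m.record.drug.get(level, np.nan),
                            }
                        )
                        long_rows.append(
                            (m.participant, group, level, f"pac_{roi}", value)
                        )

    if long_rows:
        table = make_long_table(long_rows)
        table.to_csv(out / "metrics_long.csv", index=False)
    else:
        table = pd.DataFrame(columns=["participant", "group", "level", "measure", "value"])
    if pac_rows:
        pd.DataFrame(pac_rows).to_csv(out / "pac.csv", index=False)

    # -- statistics --------------------------------------------------------
    if "stats" in cfg.stages and len(table):
        stat_rows = []
        for measure in sorted(table["measure"].unique()):
            sub = table[table["measure"] == measure]
            if sub["group"].nunique() < 2:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = mixed_anova_gg(table, measure)
                stat_rows.append({"test": "mixed_anova", "measure": measure, **{
                    k: v for k, v in res.items() if not isinstance(v, tuple)
                }})
                tk = pairwise_tukey(table, measure, "moderate")
                stat_rows.append({
                    "test": "tukey_moderate", "measure": measure,
                    "p_group": float(tk["p-adj"].iloc[0]),
                })
            except (ValueError, KeyError) as err:  # degenerate measure
                report["warnings"].append(f"stats[{measure}]: {err}")
        if pac_rows:
            pac_df = pd.DataFrame(pac_rows)
            mod = pac_df[(pac_df["level"] == "moderate") & (pac_df["roi"] == "occipital")]
            if len(mod) >= 4 and np.ptp(mod["drug_ug_ml"].to_numpy()) > 0:
                res = pac_drug_correlation(
                    mod["pac"].to_numpy(), mod["drug_ug_ml"].to_numpy()
                )
                stat_rows.append({"test": "pac_drug_regression_moderate",
                                  "measure": "pac_occipital", **res})
        sw = table[(table["measure"] == "small_worldness") & (table["level"] == "baseline")]
        if len(sw) >= 4:
            behav_rates = {
                m.participant: m.record.hit_rate("moderate") for m in members
            }
            ordered = sw.sort_values("participant")
            try:
                split = median_split_predict(
                    ordered["value"].to_numpy(),
                    np.array([behav_rates[p] for p in ordered["participant"]]),
                )
                stat_rows.append({
                    "test": "median_split_baseline_small_worldness",
                    "measure": "moderate_hit_rate",
                    "mean_hit_rate_low": split["mean_hit_rate_low"],
                    "mean_hit_rate_high": split["mean_hit_rate_high"],
                    "p_value": split["p_value"],
                })
            except ValueError as err:
                report["warnings"].append(f"median_split: {err}")
        stats_df = pd.DataFrame(stat_rows)
        stats_df.to_csv(out / "stats.csv", index=False)
        report["stages"]["stats"] = {"n_tests": len(stats_df)}

    # -- group summary tables ---------------------------------------------
    if len(table):
        summary = (
            table.groupby(["measure", "group", "level"])["value"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
        summary.to_csv(out / "group_summary.csv", index=False)
        report["stages"]["summary"] = {
            "levels": sorted(table["level"].unique()),
            "groups": sorted(table["group"].unique()),
            "measures": sorted(table["measure"].unique()),
        }

    manifest = {
        "package_version": __version__,
        "config": asdict(cfg),
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
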