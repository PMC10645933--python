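"""End-to-end orchestration: simulate → behavior → histology → stats → report.

A run is driven by a single YAML config; every analysis threshold lives
there and is echoed into the run log, and a hash of the config is
recorded in the manifest.  The analysis stages operate exclusively on
blinded animal codes — group labels are joined only at the report stage,
after the codebook is unblinded — so no intermediate file can leak group
identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import histology as hi
from . import stats as st
from . import synthdata as sd
from .studyops import randomize_groups

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run (see module docstring)."""

    seed: int = 7
    alpha: float = 0.05
    n_mice: int = 9
    groups: tuple[str, ...] = ("sham", "low", "high")
    blinded: bool = True
    # behavioral simulation (per-group dicts allow programmed group effects)
    duration_s: float = 120.0
    frame_rate_hz: float = 15.0
    novelty_preference: dict[str, float] | float = 0.75
    alternation_bias: dict[str, float] | float = 0.8
    goal_bias: dict[str, float] | float = 0.6
    # analysis thresholds (every one echoed to the run log)
    facing_max_deg: float = 45.0
    exploration_radius_cm: float = 5.0
    entry_depth_frac: float = 0.5
    # histology simulation + analysis
    image_shape: tuple[int, int] = (256, 256)
    plaque_count: int = 4
    enrichment_factor: dict[str, float] | float = 2.0
    noise_sd: float = 20.0
    nucleus_count: int = 30
    min_plaque_area_um2: float = 20.0
    annulus_near_um: tuple[float, float] = (0.0, 12.0)
    annulus_far_um: tuple[float, float] = (18.0, 60.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("groups", "image_shape", "annulus_near_um", "annulus_far_um"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def per_group(self, name: str) -> dict[str, float]:
        """Resolve possibly per-group simulation parameters for one group."""
        out = {}
        for key in ("novelty_preference", "alternation_bias", "goal_bias", "enrichment_factor"):
            v = getattr(self, key)
            out[key] = float(v[name]) if isinstance(v, dict) else float(v)
        return out

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _mouse_seed(master: int, idx: int) -> int:
    return int(np.random.SeedSequence([master, idx]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute a full synthetic study run; returns the report bundle.

    Writes, under ``outdir``: the blinding codebook, per-trial metric
    CSVs keyed by blinded code, per-plaque tables, statistical reports
    (JSON + CSV), a markdown summary, and a manifest with the config
    hash.  Deterministic given the config (bit-identical CSVs on rerun).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("run config %s: %s", config.digest(), config)

    # --- study design -------------------------------------------------
    mice = [(f"M{i:03d}", "F" if i % 2 else "M") for i in range(config.n_mice)]
    codebook = randomize_groups(mice, list(config.groups), seed=config.seed)
    codebook.save(outdir / "codebook")
    # The sealed assignment drives the generative model only: the
    # simulator plays the role of the animals, which "know" their group.
    true_group = codebook._sealed

    arenas = {
        "nort": bh.nort_arena(),
        "ymaze": bh.ymaze_arena(),
        "mwm_probe": bh.mwm_arena(probe=True),
    }

    rows = []
    plaque_tables = []
    for idx, (mouse_id, _sex) in enumerate(mice):
        code = codebook.code_of[mouse_id]
        pars = config.per_group(true_group[code])
        base = dict(duration_s=config.duration_s, frame_rate_hz=config.frame_rate_hz)

        traj, _ = sd.simulate_trajectory(
            sd.BehaviorSimParams(
                test_kind="nort", seed=_mouse_seed(config.seed, 10 * idx),
                novelty_preference=pars["novelty_preference"], **base,
            ),
            arenas["nort"],
        )
        try:
            m = bh.nort_metrics(traj, arenas["nort"], config.facing_max_deg,
                                config.exploration_radius_cm)
            rows.append({"code": code, "metric": "discrimination_index",
                         "value": m.discrimination_index})
        except bh.UndefinedMetricError:
            log.warning("NORT trial of %s excluded: no exploration", code)

        traj, _ = sd.simulate_trajectory(
            sd.BehaviorSimParams(
                test_kind="ymaze", seed=_mouse_seed(config.seed, 10 * idx + 1),
                alternation_bias=pars["alternation_bias"], **base,
            ),
            arenas["ymaze"],
        )
        try:
            m = bh.ymaze_metrics(traj, arenas["ymaze"], config.entry_depth_frac)
            rows.append({"code": code, "metric": "alternation_pct",
                         "value": 100.0 * m.alternation_ratio})
        except bh.UndefinedMetricError:
            log.warning("Y-maze trial of %s excluded: too few entries", code)

        traj, _ = sd.simulate_trajectory(
            sd.BehaviorSimParams(
                test_kind="mwm_probe", seed=_mouse_seed(config.seed, 10 * idx + 2),
                goal_bias=pars["goal_bias"], duration_s=60.0,
                frame_rate_hz=config.frame_rate_hz,
            ),
            arenas["mwm_probe"],
        )
        m = bh.mwm_probe_metrics(traj, arenas["mwm_probe"])
        rows.append({"code": code, "metric": "target_quadrant_time_s",
                     "value": m.quadrant_time_s[arenas["mwm_probe"].target_quadrant]})
        rows.append({"code": code, "metric": "mean_distance_to_platform_cm",
                     "value": m.mean_distance_to_platform_cm})

        # --- histology ---------------------------------------------------
        images, _truth = sd.simulate_histology_image(
            sd.HistoSimParams(
                image_shape=config.image_shape, plaque_count=config.plaque_count,
                enrichment_factor=pars["enrichment_factor"],
                noise_sd=config.noise_sd, nucleus_count=config.nucleus_count,
                seed=_mouse_seed(config.seed, 10 * idx + 3),
            )
        )
        region = hi.RegionAnnotation.full_frame(config.image_shape)
        labels, table = hi.segment_plaques(
            images["plaque_channel"], region, config.min_plaque_area_um2
        )
        table = table.assign(code=code)
        plaque_tables.append(table)
        rows.append({"code": code, "metric": "plaque_load",
                     "value": hi.plaque_load(labels, region)})
        resp = hi.microglia_response(
            images["microglia_channel"], labels, region,
            config.annulus_near_um, config.annulus_far_um,
        )
        rows.append({"code": code, "metric": "microglia_ratio",
                     "value": resp.summary_mean})
        n_neurons, _dens = hi.count_neurons(images["nucleus_labels"], region)
        rows.append({"code": code, "metric": "neuron_count", "value": float(n_neurons)})

    metrics = pd.DataFrame(rows).sort_values(["metric", "code"]).reset_index(drop=True)
    metrics.to_csv(outdir / "metrics_blinded.csv", index=False)
    if plaque_tables:
        pd.concat(plaque_tables, ignore_index=True).to_csv(
            outdir / "plaques_blinded.csv", index=False
        )

    # --- unblind and test --------------------------------------------
    codebook.unblind(actor="pipeline", reason="analysis complete")
    codebook.save(outdir / "codebook")
    metrics = metrics.assign(group=metrics["code"].map(codebook.group_of))

    reports: dict[str, dict] = {}
    for k, metric in enumerate(sorted(metrics["metric"].unique())):
        sub = metrics[metrics["metric"] == metric]
        if sub["value"].nunique() <= 1:
            log.info("metric %s constant across mice: no comparison", metric)
            continue
        if sub.groupby("group")["value"].count().min() >= 3:
            rep = st.compare_groups(sub, metric, alpha=config.alpha,
                                    seed=_mouse_seed(config.seed, 9000 + k))
            reports[f"{metric}__groups"] = rep.as_dict()
    one_sample_refs = {"discrimination_index": 0.0, "alternation_pct": 22.0,
                       "microglia_ratio": 1.0}
    for metric, ref in one_sample_refs.items():
        for group, sub in metrics[metrics["metric"] == metric].groupby("group"):
            vals = sub["value"].to_numpy()
            if len(vals) >= 2 and np.std(vals, ddof=1) > 0:
                rep = st.one_sample_test(vals, ref, alpha=config.alpha)
                reports[f"{metric}__{group}_vs_{ref:g}"] = rep.as_dict()

    metrics.to_csv(outdir / "metrics_unblinded.csv", index=False)
    (outdir / "stat_reports.json").write_text(json.dumps(reports, indent=2, default=str))
    flat = pd.DataFrame(
        [
            {"comparison": name, "test": r["test_name"], "statistic": r["statistic"],
             "p_value": r["p_value"], "stars": r["stars"]}
            for name, r in reports.items()
        ]
    )
    flat.to_csv(outdir / "stat_summary.csv", index=False)
    _write_report_md(outdir, config, metrics, flat)
    manifest = {
        "config_digest": config.digest(),
        "config": {k: str(v) for k, v in config.__dict__.items()},
        "n_mice": config.n_mice,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"metrics": metrics, "reports": reports, "manifest": manifest}


def _write_report_md(outdir: Path, config: RunConfig, metrics: pd.DataFrame,
                     flat: pd.DataFrame) -> None:
    lines = [
        "# Synthetic study report",
        "",
        f"Config digest: `{config.digest()}`; alpha = {config.alpha}; "
        f"n = {config.n_mice} mice in {len(config.groups)} groups.",
        "",
        "## Group means",
        "",
        metrics.groupby(["metric", "group"])["value"].mean().round(4).to_markdown(),
        "",
        "## Comparisons",
        "",
        flat.round(4).to_markdown(index=False) if len(flat) else "(none)",
        "",
    ]
    (outdir / "report.md").write_text("\n".join(lines))
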