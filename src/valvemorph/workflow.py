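"""End-to-end pipeline: simulate -> prep -> features -> classify ->
phases -> mixing, under one seeded, hashable configuration.

The pipeline replicates the full study design on synthetic data: valve
images are generated per experimental condition (temperature x silicon
status), reduced to skeleton morphometrics, classified into tree/mesh
weights, condition meshiness is aggregated, culture growth phases are
segmented per temperature, and the inheritance mixing model predicts
the meshiness of Si-limited cultures from the Si-replete ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import classify as cl
from . import imageprep as prep
from . import io as vio
from . import mixing, morphometry, popdyn, synthgen

log = logging.getLogger("valvemorph")

SCHEMA_VERSION = 1

#: per-temperature population defaults emulating the three cultures:
#: (tau_exp h, plateau density, final/plateau ratio)
TEMPERATURE_PRESETS = {
    14: {"tau_exp": 40.9, "d1": 1.16e6, "regrowth_factor": 1.66},
    18: {"tau_exp": 20.98, "d1": 1.14e6, "regrowth_factor": 1.85},
    23: {"tau_exp": 17.25, "d1": 1.02e6, "regrowth_factor": 1.36},
}


@dataclass
class Condition:
    name: str
    temperature_C: float
    si_status: str  # "L" (limited) or "NL" (non-limited)
    supply: float
    n_images: int = 30


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run; serializable and hashable."""

    seed: int = 0
    out_dir: str = "valvemorph_run"
    conditions: list[Condition] = field(
        default_factory=lambda: [
            Condition("14C_NL", 14, "NL", 0.85, 30),
            Condition("14C_L", 14, "L", 0.30, 30),
            Condition("23C_NL", 23, "NL", 0.85, 30),
            Condition("23C_L", 23, "L", 0.55, 30),
        ]
    )
    n_train_per_class: int = 25
    train_supply_tree: float = 0.05
    train_supply_mesh: float = 0.95
    pattern: dict[str, Any] = field(
        default_factory=lambda: {"radius_px": 96, "n_ribs": 12, "noise_sd": 8.0}
    )
    prep: dict[str, Any] = field(
        default_factory=lambda: {"bandpass_small": 1, "bandpass_large": 60, "prune_px": 4}
    )
    method: str = "ETC"
    n_estimators: int = 100
    d0: float = 0.33e6
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["conditions"] = [
            c if isinstance(c, Condition) else Condition(**c)
            for c in d.get("conditions", [])
        ]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where outputs land does not change the science
        payload = json.dumps(d, sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _child_seed(seed: int, *keys: int) -> int:
    return int(np.random.SeedSequence([seed, *keys]).generate_state(1)[0] % (2**31))


def image_to_features(
    img: prep.RasterImage,
    bandpass_small: int = 1,
    bandpass_large: int = 60,
    prune_px: int = 4,
    annotation: morphometry.ValveAnnotation | None = None,
) -> morphometry.FeatureVector:
    """The per-image measurement chain: filter, binarize, thin, measure."""
    filtered = prep.bandpass_filter(img, bandpass_small, bandpass_large)
    mask = prep.binarize(filtered)
    sk = prep.skeletonize(mask, prune_px=prune_px)
    g = morphometry.build_skeleton_graph(sk)
    meshes = morphometry.detect_meshes(sk)
    return morphometry.compute_features(g, meshes, annotation, mask)


def _generate_feature_rows(cfg: RunConfig) -> cl.FeatureTable:
    rows, labels, conds, index = [], [], [], []
    pattern_kw = dict(cfg.pattern)
    prep_kw = dict(cfg.prep)

    def add(name: str, supply: float, n: int, label: str | None, salt: int) -> None:
        for i in range(n):
            spec = synthgen.PatternSpec(
                supply=supply, seed=_child_seed(cfg.seed, salt, i), **pattern_kw
            )
            img, auto_label = synthgen.generate_valve_pattern(spec)
            fv = image_to_features(img, **prep_kw)
            rows.append(fv.to_series())
            labels.append(label)
            conds.append(name)
            index.append(f"{name}_{i:03d}")

    add("train", cfg.train_supply_tree, cfg.n_train_per_class, "tree", 901)
    add("train", cfg.train_supply_mesh, cfg.n_train_per_class, "mesh", 902)
    for k, cond in enumerate(cfg.conditions):
        add(cond.name, cond.supply, cond.n_images, None, 100 + k)
    data = pd.DataFrame(rows, index=index)
    return cl.FeatureTable(
        data,
        labels=pd.Series(labels, index=index, dtype=object),
        condition=pd.Series(conds, index=index),
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns (and writes) the run report.

    The generated feature table is cached in the output directory keyed
    by the config hash, so re-runs with an identical config skip image
    regeneration.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.hash()
    cfg.to_yaml(out / "config.yaml")

    cache = out / f"features_{cfg_hash}.csv"
    if cache.exists():
        log.info("stage features: cache hit (%s)", cache.name)
        table = vio.read_feature_table(cache)
    else:
        try:
            table = _generate_feature_rows(cfg)
        except Exception as exc:  # pragma: no cover - stage tagging
            raise RuntimeError(f"stage simulate/features failed: {exc}") from exc
        vio.write_feature_table(cache, table)

    try:
        norm_table, record = cl.normalize_features(table)
        train, rest = cl.select_training_set(norm_table)
        model = cl.EnsembleModel(
            cfg.method, n_estimators=cfg.n_estimators, seed=_child_seed(cfg.seed, 7)
        ).fit(train)
        result = cl.predict_meshiness(model, rest)
    except Exception as exc:
        raise RuntimeError(f"stage classify failed: {exc}") from exc

    meshiness = {}
    for cond in cfg.conditions:
        sub = result.per_image[result.per_image["condition"] == cond.name]
        meshiness[cond.name] = {
            "mean_p_mesh": float(sub["p_mesh"].mean()),
            "sd": float(sub["p_mesh"].std(ddof=1)),
            "n": int(len(sub)),
            "frac_mesh_calls": float((sub["call"] == "mesh").mean()),
        }

    # population dynamics per temperature
    temps = sorted({c.temperature_C for c in cfg.conditions})
    phases, series_by_temp = {}, {}
    for t_C in temps:
        preset = TEMPERATURE_PRESETS.get(int(t_C), TEMPERATURE_PRESETS[14])
        tau = preset["tau_exp"]
        t2 = tau * np.log2(preset["d1"] / cfg.d0)
        params = synthgen.PopulationParams(
            d0=cfg.d0,
            tau_exp=tau,
            t_phase2=float(t2),
            t_phase3=float(t2 + 36.0),
            regrowth_factor=preset["regrowth_factor"],
            obs_noise_cv=0.02,
            seed=_child_seed(cfg.seed, 11, int(t_C)),
        )
        series, _ = synthgen.generate_population_series(params)
        series_by_temp[t_C] = series
        try:
            summ = popdyn.summarize_phases(series)
        except Exception as exc:
            raise RuntimeError(f"stage phases failed at {t_C}C: {exc}") from exc
        phases[f"{t_C:g}C"] = {
            "tau_exp_h": summ.tau_exp_h,
            "t_phase2_h": summ.t_phase2_h,
            "t_phase3_h": summ.t_phase3_h,
            "d1": summ.d1,
            "d2": summ.d2,
            "ratio_d2_d1": summ.ratio_d2_d1,
        }

    # inheritance mixing model: predict L meshiness from NL meshiness
    mixing_rows = {}
    for t_C in temps:
        nl = next(
            (c for c in cfg.conditions if c.temperature_C == t_C and c.si_status == "NL"),
            None,
        )
        li = next(
            (c for c in cfg.conditions if c.temperature_C == t_C and c.si_status == "L"),
            None,
        )
        if nl is None or li is None:
            continue
        s = series_by_temp[t_C]
        d_p1 = float(np.interp(29.0, s.times_h, s.density))
        d_p2p3 = float(s.density[-1])
        inputs = mixing.MixingInputs(
            mesh_p1=meshiness[nl.name]["mean_p_mesh"], d_p1=d_p1, d_p2p3=d_p2p3
        )
        mixing_rows[f"{t_C:g}C"] = {
            "mesh_p1": inputs.mesh_p1,
            "d_p1": d_p1,
            "d_p2p3": d_p2p3,
            "predicted_L_meshiness": mixing.predict_population_meshiness(inputs),
            "observed_L_meshiness": meshiness[li.name]["mean_p_mesh"],
        }

    report = {
        "config_hash": cfg_hash,
        "schema_version": cfg.schema_version,
        "meshiness": meshiness,
        "phases": phases,
        "mixing": mixing_rows,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    _write_markdown_report(out / "report.md", report)
    return report


def _write_markdown_report(path: Path, report: dict) -> None:
    lines = [f"# valvemorph run `{report['config_hash']}`", "", "## Meshiness per condition", ""]
    lines.append("| condition | mean p_mesh | sd | n | frac mesh calls |")
    lines.append("|---|---|---|---|---|")
    for name, row in report["meshiness"].items():
        lines.append(
            f"| {name} | {row['mean_p_mesh']:.3f} | {row['sd']:.3f} "
            f"| {row['n']} | {row['frac_mesh_calls']:.2f} |"
        )
    lines += ["", "## Growth phases", ""]
    lines.append("| culture | tau_exp (h) | t_phase2 (h) | t_phase3 (h) | d1 | d2 | d2/d1 |")
    lines.append("|---|---|---|---|---|---|---|")
    for name, row in report["phases"].items():
        t3 = f"{row['t_phase3_h']:.0f}" if row["t_phase3_h"] is not None else "-"
        lines.append(
            f"| {name} | {row['tau_exp_h']:.2f} | {row['t_phase2_h']:.0f} | {t3} "
            f"| {row['d1']:.3g} | {row['d2']:.3g} | {row['ratio_d2_d1']:.2f} |"
        )
    lines += ["", "## Mixing-model prediction for Si-limited cultures", ""]
    lines.append("| culture | mesh_p1 | predicted L meshiness | observed L meshiness |")
    lines.append("|---|---|---|---|")
    for name, row in report["mixing"].items():
        lines.append(
            f"| {name} | {row['mesh_p1']:.3f} | {row['predicted_L_meshiness']:.3f} "
            f"| {row['observed_L_meshiness']:.3f} |"
        )
    path.write_text("\n".join(lines) + "\n")
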