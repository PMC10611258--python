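"""Config-driven end-to-end run: simulate -> train -> score -> integrate -> explain.

A :class:`RunConfig` fully determines a run: one generator seed, one
training seed per compartment, the geometric scale, the study design and
compound profiles. The run report records every seed and a SHA-256
content hash per stage, computed over the stage's data (pixels, weights,
tables) rather than file paths - two runs with the same config produce
identical hashes, which is the pipeline's reproducibility guarantee.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .classifier import (TrainConfig, TrainedTileModel, build_training_set,
                         train)
from .errors import ConfigurationError
from .gradcam import gradcam, save_overlays
from .images import AreaImage, manifest_frame, save_study
from .moa import (MoAPoint, classify_moa, make_moa_points,
                  make_replicate_points, manova_pairwise, plot_moa)
from .phenotypes import (CompoundProfile, Concentration, DesignRow,
                         PhenotypeParams, StudyDesign, default_design,
                         default_label_map, default_profiles)
from .scoring import (CompoundSummary, ToxicityLine, anova_dunnett,
                      probabilities_frame, score_images, summaries_frame,
                      summarize, toxicity_line)
from .simulate import generate_axon_image, generate_soma_image, generate_study
from .tiling import tile_image

log = logging.getLogger("somaxon")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    out_dir: str = "somaxon_run"
    scale: float = 0.25
    seed_generator: int | None = 0
    seed_soma_train: int | None = 1
    seed_axon_train: int | None = 2
    alpha: float = 0.05
    decision_threshold: float = 0.5
    epochs_soma: int = 8
    epochs_axon: int = 45
    augment: bool = True
    n_scale: float = 1.0            # multiplies every design row's n
    design: Any = "default"         # "default" or declarative row list
    profiles: Any = "default"       # "default" or declarative mapping
    write_images: bool = False
    explain_tiles: int = 2

    def __post_init__(self) -> None:
        for name in ("seed_generator", "seed_soma_train", "seed_axon_train"):
            v = getattr(self, name)
            if v is None:
                raise ConfigurationError(f"missing required seed {name!r}")
            if int(v) != v:
                raise ConfigurationError(f"{name} must be an integer")
        if self.scale <= 0:
            raise ConfigurationError("scale must be positive")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if not 0 <= self.decision_threshold <= 1:
            raise ConfigurationError("decision_threshold must be in [0, 1]")

    @classmethod
    def from_root_seed(cls, seed: int, **kwargs) -> "RunConfig":
        """Derive the three stage seeds deterministically from one root."""
        children = np.random.SeedSequence(seed).generate_state(3) % (2 ** 31)
        return cls(seed_generator=int(children[0]),
                   seed_soma_train=int(children[1]),
                   seed_axon_train=int(children[2]), **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Declarative design / profile parsing
# ---------------------------------------------------------------------------

def profiles_from_spec(spec: Any) -> tuple[CompoundProfile, ...]:
    if spec == "default" or spec is None:
        return default_profiles()
    out = []
    for name, body in spec.items():
        levels = []
        for lv in body["levels"]:
            conc = Concentration(float(lv["value"]), str(lv.get("unit", "uM")))
            levels.append((conc, PhenotypeParams.from_severity(
                float(lv.get("soma_severity", 0.0)),
                float(lv.get("axon_severity", 0.0)))))
        out.append(CompoundProfile(name=name, role=body["role"],
                                   levels=tuple(levels)))
    return tuple(out)


def design_from_spec(spec: Any) -> StudyDesign:
    if spec == "default" or spec is None:
        return default_design()
    rows = []
    for r in spec:
        rows.append(DesignRow(
            compound=r["compound"],
            concentration=Concentration(float(r["value"]), str(r.get("unit", "uM"))),
            area_kind=r["area_kind"], split=r["split"],
            n_images=int(r["n_images"])))
    return StudyDesign(tuple(rows))


# ---------------------------------------------------------------------------
# Hashing helpers
# ---------------------------------------------------------------------------

def _hash_images(images: Sequence[AreaImage]) -> str:
    h = hashlib.sha256()
    for img in images:
        h.update(img.image_id.encode())
        h.update(img.pixels.tobytes())
    return h.hexdigest()


def _hash_model(model: TrainedTileModel) -> str:
    h = hashlib.sha256()
    state = model.net.state_dict()
    for k in sorted(state):
        h.update(k.encode())
        h.update(np.ascontiguousarray(state[k]).tobytes())
    return h.hexdigest()


def _hash_frames(*frames: pd.DataFrame) -> str:
    h = hashlib.sha256()
    for f in frames:
        h.update(f.to_csv(index=True, float_format="%.10g").encode())
    return h.hexdigest()


def _hash_arrays(arrays: Sequence[np.ndarray]) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# The run itself
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "versions": {"somaxon": _version, "numpy": np.__version__},
        "config": config.to_dict(),
        "stage_hashes": {},
        "stage_seconds": {},
    }
    stage_t0 = time.time()

    def finish_stage(name: str, digest: str) -> None:
        nonlocal stage_t0
        report["stage_hashes"][name] = digest
        report["stage_seconds"][name] = round(time.time() - stage_t0, 2)
        log.info("stage %-12s %6.1fs  %s", name,
                 report["stage_seconds"][name], digest[:12])
        stage_t0 = time.time()

    try:
        design = design_from_spec(config.design)
        if config.n_scale != 1.0:
            design = design.scaled_counts(config.n_scale)
        profiles = profiles_from_spec(config.profiles)
        label_map = default_label_map(profiles)

        # ---- simulate -----------------------------------------------------
        images = generate_study(design, profiles, config.seed_generator,
                                scale=config.scale)
        if config.write_images:
            save_study(images, out / "images")
        else:
            manifest_frame(images).to_csv(out / "manifest.csv", index=False)
        finish_stage("simulate", _hash_images(images))

        by_area = {kind: [i for i in images if i.area_kind == kind]
                   for kind in ("soma", "axon")}
        models: dict[str, TrainedTileModel] = {}
        scores: dict[str, list] = {}
        summaries: dict[str, list[CompoundSummary]] = {}
        lines: dict[str, ToxicityLine] = {}
        negatives = {p.name for p in profiles if p.role in ("vehicle", "negative")}
        vehicle = next(p.name for p in profiles if p.role == "vehicle")

        for kind, seed, epochs in (
                ("soma", config.seed_soma_train, config.epochs_soma),
                ("axon", config.seed_axon_train, config.epochs_axon)):
            tc = TrainConfig(epochs=epochs, augment=config.augment,
                             decision_threshold=config.decision_threshold)
            trains = [i for i in by_area[kind] if i.split == "train"]
            dataset = build_training_set(trains, kind, label_map)
            model = train(dataset, seed=seed, config=tc)
            model.save(out / f"model_{kind}.npz")
            models[kind] = model
            finish_stage(f"train_{kind}", _hash_model(model))

        # ---- score --------------------------------------------------------
        stats_out: dict[str, list[dict]] = {}
        for kind in ("soma", "axon"):
            tests = [i for i in by_area[kind] if i.split == "test"]
            probs = score_images(models[kind], tests)
            scores[kind] = probs
            lines[kind] = toxicity_line(
                [p for p in probs if p.compound in negatives])
            summaries[kind] = summarize(probs)
            groups = {}
            for p in probs:
                groups.setdefault(f"{p.compound} {p.concentration}", []).append(
                    p.percent_positive)
            control_key = next(k for k in groups if k.startswith(vehicle))
            tests_res = anova_dunnett(groups, control=control_key,
                                      alpha=config.alpha)
            stats_out[kind] = [{
                "comparison": r.comparison, "statistic": r.statistic,
                "p_value": r.p_value, "significant": r.significant,
            } for r in tests_res]

            pframe = probabilities_frame(probs)
            sframe = summaries_frame(summaries[kind], lines[kind])
            pframe.to_csv(out / f"scores_{kind}.csv", index=False)
            sframe.to_csv(out / f"summary_{kind}.csv", index=False)
            (out / f"line_{kind}.json").write_text(json.dumps({
                "area_kind": kind,
                "threshold_percent": lines[kind].threshold_percent,
                "negative_mean": lines[kind].negative_mean,
                "negative_sd": lines[kind].negative_sd,
                "n_sources": len(lines[kind].source_image_ids),
            }, indent=2))
            finish_stage(f"score_{kind}", _hash_frames(pframe, sframe))

        # ---- integrate ----------------------------------------------------
        mean_points = make_moa_points(summaries["soma"], summaries["axon"])
        rep_points = make_replicate_points(scores["soma"], scores["axon"])
        calls = [classify_moa(p, lines["soma"], lines["axon"])
                 for p in mean_points]
        labels, pmat, _ = manova_pairwise(rep_points, alpha=config.alpha)

        points_frame = pd.DataFrame([{
            "compound": p.compound, "concentration": p.concentration,
            "axon_percent": p.axon_percent, "soma_percent": p.soma_percent,
            "mode": p.mode, "replicate": p.replicate,
        } for p in mean_points + rep_points])
        calls_frame = pd.DataFrame([{
            "compound": c.compound, "concentration": c.concentration,
            "category": c.category} for c in calls])
        points_frame.to_csv(out / "moa_points.csv", index=False)
        calls_frame.to_csv(out / "moa_calls.csv", index=False)
        pmat.to_csv(out / "manova_pairwise.csv")
        plot_moa(rep_points, lines["soma"], lines["axon"], out / "moa_plot.png")
        finish_stage("integrate", _hash_frames(points_frame, calls_frame, pmat))

        # ---- explain ------------------------------------------------------
        maps = []
        for kind in ("soma", "axon"):
            tests = [i for i in by_area[kind] if i.split == "test"]
            examples = [
                ("negative", next(i for i in tests if i.compound in negatives)),
                ("positive", next(i for i in tests if i.compound not in negatives)),
            ]
            for cls_name, img in examples:
                tiles = tile_image(img, models[kind].tile_side)
                chosen = tiles[:config.explain_tiles]
                save_overlays(models[kind], chosen, cls_name,
                              out / "explain" / kind)
                maps.extend(gradcam(models[kind], t, cls_name).values
                            for t in chosen)
        finish_stage("explain", _hash_arrays(maps))

        # ---- report -------------------------------------------------------
        report["lines"] = {k: lines[k].threshold_percent for k in lines}
        report["summaries"] = {
            k: summaries_frame(summaries[k], lines[k]).to_dict("records")
            for k in summaries}
        report["moa_calls"] = calls_frame.to_dict("records")
        report["dunnett"] = stats_out
        report["manova_conditions"] = labels
        (out / "report.json").write_text(json.dumps(report, indent=2))
        return report
    except Exception as exc:  # tag the failing stage for the CLI
        done = list(report["stage_hashes"])
        stage = done[-1] if done else "init"
        raise type(exc)(f"[after stage {stage}] {exc}") from exc


# ---------------------------------------------------------------------------
# Severity sweep (monotonicity probe)
# ---------------------------------------------------------------------------

def severity_sweep(models: dict[str, TrainedTileModel],
                   severities: Sequence[float] = (0.0, 0.3, 0.6, 1.0),
                   n_images: int = 20, seed: int = 0,
                   scale: float = 0.25) -> pd.DataFrame:
    """Mean toxicity probability per generator severity, per compartment.

    Generates fresh images at each severity for the compartment the
    severity targets and scores them with the already-trained models.
    """
    from .scoring import score_image

    side = int(round(2304 * scale))
    rows = []
    for kind, model in models.items():
        for si, sev in enumerate(severities):
            if kind == "soma":
                params = PhenotypeParams.from_severity(sev, 0.0)
            else:
                params = PhenotypeParams.from_severity(0.0, sev)
            vals = []
            for rep in range(n_images):
                child = int(np.random.SeedSequence(
                    [seed, 77 if kind == "soma" else 99, si, rep]
                ).generate_state(1)[0])
                if kind == "soma":
                    img = generate_soma_image(params, side, side, child,
                                              scale=scale)
                else:
                    img = generate_axon_image(params, side, side, child,
                                              scale=scale)
                img.image_id = f"sweep_{kind}_{sev}_{rep}"
                img.compound = "sweep"
                vals.extend(p.percent_positive for p in score_image(model, img))
            rows.append({"area_kind": kind, "severity": sev,
                         "mean_percent": float(np.mean(vals)),
                         "n_samples": len(vals)})
    return pd.DataFrame(rows)
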