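"""End-to-end experiment orchestration.

A single YAML-configurable entry point chains the modules: stimulus
generation -> network construction -> activation recording -> selectivity
screen -> tuning characterization -> (optionally) behavioral decoding with
silencing ablations.  Default parameters reproduce the reference protocol
(600 balanced stimuli over numerosities 0–4 and three sets, ANOVA at
alpha = 0.01, 100 selectivity repetitions, 50 behavior repetitions); desk-
scale runs override the repetition counts and/or use the reduced "tiny"
architecture.

One global seed expands deterministically into per-stage seeds, so a
results bundle is fully regenerable from its embedded config, and every
run writes a provenance block (config hash, seeds, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import behavior as _behavior
from . import hcnn, selectivity, stimuli
from . import tuning as _tuning

__all__ = ["ExperimentConfig", "StageError", "run_experiment", "report"]

log = logging.getLogger("numsense")


class StageError(RuntimeError):
    """A pipeline stage failed; earlier stages' outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ExperimentConfig:
    # network
    network_config: str | None = None  # YAML path; None -> canonical table
    tiny: bool = False
    mode: str = "untrained"  # untrained | trained-checkpoint
    checkpoint: str | None = None
    # stimulus plan
    numerosities: tuple = (0, 1, 2, 3, 4)
    sets: tuple = tuple(stimuli.SETS)
    n_images: int = 600
    # analysis
    alpha: float = 0.01
    selectivity_reps: int = 100
    # behavior
    run_behavior: bool = False
    behavior_reps: int = 50
    n_train_trials: int = 600
    n_test_trials: int = 600
    silencing_reps: int = 10
    # bookkeeping
    seed: int = 0
    out_dir: str = "results"
    make_figures: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.numerosities = tuple(cfg.numerosities)
        cfg.sets = tuple(cfg.sets)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.mode not in ("untrained", "trained-checkpoint"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "trained-checkpoint" and not self.checkpoint:
            raise ValueError("trained-checkpoint mode requires a checkpoint path")
        cells = len(self.numerosities) * len(self.sets)
        if self.n_images % cells:
            raise ValueError("n_images must divide evenly over stimulus cells")

    def network(self) -> hcnn.NetworkConfig:
        if self.network_config:
            return hcnn.config_from_yaml(self.network_config)
        return hcnn.tiny_config() if self.tiny else hcnn.default_config()

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the configured stages and write the results bundle.

    Returns the top-level summary dictionary (also written to
    ``<out_dir>/summary.json``).  On stage failure a :class:`StageError`
    is raised; outputs of completed stages stay on disk.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    if os.path.exists(os.path.join(config.out_dir, "summary.json")):
        raise FileExistsError(
            f"{config.out_dir!r} already holds a summary.json; refusing to overwrite"
        )
    net_cfg = config.network()
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(c.generate_state(1)[0] % (2**31))
        for name, c in zip(
            ["selectivity", "behavior", "weights", "stimuli", "noise"], ss.spawn(5)
        )
    }
    summary: dict = {
        "provenance": {
            "config": dataclasses.asdict(config),
            "config_hash": config.hash(),
            "stage_seeds": seeds,
            "version": _version(),
        },
        "stages": {},
    }
    stage = "selectivity"
    t0 = time.time()
    try:
        log.info("stage %s: %d repetitions", stage, config.selectivity_reps)
        study = selectivity.untrained_repetition_study(
            config=net_cfg,
            n_reps=config.selectivity_reps,
            base_seed=seeds["selectivity"],
            numerosities=config.numerosities,
            sets=config.sets,
            n_images=config.n_images,
            alpha=config.alpha,
        )
        study.per_rep.to_csv(
            os.path.join(config.out_dir, "selectivity_per_rep.csv"), index=False
        )
        summary["stages"]["selectivity"] = {
            "n_units_total": study.n_units_total,
            "n_reps": study.n_reps,
            "fraction_selective": study.fraction_selective,
            "fraction_selective_se": study.fraction_selective_se,
            "fraction_zero_preferring": study.fraction_zero_preferring,
            "fraction_zero_preferring_se": study.fraction_zero_preferring_se,
            "preferred_histogram": study.preferred_histogram,
            "numerosities": list(study.numerosities),
            "response_variability": study.response_variability,
        }
        log.info("stage selectivity done in %.1fs", time.time() - t0)
    except Exception as exc:  # pragma: no cover - defensive wrapper
        _finalize(summary, config)
        raise StageError(stage, exc) from exc

    stage = "tuning"
    t0 = time.time()
    try:
        tun = _tuning_stage(config, net_cfg, seeds)
        summary["stages"]["tuning"] = tun
        log.info("stage tuning done in %.1fs", time.time() - t0)
    except Exception as exc:
        _finalize(summary, config)
        raise StageError(stage, exc) from exc

    if config.run_behavior:
        stage = "behavior"
        t0 = time.time()
        try:
            beh = _behavior_stage(config, net_cfg, seeds)
            summary["stages"]["behavior"] = beh
            log.info("stage behavior done in %.1fs", time.time() - t0)
        except Exception as exc:
            _finalize(summary, config)
            raise StageError(stage, exc) from exc

    _finalize(summary, config)
    return summary


def _version() -> str:
    from . import __version__

    return __version__


def _finalize(summary: dict, config: ExperimentConfig) -> None:
    _write_json(summary, os.path.join(config.out_dir, "summary.json"))


def _single_rep(config, net_cfg, seeds):
    """One fully seeded screen (network + stimuli + recording + screen)."""
    net = _make_network(config, net_cfg, seeds["weights"])
    manifest = stimuli.generate_manifest(
        config.numerosities, config.sets, config.n_images,
        rng_seed=seeds["stimuli"], image_size=net_cfg.input_size,
    )
    acts = hcnn.forward_record(net, manifest.images, seed=seeds["noise"])
    _, selective = selectivity.screen_selectivity(acts, manifest, config.alpha)
    return net, manifest, acts, selective


def _make_network(config, net_cfg, seed):
    net = hcnn.build_network(net_cfg, seed=seed)
    if config.mode == "trained-checkpoint":
        hcnn.load_checkpoint(net, config.checkpoint)
    return net


def _tuning_stage(config, net_cfg, seeds) -> dict:
    net, manifest, acts, selective = _single_rep(config, net_cfg, seeds)
    if not len(selective):
        return {"n_selective": 0, "note": "no numerosity-tuned units found"}
    profiles = selectivity.tuning_profiles(acts, manifest, selective, warn_flat=False)
    selectivity.profiles_table(profiles).to_csv(
        os.path.join(config.out_dir, "unit_profiles.csv"), index=False
    )
    if profiles and profiles[0].normalized_curve.size >= 4:
        _tuning.fits_table(profiles).to_csv(
            os.path.join(config.out_dir, "unit_fits.csv"), index=False
        )
    curves = _tuning.population_curves(profiles)
    effects = _tuning.distance_size_effects(profiles)
    out: dict = {
        "n_selective": len(profiles),
        "population_curves": {
            c.preferred_numerosity: {"mean": c.mean, "sem": c.sem, "n": c.n_units}
            for c in curves
        },
        "distance_size_effects": dataclasses.asdict(effects),
    }
    try:
        sc = _tuning.scale_comparison(profiles)
        out["scale_comparison"] = {
            "mean_r2_linear": sc.mean_r2_linear,
            "mean_r2_log": sc.mean_r2_log,
            "wilcoxon_p": sc.wilcoxon_p,
            "n": sc.n,
        }
        zero = [p for p in profiles if p.preferred_numerosity == 0]
        if len(zero) >= _tuning.MIN_PAIRS:
            lc = _tuning.scale_comparison(
                curves=[p.normalized_curve for p in zero],
                numerosities=zero[0].numerosities,
                fitter=_tuning.fit_line,
            )
            out["zero_line_fit_comparison"] = {
                "mean_r2_linear": lc.mean_r2_linear,
                "mean_r2_log": lc.mean_r2_log,
                "wilcoxon_p": lc.wilcoxon_p,
                "n": lc.n,
            }
    except ValueError:
        pass
    if config.make_figures:
        _figures(config, curves)
    return out


def _behavior_stage(config, net_cfg, seeds) -> dict:
    net, manifest, acts, selective = _single_rep(config, net_cfg, seeds)
    if len(selective) < 2:
        return {"note": "too few selective units for decoding"}
    profiles = selectivity.tuning_profiles(acts, manifest, selective, warn_flat=False)
    unit_ids = np.array([p.unit_id for p in profiles])
    preferred = np.array([p.preferred_numerosity for p in profiles])

    def recorder_factory(noise_seed):
        def recorder(images):
            rec = hcnn.forward_record(net, images, seed=noise_seed)
            return rec.values[unit_ids].T

        return recorder

    study = _behavior.matching_study(
        recorder_factory,
        n_reps=config.behavior_reps,
        n_train=config.n_train_trials,
        n_test=config.n_test_trials,
        numerosities=config.numerosities,
        sets=config.sets,
        base_seed=seeds["behavior"],
        image_size=net_cfg.input_size,
    )
    study.per_rep.to_csv(
        os.path.join(config.out_dir, "matching_per_rep.csv"), index=False
    )
    study.results[-1].predictions.to_csv(
        os.path.join(config.out_dir, "matching_trials.csv"), index=False
    )
    out: dict = {
        "matching_accuracy": study.accuracy,
        "matching_accuracy_se": study.accuracy_se,
        "matching_accuracy_zero": study.accuracy_zero,
        "performance_functions": {
            pf.sample_numerosity: {"p_same": pf.p_same, "sem": pf.sem}
            for pf in study.performance
        },
    }
    try:
        fits = _behavior.performance_fits(study.performance)
        out["performance_fits"] = {
            "widths": fits.widths,
            "size_effect_r": fits.size_effect_r,
            "size_effect_p": fits.size_effect_p,
        }
    except ValueError:
        pass

    # categorization + silencing on freshly generated single displays
    rng = np.random.default_rng(seeds["behavior"] + 1)
    imgs, labels = [], []
    per_class = max(
        10, (config.n_train_trials // max(len(config.numerosities), 1)) // 2
    )
    for n in config.numerosities:
        for _ in range(per_class):
            set_id = config.sets[rng.integers(len(config.sets))]
            _, img = stimuli.generate_stimulus(n, set_id, rng, net_cfg.input_size)
            imgs.append(img)
            labels.append(n)
    feats = recorder_factory(seeds["noise"] + 1)(np.stack(imgs))
    sil = _behavior.silencing_study(
        feats,
        np.array(labels),
        preferred,
        n_reps=config.silencing_reps,
        base_seed=seeds["behavior"] + 2,
    )
    out["silencing"] = {
        "zero_tpr_mean": sil.zero_tpr_mean,
        "tests": {f"{a} vs {b}": p for (a, b), (_, p) in sil.tests.items()},
    }
    if config.make_figures:
        cat = _behavior.categorize_numerosity(
            feats, np.array(labels), rng=np.random.default_rng(seeds["behavior"] + 3)
        )
        _confusion_figure(config, cat.confusion)
    return out


def _confusion_figure(config, cm) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(cm.rates, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(cm.classes)), cm.classes)
    ax.set_yticks(range(len(cm.classes)), cm.classes)
    ax.set_xlabel("predicted numerosity")
    ax.set_ylabel("true numerosity")
    fig.colorbar(im, ax=ax, label="rate")
    fig.tight_layout()
    fig.savefig(os.path.join(config.out_dir, "confusion_matrix.png"), dpi=150)
    plt.close(fig)


def _figures(config, curves) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for c in curves:
        x = c.numerosities
        for ax, transform in zip(axes, [lambda v: v, _tuning.log_axis]):
            ax.errorbar(
                transform(x), c.mean, yerr=c.sem,
                label=f"pref {c.preferred_numerosity}", capsize=2,
            )
    axes[0].set_xlabel("numerosity (linear)")
    axes[1].set_xlabel("numerosity (log2(n+1))")
    axes[0].set_ylabel("normalized response")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(os.path.join(config.out_dir, "population_curves.png"), dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def report(bundle_dir: str) -> str:
    """Render a Markdown report from a results bundle directory."""
    path = os.path.join(bundle_dir, "summary.json")
    with open(path) as fh:
        summary = json.load(fh)
    lines = ["# Numerosity experiment report", ""]
    prov = summary.get("provenance", {})
    lines += [
        f"- config hash: `{prov.get('config_hash', '?')}`",
        f"- seed: {prov.get('config', {}).get('seed', '?')}",
        "",
    ]
    stages = summary.get("stages", {})
    sel = stages.get("selectivity")
    if sel:
        lines += [
            "## Selectivity screen",
            "",
            f"- units screened: {sel['n_units_total']}",
            f"- repetitions: {sel['n_reps']}",
            f"- fraction selective: {100 * sel['fraction_selective']:.2f}% "
            f"± {100 * sel['fraction_selective_se']:.2f}",
            f"- zero-preferring among selective: "
            f"{100 * sel['fraction_zero_preferring']:.2f}% "
            f"± {100 * sel['fraction_zero_preferring_se']:.2f}",
            f"- response variability (mean s.e. of normalized responses): "
            f"{sel['response_variability']:.3f}",
            "",
        ]
        hist = sel.get("preferred_histogram")
        if hist:
            lines += ["| preferred numerosity | mean count |", "|---|---|"]
            for q, h in zip(sel["numerosities"], hist):
                lines.append(f"| {q} | {h:.1f} |")
            lines.append("")
    tun = stages.get("tuning")
    if tun:
        lines += ["## Tuning characterization", ""]
        if tun.get("n_selective", 0) == 0:
            lines += ["No numerosity-tuned units were found.", ""]
        else:
            lines.append(f"- selective units profiled: {tun['n_selective']}")
            eff = tun.get("distance_size_effects")
            if eff:
                lines += [
                    f"- zero-unit distance effect 1 vs 2: p = "
                    f"{eff['wilcoxon_1v2_p']:.2e}",
                    f"- zero-unit distance effect 2 vs 3: p = "
                    f"{eff['wilcoxon_2v3_p']:.2e}",
                    f"- size effect (Pearson r of width vs preferred): "
                    f"r = {eff['size_effect_r']:.2f}",
                ]
            sc = tun.get("scale_comparison")
            if sc:
                lines.append(
                    f"- Gaussian fit r² linear vs log scale: "
                    f"{sc['mean_r2_linear']:.3f} vs {sc['mean_r2_log']:.3f} "
                    f"(Wilcoxon p = {sc['wilcoxon_p']:.2e}, n = {sc['n']})"
                )
            lc = tun.get("zero_line_fit_comparison")
            if lc:
                lines.append(
                    f"- zero-unit line fit r² linear vs log scale: "
                    f"{lc['mean_r2_linear']:.3f} vs {lc['mean_r2_log']:.3f} "
                    f"(Wilcoxon p = {lc['wilcoxon_p']:.2e})"
                )
            lines.append("")
    beh = stages.get("behavior")
    if beh:
        lines += ["## Behavioral decoding", ""]
        if "matching_accuracy" in beh:
            lines += [
                f"- matching accuracy: {100 * beh['matching_accuracy']:.1f}% "
                f"± {100 * beh['matching_accuracy_se']:.1f} (chance 50%)",
                f"- matching accuracy, zero-involving trials: "
                f"{100 * beh['matching_accuracy_zero']:.1f}%",
            ]
        sil = beh.get("silencing")
        if sil:
            lines.append("- zero-class true-positive rate by condition:")
            for cond, v in sil["zero_tpr_mean"].items():
                lines.append(f"    - {cond}: {100 * v:.1f}%")
            for name, p in sil["tests"].items():
                lines.append(f"    - {name}: Wilcoxon p = {p:.2e}")
        lines.append("")
    text = "\n".join(lines)
    out = os.path.join(bundle_dir, "report.md")
    with open(out, "w") as fh:
        fh.write(text)
    return text
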