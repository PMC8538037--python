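"""End-to-end orchestration: generate → measure → classify → quantify →
fit → compare, under a single seeded configuration.

A :class:`RunConfig` bundles per-class shape/marker/stiffness parameters
for one substrate condition. Two presets mirror the study conditions:
``glass_like_config`` (myofibroblast-dominated, stiffer myFib, high α-SMA
colocalization) and ``cnt_like_config`` (SMc/Fib-dominated, fewer and
smaller myofibroblasts, reduced colocalization). ``run`` executes every
stage and returns a :class:`RunReport` whose tables are reproduced
bit-identically for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import afm, classify, fluoquant, morphometry, synth

__all__ = [
    "RunConfig",
    "RunReport",
    "run",
    "compare_conditions",
    "glass_like_config",
    "cnt_like_config",
]


@dataclass
class RunConfig:
    """All knobs of one simulated condition.

    ``composition`` gives the class mix (fractions summing to 1);
    ``E_kPa``, ``fa_fraction``, ``fiber_fraction`` are per-class ground
    truths; ``sma_fraction`` is the population-level colocalized fraction.
    Stage sizes are kept modest by default so a full run stays interactive;
    they scale freely.
    """

    label: str = "condition"
    seed: int = 0
    pixel_size: float = synth.DEFAULT_PIXEL_SIZE
    n_cells: int = 150
    composition: dict = field(
        default_factory=lambda: {"SMc": 0.22, "Fib": 0.28, "myFib": 0.50}
    )
    shape_params: dict = field(default_factory=dict)  # class -> ShapeParams
    density_per_mm2: float = 773.0
    n_fields: int = 5
    field_area_mm2: float = 0.15
    E_kPa: dict = field(default_factory=lambda: {"SMc": 1.4, "Fib": 1.6, "myFib": 5.5})
    n_curves_per_class: int = 20
    force_noise_frac: float = 0.02
    fa_fraction: dict = field(default_factory=lambda: {"SMc": 0.024, "Fib": 0.020, "myFib": 0.030})
    fiber_fraction: dict = field(default_factory=lambda: {"SMc": 0.16, "Fib": 0.15, "myFib": 0.21})
    sma_fraction: float = 0.83
    n_marker_cells_per_class: int = 8
    marker_background: float = 0.2
    marker_noise_sd: float = 0.05
    alpha: float = 0.05

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if not np.isclose(total, 1.0):
            raise ValueError("composition fractions must sum to 1")
        if not self.shape_params:
            self.shape_params = {
                c: synth.default_shape_params(c, self.pixel_size) for c in synth.CLASS_NAMES
            }


def glass_like_config(seed: int = 0, **overrides) -> RunConfig:
    """Flat-substrate control condition: myofibroblast-dominated culture."""
    cfg = RunConfig(
        label="glass",
        seed=seed,
        composition={"SMc": 0.22, "Fib": 0.28, "myFib": 0.50},
        density_per_mm2=773.0,
        E_kPa={"SMc": 1.4, "Fib": 1.6, "myFib": 5.5},
        fa_fraction={"SMc": 0.024, "Fib": 0.020, "myFib": 0.030},
        fiber_fraction={"SMc": 0.16, "Fib": 0.15, "myFib": 0.21},
        sma_fraction=0.83,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def cnt_like_config(seed: int = 0, **overrides) -> RunConfig:
    """Nanostructured-substrate condition: quiescent, SMc/Fib-dominated."""
    cfg = RunConfig(
        label="CNT",
        seed=seed,
        composition={"SMc": 0.44, "Fib": 0.46, "myFib": 0.10},
        density_per_mm2=775.0,
        E_kPa={"SMc": 2.8, "Fib": 4.2, "myFib": 5.7},
        fa_fraction={"SMc": 0.038, "Fib": 0.067, "myFib": 0.073},
        fiber_fraction={"SMc": 0.15, "Fib": 0.16, "myFib": 0.17},
        sma_fraction=0.58,
    )
    # the smaller myFib footprint is specific to the nanostructured surface
    cfg.shape_params = {c: synth.default_shape_params(c, cfg.pixel_size) for c in synth.CLASS_NAMES}
    cfg.shape_params["myFib"].area_mean = 757.0
    cfg.shape_params["myFib"].area_sd = 326.0
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class RunReport:
    label: str
    features: pd.DataFrame
    assignments: pd.DataFrame
    composition_pct: pd.Series
    metrics: pd.DataFrame  # tidy: morph, metric, value
    density_per_mm2: float
    manifest: dict


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run(config: RunConfig) -> RunReport:
    """Execute every stage of one condition; deterministic given the seed."""
    cfg = config
    seeds = _spawn_seeds(cfg.seed, 6)
    rng = np.random.default_rng(seeds[0])

    # --- stage 1: morphology population -------------------------------------
    classes = list(cfg.composition)
    probs = np.array([cfg.composition[c] for c in classes])
    rows, elongations, true_labels = [], [], []
    for i in range(cfg.n_cells):
        cls = classes[rng.choice(len(classes), p=probs)]
        cell, truth = synth.gen_cell_mask(cfg.shape_params[cls], rng_seed=int(rng.integers(2**31)))
        feats = morphometry.measure_features(cell)
        rows.append(
            {
                "cell_id": f"{cfg.label}-{i}",
                "true_class": cls,
                "area_um2": feats.area_um2,
                "perimeter_um": feats.perimeter_um,
                "doc": feats.doc,
                "elongation": feats.elongation,
                "axis_ratio": feats.axis_ratio,
                "n_cusps": feats.n_cusps,
            }
        )
        elongations.append(min(feats.elongation, 0.999))
        true_labels.append(cls)
    features = pd.DataFrame(rows)

    # --- stage 2: classification --------------------------------------------
    model = classify.fit_classifier(elongations)
    assignments = model.assign(elongations, cell_ids=features["cell_id"].tolist())
    assignments["true_class"] = true_labels
    composition = classify.class_composition(assignments)
    features["predicted_class"] = assignments["predicted_class"].to_numpy()

    # --- stage 3: nuclei density --------------------------------------------
    fp = synth.FieldParams(
        density=cfg.density_per_mm2, field_area=cfg.field_area_mm2,
        n_fields=cfg.n_fields, seed=seeds[1],
    )
    fields = synth.gen_nuclei_field(fp, render=True, pixel_size=cfg.pixel_size)
    counts = [
        len(fluoquant.detect_nuclei(f["image"], f["pixel_size"])) for f in fields
    ]
    density = float(np.sum(counts) / (cfg.n_fields * cfg.field_area_mm2))

    # --- stage 4: per-class immunofluorescence ------------------------------
    metric_rows = []
    rng4 = np.random.default_rng(seeds[2])
    for cls in classes:
        for j in range(cfg.n_marker_cells_per_class):
            cell, _ = synth.gen_cell_mask(cfg.shape_params[cls], rng_seed=int(rng4.integers(2**31)))
            s = int(rng4.integers(2**31))
            fa = synth.gen_marker_field(cell, cfg.fa_fraction[cls], cfg.marker_background,
                                        cfg.marker_noise_sd, rng_seed=s, mode="punctae")
            metric_rows.append({"morph": cls, "metric": "fa_density",
                                "value": fluoquant.fa_density(fa["marker"], cell)})
            fib = synth.gen_marker_field(cell, cfg.fiber_fraction[cls], cfg.marker_background,
                                         cfg.marker_noise_sd, rng_seed=s + 1, mode="filament")
            metric_rows.append({"morph": cls, "metric": "stress_fiber_density",
                                "value": fluoquant.stress_fiber_density(fib["actin"], cell)})
            metric_rows.append({"morph": cls, "metric": "area_um2",
                                "value": float(cell.mask.sum()) * cfg.pixel_size**2})
    # population-level colocalization (substrate property, class-agnostic)
    for j in range(3 * cfg.n_marker_cells_per_class):
        cls = classes[int(rng4.choice(len(classes), p=probs))]
        cell, _ = synth.gen_cell_mask(cfg.shape_params[cls], rng_seed=int(rng4.integers(2**31)))
        co = synth.gen_marker_field(cell, cfg.sma_fraction, cfg.marker_background,
                                    cfg.marker_noise_sd, rng_seed=int(rng4.integers(2**31)),
                                    mode="coloc")
        metric_rows.append({"morph": cls, "metric": "sma_actin_ratio",
                            "value": fluoquant.sma_actin_ratio(co["marker"], co["actin"], cell)})

    # --- stage 5: AFM stiffness ---------------------------------------------
    rng5 = np.random.default_rng(seeds[3])
    for cls in classes:
        E = cfg.E_kPa[cls]
        f_max = synth.hertz_force(250.0, E, 4.0, 0.5)
        for j in range(cfg.n_curves_per_class):
            p = synth.CurveParams(E_true=E, noise_sd=cfg.force_noise_frac * f_max,
                                  seed=int(rng5.integers(2**31)))
            curve = afm.ForceCurve.from_synthetic(synth.gen_force_curve(p))
            fit = afm.analyze_curve(curve)
            metric_rows.append({"morph": cls, "metric": "E_kPa", "value": fit.E_kPa})

    metrics = pd.DataFrame(metric_rows)

    manifest = {
        "label": cfg.label,
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "config": {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
                   for k, v in asdict(cfg).items()},
        "n_cells": cfg.n_cells,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    return RunReport(
        label=cfg.label,
        features=features,
        assignments=assignments,
        composition_pct=composition,
        metrics=metrics,
        density_per_mm2=density,
        manifest=manifest,
    )


def compare_conditions(report_a: RunReport, report_b: RunReport, alpha: float = 0.05) -> pd.DataFrame:
    """Routed statistical comparisons of every shared metric.

    Shape descriptors (DOC, cusp count, area) are compared population-wide;
    per-class metrics (FA density, fiber density, stiffness) are compared
    class-by-class. Metrics present in only one report raise.
    """
    from .stats import route_and_compare

    set_a = set(report_a.metrics["metric"])
    set_b = set(report_b.metrics["metric"])
    if set_a != set_b:
        raise ValueError(f"metric mismatch between reports: {set_a ^ set_b}")

    rows = []
    for col in ("doc", "n_cusps", "area_um2", "elongation"):
        res = route_and_compare(report_a.features[col], report_b.features[col], alpha=alpha)
        rows.append({"metric": col, "morph": "all", "test": res.test_name,
                     "p_value": res.p_value, "stars": res.stars})
    for metric in sorted(set_a):
        for cls in synth.CLASS_NAMES:
            a = report_a.metrics.query("metric == @metric and morph == @cls")["value"]
            b = report_b.metrics.query("metric == @metric and morph == @cls")["value"]
            if len(a) < 3 or len(b) < 3:
                continue
            res = route_and_compare(a, b, alpha=alpha)
            rows.append({"metric": metric, "morph": cls, "test": res.test_name,
                         "p_value": res.p_value, "stars": res.stars})
    return pd.DataFrame(rows)
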