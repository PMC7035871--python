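"""End-to-end orchestration: classify → buffers → grassiness → isotopes →
permutation regression, driven by a single declarative YAML config.

Stages are skippable when their inputs are supplied pre-computed: a
classified raster can replace the classification stage, and a samples table
that already carries a ``pct_c4`` column bypasses the mixing model (the route
used for deposited per-sample %C4 data). Every run writes a JSON metadata
sidecar with seeds, library versions, a config hash and per-stage timings so
outputs are attributable and, timestamps aside, byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .buffers import DEFAULT_RADII, extract_all, profiles_to_frame
from .grassiness import grassiness_table
from .isotopes import MixingModelParams, pct_c4_table
from .landcover import (
    accuracy_summary,
    build_composite,
    classify_raster,
    confusion_matrix,
    read_band_stack,
    train_classifier,
)
from .permstats import format_report, table3_report
from .raster import LandCoverRaster, read_ascii_grid, write_ascii_grid
from .scheme import DEFAULT_SCHEME
from .synthetic_data import DietModelSpec, LandscapeSpec, generate_landscape, generate_samples

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "merge_analysis_table"]

log = logging.getLogger("grazescape")


class ConfigError(ValueError):
    """Configuration problem, carrying the offending field name."""

    def __init__(self, fld: str, message: str):
        self.field = fld
        super().__init__(f"config field '{fld}': {message}")


@dataclass
class RunConfig:
    output_dir: Path = Path("grazescape_out")
    seed: int = 0
    radii: Tuple[float, ...] = DEFAULT_RADII
    # land-cover source: a classified raster, a simulation spec, or imagery
    landcover_raster: Optional[Path] = None
    simulate_landscape: Optional[LandscapeSpec] = None
    senescent: Optional[Path] = None
    flushed: Optional[Path] = None
    train_points: Optional[Path] = None
    validation_points: Optional[Path] = None
    classifier_trees: int = 500
    # samples source: a CSV or a simulated diet model
    samples: Optional[Path] = None
    simulate_diet: Optional[DietModelSpec] = None
    reference_radius: float = 4000.0
    mixing: MixingModelParams = field(default_factory=MixingModelParams)
    min_valid_fraction: float = 0.5
    renormalise_gradient: bool = False
    iterations: int = 1000
    alpha: float = 0.05
    resampling_scheme: str = "resample"
    cl_mode: str = "sem"
    qc_plot: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Dict) -> "RunConfig":
        kw = dict(raw)
        for key in ("landcover_raster", "senescent", "flushed", "train_points",
                    "validation_points", "samples"):
            if kw.get(key) is not None:
                kw[key] = Path(kw[key])
        kw["output_dir"] = Path(kw.get("output_dir", "grazescape_out"))
        if "radii" in kw:
            kw["radii"] = tuple(float(r) for r in kw["radii"])
        sim = kw.pop("simulate", None) or {}
        if "landscape" in sim:
            kw["simulate_landscape"] = LandscapeSpec(**sim["landscape"])
        if "diet" in sim:
            d = dict(sim["diet"])
            if "specimens_range" in d:
                d["specimens_range"] = tuple(d["specimens_range"])
            if "months" in d:
                d["months"] = tuple(d["months"])
            kw["simulate_diet"] = DietModelSpec(**d)
        if "mixing" in kw and not isinstance(kw["mixing"], MixingModelParams):
            kw["mixing"] = MixingModelParams(**kw["mixing"])
        perm = kw.pop("permutation", None) or {}
        for src, dst in (("iterations", "iterations"), ("seed", "seed"),
                         ("alpha", "alpha"), ("scheme", "resampling_scheme"),
                         ("cl_mode", "cl_mode")):
            if src in perm:
                kw[dst] = perm[src]
        unknown = set(kw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration key")
        return cls(**kw)

    def validate(self) -> None:
        if not self.radii:
            raise ConfigError("radii", "at least one buffer radius is required")
        if any(r <= 0 for r in self.radii):
            raise ConfigError("radii", "radii must be positive")
        if len(set(self.radii)) != len(self.radii):
            raise ConfigError("radii", "radii must be unique")
        if self.iterations < 1:
            raise ConfigError("permutation.iterations", "must be >= 1")
        for name in ("landcover_raster", "senescent", "flushed", "train_points",
                     "validation_points", "samples"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(name, f"path does not exist: {p}")
        has_imagery = self.senescent and self.flushed and self.train_points
        if not (self.landcover_raster or self.simulate_landscape or has_imagery):
            raise ConfigError(
                "landcover_raster",
                "need a classified raster, a simulate.landscape block, or "
                "senescent+flushed imagery with training points",
            )
        if not (self.samples or self.simulate_diet):
            raise ConfigError("samples", "need a samples CSV or a simulate.diet block")

    def config_hash(self) -> str:
        def enc(o):
            if isinstance(o, Path):
                return str(o)
            if isinstance(o, tuple):
                return list(o)
            return str(o)

        blob = json.dumps(asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _read_points(path: Path) -> pd.DataFrame:
    """Labelled points from CSV or (plain) GeoJSON."""
    if path.suffix.lower() in (".geojson", ".json"):
        gj = json.loads(path.read_text())
        rows = []
        for feat in gj.get("features", []):
            x, y = feat["geometry"]["coordinates"][:2]
            rows.append({"x": x, "y": y, **feat.get("properties", {})})
        return pd.DataFrame(rows)
    return pd.read_csv(path)


def merge_analysis_table(
    samples: pd.DataFrame,
    diet: pd.DataFrame,
    grassiness: pd.DataFrame,
    radii: Sequence[float],
) -> pd.DataFrame:
    """Join samples, %C4 estimates and per-radius grassiness into the
    locality × interval analysis table consumed by the permutation stage."""
    if "locality_id" not in samples.columns:
        raise ConfigError("samples", "samples table lacks 'locality_id'")
    base = samples.copy()
    if "interval" not in base.columns:
        if "date" not in base.columns:
            raise ConfigError("samples", "samples need an 'interval' or 'date' column")
        base["interval"] = base["date"].astype(str).str[:7]
    keep = [c for c in ("sample_id", "locality_id", "interval", "season") if c in base.columns]
    merged = base[keep].merge(diet[["sample_id", "pct_c4"]], on="sample_id")
    wide = grassiness.pivot(index="sample_id", columns="radius_m", values="grassiness")
    wide.columns = [f"grassiness_{int(c)}" for c in wide.columns]
    merged = merged.merge(wide.reset_index(), on="sample_id")
    cols = [f"grassiness_{int(r)}" for r in radii]
    merged = merged.dropna(subset=[c for c in cols if c in merged.columns])
    return merged


def _qc_plot(merged: pd.DataFrame, radius: float, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    col = f"grassiness_{int(radius)}"
    fig, ax = plt.subplots(figsize=(6, 5))
    for season, marker, colour in (("dry", "o", "black"), ("wet", "^", "grey")):
        sub = merged[merged["season"] == season] if "season" in merged.columns else merged
        ax.scatter(sub[col], sub["pct_c4"], s=12, marker=marker,
                   c=colour, label=season, alpha=0.6)
    ax.set_xlabel(f"Grassiness index ({int(radius) // 1000} km buffer)")
    ax.set_ylabel("%C4 in diet")
    ax.legend(title="season")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run every configured stage; returns {artefact name: path} plus metadata.

    Stage failures raise with the stage name; partial outputs already written
    are recorded in the metadata sidecar as incomplete.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    artefacts: Dict[str, object] = {}
    timings: Dict[str, float] = {}
    skipped: List[str] = []
    scheme = DEFAULT_SCHEME

    def stage(name):
        class _T:
            def __enter__(self):
                log.info("stage %s: start", name)
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None:
                    log.error("stage %s failed: %s", name, exc)
                    _write_metadata(incomplete=name)
                    raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
                log.info("stage %s: done in %.2fs", name, timings[name])

        return _T()

    def _write_metadata(incomplete: Optional[str] = None):
        meta = {
            "grazescape_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "iterations": config.iterations,
            "resampling_scheme": config.resampling_scheme,
            "cl_mode": config.cl_mode,
            "buffer_membership": "pixel-centre within Euclidean radius",
            "skipped_stages": skipped,
            "stage_timings_s": timings,
        }
        if incomplete:
            meta["incomplete"] = incomplete
        (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    # --- land cover -------------------------------------------------------
    with stage("landcover"):
        if config.landcover_raster:
            raster = read_ascii_grid(config.landcover_raster)
            skipped.append("classify")
        elif config.simulate_landscape:
            raster = generate_landscape(config.simulate_landscape, scheme)
            skipped.append("classify")
        else:
            sen = read_band_stack(config.senescent)
            flu = read_band_stack(config.flushed)
            composite = build_composite(sen, flu)
            train = _read_points(config.train_points)
            clf = train_classifier(
                composite, train, n_estimators=config.classifier_trees,
                seed=config.seed,
            )
            raster = classify_raster(composite, clf)
        lc_path = out / "landcover.asc"
        write_ascii_grid(raster, lc_path)
        artefacts["landcover"] = lc_path

    # --- optional accuracy assessment -------------------------------------
    if config.validation_points:
        with stage("validate"):
            val = _read_points(config.validation_points)
            cm = confusion_matrix(raster, val)
            acc = accuracy_summary(cm).rounded()
            acc_path = out / "accuracy.csv"
            frame = acc.to_frame(scheme if all(c in scheme for c in cm.classes) else None)
            frame.attrs["overall"] = acc.overall
            frame.to_csv(acc_path, index=False)
            (out / "confusion_matrix.csv").write_text(cm.to_frame().to_csv())
            artefacts["accuracy"] = acc_path
            artefacts["overall_accuracy_pct"] = acc.overall

    # --- samples -----------------------------------------------------------
    with stage("samples"):
        if config.samples:
            samples = pd.read_csv(config.samples)
        else:
            samples = generate_samples(
                raster, scheme, config.simulate_diet,
                reference_radius=config.reference_radius, mixing=config.mixing,
            )
        s_path = out / "samples.csv"
        samples.to_csv(s_path, index=False)
        artefacts["samples"] = s_path

    # --- isotopes (skipped when %C4 is supplied) ---------------------------
    with stage("isotopes"):
        if "pct_c4" in samples.columns:
            diet = samples[["sample_id", "pct_c4"]].copy()
            diet["clamped"] = False
            skipped.append("isotopes")
            log.info("isotopes stage skipped: %%C4 supplied with the samples")
        else:
            if "d13C" not in samples.columns:
                raise ConfigError("samples", "need a 'd13C' or 'pct_c4' column")
            diet = pct_c4_table(samples, config.mixing)
        d_path = out / "diet.csv"
        diet.to_csv(d_path, index=False)
        artefacts["diet"] = d_path

    # --- buffers & grassiness ----------------------------------------------
    with stage("buffers"):
        profiles = extract_all(raster, samples, config.radii)
        p_path = out / "profiles.csv"
        profiles_to_frame(profiles).to_csv(p_path, index=False)
        artefacts["profiles"] = p_path
    with stage("grassiness"):
        gtab = grassiness_table(
            profiles, scheme,
            renormalise_gradient=config.renormalise_gradient,
            min_valid_fraction=config.min_valid_fraction,
        )
        g_path = out / "grassiness.csv"
        gtab.to_csv(g_path, index=False)
        artefacts["grassiness"] = g_path

    # --- permutation regression --------------------------------------------
    with stage("permstats"):
        merged = merge_analysis_table(samples, diet, gtab, config.radii)
        m_path = out / "merged.csv"
        merged.to_csv(m_path, index=False)
        summaries, comparisons = table3_report(
            merged, radii=config.radii, iterations=config.iterations,
            seed=config.seed, scheme=config.resampling_scheme,
            cl_mode=config.cl_mode, alpha=config.alpha,
        )
        summaries.to_csv(out / "permutation_summaries.csv", index=False)
        comparisons.to_csv(out / "season_comparisons.csv", index=False)
        format_report(summaries, comparisons).to_csv(out / "report.csv", index=False)
        artefacts["summaries"] = out / "permutation_summaries.csv"
        artefacts["comparisons"] = out / "season_comparisons.csv"
        artefacts["report"] = out / "report.csv"

    if config.qc_plot:
        with stage("qc_plot"):
            radius = config.radii[min(1, len(config.radii) - 1)]
            plot_path = out / "qc_pct_c4_vs_grassiness.png"
            _qc_plot(merged, radius, plot_path)
            artefacts["qc_plot"] = plot_path

    _write_metadata()
    log.removeHandler(handler)
    handler.close()
    artefacts["metadata"] = out / "metadata.json"
    return artefacts
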