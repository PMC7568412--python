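"""End-to-end orchestration: generate -> render -> measure -> correct -> summarise.

The pipeline has two routes to a measured cohort:

* the *file* route (``simulate`` then ``analyze``) writes one phantom image
  plus JSON sidecar per rat and scan, a manifest linking them, and all
  downstream CSV/JSON reports — this is what the command line drives;
* the *in-memory* route (``render_and_measure_cohort``) renders and
  measures without touching disk, for simulations where only the final
  statistics matter.

All randomness descends from the single seed in the cohort configuration;
rendering uses its own substream per (group, rat, timepoint) so cohorts,
bookkeeping noise and speckle are mutually independent and individually
reproducible.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort as coh
from . import correction, stats
from .laws import ThicknessLaw
from .measure import MeasurementError, measure_phantom
from .phantom import (
    DEFAULT_SHAPE,
    DEFAULT_SPACING_MM,
    BModePhantom,
    SpeckleModel,
    geometry_for_volume,
    load_phantom,
    render,
    save_phantom,
)

__all__ = [
    "RunConfig",
    "render_scan",
    "render_and_measure_cohort",
    "simulate",
    "analyze",
    "run_all",
    "analyze_filling_series",
]

_STREAM_RENDER = coh._STREAM_RENDER


@dataclass
class RunConfig:
    """Single configuration object for a full pipeline run."""

    cohort: coh.CohortConfig = field(default_factory=coh.CohortConfig)
    spacing_mm: float = DEFAULT_SPACING_MM
    grid: tuple[int, int] = DEFAULT_SHAPE
    speckle: bool = True
    speckle_grain_px: float = 1.0
    mode: str = "auto"
    segment_length_mm: float = 4.0
    plateau_tolerance: float = correction.DEFAULT_PLATEAU_TOLERANCE
    volume_range_ml: tuple[float, float] = (0.2, 3.0)
    design: stats.EffectDesign = field(default_factory=stats.EffectDesign)

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "oracle"):
            raise ValueError("measurement mode must be 'auto' or 'oracle'")
        if self.spacing_mm <= 0 or min(self.grid) < 256:
            raise ValueError("invalid renderer settings")

    @property
    def seed(self) -> int:
        return self.cohort.seed

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["law"] = asdict(self.cohort.law)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        c = dict(d.pop("cohort", {}))
        if "law" in c:
            c["law"] = ThicknessLaw(**c["law"])
        if "groups" in c:
            c["groups"] = tuple(
                coh.GroupSpec(
                    label=g["label"],
                    n=g["n"],
                    dose_gy=tuple(g["dose_gy"]) if g.get("dose_gy") else None,
                    effect_by_day={int(k): tuple(v) for k, v in g["effect_by_day"].items()},
                )
                for g in c["groups"]
            )
        for key in ("days", "filling_range_ml", "impaired_filling_range_ml"):
            if key in c:
                c[key] = tuple(c[key])
        design = d.pop("design", None)
        grid = d.pop("grid", None)
        vr = d.pop("volume_range_ml", None)
        kwargs = dict(d)
        kwargs["cohort"] = coh.CohortConfig(**c)
        if design is not None:
            kwargs["design"] = stats.EffectDesign(**design)
        if grid is not None:
            kwargs["grid"] = tuple(grid)
        if vr is not None:
            kwargs["volume_range_ml"] = tuple(vr)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def render_scan(
    rat: coh.RatRecord,
    tp_index: int,
    config: RunConfig,
) -> BModePhantom:
    """Render one rat/timepoint scan with its deterministic speckle stream.

    The grid grows (in 128-px steps) beyond the configured default when an
    unusually thick wall would otherwise touch the field-of-view margin.
    """
    tp = rat.timepoints[tp_index]
    radius_mm = 10.0 * (3.0 * tp.volume_ml / (4.0 * np.pi)) ** (1.0 / 3.0)
    reach_mm = radius_mm + max(tp.t_ventral_mm, tp.t_dorsal_mm) + 0.3
    n_needed = int(np.ceil(2.0 * reach_mm / config.spacing_mm))
    shape = config.grid
    if n_needed > min(shape):
        n = int(np.ceil(n_needed / 128.0)) * 128
        shape = (max(shape[0], n), max(shape[1], n))
    truth = geometry_for_volume(
        tp.volume_ml, tp.t_ventral_mm, tp.t_dorsal_mm, shape, config.spacing_mm
    )
    seed = np.random.SeedSequence(
        config.seed, spawn_key=(_STREAM_RENDER, rat.group_index, rat.rat_index, tp_index)
    )
    return render(
        truth,
        spacing_mm=config.spacing_mm,
        shape=shape,
        speckle=SpeckleModel(enabled=config.speckle, grain_px=config.speckle_grain_px),
        seed=seed,
    )


def _measure_rows(
    phantom: BModePhantom, rat_id: str, group: str, day: int, config: RunConfig,
    sides: Sequence[str] = ("ventral", "dorsal"),
) -> list[dict]:
    rows = []
    for side in sides:
        try:
            m = measure_phantom(
                phantom, side=side, mode=config.mode,
                segment_length_mm=config.segment_length_mm,
            )
            rows.append(
                {
                    "rat_id": rat_id,
                    "group": group,
                    "day": day,
                    "side": side,
                    "BWA_mm2": m.bwa_mm2,
                    "BWT_mean_mm": m.bwt_mean_mm,
                    "lumen_area_mm2": m.lumen_area_mm2,
                    "diam_mm": m.diameter_mm,
                    "volume_mL": m.volume_ml,
                    "flags": ";".join(m.flags),
                }
            )
        except MeasurementError as exc:
            rows.append(
                {
                    "rat_id": rat_id,
                    "group": group,
                    "day": day,
                    "side": side,
                    "BWA_mm2": np.nan,
                    "BWT_mean_mm": np.nan,
                    "lumen_area_mm2": np.nan,
                    "diam_mm": np.nan,
                    "volume_mL": np.nan,
                    "flags": f"failed:{exc}",
                }
            )
    return rows


def render_and_measure_cohort(
    records: Sequence[coh.RatRecord],
    config: RunConfig,
    sides: Sequence[str] = ("ventral",),
    days: Sequence[int] | None = None,
) -> pd.DataFrame:
    """In-memory render+measure of every rat/scan; long measurement table.

    ``days`` optionally restricts which timepoints are rendered (baseline is
    always included — without it no ratio exists).
    """
    rows: list[dict] = []
    baseline_day = config.cohort.baseline_day
    for rat in records:
        for ti, tp in enumerate(rat.timepoints):
            if days is not None and tp.day != baseline_day and tp.day not in days:
                continue
            phantom = render_scan(rat, ti, config)
            rows.extend(_measure_rows(phantom, rat.rat_id, rat.group, tp.day, config, sides))
    return pd.DataFrame(rows)


def simulate(config: RunConfig, outdir: str) -> dict[str, str]:
    """Generate the cohort and render every scan to disk.

    Writes ``cohort.csv`` (true per-scan state), one ``<rat>_d<day>.png`` +
    JSON sidecar per scan under ``phantoms/``, and ``manifest.csv`` linking
    rats/days to image paths.  Idempotent for a fixed seed.
    """
    out = Path(outdir)
    (out / "phantoms").mkdir(parents=True, exist_ok=True)
    records = coh.generate_cohort(config.cohort)
    records = coh.simulate_measurements(records, config.cohort)
    coh.cohort_to_frame(records).to_csv(out / "cohort.csv", index=False)
    manifest_rows = []
    for rat in records:
        for ti, tp in enumerate(rat.timepoints):
            phantom = render_scan(rat, ti, config)
            base = out / "phantoms" / f"{rat.rat_id}_d{tp.day}"
            save_phantom(phantom, str(base))
            manifest_rows.append(
                {
                    "rat_id": rat.rat_id,
                    "group": rat.group,
                    "dose_Gy": rat.dose_gy,
                    "day": tp.day,
                    "volume_mL": tp.volume_ml,
                    "image": str(Path("phantoms") / f"{rat.rat_id}_d{tp.day}"),
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    config.to_yaml(str(out / "config.yaml"))
    print(f"[vesica] simulate: seed={config.seed} rats={len(records)} "
          f"scans={len(manifest_rows)} out={out}", file=sys.stderr)
    return {"cohort": str(out / "cohort.csv"), "manifest": str(out / "manifest.csv")}


def analyze(
    manifest_path: str,
    outdir: str,
    mode: str | None = None,
    config: RunConfig | None = None,
) -> dict[str, str]:
    """Measure every manifest scan and build ratio and group reports.

    Individual failed scans become flagged rows, not aborts.  Raises if any
    referenced image file is missing (itemised).
    """
    config = config or RunConfig()
    if mode is not None:
        config.mode = mode
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(manifest_path)
    root = Path(manifest_path).parent
    missing = [
        str(root / f"{p}.png") for p in manifest["image"]
        if not (root / f"{p}.png").exists() or not (root / f"{p}.json").exists()
    ]
    if missing:
        raise FileNotFoundError("missing phantom files:\n" + "\n".join(missing))
    rows: list[dict] = []
    for _, r in manifest.iterrows():
        phantom = load_phantom(str(root / r["image"]))
        rows.extend(
            _measure_rows(phantom, r["rat_id"], r["group"], int(r["day"]), config)
        )
    meas = pd.DataFrame(rows)
    meas.to_csv(out / "measurements.csv", index=False)

    ventral = meas[(meas["side"] == "ventral") & meas["BWT_mean_mm"].notna()].rename(
        columns={"BWT_mean_mm": "bwt_mm", "diam_mm": "diam_mm"}
    )
    ratios = correction.build_ratio_series(
        ventral[["rat_id", "group", "day", "bwt_mm", "diam_mm", "volume_mL"]],
        baseline_day=config.cohort.baseline_day,
    )
    ratios.to_csv(out / "ratios.csv", index=False)
    report = stats.build_table1(ratios, design=config.design)
    report.to_frame().to_csv(out / "table1.csv", index=False)
    (out / "table1.json").write_text(report.to_json())
    print(f"[vesica] analyze: scans={len(manifest)} rats_with_ratios="
          f"{ratios['rat_id'].nunique()} out={out}", file=sys.stderr)
    return {
        "measurements": str(out / "measurements.csv"),
        "ratios": str(out / "ratios.csv"),
        "table1": str(out / "table1.csv"),
        "table1_json": str(out / "table1.json"),
        "report_text": report.format_text(),
    }


def analyze_filling_series(
    series: pd.DataFrame,
    volume_range_ml: tuple[float, float] = (0.2, 3.0),
    tolerance: float = correction.DEFAULT_PLATEAU_TOLERANCE,
    side: str = "ventral",
) -> dict:
    """Power-law fit and plateau detection on a filling-series table."""
    sub = series[series["side"] == side]
    fit = correction.fit_power_law(sub["volume_mL"], sub["t_meas_mm"])
    plateau = correction.plateau_onset(fit, volume_range_ml, tolerance)
    return {
        "side": side,
        "fit": {
            "coefficient_mm": fit.coefficient,
            "exponent": fit.exponent,
            "log_rse": fit.log_rse,
            "n": fit.n,
        },
        "plateau": {
            "found": plateau.found,
            "onset_mL": plateau.onset_ml,
            "mean_mm": plateau.plateau_mean_mm,
            "max_rel_deviation": plateau.max_rel_deviation,
            "tolerance": plateau.tolerance,
        },
    }


def run_all(config: RunConfig, outdir: str) -> dict[str, str]:
    """simulate + analyze + filling-series report in one call."""
    paths = simulate(config, outdir)
    paths.update(analyze(paths["manifest"], outdir, config=config))
    series = coh.generate_filling_series(
        config.cohort.law,
        n_rats=4,
        volumes_per_rat=np.linspace(*config.volume_range_ml, 10),
        noise_cv=0.05,
        seed=config.seed,
    )
    series.to_csv(Path(outdir) / "filling_series.csv", index=False)
    filling = analyze_filling_series(series, config.volume_range_ml, config.plateau_tolerance)
    (Path(outdir) / "filling_fit.json").write_text(json.dumps(filling, indent=1))
    paths["filling_fit"] = str(Path(outdir) / "filling_fit.json")
    return paths
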