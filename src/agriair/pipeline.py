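"""Pipeline orchestration, configuration, panel I/O and run manifests.

Ties the stages — simulate → metrics → tfp → fit → counterfactual →
placebo — into reproducible end-to-end runs driven by a single YAML
config.  Every run writes a manifest (config hash, package version,
seeds, per-stage output checksums); re-runs with unchanged inputs reuse
cached stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import exposure, production, scenario, synth
from .paneliv import PanelIVModel
from .placebo import placebo_distribution

__all__ = [
    "RunConfig",
    "read_panel",
    "write_panel",
    "run_pipeline",
    "exposure_table_from_hourly",
    "STAGES",
]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "metrics", "tfp", "fit", "counterfactual", "placebo")

#: Columns a panel CSV must provide to be estimable.
REQUIRED_PANEL_COLUMNS = ("county", "year")


@dataclasses.dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    synth: dict = dataclasses.field(default_factory=dict)
    tfp_estimator: str = "tlcpf"
    fit: dict = dataclasses.field(default_factory=lambda: {"method": "2sls", "ozone": "annual"})
    scenarios: list = dataclasses.field(
        default_factory=lambda: [
            {"variable": "ozone_nonwinter", "rule": "cap_at_threshold", "value": 31.0}
        ]
    )
    placebo: dict = dataclasses.field(
        default_factory=lambda: {"n_reps": 200, "mode": "global"}
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        raw["out_dir"] = Path(raw.get("out_dir", "run_out"))
        if "stages" in raw:
            bad = set(raw["stages"]) - set(STAGES)
            if bad:
                raise ValueError(f"unknown stages: {sorted(bad)}")
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def canonical(self) -> str:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        d["stages"] = list(d["stages"])
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------
# panel I/O


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    """Write a panel as UTF-8 CSV with header row and empty-string NA."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    panel.to_csv(path, index=False, na_rep="")


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read and validate a panel CSV (round-trip inverse of
    :func:`write_panel`).

    Unknown columns warn; missing required columns or non-numeric values
    in numeric columns raise with the offending row and column named.
    """
    df = pd.read_csv(path, na_values=[""], keep_default_na=True)
    missing = [c for c in REQUIRED_PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel {path} missing required columns: {missing}")
    known_prefixes = (
        "county", "year", "group", "lon", "lat", "weight", "log_tfp", "tfp",
        "ozone", "pm25", "aot40", "sum06", "w126", "wd_bin", "tbin",
        "precip", "sunshine", "humidity", "pressure", "wind_speed", "coverage",
    )
    for col in df.columns:
        if not col.startswith(known_prefixes):
            logger.warning("unknown panel column %r", col)
        if col == "county":
            continue
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & coerced.isna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, "
                    f"row {row + 2} of {path}"
                )
            df[col] = coerced
    return df


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------
# metrics from hourly station data


def exposure_table_from_hourly(hourly: pd.DataFrame, region_col: str = "region") -> pd.DataFrame:
    """Per-region-year exposure table from hourly station observations.

    Computes daily MDA8, monthly means, winter/nonwinter seasonal means,
    and the annual cumulative indices via the peak/nonpeak hourly
    reconstruction.  Input columns: ``region`` (or ``station_id``),
    ``timestamp`` (ISO-8601, hourly), ``concentration`` (ppb).
    """
    df = hourly.copy()
    if region_col not in df.columns and "station_id" in df.columns:
        region_col = "station_id"
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["date"] = df["timestamp"].dt.normalize()
    daily = []
    for (region, date), day in df.groupby([region_col, "date"]):
        vals = day.sort_values("timestamp")["concentration"].to_numpy(float)
        if len(vals) != 24:
            continue
        daily.append({region_col: region, "date": date, "mda8": exposure.mda8(vals)})
    daily = pd.DataFrame(daily)
    daily["year"] = daily["date"].dt.year
    daily["month"] = daily["date"].dt.month
    monthly = (
        daily.groupby([region_col, "year", "month"])["mda8"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mda8", "count": "coverage"})
    )
    ratios = exposure.estimate_ratios(df, region_col=region_col)
    seasons = exposure.seasonal_means(monthly, region_col=region_col)
    rows = []
    for (region, year), cell in monthly.groupby([region_col, "year"]):
        by_month = cell.set_index("month")["mda8"].reindex(range(1, 13))
        if by_month.isna().any():
            logger.warning("incomplete year %s for region %s; indices skipped", year, region)
            continue
        rmap = ratios.set_index("month").loc[:, "ratio"] if region_col not in ratios else None
        rvec = (
            ratios[ratios[region_col] == region].set_index("month")["ratio"].reindex(range(1, 13))
        )
        idx = exposure.annual_indices_from_monthly(
            by_month.to_numpy(), rvec.fillna(rvec.mean()).to_numpy()
        )
        srow = seasons[(seasons[region_col] == region) & (seasons["year"] == year)].iloc[0]
        rows.append(
            {
                region_col: region, "year": year,
                "ozone_annual": float(by_month.mean()),
                "ozone_winter": float(srow["winter"]),
                "ozone_nonwinter": float(srow["nonwinter"]),
                **{k: float(v) for k, v in idx.items()},
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# the pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run manifest.

    Stage outputs live under ``config.out_dir``.  A stage is skipped when
    the manifest of a previous run records the same config hash and its
    output files are present with unchanged checksums; partial failures
    abort with the stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous = {}
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            logger.warning("unreadable previous manifest; recomputing all stages")
    reuse_ok = previous.get("config_hash") == config.config_hash()

    manifest = {
        "config_hash": config.config_hash(),
        "config": json.loads(config.canonical()),
        "seed": config.seed,
        "versions": _versions(),
        "stages": {},
    }

    def _cached(stage: str, outputs: list[Path]) -> bool:
        if not reuse_ok or stage not in previous.get("stages", {}):
            return False
        recorded = previous["stages"][stage]["outputs"]
        for p in outputs:
            if not p.exists() or recorded.get(p.name) != _checksum(p):
                return False
        manifest["stages"][stage] = previous["stages"][stage]
        logger.info("stage %s: cached outputs reused", stage)
        return True

    def _record(stage: str, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "outputs": {p.name: _checksum(p) for p in outputs}
        }

    stage = "configure"
    cfg = synth.SynthConfig(**{**config.synth, "seed": config.seed})
    panel_path = out / "panel.csv"
    prod_path = out / "production.csv"
    panel = None

    def _panel() -> pd.DataFrame:
        nonlocal panel
        if panel is None:
            panel = read_panel(panel_path)
        return panel

    try:
        for stage in config.stages:
            if stage == "simulate":
                outputs = [panel_path, prod_path, out / "truth.json"]
                if _cached(stage, outputs):
                    continue
                pnl, truth = synth.generate_panel(cfg)
                write_panel(pnl, panel_path)
                records = synth.generate_production_records(cfg, pnl)
                records.to_csv(prod_path, index=False)
                (out / "truth.json").write_text(
                    json.dumps(
                        {
                            "beta": truth.beta.to_dict(),
                            "alpha_sd": float(truth.alpha.std()),
                            "lambda": truth.lam.to_dict(),
                            "groups": truth.groups.tolist(),
                        },
                        indent=1,
                    )
                )
                panel = pnl
                _record(stage, outputs)

            elif stage == "metrics":
                path = out / "metrics.csv"
                if _cached(stage, [path]):
                    continue
                cols = [
                    "county", "year", "ozone_annual", "ozone_winter",
                    "ozone_nonwinter", "aot40", "sum06", "w126", "pm25",
                ]
                _panel()[cols].to_csv(path, index=False)
                _record(stage, [path])

            elif stage == "tfp":
                paths = [out / "tfp.csv", out / "tfp_report.txt"]
                if _cached(stage, paths):
                    continue
                records = pd.read_csv(prod_path)
                fit = production.ProductionModel(records).fit(config.tfp_estimator)
                tfp = fit.tfp()
                res = records[["county", "year"]].copy()
                res["tfp"] = tfp
                res["log_tfp"] = np.log(tfp)
                res.to_csv(paths[0], index=False)
                paths[1].write_text(fit.summary() + "\n")
                _record(stage, paths)

            elif stage == "fit":
                paths = [out / "coefficients.csv", out / "fit_report.txt"]
                if _cached(stage, paths):
                    continue
                fit_kw = dict(config.fit)
                method = fit_kw.pop("method", "2sls")
                res = PanelIVModel.from_panel(_panel(), **fit_kw).fit(method)
                table = pd.DataFrame(
                    {"coef": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues}
                )
                table.to_csv(paths[0])
                paths[1].write_text(res.summary(top=None) + "\n")
                _record(stage, paths)

            elif stage == "counterfactual":
                path = out / "scenarios.csv"
                if _cached(stage, [path]):
                    continue
                fit_kw = dict(config.fit)
                method = fit_kw.pop("method", "2sls")
                res = PanelIVModel.from_panel(_panel(), **fit_kw).fit(method)
                rows = []
                for sc in config.scenarios:
                    spec = scenario.ScenarioSpec(**sc)
                    daily = None
                    if spec.variable == "temperature":
                        daily = synth.weather_cube(cfg)
                    result = scenario.project(res, _panel(), spec, daily=daily)
                    lo, hi = result.conf_int
                    rows.append(
                        {
                            "variable": spec.variable, "rule": spec.rule,
                            "value": spec.value,
                            "national_pct_change": result.national_pct_change,
                            "ci_lower": lo, "ci_upper": hi,
                        }
                    )
                pd.DataFrame(rows).to_csv(path, index=False)
                _record(stage, [path])

            elif stage == "placebo":
                paths = [out / "placebo_estimates.csv", out / "placebo_summary.txt"]
                if _cached(stage, paths):
                    continue
                kw = dict(config.placebo)
                run = placebo_distribution(
                    _panel(), seed=config.seed, ozone=config.fit.get("ozone", "annual"), **kw
                )
                pd.DataFrame({"estimate": run.estimates}).to_csv(paths[0], index=False)
                paths[1].write_text(run.summary() + "\n")
                _record(stage, paths)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels

    from . import __version__

    return {
        "agriair": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "sklearn": sklearn.__version__,
    }
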